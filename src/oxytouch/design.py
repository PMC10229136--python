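"""Block design of the touch/massage stimulation protocol.

A session is 20 stimulation blocks of 30 s, each followed by 15 s of rest
(total 900 s = 15 min), sampled at 6.78 Hz.  Gentle stroking touch (CT-fiber
optimal, 5 cm/s) and medium pressure massage were delivered in separate
sessions; the rest interval after each stimulation type is modelled as its
own condition so the first-level GLM can use four task regressors (massage,
touch, rest-after-massage, rest-after-touch).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GENTLE_TOUCH",
    "MEDIUM_MASSAGE",
    "REST_AFTER_TOUCH",
    "REST_AFTER_MASSAGE",
    "CONDITIONS",
    "STIM_CONDITIONS",
    "REST_OF",
    "Event",
    "BlockDesign",
    "make_block_design",
    "concat_designs",
]

GENTLE_TOUCH = "gentle_touch"
MEDIUM_MASSAGE = "medium_massage"
REST_AFTER_TOUCH = "rest_after_touch"
REST_AFTER_MASSAGE = "rest_after_massage"

#: Regressor order of the first-level design matrix.
CONDITIONS = (MEDIUM_MASSAGE, GENTLE_TOUCH, REST_AFTER_MASSAGE, REST_AFTER_TOUCH)
STIM_CONDITIONS = (MEDIUM_MASSAGE, GENTLE_TOUCH)
REST_OF = {GENTLE_TOUCH: REST_AFTER_TOUCH, MEDIUM_MASSAGE: REST_AFTER_MASSAGE}

DEFAULT_SAMPLING_RATE = 6.78


@dataclass(frozen=True)
class Event:
    condition: str
    onset: float  # s
    duration: float  # s

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class BlockDesign:
    """Ordered, non-overlapping stimulation/rest events plus sampling rate."""

    events: tuple[Event, ...]
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        prev_end = -float("inf")
        prev_onset = -float("inf")
        for ev in self.events:
            if ev.duration <= 0:
                raise ValueError(f"event duration must be positive, got {ev.duration}")
            if ev.onset <= prev_onset:
                raise ValueError("event onsets must be strictly increasing")
            if ev.onset < prev_end - 1e-9:
                raise ValueError("events overlap")
            prev_onset, prev_end = ev.onset, ev.offset

    @property
    def total_duration(self) -> float:
        """Duration in seconds from 0 to the end of the last event."""
        return self.events[-1].offset if self.events else 0.0

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sampling_rate))

    def onsets(self, condition: str) -> list[float]:
        return [ev.onset for ev in self.events if ev.condition == condition]

    def conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for ev in self.events:
            if ev.condition not in seen:
                seen.append(ev.condition)
        return tuple(seen)


def make_block_design(
    n_blocks: int = 20,
    stim_s: float = 30.0,
    rest_s: float = 15.0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    condition: str = GENTLE_TOUCH,
    rest_condition: str | None = None,
    start_s: float = 0.0,
) -> BlockDesign:
    """Alternating stimulation/rest session design.

    Block ``k`` (0-based) starts at ``start_s + k*(stim_s+rest_s)``; the
    default 20 x (30 s + 15 s) session lasts 900 s.
    """
    if n_blocks < 0:
        raise ValueError("n_blocks must be >= 0")
    if stim_s <= 0 or rest_s <= 0:
        raise ValueError("stim_s and rest_s must be positive")
    if rest_condition is None:
        rest_condition = REST_OF.get(condition, f"rest_after_{condition}")
    events: list[Event] = []
    for k in range(n_blocks):
        onset = start_s + k * (stim_s + rest_s)
        events.append(Event(condition, onset, stim_s))
        events.append(Event(rest_condition, onset + stim_s, rest_s))
    return BlockDesign(events=tuple(events), sampling_rate=sampling_rate)


def concat_designs(first: BlockDesign, second: BlockDesign, gap_s: float = 0.0) -> BlockDesign:
    """Concatenate two designs in time (second shifted after the first)."""
    if first.sampling_rate != second.sampling_rate:
        raise ValueError("sampling rates differ")
    shift = first.total_duration + gap_s
    events = list(first.events) + [
        Event(ev.condition, ev.onset + shift, ev.duration) for ev in second.events
    ]
    return BlockDesign(events=tuple(events), sampling_rate=first.sampling_rate)
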