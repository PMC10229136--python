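"""Probe geometry: the 26-channel OFC/STS/S1 montage.

The study probe covers five bilateral regions involved in affective-touch
processing — posterior superior temporal sulcus (pSTS), primary somatosensory
cortex (S1), and lateral / mediolateral / medial orbitofrontal cortex (lOFC,
mlOFC, mOFC) — with 12 sources and 13 detectors forming 26 measurement
channels at 3 cm source–detector separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Montage", "make_montage", "ROI_ORDER", "DEFAULT_ROI_MAP"]

#: Fixed ROI ordering used wherever ROI curves are concatenated.
ROI_ORDER = ("pSTS", "S1", "lOFC", "mlOFC", "mOFC")

DEFAULT_ROI_MAP: dict[str, frozenset[int]] = {
    "pSTS": frozenset({1, 2, 3, 4, 23, 24, 25, 26}),
    "S1": frozenset({5, 6, 7, 8, 19, 20, 21, 22}),
    "lOFC": frozenset({9, 18}),
    "mlOFC": frozenset({10, 11, 16, 17}),
    "mOFC": frozenset({12, 13, 14, 15}),
}


@dataclass(frozen=True)
class Montage:
    """Channel list with source/detector assignment and ROI partition.

    Parameters
    ----------
    channels
        Tuples ``(channel_id, source_id, detector_id)``.
    roi_map
        Mapping ROI name -> set of member channel ids.  Must partition the
        channel set (no channel in two ROIs).
    source_detector_distance
        Optode separation in cm.
    """

    channels: tuple[tuple[int, int, int], ...]
    roi_map: dict[str, frozenset[int]] = field(default_factory=dict)
    source_detector_distance: float = 3.0

    def __post_init__(self) -> None:
        ids = [c[0] for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate channel ids in montage")
        seen: set[int] = set()
        for roi, members in self.roi_map.items():
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"channels {sorted(overlap)} assigned to more than one ROI (last: {roi})")
            seen |= set(members)
        if self.roi_map and seen != set(ids):
            raise ValueError("roi_map does not cover every channel")

    @property
    def channel_ids(self) -> tuple[int, ...]:
        return tuple(c[0] for c in self.channels)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_sources(self) -> int:
        return len({c[1] for c in self.channels})

    @property
    def n_detectors(self) -> int:
        return len({c[2] for c in self.channels})

    def roi_of(self, channel_id: int) -> str:
        for roi, members in self.roi_map.items():
            if channel_id in members:
                return roi
        raise KeyError(f"channel {channel_id} not in any ROI")

    def channel_indices(self, roi: str) -> list[int]:
        """Positional indices (into the channel axis) of an ROI's channels."""
        if roi not in self.roi_map:
            raise KeyError(f"unknown ROI {roi!r}; known: {sorted(self.roi_map)}")
        members = self.roi_map[roi]
        return [i for i, cid in enumerate(self.channel_ids) if cid in members]


def make_montage() -> Montage:
    """Return the default 26-channel, 12-source, 13-detector montage.

    The source/detector assignment cycles channel ``i`` through source
    ``((i-1) mod 12)+1`` and detector ``((i-1) mod 13)+1``, which yields 26
    distinct pairs touching every optode; the physical head placement is not
    modelled (see package non-goals).
    """
    channels = tuple((i, (i - 1) % 12 + 1, (i - 1) % 13 + 1) for i in range(1, 27))
    return Montage(channels=channels, roi_map=dict(DEFAULT_ROI_MAP), source_detector_distance=3.0)
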