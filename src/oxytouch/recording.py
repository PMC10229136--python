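"""In-memory container for multichannel fNIRS time series."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .montage import Montage

__all__ = ["FnirsRecording", "SIGNAL_KINDS"]

SIGNAL_KINDS = ("intensity", "od", "concentration")


@dataclass
class FnirsRecording:
    """Channel x sample series with a unit tag.

    ``signal_kind`` tracks the processing state: raw optical ``intensity``
    (arbitrary units, one wavelength per recording), optical density ``od``
    (dimensionless, natural-log convention, one wavelength per recording), or
    chromophore ``concentration`` change in µM (``chromophore`` = HbO or HbR).
    """

    data: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    signal_kind: str = "concentration"
    chromophore: Optional[str] = "HbO"
    wavelength: Optional[float] = None  # nm, for intensity / od recordings
    montage: Optional[Montage] = None
    channel_ids: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {SIGNAL_KINDS}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if not self.channel_ids:
            if self.montage is not None:
                self.channel_ids = self.montage.channel_ids
            else:
                self.channel_ids = tuple(range(1, self.data.shape[0] + 1))
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length does not match data rows")
        if self.montage is not None and self.montage.n_channels != self.data.shape[0]:
            raise ValueError("channel count does not match montage")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def with_data(self, data: np.ndarray, **changes) -> "FnirsRecording":
        """Copy of the recording with new sample data (same metadata)."""
        return replace(self, data=np.asarray(data, dtype=float), **changes)

    def concat(self, other: "FnirsRecording") -> "FnirsRecording":
        if self.sampling_rate != other.sampling_rate:
            raise ValueError("sampling rates differ")
        if self.channel_ids != other.channel_ids:
            raise ValueError("channel sets differ")
        return self.with_data(np.concatenate([self.data, other.data], axis=1))
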