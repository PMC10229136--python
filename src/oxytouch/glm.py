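"""First-level GLM on oxy-Hb: canonical HRF, design matrix, OLS fit,
stimulation-minus-rest contrasts, and channel-to-ROI aggregation.

The task model regresses each channel's preprocessed concentration series on
HRF-convolved boxcars for the four conditions (medium pressure massage,
gentle stroking touch, rest after massage, rest after touch) plus an
intercept.  Contrasts are formed as stimulation beta minus the matching rest
beta, and channel values are averaged (unweighted) within each ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONDITIONS, REST_OF, BlockDesign
from .montage import Montage
from .recording import FnirsRecording

__all__ = [
    "HrfParams",
    "canonical_hrf",
    "DesignMatrix",
    "build_design",
    "GlmResult",
    "fit_glm",
    "contrast_stim_minus_rest",
    "roi_aggregate",
]


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma HRF parameters (seconds, dimensionless ratio).

    The positive lobe peaks at ``peak_delay`` and the undershoot at
    ``undershoot_delay``; ``ratio`` is the undershoot:peak amplitude ratio.
    Defaults are the field-standard 6 s peak / 16 s undershoot / 1:6 ratio.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 0.9
    undershoot_dispersion: float = 0.9
    ratio: float = 1.0 / 6.0
    duration: float = 32.0


def canonical_hrf(sampling_rate: float, params: HrfParams | None = None) -> np.ndarray:
    """Sampled double-gamma kernel, peak-normalized to 1, truncated at 32 s.

    Each lobe is ``(t/d)**(d/b) * exp(-(t-d)/b)`` which peaks exactly at its
    delay ``d``; the kernel is zero at t=0.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    p = params or HrfParams()
    t = np.arange(0.0, p.duration, 1.0 / sampling_rate)

    def lobe(delay: float, disp: float) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(t > 0, (t / delay) ** (delay / disp) * np.exp(-(t - delay) / disp), 0.0)
        return out

    h = lobe(p.peak_delay, p.peak_dispersion) - p.ratio * lobe(p.undershoot_delay, p.undershoot_dispersion)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate HRF parameters")
    return h / peak


@dataclass
class DesignMatrix:
    """Sample x regressor matrix with ordered column labels.

    Task columns are HRF-convolved condition boxcars scaled so that a
    sustained block plateaus at 1 — a beta of A therefore corresponds to a
    sustained concentration change of A µM.  The last column is the
    intercept.
    """

    values: np.ndarray
    columns: tuple[str, ...]
    sampling_rate: float
    hrf_params: HrfParams = field(default_factory=HrfParams)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.columns.index(label)]


def _boxcar(design: BlockDesign, condition: str, n_samples: int) -> np.ndarray:
    t = np.arange(n_samples) / design.sampling_rate
    box = np.zeros(n_samples)
    for ev in design.events:
        if ev.condition == condition:
            box[(t >= ev.onset - 1e-9) & (t < ev.offset - 1e-9)] = 1.0
    return box


def build_design(
    block_design: BlockDesign,
    sampling_rate: float | None = None,
    hrf_params: HrfParams | None = None,
    n_samples: int | None = None,
) -> DesignMatrix:
    """Build the four-regressor-plus-intercept design matrix.

    Every canonical condition gets a column (identically zero if it has no
    events), so single-session designs yield rank-deficient matrices unless
    the empty columns are dropped by the caller or sessions are concatenated.
    """
    if not block_design.events:
        raise ValueError("empty block design")
    fs = sampling_rate or block_design.sampling_rate
    params = hrf_params or HrfParams()
    if n_samples is None:
        n_samples = int(round(block_design.total_duration * fs))
    kernel = canonical_hrf(fs, params)
    scale = kernel.sum()  # sustained-response plateau normalisation
    cols = []
    for cond in CONDITIONS:
        box = _boxcar(block_design, cond, n_samples)
        cols.append(np.convolve(box, kernel)[:n_samples] / scale)
    cols.append(np.ones(n_samples))
    return DesignMatrix(
        values=np.column_stack(cols),
        columns=CONDITIONS + ("intercept",),
        sampling_rate=fs,
        hrf_params=params,
    )


@dataclass
class GlmResult:
    betas: pd.DataFrame  # channels x regressors
    residual_variance: pd.Series  # per channel, RSS / dof
    dof: int


def fit_glm(recording: FnirsRecording, design_matrix: DesignMatrix, drop_empty: bool = False) -> GlmResult:
    """Ordinary least-squares fit per channel.

    ``drop_empty`` removes identically-zero task columns (their betas are
    reported as 0) instead of raising on rank deficiency.
    """
    X = design_matrix.values
    labels = list(design_matrix.columns)
    if X.shape[0] != recording.n_samples:
        raise ValueError(
            f"design has {X.shape[0]} rows but recording has {recording.n_samples} samples"
        )
    norms = np.linalg.norm(X, axis=0)
    empty = [lab for lab, nrm in zip(labels, norms) if nrm == 0]
    if empty and drop_empty:
        keep = [i for i, lab in enumerate(labels) if lab not in empty]
        X = X[:, keep]
        kept_labels = [labels[i] for i in keep]
    else:
        kept_labels = labels
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        offending = empty or kept_labels
        raise ValueError(f"design matrix is rank deficient (offending columns: {offending})")
    dof = X.shape[0] - len(labels)
    if dof <= 0:
        raise ValueError("not enough samples for the number of regressors")
    Y = recording.data.T  # samples x channels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.sum(resid**2, axis=0)
    full = np.zeros((len(labels), Y.shape[1]))
    for i, lab in enumerate(kept_labels):
        full[labels.index(lab)] = beta[i]
    betas = pd.DataFrame(full.T, index=list(recording.channel_ids), columns=labels)
    betas.index.name = "channel"
    rv = pd.Series(rss / dof, index=betas.index, name="residual_variance")
    return GlmResult(betas=betas, residual_variance=rv, dof=dof)


def contrast_stim_minus_rest(glm_result: GlmResult, condition: str) -> pd.Series:
    """Per-channel beta(condition) − beta(matching rest regressor)."""
    if condition not in REST_OF:
        raise ValueError(f"unknown stimulation condition {condition!r}; expected one of {sorted(REST_OF)}")
    rest = REST_OF[condition]
    out = glm_result.betas[condition] - glm_result.betas[rest]
    out.name = f"{condition}_minus_rest"
    return out


def roi_aggregate(channel_values: pd.Series, montage: Montage) -> dict[str, float]:
    """Unweighted mean of member-channel values per ROI."""
    missing = set(montage.channel_ids) - set(channel_values.index)
    if missing:
        raise ValueError(f"missing values for channels {sorted(missing)}")
    return {
        roi: float(channel_values.loc[sorted(members)].mean())
        for roi, members in montage.roi_map.items()
    }
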