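"""Multichannel-pattern classification of treatment group.

Features are the block-averaged oxy-Hb time courses of mOFC, mlOFC and pSTS
in the 5-35 s window after gentle-touch onset, concatenated in that fixed
ROI order.  A held-out subject is assigned to whichever group's mean
pattern (computed without that subject) its feature vector is more similar
to — Pearson correlation by default, cosine similarity optionally.
Significance comes from a permutation null: group labels are shuffled
(default 10,000 times) and the p-value is the proportion of null accuracies
greater than or equal to the actual accuracy.

Ties (identical similarity to both group means, or an undefined similarity
for a constant feature vector) are conservatively scored as incorrect and
tallied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .design import GENTLE_TOUCH, BlockDesign
from .montage import Montage
from .recording import FnirsRecording

__all__ = [
    "FEATURE_ROIS",
    "ClassificationResult",
    "block_average",
    "extract_features",
    "loo_classify",
    "permutation_test",
]

#: ROI concatenation order for feature vectors.
FEATURE_ROIS = ("mOFC", "mlOFC", "pSTS")

DEFAULT_WINDOW = (5.0, 35.0)


@dataclass
class ClassificationResult:
    accuracy: float
    predictions: list[Optional[str]]
    n_ties: int
    labels: tuple[str, ...] = ()
    null_distribution: Optional[np.ndarray] = None
    p_value: Optional[float] = None
    n_permutations: int = 0
    seed: Optional[int] = None


def block_average(
    recording: FnirsRecording,
    design: BlockDesign,
    condition: str,
    window: tuple[float, float] = DEFAULT_WINDOW,
    baseline_correct: bool = False,
) -> np.ndarray:
    """Mean across a condition's blocks of the windowed segments, per channel.

    Returns an array of shape (n_channels, floor(window_length * fs)).
    With ``baseline_correct`` the mean of the onset-to-window-start span is
    subtracted per block (off by default).
    """
    fs = recording.sampling_rate
    w0, w1 = window
    length = int(np.floor((w1 - w0) * fs))
    onsets = design.onsets(condition)
    if not onsets:
        raise ValueError(f"no blocks for condition {condition!r}")
    segments = []
    for onset in onsets:
        start = int(round((onset + w0) * fs))
        stop = start + length
        if start < 0 or stop > recording.n_samples:
            raise ValueError(
                f"window ({w0}, {w1}) s at onset {onset} s exceeds recording bounds"
            )
        seg = recording.data[:, start:stop]
        if baseline_correct:
            b0 = int(round(onset * fs))
            seg = seg - recording.data[:, b0:start].mean(axis=1, keepdims=True)
        segments.append(seg)
    return np.mean(segments, axis=0)


def extract_features(
    recording: FnirsRecording,
    design: BlockDesign,
    montage: Montage,
    rois: Sequence[str] = FEATURE_ROIS,
    condition: str = GENTLE_TOUCH,
    window: tuple[float, float] = DEFAULT_WINDOW,
    baseline_correct: bool = False,
) -> np.ndarray:
    """Concatenated per-ROI block-averaged curves (fixed ROI order)."""
    unknown = [r for r in rois if r not in montage.roi_map]
    if unknown:
        raise ValueError(f"unknown ROI(s) {unknown}; montage has {sorted(montage.roi_map)}")
    avg = block_average(recording, design, condition, window, baseline_correct)
    parts = [avg[montage.channel_indices(roi)].mean(axis=0) for roi in rois]
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# leave-one-out nearest-group-mean classification


def _corr_with_mean(X, S, c, delta, metric):
    """Similarity of each row x_i of X with m_i = (S_i - delta_i * x_i) / c_i.

    ``S`` has one row per subject (the relevant group sum), ``delta`` is 1
    where the subject belongs to that group (and must be removed) else 0,
    ``c`` is the member count after removal.  Supports 'pearson'/'cosine'.
    All inputs broadcast along the subject axis.
    """
    d = X.shape[1]
    xs = (X * S).sum(axis=-1)
    sxx = (X**2).sum(axis=-1)
    sx = X.sum(axis=-1)
    sS = S.sum(axis=-1)
    sSS = (S**2).sum(axis=-1)
    # moments of m
    sm = (sS - delta * sx) / c
    smm = (sSS - 2 * delta * xs + delta * sxx) / c**2
    xm = (xs - delta * sxx) / c
    if metric == "cosine":
        denom = np.sqrt(sxx * smm)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, xm / denom, np.nan)
    cov = d * xm - sx * sm
    varx = d * sxx - sx**2
    varm = d * smm - sm**2
    denom = np.sqrt(varx * varm)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, cov / denom, np.nan)


def _loo_accuracy_batch(X: np.ndarray, Y: np.ndarray, metric: str) -> np.ndarray:
    """LOO nearest-group-mean accuracy for a batch of binary labelings.

    X: (n, d) features; Y: (batch, n) 0/1 labels.  Returns (batch,)
    accuracies with ties / undefined similarities scored incorrect.
    """
    n = X.shape[0]
    n1 = Y.sum(axis=1, keepdims=True)  # (batch, 1)
    n0 = n - n1
    S1 = Y @ X  # (batch, d)
    S0 = X.sum(axis=0)[None, :] - S1
    # similarity of subject i to group-1 mean (leave out if member) and group-0 mean
    d1 = Y  # delta for group 1
    d0 = 1.0 - Y
    c1 = n1 - d1
    c0 = n0 - d0
    r1 = _corr_with_mean(X[None, :, :], S1[:, None, :], c1, d1, metric)
    r0 = _corr_with_mean(X[None, :, :], S0[:, None, :], c0, d0, metric)
    own = np.where(Y == 1, r1, r0)
    other = np.where(Y == 1, r0, r1)
    correct = own > other  # NaN or tie -> False
    return correct.mean(axis=1)


def _validate_two_groups(labels: Sequence[str]) -> tuple[np.ndarray, tuple[str, str]]:
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly 2 distinct labels required, got {uniq}")
    y = np.array([uniq.index(lab) for lab in labels], dtype=float)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per group")
    return y, (uniq[0], uniq[1])


def loo_classify(
    features: np.ndarray,
    labels: Sequence[str],
    similarity: str = "pearson",
) -> ClassificationResult:
    """Leave-one-out nearest-group-mean classification (no permutation null)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise ValueError("features must be (n_subjects, n_features)")
    if similarity not in ("pearson", "cosine"):
        raise ValueError("similarity must be 'pearson' or 'cosine'")
    y, uniq = _validate_two_groups(labels)

    n1 = y.sum()
    n0 = len(y) - n1
    S1 = (X * y[:, None]).sum(axis=0)
    S0 = X.sum(axis=0) - S1
    r1 = _corr_with_mean(X, S1[None, :], n1 - y, y, similarity)
    r0 = _corr_with_mean(X, S0[None, :], n0 - (1 - y), 1 - y, similarity)

    predictions: list[Optional[str]] = []
    n_ties = 0
    correct = 0
    for i in range(len(y)):
        if np.isnan(r0[i]) or np.isnan(r1[i]) or r0[i] == r1[i]:
            n_ties += 1
            predictions.append(None)
            continue
        pred = uniq[1] if r1[i] > r0[i] else uniq[0]
        predictions.append(pred)
        if pred == labels[i]:
            correct += 1
    return ClassificationResult(
        accuracy=correct / len(y),
        predictions=predictions,
        n_ties=n_ties,
        labels=uniq,
    )


def permutation_test(
    features: np.ndarray,
    labels: Sequence[str],
    n_permutations: int = 10000,
    seed: Optional[int] = None,
    similarity: str = "pearson",
    add_one: bool = False,
    batch_size: int = 256,
) -> ClassificationResult:
    """LOO classification with a shuffled-label null distribution.

    p = proportion of null accuracies >= the actual accuracy (literal
    proportion; ``add_one`` switches to the (b+1)/(m+1) estimator).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    result = loo_classify(features, labels, similarity)
    X = np.asarray(features, dtype=float)
    y, _ = _validate_two_groups(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        b = min(batch_size, n_permutations - done)
        Y = np.empty((b, len(y)))
        for j in range(b):
            Y[j] = rng.permutation(y)
        null[done : done + b] = _loo_accuracy_batch(X, Y, similarity)
        done += b
    b_ge = int((null >= result.accuracy).sum())
    p = (b_ge + 1) / (n_permutations + 1) if add_one else b_ge / n_permutations
    result.null_distribution = null
    result.p_value = float(p)
    result.n_permutations = n_permutations
    result.seed = seed
    return result
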