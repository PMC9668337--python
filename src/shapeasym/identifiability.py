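"""Subject identifiability from test-retest feature vectors.

Given per-subject feature vectors at two sessions (eigenvalue spectra, SAS
vectors, or any other descriptor), the t1-t2 Pearson correlations between
all subject pairs form an N x N matrix whose diagonal holds within-subject
and whose off-diagonal holds between-subject similarities.  The
identifiability score is Glass's delta,

    score = (mean(r_ii) - mean(r_ij)) / SD(r_ij),

i.e. the standardized difference of within- and between-subject
correlations normalized by the between-subject (control group) standard
deviation.  Sweeping the truncation (the number of leading features used)
traces how identifiability varies with spatial scale; permutation of the
t2 subject order gives a null distribution for the peak score.

The first feature (the near-zero eigenvalue / near-zero SAS entry of a
closed surface) carries no variance and is excluded from correlations by
default; ``include_first=True`` restores the literal first-k convention,
in which k = 2 yields degenerate two-point correlations of +/-1 (such
truncations are flagged in the result).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from shapeasym.eigengroups import group_of_index

__all__ = [
    "IdentifiabilityResult",
    "SweepCurve",
    "correlation_matrix",
    "glass_delta",
    "identifiability_score",
    "sweep",
    "permutation_null",
    "cross_feature_identifiability",
    "rank1_accuracy",
]


@dataclass
class IdentifiabilityResult:
    corr: np.ndarray
    score: float
    k_used: int
    mean_within: float
    mean_between: float
    sd_between: float


@dataclass
class SweepCurve:
    """Identifiability as a function of the truncation k."""

    ks: np.ndarray
    scores: np.ndarray
    peak_k: int
    peak_score: float
    degenerate: np.ndarray = field(default=None)

    def group_mean_scores(self, lmax: int) -> np.ndarray:
        """Mean score over truncations falling inside each group 1..lmax."""
        groups = np.array([group_of_index(int(k)) for k in self.ks])
        out = np.full(lmax, np.nan)
        for L in range(1, lmax + 1):
            sel = (groups == L) & np.isfinite(self.scores)
            if sel.any():
                out[L - 1] = self.scores[sel].mean()
        return out


def _as_features(F) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.ndim != 2:
        raise ValueError("features must be a (subjects x k) array")
    return F


def correlation_matrix(F1, F2) -> np.ndarray:
    """Entry (i, j): Pearson correlation of subject i at t1 with subject j at t2.

    Rows of F1 and F2 must follow the same subject ordering.  Zero-variance
    feature vectors are rejected (Pearson is undefined for them).
    """
    F1, F2 = _as_features(F1), _as_features(F2)
    if F1.shape != F2.shape:
        raise ValueError(f"feature shapes differ: {F1.shape} vs {F2.shape}")
    for name, F in (("t1", F1), ("t2", F2)):
        sd = F.std(axis=1)
        if np.any(sd == 0):
            bad = int(np.argmax(sd == 0))
            raise ValueError(f"zero-variance {name} feature vector for subject {bad}")
    A = F1 - F1.mean(axis=1, keepdims=True)
    B = F2 - F2.mean(axis=1, keepdims=True)
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    B /= np.linalg.norm(B, axis=1, keepdims=True)
    return np.clip(A @ B.T, -1.0, 1.0)


def glass_delta(matrix: np.ndarray) -> float:
    """Glass's delta of a subject-correlation matrix.

    SD of the between-subject (off-diagonal) population uses ddof=1 over
    all N^2 - N entries of the (generally non-symmetric) matrix.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or n < 3:
        raise ValueError("need a square matrix with N >= 3")
    off_mask = ~np.eye(n, dtype=bool)
    within = np.diag(matrix)
    between = matrix[off_mask]
    sd = between.std(ddof=1)
    if sd == 0:
        raise ValueError("between-subject correlations have zero variance")
    return float((within.mean() - between.mean()) / sd)


def pooled_delta(matrix: np.ndarray) -> float:
    """Cohen's-d style variant using the pooled within/between SD."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    off_mask = ~np.eye(n, dtype=bool)
    within = np.diag(matrix)
    between = matrix[off_mask]
    sp = np.sqrt(((within.size - 1) * within.var(ddof=1)
                  + (between.size - 1) * between.var(ddof=1))
                 / (within.size + between.size - 2))
    return float((within.mean() - between.mean()) / sp)


def identifiability_score(F1, F2, k: int | None = None,
                          include_first: bool = False) -> IdentifiabilityResult:
    """Glass's-delta identifiability for one truncation."""
    F1, F2 = _as_features(F1), _as_features(F2)
    if k is None:
        k = F1.shape[1]
    lo = 0 if include_first else 1
    corr = correlation_matrix(F1[:, lo:k], F2[:, lo:k])
    n = corr.shape[0]
    off = corr[~np.eye(n, dtype=bool)]
    return IdentifiabilityResult(
        corr=corr,
        score=glass_delta(corr),
        k_used=k,
        mean_within=float(np.diag(corr).mean()),
        mean_between=float(off.mean()),
        sd_between=float(off.std(ddof=1)),
    )


def _running_correlations(F1: np.ndarray, F2: np.ndarray) -> np.ndarray:
    """Correlation matrices over leading-feature prefixes.

    Returns C of shape (K, N, N) where C[m] is the correlation matrix over
    features 0..m; entries are NaN where fewer than 2 features contribute.
    """
    N, K = F1.shape
    S1 = np.cumsum(F1, axis=1)
    S2 = np.cumsum(F2, axis=1)
    Q1 = np.cumsum(F1 ** 2, axis=1)
    Q2 = np.cumsum(F2 ** 2, axis=1)
    X = np.einsum("ik,jk->ijk", F1, F2)
    SX = np.cumsum(X, axis=2)
    m = np.arange(1, K + 1, dtype=float)
    cov = SX - S1[:, None, :] * S2[None, :, :] / m
    v1 = Q1 - S1 ** 2 / m
    v2 = Q2 - S2 ** 2 / m
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.sqrt(v1[:, None, :] * v2[None, :, :])
    corr = np.moveaxis(corr, 2, 0)  # (K, N, N)
    corr[0] = np.nan
    return np.clip(corr, -1.0, 1.0)


def _delta_from_stack(corr: np.ndarray) -> np.ndarray:
    """Glass's delta for each correlation matrix in a (K, N, N) stack."""
    K, n, _ = corr.shape
    eye = np.eye(n, dtype=bool)
    within = corr[:, eye]
    between = corr[:, ~eye]
    sd = between.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (within.mean(axis=1) - between.mean(axis=1)) / sd


def sweep(F1, F2, k_min: int = 2, k_max: int | None = None,
          include_first: bool = False) -> SweepCurve:
    """Identifiability score at every truncation k = k_min..k_max.

    Truncation k means "the first k features"; with the default exclusion
    of the constant first feature, the correlation at truncation k uses
    features 2..k.  Ties in the peak are broken toward the smallest k
    (the coarsest spatial scale).
    """
    F1, F2 = _as_features(F1), _as_features(F2)
    K = F1.shape[1]
    if k_max is None:
        k_max = K
    if k_max > K:
        raise ValueError(f"k_max={k_max} exceeds available features {K}")
    if not (1 <= k_min <= k_max):
        raise ValueError("need 1 <= k_min <= k_max")
    lo = 0 if include_first else 1
    corr = _running_correlations(F1[:, lo:k_max], F2[:, lo:k_max])
    deltas = _delta_from_stack(corr)  # index m-1: prefix of m features
    ks = np.arange(k_min, k_max + 1)
    nfeat = ks - lo  # features used at truncation k
    scores = np.full(ks.size, np.nan)
    valid = nfeat >= 2
    scores[valid] = deltas[nfeat[valid] - 1]
    degenerate = nfeat <= 2
    if np.all(np.isnan(scores)):
        raise ValueError("no truncation yields a defined score")
    peak_idx = int(np.nanargmax(scores))
    return SweepCurve(ks=ks, scores=scores, peak_k=int(ks[peak_idx]),
                      peak_score=float(scores[peak_idx]), degenerate=degenerate)


def permutation_null(F1, F2, k_min: int = 2, k_max: int | None = None,
                     n_perm: int = 1000, seed: int = 0,
                     include_first: bool = False):
    """Permutation test of the observed peak identifiability.

    Each iteration shuffles the subject order of the t2 features, recomputes
    the full sweep, and records the permuted peak score.  Returns
    ``(p_corrected, raw_count, null_peaks, observed_curve)`` where
    ``p_corrected = (#{null >= observed} + 1) / (n_perm + 1)`` and
    ``raw_count / n_perm`` is the uncorrected proportion (which can be 0).

    Shuffling the t2 order only permutes the columns of each correlation
    matrix, so the prefix correlation stack is computed once.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    F1, F2 = _as_features(F1), _as_features(F2)
    K = F1.shape[1]
    if k_max is None:
        k_max = K
    lo = 0 if include_first else 1
    corr = _running_correlations(F1[:, lo:k_max], F2[:, lo:k_max])
    ks = np.arange(k_min, k_max + 1)
    nfeat = ks - lo

    def peak_from(corr_stack: np.ndarray) -> float:
        deltas = _delta_from_stack(corr_stack)
        valid = nfeat >= 2
        sel = deltas[nfeat[valid] - 1]
        return float(np.nanmax(sel))

    observed_curve = sweep(F1, F2, k_min=k_min, k_max=k_max,
                           include_first=include_first)
    observed = observed_curve.peak_score
    rng = np.random.default_rng(seed)
    n = F1.shape[0]
    null_peaks = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        null_peaks[b] = peak_from(corr[:, :, perm])
    raw_count = int((null_peaks >= observed).sum())
    p = (raw_count + 1) / (n_perm + 1)
    return p, raw_count, null_peaks, observed_curve


def cross_feature_identifiability(FA, FB, include_first: bool = False) -> IdentifiabilityResult:
    """Identifiability across heterogeneous feature pairs.

    E.g. identifying a subject's left hemisphere from right-hemisphere
    descriptors: FA and FB are matched by subject but may be different
    descriptor types (they must share the feature count).
    """
    return identifiability_score(FA, FB, include_first=include_first)


def rank1_accuracy(matrix: np.ndarray) -> float:
    """Supplementary binary metric: fraction of subjects whose within-subject
    correlation is the row maximum."""
    matrix = np.asarray(matrix, dtype=float)
    return float((matrix.argmax(axis=1) == np.arange(matrix.shape[0])).mean())
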