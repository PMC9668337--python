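"""Association statistics for SAS features.

* Permutation GLM: the coefficient of a predictor (e.g. sex or a
  continuous handedness score) on a per-subject feature, with covariates,
  tested against a block-respecting permutation distribution.  Family
  blocks are exchanged whole among blocks of identical size, preserving
  relatedness structure; blocks of size 1 reduce to unrestricted
  permutation.
* Benjamini-Hochberg FDR across features.
* PCA reduction of a multi-measure block to the fewest components
  explaining a target share of variance (default 80%).
* A CCA pipeline relating per-eigen-group SAS means to the reduced
  cognitive components, with max-statistic permutation FWER inference per
  canonical mode and block-bootstrap standard errors for the loadings.

Canonical correlations are computed classically (QR of each centred block,
then the SVD of the cross-product of the orthonormal factors), which makes
them exactly invariant to invertible affine transforms of either block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExchangeabilityBlocks",
    "CCAResult",
    "glm_permutation",
    "cohens_d",
    "fdr_bh",
    "pca_reduce",
    "canonical_correlations",
    "cca_pipeline",
]


@dataclass
class ExchangeabilityBlocks:
    """Family (block) labels defining admissible subject permutations."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)

    @property
    def n(self) -> int:
        return self.labels.size

    def block_indices(self) -> list[np.ndarray]:
        order = {}
        for i, lab in enumerate(self.labels):
            order.setdefault(lab, []).append(i)
        return [np.array(v) for v in order.values()]

    @classmethod
    def singletons(cls, n: int) -> "ExchangeabilityBlocks":
        return cls(np.arange(n))

    def permutation(self, rng: np.random.Generator) -> np.ndarray:
        """Whole-block exchange among blocks of identical size.

        Within-block order is preserved, so families are never split.
        """
        blocks = self.block_indices()
        by_size: dict[int, list[np.ndarray]] = {}
        for b in blocks:
            by_size.setdefault(len(b), []).append(b)
        perm = np.empty(self.n, dtype=int)
        for size, group in by_size.items():
            shuffled = [group[i] for i in rng.permutation(len(group))]
            for dest, src in zip(group, shuffled):
                perm[dest] = src
        return perm

    def bootstrap(self, rng: np.random.Generator) -> np.ndarray:
        """Indices of whole blocks resampled with replacement."""
        blocks = self.block_indices()
        picks = rng.integers(0, len(blocks), size=len(blocks))
        return np.concatenate([blocks[i] for i in picks])


def cohens_d(a, b) -> float:
    """Standardized mean difference with the pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    sp = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                 / (a.size + b.size - 2))
    if sp == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / sp)


def fdr_bh(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up: (reject mask, adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


def _glm_coefficient(y: np.ndarray, x: np.ndarray, Z: np.ndarray) -> float:
    """Partial regression coefficient of x on y given covariates Z."""
    xr = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    yr = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    denom = xr @ xr
    if denom == 0:
        raise ValueError("predictor is collinear with the covariates")
    return float(xr @ yr / denom)


def glm_permutation(y, x, covariates=None, blocks: ExchangeabilityBlocks | None = None,
                    n_perm: int = 1000, seed: int = 0):
    """Permutation test of a GLM coefficient.

    Freedman-Lane scheme: the reduced-model (covariates-only) residuals of
    ``y`` are shuffled by block-respecting subject permutations and the
    coefficient of the residualized predictor is recomputed each time,
    which stays calibrated even when the predictor is collinear with the
    covariates.  Returns the observed coefficient, the two-sided p-value
    with the +1 correction, and the permutation coefficients.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if covariates is None:
        Z = np.ones((n, 1))
    else:
        Z = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    if np.linalg.matrix_rank(np.column_stack([Z, x])) < Z.shape[1] + 1:
        raise ValueError("rank-deficient design")
    if blocks is None:
        blocks = ExchangeabilityBlocks.singletons(n)
    if blocks.n != n:
        raise ValueError("block labels do not match the number of subjects")

    Q, _ = np.linalg.qr(Z)
    yr = y - Q @ (Q.T @ y)
    xr = x - Q @ (Q.T @ x)
    denom = float(xr @ xr)
    beta_obs = float(xr @ yr / denom)

    rng = np.random.default_rng(seed)
    perms = np.stack([blocks.permutation(rng) for _ in range(n_perm)])
    betas = (yr[perms] @ xr) / denom
    count = int((np.abs(betas) >= abs(beta_obs)).sum())
    p = (count + 1) / (n_perm + 1)
    return beta_obs, p, betas


def pca_reduce(table, variance_target: float = 0.80):
    """Standardize columns and keep the fewest PCs reaching the target.

    Rejects missing values: callers must filter to complete cases first
    (component scores are not defined for incomplete rows).
    Returns ``(scores, loadings, explained_ratio)``.
    """
    X = np.asarray(table, dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values present; filter to complete cases first")
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    pca = PCA()
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    m = min(m, scores.shape[1])
    return scores[:, :m], pca.components_[:m], pca.explained_variance_ratio_


def canonical_correlations(X, Y):
    """Classical CCA on centred blocks.

    Returns ``(r, U, V)``: canonical correlations (non-increasing) and the
    canonical variates of each block, computed from the SVD of Qx'Qy.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("blocks must have equal subject rows")
    if n <= X.shape[1] + Y.shape[1]:
        raise ValueError("need more subjects than total features")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Qx, Rx = np.linalg.qr(Xc)
    Qy, Ry = np.linalg.qr(Yc)
    if (np.abs(np.diag(Rx)).min() < 1e-12 * max(1, np.abs(np.diag(Rx)).max())
            or np.abs(np.diag(Ry)).min() < 1e-12 * max(1, np.abs(np.diag(Ry)).max())):
        raise ValueError("degenerate (rank-deficient) covariance in a block")
    U_, s, Vt = np.linalg.svd(Qx.T @ Qy)
    r = np.clip(s, 0.0, 1.0)
    U = Qx @ U_
    V = Qy @ Vt.T
    return r, U, V


@dataclass
class CCAResult:
    correlations: np.ndarray
    p_fwer: np.ndarray
    x_loadings: np.ndarray
    x_loading_se: np.ndarray
    x_loading_z: np.ndarray
    x_loading_p_fdr: np.ndarray
    y_loadings: np.ndarray
    y_loading_se: np.ndarray
    y_loading_p_fdr: np.ndarray
    n_modes: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_modes = self.correlations.size


def _loadings(block: np.ndarray, variate: np.ndarray) -> np.ndarray:
    """Structure correlations of each input column with a canonical variate."""
    bc = block - block.mean(axis=0)
    vc = variate - variate.mean()
    denom = np.linalg.norm(bc, axis=0) * np.linalg.norm(vc)
    return (bc.T @ vc) / denom


def cca_pipeline(X, Y, blocks: ExchangeabilityBlocks | None = None,
                 n_perm: int = 1000, n_boot: int = 1000, seed: int = 0,
                 q: float = 0.05) -> CCAResult:
    """CCA with permutation FWER inference and bootstrap loadings.

    ``X`` is the subjects x eigen-group-means block, ``Y`` the reduced
    cognitive block (already passed through :func:`pca_reduce`).  Mode
    significance compares each observed canonical correlation with the
    permutation distribution of the largest canonical correlation (Roy's
    largest root as the max statistic), permuting Y rows by whole family
    blocks.  Loadings are structure correlations; their bootstrap SEs
    (whole-block resampling) give z = loading / SE and two-sided normal
    p-values, FDR-corrected within each block.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if blocks is None:
        blocks = ExchangeabilityBlocks.singletons(n)
    rng = np.random.default_rng(seed)

    r_obs, U, V = canonical_correlations(X, Y)

    # permutation null of the max canonical correlation
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Qx, _ = np.linalg.qr(Xc)
    Qy, _ = np.linalg.qr(Yc)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        perm = blocks.permutation(rng)
        # permuting rows of Y permutes rows of Qy (same column span)
        s = np.linalg.svd(Qx.T @ Qy[perm], compute_uv=False)
        null_max[b] = s[0]
    p_fwer = np.array([(np.sum(null_max >= r) + 1) / (n_perm + 1) for r in r_obs])
    # step-down monotonicity: later modes cannot be more significant
    p_fwer = np.maximum.accumulate(p_fwer)

    x_load = _loadings(X, U[:, 0])
    y_load = _loadings(Y, V[:, 0])

    boot_x = np.empty((n_boot, X.shape[1]))
    boot_y = np.empty((n_boot, Y.shape[1]))
    for b in range(n_boot):
        idx = blocks.bootstrap(rng)
        try:
            _, Ub, Vb = canonical_correlations(X[idx], Y[idx])
        except ValueError:
            boot_x[b] = np.nan
            boot_y[b] = np.nan
            continue
        xl = _loadings(X[idx], Ub[:, 0])
        yl = _loadings(Y[idx], Vb[:, 0])
        # canonical variates are sign-indeterminate: align to the observed mode
        if xl @ x_load < 0:
            xl, yl = -xl, -yl
        boot_x[b] = xl
        boot_y[b] = yl
    se_x = np.nanstd(boot_x, axis=0, ddof=1)
    se_y = np.nanstd(boot_y, axis=0, ddof=1)
    z_x = x_load / se_x
    z_y = y_load / se_y
    p_x = 2 * stats.norm.sf(np.abs(z_x))
    p_y = 2 * stats.norm.sf(np.abs(z_y))
    _, p_x_fdr = fdr_bh(p_x, q)
    _, p_y_fdr = fdr_bh(p_y, q)

    return CCAResult(
        correlations=r_obs,
        p_fwer=p_fwer,
        x_loadings=x_load,
        x_loading_se=se_x,
        x_loading_z=z_x,
        x_loading_p_fdr=p_x_fdr,
        y_loadings=y_load,
        y_loading_se=se_y,
        y_loading_p_fdr=p_y_fdr,
    )
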