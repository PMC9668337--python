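"""Twin variance-component models of shape phenotypes.

Phenotypic variance is decomposed into additive genetic (A), common
environmental (C), twin-specific environmental (T) and unique
environmental (E) components by maximum likelihood on per-family
multivariate normals with the classical expected covariances:

    var            = a2 + c2 + t2 + e2
    cov(MZ twins)  = a2 + c2 + t2
    cov(DZ twins)  = a2/2 + c2 + t2
    cov(twin,sib)  = cov(sib,sib) = a2/2 + c2

Components are constrained non-negative (bounded optimization); the
boundary makes likelihood-ratio tests of A or C conservative, which is
the standard behaviour in twin modelling.  The model family is
ACTE, ACE, ATE, CTE, TE, CE, E; the best model per phenotype is chosen by
lowest AIC (ties to the simpler model) and h^2 is the standardized A
share of the selected model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from shapeasym.group_stats import fdr_bh

log = logging.getLogger(__name__)

__all__ = [
    "MODEL_LABELS",
    "TwinCohort",
    "VarianceComponents",
    "exclude_outliers_iqr",
    "residualize",
    "fit_variance_components",
    "select_model_aic",
    "significance_lrt",
    "heritability_pipeline",
]

MODEL_LABELS = ("ACTE", "ACE", "ATE", "CTE", "TE", "CE", "E")


def exclude_outliers_iqr(values: np.ndarray):
    """Keep points v with Q1 - 1.5*IQR < v < Q3 + 1.5*IQR (strict).

    Returns ``(filtered values, keep mask)``.  With constant data the IQR
    is zero and the strict inequalities remove everything; this is flagged
    with a warning rather than silently passed through.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for quartile-based exclusion")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    keep = (values > q1 - 1.5 * iqr) & (values < q3 + 1.5 * iqr)
    if not keep.any():
        log.warning("IQR filter removed every value (constant data?)")
    return values[keep], keep


def residualize(y, covariates):
    """Least-squares residuals of y on covariates (with intercept)."""
    y = np.asarray(y, dtype=float)
    Z = np.column_stack([np.ones(y.size), np.asarray(covariates, dtype=float)])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ beta


@dataclass
class VarianceComponents:
    """Standardized ACTE components of a fitted model."""

    a2: float
    c2: float
    t2: float
    e2: float
    model: str
    loglik: float
    aic: float
    n_params: int
    total_variance: float

    @property
    def h2(self) -> float:
        return self.a2


class TwinCohort:
    """Phenotyped twin/sibling families.

    Built from a tidy table with columns ``subject, family, zygosity,
    role`` (role in twin1/twin2/sib) plus covariates.  For twin pairs with
    more than one non-twin sibling, one sibling is selected at random with
    a fixed seed.
    """

    def __init__(self, table: pd.DataFrame, seed: int = 0):
        required = {"subject", "family", "zygosity", "role"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"cohort table lacks columns {sorted(missing)}")
        table = table.copy()
        rng = np.random.default_rng(seed)
        keep_rows = []
        for _, fam in table.groupby("family", sort=False):
            twins = fam[fam["role"].str.startswith("twin")]
            sibs = fam[~fam["role"].str.startswith("twin")]
            if len(twins) > 2:
                raise ValueError(
                    f"family {fam['family'].iloc[0]!r} has {len(twins)} twins")
            if len(sibs) > 1:
                sibs = sibs.iloc[[rng.integers(len(sibs))]]
            keep_rows.append(pd.concat([twins, sibs]))
        self.table = pd.concat(keep_rows, ignore_index=True)

    def family_arrays(self, values: np.ndarray, mask: np.ndarray | None = None):
        """Group phenotype values by family pattern.

        Returns ``{(zygosity, roles): (n_fam, m) array}`` with excluded
        individuals dropped (families shrink rather than disappear).
        """
        tab = self.table
        if mask is None:
            mask = np.ones(len(tab), dtype=bool)
        groups: dict[tuple, list[np.ndarray]] = {}
        for _, fam in tab[mask].assign(_y=values[mask]).groupby("family", sort=False):
            fam = fam.sort_values("role")
            roles = tuple("twin" if r.startswith("twin") else "sib"
                          for r in fam["role"])
            key = (fam["zygosity"].iloc[0], roles)
            groups.setdefault(key, []).append(fam["_y"].to_numpy())
        return {key: np.vstack(v) for key, v in groups.items()}


def _pattern_cov(zygosity: str, roles: tuple, va: float, vc: float,
                 vt: float, ve: float) -> np.ndarray:
    m = len(roles)
    S = np.empty((m, m))
    total = va + vc + vt + ve
    for i in range(m):
        for j in range(m):
            if i == j:
                S[i, j] = total
            elif roles[i] == "twin" and roles[j] == "twin":
                S[i, j] = (va if zygosity == "MZ" else 0.5 * va) + vc + vt
            else:
                S[i, j] = 0.5 * va + vc
    return S


def _neg_loglik(params: np.ndarray, free: list[str],
                groups: dict) -> float:
    comp = dict(a=0.0, c=0.0, t=0.0, e=0.0)
    mu = params[0]
    for name, val in zip(free, params[1:]):
        comp[name] = val
    nll = 0.0
    for (zyg, roles), Y in groups.items():
        S = _pattern_cov(zyg, roles, comp["a"], comp["c"], comp["t"], comp["e"])
        m = S.shape[0]
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * np.log(np.diag(L)).sum()
        resid = Y - mu
        sol = np.linalg.solve(L, resid.T)
        quad = np.einsum("ij,ij->j", sol, sol)
        nll += 0.5 * (Y.shape[0] * (m * np.log(2 * np.pi) + logdet) + quad.sum())
    return float(nll)


def fit_variance_components(cohort: TwinCohort, values: np.ndarray,
                            model: str = "ACTE",
                            mask: np.ndarray | None = None) -> VarianceComponents:
    """Maximum-likelihood fit of one model of the ACTE family.

    ``values`` are per-individual phenotypes aligned with ``cohort.table``;
    ``mask`` optionally drops excluded individuals.  Components of the
    fitted model are returned standardized (they sum to 1).
    """
    model = model.upper()
    # any subset of ACTE containing E is fittable (the AIC selection uses
    # MODEL_LABELS; LRT comparators may fall outside that family)
    if ("E" not in model or len(set(model)) != len(model)
            or not set(model) <= set("ACTE")):
        raise ValueError(f"invalid model label {model!r}")
    values = np.asarray(values, dtype=float)
    groups = cohort.family_arrays(values, mask)
    if not groups:
        raise ValueError("no families with phenotype data")
    if "T" in model and not any(
            sum(r == "twin" for r in roles) == 2 for (_, roles) in groups):
        raise ValueError("model with T requires complete twin pairs")
    free = [ch.lower() for ch in model]
    used = values if mask is None else values[mask]
    vtot = used.var(ddof=1)
    mu0 = used.mean()

    bounds = [(None, None)] + [
        (1e-8 * vtot if ch == "e" else 0.0, None) for ch in free]
    starts = []
    eq = vtot / len(free)
    starts.append([mu0] + [eq] * len(free))
    starts.append([mu0] + [0.1 * vtot if ch != "e" else 0.9 * vtot for ch in free])
    best = None
    for x0 in starts:
        res = optimize.minimize(_neg_loglik, x0, args=(free, groups),
                                method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError(f"variance-component fit failed: {best}")
    comp = dict(a=0.0, c=0.0, t=0.0, e=0.0)
    for name, val in zip(free, best.x[1:]):
        comp[name] = max(val, 0.0)
    total = comp["a"] + comp["c"] + comp["t"] + comp["e"]
    n_params = len(free) + 1  # variance components + mean
    loglik = -float(best.fun)
    return VarianceComponents(
        a2=comp["a"] / total, c2=comp["c"] / total,
        t2=comp["t"] / total, e2=comp["e"] / total,
        model=model, loglik=loglik,
        aic=2.0 * n_params - 2.0 * loglik,
        n_params=n_params, total_variance=total,
    )


def select_model_aic(fits) -> VarianceComponents:
    """Lowest AIC wins; exact ties go to the model with fewer parameters."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to select from")
    return min(fits, key=lambda f: (f.aic, f.n_params))


def significance_lrt(full: VarianceComponents, reduced: VarianceComponents) -> float:
    """Likelihood-ratio p-value for nested variance-component models."""
    if not set(reduced.model) < set(full.model):
        raise ValueError(f"{reduced.model} is not nested in {full.model}")
    df = full.n_params - reduced.n_params
    lr = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    return float(stats.chi2.sf(lr, df))


def _toggle(model: str, letter: str) -> str:
    """Model label with the given component removed or added."""
    order = "ACTE"
    present = set(model)
    if letter in present:
        present.remove(letter)
    else:
        present.add(letter)
    return "".join(ch for ch in order if ch in present)


def _component_p(fits: dict, best: VarianceComponents, letter: str,
                 cohort, values, mask) -> float:
    """LRT p for one component: compare the best model with / without it."""
    other = _toggle(best.model, letter)
    if other not in fits:
        fits[other] = fit_variance_components(cohort, values, other, mask)
    pair = (best, fits[other])
    full, reduced = (pair if letter in best.model else pair[::-1])
    return significance_lrt(full, reduced)


def heritability_pipeline(phenotypes: pd.DataFrame, cohort: TwinCohort,
                          covariate_cols=("age", "sex"), q: float = 0.05,
                          models=MODEL_LABELS) -> pd.DataFrame:
    """Per-feature heritability with outlier handling and model selection.

    ``phenotypes`` is a subjects x features table (indexed by subject id,
    or carrying a ``subject`` column); rows are matched to the cohort by
    id.  For each feature: IQR outlier exclusion, covariate residualization,
    fit of every model in ``models``, AIC selection, LRT p-values for the
    A and C components and the full-ACTE h^2 for the robustness
    comparison.  p-values are FDR-corrected across features.  Per-feature
    failures are recorded and the remaining features continue.
    """
    tab = cohort.table
    cov = tab.loc[:, list(covariate_cols)].to_numpy(dtype=float)
    if "subject" in phenotypes.columns:
        phenotypes = phenotypes.set_index("subject")
    phenotypes = phenotypes.reindex(tab["subject"])
    rows = []
    for col in phenotypes.columns:
        y = phenotypes[col].to_numpy(dtype=float)
        try:
            valid = np.isfinite(y) & np.isfinite(cov).all(axis=1)
            n_missing = int((~valid).sum())
            if n_missing:
                log.info("%s: dropping %d subjects with missing data", col, n_missing)
            _, keep = exclude_outliers_iqr(y[valid])
            mask = valid.copy()
            mask[np.flatnonzero(valid)[~keep]] = False
            resid = np.full_like(y, np.nan)
            resid[mask] = residualize(y[mask], cov[mask])
            fits = {m: fit_variance_components(cohort, resid, m, mask)
                    for m in models}
            best = select_model_aic(fits.values())
            p_a = _component_p(fits, best, "A", cohort, resid, mask)
            p_c = _component_p(fits, best, "C", cohort, resid, mask)
            rows.append({
                "feature": col, "model": best.model, "h2": best.h2,
                "a2": best.a2, "c2": best.c2, "t2": best.t2, "e2": best.e2,
                "p_A": p_a, "p_C": p_c,
                "h2_acte": fits["ACTE"].a2 if "ACTE" in fits else np.nan,
                "n_used": int(mask.sum()), "error": "",
            })
        except Exception as exc:
            log.warning("feature %s failed: %s", col, exc)
            rows.append({"feature": col, "model": "", "h2": np.nan,
                         "a2": np.nan, "c2": np.nan, "t2": np.nan, "e2": np.nan,
                         "p_A": np.nan, "p_C": np.nan, "h2_acte": np.nan,
                         "n_used": 0, "error": str(exc)})
    out = pd.DataFrame(rows).set_index("feature")
    for col in ("p_A", "p_C"):
        padj = np.full(len(out), np.nan)
        ok = out[col].notna().to_numpy()
        if ok.any():
            _, padj[ok] = fdr_bh(out[col].to_numpy()[ok], q)
        out[col + "_fdr"] = padj
    return out
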