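"""Shape asymmetry signature (SAS) and regional asymmetry indices.

The SAS is the per-index difference between the area-normalized left- and
right-hemisphere eigenvalue spectra of a subject.  Because the spectra are
isometry invariant, mirror-symmetric hemispheres have an identically zero
SAS without any registration or smoothing, and the area normalization makes
the signature independent of brain size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from shapeasym.spectra import EigenSpectrum
from shapeasym.tables import value_columns

log = logging.getLogger(__name__)

__all__ = [
    "SASVector",
    "RegionalAsymmetry",
    "compute_sas",
    "overall_asymmetry",
    "traditional_ai",
    "revised_ai",
    "qc_flag_outliers",
]


@dataclass
class SASVector:
    """Per-index left-minus-right normalized eigenvalue differences."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def k(self) -> int:
        return self.values.size


@dataclass
class RegionalAsymmetry:
    """Per-region asymmetry values with undefined regions flagged."""

    values: np.ndarray
    undefined: np.ndarray
    measurement: str = ""


def compute_sas(left: EigenSpectrum, right: EigenSpectrum) -> SASVector:
    """SAS_i = lambda_L,i - lambda_R,i on area-normalized spectra.

    Both spectra must be area normalized (size independence is the point
    of the signature) and share the same length.
    """
    if left.normalization != "area" or right.normalization != "area":
        raise ValueError("SAS requires area-normalized spectra on both sides")
    if left.k != right.k:
        raise ValueError(f"spectra lengths differ: {left.k} vs {right.k}")
    return SASVector(left.values - right.values)


def overall_asymmetry(sas: SASVector, index_range: tuple[int, int] | None = None,
                      absolute: bool = False) -> float:
    """Sum of SAS entries over a 1-based inclusive index range.

    ``absolute=True`` sums magnitudes instead (the signed and absolute
    variants answer different questions: net direction vs overall level).
    """
    if index_range is None:
        index_range = (1, sas.k)
    lo, hi = index_range
    if not (1 <= lo <= hi <= sas.k):
        raise ValueError(f"index range {index_range} outside 1..{sas.k}")
    chunk = sas.values[lo - 1:hi]
    if chunk.size == 0:
        raise ValueError("empty index range")
    return float(np.abs(chunk).sum() if absolute else chunk.sum())


def traditional_ai(pl: float, pr: float) -> float:
    """Classical asymmetry index (pl - pr) / (0.5 * (pl + pr)).

    Returns NaN when the denominator vanishes.
    """
    denom = 0.5 * (pl + pr)
    if denom == 0:
        return float("nan")
    return (pl - pr) / denom


def revised_ai(pl, pr, measurement: str = "") -> RegionalAsymmetry:
    """Mean-adjusted asymmetry index.

    The subject mean M over all regions of both hemispheres is removed
    from each side before forming the classical index, which cancels the
    additive whole-brain size term that survives in the traditional index:
    RAI_i = ((pl_i - M) - (pr_i - M)) / (0.5 * ((pl_i - M) + (pr_i - M))).
    Adding a constant to every region of both hemispheres leaves RAI
    unchanged.
    """
    pl = np.asarray(pl, dtype=float)
    pr = np.asarray(pr, dtype=float)
    if pl.shape != pr.shape:
        raise ValueError("left/right region counts differ")
    M = np.concatenate([pl, pr]).mean()
    num = (pl - M) - (pr - M)
    denom = 0.5 * ((pl - M) + (pr - M))
    undefined = denom == 0
    values = np.full(pl.shape, np.nan)
    values[~undefined] = num[~undefined] / denom[~undefined]
    if undefined.any():
        log.warning("revised AI undefined for %d region(s)", int(undefined.sum()))
    return RegionalAsymmetry(values, undefined, measurement)


def qc_flag_outliers(table, n_eigen: int = 200, sd_thresh: float = 4.0,
                     max_violations: int = 2) -> pd.Series:
    """Cohort QC: flag subjects with gross spectral outliers.

    A subject is flagged iff strictly more than ``max_violations`` of its
    first ``n_eigen`` values deviate from the cohort mean by more than
    ``sd_thresh`` cohort standard deviations (ddof=1).

    ``table`` is either a DataFrame in the spectra/SAS layout or a plain
    (subjects x k) array; the returned Series is indexed by subject.
    """
    if isinstance(table, pd.DataFrame):
        cols = value_columns(table, "ev") or value_columns(table, "sas")
        data = table[cols].to_numpy(dtype=float)
        index = table["subject"] if "subject" in table.columns else table.index
    else:
        data = np.asarray(table, dtype=float)
        index = pd.RangeIndex(len(data))
    if data.shape[0] < 3:
        raise ValueError("QC needs at least 3 subjects")
    if n_eigen > data.shape[1]:
        raise ValueError(f"n_eigen={n_eigen} exceeds available k={data.shape[1]}")
    data = data[:, :n_eigen]
    mu = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(data - mu) / sd
    violations = (z > sd_thresh).sum(axis=1)
    return pd.Series(violations > max_violations, index=index, name="qc_flagged")
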