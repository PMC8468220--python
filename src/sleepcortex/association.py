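"""Correlation of sleep-EEG indexes with regional cortical thickness.

For every cortical region and hemisphere, the thickness vector across
subjects is tested against the 18 sleep-EEG indexes (3 indexes x 6 scalp
clusters) with two-tailed Pearson correlations; Benjamini-Hochberg FDR is
applied within that 18-test family, separately for left and right
hemispheres.  The hemispheric mean thickness forms an additional family.
Significant correlations are optionally re-examined with partial
correlations controlling for age and sex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, SpecError
from .spectral import CLUSTER_NAMES, INDEX_NAMES


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SpecError("x and y must be 1-d vectors of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    if keep.sum() < x.size:
        warnings.warn(
            f"dropping {x.size - int(keep.sum())} incomplete pair(s)", stacklevel=3
        )
    return x[keep], y[keep]


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and its two-tailed p (t with n-2 df).

    Missing values are removed pairwise (with a warning); fewer than 4
    complete pairs, or a zero-variance input, is an error.  ``r = +-1``
    returns ``p = 0``.
    """
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 4:
        raise DegenerateInputError(f"need at least 4 complete pairs, have {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0 - 1e-12:  # exact linear relation up to rounding
        return float(np.sign(r)), 0.0
    return float(r), float(p)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise SpecError("p must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise SpecError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def partial_pearson(
    x: Sequence[float],
    y: Sequence[float],
    covariates: pd.DataFrame | np.ndarray,
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [intercept, covariates] by least
    squares and the residuals correlated; p is two-tailed from t with
    ``n - 2 - k`` degrees of freedom (k = number of retained covariates).
    Constant (collinearity-degenerate) covariate columns are dropped with a
    warning and k adjusted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    n = x.size
    if y.size != n or cov.shape[0] != n:
        raise SpecError("x, y and covariates must share the subject dimension")
    keep_cols = []
    for j in range(cov.shape[1]):
        if np.ptp(cov[:, j]) == 0:
            warnings.warn(f"dropping constant covariate column {j}", stacklevel=2)
        else:
            keep_cols.append(j)
    cov = cov[:, keep_cols]
    k = cov.shape[1]
    if n - 2 - k < 1:
        raise DegenerateInputError(f"too few subjects (n={n}) for {k} covariates")
    design = np.column_stack([np.ones(n), cov])
    # rank-deficiency beyond constant columns (e.g. duplicated covariates)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("collinear covariates; degrees of freedom use matrix rank", stacklevel=2)
        k = rank - 1
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    # a variable fully explained by the covariates has nothing left to correlate
    if (rx**2).sum() <= 1e-20 * max((x**2).sum(), 1e-30) or (ry**2).sum() <= 1e-20 * max(
        (y**2).sum(), 1e-30
    ):
        return 0.0, 1.0
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    r = float((rx * ry).sum() / denom)
    df = n - 2 - k
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt(df) / np.sqrt(1 - r**2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


@dataclass
class CorrelationRecord:
    """One (region, hemisphere) x (index, cluster) correlation result."""

    region: str
    hemisphere: str
    index_name: str
    cluster: str
    n: int
    r: float
    p_unc: float
    p_fdr: float
    significant: bool
    partial_r: Optional[float] = None
    partial_p: Optional[float] = None


def run_family(
    region: str,
    hemisphere: str,
    thickness: pd.Series,
    indexes: pd.DataFrame,
    alpha: float = 0.05,
) -> list[CorrelationRecord]:
    """The 18-test FDR family of one (region, hemisphere) thickness vector.

    ``indexes`` has one row per subject and a (index_name, cluster) column
    MultiIndex; ``thickness`` is indexed by the same subjects.  Returns 18
    records with BH-adjusted p-values (family size m = 18).
    """
    subjects = list(indexes.index)
    if list(thickness.index) != subjects:
        thickness = thickness.reindex(subjects)
        if thickness.isna().any():
            raise SpecError("thickness and indexes subjects do not match")
    cells = [(i, c) for i in INDEX_NAMES for c in CLUSTER_NAMES]
    results = []
    for index_name, cluster in cells:
        x = indexes[(index_name, cluster)].to_numpy(dtype=float)
        yv = thickness.to_numpy(dtype=float)
        keep = ~(np.isnan(x) | np.isnan(yv))
        if keep.sum() < 4:
            # cell not testable (e.g. too few subjects with REM sleep);
            # reported as missing but the family stays m=18
            results.append((index_name, cluster, int(keep.sum()), np.nan, np.nan))
        else:
            r, p = pearson(x[keep], yv[keep])
            results.append((index_name, cluster, int(keep.sum()), r, p))
    raw = np.array([row[4] for row in results], dtype=float)
    missing = np.isnan(raw)
    p_fdr = bh_adjust(np.where(missing, 1.0, raw))
    p_fdr[missing] = np.nan
    return [
        CorrelationRecord(
            region=region,
            hemisphere=hemisphere,
            index_name=index_name,
            cluster=cluster,
            n=n,
            r=r,
            p_unc=p,
            p_fdr=float(q),
            significant=bool(q <= alpha),
        )
        for (index_name, cluster, n, r, p), q in zip(results, p_fdr)
    ]


def records_to_frame(records: Iterable[CorrelationRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(rec) for rec in records])
    return df


def _format_r(r: float) -> str:
    return f"{r:.2f}"


def _format_p(p: float) -> str:
    if p == 0:
        return "0"
    return f"{p:.2g}"


def format_significant_table(records: Iterable[CorrelationRecord]) -> pd.DataFrame:
    """Significant records in the published summary-table layout.

    Long-form rows (region, side, sleep index, EEG cluster, r, p) restricted
    to FDR-significant correlations, sorted by region then index, with r to
    two decimals and the uncorrected p to two significant figures.
    """
    rows = [
        {
            "MR cortical area": rec.region,
            "Side": rec.hemisphere,
            "Sleep index": rec.index_name,
            "EEG cluster": rec.cluster,
            "r": _format_r(rec.r),
            "p": _format_p(rec.p_unc),
        }
        for rec in records
        if rec.significant
    ]
    df = pd.DataFrame(
        rows,
        columns=["MR cortical area", "Side", "Sleep index", "EEG cluster", "r", "p"],
    )
    if len(df):
        df = df.sort_values(
            ["MR cortical area", "Side", "Sleep index", "EEG cluster"]
        ).reset_index(drop=True)
    return df
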