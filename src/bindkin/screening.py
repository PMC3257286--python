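"""Correlation screening of molecular descriptors against log10 rates.

Each descriptor is tested for Pearson correlation with the response and
kept when the two-sided t-test p-value falls below a strict significance
level (default 0.01 — many descriptors are tested, so a tight alpha
stands in for an explicit multiplicity correction).  Output order is by
signed r ascending, most negative correlations first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tables_io import RateTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationRecord:
    descriptor: str
    r: float
    n: int
    p: float


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Raises ``ValueError`` for constant input, where r is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def correlation_pvalue(r, n: int) -> float:
    """Two-sided significance of a Pearson correlation.

    Uses t = r·sqrt((n−2)/(1−r²)) on Student-t with n−2 degrees of
    freedom.  |r| = 1 is degenerate (p = 0, warned).  Vectorised over r.
    """
    rr = np.asarray(r, dtype=float)
    if n < 4:
        raise ValueError("need n >= 4 for a correlation test")
    if np.any(np.abs(rr) > 1):
        raise ValueError("|r| cannot exceed 1")
    degenerate = np.abs(rr) == 1.0
    if np.any(degenerate):
        logger.warning("degenerate |r| = 1 encountered; returning p = 0")
    with np.errstate(divide="ignore"):
        t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    p = np.where(degenerate, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    return float(p) if p.ndim == 0 else p


def screen_descriptors(table: RateTable, alpha: float = 0.01) -> list[CorrelationRecord]:
    """All descriptors whose correlation with the response has p < alpha.

    Constant columns are skipped with a warning.  Records are sorted by
    signed r ascending (strongest negative correlation first).
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    X = table.base.values
    y = table.response
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 complexes to screen")

    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    sy = np.sqrt(yc @ yc)
    if sy == 0.0:
        raise ValueError("response is constant; correlations undefined")
    constant = sx == 0.0
    if constant.any():
        skipped = [d for d, c in zip(table.base.descriptor_names, constant) if c]
        logger.warning("skipping %d constant descriptor columns: %s",
                       len(skipped), skipped)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((yc @ Xc) / (sx * sy), -1.0, 1.0)
    r = np.where(constant, np.nan, r)
    p = np.full_like(r, np.nan)
    ok = ~constant
    p[ok] = correlation_pvalue(r[ok], n)

    records = [
        CorrelationRecord(descriptor=d, r=float(ri), n=n, p=float(pi))
        for d, ri, pi in zip(table.base.descriptor_names, r, p)
        if np.isfinite(pi) and pi < alpha
    ]
    records.sort(key=lambda rec: (rec.r, rec.descriptor))
    return records
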