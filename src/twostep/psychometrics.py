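"""Reliability statistics: odd–even split-half, Spearman-Brown, one-way ICC.

Interpretation bands follow the conventional guideline: below 0.4 poor,
0.4–0.7 fair, 0.7–0.9 good, above 0.9 excellent; values exactly on a
boundary map to the higher band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .taskmodel import InvalidArgument
from . import stayfit

log = logging.getLogger(__name__)

BANDS = ("poor", "fair", "good", "excellent")


def interpret_reliability(r: float) -> str:
    if not (-1.0 <= r <= 1.0):
        raise InvalidArgument("coefficient must lie in [-1, 1]")
    if r < 0.4:
        return "poor"
    if r < 0.7:
        return "fair"
    if r < 0.9:
        return "good"
    return "excellent"


def spearman_brown(r: float) -> float:
    """Project a half-length reliability to full length: 2r / (1 + r)."""
    if r == -1.0:
        raise InvalidArgument("Spearman-Brown is undefined at r = -1")
    if not (-1.0 < r <= 1.0):
        raise InvalidArgument("coefficient must lie in (-1, 1]")
    return 2.0 * r / (1.0 + r)


@dataclass
class ReliabilityReport:
    method: str                  # "split_half" or "icc1"
    r: float
    ci_low: float
    ci_high: float
    n: int
    corrected: Optional[float] = None
    band: str = "poor"
    n_dropped: int = 0
    p: Optional[float] = None

    def __post_init__(self):
        self.band = interpret_reliability(max(-1.0, min(1.0, self.r)))

    def to_dict(self) -> dict:
        return {"method": self.method, "r": self.r,
                "ci": [self.ci_low, self.ci_high], "n": self.n,
                "corrected": self.corrected, "band": self.band,
                "p": self.p, "n_dropped": self.n_dropped}


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    crit = stats.norm.ppf(0.5 + level / 2)
    return (float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se)))


def _estimate_mbi(rows: pd.DataFrame, estimator) -> pd.Series:
    if callable(estimator):
        return pd.Series(estimator(rows)).sort_index()
    if estimator == "hierarchical":
        return stayfit.extract_mbi(stayfit.fit_hierarchical(rows))
    if estimator == "pointwise":
        return stayfit.extract_mbi(stayfit.pointwise_table(rows))
    raise InvalidArgument(f"unknown estimator {estimator!r}")


def split_half_oddeven(
    rows: pd.DataFrame,
    estimator: Union[str, Callable[[pd.DataFrame], pd.Series]] = "hierarchical",
    min_rows_per_half: int = 2,
) -> ReliabilityReport:
    """Odd–even split-half reliability of the model-based index.

    Each subject's stay rows are partitioned by the parity of the stay
    trial's index; the MBI is estimated separately in each half and the
    two per-subject vectors are Pearson-correlated (Fisher-z 95% CI).
    Subjects with fewer than ``min_rows_per_half`` rows in either half are
    dropped (counted in ``n_dropped``).
    """
    parity = rows["trial"].to_numpy() % 2
    halves = [rows[parity == 1], rows[parity == 0]]
    counts = [h.groupby("subject").size() for h in halves]
    all_subjects = rows["subject"].unique()
    keep = [s for s in all_subjects
            if all(c.get(s, 0) >= min_rows_per_half for c in counts)]
    n_dropped = len(all_subjects) - len(keep)
    if n_dropped:
        log.info("split_half_oddeven: dropped %d subject(s) with an empty "
                 "or too-small half", n_dropped)
    if len(keep) < 3:
        raise InvalidArgument("split-half needs at least 3 usable subjects")
    keep_set = set(keep)
    scores = [
        _estimate_mbi(h[h["subject"].isin(keep_set)], estimator)
        for h in halves
    ]
    a, b = scores[0].align(scores[1], join="inner")
    n = len(a)
    if a.std() == 0 and b.std() == 0 and np.allclose(a, a.iloc[0]) \
            and np.allclose(b, b.iloc[0]):
        # degenerate constant estimator: identical halves count as perfect
        r, p = (1.0, 0.0) if np.allclose(a, b) else (np.nan, np.nan)
    else:
        r, p = stats.pearsonr(a, b)
    lo, hi = _fisher_ci(r, n)
    corrected = spearman_brown(r) if r > -1 else None
    return ReliabilityReport("split_half", float(r), lo, hi, n,
                             corrected=corrected, n_dropped=n_dropped,
                             p=float(p))


def icc_oneway(x, y) -> ReliabilityReport:
    """One-way random-effects ICC(1,1) for two paired sessions.

    From the one-way ANOVA decomposition with k = 2 measurements per
    subject: ICC = (MSB − MSW) / (MSB + MSW), with the standard F-based
    confidence interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgument("x and y must be 1-d and paired")
    n = x.size
    if n < 3:
        raise InvalidArgument("ICC needs at least 3 subjects")
    data = np.column_stack([x, y])
    if np.allclose(data, data.flat[0]):
        raise InvalidArgument("zero total variance: ICC undefined")
    k = 2
    subj_means = data.mean(axis=1)
    grand = data.mean()
    ssb = k * np.sum((subj_means - grand) ** 2)
    ssw = np.sum((data - subj_means[:, None]) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msb + msw == 0:
        raise InvalidArgument("zero total variance: ICC undefined")
    icc = (msb - msw) / (msb + msw)

    if msw > 0:
        F = msb / msw
        df1, df2 = n - 1, n * (k - 1)
        p = float(stats.f.sf(F, df1, df2))
        f_lo = F / stats.f.ppf(0.975, df1, df2)
        f_hi = F * stats.f.ppf(0.975, df2, df1)
        lo = (f_lo - 1) / (f_lo + k - 1)
        hi = (f_hi - 1) / (f_hi + k - 1)
    else:
        p, lo, hi = 0.0, 1.0, 1.0
    return ReliabilityReport("icc1", float(icc), float(lo), float(hi), n, p=p)
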