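"""Method-agreement statistics for paired dose tables.

Lin's concordance correlation coefficient (CCC) with population (1/n)
moments, Bland-Altman percentage-difference analysis with limits of
agreement at mean ± 1.96 SD, and the signed relative-difference convention
100·(a − b)/b used throughout the dose comparisons (a = the method under
test, b = the reference). Paired tables carry explicit missing flags and
every statistic applies pairwise deletion — a pair contributes only when
both methods report a value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BA_MODES = ("percent_of_reference", "percent_of_mean", "absolute")


@dataclass
class AgreementSummary:
    """Concordance + Bland-Altman summary over complete pairs."""

    n_pairs: int
    ccc: float | None
    mean_diff: float
    mean_abs_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    mode: str = "percent_of_reference"

    def __post_init__(self) -> None:
        if self.ccc is not None and not -1.0 <= self.ccc <= 1.0 + 1e-12:
            raise ValueError("CCC must lie in [-1, 1]")
        if not (self.loa_low - 1e-9 <= self.mean_diff <= self.loa_high + 1e-9):
            raise ValueError("mean difference must lie within the LoA")


@dataclass
class PairedDoseTable:
    """Long-form (case, organ, method) -> dose table with missing support.

    Missing values are NaN and explicitly flagged, never zero-filled; one
    value per (case, organ, method) triple.
    """

    rows: pd.DataFrame  # columns: case, organ, method, dose
    dose_column: str = "dose"

    def __post_init__(self) -> None:
        needed = {"case", "organ", "method", self.dose_column}
        missing = needed - set(self.rows.columns)
        if missing:
            raise ValueError(f"paired table missing columns {sorted(missing)}")
        dup = self.rows.duplicated(subset=["case", "organ", "method"])
        if dup.any():
            raise ValueError("duplicate (case, organ, method) rows")

    @classmethod
    def from_csv(cls, path: str | Path, dose_column: str | None = None
                 ) -> "PairedDoseTable":
        df = pd.read_csv(path)
        if dose_column is None:
            candidates = [c for c in df.columns
                          if c not in ("case", "organ", "method")]
            if len(candidates) != 1:
                raise ValueError(f"ambiguous dose column among {candidates}")
            dose_column = candidates[0]
        return cls(rows=df, dose_column=dose_column)

    @property
    def methods(self) -> list[str]:
        return sorted(self.rows["method"].unique())

    @property
    def organs(self) -> list[str]:
        return sorted(self.rows["organ"].unique())

    def pivot(self, organ: str | None = None) -> pd.DataFrame:
        """(case, organ) x method wide table; NaN marks missing."""
        df = self.rows
        if organ is not None:
            df = df[df["organ"] == organ]
        return df.pivot_table(index=["case", "organ"], columns="method",
                              values=self.dose_column, aggfunc="first",
                              dropna=False)

    def complete_pairs(self, method_a: str, method_b: str,
                       organ: str | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
        """Paired values for two methods after pairwise deletion of missing."""
        wide = self.pivot(organ)
        for m in (method_a, method_b):
            if m not in wide.columns:
                raise KeyError(f"method {m!r} not present in table")
        if method_a == method_b:
            vals = wide[method_a].dropna().to_numpy(float)
            return vals, vals.copy()
        sub = wide[[method_a, method_b]].dropna()
        return sub[method_a].to_numpy(float), sub[method_b].to_numpy(float)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def lin_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient, population (1/n) moments.

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (x̄ − ȳ)^2). NaN pairs are dropped
    pairwise; fewer than two remaining pairs, or a zero denominator
    (both vectors constant and equal), raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 2:
        raise ValueError("need at least 2 complete pairs")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    denom = float(x.var() + y.var() + (x.mean() - y.mean()) ** 2)
    if denom == 0.0:
        raise ValueError("zero denominator: both vectors constant and equal")
    return 2.0 * sxy / denom


def lin_ccc_ci(x: Sequence[float], y: Sequence[float],
               alpha: float = 0.05) -> tuple[float, float, float]:
    """CCC with an asymptotic confidence interval via the Fisher z transform.

    Returns (ccc, low, high). Reported for context; the point estimate is
    the quantity of record.
    """
    from scipy.stats import norm, pearsonr

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    rho_c = lin_ccc(x, y)
    n = len(x)
    r = pearsonr(x, y).statistic
    u = (x.mean() - y.mean()) / math.sqrt(x.std() * y.std())
    # Lin (1989) variance of the z-transformed estimator
    var_z = ((1 - r**2) * rho_c**2 / ((1 - rho_c**2) * r**2)
             + 4 * rho_c**3 * (1 - rho_c) * u**2 / (r * (1 - rho_c**2) ** 2)
             - 2 * rho_c**4 * u**4 / (r**2 * (1 - rho_c**2) ** 2)) / (n - 2)
    z = np.arctanh(rho_c)
    half = norm.ppf(1 - alpha / 2) * math.sqrt(max(var_z, 0.0))
    return rho_c, float(np.tanh(z - half)), float(np.tanh(z + half))


def relative_difference(a: float | np.ndarray,
                        b: float | np.ndarray) -> float | np.ndarray:
    """Signed percentage difference 100·(a − b)/b of ``a`` vs reference ``b``."""
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr == 0):
        raise ValueError("zero reference dose in relative difference")
    out = 100.0 * (np.asarray(a, dtype=float) - b_arr) / b_arr
    return float(out) if out.ndim == 0 else out


def bland_altman(x: Sequence[float], y: Sequence[float],
                 mode: str = "percent_of_reference") -> AgreementSummary:
    """Bland-Altman analysis of ``x`` against reference ``y``.

    Differences per pair: 100(x−y)/y (percent_of_reference, the plotting
    convention used for dose comparisons), 100(x−y)/mean(x,y)
    (percent_of_mean) or x−y (absolute). Limits of agreement are
    mean ± 1.96 SD (population SD). Pairs with a zero reference in the
    percent modes are dropped with a warning.
    """
    if mode not in BA_MODES:
        raise ValueError(f"mode must be one of {BA_MODES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if mode == "percent_of_reference":
        ok = y != 0
        if not ok.all():
            logger.warning("dropping %d pair(s) with zero reference",
                           int((~ok).sum()))
        x, y = x[ok], y[ok]
        diffs = 100.0 * (x - y) / y
    elif mode == "percent_of_mean":
        m = 0.5 * (x + y)
        ok = m != 0
        if not ok.all():
            logger.warning("dropping %d pair(s) with zero mean",
                           int((~ok).sum()))
        x, y = x[ok], y[ok]
        diffs = 100.0 * (x - y) / (0.5 * (x + y))
    else:
        diffs = x - y
    if len(diffs) < 2:
        raise ValueError("need at least 2 complete pairs")
    mean = float(diffs.mean())
    sd = float(diffs.std())
    return AgreementSummary(
        n_pairs=len(diffs), ccc=None, mean_diff=mean,
        mean_abs_diff=float(np.abs(diffs).mean()), sd_diff=sd,
        loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd, mode=mode)


def compare_methods(table: PairedDoseTable, method_a: str, method_b: str,
                    grouping: str = "per_organ",
                    mode: str = "percent_of_reference"
                    ) -> dict[str, AgreementSummary]:
    """CCC + Bland-Altman of method_a vs reference method_b, per group.

    ``grouping='per_organ'`` returns one summary per organ; ``'pooled'``
    one summary over all organ-patient pairs. Groups with fewer than two
    complete pairs are skipped with a warning.
    """
    if grouping not in ("per_organ", "pooled"):
        raise ValueError("grouping must be 'per_organ' or 'pooled'")
    groups = table.organs if grouping == "per_organ" else [None]
    out: dict[str, AgreementSummary] = {}
    for organ in groups:
        key = organ if organ is not None else "pooled"
        x, y = table.complete_pairs(method_a, method_b, organ)
        if len(x) < 2:
            logger.warning("group %s skipped: <2 complete pairs", key)
            continue
        summary = bland_altman(x, y, mode=mode)
        summary.ccc = lin_ccc(x, y)
        out[key] = summary
    return out
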