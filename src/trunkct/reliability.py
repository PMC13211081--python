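"""Multi-rater agreement statistics.

ICC(2,k) — two-way random-effects, absolute agreement, reliability of the
mean of k raters — computed from the two-way ANOVA decomposition
(rows = cases, columns = raters):

    ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

with percentile-bootstrap confidence intervals over case resampling, a
Bland-Altman analysis of each rating against its own case's k-rater mean,
and per-case SD summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RaterMatrix:
    """n_cases x k_raters measurement matrix (no missing entries)."""

    values: np.ndarray
    case_ids: list[str] = field(default_factory=list)
    rater_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("rater matrix must be 2D (cases x raters)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 cases and 2 raters")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rater matrix must have no missing/non-finite entries")
        if not self.case_ids:
            self.case_ids = [f"case_{i + 1}" for i in range(n)]
        if not self.rater_ids:
            self.rater_ids = [f"rater_{j + 1}" for j in range(k)]
        if len(self.case_ids) != n or len(self.rater_ids) != k:
            raise ValueError("id lists must match matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.rater_ids)
        df.insert(0, "case_id", self.case_ids)
        return df

    @classmethod
    def from_csv(cls, path: str | Path) -> "RaterMatrix":
        df = pd.read_csv(path)
        if "case_id" in df.columns:
            case_ids = df["case_id"].astype(str).tolist()
            df = df.drop(columns=["case_id"])
        else:
            case_ids = []
        return cls(values=df.to_numpy(dtype=float), case_ids=case_ids,
                   rater_ids=[str(c) for c in df.columns])


@dataclass(frozen=True)
class ICCResult:
    icc2k: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int
    ci_low: float | None = None
    ci_high: float | None = None
    n_bootstrap: int = 0
    n_degenerate_replicates: int = 0
    seed: int | None = None


@dataclass(frozen=True)
class BlandAltmanResult:
    case_means: np.ndarray       # n*k entries, case mean repeated per rating
    differences: np.ndarray      # rating - own-case mean
    bias: float
    loa_low: float
    loa_high: float
    sd_differences: float


def _anova_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((values - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, max(mse, 0.0)  # guard tiny negative from cancellation


def icc2k(m: RaterMatrix) -> ICCResult:
    """Point estimate of ICC(2,k), absolute agreement, mean of k raters."""
    msr, msc, mse = _anova_mean_squares(m.values)
    denom = msr + (msc - mse) / m.n
    if msr == 0.0 or denom == 0.0:
        raise ValueError("zero between-case variance: ICC(2,k) undefined")
    return ICCResult(icc2k=(msr - mse) / denom, ms_rows=msr, ms_cols=msc,
                     ms_error=mse, n=m.n, k=m.k)


def bootstrap_ci(m: RaterMatrix, n_bootstrap: int = 2000, level: float = 0.95,
                 seed: int = 0) -> ICCResult:
    """Percentile bootstrap CI for ICC(2,k): cases resampled, raters fixed.

    Degenerate replicates (zero between-case variance) are skipped and
    counted in the result.
    """
    if n_bootstrap < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    point = icc2k(m)
    rng = np.random.default_rng(seed)
    stats = []
    n_bad = 0
    for _ in range(n_bootstrap):
        idx = rng.integers(0, m.n, size=m.n)
        resampled = m.values[idx]
        try:
            msr, msc, mse = _anova_mean_squares(resampled)
            denom = msr + (msc - mse) / m.n
            if msr == 0.0 or denom == 0.0:
                raise ZeroDivisionError
            stats.append((msr - mse) / denom)
        except ZeroDivisionError:
            n_bad += 1
    if not stats:
        raise ValueError("every bootstrap replicate was degenerate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return ICCResult(icc2k=point.icc2k, ms_rows=point.ms_rows,
                     ms_cols=point.ms_cols, ms_error=point.ms_error,
                     n=point.n, k=point.k, ci_low=float(lo), ci_high=float(hi),
                     n_bootstrap=n_bootstrap, n_degenerate_replicates=n_bad,
                     seed=seed)


def bland_altman(m: RaterMatrix) -> BlandAltmanResult:
    """Each rating versus its own case's k-rater mean (single LoA pair).

    The bias is the grand mean of the differences, which is identically 0 by
    construction; limits of agreement are +/- 1.96 x SD of the pooled
    differences.
    """
    case_means = m.values.mean(axis=1)
    diffs = m.values - case_means[:, None]
    flat = diffs.ravel()
    bias = float(flat.mean())
    sd = float(flat.std(ddof=1))
    return BlandAltmanResult(
        case_means=np.repeat(case_means, m.k),
        differences=flat,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_differences=sd,
    )


def per_case_sd(m: RaterMatrix) -> tuple[float, float]:
    """(mean, SD) over cases of the across-rater sample SD (ddof=1)."""
    sds = m.values.std(axis=1, ddof=1)
    return float(sds.mean()), float(sds.std(ddof=1))


def grand_mean_from_rater_means(per_rater_means) -> float:
    """Equal-weight grand mean of per-rater mean angles.

    With a complete matrix (equal n per rater) this equals the mean over all
    n*k ratings.
    """
    means = np.asarray(per_rater_means, dtype=float)
    if means.size == 0:
        raise ValueError("need at least one rater mean")
    return float(means.mean())


def rater_summary(m: RaterMatrix) -> pd.DataFrame:
    """Per-rater mean +/- SD plus a grand-mean row over all n*k entries."""
    rows = [
        {"rater": rid, "mean": float(col.mean()), "sd": float(col.std(ddof=1))}
        for rid, col in zip(m.rater_ids, m.values.T)
    ]
    rows.append({"rater": "grand", "mean": float(m.values.mean()),
                 "sd": float(m.values.std(ddof=1))})
    return pd.DataFrame(rows)
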