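"""Cohort correlation analysis: exclusion rules, Pearson correlations,
stratified and sensitivity variants, and summary tables.

The cohort is a pandas DataFrame with one row per case (see
``trunkct.phantom.generate_cohort`` for the canonical column layout):
``case_id``, an outcome column (default ``cobb_mean``), ``fat_<group>``
columns, boolean confounder flags (surgery / atrophy / fracture /
transitional) and ``sex``.

Exclusion semantics follow the study design: cases with prior spine surgery
OR profound fatty atrophy (paraspinal fat% above a threshold, default 50)
are removed globally; per-muscle ID lists (e.g. trapezius crop/absence
cases) are removed only from that muscle's analysis.  No multiple-testing
correction is applied; tables are exploratory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import MUSCLE_GROUPS

ATROPHY_THRESHOLD_DEFAULT = 50.0


@dataclass
class ExclusionRules:
    exclude_surgery: bool = True
    exclude_atrophy: bool = True
    atrophy_threshold: float = ATROPHY_THRESHOLD_DEFAULT
    #: group -> list of case_ids removed only from that muscle's analysis
    per_muscle: dict[str, list] = field(default_factory=dict)
    #: whether per-muscle exclusions also apply to the "raw" tables
    per_muscle_in_raw: bool = True


def derive_atrophy_flag(cohort: pd.DataFrame,
                        threshold: float = ATROPHY_THRESHOLD_DEFAULT) -> pd.Series:
    """Atrophy flag derived from the paraspinal fat% column only."""
    if "fat_paraspinal" not in cohort.columns:
        raise KeyError("cohort lacks a fat_paraspinal column")
    return cohort["fat_paraspinal"] > threshold


def apply_exclusions(cohort: pd.DataFrame, rules: ExclusionRules | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove surgery/atrophy cases; return (filtered cohort, exclusion log).

    The log has one row per excluded case with the triggering rule(s) joined
    by '+': a case hit by several rules is counted once.  Per-muscle
    exclusions are NOT applied here — they belong to the individual muscle's
    analysis (see :func:`correlate`).
    """
    rules = rules or ExclusionRules()
    reasons: dict[object, list[str]] = {}
    if rules.exclude_surgery and "surgery" in cohort.columns:
        for cid in cohort.loc[cohort["surgery"].astype(bool), "case_id"]:
            reasons.setdefault(cid, []).append("surgery")
    if rules.exclude_atrophy:
        if "fat_paraspinal" in cohort.columns:
            atrophy = derive_atrophy_flag(cohort, rules.atrophy_threshold)
        elif "atrophy" in cohort.columns:
            atrophy = cohort["atrophy"].astype(bool)
        else:
            atrophy = pd.Series(False, index=cohort.index)
        for cid in cohort.loc[atrophy, "case_id"]:
            reasons.setdefault(cid, []).append("atrophy")
    log = pd.DataFrame(
        [{"case_id": cid, "rule": "+".join(r)} for cid, r in reasons.items()],
        columns=["case_id", "rule"],
    )
    kept = cohort[~cohort["case_id"].isin(set(reasons))].reset_index(drop=True)
    return kept, log


def correlate(cohort: pd.DataFrame, muscle: str, outcome: str = "cobb_mean",
              rules: ExclusionRules | None = None,
              apply_per_muscle: bool = True) -> tuple[float, float, int]:
    """Sample Pearson r between a muscle's fat% and the outcome.

    Two-sided p-value from the t transform with n-2 df (scipy's pearsonr).
    Muscle-specific case exclusions from ``rules.per_muscle`` are applied
    here when requested.  Requires n >= 3 after exclusions.
    """
    col = f"fat_{muscle}" if f"fat_{muscle}" in cohort.columns else muscle
    if col not in cohort.columns:
        raise KeyError(f"no fat column for muscle {muscle!r}")
    sub = cohort
    if apply_per_muscle and rules is not None:
        drop = set(rules.per_muscle.get(muscle, []))
        if drop:
            sub = sub[~sub["case_id"].isin(drop)]
    x = sub[col].to_numpy(dtype=float)
    y = sub[outcome].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError(f"need n >= 3 for correlation, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in fat% or outcome")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def _table_for(cohort: pd.DataFrame, label: str, outcome: str,
               rules: ExclusionRules, apply_per_muscle: bool,
               muscles=MUSCLE_GROUPS) -> list[dict]:
    rows = []
    for muscle in muscles:
        col = f"fat_{muscle}"
        if col not in cohort.columns:
            continue
        try:
            r, p, n = correlate(cohort, muscle, outcome=outcome, rules=rules,
                                apply_per_muscle=apply_per_muscle)
        except ValueError:
            r, p, n = np.nan, np.nan, int(len(cohort))
        rows.append({"muscle": muscle, "cohort_label": label,
                     "r": r, "p_two_sided": p, "n_used": n})
    return rows


def run_table(cohort: pd.DataFrame, rules: ExclusionRules | None = None,
              outcome: str = "cobb_mean") -> pd.DataFrame:
    """Raw and adjusted correlation tables, one row per muscle per cohort."""
    rules = rules or ExclusionRules()
    adjusted, _log = apply_exclusions(cohort, rules)
    rows = _table_for(cohort, "raw", outcome, rules,
                      apply_per_muscle=rules.per_muscle_in_raw)
    rows += _table_for(adjusted, "adjusted", outcome, rules, apply_per_muscle=True)
    return pd.DataFrame(rows)


def stratify(cohort: pd.DataFrame, by: str, rules: ExclusionRules | None = None,
             outcome: str = "cobb_mean") -> pd.DataFrame:
    """Correlation table per stratum of ``by`` (e.g. sex or a flag column).

    Strata with fewer than 3 cases are reported with NaN r/p, never raised.
    """
    rules = rules or ExclusionRules()
    if by not in cohort.columns:
        raise KeyError(f"no column {by!r} to stratify by")
    frames = []
    seen = []
    for value, sub in cohort.groupby(by, sort=True):
        seen.append(value)
        frames += _table_for(sub.reset_index(drop=True), f"{by}={value}",
                             outcome, rules, apply_per_muscle=True)
    if by == "sex":  # report empty sex strata as undefined rather than omitting them
        for value in ("F", "M"):
            if value not in seen:
                frames += [{"muscle": m, "cohort_label": f"sex={value}",
                            "r": np.nan, "p_two_sided": np.nan, "n_used": 0}
                           for m in MUSCLE_GROUPS
                           if f"fat_{m}" in cohort.columns]
    return pd.DataFrame(frames)


def sensitivity(cohort: pd.DataFrame, drop_flag: str,
                rules: ExclusionRules | None = None,
                outcome: str = "cobb_mean") -> pd.DataFrame:
    """Correlation table after additionally dropping cases with a flag set."""
    rules = rules or ExclusionRules()
    if drop_flag not in cohort.columns:
        raise KeyError(f"no flag column {drop_flag!r}")
    sub = cohort[~cohort[drop_flag].astype(bool)].reset_index(drop=True)
    return pd.DataFrame(
        _table_for(sub, f"sans_{drop_flag}", outcome, rules, apply_per_muscle=True))


def summarize_fat(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-muscle fat% mean and sample SD over the cohort."""
    rows = []
    for muscle in MUSCLE_GROUPS:
        col = f"fat_{muscle}"
        if col not in cohort.columns:
            continue
        x = cohort[col].to_numpy(dtype=float)
        rows.append({"muscle": muscle, "mean": float(x.mean()),
                     "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                     "n": int(x.size)})
    return pd.DataFrame(rows)
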