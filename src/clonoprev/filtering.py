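"""Filtering and summarizing of normal-tissue somatic variant calls.

Ultra-sensitive assays detect mutations in histologically normal tissue,
but calls must be cleaned before prevalence statements are made:

1. tumour-contamination filter — a normal-tissue call is discarded when
   the identical variant is present in any region of the patient's
   matched tumour (contamination cannot be excluded);
2. driver filter — only variants in cancer gene census genes with
   literature driver evidence at or above a chosen tier
   (strong > some > weak) are retained;
3. high-confidence filter — duplex-sequencing calls additionally require
   at least 2 supporting variant reads and strong driver evidence.

Call tables, driver annotations and sample rosters are pandas DataFrames;
variant identity for matching is the (patient_id, gene, variant_key)
triple, where ``variant_key`` is a normalized protein- or genomic-change
string.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EVIDENCE_TIERS",
    "tumour_contamination_filter",
    "driver_filter",
    "high_confidence_filter",
    "prevalence_summary",
    "compare_vaf",
    "compare_proportions",
]

#: Driver-evidence tiers, strongest first.
EVIDENCE_TIERS = {"strong": 3, "some": 2, "weak": 1, "none": 0}

_KEY_COLS = ["patient_id", "gene", "variant_key"]


def _require(df: pd.DataFrame, cols, name: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{name} table missing columns: {sorted(missing)}")


def tumour_contamination_filter(
    normal_calls: pd.DataFrame, tumour_calls: pd.DataFrame
) -> pd.DataFrame:
    """Remove normal-tissue calls whose variant occurs in the matched tumour.

    A call is removed iff the same (patient_id, gene, variant_key) appears
    in *any* tumour region of that patient — the union over regions, since
    multi-region tumour profiling exists precisely to catch subclonal
    presence.  Patients without tumour calls keep all their normal calls.
    """
    _require(normal_calls, _KEY_COLS, "normal calls")
    if len(tumour_calls) == 0:
        return normal_calls.copy()
    _require(tumour_calls, _KEY_COLS, "tumour calls")
    tumour_keys = set(map(tuple, tumour_calls[_KEY_COLS].itertuples(index=False)))
    keep = [
        tuple(row) not in tumour_keys
        for row in normal_calls[_KEY_COLS].itertuples(index=False)
    ]
    return normal_calls.loc[keep].copy()


def driver_filter(
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
    min_tier: str = "weak",
) -> pd.DataFrame:
    """Keep census-gene calls with driver evidence at or above ``min_tier``.

    ``annotation`` is keyed by ``variant_key`` with columns
    ``census_member`` (bool) and ``evidence`` (strong/some/weak/none).
    Unannotated variants are treated as non-census, tier ``none``.  The
    returned calls carry the merged ``census_member``/``evidence``
    columns, which downstream filters reuse.
    """
    if min_tier not in EVIDENCE_TIERS:
        raise ValueError(f"unknown evidence tier {min_tier!r}")
    _require(calls, ["variant_key"], "calls")
    _require(annotation, ["variant_key", "census_member", "evidence"], "annotation")
    bad = set(annotation["evidence"]) - set(EVIDENCE_TIERS)
    if bad:
        raise ValueError(f"unknown evidence tiers in annotation: {sorted(bad)}")
    if annotation["variant_key"].duplicated().any():
        raise ValueError("annotation must have exactly one tier per variant_key")

    merged = calls.drop(columns=["census_member", "evidence"], errors="ignore").merge(
        annotation[["variant_key", "census_member", "evidence"]],
        on="variant_key",
        how="left",
    )
    merged["census_member"] = merged["census_member"].eq(True)
    merged["evidence"] = merged["evidence"].fillna("none")
    rank = merged["evidence"].map(EVIDENCE_TIERS)
    keep = merged["census_member"] & (rank >= EVIDENCE_TIERS[min_tier])
    out = merged.loc[keep].copy()
    out.index = calls.index[keep.to_numpy()]
    return out


def high_confidence_filter(calls: pd.DataFrame) -> pd.DataFrame:
    """Keep calls with >=2 supporting variant reads and strong evidence.

    Calls lacking a ``var_count`` value are excluded with a warning (they
    cannot meet the read-support requirement).
    """
    _require(calls, ["evidence"], "calls")
    if "var_count" not in calls.columns:
        warnings.warn(
            "no var_count column; all calls excluded by the high-confidence filter",
            stacklevel=2,
        )
        return calls.iloc[0:0].copy()
    var_count = pd.to_numeric(calls["var_count"], errors="coerce")
    n_missing = int(var_count.isna().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} call(s) without var_count excluded from the "
            "high-confidence filter",
            stacklevel=2,
        )
    keep = (var_count >= 2) & (calls["evidence"] == "strong")
    return calls.loc[keep.fillna(False)].copy()


def prevalence_summary(
    calls: pd.DataFrame,
    roster: pd.DataFrame,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Per-group and pooled mutation prevalence at the sample level.

    A sample is positive when it has at least one retained call; the
    proportion is positive samples over all roster samples of the group.
    ``percent`` rounds to the nearest integer (half-even), matching the
    reporting style of cohort prevalence statements such as
    "54 out of 295 (18%)".

    Parameters
    ----------
    calls : DataFrame
        Retained calls with a ``sample_id`` column.
    roster : DataFrame
        One row per sample: ``sample_id`` plus any grouping columns.
    group_col : str, optional
        Roster column to stratify by; a pooled ``"all"`` row is always
        appended.
    """
    _require(roster, ["sample_id"], "roster")
    if roster["sample_id"].duplicated().any():
        raise ValueError("roster sample_ids must be unique")
    _require(calls, ["sample_id"], "calls")
    unknown = set(calls["sample_id"]) - set(roster["sample_id"])
    if unknown:
        raise ValueError(f"calls reference samples not in roster: {sorted(unknown)}")

    positive_samples = set(calls["sample_id"])
    roster = roster.copy()
    roster["_positive"] = roster["sample_id"].isin(positive_samples)

    rows = []
    if group_col is not None:
        _require(roster, [group_col], "roster")
        for group, grp in roster.groupby(group_col, sort=True):
            rows.append((group, int(grp["_positive"].sum()), len(grp)))
    rows.append(("all", int(roster["_positive"].sum()), len(roster)))

    out = pd.DataFrame(rows, columns=["group", "positive", "total"])
    out["proportion"] = out["positive"] / out["total"]
    # numpy rounds half-to-even, matching the package-wide convention
    out["percent"] = np.round(out["proportion"] * 100).astype(int)
    return out


def compare_vaf(
    calls: pd.DataFrame, by: str, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided t-test of VAF between the two levels of ``by``.

    Delegated contract: Welch's t-test from scipy.  Returns (statistic, p).
    """
    _require(calls, ["vaf", by], "calls")
    levels = sorted(calls[by].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"{by!r} must have exactly two levels, got {levels}")
    a = calls.loc[calls[by] == levels[0], "vaf"].dropna()
    b = calls.loc[calls[by] == levels[1], "vaf"].dropna()
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def compare_proportions(
    positive: tuple[int, int], total: tuple[int, int]
) -> tuple[float, float]:
    """Two-sided chi-squared comparison of two sample proportions.

    Delegated contract: 2x2 contingency chi-squared (with continuity
    correction) from scipy.  Returns (statistic, p).
    """
    table = np.array(
        [
            [positive[0], total[0] - positive[0]],
            [positive[1], total[1] - positive[1]],
        ]
    )
    if np.any(table < 0):
        raise ValueError("positive counts cannot exceed totals")
    res = stats.chi2_contingency(table)
    return float(res.statistic), float(res.pvalue)
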