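"""Tabular analyses of pegRNA efficiency screens.

Group means by PBS length (library re-analysis style), fold-change
normalization against no-modification controls, conflicting-record
deduplication, and a plain Welch two-sample comparison. The larger test
battery used for screen significance calls (ANOVA, Kruskal-Wallis, Dunnett,
Box-Cox) is deliberately not re-implemented here: those are routine and
available in standard statistics packages; only the two-sample comparison
ships.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqcore import DesignError

#: Expected columns of an efficiency table.
EFFICIENCY_COLUMNS = [
    "pegrna_id", "target_id", "construct_type", "editor", "pbs_length",
    "efficiency", "replicate",
]


def _validate(table: pd.DataFrame, columns: list[str]) -> None:
    missing = set(columns) - set(table.columns)
    if missing:
        raise DesignError(f"efficiency table missing column(s): {sorted(missing)}")


def dedupe_conflicting(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop pegRNAs that carry conflicting efficiency records.

    A pegRNA id reported with two or more *different* efficiency values for
    the same replicate slot (i.e. outside the replicate structure) is
    removed entirely and logged; exact duplicate rows collapse to one.
    Returns ``(clean_table, exclusion_log)``.
    """
    _validate(table, ["pegrna_id", "efficiency", "replicate"])
    if table.empty:
        raise DesignError("empty efficiency table")
    table = table.drop_duplicates()
    conflict = (
        table.groupby(["pegrna_id", "replicate"])["efficiency"]
        .nunique()
        .reset_index(name="n_values")
    )
    bad_ids = sorted(conflict.loc[conflict["n_values"] > 1, "pegrna_id"].unique())
    log = pd.DataFrame(
        {"pegrna_id": bad_ids,
         "reason": ["conflicting efficiency values for one pegRNA"] * len(bad_ids)}
    )
    clean = table[~table["pegrna_id"].isin(bad_ids)].reset_index(drop=True)
    return clean, log


def mean_by_pbs_length(
    table: pd.DataFrame,
    group_keys: tuple[str, ...] = ("construct_type", "editor"),
    ngg_only: bool = False,
) -> pd.DataFrame:
    """Per (group, PBS length): n, mean and SD of efficiency.

    With ``ngg_only`` the table is pre-filtered to rows whose ``pam``
    column matches NGG (requires that column). Single-observation groups
    report SD 0 with ``n = 1`` so they are identifiable.
    """
    _validate(table, ["pbs_length", "efficiency", *group_keys])
    if ngg_only:
        _validate(table, ["pam"])
        table = table[
            table["pam"].str.upper().str.fullmatch("[ACGT]GG")
        ]
    grouped = (
        table.groupby([*group_keys, "pbs_length"])["efficiency"]
        .agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )
    grouped["sd"] = grouped["sd"].fillna(0.0)
    return grouped.sort_values([*group_keys, "pbs_length"]).reset_index(drop=True)


@dataclass(frozen=True)
class FoldChange:
    fold: float
    low_control_flag: bool


def fold_change_vs_control(
    values: list[float],
    control_values: list[float],
    control_floor: float = 0.5,
) -> FoldChange:
    """Mean(values) / mean(control), the heatmap normalization.

    Means of replicates are used (not per-replicate ratios). A control
    mean below ``control_floor`` sets the near-zero-control flag; a
    non-positive control mean is an error.
    """
    control_mean = float(np.mean(control_values))
    if control_mean <= 0:
        raise DesignError("control mean must be > 0 for fold change")
    fold = float(np.mean(values)) / control_mean
    return FoldChange(fold, control_mean < control_floor)


def two_sample_compare(a: list[float], b: list[float]) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t-test: (statistic, p)."""
    if len(a) < 2 or len(b) < 2:
        raise DesignError("each group needs n >= 2")
    result = stats.ttest_ind(a, b, equal_var=False)
    return float(result.statistic), float(result.pvalue)


def to_long_format(summary: pd.DataFrame) -> pd.DataFrame:
    """Heatmap-ready long format of a mean_by_pbs_length summary."""
    return summary.melt(
        id_vars=[c for c in summary.columns if c not in ("n", "mean", "sd")],
        value_vars=["n", "mean", "sd"],
        var_name="statistic",
        value_name="value",
    )
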