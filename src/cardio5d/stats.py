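"""Cohort statistics: Kruskal-Wallis + Dunn's post hoc over 8 motion metrics.

Subjects are the sampling unit: for each grouping, motion type and metric,
each subject contributes one value per group (the mean over that group's
substructures).  A grouping is called significant for a motion type when at
least ``min_significant`` (default 4) of the 8 metrics have a Kruskal-Wallis
p-value below alpha.  Dunn's pairwise tests are Bonferroni-corrected over the
number of pairs within one battery; the 8 metrics are not corrected across.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .errors import ParameterError
from .motion_metrics import METRICS_8

__all__ = [
    "kruskal_wallis",
    "dunn_posthoc",
    "compare_groupings",
    "ComparisonResult",
    "DEFAULT_GROUPINGS",
]

#: standard physiological/laterality/axial substructure groupings
DEFAULT_GROUPINGS: dict[str, dict[str, list[str]]] = {
    "physiological": {
        "coronary_arteries": ["RCA", "LMCA", "LADA", "LCX"],
        "chambers": ["LV", "RV", "LA", "RA"],
        "great_vessels": ["AA", "DA", "PA", "PVs", "IVC", "SVC"],
        "whole_heart": ["WH"],
    },
    "right_vs_left": {
        "right": ["RCA", "RA", "RV"],
        "left": ["LADA", "LMCA", "LCX", "LV", "LA"],
    },
    "base_vs_apex": {
        "base": ["RCA", "LADA", "LMCA", "LCX", "AA", "DA", "PA", "PVs", "SVC"],
        "apex": ["LV", "RV", "LA", "RA", "IVC"],
    },
}


def _pooled_ranks(groups: list[np.ndarray]) -> tuple[list[np.ndarray], float, int]:
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    out, start = [], 0
    for g in groups:
        out.append(ranks[start : start + g.size])
        start += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    return out, tie_sum, pooled.size


def _validate_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise ParameterError("need at least 2 groups")
    if any(g.size == 0 for g in gs):
        raise ParameterError("every group must have at least one observation")
    return gs


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-squared p with k-1 dof.

    All observations identical (tie correction degenerate) is defined as
    H = 0, p = 1.
    """
    gs = _validate_groups(groups)
    rank_groups, tie_sum, n = _pooled_ranks(gs)
    k = len(gs)
    correction = 1.0 - tie_sum / (n**3 - n) if n > 1 else 0.0
    if correction <= 0:
        return 0.0, 1.0
    h = 12.0 / (n * (n + 1)) * sum(r.sum() ** 2 / r.size for r in rank_groups) - 3.0 * (n + 1)
    h /= correction
    h = max(0.0, float(h))
    return h, float(chi2.sf(h, k - 1))


def dunn_posthoc(groups, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z-tests on mean ranks with tie correction.

    Returns a DataFrame (group_i, group_j, z, p_raw, p_adj); two-sided p,
    Bonferroni-adjusted over the number of pairs (capped at 1).  Identical
    groups give z = 0, p = 1.
    """
    gs = _validate_groups(groups)
    rank_groups, tie_sum, n = _pooled_ranks(gs)
    mean_ranks = [r.mean() for r in rank_groups]
    sigma2_base = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1)) if n > 1 else 0.0
    pairs = list(combinations(range(len(gs)), 2))
    rows = []
    for i, j in pairs:
        var = sigma2_base * (1.0 / gs[i].size + 1.0 / gs[j].size)
        if var <= 0:
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
        rows.append({"group_i": i, "group_j": j, "z": float(z), "p_raw": p})
    df = pd.DataFrame(rows)
    if adjust == "bonferroni":
        df["p_adj"] = np.minimum(1.0, df["p_raw"] * len(pairs))
    elif adjust in (None, "none"):
        df["p_adj"] = df["p_raw"]
    else:
        raise ParameterError(f"unknown adjustment {adjust!r}")
    return df


@dataclass
class ComparisonResult:
    """One grouping x motion-type test battery across the 8 metrics."""

    grouping: str
    motion_type: str
    group_labels: list[str]
    metrics: pd.DataFrame  # columns: metric, H, p, significant
    dunn: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_significant_metrics: int = 0
    n_metrics: int = len(METRICS_8)
    overall_significant: bool = False


def _group_values(
    table: pd.DataFrame, substructures: list[str], motion_type: str, metric: str
) -> np.ndarray:
    sel = table[
        table["substructure"].isin(substructures)
        & (table["motion_type"] == motion_type)
        & (table["metric"] == metric)
    ]
    if sel.empty:
        return np.array([])
    return sel.groupby("subject", observed=True)["value_mm"].mean().to_numpy()


def compare_groupings(
    table: pd.DataFrame,
    groupings: dict[str, dict[str, list[str]]] | None = None,
    motion_types=("cardiac", "respiratory"),
    metrics=METRICS_8,
    alpha: float = 0.05,
    min_significant: int = 4,
) -> list[ComparisonResult]:
    """Run the full test battery per grouping and motion type.

    ``table`` is the long-format metric table (subject, substructure,
    motion_type, metric, value_mm).  Unknown substructures in a grouping
    raise a configuration error.
    """
    groupings = groupings if groupings is not None else DEFAULT_GROUPINGS
    present = set(table["substructure"].unique())
    results = []
    for gname, gspec in groupings.items():
        if len(gspec) < 2:
            raise ParameterError(f"grouping {gname!r} needs >= 2 groups")
        for label, subs in gspec.items():
            missing = set(subs) - present
            if missing:
                raise ParameterError(
                    f"grouping {gname!r}/{label!r} references substructures "
                    f"absent from the table: {sorted(missing)}"
                )
        labels = list(gspec)
        for mt in motion_types:
            rows, dunn_results = [], {}
            for metric in metrics:
                groups = [_group_values(table, gspec[lab], mt, metric) for lab in labels]
                if any(g.size == 0 for g in groups):
                    continue  # metric absent for this motion type
                h, p = kruskal_wallis(groups)
                rows.append(
                    {"metric": metric, "H": h, "p": p, "significant": p < alpha}
                )
                dunn_results[metric] = dunn_posthoc(groups)
            mdf = pd.DataFrame(rows)
            n_sig = int(mdf["significant"].sum()) if not mdf.empty else 0
            results.append(
                ComparisonResult(
                    grouping=gname,
                    motion_type=mt,
                    group_labels=labels,
                    metrics=mdf,
                    dunn=dunn_results,
                    n_significant_metrics=n_sig,
                    n_metrics=len(mdf),
                    overall_significant=n_sig >= min_significant,
                )
            )
    return results


def summary_matrix(results: list[ComparisonResult]) -> pd.DataFrame:
    """Counts of significant metrics: rows groupings, columns motion types."""
    rows = []
    for r in results:
        rows.append(
            {
                "grouping": r.grouping,
                "motion_type": r.motion_type,
                "n_significant": r.n_significant_metrics,
                "n_metrics": r.n_metrics,
                "overall_significant": r.overall_significant,
            }
        )
    return pd.DataFrame(rows)
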