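"""Evaluation against experimental essentiality and cross-species meta-analysis.

Per-member precision/recall against an experimental gene-essentiality
table (experimental essential = positive class, restricted to shared
genes), Mann–Whitney comparison of the two simulation clusters with
Benjamini–Hochberg control, pan-species aggregation of curation metrics,
and subsystem-level Kruskal–Wallis with post-hoc pairwise Dunn tests
under Bonferroni correction.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ensemble import EssentialityMatrix
from .errors import ValidationError
from .model import SubsystemAnnotation


def precision_recall(
    matrix: EssentialityMatrix,
    experimental: dict[str, bool],
    cluster_labels: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-member confusion counts vs experimental essentiality.

    Only genes present in both the matrix and the experimental table are
    compared (experimentally assayed genes missing from the model are
    excluded).  Members predicting no essential gene get precision NaN
    (undefined, flagged) rather than 0.
    """
    shared = [g for g in matrix.genes if g in experimental]
    if not shared:
        raise ValidationError(
            "no overlap between predicted genes "
            f"({len(matrix.genes)}) and experimental genes ({len(experimental)})"
        )
    idx = [matrix.genes.index(g) for g in shared]
    truth = np.array([bool(experimental[g]) for g in shared])
    pred = matrix.values[:, idx]
    tp = (pred & truth).sum(axis=1)
    fp = (pred & ~truth).sum(axis=1)
    fn = (~pred & truth).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
    df = pd.DataFrame(
        {
            "member": matrix.member_ids,
            "precision": precision,
            "recall": recall,
            "TP": tp,
            "FP": fp,
            "FN": fn,
        }
    ).set_index("member")
    if cluster_labels is not None:
        df["cluster"] = [cluster_labels[m] for m in matrix.member_ids]
    return df


def compare_cluster_performance(report: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Mann–Whitney U on precision and recall between clusters,
    Benjamini–Hochberg adjusted across the tests performed.

    Members with undefined (NaN) precision are excluded from the precision
    test only.
    """
    if "cluster" not in report.columns:
        raise ValidationError("report lacks a 'cluster' column")
    clusters = sorted(report["cluster"].unique())
    if len(clusters) != 2:
        raise ValidationError(f"expected 2 clusters, got {clusters}")
    rows = []
    for metric in ("precision", "recall"):
        a = report.loc[report["cluster"] == clusters[0], metric].dropna()
        b = report.loc[report["cluster"] == clusters[1], metric].dropna()
        if len(a) < 2 or len(b) < 2:
            raise ValidationError(
                f"cluster with <2 members for metric {metric!r}"
            )
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append((metric, float(u), float(p)))
    df = pd.DataFrame(rows, columns=["metric", "U", "p_raw"])
    df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    return df


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (convenience wrapper)."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Pan-species aggregation
# ---------------------------------------------------------------------------

def aggregate_pan_species(
    per_species: dict[str, pd.DataFrame],
    min_species: int | None = None,
) -> pd.DataFrame:
    """Average curation metrics per reaction over the species in which it
    was gap filled.

    Input: species name → metrics table indexed by reaction_id with
    ``fractional_importance`` and ``cluster_ratio`` columns.  Output rows
    carry the contributing-species count; ``min_species`` optionally
    filters rare reactions.
    """
    if not per_species:
        raise ValidationError("at least one species is required")
    frames = []
    for species, df in per_species.items():
        f = df[["fractional_importance", "cluster_ratio"]].copy()
        f["species"] = species
        frames.append(f.reset_index())
    allf = pd.concat(frames, ignore_index=True)
    out = (
        allf.groupby("reaction_id")
        .agg(
            mean_fractional_importance=("fractional_importance", "mean"),
            mean_cluster_ratio=("cluster_ratio", "mean"),
            n_species=("species", "nunique"),
        )
        .sort_index()
    )
    if min_species is not None:
        out = out[out["n_species"] >= min_species]
    return out


# ---------------------------------------------------------------------------
# Subsystem analysis
# ---------------------------------------------------------------------------

def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Dunn z-tests on rank sums with tie correction; Bonferroni
    across all pairs."""
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    n = len(values)
    ranks = stats.rankdata(values)
    offsets = np.cumsum([0] + [sizes[g] for g in names])
    mean_rank = {
        g: ranks[offsets[i]:offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    pairs = list(combinations(names, 2))
    rows = []
    for a, b in pairs:
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        z = (mean_rank[a] - mean_rank[b]) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, float(z), float(p), float(min(1.0, p * len(pairs)))))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw", "p_adj"])


def subsystem_stats(
    metrics: pd.DataFrame,
    annotation: SubsystemAnnotation,
    value_column: str = "mean_fractional_importance",
    min_reactions: int = 10,
) -> dict:
    """Kruskal–Wallis omnibus + Dunn/Bonferroni post-hoc across subsystems.

    A reaction annotated with several subsystems contributes one
    observation to each.  Only subsystems with at least ``min_reactions``
    gap-filled reactions are tested.
    """
    obs: dict[str, list[float]] = {}
    for rid, value in metrics[value_column].items():
        if np.isnan(value):
            continue
        for sub in annotation.get(str(rid), []):
            obs.setdefault(sub, []).append(float(value))
    qualified = {s: np.array(v) for s, v in obs.items() if len(v) >= min_reactions}
    if len(qualified) < 2:
        raise ValidationError(
            f"fewer than 2 subsystems with ≥{min_reactions} gap-filled reactions"
        )
    h, p = stats.kruskal(*qualified.values())
    pairwise = dunn_posthoc(qualified)
    summary = pd.DataFrame(
        {
            "subsystem": list(qualified),
            "n_reactions": [len(v) for v in qualified.values()],
            "mean": [float(v.mean()) for v in qualified.values()],
            "median": [float(np.median(v)) for v in qualified.values()],
        }
    ).set_index("subsystem")
    return {
        "statistic": float(h),
        "p_value": float(p),
        "summary": summary,
        "pairwise": pairwise,
        "value_column": value_column,
    }
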