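"""Multi-round allele-frequency trajectories: trends, co-origin clusters,
isolate reconciliation and candidate ranking.

A trajectory is a locus's pooled frequency across archived evolution
rounds (UV pool, then shuffling rounds).  Trends formalize the narrative
categories used when reading such data: *rising* and *falling* compare
the endpoints beyond a margin, *transient* requires an interior peak
above both endpoints, *stable* is everything else detected, and
*not_detected* means no round reached the detection threshold.

Loci mutated in a single founder clone share its pool frequency, so
near-identical frequencies in the starting (UV) pool are evidence of
co-origin; clusters are built by single linkage on those frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

__all__ = [
    "TrendConfig",
    "CoOriginCluster",
    "build_frequency_matrix",
    "classify_trajectory",
    "classify_all_trajectories",
    "co_origin_clusters",
    "isolate_allele_frequency",
    "isolate_frequency_table",
    "compare_population_vs_isolates",
    "rank_candidates",
    "TRENDS",
]

TRENDS = ("rising", "falling", "transient", "stable", "not_detected")

# Ranking priority: rising alleles are the reverse-engineering candidates,
# then still-present classes, then lost/undetected ones.
_TREND_PRIORITY = {"rising": 0, "transient": 1, "stable": 1, "falling": 2, "not_detected": 2}


@dataclass(frozen=True)
class TrendConfig:
    trend_margin: float = 0.02
    cluster_tolerance: float = 0.03
    cluster_min_frequency: float = 0.20

    def __post_init__(self) -> None:
        for name in ("trend_margin", "cluster_tolerance", "cluster_min_frequency"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class CoOriginCluster:
    member_loci: frozenset
    mean_uv_frequency: float
    tolerance_used: float

    def __post_init__(self) -> None:
        if len(self.member_loci) < 2:
            raise ValueError("a co-origin cluster needs at least 2 loci")
        if not 0 <= self.mean_uv_frequency <= 1:
            raise ValueError("mean_uv_frequency must lie in [0, 1]")


def build_frequency_matrix(
    records: pd.DataFrame,
    round_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pivot long frequency records into a loci x rounds matrix.

    ``records`` needs columns locus_id, sample, frequency, detected.
    Undetected cells are stored as NaN (absent), never as zero.  Round
    columns follow ``round_order`` or first appearance.
    """
    required = {"locus_id", "sample", "frequency", "detected"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"frequency records missing columns: {sorted(missing)}")
    dupes = records.duplicated(subset=["locus_id", "sample"])
    if dupes.any():
        pairs = records.loc[dupes, ["locus_id", "sample"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (locus, round) records: {pairs}")
    vals = records.copy()
    vals.loc[~vals["detected"].astype(bool), "frequency"] = np.nan
    matrix = vals.pivot(index="locus_id", columns="sample", values="frequency")
    if round_order is None:
        round_order = list(dict.fromkeys(records["sample"]))
    matrix = matrix.reindex(columns=list(round_order))
    matrix = matrix.reindex(index=list(dict.fromkeys(records["locus_id"])))
    matrix.columns.name = "round"
    return matrix


def classify_trajectory(row: Sequence[float],
                        config: TrendConfig = TrendConfig()) -> str:
    """Assign one trend label to a frequency series.

    NaN cells (below detection) count as 0 in the comparisons; a series
    no round of which was detected is *not_detected*.
    """
    values = np.asarray(row, dtype=float)
    if values.size < 2:
        raise ValueError("a trajectory needs at least 2 rounds")
    if np.all(np.isnan(values)):
        return "not_detected"
    f = np.nan_to_num(values, nan=0.0)
    first, final = f[0], f[-1]
    margin = config.trend_margin
    if final > first + margin:
        return "rising"
    if final < first - margin:
        return "falling"
    interior = f[1:-1]
    if interior.size and interior.max() > max(first, final) + margin:
        return "transient"
    return "stable"


def classify_all_trajectories(matrix: pd.DataFrame,
                              config: TrendConfig = TrendConfig()) -> pd.DataFrame:
    """Trend labels plus endpoint frequencies for every matrix row."""
    rows = []
    for locus_id, row in matrix.iterrows():
        trend = classify_trajectory(row.to_numpy(), config)
        f = row.fillna(0.0)
        rows.append(
            {
                "locus_id": locus_id,
                "trend": trend,
                "first_frequency": f.iloc[0],
                "final_frequency": f.iloc[-1],
                "max_frequency": f.max(),
            }
        )
    return pd.DataFrame(rows)


def co_origin_clusters(
    uv_frequencies: Mapping[str, float],
    config: TrendConfig = TrendConfig(),
) -> list[CoOriginCluster]:
    """Group loci whose starting-pool frequencies are mutually close.

    Single-linkage clustering joins loci whose frequency gap chain stays
    within ``cluster_tolerance``; only clusters of two or more loci with
    mean frequency >= ``cluster_min_frequency`` are reported — rarer
    coincidences carry no co-origin signal.
    """
    items = [(lid, float(f)) for lid, f in uv_frequencies.items()]
    for lid, f in items:
        if not 0 <= f <= 1:
            raise ValueError(f"{lid}: frequency {f} outside [0, 1]")
    if len(items) < 2:
        return []
    ids = [lid for lid, _ in items]
    values = np.array([[f] for _, f in items])
    labels = fcluster(
        linkage(pdist(values), method="single"),
        t=config.cluster_tolerance,
        criterion="distance",
    )
    clusters = []
    for lab in np.unique(labels):
        members = [ids[i] for i in np.flatnonzero(labels == lab)]
        if len(members) < 2:
            continue
        mean = float(np.mean([dict(items)[m] for m in members]))
        if mean >= config.cluster_min_frequency:
            clusters.append(
                CoOriginCluster(
                    member_loci=frozenset(members),
                    mean_uv_frequency=mean,
                    tolerance_used=config.cluster_tolerance,
                )
            )
    clusters.sort(key=lambda c: (-c.mean_uv_frequency, sorted(c.member_loci)))
    return clusters


def isolate_allele_frequency(calls: pd.DataFrame, locus_id: str) -> float:
    """Allele frequency at one locus from diploid isolate genotypes.

    (2 * n_homo + n_het) / (2 * N) over an isolates x loci call matrix
    with values homo/het/none.
    """
    if calls.shape[0] == 0:
        raise ValueError("empty isolate matrix")
    col = calls[locus_id]
    n = len(col)
    n_homo = int((col == "homo").sum())
    n_het = int((col == "het").sum())
    return (2 * n_homo + n_het) / (2 * n)


def isolate_frequency_table(calls: pd.DataFrame) -> pd.Series:
    """Per-locus allele frequencies across all isolates."""
    return pd.Series(
        {lid: isolate_allele_frequency(calls, lid) for lid in calls.columns},
        name="isolate_frequency",
    )


def compare_population_vs_isolates(
    pop_freqs: Mapping[str, float],
    isolate_freqs: Mapping[str, float],
) -> tuple[pd.DataFrame, dict]:
    """Reconcile pool-sequencing and single-colony frequency estimates.

    Returns a paired per-locus table (pool, isolate, absolute deviation)
    over the shared loci plus summary statistics: mean/max absolute
    deviation and the Spearman rank correlation (NaN, flagged undefined,
    with fewer than two shared loci or zero variance).
    """
    pop = pd.Series(dict(pop_freqs), dtype=float)
    iso = pd.Series(dict(isolate_freqs), dtype=float)
    shared = pop.index.intersection(iso.index)
    if len(shared) == 0:
        raise ValueError("population and isolate locus sets are disjoint")
    table = pd.DataFrame(
        {
            "population_frequency": pop[shared],
            "isolate_frequency": iso[shared],
        }
    )
    table["abs_deviation"] = (
        table["population_frequency"] - table["isolate_frequency"]
    ).abs()
    table.index.name = "locus_id"
    if len(shared) >= 2 and pop[shared].nunique() > 1 and iso[shared].nunique() > 1:
        rho = float(spearmanr(table["population_frequency"], table["isolate_frequency"])[0])
        defined = not math.isnan(rho)
    else:
        rho, defined = float("nan"), False
    summary = {
        "n_shared_loci": int(len(shared)),
        "mean_abs_deviation": float(table["abs_deviation"].mean()),
        "max_abs_deviation": float(table["abs_deviation"].max()),
        "rank_correlation": rho,
        "rank_correlation_defined": defined,
    }
    return table, summary


def rank_candidates(trajectories: pd.DataFrame,
                    catalogue=None) -> pd.DataFrame:
    """Order loci by reverse-engineering interest.

    Rising trajectories first, then transient/stable, then falling and
    undetected; ties break by final-round frequency (descending) then by
    locus id.  If a mutation catalogue is given, gene and protein-change
    annotations are joined on locus id.
    """
    if trajectories.empty:
        return pd.DataFrame(
            columns=["rank", "locus_id", "trend", "final_frequency"]
        )
    df = trajectories.copy()
    df["_priority"] = df["trend"].map(_TREND_PRIORITY)
    df = df.sort_values(
        by=["_priority", "final_frequency", "locus_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).drop(columns="_priority")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    if catalogue is not None:
        ann = pd.DataFrame(
            {
                "locus_id": [r.locus_id for r in catalogue],
                "gene": [r.gene for r in catalogue],
                "protein_change": [r.protein_change or "." for r in catalogue],
            }
        )
        df = df.merge(ann, on="locus_id", how="left")
    return df.reset_index(drop=True)
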