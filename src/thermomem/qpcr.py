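"""Comparative-Ct quantification and trajectory clustering of qPCR panels.

Expression of each gene is scored as ``40 - dCt`` where ``dCt`` is the Ct
difference from a reference gene within the same sample (higher score = more
transcript).  Log2 fold change between two treatment arms at a shared
timepoint is then simply the difference of the two scores, since both are on
a log2 scale.  Genes are called differentially expressed when the fold change
passes a threshold (1.5-fold by default, boundary inclusive) at any
timepoint, and per-gene trajectories are grouped by k-means.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionProfiles",
    "ClusterAssignment",
    "QpcrInputError",
    "compute_expression",
    "fold_change_profile",
    "call_differential",
    "cluster_profiles",
]

DEFAULT_CEILING = 38.0


class QpcrInputError(ValueError):
    """Invalid Ct table or incompatible arms/timepoints."""


@dataclass
class ExpressionProfiles:
    """Per-(gene, arm, timepoint) expression scores.

    ``expression`` holds 40-dCt averaged over biological replicates (technical
    replicates are arithmetic-mean aggregated first); ``undetectable`` maps
    each arm to the genes whose Ct never dropped below the detection ceiling
    in any sample of that arm.
    """

    expression: pd.DataFrame  # MultiIndex rows (gene_id), columns (arm, timepoint)
    undetectable: dict[str, set[str]]
    reference_gene: str
    ceiling: float


def compute_expression(
    ct: pd.DataFrame,
    reference_gene: str,
    ceiling: float = DEFAULT_CEILING,
) -> ExpressionProfiles:
    """Comparative-Ct expression scores from a long-format Ct table.

    Required columns: sample_id, arm, timepoint, gene_id, ct.  Per sample,
    technical replicates are averaged, dCt = Ct_gene - Ct_reference, and the
    score is 40 - dCt; scores are then averaged across the samples of each
    (arm, timepoint).  Samples missing a gene are excluded for that gene with
    a logged warning; a sample missing the reference gene is an error.
    """
    required = {"sample_id", "arm", "timepoint", "gene_id", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise QpcrInputError(f"Ct table missing columns: {sorted(missing)}")

    per_sample = (
        ct.groupby(["sample_id", "arm", "timepoint", "gene_id"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    ref = per_sample[per_sample["gene_id"] == reference_gene].set_index("sample_id")
    all_samples = per_sample["sample_id"].unique()
    missing_ref = set(all_samples) - set(ref.index)
    if missing_ref:
        raise QpcrInputError(
            f"reference gene {reference_gene!r} missing in samples: "
            f"{sorted(missing_ref)[:5]}"
        )

    gene_rows = per_sample[per_sample["gene_id"] != reference_gene].copy()
    gene_rows["dct"] = gene_rows["ct"].to_numpy() - ref.loc[
        gene_rows["sample_id"], "ct"
    ].to_numpy()
    gene_rows["expression"] = 40.0 - gene_rows["dct"]

    n_expected = len(all_samples)
    counts = gene_rows.groupby("gene_id")["sample_id"].nunique()
    partial = counts[counts < n_expected]
    if len(partial):
        logger.warning(
            "genes measured in only a subset of samples (excluded there): %s",
            list(partial.index[:5]),
        )

    expr = (
        gene_rows.groupby(["gene_id", "arm", "timepoint"], sort=False)["expression"]
        .mean()
        .unstack(["arm", "timepoint"])
    )
    # order columns by appearance in the input
    arms = list(dict.fromkeys(ct["arm"]))
    tps = list(dict.fromkeys(ct["timepoint"]))
    expr = expr.reindex(
        columns=pd.MultiIndex.from_product([arms, tps], names=["arm", "timepoint"]),
    )

    undetectable: dict[str, set[str]] = {}
    for arm in arms:
        arm_rows = gene_rows[gene_rows["arm"] == arm]
        detected = arm_rows.loc[arm_rows["ct"] < ceiling, "gene_id"].unique()
        undetectable[arm] = set(expr.index) - set(detected)

    return ExpressionProfiles(
        expression=expr,
        undetectable=undetectable,
        reference_gene=reference_gene,
        ceiling=ceiling,
    )


def fold_change_profile(
    profiles: ExpressionProfiles, case_arm: str, comparator_arm: str
) -> tuple[pd.DataFrame, set[str]]:
    """Per-timepoint log2 ratios of case vs comparator arm.

    The comparator is taken at the same clock time.  Returns (genes x
    timepoints log2-ratio frame, flagged genes).  A gene is flagged — and its
    ratios withheld — when it is undetectable in either arm (including the
    case where the comparator alone is undetectable: the ratio would be
    unbounded, not large).
    """
    expr = profiles.expression
    for arm in (case_arm, comparator_arm):
        if arm not in expr.columns.get_level_values("arm"):
            raise QpcrInputError(f"arm {arm!r} not present in profiles")
    case = expr[case_arm]
    comp = expr[comparator_arm]
    shared = [tp for tp in case.columns if tp in set(comp.columns)]
    shared = [
        tp for tp in shared
        if case[tp].notna().any() and comp[tp].notna().any()
    ]
    if not shared:
        raise QpcrInputError(
            f"arms {case_arm!r} and {comparator_arm!r} share no timepoints"
        )
    ratios = case[shared] - comp[shared]
    flagged = profiles.undetectable.get(case_arm, set()) | profiles.undetectable.get(
        comparator_arm, set()
    )
    ratios.loc[ratios.index.isin(flagged)] = np.nan
    ratios.columns.name = "timepoint"
    return ratios, flagged


def call_differential(
    ratios: pd.DataFrame,
    undetectable: set[str] | None = None,
    threshold_fold: float = 1.5,
) -> dict[str, set[str]]:
    """Partition the panel into up / down / unchanged / undetectable.

    A gene is differentially expressed when |log2 ratio| >= log2(threshold)
    at >=1 timepoint (boundary inclusive); the direction comes from the sign
    at the timepoint of maximal |ratio|.  The four sets are disjoint and
    cover the assayed panel.
    """
    if threshold_fold <= 1:
        raise QpcrInputError(
            f"threshold_fold must be > 1, got {threshold_fold}"
        )
    undetectable = set(undetectable or ())
    cut = np.log2(threshold_fold)
    up: set[str] = set()
    down: set[str] = set()
    unchanged: set[str] = set()
    for gid, row in ratios.iterrows():
        if gid in undetectable:
            continue
        vals = row.dropna()
        if len(vals) == 0:
            undetectable.add(gid)
            continue
        amax = vals.abs().max()
        if amax >= cut:
            (up if vals[vals.abs().idxmax()] > 0 else down).add(gid)
        else:
            unchanged.add(gid)
    return {
        "up": up,
        "down": down,
        "unchanged": unchanged,
        "undetectable": undetectable,
    }


@dataclass
class ClusterAssignment:
    """k-means result over per-gene log2-ratio trajectories."""

    labels: pd.Series  # gene_id -> cluster label in 1..k
    k: int
    seed: int
    inertia: float
    centers: pd.DataFrame  # cluster label x timepoint

    def genes_in(self, label: int) -> set[str]:
        return set(self.labels.index[self.labels == label])


def cluster_profiles(
    ratios: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = 25,
    impute_missing: bool = True,
) -> ClusterAssignment:
    """k-means (Euclidean, best of ``n_restarts``) on trajectory vectors.

    Genes with isolated missing timepoints are mean-imputed (column mean);
    genes with no observed values are dropped.  Cluster labels are renumbered
    1..k in decreasing cluster-size order so runs are comparable.
    """
    x = ratios.copy()
    x = x.dropna(how="all")
    if impute_missing:
        x = x.fillna(x.mean(axis=0))
    else:
        x = x.dropna()
    if len(x) < k:
        raise QpcrInputError(
            f"need >= k={k} complete profiles, have {len(x)}"
        )
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(x.to_numpy())
    # relabel by decreasing cluster size (ties by original label for determinism)
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], lab))
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = pd.Series([remap[r] for r in raw], index=x.index, name="cluster")
    centers = pd.DataFrame(
        km.cluster_centers_[order], index=range(1, k + 1), columns=x.columns
    )
    return ClusterAssignment(
        labels=labels, k=k, seed=seed, inertia=float(km.inertia_), centers=centers
    )
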