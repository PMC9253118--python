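"""Weighted co-expression network: soft threshold, TOM, modules, enrichment.

Adjacency is a power of the gene-gene Pearson correlation (unsigned by
default: ``a_ij = |cor|^beta``), the topological overlap measure (TOM) folds
in shared neighbourhoods, modules come from average-linkage clustering of
``1 - TOM`` with a static tree cut, and TF-target overrepresentation per
module is an upper-tail hypergeometric test with BH correction across all
module x target-set tests.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .diffexpr import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "ModulePartition",
    "CoexprError",
    "soft_power_scan",
    "build_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_enrichment",
]


class CoexprError(ValueError):
    """Invalid network configuration or degenerate expression input."""


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the weighted network and module detection.

    ``soft_power`` defaults to 6 (the exponent at which scale-free topology
    is typically reached for this kind of design); ``cut_height`` is the
    static tree-cut level on the 1-TOM dendrogram, and clusters smaller than
    ``min_module_size`` are relabelled 0 (unassigned).
    """

    soft_power: float = 6.0
    signed: bool = False
    min_module_size: int = 30
    cut_height: float = 0.99
    power_grid: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16)

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise CoexprError("soft_power must be >= 1")
        if self.min_module_size < 3:
            raise CoexprError("min_module_size must be >= 3")
        if not 0 < self.cut_height < 1:
            raise CoexprError("cut_height must be in (0, 1)")


def _correlation(expr: pd.DataFrame) -> np.ndarray:
    arr = expr.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        raise CoexprError(
            f"constant gene rows: {list(expr.index[sd == 0][:5])}"
        )
    cor = np.corrcoef(arr)
    if not np.isfinite(cor).all():
        bad = np.unique(np.where(~np.isfinite(cor))[0])
        raise CoexprError(
            f"non-finite correlations involving genes: {list(expr.index[bad][:5])}"
        )
    return cor


def build_adjacency(
    expr: pd.DataFrame, config: NetworkConfig | None = None
) -> pd.DataFrame:
    """Soft-thresholded adjacency from gene x sample expression.

    Unsigned: ``a_ij = |cor(g_i, g_j)|^beta``; signed:
    ``a_ij = ((1 + cor)/2)^beta``; unit diagonal.
    """
    config = config or NetworkConfig()
    cor = _correlation(expr)
    if config.signed:
        a = ((1.0 + cor) / 2.0) ** config.soft_power
    else:
        a = np.abs(cor) ** config.soft_power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit index of a connectivity distribution.

    R^2 of log10(frequency) on log10(mean connectivity) over equal-width
    bins, signed so that a positive slope (anti-scale-free) is penalised:
    index = -sign(slope) * R^2.  Empty or zero-frequency bins are dropped.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / len(k)))
    if len(xs) < 3:
        return float("nan")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)


def soft_power_scan(
    expr: pd.DataFrame, config: NetworkConfig | None = None
) -> pd.DataFrame:
    """Scale-free fit index and mean connectivity per candidate power.

    Constant gene rows are dropped with a warning before the correlation.
    """
    config = config or NetworkConfig()
    arr = expr.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        logger.warning(
            "dropping %d constant gene rows before power scan", int((sd == 0).sum())
        )
        expr = expr.loc[sd > 0]
    if len(expr) < 50:
        raise CoexprError("need >= 50 variable genes for the power scan")
    cor = np.abs(_correlation(expr))
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in config.power_grid:
        a = cor**beta
        k = a.sum(axis=1)
        rows.append(
            {
                "power": beta,
                "fit_index": scale_free_fit(k),
                "mean_connectivity": float(k.mean()),
            }
        )
    return pd.DataFrame(rows)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity of a symmetric adjacency in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j with k_i = sum_{u != i} a_iu, and TOM_ii = 1.
    """
    a = adjacency.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise CoexprError("adjacency must be square symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise CoexprError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # includes u = i and u = j terms which are 0 off-diagonal
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    assert (den > 0).all(), "TOM denominator must be positive"
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


@dataclass
class ModulePartition:
    """Module labels (0 = unassigned) with per-module eigengenes."""

    labels: pd.Series                  # gene -> module label
    eigengenes: pd.DataFrame           # samples x modules ("ME1", ...)
    n_modules: int

    def genes_in(self, label: int) -> set[str]:
        return set(self.labels.index[self.labels == label])

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def detect_modules(
    tom: pd.DataFrame,
    expr: pd.DataFrame,
    config: NetworkConfig | None = None,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static tree cut.

    Clusters smaller than ``min_module_size`` are relabelled 0; surviving
    modules are renumbered 1..M in decreasing size order.  Each module's
    eigengene is the first principal component of its standardised
    expression, sign-anchored so the mean gene loading is positive.
    """
    config = config or NetworkConfig()
    d = 1.0 - tom.to_numpy()
    np.fill_diagonal(d, 0.0)
    z = average(squareform(np.clip(d, 0.0, None), checks=False))
    raw = fcluster(z, t=config.cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= config.min_module_size]
    order = sorted(keep.index, key=lambda lab: (-keep[lab], lab))
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = pd.Series(
        [remap.get(r, 0) for r in raw], index=tom.index, name="module"
    )

    eig = {}
    expr = expr.loc[tom.index]
    for m in range(1, len(order) + 1):
        sub = expr.loc[labels.index[labels == m]].to_numpy(dtype=float)
        sub = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
        # first right singular vector over samples
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        pc1 = vt[0]
        loadings = sub @ pc1
        if loadings.mean() < 0:
            pc1 = -pc1
        eig[f"ME{m}"] = pc1
    eigengenes = pd.DataFrame(eig, index=expr.columns)
    return ModulePartition(labels=labels, eigengenes=eigengenes,
                           n_modules=len(order))


def module_enrichment(
    partition: ModulePartition,
    target_sets: dict[str, set[str]],
    universe: set[str] | None = None,
    include_intersection: bool = True,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of TF targets in each module.

    The universe defaults to the genes in the partition; target genes outside
    it are dropped with a warning.  When several TFs are given and
    ``include_intersection`` is set, the intersection set (genes targeted by
    all TFs) is tested as well.  BH adjustment is applied jointly across all
    module x set tests.  Upper-tail p: P(X >= x) for x of K targets in a
    module of n drawn from N.
    """
    universe = set(partition.labels.index) if universe is None else set(universe)
    N = len(universe)
    sets = dict(target_sets)
    if include_intersection and len(target_sets) > 1:
        inter = set.intersection(*target_sets.values())
        sets["&".join(sorted(target_sets))] = inter

    rows = []
    for set_name, targets in sets.items():
        outside = targets - universe
        if outside:
            logger.warning(
                "%s: %d target genes outside the universe dropped",
                set_name, len(outside),
            )
        targets = targets & universe
        K = len(targets)
        for m in sorted(set(partition.labels) - {0}):
            module_genes = partition.genes_in(m) & universe
            n = len(module_genes)
            x = len(module_genes & targets)
            p = float(stats.hypergeom.sf(x - 1, N, K, n))
            rows.append(
                {"module": m, "set": set_name, "overlap": x, "module_size": n,
                 "n_targets": K, "universe": N, "p": min(p, 1.0)}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = benjamini_hochberg(out["p"].to_numpy())
    return out
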