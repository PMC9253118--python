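"""Synthetic inputs with planted ground truth.

Everything the downstream pipeline consumes can be generated here: a
negative-binomial RNA-seq count matrix over a full genotype x condition x
timepoint factorial, a long-format qPCR Ct table for a TF panel, GFF3 gene
models on one synthetic chromosome, and narrowPeak TF-binding intervals.  The
generator records exactly what it planted (direct targets and their
interaction directions and affected timepoints, co-expression module labels,
promoter-peak qualifications, trajectory archetypes), so every downstream
stage has a recovery oracle.

Count model
-----------
For gene ``g`` in sample ``s`` the log2 relative abundance is

    mu_gs = b_g + h_{g,t}*heat_s + sigma*I[target, affected tp]*lfc*heat_s
            + lambda * z_{m(g), s}

with baseline ``b_g ~ U(1, 9)``, per-timepoint heat effects
``h_{g,t} ~ N(0, heat_effect_sd)`` shared across genotypes, a planted
heat x genotype interaction of magnitude ``target_interaction_lfc`` applied
with opposite sign in the overexpressor (OE) and knockout (KO) genotypes
(activated targets: up in OE, down in KO), and a per-module latent factor
``z`` inducing within-module correlation.  Baseline relative abundances
are normalised once (so planted effects pass into count means exactly),
scaled by a log-normal library size, and counts are drawn negative-binomial
with variance ``mu + dispersion * mu^2``.
"""
from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneModel, PeakRecord, write_peaks

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "TargetSpec",
    "ConfigurationError",
    "plant_truth",
    "simulate_counts",
    "simulate_ct_table",
    "simulate_annotation_and_peaks",
    "write_gff3",
    "write_truth_json",
]

GENOTYPES = ("WT", "OE", "KO")
CONDITIONS = ("control", "heat")
TIMEPOINTS = ("0h", "1h", "4h")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic data.

    Defaults mirror the emulated study design: 3 genotypes (wild type, TF
    overexpressor, TF knockout) x 2 conditions x 3 post-priming timepoints
    with 3 biological replicates per cell, 2000 genes of which 50 are planted
    direct targets with a log2 interaction effect of 2, and a 1000-bp
    upstream promoter window for binding-peak qualification.
    """

    n_genes: int = 2000
    n_direct_targets: int = 50
    n_modules: int = 4
    module_sizes: tuple[int, ...] | None = None
    genotypes: tuple[str, ...] = GENOTYPES
    conditions: tuple[str, ...] = CONDITIONS
    timepoints: tuple[str, ...] = TIMEPOINTS
    replicates: int = 3
    lib_size_mean: float = 5e6
    nb_dispersion: float = 0.02
    heat_effect_sd: float = 1.0
    target_interaction_lfc: float = 2.0
    p_all_timepoints: float = 0.4
    module_latent_sd: float = 0.6
    ct_noise_sd: float = 0.15
    n_ct_genes: int = 104
    n_ct_clusters: int = 5
    n_ct_undetectable: int = 29
    ct_timepoints: tuple[str, ...] = ("0h", "1h", "2h", "4h", "24h", "48h")
    ct_technical_replicates: int = 2
    n_decoy_peaks: int = 100
    promoter_window: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            sizes = tuple([50] * self.n_modules)
            object.__setattr__(self, "module_sizes", sizes)
        else:
            object.__setattr__(self, "module_sizes", tuple(self.module_sizes))
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1 or self.replicates < 1 or self.n_ct_genes < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.n_direct_targets < 0 or self.n_direct_targets > self.n_genes:
            raise ConfigurationError(
                f"n_direct_targets must be in [0, n_genes], got {self.n_direct_targets}"
            )
        if len(self.module_sizes) != self.n_modules:
            raise ConfigurationError("module_sizes length must equal n_modules")
        if any(s < 1 for s in self.module_sizes):
            raise ConfigurationError("module sizes must be >= 1")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError("sum(module_sizes) exceeds n_genes")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.promoter_window <= 0:
            raise ConfigurationError("promoter_window must be > 0")
        if not 0.0 <= self.p_all_timepoints <= 1.0:
            raise ConfigurationError("p_all_timepoints must be in [0, 1]")
        if self.n_ct_undetectable > self.n_ct_genes:
            raise ConfigurationError("n_ct_undetectable exceeds n_ct_genes")
        for geno in ("WT", "OE", "KO"):
            if geno not in self.genotypes:
                raise ConfigurationError(f"genotypes must include {geno}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TargetSpec:
    """Planted direct target: regulation direction and affected timepoints."""

    gene_id: str
    direction: str  # "activated" | "repressed"
    timepoints: tuple[str, ...]


@dataclass
class PlantedTruth:
    """Everything the generator planted, for downstream recovery checks."""

    config: SimulationConfig
    genes: list[GeneModel]
    direct_targets: dict[str, TargetSpec]
    module_assignments: dict[str, int]  # gene -> module label, 0 = none
    heat_effects: pd.DataFrame  # genes x timepoints, log2 units
    peaks: list[PeakRecord]
    peak_qualifies: dict[str, bool]  # peak name -> planted promoter flag
    ct_genes: list[str]
    ct_trajectories: pd.DataFrame  # ct genes x ct timepoints, log2 FC
    ct_cluster_labels: dict[str, int]
    ct_undetectable: set[str]

    @property
    def target_ids(self) -> set[str]:
        return set(self.direct_targets)


REFERENCE_GENE = "ACTIN2"
CT_DETECTION_CEILING = 38.0
_CT_REF_LEVEL = 20.0


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def plant_truth(config: SimulationConfig) -> PlantedTruth:
    """Draw the planted truth (deterministic for a fixed config seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids = _gene_ids(config.n_genes)

    # --- gene models on one synthetic chromosome, non-overlapping, both strands
    genes: list[GeneModel] = []
    cursor = config.promoter_window + 500
    for gid in ids:
        length = int(rng.integers(800, 3001))
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor
        end = start + length - 1
        genes.append(GeneModel(gene_id=gid, chrom="chr1", strand=strand,
                               start=start, end=end))
        gap = int(rng.integers(2 * config.promoter_window + 400,
                               2 * config.promoter_window + 1200))
        cursor = end + gap
    gene_by_id = {g.gene_id: g for g in genes}

    # --- direct targets: half activated / half repressed, >=2 affected timepoints
    target_ids = sorted(rng.choice(ids, size=config.n_direct_targets, replace=False))
    direct_targets: dict[str, TargetSpec] = {}
    for i, gid in enumerate(target_ids):
        direction = "activated" if i % 2 == 0 else "repressed"
        if rng.random() < config.p_all_timepoints:
            tps = tuple(config.timepoints)
        else:
            keep = sorted(rng.choice(len(config.timepoints), size=2, replace=False))
            tps = tuple(config.timepoints[j] for j in keep)
        direct_targets[gid] = TargetSpec(gene_id=gid, direction=direction,
                                         timepoints=tps)

    # --- module assignments (disjoint blocks of genes)
    module_assignments = {gid: 0 for gid in ids}
    pool = list(rng.permutation(ids))
    for m, size in enumerate(config.module_sizes, start=1):
        for gid in pool[:size]:
            module_assignments[gid] = m
        pool = pool[size:]

    # --- heat effects shared across genotypes (log2)
    heat_effects = pd.DataFrame(
        rng.normal(0.0, config.heat_effect_sd,
                   size=(config.n_genes, len(config.timepoints))),
        index=ids, columns=list(config.timepoints),
    )

    # --- promoter peaks for targets, decoys far from every TSS
    peaks: list[PeakRecord] = []
    peak_qualifies: dict[str, bool] = {}
    w = config.promoter_window
    for k, gid in enumerate(target_ids):
        g = gene_by_id[gid]
        width = int(rng.integers(150, 301))
        if g.strand == "+":
            s1 = int(rng.integers(g.tss - w + 1, g.tss - width))
        else:
            s1 = int(rng.integers(g.tss + 1, g.tss + w - width))
        name = f"peak_t{k:04d}"
        peaks.append(PeakRecord(chrom="chr1", start=s1 - 1, end=s1 - 1 + width,
                                name=name, score=500, strand=".",
                                signal=float(rng.uniform(5, 50)),
                                summit=width // 2))
        peak_qualifies[name] = True
    # decoys: in intergenic gaps, > window bp from both flanking TSSs
    n_placed = 0
    gap_order = rng.permutation(len(genes) - 1)
    for idx in gap_order:
        if n_placed >= config.n_decoy_peaks:
            break
        prev_g, next_g = genes[idx], genes[idx + 1]
        width = int(rng.integers(150, 301))
        lo = prev_g.end + w + 1
        hi = next_g.start - w - 1 - width
        if hi <= lo:
            continue
        s1 = int(rng.integers(lo, hi + 1))
        name = f"peak_d{n_placed:04d}"
        peaks.append(PeakRecord(chrom="chr1", start=s1 - 1, end=s1 - 1 + width,
                                name=name, score=200, strand=".",
                                signal=float(rng.uniform(1, 10)),
                                summit=width // 2))
        peak_qualifies[name] = False
        n_placed += 1

    # --- qPCR panel: archetype trajectories plus per-gene jitter
    ct_genes = [f"NAC{i:03d}" for i in range(1, config.n_ct_genes + 1)]
    n_tp = len(config.ct_timepoints)
    archetypes = rng.normal(0.0, 2.0, size=(config.n_ct_clusters, n_tp))
    labels = rng.integers(1, config.n_ct_clusters + 1, size=config.n_ct_genes)
    traj = archetypes[labels - 1] + rng.normal(0.0, 0.3,
                                               size=(config.n_ct_genes, n_tp))
    ct_trajectories = pd.DataFrame(traj, index=ct_genes,
                                   columns=list(config.ct_timepoints))
    ct_cluster_labels = dict(zip(ct_genes, (int(x) for x in labels)))
    undet = set(
        rng.choice(ct_genes, size=config.n_ct_undetectable, replace=False).tolist()
    )

    return PlantedTruth(
        config=config,
        genes=genes,
        direct_targets=direct_targets,
        module_assignments=module_assignments,
        heat_effects=heat_effects,
        peaks=peaks,
        peak_qualifies=peak_qualifies,
        ct_genes=ct_genes,
        ct_trajectories=ct_trajectories,
        ct_cluster_labels=ct_cluster_labels,
        ct_undetectable=undet,
    )


def make_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for geno in config.genotypes:
        for cond in config.conditions:
            for tp in config.timepoints:
                for rep in range(1, config.replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{geno}_{cond}_{tp}_r{rep}",
                            "genotype": geno,
                            "condition": cond,
                            "timepoint": tp,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(
    config: SimulationConfig, truth: PlantedTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix (genes x samples) plus sample sheet."""
    rng = np.random.default_rng([config.seed, 17])
    sheet = make_sample_sheet(config)
    ids = [g.gene_id for g in truth.genes]
    n_samples = len(sheet)

    baseline = rng.uniform(1.0, 9.0, size=config.n_genes)
    mu = np.tile(baseline[:, None], (1, n_samples))

    tp_index = {tp: j for j, tp in enumerate(config.timepoints)}
    heat_fx = truth.heat_effects.to_numpy()
    gene_pos = {gid: i for i, gid in enumerate(ids)}

    # module latent factors (log2 scale)
    n_modules = len(config.module_sizes)
    z = rng.normal(0.0, 1.0, size=(n_modules, n_samples))

    for s, (sid, row) in enumerate(sheet.iterrows()):
        is_heat = row["condition"] == "heat"
        tj = tp_index[row["timepoint"]]
        if is_heat:
            mu[:, s] += heat_fx[:, tj]
            for gid, spec in truth.direct_targets.items():
                if row["timepoint"] in spec.timepoints:
                    sign = 1.0 if spec.direction == "activated" else -1.0
                    if row["genotype"] == "OE":
                        mu[gene_pos[gid], s] += sign * config.target_interaction_lfc
                    elif row["genotype"] == "KO":
                        mu[gene_pos[gid], s] -= sign * config.target_interaction_lfc
    for gid, m in truth.module_assignments.items():
        if m > 0:
            mu[gene_pos[gid], :] += config.module_latent_sd * z[m - 1, :]

    # baseline relative abundances are normalised once (not per sample), so
    # planted effects translate into count means exactly: mean = lib * b * 2^eff
    rel = np.exp2(mu)
    rel /= np.exp2(baseline).sum()
    lib = rng.lognormal(mean=np.log(config.lib_size_mean), sigma=0.1,
                        size=n_samples)
    mean = rel * lib[None, :]

    alpha = config.nb_dispersion
    if alpha < 1e-8:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / alpha
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts.astype(np.int64), index=ids,
                             columns=sheet.index.tolist())
    return counts_df, sheet.reset_index()


def simulate_ct_table(
    config: SimulationConfig,
    truth: PlantedTruth,
    arms: tuple[str, str] = ("control", "primed"),
    n_bio_replicates: int = 3,
) -> pd.DataFrame:
    """Long-format Ct table for the TF panel.

    The second arm carries the planted log2 fold-change trajectories relative
    to the first (Ct drops by the planted log2 FC: a 4-fold induction lowers
    Ct by exactly 2 cycles at zero noise).  A stable reference gene is
    included in every sample; undetectable genes sit above the detection
    ceiling everywhere.
    """
    rng = np.random.default_rng([config.seed, 29])
    base_dct = rng.uniform(5.0, 12.0, size=config.n_ct_genes)
    rows = []
    for arm_i, arm in enumerate(arms):
        for tp in config.ct_timepoints:
            for rep in range(1, n_bio_replicates + 1):
                sid = f"{arm}_{tp}_r{rep}"
                for tech in range(1, config.ct_technical_replicates + 1):
                    ref_ct = _CT_REF_LEVEL + rng.normal(0.0, config.ct_noise_sd)
                    rows.append(
                        {"sample_id": sid, "arm": arm, "timepoint": tp,
                         "replicate": rep, "tech_rep": tech,
                         "gene_id": REFERENCE_GENE, "ct": ref_ct}
                    )
                    for gi, gid in enumerate(truth.ct_genes):
                        if gid in truth.ct_undetectable:
                            ct = CT_DETECTION_CEILING + 1.0 + abs(
                                rng.normal(0.0, 0.3)
                            )
                        else:
                            lfc = (
                                truth.ct_trajectories.loc[gid, tp]
                                if arm_i == 1
                                else 0.0
                            )
                            ct = (
                                ref_ct
                                + base_dct[gi]
                                - lfc
                                + rng.normal(0.0, config.ct_noise_sd)
                            )
                        rows.append(
                            {"sample_id": sid, "arm": arm, "timepoint": tp,
                             "replicate": rep, "tech_rep": tech,
                             "gene_id": gid, "ct": ct}
                        )
    return pd.DataFrame(rows)


def write_gff3(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [g.chrom, "thermomem_sim", "gene", str(g.start), str(g.end),
                     ".", g.strand, ".", f"ID={g.gene_id}"]
                )
                + "\n"
            )


def simulate_annotation_and_peaks(
    config: SimulationConfig,
    truth: PlantedTruth,
    gff3_path: str | os.PathLike,
    peaks_path: str | os.PathLike,
) -> None:
    """Write the planted gene models (GFF3) and peaks (narrowPeak) to disk."""
    write_gff3(truth.genes, gff3_path)
    write_peaks(truth.peaks, peaks_path)


def write_truth_json(truth: PlantedTruth, path: str | os.PathLike) -> None:
    payload = {
        "config": truth.config.to_dict(),
        "direct_targets": {
            gid: {"direction": t.direction, "timepoints": list(t.timepoints)}
            for gid, t in truth.direct_targets.items()
        },
        "module_assignments": truth.module_assignments,
        "peak_qualifies": truth.peak_qualifies,
        "tss": {g.gene_id: {"tss": g.tss, "strand": g.strand}
                for g in truth.genes},
        "ct_cluster_labels": truth.ct_cluster_labels,
        "ct_undetectable": sorted(truth.ct_undetectable),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def simulate_module_expression(
    n_per_module: tuple[int, ...],
    n_noise: int,
    n_samples: int,
    within_cor: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Gaussian log-scale expression with planted co-expression modules.

    Genes in module ``m`` share a latent sample factor so that the expected
    pairwise within-module correlation is ``within_cor``; across modules and
    for noise genes the expected correlation is 0.  Returns (genes x samples
    matrix, gene -> planted module label with 0 for noise genes).
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], {}
    gidx = 0
    for m, size in enumerate(n_per_module, start=1):
        z = rng.normal(size=n_samples)
        for _ in range(size):
            gid = f"MG{gidx:04d}"
            gidx += 1
            eps = rng.normal(size=n_samples)
            rows.append(np.sqrt(within_cor) * z + np.sqrt(1 - within_cor) * eps)
            labels[gid] = m
    for _ in range(n_noise):
        gid = f"MG{gidx:04d}"
        gidx += 1
        rows.append(rng.normal(size=n_samples))
        labels[gid] = 0
    expr = pd.DataFrame(
        np.asarray(rows),
        index=list(labels),
        columns=[f"S{j:03d}" for j in range(n_samples)],
    )
    return expr, labels
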