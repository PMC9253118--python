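"""End-to-end orchestration: simulated inputs -> candidate direct targets.

Glues the stages together the way a real analysis would run them: counts ->
precision-weighted normalised expression -> per-gene moderated linear models
-> interaction contrasts with a global BH decision -> discordance filter ->
promoter-binding filter -> timepoint-commonality filter.  Used by the
acceptance checks for planted-truth recovery and available as a library
entry point.
"""
from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass

import pandas as pd

from . import annotation, targets as targets_mod
from .diffexpr import GeneExpressionLM, decide_global
from .simulate import (
    SimulationConfig,
    PlantedTruth,
    plant_truth,
    simulate_annotation_and_peaks,
    simulate_counts,
)
from .targets import DecisionCube

__all__ = ["TargetRecoveryResult", "run_target_recovery", "call_targets"]


@dataclass
class TargetRecoveryResult:
    """Predicted candidate targets with planted-truth comparison metrics."""

    predicted: set[str]
    truth: set[str]
    candidates: dict
    precision: float
    recall: float
    f1: float
    n_bound: int
    results: list


def _f1(predicted: set[str], truth: set[str]) -> tuple[float, float, float]:
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth) if truth else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def call_targets(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    bound_genes: set[str],
    timepoints: tuple[str, ...] = ("0h", "1h", "4h"),
    alpha: float = 0.05,
    lfc: float = 0.0,
    min_timepoints: int = 2,
) -> tuple[dict, list]:
    """DE + discordance + binding + commonality target calls from counts."""
    model = GeneExpressionLM.from_counts(counts, sheet)
    res = model.fit()
    results = []
    keyed = {}
    for tp in timepoints:
        for geno in ("OE", "KO"):
            r = res.interaction_contrast(geno, "WT", tp)
            results.append(r)
            keyed[(f"{geno}_vs_WT", tp)] = r
    decide_global(results, alpha=alpha, lfc=lfc)
    cube = DecisionCube.from_results(keyed)
    discordant = {
        tp: targets_mod.discordant_by_genotype(cube, tp) for tp in timepoints
    }
    candidates = targets_mod.candidate_direct_targets(discordant, bound_genes)
    common = targets_mod.commonality_filter(
        candidates, min_timepoints=min_timepoints, n_timepoints=len(timepoints)
    )
    return common, results


def run_target_recovery(
    config: SimulationConfig,
    alpha: float = 0.05,
    lfc: float = 0.0,
    min_timepoints: int = 2,
    workdir: str | os.PathLike | None = None,
) -> TargetRecoveryResult:
    """Simulate a study under ``config`` and recover the planted targets.

    The annotation stage runs through files: the planted gene models and
    peaks are written to GFF3/narrowPeak and parsed back, exercising the same
    round trip a real analysis performs.
    """
    truth = plant_truth(config)
    counts, sheet = simulate_counts(config, truth)

    with tempfile.TemporaryDirectory() as tmp:
        outdir = str(workdir) if workdir is not None else tmp
        gff = os.path.join(outdir, "genes.gff3")
        npk = os.path.join(outdir, "peaks.narrowPeak")
        simulate_annotation_and_peaks(config, truth, gff, npk)
        genes = annotation.parse_gene_models(gff)
        peaks = annotation.parse_peaks(npk)
    bound = annotation.promoter_bound_genes(
        peaks, genes, window=config.promoter_window
    )

    common, results = call_targets(
        counts,
        sheet,
        bound,
        timepoints=config.timepoints,
        alpha=alpha,
        lfc=lfc,
        min_timepoints=min_timepoints,
    )
    predicted = set(common)
    truth_ids = truth.target_ids
    precision, recall, f1 = _f1(predicted, truth_ids)
    return TargetRecoveryResult(
        predicted=predicted,
        truth=truth_ids,
        candidates=common,
        precision=precision,
        recall=recall,
        f1=f1,
        n_bound=len(bound),
        results=results,
    )
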