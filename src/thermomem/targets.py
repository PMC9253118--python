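"""Candidate direct-target calling from DE decisions and binding evidence.

The logic mirrors the genetic argument: a gene is a candidate direct target
of the TF when its heat response depends on TF dosage in opposite directions
in the overexpressor (OE) and knockout (KO) genotypes (discordance on the
second-order interaction contrasts), when its promoter carries a binding
peak, and when the discordance recurs at at least 2 of the 3 post-priming
timepoints.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import ModeratedTestResult

__all__ = [
    "DecisionCube",
    "CandidateTarget",
    "TargetsInputError",
    "heat_response_sets",
    "priming_associated_sets",
    "discordant_by_genotype",
    "candidate_direct_targets",
    "commonality_filter",
]


class TargetsInputError(ValueError):
    """Missing contrast/timepoint or invalid configuration."""


class DecisionCube:
    """Decisions and logFCs indexed by gene x (contrast name, timepoint).

    Contrast naming convention: ``heat_<genotype>`` for the within-genotype
    heat response and ``<genotype>_vs_WT`` for the genotype-dependent
    response (interaction) contrasts.
    """

    def __init__(self, decisions: pd.DataFrame, logfc: pd.DataFrame):
        if not decisions.columns.equals(logfc.columns) or not decisions.index.equals(
            logfc.index
        ):
            raise TargetsInputError("decision and logFC frames must align")
        self.decisions = decisions
        self.logfc = logfc

    @classmethod
    def from_results(
        cls, results: dict[tuple[str, str], ModeratedTestResult]
    ) -> "DecisionCube":
        """Build from decided test results keyed by (contrast, timepoint)."""
        dec, lfc = {}, {}
        for key, r in results.items():
            if "decision" not in r.table.columns:
                raise TargetsInputError(
                    f"result {r.name!r} has no decisions; run decide_global first"
                )
            dec[key] = r.table["decision"]
            lfc[key] = r.table["logFC"]
        decisions = pd.DataFrame(dec)
        logfc = pd.DataFrame(lfc)
        decisions.columns = pd.MultiIndex.from_tuples(
            decisions.columns, names=["contrast", "timepoint"]
        )
        logfc.columns = decisions.columns
        return cls(decisions, logfc)

    def timepoints(self, contrast: str) -> list[str]:
        return [
            tp for (c, tp) in self.decisions.columns if c == contrast
        ]

    def _col(self, contrast: str, timepoint: str) -> pd.Series:
        key = (contrast, timepoint)
        if key not in self.decisions.columns:
            raise TargetsInputError(f"contrast {key} not present")
        return self.decisions[key]


@dataclass(frozen=True)
class CandidateTarget:
    """A putative direct target with its supporting evidence."""

    gene_id: str
    direction: str                 # "activated" | "repressed"
    timepoints: frozenset[str]
    binding: bool


def heat_response_sets(
    cube: DecisionCube, genotype: str
) -> dict[str, dict[str, set[str]]]:
    """Per-timepoint heat-induced / heat-repressed gene sets for a genotype."""
    contrast = f"heat_{genotype}"
    tps = cube.timepoints(contrast)
    if not tps:
        raise TargetsInputError(f"no heat-vs-control decisions for {genotype!r}")
    out: dict[str, dict[str, set[str]]] = {}
    for tp in tps:
        d = cube._col(contrast, tp)
        out[tp] = {
            "induced": set(d.index[d == 1]),
            "repressed": set(d.index[d == -1]),
        }
    return out


def priming_associated_sets(
    cube: DecisionCube, genotype: str, mode: str = "strict"
) -> dict[str, set[str]]:
    """Genes induced (or repressed) at 0h that stay so through the memory phase.

    strict: significant in the same direction at every timepoint.
    lenient: significant at the first timepoint, same-sign logFC (significant
    or not) at the later ones.
    """
    if mode not in ("strict", "lenient"):
        raise TargetsInputError(f"unknown mode {mode!r}")
    contrast = f"heat_{genotype}"
    tps = cube.timepoints(contrast)
    if len(tps) < 2:
        raise TargetsInputError("need decisions at multiple timepoints")
    first, later = tps[0], tps[1:]
    d0 = cube._col(contrast, first)
    out = {}
    for label, sign in (("sustained_induced", 1), ("sustained_repressed", -1)):
        keep = set(d0.index[d0 == sign])
        for tp in later:
            d = cube._col(contrast, tp)
            if mode == "strict":
                keep &= set(d.index[d == sign])
            else:
                lf = cube.logfc[(contrast, tp)]
                keep &= set(lf.index[np.sign(lf) == sign])
        out[label] = keep
    return out


def discordant_by_genotype(
    cube: DecisionCube,
    timepoint: str,
    oe: str = "OE",
    ko: str = "KO",
) -> dict[str, set[str]]:
    """Direction-discordant genes on the OE-vs-WT / KO-vs-WT interaction
    contrasts at one timepoint.

    Both calls are required (conjunction): a gene is "up in OE, down in KO"
    only when the OE contrast decision is +1 AND the KO contrast decision is
    -1; the mirrored set is disjoint by construction.
    """
    d_oe = cube._col(f"{oe}_vs_WT", timepoint)
    d_ko = cube._col(f"{ko}_vs_WT", timepoint)
    up_oe_down_ko = set(d_oe.index[(d_oe == 1) & (d_ko == -1)])
    down_oe_up_ko = set(d_oe.index[(d_oe == -1) & (d_ko == 1)])
    return {
        "up_in_oe_down_in_ko": up_oe_down_ko,
        "down_in_oe_up_in_ko": down_oe_up_ko,
    }


def candidate_direct_targets(
    discordant_per_tp: dict[str, dict[str, set[str]]],
    tf_bound: set[str],
) -> dict[str, CandidateTarget]:
    """Intersect per-timepoint discordant sets with promoter-bound genes.

    ``discordant_per_tp`` maps timepoint -> the two discordance classes.
    Activated targets are up-in-OE/down-in-KO; repressed the mirror.
    """
    import warnings

    if not tf_bound:
        warnings.warn("empty binding set: no candidates possible", stacklevel=2)
    support: dict[str, set[str]] = {}
    direction: dict[str, str] = {}
    for tp, classes in discordant_per_tp.items():
        for cls_name, genes in classes.items():
            dirn = "activated" if cls_name == "up_in_oe_down_in_ko" else "repressed"
            for g in genes & tf_bound:
                support.setdefault(g, set()).add(tp)
                direction.setdefault(g, dirn)
    return {
        g: CandidateTarget(
            gene_id=g,
            direction=direction[g],
            timepoints=frozenset(tps),
            binding=True,
        )
        for g, tps in support.items()
    }


def commonality_filter(
    candidates: dict[str, CandidateTarget],
    min_timepoints: int = 2,
    n_timepoints: int = 3,
) -> dict[str, CandidateTarget]:
    """Keep candidates supported at >= ``min_timepoints`` of the timepoints."""
    if not 1 <= min_timepoints <= n_timepoints:
        raise TargetsInputError(
            f"min_timepoints must be in 1..{n_timepoints}, got {min_timepoints}"
        )
    return {
        g: c for g, c in candidates.items() if len(c.timepoints) >= min_timepoints
    }
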