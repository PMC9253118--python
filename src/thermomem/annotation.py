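"""Gene models, binding peaks and promoter-proximal target assignment.

Binding evidence for a transcription factor comes as narrowPeak intervals
(0-based, half-open, as written by peak callers); gene models come from GFF3
(1-based, inclusive).  A gene is called a putative TF target when at least one
peak falls within a fixed window immediately upstream of its transcription
start site (TSS), taken strand-aware: upstream of a plus-strand gene is to the
left of its start coordinate, upstream of a minus-strand gene is to the right
of its end coordinate.

Internally everything is normalised to 1-based inclusive coordinates.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "PeakRecord",
    "PeakGeneAssignment",
    "parse_gene_models",
    "parse_peaks",
    "write_peaks",
    "nearest_tss",
    "promoter_bound_genes",
    "AnnotationError",
]


class AnnotationError(ValueError):
    """Malformed annotation input (bad GFF3/narrowPeak line, missing ID...)."""


@dataclass(frozen=True)
class GeneModel:
    """A gene feature with strand-aware TSS.

    ``start``/``end`` are 1-based inclusive, as in GFF3.  The TSS is the
    5'-most coordinate of the gene body: ``start`` on the plus strand,
    ``end`` on the minus strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    def promoter_interval(self, window: int) -> tuple[int, int]:
        """Open upstream interval as a closed 1-based [lo, hi] position range.

        Plus strand: positions in (TSS-window, TSS) -> [TSS-window+1, TSS-1].
        Minus strand: positions in (TSS, TSS+window) -> [TSS+1, TSS+window-1].
        """
        if window <= 0:
            raise AnnotationError(f"promoter window must be positive, got {window}")
        if self.strand == "+":
            return (self.tss - window + 1, self.tss - 1)
        return (self.tss + 1, self.tss + window - 1)


@dataclass(frozen=True)
class PeakRecord:
    """One narrowPeak interval, kept 0-based half-open as written."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal: float = 0.0
    pvalue: float = -1.0
    qvalue: float = -1.0
    summit: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"peak {self.name}: start {self.start} >= end {self.end}"
            )

    @property
    def start1(self) -> int:
        """1-based inclusive start."""
        return self.start + 1

    @property
    def end1(self) -> int:
        """1-based inclusive end."""
        return self.end

    @property
    def summit_pos(self) -> int:
        """1-based summit position; interval midpoint when summit is -1."""
        if self.summit >= 0:
            return self.start + self.summit + 1
        return (self.start1 + self.end1) // 2


@dataclass(frozen=True)
class PeakGeneAssignment:
    """Nearest-TSS assignment of one peak.

    ``distance`` is 0 when the TSS lies inside the peak, otherwise the gap in
    bp between the TSS and the nearest peak edge.  ``upstream`` says whether
    the peak lies on the promoter side of the gene's TSS.
    """

    peak: PeakRecord
    gene_id: str | None
    distance: float
    upstream: bool
    tie: bool


def parse_gene_models(gff3_path: str | os.PathLike) -> list[GeneModel]:
    """Read ``gene`` features from a GFF3 file.

    Non-gene features are skipped (and counted in the log).  Every gene
    feature must carry an ``ID`` attribute.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise AnnotationError(f"failed to parse GFF3 {gff3_path}: {exc}") from exc

    genes: list[GeneModel] = []
    skipped = 0
    for feat in db.all_features():
        if feat.featuretype != "gene":
            skipped += 1
            continue
        ids = feat.attributes.get("ID")
        if not ids:
            raise AnnotationError(
                f"{gff3_path}: gene feature at {feat.seqid}:{feat.start}-{feat.end} "
                "has no ID attribute"
            )
        genes.append(
            GeneModel(
                gene_id=ids[0],
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
            )
        )
    if skipped:
        logger.info("parse_gene_models: skipped %d non-gene features", skipped)
    return genes


def parse_peaks(path: str | os.PathLike) -> list[PeakRecord]:
    """Parse a narrowPeak (BED6+4) file; plain BED6 is accepted too."""
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(
                    f"{path}:{lineno}: expected >=6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                rec = PeakRecord(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3],
                    score=float(fields[4]),
                    strand=fields[5],
                    signal=float(fields[6]) if len(fields) > 6 else 0.0,
                    pvalue=float(fields[7]) if len(fields) > 7 else -1.0,
                    qvalue=float(fields[8]) if len(fields) > 8 else -1.0,
                    summit=int(fields[9]) if len(fields) > 9 else -1,
                )
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(rec)
    return peaks


def write_peaks(peaks: Iterable[PeakRecord], path: str | os.PathLike) -> None:
    """Write peaks back out in narrowPeak layout (0-based half-open)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        p.chrom,
                        p.start,
                        p.end,
                        p.name,
                        _fmt_num(p.score),
                        p.strand,
                        _fmt_num(p.signal),
                        _fmt_num(p.pvalue),
                        _fmt_num(p.qvalue),
                        p.summit,
                    )
                )
                + "\n"
            )


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def nearest_tss(
    peaks: Sequence[PeakRecord], genes: Sequence[GeneModel]
) -> list[PeakGeneAssignment]:
    """Assign each peak to the gene with the closest TSS.

    Distance is 0 when a TSS falls inside the peak; otherwise the gap between
    the TSS and the nearest peak edge (1-based inclusive conversion applied
    first).  Equidistant genes tie: the lexicographically smallest gene id
    wins deterministically, and every tied gene is reported with ``tie=True``.
    A peak on a chromosome without genes gets ``gene_id=None`` and infinite
    distance.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom, gl in by_chrom.items():
        gl_sorted = sorted(gl, key=lambda g: (g.tss, g.gene_id))
        index[chrom] = (np.array([g.tss for g in gl_sorted]), gl_sorted)

    out: list[PeakGeneAssignment] = []
    for peak in peaks:
        if peak.chrom not in index:
            out.append(
                PeakGeneAssignment(
                    peak=peak, gene_id=None, distance=float("inf"),
                    upstream=False, tie=False,
                )
            )
            continue
        tss_arr, gl_sorted = index[peak.chrom]
        lo, hi = peak.start1, peak.end1
        dists = np.where(
            (tss_arr >= lo) & (tss_arr <= hi),
            0,
            np.minimum(np.abs(tss_arr - lo), np.abs(tss_arr - hi)),
        )
        dmin = int(dists.min())
        winners = [gl_sorted[i] for i in np.flatnonzero(dists == dmin)]
        tie = len(winners) > 1
        for g in sorted(winners, key=lambda g: g.gene_id):
            out.append(
                PeakGeneAssignment(
                    peak=peak,
                    gene_id=g.gene_id,
                    distance=float(dmin),
                    upstream=_is_upstream(peak, g),
                    tie=tie,
                )
            )
    return out


def _is_upstream(peak: PeakRecord, gene: GeneModel) -> bool:
    """Whether the peak lies on the promoter side of the gene's TSS."""
    if gene.strand == "+":
        return peak.end1 <= gene.tss
    return peak.start1 >= gene.tss


def promoter_bound_genes(
    peaks: Sequence[PeakRecord],
    genes: Sequence[GeneModel],
    window: int = 1000,
    mode: str = "overlap",
) -> set[str]:
    """Genes with >=1 peak within the strand-aware upstream promoter window.

    ``mode='overlap'`` (default): any overlap of the peak interval with the
    open window ``(TSS-window, TSS)`` (reflected for minus-strand genes)
    qualifies.  ``mode='summit'``: the peak summit (midpoint when unknown)
    must fall inside the window.  A peak covering the TSS itself also
    qualifies (distance 0).
    """
    if window <= 0:
        raise AnnotationError(f"promoter window must be positive, got {window}")
    if mode not in ("overlap", "summit"):
        raise AnnotationError(f"unknown promoter mode {mode!r}")

    bound: set[str] = set()
    by_chrom: dict[str, list[PeakRecord]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for gene in genes:
        lo, hi = gene.promoter_interval(window)
        for p in by_chrom.get(gene.chrom, ()):
            if mode == "overlap":
                hit = p.end1 >= lo and p.start1 <= hi
            else:
                hit = lo <= p.summit_pos <= hi
            # a peak spanning the TSS itself counts (distance 0)
            hit = hit or (p.start1 <= gene.tss <= p.end1)
            if hit:
                bound.add(gene.gene_id)
                break
    return bound
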