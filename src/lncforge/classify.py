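"""Genomic-context classification of lncRNA candidates.

Each candidate is assigned exactly one class relative to the protein-coding
annotation, by rules applied in precedence order:

(a) any exon overlaps a coding exon on the opposite strand -> antisense;
(b) else, the candidate lies entirely within one gene's span with zero
    exon-exon overlap on either strand -> intronic;
(c) else, any exon overlaps a coding exon on the same strand ->
    discarded_sense_overlap (not an lncRNA);
(d) else -> intergenic.

Overlap means >= 1 shared base. The antisense-before-intronic order mirrors
Cuffcompare class-code semantics (x before i). Transcripts of unknown
strand cannot be classified and are excluded with a warning rather than
guessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from intervaltree import IntervalTree

from .identify import CandidateTranscript
from .io_formats import ExpressionMatrix, GeneAnnotation

CLASSES = ("intergenic", "intronic", "antisense", "discarded_sense_overlap")


class ClassificationError(ValueError):
    pass


@dataclass
class NearestPcg:
    gene_id: str | None
    distance: int | None
    relative_position: str | None  # 'upstream' | 'downstream' | 'overlapping'


@dataclass
class LncRNARecord:
    candidate: CandidateTranscript
    context_class: str
    nearest_pcg: NearestPcg

    @property
    def transcript_id(self) -> str:
        return self.candidate.model.transcript_id


class AnnotationIndex:
    """Interval indexes over a GeneAnnotation: coding exons by (scaffold,
    strand) and gene spans by scaffold. Intervals are stored half-open
    internally (intervaltree convention); the 1-based inclusive domain
    coordinates convert at this boundary only."""

    def __init__(self, annotation: GeneAnnotation):
        self.annotation = annotation
        self.exons: dict[tuple[str, str], IntervalTree] = {}
        self.spans: dict[str, IntervalTree] = {}
        for gene_id in annotation.gene_ids:
            scaffold, gstart, gend, strand = annotation.gene_span(gene_id)
            self.spans.setdefault(scaffold, IntervalTree())[gstart : gend + 1] = gene_id
            tree = self.exons.setdefault((scaffold, strand), IntervalTree())
            for s, e in annotation.exons_of(gene_id):
                tree[s : e + 1] = gene_id


def classify_context(
    candidate: CandidateTranscript, index: AnnotationIndex | GeneAnnotation
) -> LncRNARecord:
    """Assign the genomic-context class and locate the nearest coding gene."""
    if isinstance(index, GeneAnnotation):
        index = AnnotationIndex(index)
    model = candidate.model
    if model.strand == ".":
        raise ClassificationError(
            f"transcript {model.transcript_id} has unknown strand; cannot classify"
        )
    opposite = "-" if model.strand == "+" else "+"

    def exon_overlaps(strand: str) -> set[str]:
        tree = index.exons.get((model.scaffold, strand))
        if tree is None:
            return set()
        genes: set[str] = set()
        for s, e in model.exons:
            for iv in tree.overlap(s, e + 1):
                genes.add(iv.data)
        return genes

    label: str
    if exon_overlaps(opposite):
        label = "antisense"
    else:
        span_s, span_e = model.span
        containing = {
            iv.data
            for iv in index.spans.get(model.scaffold, IntervalTree()).overlap(span_s, span_e + 1)
            if iv.begin <= span_s and iv.end >= span_e + 1
        }
        same_strand_overlap = exon_overlaps(model.strand)
        if containing and not same_strand_overlap:
            label = "intronic"
        elif same_strand_overlap:
            label = "discarded_sense_overlap"
        else:
            label = "intergenic"
    return LncRNARecord(
        candidate=candidate,
        context_class=label,
        nearest_pcg=nearest_pcg(candidate, index),
    )


def nearest_pcg(
    candidate: CandidateTranscript, index: AnnotationIndex | GeneAnnotation
) -> NearestPcg:
    """Closest coding gene by span-edge distance (0 if the spans overlap);
    ties broken by lexicographically smaller gene_id. The relative position
    of the lncRNA is given in the gene's 5'->3' frame (upstream/downstream),
    or 'overlapping' when the spans share bases."""
    if isinstance(index, GeneAnnotation):
        index = AnnotationIndex(index)
    model = candidate.model
    span_s, span_e = model.span
    annotation = index.annotation
    best: tuple[int, str] | None = None
    for gene_id in annotation.genes_on(model.scaffold):
        _, gs, ge, _ = annotation.gene_span(gene_id)
        dist = max(0, gs - span_e, span_s - ge)
        key = (dist, gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return NearestPcg(gene_id=None, distance=None, relative_position=None)
    dist, gene_id = best
    _, gs, ge, gstrand = annotation.gene_span(gene_id)
    if dist == 0:
        rel = "overlapping"
    else:
        lnc_before = span_e < gs
        five_prime_first = gstrand != "-"  # unknown strand falls back to + orientation
        rel = "upstream" if lnc_before == five_prime_first else "downstream"
    return NearestPcg(gene_id=gene_id, distance=dist, relative_position=rel)


def classify_all(
    candidates: Iterable[CandidateTranscript], annotation: GeneAnnotation
) -> list[LncRNARecord]:
    """Classify every candidate; unknown-strand candidates are excluded
    with one summary warning."""
    index = AnnotationIndex(annotation)
    records: list[LncRNARecord] = []
    skipped: list[str] = []
    for c in candidates:
        try:
            records.append(classify_context(c, index))
        except ClassificationError:
            skipped.append(c.model.transcript_id)
    if skipped:
        warnings.warn(f"{len(skipped)} unknown-strand candidates excluded: {skipped[:10]}")
    return records


def summarize_classes(
    records: Iterable[LncRNARecord], expr: ExpressionMatrix | None = None
) -> pd.DataFrame:
    """Per-class counts and averages (genomic span, exon number, expression),
    plus a 'total' row over the three lncRNA classes.

    Expression is the per-transcript mean FPKM over samples when ``expr``
    is given, else the candidate's max FPKM from the filter cascade.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to summarize")
    rows = []
    lnc_classes = ("intergenic", "intronic", "antisense")
    by_class = {cls: [r for r in records if r.context_class == cls] for cls in lnc_classes}
    by_class["total"] = [r for r in records if r.context_class in lnc_classes]

    def expression_of(r: LncRNARecord) -> float:
        tid = r.transcript_id
        if expr is not None and tid in expr.values.index:
            return float(expr.values.loc[tid].mean())
        return r.candidate.max_fpkm

    for cls, group in by_class.items():
        if group:
            rows.append(
                {
                    "class": cls,
                    "count": len(group),
                    "avg_genomic_span": sum(r.candidate.model.genomic_length for r in group)
                    / len(group),
                    "avg_exon_number": sum(r.candidate.model.exon_count for r in group)
                    / len(group),
                    "avg_expression": sum(expression_of(r) for r in group) / len(group),
                }
            )
        else:
            rows.append(
                {
                    "class": cls,
                    "count": 0,
                    "avg_genomic_span": float("nan"),
                    "avg_exon_number": float("nan"),
                    "avg_expression": float("nan"),
                }
            )
    return pd.DataFrame(rows).set_index("class")
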