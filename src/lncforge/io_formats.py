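"""Domain types and readers/writers for every external format the pipeline touches.

All in-memory genomic intervals are 1-based inclusive, the GTF convention.
Conversion to half-open coordinates happens only at format boundaries
(BED6 export). Downstream modules operate exclusively on the types defined
here: :class:`TranscriptModel`, :class:`GeneAnnotation`, :class:`HitRecord`,
:class:`ExpressionMatrix` and :class:`AnnotationMap`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class GtfParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class TranscriptModel:
    """An assembled transcript: the unit flowing through the filter cascade.

    ``exons`` are 1-based inclusive (start, end) intervals, non-empty,
    non-overlapping and sorted ascending by start. Strand ``.`` means
    unknown; strand-dependent operations reject such transcripts rather
    than guess.
    """

    transcript_id: str
    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype_hint: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"transcript {self.transcript_id}: invalid strand {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon start {start} > end {end}"
                )
            if prev_end is not None and start <= prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (first exon start, last exon end), 1-based inclusive."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def genomic_length(self) -> int:
        s, e = self.span
        return e - s + 1

    @property
    def exonic_length(self) -> int:
        """Total exonic (RNA) length in bp; this is the 200 bp-rule length."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)


@dataclass
class GeneAnnotation:
    """Protein-coding transcripts grouped by gene, with per-gene spans."""

    transcripts_by_gene: dict[str, list[TranscriptModel]]

    def __post_init__(self) -> None:
        for gene_id, models in self.transcripts_by_gene.items():
            if not models:
                raise ValidationError(f"gene {gene_id} has no transcripts")

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[TranscriptModel]) -> "GeneAnnotation":
        grouped: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            grouped.setdefault(t.gene_id, []).append(t)
        return cls(grouped)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.transcripts_by_gene)

    def gene_span(self, gene_id: str) -> tuple[str, int, int, str]:
        """(scaffold, start, end, strand) covering all exons of the gene."""
        models = self.transcripts_by_gene[gene_id]
        scaffold = models[0].scaffold
        strand = models[0].strand
        start = min(t.span[0] for t in models)
        end = max(t.span[1] for t in models)
        return scaffold, start, end, strand

    def exons_of(self, gene_id: str) -> list[tuple[int, int]]:
        exons: list[tuple[int, int]] = []
        for t in self.transcripts_by_gene[gene_id]:
            exons.extend(t.exons)
        return sorted(exons)

    def genes_on(self, scaffold: str) -> list[str]:
        return [
            g
            for g, models in self.transcripts_by_gene.items()
            if models[0].scaffold == scaffold
        ]


@dataclass(frozen=True)
class HitRecord:
    """One pairwise homology hit — the universal BLAST-derived input.

    ``query_coverage``/``target_coverage`` are percentages of the query
    (resp. target) sequence covered by the alignment; both are carried
    explicitly because the retention rules need both.
    """

    query_id: str
    target_id: str
    identity: float
    query_coverage: float
    target_coverage: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        for name, val in (
            ("identity", self.identity),
            ("query_coverage", self.query_coverage),
            ("target_coverage", self.target_coverage),
        ):
            if not 0.0 <= val <= 100.0:
                raise ValidationError(
                    f"hit {self.query_id}->{self.target_id}: {name}={val} outside [0, 100]"
                )
        if self.evalue < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.target_id}: negative evalue {self.evalue}"
            )


@dataclass
class ExpressionMatrix:
    """FPKM table (rows = features, columns = samples) plus sample metadata.

    ``sample_meta`` is indexed by sample id with columns ``tissue`` and
    ``condition``; every matrix column must have metadata.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative FPKM values present")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")
        for col in ("tissue", "condition"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample metadata lacks column {col!r}")
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def groups(self, by: str) -> dict[str, list[str]]:
        """Sample ids grouped by 'tissue', 'condition' or 'tissue_condition'."""
        if by == "tissue_condition":
            labels = (
                self.sample_meta["tissue"].astype(str)
                + ":"
                + self.sample_meta["condition"].astype(str)
            )
        elif by in ("tissue", "condition"):
            labels = self.sample_meta[by].astype(str)
        else:
            raise ValueError(f"unknown grouping {by!r}")
        out: dict[str, list[str]] = {}
        for sample, label in labels.items():
            out.setdefault(label, []).append(sample)
        return out

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)].copy(), self.sample_meta.copy())


@dataclass
class AnnotationMap:
    """Gene -> functional-term mapping (one GO or KEGG namespace)."""

    gene_terms: dict[str, set[str]]
    term_descriptions: dict[str, str] = field(default_factory=dict)
    namespace: str = "GO"

    def __post_init__(self) -> None:
        empty = [g for g, terms in self.gene_terms.items() if not terms]
        if empty:
            raise ValidationError(f"genes mapped to no term: {empty}")

    @property
    def annotated_genes(self) -> set[str]:
        return set(self.gene_terms)

    def genes_with_term(self, term_id: str) -> set[str]:
        return {g for g, terms in self.gene_terms.items() if term_id in terms}

    @property
    def term_ids(self) -> set[str]:
        out: set[str] = set()
        for terms in self.gene_terms.values():
            out |= terms
        return out


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"?([^";]*)"?\s*;?')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return {k: v.strip() for k, v in _ATTR_RE.findall(attr_field)}


def read_gtf(path: str | Path, feature_filter: str | None = "exon") -> list[TranscriptModel]:
    """Read a GTF file into TranscriptModels, one per distinct transcript_id.

    Only rows whose feature column equals ``feature_filter`` (default
    ``exon``) contribute intervals; exons are grouped per transcript and
    sorted ascending. Raises :class:`GtfParseError` naming the offending
    line on malformed input.
    """
    path = Path(path)
    exons: dict[str, list[tuple[int, int]]] = {}
    info: dict[str, tuple[str, str, str, str | None]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            scaffold, _source, feature, start_s, end_s, _score, strand, _frame, attrs = cols
            if feature_filter is not None and feature != feature_filter:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise GtfParseError(f"{path}:{lineno}: start {start} > end {end}")
            if strand not in VALID_STRANDS:
                raise GtfParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            attributes = _parse_attributes(attrs)
            if "transcript_id" not in attributes:
                raise ValidationError(f"{path}:{lineno}: missing transcript_id attribute")
            tid = attributes["transcript_id"]
            gid = attributes.get("gene_id", tid)
            biotype = attributes.get("gene_biotype") or attributes.get("transcript_biotype")
            if tid not in exons:
                order.append(tid)
                exons[tid] = []
                info[tid] = (gid, scaffold, strand, biotype)
            exons[tid].append((start, end))
    models = []
    for tid in order:
        gid, scaffold, strand, biotype = info[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                scaffold=scaffold,
                strand=strand,
                exons=tuple(sorted(exons[tid])),
                biotype_hint=biotype,
            )
        )
    return models


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path,
              source: str = "lncforge", extra_attrs: Mapping[str, Mapping[str, str]] | None = None) -> None:
    """Write TranscriptModels as GTF exon rows (round-trips with read_gtf)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.biotype_hint:
                attrs += f' gene_biotype "{t.biotype_hint}";'
            if extra_attrs and t.transcript_id in extra_attrs:
                for k, v in extra_attrs[t.transcript_id].items():
                    attrs += f' {k} "{v}";'
            for start, end in t.exons:
                fh.write(
                    f"{t.scaffold}\t{source}\texon\t{start}\t{end}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def write_bed6(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Export transcript spans as BED6 (0-based half-open, by convention)."""
    with open(path, "w") as fh:
        for t in transcripts:
            s, e = t.span
            fh.write(f"{t.scaffold}\t{s - 1}\t{e}\t{t.transcript_id}\t0\t{t.strand}\n")


# ---------------------------------------------------------------------------
# Hit tables (extended outfmt-6 dialect: 7 columns, both coverages explicit)

HIT_COLUMNS = ["query", "target", "identity", "qcov", "tcov", "evalue", "bitscore"]


def read_hits_tsv(path: str | Path) -> list[HitRecord]:
    """Read a 7-column hit table (query, target, identity, qcov, tcov,
    evalue, bitscore). A header row naming the columns is permitted.
    Duplicate (query, target) pairs are retained; best-hit selection is a
    downstream concern."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != len(HIT_COLUMNS):
        raise GtfParseError(
            f"{path}: expected {len(HIT_COLUMNS)} columns, got {df.shape[1]}"
        )
    df.columns = HIT_COLUMNS
    if df.iloc[0]["query"].lower() in ("query", "qseqid"):
        df = df.iloc[1:]
    records = []
    for row_idx, row in df.iterrows():
        try:
            rec = HitRecord(
                query_id=row["query"],
                target_id=row["target"],
                identity=float(row["identity"]),
                query_coverage=float(row["qcov"]),
                target_coverage=float(row["tcov"]),
                evalue=float(row["evalue"]),
                bitscore=float(row["bitscore"]),
            )
        except ValueError as exc:
            if isinstance(exc, ValidationError):
                raise
            raise GtfParseError(f"{path}: row {row_idx}: non-numeric field") from exc
        records.append(rec)
    return records


def write_hits_tsv(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.identity}\t{h.query_coverage}\t"
                f"{h.target_coverage}\t{h.evalue:g}\t{h.bitscore}\n"
            )


def hits_with_computed_coverage(
    rows: Iterable[Mapping[str, float | str]],
    query_lengths: Mapping[str, int],
    target_lengths: Mapping[str, int],
) -> list[HitRecord]:
    """Build HitRecords from 12-column outfmt-6-style rows lacking coverages,
    computing qcov/tcov from alignment length and sequence-length tables."""
    out = []
    for row in rows:
        q, t = str(row["query"]), str(row["target"])
        aln_len = float(row["length"])
        out.append(
            HitRecord(
                query_id=q,
                target_id=t,
                identity=float(row["identity"]),
                query_coverage=min(100.0, 100.0 * aln_len / query_lengths[q]),
                target_coverage=min(100.0, 100.0 * aln_len / target_lengths[t]),
                evalue=float(row["evalue"]),
                bitscore=float(row["bitscore"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Expression matrices

def read_expression_tsv(path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read an FPKM matrix (feature ids in first column, sample ids in the
    header) and its sample sheet (sample, tissue, condition)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ValidationError(f"samples in matrix missing from metadata: {missing}")
    return ExpressionMatrix(values=values, sample_meta=meta)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path, meta_path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="feature_id")
    expr.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_scores_tsv(path: str | Path) -> dict[str, float]:
    """Read a two-column id -> score table (e.g. coding-potential scores)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "score"], dtype=str)
    if str(df.iloc[0]["score"]).lower() in ("score", "cpc", "cpc_score"):
        df = df.iloc[1:]
    return {row["id"]: float(row["score"]) for _, row in df.iterrows()}


# ---------------------------------------------------------------------------
# Annotation maps

def read_annotation_map(path: str | Path, namespace: str | None = None) -> AnnotationMap:
    """Read a flat gene->term map: columns gene_id, term_id, namespace,
    description (tab-separated, no header required)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["gene_id", "term_id", "namespace", "description"], dtype=str,
    )
    if str(df.iloc[0]["gene_id"]).lower() == "gene_id":
        df = df.iloc[1:]
    if namespace is not None:
        df = df[df["namespace"] == namespace]
    gene_terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for _, row in df.iterrows():
        gene_terms.setdefault(row["gene_id"], set()).add(row["term_id"])
        if isinstance(row["description"], str):
            descriptions[row["term_id"]] = row["description"]
    ns = namespace or (df["namespace"].iloc[0] if len(df) else "GO")
    return AnnotationMap(gene_terms=gene_terms, term_descriptions=descriptions, namespace=ns)


def write_annotation_map(amap: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, terms in amap.gene_terms.items():
            for term in sorted(terms):
                desc = amap.term_descriptions.get(term, "")
                fh.write(f"{gene}\t{term}\t{amap.namespace}\t{desc}\n")
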