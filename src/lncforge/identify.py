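"""Candidate-filter cascade for lncRNA identification.

Assembled transcripts pass four filters, in order: (1) exonic length
>= 200 bp (the operational lncRNA definition); (2) coding potential —
transcripts with a CPC-scale score >= -1 are eliminated as coding;
(3) protein-domain evidence — any Pfam or NR hit eliminates; (4) expression
— maximum FPKM across samples must reach 0.3. A transcript failing a step
is not evaluated at later steps, and the report records survivor counts
after every step.

"Length" here is total exonic (RNA) length, not genomic span: the 200 bp
rule defines the RNA molecule. Genomic span is reported separately by the
classification summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io_formats import ExpressionMatrix, HitRecord, TranscriptModel

STEP_ORDER = ("length", "cpc", "domain", "fpkm")


@dataclass
class FilterThresholds:
    """Cascade cutoffs. ``cpc_eliminate_at`` eliminates transcripts whose
    coding-potential score is >= the value; the -1 default is deliberately
    stricter than the conventional CPC coding call (score > 0) and is kept
    configurable for that reason. ``domain_evalue_max=None`` means any
    Pfam/NR hit at any E-value eliminates."""

    min_length: int = 200
    cpc_eliminate_at: float = -1.0
    domain_evalue_max: float | None = None
    min_fpkm: float = 0.3
    step_order: tuple[str, ...] = STEP_ORDER

    def __post_init__(self) -> None:
        if set(self.step_order) != set(STEP_ORDER):
            raise ValueError(f"step_order must be a permutation of {STEP_ORDER}")


@dataclass
class CandidateTranscript:
    model: TranscriptModel
    length: int
    cpc_score: float | None
    has_pfam_hit: bool
    has_nr_hit: bool
    max_fpkm: float
    filter_trace: list[tuple[str, bool]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(ok for _, ok in self.filter_trace)


@dataclass
class FilterReport:
    input_count: int
    survivors_after: dict[str, int]
    thresholds: FilterThresholds

    def as_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "survivors_after": dict(self.survivors_after),
            "thresholds": {
                "min_length": self.thresholds.min_length,
                "cpc_eliminate_at": self.thresholds.cpc_eliminate_at,
                "domain_evalue_max": self.thresholds.domain_evalue_max,
                "min_fpkm": self.thresholds.min_fpkm,
                "step_order": list(self.thresholds.step_order),
            },
        }


def _hit_ids(hits: Iterable[HitRecord], evalue_max: float | None) -> set[str]:
    return {
        h.query_id
        for h in hits
        if evalue_max is None or h.evalue <= evalue_max
    }


def filter_candidates(
    transcripts: Iterable[TranscriptModel],
    expr: ExpressionMatrix | None,
    pfam_hits: Iterable[HitRecord] = (),
    nr_hits: Iterable[HitRecord] = (),
    cpc_scores: Mapping[str, float] | None = None,
    thresholds: FilterThresholds | None = None,
) -> tuple[list[CandidateTranscript], FilterReport]:
    """Run the stepwise cascade and return survivors plus per-step counts.

    Transcripts absent from the expression matrix are treated as FPKM 0
    (they fail the expression step) with a warning. If CPC filtering is
    enabled (``cpc_scores`` given) every transcript must have a score;
    missing ids raise rather than silently passing. Passing
    ``cpc_scores=None`` disables the coding-potential step (it counts all
    current survivors as passing).
    """
    thresholds = thresholds or FilterThresholds()
    transcripts = list(transcripts)
    pfam_ids = _hit_ids(pfam_hits, thresholds.domain_evalue_max)
    nr_ids = _hit_ids(nr_hits, thresholds.domain_evalue_max)

    if cpc_scores is not None:
        missing = [t.transcript_id for t in transcripts if t.transcript_id not in cpc_scores]
        if missing:
            raise KeyError(
                f"CPC filtering enabled but {len(missing)} transcripts lack scores: {missing[:10]}"
            )

    absent_from_expr: list[str] = []
    candidates: list[CandidateTranscript] = []
    for t in transcripts:
        if expr is not None and t.transcript_id in expr.values.index:
            max_fpkm = float(expr.values.loc[t.transcript_id].max())
        else:
            max_fpkm = 0.0
            if expr is not None:
                absent_from_expr.append(t.transcript_id)
        candidates.append(
            CandidateTranscript(
                model=t,
                length=t.exonic_length,
                cpc_score=None if cpc_scores is None else float(cpc_scores[t.transcript_id]),
                has_pfam_hit=t.transcript_id in pfam_ids,
                has_nr_hit=t.transcript_id in nr_ids,
                max_fpkm=max_fpkm,
            )
        )
    if absent_from_expr:
        warnings.warn(
            f"{len(absent_from_expr)} transcripts absent from the expression matrix "
            "treated as FPKM 0"
        )

    def predicate(step: str, c: CandidateTranscript) -> bool:
        if step == "length":
            return c.length >= thresholds.min_length
        if step == "cpc":
            return c.cpc_score is None or c.cpc_score < thresholds.cpc_eliminate_at
        if step == "domain":
            return not (c.has_pfam_hit or c.has_nr_hit)
        if step == "fpkm":
            return c.max_fpkm >= thresholds.min_fpkm
        raise ValueError(f"unknown step {step!r}")

    alive = candidates
    survivors_after: dict[str, int] = {}
    for step in thresholds.step_order:
        next_alive = []
        for c in alive:
            ok = predicate(step, c)
            c.filter_trace.append((step, ok))
            if ok:
                next_alive.append(c)
        alive = next_alive
        survivors_after[step] = len(alive)

    report = FilterReport(
        input_count=len(candidates),
        survivors_after=survivors_after,
        thresholds=thresholds,
    )
    return alive, report


# ---------------------------------------------------------------------------
# Built-in coding-potential surrogate

_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _longest_orf_in_frames(seq: str) -> int:
    """Longest ATG->stop ORF length in nt (stop codon included) over the
    three forward frames of ``seq``. ORFs without an in-frame stop do not
    count."""
    best = 0
    n = len(seq)
    for frame in range(3):
        start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOPS:
                best = max(best, pos + 3 - start)
                start = None
    return best


def longest_orf(sequence: str, include_reverse: bool = True) -> int:
    """Longest open reading frame (ATG through stop, nt) over 3 forward
    frames, and the 3 reverse-complement frames when the strand is
    unknown (``include_reverse=True``)."""
    seq = sequence.upper()
    best = _longest_orf_in_frames(seq)
    if include_reverse:
        rc = seq.translate(_COMPLEMENT)[::-1]
        best = max(best, _longest_orf_in_frames(rc))
    return best


def surrogate_coding_score(sequence: str, include_reverse: bool = True) -> float:
    """A coding-potential score on the CPC-like scale, computed from ORF
    coverage: s = -2 + 4 * (longest ORF / sequence length). No ATG-to-stop
    ORF gives -2 (clearly noncoding); a transcript that is one
    uninterrupted ORF gives +2; ORF coverage >= 25% maps to s >= -1, the
    cascade's elimination threshold.
    """
    seq = sequence.upper()
    if len(seq) < 200:
        raise ValueError(f"sequence shorter than 200 nt ({len(seq)})")
    bad = sum(1 for c in seq if c not in "ACGTN")
    if bad > 0.1 * len(seq):
        raise ValueError("more than 10% of bases outside the ACGTN alphabet")
    return -2.0 + 4.0 * longest_orf(seq, include_reverse=include_reverse) / len(seq)
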