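"""Thresholded Pearson coexpression against curated gene sets — the
cancer-association core.

A lncRNA-gene pair's coexpression is summarized by the Pearson correlation
r over matched samples and its correlation P value (cP), the two-sided
p-value of t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom. Pairs are
tiered: strong when 0.8 <= |r| < 0.9 with cP <= 0.01, intensive when
|r| >= 0.9 with cP <= 0.01 (intensive implies at least strong). At n = 12
samples any |r| >= 0.8 already gives cP < 0.01, so the cP gate is
non-binding at the default thresholds and sample size; it matters for
smaller designs.

Also here: the coverage/E-value retention rule for cancer-lncRNA and
tumor-suppressor homology hits, dual-sign pattern detection (a lncRNA
positively coexpressed with one pathway gene and negatively with another),
and the two-species comparison summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .expression_profiles import benjamini_hochberg
from .io_formats import ExpressionMatrix, HitRecord

STRONG_R = 0.8
INTENSIVE_R = 0.9
CP_MAX = 0.01


class ConstantVectorError(ValueError):
    """Pearson correlation is undefined for a zero-variance vector."""


def filter_homology_hits(
    hits: Iterable[HitRecord],
    coverage_min: float = 40.0,
    evalue_max: float = 1e-5,
    rule: str = "either",
) -> list[HitRecord]:
    """Retain hits with E-value strictly below ``evalue_max`` and coverage
    strictly above ``coverage_min`` on the query and/or target
    (``rule='either'``, the default reading of "query and/or target") or on
    both (``rule='both'``)."""
    if rule not in ("either", "both"):
        raise ValueError(f"rule must be 'either' or 'both', got {rule!r}")
    out = []
    for h in hits:
        if h.evalue >= evalue_max:
            continue
        q_ok = h.query_coverage > coverage_min
        t_ok = h.target_coverage > coverage_min
        if (q_ok or t_ok) if rule == "either" else (q_ok and t_ok):
            out.append(h)
    return out


def best_hit_per_query(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Best hit per query by bitscore, ties by lower E-value then
    lexicographic target id (used for tumor-suppressor homolog mapping)."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (-h.bitscore, h.evalue, h.target_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.target_id,
        ):
            best[h.query_id] = h
    return best


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and its two-sided t-distribution p-value (cP).

    Requires n >= 3 and non-constant vectors; |r| = 1 gives cP = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3 samples")
    if x.std() == 0 or y.std() == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    # exact linear dependence can land at 1 - O(eps) in floating point;
    # snap to +/-1 so perfect correlation reports cP = 0
    if 1.0 - abs(r) < 1e-12:
        return float(np.sign(r)), 0.0
    return r, float(res.pvalue)


def cp_from_r(r: float, n: int) -> float:
    """cP for a known correlation coefficient at sample size n: two-sided
    p of t = r*sqrt((n-2)/(1-r^2)) on n-2 df. Lets reported r values (with
    their sample size) be tiered without the underlying vectors."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass(frozen=True)
class CorrelationResult:
    lnc_id: str
    gene_id: str
    r: float
    cP: float
    n: int

    @property
    def tier(self) -> str:
        if self.cP <= CP_MAX:
            if abs(self.r) >= INTENSIVE_R:
                return "intensive"
            if abs(self.r) >= STRONG_R:
                return "strong"
        return "none"

    @property
    def sign(self) -> str:
        return "positive" if self.r >= 0 else "negative"

    @classmethod
    def from_r(cls, lnc_id: str, gene_id: str, r: float, n: int) -> "CorrelationResult":
        """Build a result from a reported r value, deriving cP from r and n."""
        return cls(lnc_id=lnc_id, gene_id=gene_id, r=r, cP=cp_from_r(r, n), n=n)

    def at_least(self, tier: str) -> bool:
        """True when this pair reaches ``tier`` ('strong' counts intensive
        pairs too, since intensive implies strong-or-better)."""
        if tier == "strong":
            return self.tier in ("strong", "intensive")
        if tier == "intensive":
            return self.tier == "intensive"
        raise ValueError(f"unknown tier {tier!r}")


def expressed_in_all_groups(
    expr: ExpressionMatrix, grouping: str = "tissue_condition", threshold: float = 0.3
) -> list[str]:
    """Feature ids expressed (FPKM >= threshold in >= 1 sample) in every
    group of the grouping — the reserve-for-analysis prefilter."""
    groups = expr.groups(grouping)
    out = []
    for fid in expr.feature_ids:
        row = expr.values.loc[fid]
        if all((row[samples] >= threshold).any() for samples in groups.values()):
            out.append(fid)
    return out


def expressed_in_at_least(
    expr: ExpressionMatrix, k: int, grouping: str = "condition", threshold: float = 0.3
) -> list[str]:
    """Feature ids expressed in >= k groups (the >=4-developmental-tissues
    variant of the prefilter)."""
    groups = expr.groups(grouping)
    out = []
    for fid in expr.feature_ids:
        row = expr.values.loc[fid]
        n_expr = sum(1 for samples in groups.values() if (row[samples] >= threshold).any())
        if n_expr >= k:
            out.append(fid)
    return out


def coexpress(
    lnc_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    prefilter: str | None = "all_groups",
    prefilter_grouping: str = "tissue_condition",
    threshold: float = 0.3,
    bh_correct: bool = False,
) -> list[CorrelationResult]:
    """Score every lncRNA x gene pair that passes the expression prefilter.

    ``prefilter='all_groups'`` keeps features expressed in every sample
    group; ``None`` disables it. Pairs whose vectors are constant are
    skipped (counted in a warning by the caller if desired). No
    multiple-testing correction is applied across the pair grid by default
    (fixed r/cP cutoffs are the contract); ``bh_correct=True`` replaces cP
    with BH-adjusted values for users who want it.
    """
    if list(lnc_expr.sample_ids) != list(gene_expr.sample_ids):
        raise ValueError("lncRNA and gene matrices must share identical sample columns")
    if prefilter == "all_groups":
        lnc_ids = expressed_in_all_groups(lnc_expr, prefilter_grouping, threshold)
        gene_ids = expressed_in_all_groups(gene_expr, prefilter_grouping, threshold)
    elif prefilter is None:
        lnc_ids = lnc_expr.feature_ids
        gene_ids = gene_expr.feature_ids
    else:
        raise ValueError(f"unknown prefilter {prefilter!r}")

    n = len(lnc_expr.sample_ids)
    results: list[CorrelationResult] = []
    for lnc_id in lnc_ids:
        x = lnc_expr.values.loc[lnc_id].to_numpy(dtype=float)
        if x.std() == 0:
            continue
        for gene_id in gene_ids:
            y = gene_expr.values.loc[gene_id].to_numpy(dtype=float)
            if y.std() == 0:
                continue
            r, cp = pearson_with_p(x, y)
            results.append(CorrelationResult(lnc_id=lnc_id, gene_id=gene_id, r=r, cP=cp, n=n))
    if bh_correct and results:
        adj = benjamini_hochberg(np.array([res.cP for res in results]))
        results = [
            CorrelationResult(lnc_id=res.lnc_id, gene_id=res.gene_id, r=res.r,
                              cP=float(a), n=res.n)
            for res, a in zip(results, adj)
        ]
    return results


@dataclass
class DualSignPattern:
    lnc_id: str
    positive_partners: set[str] = field(default_factory=set)
    negative_partners: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.positive_partners & self.negative_partners:
            raise ValueError("partner sets must be disjoint")

    def has_pattern(self, positive_gene: str | None, negative_gene: str | None) -> bool:
        ok = True
        if positive_gene is not None:
            ok &= positive_gene in self.positive_partners
        if negative_gene is not None:
            ok &= negative_gene in self.negative_partners
        return ok


def dual_sign_patterns(
    results: Iterable[CorrelationResult],
    gene_set: Sequence[str],
    tier: str = "strong",
) -> list[DualSignPattern]:
    """Per lncRNA, split its qualifying partners (at ``tier`` or better,
    restricted to ``gene_set``) by correlation sign. Only lncRNAs with
    partners of both signs — dual-sign coexpression — are returned."""
    genes = set(gene_set)
    by_lnc: dict[str, DualSignPattern] = {}
    for res in results:
        if res.gene_id not in genes or not res.at_least(tier):
            continue
        pat = by_lnc.setdefault(res.lnc_id, DualSignPattern(lnc_id=res.lnc_id))
        (pat.positive_partners if res.sign == "positive" else pat.negative_partners).add(
            res.gene_id
        )
    return [
        p for p in by_lnc.values() if p.positive_partners and p.negative_partners
    ]


@dataclass
class SpeciesComparison:
    fraction_a: float
    fraction_b: float
    n_qualifying_a: int
    n_qualifying_b: int
    n_lnc_a: int
    n_lnc_b: int
    patterns_only_a: set[tuple[frozenset[str], frozenset[str]]]
    patterns_only_b: set[tuple[frozenset[str], frozenset[str]]]


def _pattern_signatures(
    patterns: Iterable[DualSignPattern],
) -> set[tuple[frozenset[str], frozenset[str]]]:
    return {
        (frozenset(p.positive_partners), frozenset(p.negative_partners)) for p in patterns
    }


def species_comparison(
    results_a: Iterable[CorrelationResult],
    results_b: Iterable[CorrelationResult],
    gene_set: Sequence[str] | None = None,
    tier: str = "strong",
) -> SpeciesComparison:
    """Fraction of lncRNAs with >= 1 qualifying partner in each species,
    and dual-sign pattern signatures present in one species but not the
    other."""
    results_a = list(results_a)
    results_b = list(results_b)

    def summarize(results: list[CorrelationResult]) -> tuple[int, int]:
        lncs = {r.lnc_id for r in results}
        qualifying = {r.lnc_id for r in results if r.at_least(tier)}
        return len(qualifying), len(lncs)

    qa, na = summarize(results_a)
    qb, nb = summarize(results_b)
    gene_set = gene_set if gene_set is not None else sorted(
        {r.gene_id for r in results_a} | {r.gene_id for r in results_b}
    )
    sig_a = _pattern_signatures(dual_sign_patterns(results_a, gene_set, tier))
    sig_b = _pattern_signatures(dual_sign_patterns(results_b, gene_set, tier))
    return SpeciesComparison(
        fraction_a=qa / na if na else float("nan"),
        fraction_b=qb / nb if nb else float("nan"),
        n_qualifying_a=qa,
        n_qualifying_b=qb,
        n_lnc_a=na,
        n_lnc_b=nb,
        patterns_only_a=sig_a - sig_b,
        patterns_only_b=sig_b - sig_a,
    )
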