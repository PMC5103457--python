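"""Expression-based characterization: expressed/specific calls per group,
differential expression across tissues, and lncRNA-vs-PCG feature summaries.

A feature counts as expressed in a group when FPKM reaches the threshold
(default 0.3, the identification cutoff) in at least one sample of that
group, and as group-specific when it is expressed in exactly one group.

Differential expression uses a transparent replacement for assembly-era
tooling: log2 fold change on pseudocounted group means, a two-sided Welch
t-test on log2(FPKM + 1), and Benjamini-Hochberg FDR within each contrast.
A feature is significant when |log2FC| > 1 (fold change > 2) and FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import LncRNARecord
from .io_formats import ExpressionMatrix, GeneAnnotation


@dataclass
class SpecificityCall:
    feature_id: str
    expressed_groups: set[str]
    specific_to: str | None

    def __post_init__(self) -> None:
        if self.specific_to is not None and self.specific_to not in self.expressed_groups:
            raise ValueError("specific_to must be one of expressed_groups")


@dataclass
class DEResult:
    feature_id: str
    contrast: tuple[str, str]
    log2_fold_change: float
    raw_p: float
    fdr: float

    @property
    def significant(self) -> bool:
        return abs(self.log2_fold_change) > 1.0 and self.fdr < 0.05


def call_expressed(
    expr: ExpressionMatrix, grouping: str = "tissue", threshold: float = 0.3
) -> list[SpecificityCall]:
    """Expressed/specific calls per group ('tissue', 'condition' or
    'tissue_condition')."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    groups = expr.groups(grouping)
    calls = []
    for fid in expr.feature_ids:
        row = expr.values.loc[fid]
        expressed = {
            label for label, samples in groups.items() if (row[samples] >= threshold).any()
        }
        calls.append(
            SpecificityCall(
                feature_id=fid,
                expressed_groups=expressed,
                specific_to=next(iter(expressed)) if len(expressed) == 1 else None,
            )
        )
    return calls


def differential_expression(
    expr: ExpressionMatrix,
    contrasts: Sequence[tuple[str, str]],
    grouping: str = "tissue",
) -> list[DEResult]:
    """Per-contrast DE over all features: Welch t on log2(FPKM+1), BH-FDR
    within the contrast, log2FC on pseudocounted means. Each contrast group
    needs >= 2 samples."""
    groups = expr.groups(grouping)
    results: list[DEResult] = []
    log_values = np.log2(expr.values + 1.0)
    for group_a, group_b in contrasts:
        for g in (group_a, group_b):
            if g not in groups:
                raise KeyError(f"unknown group {g!r} for grouping {grouping!r}")
            if len(groups[g]) < 2:
                raise ValueError(f"contrast group {g!r} has < 2 samples; test degenerates")
        a = log_values[groups[group_a]].to_numpy()
        b = log_values[groups[group_b]].to_numpy()
        mean_a = expr.values[groups[group_a]].mean(axis=1).to_numpy()
        mean_b = expr.values[groups[group_b]].mean(axis=1).to_numpy()
        log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
        _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
        pvals = np.nan_to_num(pvals, nan=1.0)  # constant rows give p = 1
        fdr = benjamini_hochberg(pvals)
        for i, fid in enumerate(expr.feature_ids):
            results.append(
                DEResult(
                    feature_id=fid,
                    contrast=(group_a, group_b),
                    log2_fold_change=float(log2fc[i]),
                    raw_p=float(pvals[i]),
                    fdr=float(fdr[i]),
                )
            )
    return results


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, >= raw, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def gc_content(sequence: str) -> float:
    """GC percentage of a nucleotide sequence (N bases excluded from the
    denominator)."""
    seq = sequence.upper()
    counted = [c for c in seq if c in "ACGT"]
    if not counted:
        return float("nan")
    gc = sum(1 for c in counted if c in "GC")
    return 100.0 * gc / len(counted)


def summarize_features(
    lnc_records: Iterable[LncRNARecord],
    pcg: GeneAnnotation,
    expr: ExpressionMatrix,
    sequences: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """lncRNA-vs-PCG comparison of transcript length, exon count, mean FPKM
    and (when sequences are supplied) GC content: per-group medians and a
    two-sided Mann-Whitney p-value per feature."""
    lnc_models = [r.candidate.model for r in lnc_records]
    pcg_models = [m for ms in pcg.transcripts_by_gene.values() for m in ms]

    def mean_fpkm(tid: str) -> float | None:
        if tid in expr.values.index:
            return float(expr.values.loc[tid].mean())
        return None

    features: dict[str, tuple[list[float], list[float]]] = {
        "length": (
            [float(m.exonic_length) for m in lnc_models],
            [float(m.exonic_length) for m in pcg_models],
        ),
        "exon_count": (
            [float(m.exon_count) for m in lnc_models],
            [float(m.exon_count) for m in pcg_models],
        ),
        "mean_fpkm": (
            [v for m in lnc_models if (v := mean_fpkm(m.transcript_id)) is not None],
            [v for m in pcg_models if (v := mean_fpkm(m.transcript_id)) is not None],
        ),
    }
    if sequences is not None:
        features["gc_percent"] = (
            [gc_content(sequences[m.transcript_id]) for m in lnc_models
             if m.transcript_id in sequences],
            [gc_content(sequences[m.transcript_id]) for m in pcg_models
             if m.transcript_id in sequences],
        )

    rows = []
    for name, (lnc_vals, pcg_vals) in features.items():
        if not lnc_vals or not pcg_vals:
            raise ValueError(f"feature {name!r} has an empty group (missing sequences?)")
        identical = set(lnc_vals) == set(pcg_vals) and len(set(lnc_vals)) == 1
        if identical:
            p = 1.0
        else:
            _, p = stats.mannwhitneyu(lnc_vals, pcg_vals, alternative="two-sided")
        rows.append(
            {
                "feature": name,
                "lnc_median": float(np.median(lnc_vals)),
                "pcg_median": float(np.median(pcg_vals)),
                "mannwhitney_p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("feature")
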