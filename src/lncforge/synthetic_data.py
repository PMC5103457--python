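"""Seeded synthetic inputs with planted, recoverable ground truth.

Every pipeline stage gets an input generator whose truth labels are recorded
in a :class:`TruthSet`: an annotation with planted lncRNAs of the three
genomic-context classes, 12-sample FPKM matrices with planted pairwise
Pearson correlations, homology hit tables with controlled decoy noise,
collinear gene orders between two "species" with planted syntenic lncRNA
pairs, and gene->term maps with one over-represented term.

The default design mirrors a 12-transcriptome study: 3 tissues (brain,
kidney, liver) x 4 age/condition groups (newborn, young adult, young adult
under low oxygen, old adult). One RNG stream per sub-generator, all derived
from the master seed, so adding features to one generator never shifts the
outputs of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conservation import GeneLocus, OrthologPair
from .io_formats import (
    AnnotationMap,
    ExpressionMatrix,
    GeneAnnotation,
    HitRecord,
    TranscriptModel,
    write_annotation_map,
    write_expression_tsv,
    write_gtf,
    write_hits_tsv,
)


class SizingError(ValueError):
    """Requested features cannot be placed on the configured scaffolds."""


TISSUES = ("brain", "kidney", "liver")
CONDITIONS = ("newborn", "4y", "4y_lowO2", "20y")


@dataclass
class HitNoise:
    """Decoy-hit model for simulated homology tables.

    ``decoy_rate`` is the number of decoy hits as a fraction of true
    within-group hits. ``mode='filtered'`` draws decoys that fail the
    coverage>=50%/E<=1e-5 retention rule (removed upstream of clustering);
    ``mode='low_weight'`` draws decoys that pass it with near-threshold
    E-values, producing weak cross-cluster edges that stress the clustering.
    """

    decoy_rate: float = 0.0
    mode: str = "filtered"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_pcg: int = 20
    n_lnc_per_class: tuple[int, int, int] = (5, 5, 5)  # intergenic, intronic, antisense
    tissues: tuple[str, ...] = TISSUES
    conditions: tuple[str, ...] = CONDITIONS
    fpkm_lognormal_params: tuple[float, float] = (1.0, 1.2)  # lncRNA baseline
    pcg_lognormal_params: tuple[float, float] = (2.5, 1.0)
    planted_correlations: tuple[tuple[str, str, float], ...] = ()
    planted_specific: tuple[tuple[str, str, str], ...] = ()  # (feature, by, group)
    planted_ortholog_groups: tuple[int, ...] = ()  # group sizes
    synteny_layout: tuple[int, int, tuple[bool, ...]] = (6, 2, (False, False))
    n_syntenic_pairs: int = 4
    hit_noise: HitNoise = field(default_factory=HitNoise)
    enriched_term: tuple[str, float] = ("T000", 8.0)
    expressed_threshold: float = 0.3

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_lnc_per_class) or self.n_pcg < 0:
            raise ValueError("counts must be >= 0")
        for _, _, r in self.planted_correlations:
            if abs(r) > 1:
                raise ValueError(f"|target_r| must be <= 1, got {r}")

    @property
    def n_samples(self) -> int:
        return len(self.tissues) * len(self.conditions)

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for a named sub-generator stream (stable
        across processes: keyed by CRC32 of the stream name)."""
        key = zlib.crc32(stream.encode("utf-8"))
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class TruthSet:
    """Planted ground truth recoverable by the analysis modules."""

    class_labels: dict[str, str] = field(default_factory=dict)
    specific_groups: dict[str, tuple[str, str]] = field(default_factory=dict)
    planted_r: dict[tuple[str, str], float] = field(default_factory=dict)
    ortholog_groups: list[frozenset[str]] = field(default_factory=list)
    hit_labels: dict[tuple[str, str], str] = field(default_factory=dict)
    syntenic_pairs: list[tuple[str, str]] = field(default_factory=list)
    enriched_terms: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Annotation with planted lncRNA classes

def simulate_annotation(
    config: SimulationConfig,
) -> tuple[GeneAnnotation, list[TranscriptModel], TruthSet]:
    """Lay out protein-coding genes on a scaffold and plant lncRNAs of the
    three genomic-context classes.

    Intergenic lncRNAs sit in gene-free gaps; intronic lncRNAs sit wholly
    inside an intron on the host gene's strand with no exon overlap;
    antisense lncRNAs overlap a coding exon on the opposite strand. The
    construction guarantees the class labels, so a correct classifier must
    recover them exactly.
    """
    n_inter, n_intron, n_anti = config.n_lnc_per_class
    if config.n_pcg == 0 and (n_intron > 0 or n_anti > 0):
        raise SizingError(
            "intronic/antisense lncRNAs require protein-coding genes to host them; "
            "increase n_pcg or set those counts to 0"
        )
    rng = config.rng("annotation")
    scaffold = "scaffold_1"
    gap = 50_000

    pcg_models: list[TranscriptModel] = []
    introns_by_gene: dict[str, list[tuple[int, int]]] = {}
    cursor = gap
    for i in range(config.n_pcg):
        gene_id = f"PCG{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 15))  # mean 8, echoing a typical coding gene
        exons: list[tuple[int, int]] = []
        pos = cursor
        introns: list[tuple[int, int]] = []
        for j in range(n_exons):
            exon_len = int(rng.integers(100, 400))
            exons.append((pos, pos + exon_len - 1))
            pos += exon_len
            if j < n_exons - 1:
                intron_len = int(rng.integers(1500, 4000))
                introns.append((pos, pos + intron_len - 1))
                pos += intron_len
        pcg_models.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.t1",
                gene_id=gene_id,
                scaffold=scaffold,
                strand=strand,
                exons=tuple(exons),
                biotype_hint="protein_coding",
            )
        )
        introns_by_gene[gene_id] = introns
        cursor = pos + gap

    truth = TruthSet()
    lnc_models: list[TranscriptModel] = []
    n_lnc = 0

    def add_lnc(exons: list[tuple[int, int]], strand: str, label: str) -> None:
        nonlocal n_lnc
        tid = f"LNC{n_lnc:04d}"
        n_lnc += 1
        lnc_models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=tid,
                scaffold=scaffold,
                strand=strand,
                exons=tuple(exons),
            )
        )
        truth.class_labels[tid] = label

    # intergenic: placed in the gene-free region downstream of the last gene
    last_end = pcg_models[-1].span[1] if pcg_models else 0
    for k in range(n_inter):
        start = last_end + gap + k * 10_000 + 2_000
        n_ex = int(rng.integers(1, 4))
        exons = []
        pos = start
        for j in range(n_ex):
            ln = int(rng.integers(300, 1500))
            exons.append((pos, pos + ln - 1))
            pos += ln + int(rng.integers(200, 800))
        add_lnc(exons, "+" if rng.random() < 0.5 else "-", "intergenic")

    # intronic: single exon wholly inside a host intron, same strand, margins kept
    host_pool = [
        (g, iv)
        for g, ivs in introns_by_gene.items()
        for iv in ivs
        if iv[1] - iv[0] + 1 >= 900
    ]
    if n_intron > len(host_pool):
        raise SizingError(
            f"only {len(host_pool)} introns can host the {n_intron} requested "
            "intronic lncRNAs; increase n_pcg"
        )
    order = rng.permutation(len(host_pool))
    gene_strand = {m.gene_id: m.strand for m in pcg_models}
    for k in range(n_intron):
        gene_id, (istart, iend) = host_pool[order[k]]
        start = istart + 200
        end = min(iend - 200, start + int(rng.integers(300, 500)))
        add_lnc([(start, end)], gene_strand[gene_id], "intronic")

    # antisense: single exon overlapping a coding exon, opposite strand
    if n_anti > 0 and not pcg_models:
        raise SizingError("no genes available for antisense placement")
    for k in range(n_anti):
        host = pcg_models[int(rng.integers(0, len(pcg_models)))]
        ex_s, ex_e = host.exons[int(rng.integers(0, len(host.exons)))]
        mid = (ex_s + ex_e) // 2
        length = int(rng.integers(400, 900))
        add_lnc([(mid, mid + length - 1)], "-" if host.strand == "+" else "+", "antisense")

    annotation = GeneAnnotation.from_transcripts(pcg_models)
    return annotation, lnc_models, truth


# ---------------------------------------------------------------------------
# Expression with planted correlations and group-specific features

def blend_weight(target_r: float) -> float:
    """Blend weight w such that x = w*z + (1-w)*e has expected Pearson
    correlation ``target_r`` with z, for unit-variance independent z and e:
    r = w / sqrt(w^2 + (1-w)^2), solved for w in [0, 1]."""
    r = abs(target_r)
    if r >= 1.0:
        return 1.0
    return r / (r + np.sqrt(1.0 - r * r))


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("zero-variance vector cannot be standardized")
    return (v - v.mean()) / sd


def simulate_expression(
    config: SimulationConfig,
    features: list[str],
    lnc_features: set[str] | None = None,
    truth: TruthSet | None = None,
) -> tuple[ExpressionMatrix, TruthSet]:
    """Draw a features x samples FPKM matrix with planted structure.

    Baseline rows are log-normal (separate (mu, sigma) for lncRNA vs PCG
    rows). For each planted (lnc, gene, target_r) the lncRNA row is a
    deterministic blend of the standardized partner row and independent
    noise, mapped back to positive FPKM by a positive affine transform --
    Pearson-invariant, so the planted correlation survives exactly in
    expectation (and exactly, sample-wise, at |target_r| = 1).
    Group-specific features exceed the expressed threshold only in their
    group's samples.
    """
    truth = truth if truth is not None else TruthSet()
    rng = config.rng("expression")
    n = config.n_samples
    sample_ids = [f"{t}_{c}" for t in config.tissues for c in config.conditions]
    meta = pd.DataFrame(
        {
            "tissue": [s.split("_", 1)[0] for s in sample_ids],
            "condition": [s.split("_", 1)[1] for s in sample_ids],
        },
        index=sample_ids,
    )
    lnc_features = lnc_features or set()

    rows: dict[str, np.ndarray] = {}
    for f in features:
        mu, sigma = (
            config.fpkm_lognormal_params if f in lnc_features else config.pcg_lognormal_params
        )
        rows[f] = rng.lognormal(mean=mu, sigma=sigma, size=n)

    for lnc_id, gene_id, target_r in config.planted_correlations:
        if gene_id not in rows or lnc_id not in rows:
            raise KeyError(f"planted pair ({lnc_id}, {gene_id}) references unknown features")
        partner = rows[gene_id]
        if partner.std() == 0:
            raise ValueError(f"partner {gene_id} has zero variance; cannot plant r")
        z = _standardize(partner)
        w = blend_weight(target_r)
        if w == 1.0:
            x = np.sign(target_r) * z
        else:
            e = _standardize(rng.standard_normal(n))
            x = np.sign(target_r) * w * z + (1.0 - w) * e
        # positive affine map to the FPKM scale; leaves Pearson r unchanged
        rows[lnc_id] = (x - x.min()) * 5.0 + 0.5
        truth.planted_r[(lnc_id, gene_id)] = target_r

    thr = config.expressed_threshold
    for feature, by, group in config.planted_specific:
        if feature not in rows:
            raise KeyError(f"planted specific feature {feature} unknown")
        labels = meta[by]
        in_group = (labels == group).to_numpy()
        vals = np.empty(n)
        vals[in_group] = thr + rng.lognormal(mean=0.5, sigma=0.5, size=in_group.sum())
        vals[~in_group] = rng.uniform(0.0, thr * 0.3, size=(~in_group).sum())
        rows[feature] = vals
        truth.specific_groups[feature] = (by, group)

    values = pd.DataFrame(rows, index=sample_ids).T
    values.index.name = "feature_id"
    return ExpressionMatrix(values=values, sample_meta=meta), truth


# ---------------------------------------------------------------------------
# Homology hits with planted ortholog groups

SPECIES_CYCLE = ("NMR", "HUM", "MUS")


def make_ortholog_groups(config: SimulationConfig) -> TruthSet:
    """Materialize planted ortholog groups as species-tagged sequence ids
    (``SPECIES|name``), cycling members through the three species so each
    group is cross-species."""
    truth = TruthSet()
    counter = 0
    for size in config.planted_ortholog_groups:
        members = []
        for j in range(size):
            sp = SPECIES_CYCLE[j % len(SPECIES_CYCLE)]
            members.append(f"{sp}|lnc{counter:04d}")
            counter += 1
        truth.ortholog_groups.append(frozenset(members))
    return truth


def simulate_hits(config: SimulationConfig, truth: TruthSet) -> list[HitRecord]:
    """Emit all-vs-all-style hits: every within-group pair gets a
    high-coverage, low-E hit; decoy cross-group hits follow
    ``config.hit_noise``. Each emitted hit is labeled true/decoy in
    ``truth.hit_labels``."""
    rng = config.rng("hits")
    hits: list[HitRecord] = []

    def true_hit(a: str, b: str) -> HitRecord:
        return HitRecord(
            query_id=a,
            target_id=b,
            identity=float(rng.uniform(80, 99)),
            query_coverage=float(rng.uniform(60, 95)),
            target_coverage=float(rng.uniform(60, 95)),
            evalue=float(10.0 ** -rng.uniform(10, 50)),
            bitscore=float(rng.uniform(100, 500)),
        )

    for group in truth.ortholog_groups:
        members = sorted(group)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                h = true_hit(members[i], members[j])
                hits.append(h)
                truth.hit_labels[(h.query_id, h.target_id)] = "true"

    n_true = len(hits)
    n_decoy = int(round(config.hit_noise.decoy_rate * n_true))
    all_ids = sorted({m for g in truth.ortholog_groups for m in g})
    group_of = {m: gi for gi, g in enumerate(truth.ortholog_groups) for m in g}
    made = 0
    while made < n_decoy and len(all_ids) >= 2:
        a, b = rng.choice(all_ids, size=2, replace=False)
        if group_of[a] == group_of[b]:
            continue
        if config.hit_noise.mode == "low_weight":
            # passes the coverage/E retention rule but with near-threshold weight
            h = HitRecord(
                query_id=a,
                target_id=b,
                identity=float(rng.uniform(70, 85)),
                query_coverage=float(rng.uniform(50, 60)),
                target_coverage=float(rng.uniform(20, 45)),
                evalue=float(10.0 ** -rng.uniform(5, 6.5)),
                bitscore=float(rng.uniform(40, 80)),
            )
        else:
            if rng.random() < 0.5:  # fails the coverage rule
                h = HitRecord(
                    query_id=a,
                    target_id=b,
                    identity=float(rng.uniform(70, 90)),
                    query_coverage=float(rng.uniform(5, 45)),
                    target_coverage=float(rng.uniform(5, 45)),
                    evalue=float(10.0 ** -rng.uniform(6, 20)),
                    bitscore=float(rng.uniform(40, 100)),
                )
            else:  # fails the E-value rule
                h = HitRecord(
                    query_id=a,
                    target_id=b,
                    identity=float(rng.uniform(70, 90)),
                    query_coverage=float(rng.uniform(55, 90)),
                    target_coverage=float(rng.uniform(55, 90)),
                    evalue=float(10.0 ** -rng.uniform(0.1, 4.9)),
                    bitscore=float(rng.uniform(30, 60)),
                )
        hits.append(h)
        truth.hit_labels[(h.query_id, h.target_id)] = "decoy"
        made += 1
    return hits


# ---------------------------------------------------------------------------
# Synteny: collinear anchors + planted positionally conserved lncRNA pairs

def simulate_synteny(
    config: SimulationConfig,
) -> tuple[list[OrthologPair], list[TranscriptModel], list[TranscriptModel], TruthSet]:
    """Two "species" genomes with collinear (or inverted, per flag) ortholog
    anchor blocks, plus planted lncRNA pairs placed on the same side of an
    anchor pair with the same relative orientation — recoverable by the
    positional-conservation module at 100% precision/recall."""
    n_anchors, n_blocks, inversions = config.synteny_layout
    rng = config.rng("synteny")
    anchors: list[OrthologPair] = []
    gene_len = 20_000
    # anchors spaced wider than the positional windows (815/894 kb), so a
    # lncRNA planted within 100 kb of its anchor is in range of that anchor
    # only — planted pairs are then exactly the rule-implied matches
    spacing = 1_500_000
    counter = 0
    for b in range(n_blocks):
        inverted = bool(inversions[b]) if b < len(inversions) else False
        for i in range(n_anchors):
            j = n_anchors - 1 - i if inverted else i
            strand = "+" if rng.random() < 0.5 else "-"
            g1 = GeneLocus(
                gene_id=f"A_G{counter:03d}",
                scaffold=f"sp1_chr{b}",
                start=spacing * (i + 1),
                end=spacing * (i + 1) + gene_len,
                strand=strand,
                index=i,
            )
            g2 = GeneLocus(
                gene_id=f"B_G{counter:03d}",
                scaffold=f"sp2_chr{b}",
                start=spacing * (j + 1),
                end=spacing * (j + 1) + gene_len,
                strand=strand,
                index=j,
            )
            anchors.append(OrthologPair(sp1=g1, sp2=g2))
            counter += 1

    truth = TruthSet()
    lnc1: list[TranscriptModel] = []
    lnc2: list[TranscriptModel] = []

    def place_near(gene: GeneLocus, side: str, rel_same: bool, lnc_id: str) -> TranscriptModel:
        """Place a single-exon lncRNA fully on the requested side of the
        gene (side defined in the gene's 5'->3' frame), within 100 kb."""
        d = int(rng.integers(5_000, 100_000))
        ln = int(rng.integers(500, 3_000))
        five_prime_first = gene.strand == "+"
        before = (side == "upstream") == five_prime_first
        if before:
            end = gene.start - d
            start = end - ln + 1
        else:
            start = gene.end + d
            end = start + ln - 1
        strand = gene.strand if rel_same else ("-" if gene.strand == "+" else "+")
        return TranscriptModel(
            transcript_id=lnc_id,
            gene_id=lnc_id,
            scaffold=gene.scaffold,
            strand=strand,
            exons=((start, end),),
        )

    # each planted pair takes a distinct (side, orientation) combination so
    # that pairs whose distance windows overlap cannot cross-match: the
    # planted pairs are then exactly the rule-implied matches (zero noise)
    combos = (
        ("upstream", True),
        ("downstream", True),
        ("upstream", False),
        ("downstream", False),
    )
    chosen = rng.choice(len(anchors), size=min(config.n_syntenic_pairs, len(anchors)), replace=False)
    for k, ai in enumerate(sorted(int(c) for c in chosen)):
        pair = anchors[ai]
        side, rel_same = combos[k % len(combos)]
        l1 = place_near(pair.sp1, side, rel_same, f"sp1_L{k:03d}")
        l2 = place_near(pair.sp2, side, rel_same, f"sp2_L{k:03d}")
        lnc1.append(l1)
        lnc2.append(l2)
        truth.syntenic_pairs.append((l1.transcript_id, l2.transcript_id))
    return anchors, lnc1, lnc2, truth


# ---------------------------------------------------------------------------
# Enrichment inputs

def simulate_enrichment_inputs(
    config: SimulationConfig,
    n_universe: int = 300,
    n_terms: int = 20,
    term_size: tuple[int, int] = (8, 25),
    list_size: int = 40,
) -> tuple[AnnotationMap, list[str], set[str], TruthSet]:
    """A gene universe, random term assignments, and a gene list in which
    one configured term's genes are over-represented by the configured
    fold."""
    rng = config.rng("enrichment")
    universe = [f"G{i:04d}" for i in range(n_universe)]
    enriched_id, fold = config.enriched_term
    gene_terms: dict[str, set[str]] = {}
    term_ids = [enriched_id] + [f"T{i:03d}" for i in range(1, n_terms)]
    for term in term_ids:
        k = int(rng.integers(term_size[0], term_size[1]))
        for g in rng.choice(universe, size=k, replace=False):
            gene_terms.setdefault(str(g), set()).add(term)
    amap = AnnotationMap(gene_terms=gene_terms, namespace="GO")
    enriched_genes = amap.genes_with_term(enriched_id)
    weights = np.array([fold if g in enriched_genes else 1.0 for g in universe])
    weights = weights / weights.sum()
    gene_list = [str(g) for g in rng.choice(universe, size=list_size, replace=False, p=weights)]
    truth = TruthSet(enriched_terms={enriched_id})
    return amap, gene_list, set(universe), truth


# ---------------------------------------------------------------------------
# Whole-dataset writer (used by `lncforge simulate`)

def write_simulated_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Generate and write a coherent synthetic dataset to ``outdir``:
    pcg.gtf, transcripts.gtf (lncRNAs), fpkm.tsv + samples.tsv, hits.tsv
    and truth.tsv. Deterministic in the config seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, lncs, truth = simulate_annotation(config)
    pcg_models = [m for ms in annotation.transcripts_by_gene.values() for m in ms]
    features = [m.transcript_id for m in pcg_models] + [t.transcript_id for t in lncs]
    expr, truth = simulate_expression(
        config, features, lnc_features={t.transcript_id for t in lncs}, truth=truth
    )
    group_truth = make_ortholog_groups(config)
    truth.ortholog_groups = group_truth.ortholog_groups
    hits = simulate_hits(config, truth)

    paths = {
        "pcg_gtf": str(outdir / "pcg.gtf"),
        "lnc_gtf": str(outdir / "transcripts.gtf"),
        "expr": str(outdir / "fpkm.tsv"),
        "meta": str(outdir / "samples.tsv"),
        "hits": str(outdir / "hits.tsv"),
        "truth": str(outdir / "truth.tsv"),
    }
    write_gtf(pcg_models, paths["pcg_gtf"])
    write_gtf(lncs, paths["lnc_gtf"])
    write_expression_tsv(expr, paths["expr"], paths["meta"])
    write_hits_tsv(hits, paths["hits"])
    with open(paths["truth"], "w") as fh:
        for tid, label in truth.class_labels.items():
            fh.write(f"class\t{tid}\t{label}\n")
        for (lnc, gene), r in truth.planted_r.items():
            fh.write(f"planted_r\t{lnc}\t{gene}\t{r}\n")
        for gi, group in enumerate(truth.ortholog_groups):
            for m in sorted(group):
                fh.write(f"ortholog_group\t{gi}\t{m}\n")
    return paths
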