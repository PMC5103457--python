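"""Cross-species lncRNA conservation: sequence and position.

Sequence conservation: homology hits are filtered (coverage >= 50%,
E <= 1e-5), assembled into a weighted graph and clustered with the Markov
Cluster (MCL) algorithm into orthologous groups of >= 2 members.

Positional conservation: orthologous protein-coding anchors are chained
into syntenic blocks (longest monotone chains of gene ordinals, collinear
or inverted), and lncRNAs near an anchor pair are matched when they lie on
the same side (upstream/downstream in the anchor gene's 5'->3' frame) in
both species, within per-species distance windows (defaults 815 kb and
894 kb), with the same orientation relative to their anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .io_formats import HitRecord, TranscriptModel

WEIGHT_CAP = 200.0  # -log10(E) cap; E = 0 maps here


@dataclass(frozen=True)
class GeneLocus:
    """A protein-coding gene's position in one species: genomic span plus
    its ordinal index along the scaffold (used for chaining)."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    index: int


@dataclass(frozen=True)
class OrthologPair:
    sp1: GeneLocus
    sp2: GeneLocus


@dataclass(frozen=True)
class OrthologGroup:
    group_id: int
    members: frozenset[tuple[str, str]]  # (species, sequence id)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("ortholog groups need >= 2 members")


@dataclass
class SyntenyBlock:
    scaffold_pair: tuple[str, str]
    anchors: list[OrthologPair]
    orientation: str  # 'collinear' | 'inverted'


@dataclass(frozen=True)
class PositionalMatch:
    lnc1_id: str
    lnc2_id: str
    anchor1_id: str
    anchor2_id: str
    side: str  # 'upstream' | 'downstream'
    relative_orientation: str  # 'same' | 'opposite'


def species_of(seq_id: str, sep: str = "|") -> str:
    if sep not in seq_id:
        raise ValueError(f"sequence id {seq_id!r} carries no species tag (expected 'SPECIES{sep}name')")
    return seq_id.split(sep, 1)[0]


def edge_weight(evalue: float) -> float:
    """-log10(E), capped at 200; E = 0 takes the cap."""
    if evalue <= 0:
        return WEIGHT_CAP
    return min(WEIGHT_CAP, -np.log10(evalue))


def build_homology_graph(
    hits: Iterable[HitRecord],
    coverage_min: float = 50.0,
    evalue_max: float = 1e-5,
    coverage_rule: str = "max",
    species_sep: str = "|",
) -> nx.Graph:
    """Retain hits passing the coverage/E-value rule and assemble an
    undirected weighted graph.

    ``coverage_rule='max'`` retains when either coverage reaches the cutoff
    (the permissive reading of an unqualified "coverage"); ``'min'``
    requires both. Reciprocal hits are merged keeping the larger weight;
    self-hits are dropped. Node attribute ``species`` comes from the id's
    prefix tag.
    """
    g = nx.Graph()
    for h in hits:
        if h.query_id == h.target_id:
            continue
        cov = (
            max(h.query_coverage, h.target_coverage)
            if coverage_rule == "max"
            else min(h.query_coverage, h.target_coverage)
        )
        if cov < coverage_min or h.evalue > evalue_max:
            continue
        w = edge_weight(h.evalue)
        for node in (h.query_id, h.target_id):
            g.add_node(node, species=species_of(node, species_sep))
        if g.has_edge(h.query_id, h.target_id):
            g[h.query_id][h.target_id]["weight"] = max(g[h.query_id][h.target_id]["weight"], w)
        else:
            g.add_edge(h.query_id, h.target_id, weight=w)
    return g


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 1.5,
    max_iter: int = 100,
    tol: float = 1e-6,
    species_sep: str = "|",
) -> list[OrthologGroup]:
    """Markov clustering of the homology graph into orthologous groups.

    The transition matrix is column-stochastic with per-node self-loops
    weighted by the node's maximum incident edge weight; iterations
    alternate expansion (matrix squaring) and inflation (entrywise power
    then column renormalization) until the largest entry change falls below
    ``tol``. Clusters are read off the converged matrix's nonzero
    structure; singletons are dropped (a group needs >= 2 members).
    """
    if inflation <= 1:
        raise ValueError(f"inflation must be > 1, got {inflation}")
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("empty graph")
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = data.get("weight", 1.0)
    for i, v in enumerate(nodes):
        incident = [graph[v][u]["weight"] for u in graph[v]]
        m[i, i] = max(incident) if incident else 1.0
    m = m / m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = np.power(expanded, inflation)
        inflated[inflated < 1e-12] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new = inflated / colsum
        if np.max(np.abs(new - m)) < tol:
            m = new
            converged = True
            break
        m = new
    if not converged:
        warnings.warn("MCL did not converge within max_iter; clustering the final matrix")

    structure = nx.Graph()
    structure.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > 1e-8)
    structure.add_edges_from(zip(rows.tolist(), cols.tolist()))
    groups: list[OrthologGroup] = []
    gid = 0
    for comp in sorted(nx.connected_components(structure), key=lambda c: sorted(c)[0]):
        if len(comp) < 2:
            continue
        members = frozenset(
            (species_of(nodes[i], species_sep), nodes[i]) for i in comp
        )
        groups.append(OrthologGroup(group_id=gid, members=members))
        gid += 1
    return groups


# ---------------------------------------------------------------------------
# Syntenic blocks

def _best_chain(
    anchors: Sequence[OrthologPair], direction: int, max_gap: int
) -> list[int]:
    """Longest chain of anchors with sp1 ordinals strictly increasing and
    sp2 ordinals strictly monotone (``direction`` +1/-1), consecutive
    anchors differing by <= max_gap ordinals in both species. Quadratic DP;
    returns indices into ``anchors`` (already sorted by sp1 ordinal)."""
    n = len(anchors)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            a, b = anchors[j], anchors[i]
            if b.sp1.index <= a.sp1.index or b.sp1.index - a.sp1.index > max_gap:
                continue
            d2 = (b.sp2.index - a.sp2.index) * direction
            if d2 <= 0 or d2 > max_gap:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = int(np.argmax(best_len))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def find_synteny_blocks(
    orthologs: Iterable[OrthologPair],
    min_block_size: int = 5,
    max_gap: int = 25,
) -> list[SyntenyBlock]:
    """Chain ortholog anchors into syntenic blocks per scaffold pair.

    Chains are extracted greedily by size: the longest strictly monotone
    chain (increasing = collinear, decreasing = inverted) is emitted as a
    block, its anchors removed, and the search repeated until no chain
    reaches ``min_block_size``. Each anchor therefore belongs to at most
    one block. Duplicate ortholog pairs are deduplicated with a warning.
    """
    seen: set[tuple[str, str]] = set()
    by_pair: dict[tuple[str, str], list[OrthologPair]] = {}
    for p in orthologs:
        key = (p.sp1.gene_id, p.sp2.gene_id)
        if key in seen:
            warnings.warn(f"duplicate ortholog pair {key} dropped")
            continue
        seen.add(key)
        by_pair.setdefault((p.sp1.scaffold, p.sp2.scaffold), []).append(p)

    blocks: list[SyntenyBlock] = []
    for scaffold_pair in sorted(by_pair):
        remaining = sorted(by_pair[scaffold_pair], key=lambda p: (p.sp1.index, p.sp2.index))
        while len(remaining) >= min_block_size:
            up = _best_chain(remaining, +1, max_gap)
            down = _best_chain(remaining, -1, max_gap)
            chain, orientation = (
                (up, "collinear") if len(up) >= len(down) else (down, "inverted")
            )
            if len(chain) < min_block_size:
                break
            chosen = [remaining[i] for i in chain]
            blocks.append(
                SyntenyBlock(scaffold_pair=scaffold_pair, anchors=chosen, orientation=orientation)
            )
            picked = set(chain)
            remaining = [a for i, a in enumerate(remaining) if i not in picked]
    return blocks


# ---------------------------------------------------------------------------
# Positional conservation

def _sides_of(lnc: TranscriptModel, gene: GeneLocus) -> set[str]:
    """Side(s) of a lncRNA relative to a gene, in the gene's 5'->3' frame:
    upstream if the lncRNA overlaps, or ends at/before, the 5' end;
    downstream if it overlaps, or starts at/after, the 3' end. A lncRNA
    strictly inside the gene body is on neither side; one spanning the
    whole gene is on both."""
    ls, le = lnc.span
    sides: set[str] = set()
    if gene.strand == "+":
        if ls <= gene.start:
            sides.add("upstream")
        if le >= gene.end:
            sides.add("downstream")
    else:
        if le >= gene.end:
            sides.add("upstream")
        if ls <= gene.start:
            sides.add("downstream")
    return sides


def _edge_distance(lnc: TranscriptModel, gene: GeneLocus) -> int:
    ls, le = lnc.span
    return max(0, gene.start - le, ls - gene.end)


def positional_matches(
    lnc_sp1: Iterable[TranscriptModel],
    lnc_sp2: Iterable[TranscriptModel],
    blocks: Iterable[SyntenyBlock],
    window_sp1: int = 815_000,
    window_sp2: int = 894_000,
) -> list[PositionalMatch]:
    """Positionally conserved lncRNA pairs across two species.

    For every anchor pair (G1, G2) in every block, lncRNAs within the
    species window of the respective gene (closest-edge distance) are
    paired when they lie on the same side of both anchors and have the
    same orientation relative to their anchor gene. Anchors or lncRNAs
    with unknown strand are skipped with a warning.
    """
    lnc1 = [t for t in lnc_sp1]
    lnc2 = [t for t in lnc_sp2]
    for pool in (lnc1, lnc2):
        unknown = [t.transcript_id for t in pool if t.strand == "."]
        if unknown:
            warnings.warn(f"lncRNAs with unknown strand skipped: {unknown}")
    lnc1 = [t for t in lnc1 if t.strand != "."]
    lnc2 = [t for t in lnc2 if t.strand != "."]

    matches: list[PositionalMatch] = []
    seen: set[tuple[str, str, str, str]] = set()
    for block in blocks:
        for anchor in block.anchors:
            g1, g2 = anchor.sp1, anchor.sp2
            if g1.strand == "." or g2.strand == ".":
                warnings.warn(f"anchor ({g1.gene_id}, {g2.gene_id}) has unknown strand; skipped")
                continue
            cands1 = [
                t for t in lnc1
                if t.scaffold == g1.scaffold and _edge_distance(t, g1) <= window_sp1
            ]
            cands2 = [
                t for t in lnc2
                if t.scaffold == g2.scaffold and _edge_distance(t, g2) <= window_sp2
            ]
            for t1 in cands1:
                sides1 = _sides_of(t1, g1)
                if not sides1:
                    continue
                rel1 = t1.strand == g1.strand
                for t2 in cands2:
                    rel2 = t2.strand == g2.strand
                    if rel1 != rel2:
                        continue
                    common = sides1 & _sides_of(t2, g2)
                    for side in sorted(common):
                        key = (t1.transcript_id, t2.transcript_id, anchor.sp1.gene_id, side)
                        if key in seen:
                            continue
                        seen.add(key)
                        matches.append(
                            PositionalMatch(
                                lnc1_id=t1.transcript_id,
                                lnc2_id=t2.transcript_id,
                                anchor1_id=g1.gene_id,
                                anchor2_id=g2.gene_id,
                                side=side,
                                relative_orientation="same" if rel1 else "opposite",
                            )
                        )
    return matches


def matched_lnc_pairs(matches: Iterable[PositionalMatch]) -> set[tuple[str, str]]:
    """Unique (lnc1, lnc2) pairs supported by >= 1 anchor."""
    return {(m.lnc1_id, m.lnc2_id) for m in matches}
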