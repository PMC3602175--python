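"""Gene-order dot-plots, colinear blocks and reference-guided contig ordering.

The dot-plot axis is gene rank (order index along the genome), not
nucleotide coordinate: each dot is a protein match between two genomes,
same-orientation matches drawn black, reverse-orientation gray, mutual
best hits larger.  Colinear blocks are maximal monotone chains of matches
(longest-increasing/decreasing-subsequence chaining on rank pairs) under a
configurable rank-gap tolerance, so block length is a gene count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .families import EVALUE_MAX
from .genome_io import AnnotatedGenome


@dataclass(frozen=True)
class GeneMatch:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    orientation: str  # "same" | "reverse" (product of strands)
    is_best: bool


@dataclass
class ColinearBlock:
    matches: list[GeneMatch]
    direction: str  # "same" (both ranks increasing) | "inverted"

    @property
    def length(self) -> int:
        return len(self.matches)


def _mutual_best_pairs(sub: pd.DataFrame) -> set[frozenset[str]]:
    """Mutual best hits within a two-genome (or self-comparison) hit subset."""
    best: dict[str, tuple] = {}
    for row in sub.itertuples(index=False):
        rank = (-row.score, row.evalue, -row.aln_length, row.subject_id)
        if row.query_id not in best or rank < best[row.query_id][0]:
            best[row.query_id] = (rank, row.subject_id)
    pairs = set()
    for query, (_, subject) in best.items():
        back = best.get(subject)
        if back is not None and back[1] == query:
            pairs.add(frozenset((query, subject)))
    return pairs


def dotplot_matches(genome_a: AnnotatedGenome, genome_b: AnnotatedGenome,
                    hits: pd.DataFrame,
                    evalue_max: float = EVALUE_MAX) -> list[GeneMatch]:
    """One match per hit between the two genomes passing the e-value filter."""
    rank_a = {g.gene_id: i for i, g in enumerate(genome_a.genes)}
    rank_b = {g.gene_id: i for i, g in enumerate(genome_b.genes)}
    strand_a = {g.gene_id: g.strand for g in genome_a.genes}
    strand_b = {g.gene_id: g.strand for g in genome_b.genes}
    ids = {genome_a.genome_id, genome_b.genome_id}
    both = hits[hits["query_genome"].isin(ids)
                & hits["subject_genome"].isin(ids)
                & (hits["evalue"] < evalue_max)]
    best_pairs = _mutual_best_pairs(both)
    sub = both[(both["query_genome"] == genome_a.genome_id)
               & (both["subject_genome"] == genome_b.genome_id)]
    matches = []
    seen = set()
    for row in sub.itertuples(index=False):
        key = (row.query_id, row.subject_id)
        if key in seen or row.query_id not in rank_a or \
                row.subject_id not in rank_b:
            continue
        seen.add(key)
        orientation = ("same" if strand_a[row.query_id] == strand_b[row.subject_id]
                       else "reverse")
        matches.append(GeneMatch(
            row.query_id, row.subject_id,
            rank_a[row.query_id], rank_b[row.subject_id], orientation,
            frozenset((row.query_id, row.subject_id)) in best_pairs))
    return matches


def self_matches(genome: AnnotatedGenome) -> list[GeneMatch]:
    """Identity dot-plot of a genome against itself (main diagonal)."""
    return [GeneMatch(g.gene_id, g.gene_id, i, i, "same", True)
            for i, g in enumerate(genome.genes)]


# ---------------------------------------------------------------------------
# Colinear block chaining
# ---------------------------------------------------------------------------

def _longest_chain(matches: list[GeneMatch], max_gap: int,
                   inverted: bool) -> list[int]:
    """Indices of the longest monotone chain by O(n^2) DP.

    rank_a strictly increases; rank_b strictly increases (same-direction)
    or strictly decreases (inverted); consecutive rank gaps on both axes
    are at most ``max_gap`` intervening genes (rank difference <= max_gap+1).
    """
    order = sorted(range(len(matches)),
                   key=lambda i: (matches[i].rank_a,
                                  matches[i].rank_b if not inverted
                                  else -matches[i].rank_b))
    n = len(order)
    best_len = [1] * n
    prev = [-1] * n
    step = max_gap + 1
    for i in range(n):
        mi = matches[order[i]]
        for j in range(i):
            mj = matches[order[j]]
            if not (0 < mi.rank_a - mj.rank_a <= step):
                continue
            db = mi.rank_b - mj.rank_b
            if inverted:
                db = -db
            if not (0 < db <= step):
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: best_len[i], default=-1)
    if end < 0:
        return []
    chain = []
    while end != -1:
        chain.append(order[end])
        end = prev[end]
    return chain[::-1]


def colinear_blocks(matches: Sequence[GeneMatch], max_gap: int = 3,
                    min_length: int = 2) -> list[ColinearBlock]:
    """Greedily extract maximal colinear blocks, longest first.

    At each step the longest same-direction or inverted chain over the
    remaining matches is removed and reported; extraction stops when no
    chain reaches ``min_length``.
    """
    remaining = list(matches)
    blocks: list[ColinearBlock] = []
    while remaining:
        fwd = _longest_chain(remaining, max_gap, inverted=False)
        rev = _longest_chain(remaining, max_gap, inverted=True)
        chain, direction = ((fwd, "same") if len(fwd) >= len(rev)
                            else (rev, "inverted"))
        if len(chain) < min_length:
            break
        chosen = set(chain)
        blocks.append(ColinearBlock([remaining[i] for i in chain], direction))
        remaining = [m for i, m in enumerate(remaining) if i not in chosen]
    return blocks


def blocks_to_frame(blocks: Sequence[ColinearBlock]) -> pd.DataFrame:
    rows = []
    for bid, block in enumerate(blocks):
        for m in block.matches:
            rows.append({"block_id": bid, "direction": block.direction,
                         "block_length": block.length,
                         "gene_a": m.gene_a, "gene_b": m.gene_b,
                         "rank_a": m.rank_a, "rank_b": m.rank_b})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference-guided contig ordering
# ---------------------------------------------------------------------------

def order_contigs(assembly: AnnotatedGenome, reference: AnnotatedGenome,
                  hits: pd.DataFrame) -> tuple[AnnotatedGenome, pd.DataFrame]:
    """Order and orient assembly contigs by colinearity with a reference.

    Each contig is anchored by its genes' mutual best hits in the
    reference: placement is the median reference rank of the anchors,
    orientation the majority strand agreement.  Contigs are sorted by
    anchor median (ties: longer contig first, then id); unanchored contigs
    are appended last and flagged.  With no anchors at all, the assembly
    is returned unchanged with a warning in the report.
    """
    import statistics
    import warnings as _warnings

    ref_rank = {g.gene_id: i for i, g in enumerate(reference.genes)}
    ref_strand = {g.gene_id: g.strand for g in reference.genes}
    ids = {assembly.genome_id, reference.genome_id}
    sub = hits[hits["query_genome"].isin(ids) & hits["subject_genome"].isin(ids)
               & (hits["query_genome"] != hits["subject_genome"])]
    best_pairs = _mutual_best_pairs(sub)
    best_of = {}
    for pair in best_pairs:
        a, b = pair
        if a in ref_rank:
            a, b = b, a
        best_of[a] = b  # assembly gene -> reference gene

    contig_len = {cid: len(seq) for cid, seq in assembly.contigs}
    placements = []
    for cid, _seq in assembly.contigs:
        anchors = [(g, best_of[g.gene_id]) for g in assembly.genes
                   if g.contig_id == cid and g.gene_id in best_of]
        if not anchors:
            placements.append({"contig_id": cid, "anchored": False,
                               "median_rank": None, "orientation": "+",
                               "n_anchors": 0})
            continue
        ranks = [ref_rank[ref_gene] for _g, ref_gene in anchors]
        agree = sum(g.strand == ref_strand[ref_gene] for g, ref_gene in anchors)
        orientation = "+" if 2 * agree >= len(anchors) else "-"
        placements.append({"contig_id": cid, "anchored": True,
                           "median_rank": statistics.median(ranks),
                           "orientation": orientation,
                           "n_anchors": len(anchors)})
    report = pd.DataFrame(placements)
    if not report["anchored"].any():
        _warnings.warn(f"{assembly.genome_id}: no anchors to {reference.genome_id}; "
                       "contig order unchanged and must be taken with caution")
        return assembly, report

    anchored = sorted(
        (p for p in placements if p["anchored"]),
        key=lambda p: (p["median_rank"], -contig_len[p["contig_id"]],
                       p["contig_id"]))
    unanchored = sorted(
        (p for p in placements if not p["anchored"]),
        key=lambda p: (-contig_len[p["contig_id"]], p["contig_id"]))

    seqs = dict(assembly.contigs)
    new_contigs = []
    new_genes = []
    for p in anchored + unanchored:
        cid = p["contig_id"]
        seq = seqs[cid]
        genes_here = [g for g in assembly.genes if g.contig_id == cid]
        if p["orientation"] == "-":
            from dataclasses import replace
            from .genome_io import reverse_complement
            L = len(seq)
            seq = reverse_complement(seq)
            genes_here = [replace(g, start=L - g.end, end=L - g.start,
                                  strand="-" if g.strand == "+" else "+")
                          for g in genes_here]
        new_contigs.append((cid, seq))
        new_genes.extend(genes_here)
    ordered = AnnotatedGenome(assembly.genome_id, new_contigs, new_genes,
                              host_group=assembly.host_group)
    return ordered, report


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_dotplot(matches: Sequence[GeneMatch], out: str | Path,
                   label_a: str = "genome A", label_b: str = "genome B") -> None:
    """Scatter rank_a vs rank_b: same-orientation black, reverse gray,
    mutual best hits larger."""
    if not matches:
        raise ValueError("no matches to plot")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for orientation, color in (("same", "black"), ("reverse", "0.6")):
        for best, size in ((True, 18), (False, 5)):
            xs = [m.rank_a for m in matches
                  if m.orientation == orientation and m.is_best == best]
            ys = [m.rank_b for m in matches
                  if m.orientation == orientation and m.is_best == best]
            if xs:
                ax.scatter(xs, ys, s=size, c=color, marker="o", linewidths=0)
    ax.set_xlabel(f"gene rank in {label_a}")
    ax.set_ylabel(f"gene rank in {label_b}")
    fig.tight_layout()
    fig.savefig(str(out))
    plt.close(fig)
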