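"""Ortholog family construction from pairwise protein similarity.

Families are built the classical way for small viral proteomes: putative
ortholog pairs are cross-genome reciprocal best hits (RBH) by alignment
score, RBH pairs are assembled into clusters by single linkage (connected
components of the RBH graph), and within-genome duplicates (in-paralogs)
are appended to an existing cluster when their score to some member exceeds
every score between that member and the rest of the cluster.  Remaining
proteins become singletons.

Two hit sources are supported: an internal Smith-Waterman engine
(BLOSUM62, affine gaps, Karlin-Altschul-style e-values) so the pipeline
runs with no external binary, and an imported 12-column tabular hit file
(BLAST ``outfmt 6`` dialect) for full-scale runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

EVALUE_MAX = 1e-5

# Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1
_KA_LAMBDA = 0.267
_KA_K = 0.041

HIT_COLUMNS = ["query_id", "subject_id", "query_genome", "subject_genome",
               "score", "evalue", "identity", "aln_length"]

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    """Expectation value for a local alignment score over an m x n search space."""
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def _alignment_stats(alignment) -> tuple[float, int]:
    """Percent identity and aligned length (incl. gaps) of one alignment."""
    a, b = alignment[0], alignment[1]
    matches = sum(x == y for x, y in zip(a, b) if x != "-" and y != "-")
    length = len(a)
    return (100.0 * matches / length if length else 0.0), length


def _sanitize(seq: str) -> str:
    # internal stops in deposited ORFs are scored as unknown residues
    return seq.replace("*", "X").upper()


def pairwise_scores(proteomes: Mapping[str, Mapping[str, str]],
                    engine: str = "internal",
                    hits_path: str | Path | None = None,
                    evalue_max: float = EVALUE_MAX) -> pd.DataFrame:
    """All-vs-all directed protein hits, filtered at ``evalue_max``.

    ``proteomes`` maps genome_id -> {protein_id: sequence}.  The internal
    engine aligns every unordered pair once (Smith-Waterman is symmetric)
    and emits both directed records.  Within-genome pairs are included:
    the in-paralog rule needs them.
    """
    if engine == "imported":
        if hits_path is None:
            raise ValueError("imported engine requires hits_path")
        genome_of = {p: g for g, prots in proteomes.items() for p in prots}
        return read_hit_table(hits_path, genome_of, evalue_max=evalue_max)
    if engine != "internal":
        raise ValueError(f"unknown engine {engine!r}")

    items: list[tuple[str, str, str]] = []  # (genome, protein, seq)
    for genome, prots in proteomes.items():
        if not prots:
            warnings.warn(f"genome {genome} has an empty proteome; excluded")
            continue
        for pid, seq in prots.items():
            items.append((genome, pid, _sanitize(seq)))

    aligner = make_aligner()
    rows = []
    for i in range(len(items)):
        gi, pi, si = items[i]
        for j in range(i + 1, len(items)):
            gj, pj, sj = items[j]
            score = aligner.score(si, sj)
            ev = karlin_altschul_evalue(score, len(si), len(sj))
            if ev >= evalue_max:
                continue
            identity, aln_len = _alignment_stats(aligner.align(si, sj)[0])
            rows.append((pi, pj, gi, gj, score, ev, identity, aln_len))
            rows.append((pj, pi, gj, gi, score, ev, identity, aln_len))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def read_hit_table(path: str | Path, genome_of: Mapping[str, str],
                   evalue_max: float = EVALUE_MAX) -> pd.DataFrame:
    """Parse a 12-column tabular hit file (BLAST outfmt-6 dialect)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}")
            try:
                rec = dict(zip(OUTFMT6_COLUMNS, cols))
                q, s = rec["qseqid"], rec["sseqid"]
                ev = float(rec["evalue"])
                if ev >= evalue_max:
                    continue
                rows.append((q, s, genome_of[q], genome_of[s],
                             float(rec["bitscore"]), ev,
                             float(rec["pident"]), int(rec["length"])))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})")
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    # collapse multiple HSPs per (query, subject) to the best-scoring one
    return (df.sort_values(["score", "evalue"], ascending=[False, True])
              .drop_duplicates(["query_id", "subject_id"])
              .reset_index(drop=True))


# ---------------------------------------------------------------------------
# RBH and clustering
# ---------------------------------------------------------------------------

def _best_hits(hits: pd.DataFrame) -> dict[tuple[str, str], str]:
    """Best subject per (query, subject_genome), cross-genome hits only.

    Ties broken by higher score, lower e-value, longer alignment, then
    lexicographically smaller subject id.
    """
    cross = hits[hits["query_genome"] != hits["subject_genome"]]
    best: dict[tuple[str, str], tuple] = {}
    for row in cross.itertuples(index=False):
        key = (row.query_id, row.subject_genome)
        rank = (-row.score, row.evalue, -row.aln_length, row.subject_id)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, row.subject_id)
    return {key: subject for key, (_, subject) in best.items()}


def reciprocal_best_hits(hits: pd.DataFrame,
                         genome_of: Mapping[str, str] | None = None,
                         ) -> set[frozenset[str]]:
    """Unordered cross-genome pairs that are mutually each other's best hit."""
    if hits.empty:
        return set()
    if genome_of is None:
        genome_of = {}
        for row in hits.itertuples(index=False):
            genome_of[row.query_id] = row.query_genome
            genome_of[row.subject_id] = row.subject_genome
    best = _best_hits(hits)
    pairs = set()
    for (query, sgenome), subject in best.items():
        if best.get((subject, genome_of[query])) == query:
            pairs.add(frozenset((query, subject)))
    return pairs


@dataclass
class FamilySet:
    """A partition of the proteome into ortholog clusters and singletons."""

    clusters: dict[str, set[str]]
    singletons: list[str]
    membership_type: dict[str, str]  # protein -> ortholog | inparalog | singleton
    rbh_pairs: set[frozenset[str]] = field(default_factory=set)
    inparalog_assignments: dict[str, str] = field(default_factory=dict)

    def family_of(self) -> dict[str, str]:
        out = {p: fid for fid, members in self.clusters.items() for p in members}
        for p in self.singletons:
            out[p] = f"singleton:{p}"
        return out

    def all_proteins(self) -> set[str]:
        out = set(self.singletons)
        for members in self.clusters.values():
            out |= members
        return out

    def to_frame(self, genome_of: Mapping[str, str]) -> pd.DataFrame:
        rows = []
        for fid, members in sorted(self.clusters.items()):
            for p in sorted(members):
                rows.append((fid, p, genome_of[p], self.membership_type[p]))
        for p in sorted(self.singletons):
            rows.append((f"singleton:{p}", p, genome_of[p], "singleton"))
        return pd.DataFrame(rows, columns=["family_id", "protein_id",
                                           "genome_id", "membership_type"])


def single_linkage_clusters(pairs: Iterable[frozenset[str]]) -> FamilySet:
    """Clusters are the connected components of the RBH graph.

    Cluster ids are assigned deterministically: components sorted by their
    lexicographically smallest member.
    """
    graph = nx.Graph()
    for pair in pairs:
        a, b = sorted(pair)
        graph.add_edge(a, b)
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    clusters = {f"CL{i:04d}": set(comp) for i, comp in enumerate(components)}
    membership = {p: "ortholog" for comp in components for p in comp}
    return FamilySet(clusters=clusters, singletons=[],
                     membership_type=membership, rbh_pairs=set(pairs))


def _score_lookup(hits: pd.DataFrame) -> dict[frozenset[str], float]:
    scores: dict[frozenset[str], float] = {}
    for row in hits.itertuples(index=False):
        key = frozenset((row.query_id, row.subject_id))
        if len(key) < 2:
            continue
        if key not in scores or row.score > scores[key]:
            scores[key] = row.score
    return scores


def assign_inparalogs(families: FamilySet, hits: pd.DataFrame,
                      proteome: Iterable[str]) -> FamilySet:
    """Append unassigned proteins to clusters by the score-margin rule.

    A protein p joins cluster C if some member m of C satisfies
    score(p, m) > max over other members m' of score(m, m'); when several
    clusters qualify, p joins the one with the largest margin.  For a
    single-member cluster the inner max is vacuous (treated as -inf), so
    any scored hit suffices.  Proteins joining no cluster become singletons.

    The rule is evaluated for every candidate against the *original*
    cluster memberships, so the result does not depend on candidate order.
    """
    scores = _score_lookup(hits)
    assigned = families.all_proteins()
    original = {fid: frozenset(members)
                for fid, members in families.clusters.items()}
    clusters = {fid: set(members) for fid, members in families.clusters.items()}
    membership = dict(families.membership_type)
    inparalog_assignments = dict(families.inparalog_assignments)
    singletons: list[str] = []

    for p in sorted(set(proteome) - assigned):
        best_margin, best_fid = None, None
        for fid, members in original.items():
            for m in members:
                s_pm = scores.get(frozenset((p, m)))
                if s_pm is None:
                    continue
                inner = [scores.get(frozenset((m, m2)), float("-inf"))
                         for m2 in members if m2 != m]
                threshold = max(inner) if inner else float("-inf")
                if s_pm > threshold:
                    margin = s_pm - threshold  # inf for single-member clusters
                    if best_margin is None or margin > best_margin or (
                            margin == best_margin and fid < best_fid):
                        best_margin, best_fid = margin, fid
        if best_fid is None:
            singletons.append(p)
            membership[p] = "singleton"
        else:
            clusters[best_fid].add(p)
            membership[p] = "inparalog"
            inparalog_assignments[p] = best_fid
    return FamilySet(clusters=clusters, singletons=singletons,
                     membership_type=membership, rbh_pairs=families.rbh_pairs,
                     inparalog_assignments=inparalog_assignments)


def cluster_proteomes(proteomes: Mapping[str, Mapping[str, str]],
                      hits: pd.DataFrame | None = None,
                      evalue_max: float = EVALUE_MAX,
                      outgroup: set[str] | None = None,
                      ) -> tuple[FamilySet, pd.DataFrame]:
    """Full clustering pipeline: hits -> RBH -> single linkage -> in-paralogs.

    ``outgroup`` names genomes included in clustering (to polarise
    downstream analyses) whose unclustered proteins are dropped rather than
    listed as focal singletons.
    """
    outgroup = outgroup or set()
    if hits is None:
        hits = pairwise_scores(proteomes, evalue_max=evalue_max)
    pairs = reciprocal_best_hits(hits)
    families = single_linkage_clusters(pairs)
    all_proteins = [p for g, prots in proteomes.items() for p in prots]
    families = assign_inparalogs(families, hits, all_proteins)
    genome_of = {p: g for g, prots in proteomes.items() for p in prots}
    families.singletons = [p for p in families.singletons
                           if genome_of[p] not in outgroup]
    families.membership_type = {
        p: t for p, t in families.membership_type.items()
        if not (t == "singleton" and genome_of[p] in outgroup)}
    return families, hits
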