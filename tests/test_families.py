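"""Ortholog family construction against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from chlorocomp import families
from chlorocomp.families import (FamilySet, HIT_COLUMNS, assign_inparalogs,
                                 cluster_proteomes, make_aligner,
                                 pairwise_scores, read_hit_table,
                                 reciprocal_best_hits, single_linkage_clusters)

AA = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a, b, open_score=-11.0, extend_score=-1.0):
    """Quadratic-time Smith-Waterman with affine gaps (independent oracle)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_score, E[i][j - 1] + extend_score)
            F[i][j] = max(H[i - 1][j] + open_score, F[i - 1][j] + extend_score)
            H[i][j] = max(0.0, H[i - 1][j - 1] + BLOSUM62[a[i - 1], b[j - 1]],
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def test_internal_scores_match_dp_oracle():
    rng = np.random.default_rng(1)
    aligner = make_aligner()
    for _ in range(10):
        a = "".join(rng.choice(list(AA), size=rng.integers(10, 51)))
        b = "".join(rng.choice(list(AA), size=rng.integers(10, 51)))
        assert aligner.score(a, b) == pytest.approx(gotoh_local_score(a, b))


def test_identical_proteins_yield_mutual_full_identity_hits():
    seq = "M" + "ACDEFGHIKL" * 10
    hits = pairwise_scores({"g1": {"p1": seq}, "g2": {"p2": seq}})
    assert len(hits) == 2
    assert set(zip(hits["query_id"], hits["subject_id"])) == \
        {("p1", "p2"), ("p2", "p1")}
    assert (hits["identity"] == 100.0).all()


def test_outfmt6_line_parses_positionally(tmp_path):
    line = "p1\tp2\t97.5\t200\t5\t0\t1\t200\t1\t200\t1e-50\t350.0\n"
    path = tmp_path / "hits.tsv"
    path.write_text(line)
    df = read_hit_table(path, {"p1": "g1", "p2": "g2"})
    row = df.iloc[0]
    assert (row.query_id, row.subject_id) == ("p1", "p2")
    assert row.score == 350.0 and row.evalue == 1e-50
    assert row.identity == 97.5 and row.aln_length == 200


def test_malformed_hit_line_reports_line_number(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text("p1\tp2\t97.5\n")
    with pytest.raises(ValueError, match=":1"):
        read_hit_table(path, {"p1": "g1", "p2": "g2"})


def _hits_frame(rows):
    """rows: (query, subject, qgenome, sgenome, score)"""
    return pd.DataFrame(
        [(q, s, qg, sg, sc, 1e-30, 50.0, 100) for q, s, qg, sg, sc in rows],
        columns=HIT_COLUMNS)


def test_rbh_mutual_best_pair():
    hits = _hits_frame([("a", "b", "A", "B", 100), ("b", "a", "B", "A", 100)])
    assert reciprocal_best_hits(hits) == {frozenset(("a", "b"))}


def test_rbh_asymmetric_best_is_rejected():
    # a's best in B is b, but b's best in A is a2
    hits = _hits_frame([
        ("a", "b", "A", "B", 90), ("b", "a", "B", "A", 90),
        ("b", "a2", "B", "A", 95), ("a2", "b", "A", "B", 95),
    ])
    assert reciprocal_best_hits(hits) == {frozenset(("a2", "b"))}


def _rbh_oracle(hits):
    """Literal double-loop re-evaluation of the RBH definition."""
    recs = list(hits.itertuples(index=False))
    queries = {(r.query_id, r.query_genome) for r in recs}

    def best(query, genome):
        cand = [r for r in recs if r.query_id == query
                and r.subject_genome == genome
                and r.query_genome != genome]
        if not cand:
            return None
        return min(cand, key=lambda r: (-r.score, r.evalue, -r.aln_length,
                                        r.subject_id)).subject_id

    genome_of = {}
    for r in recs:
        genome_of[r.query_id] = r.query_genome
        genome_of[r.subject_id] = r.subject_genome
    pairs = set()
    for a, ga in queries:
        for b, gb in queries:
            if ga == gb:
                continue
            if best(a, gb) == b and best(b, ga) == a:
                pairs.add(frozenset((a, b)))
    return pairs


def _random_hit_table(rng, n_genomes=3, n_per_genome=4):
    prots = [(f"g{i}p{j}", f"g{i}") for i in range(n_genomes)
             for j in range(n_per_genome)]
    rows = []
    for (p, gp), (q, gq) in itertools.combinations(prots, 2):
        if rng.random() < 0.6:
            score = float(rng.integers(10, 200))
            rows.append((p, q, gp, gq, score))
            rows.append((q, p, gq, gp, score))
    return _hits_frame(rows)


@pytest.mark.parametrize("seed", range(25))
def test_rbh_matches_exhaustive_oracle(seed):
    hits = _random_hit_table(np.random.default_rng(seed))
    assert reciprocal_best_hits(hits) == _rbh_oracle(hits)


def test_single_linkage_transitive_chain():
    fams = single_linkage_clusters([frozenset("ab"), frozenset("bc")])
    assert list(fams.clusters.values()) == [{"a", "b", "c"}]


def test_single_linkage_disjoint_pairs():
    fams = single_linkage_clusters([frozenset("ab"), frozenset("cd")])
    assert sorted(map(sorted, fams.clusters.values())) == [["a", "b"], ["c", "d"]]


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


@pytest.mark.parametrize("seed", range(10))
def test_single_linkage_matches_union_find(seed):
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(rng.integers(5, 200))]
    pairs = {frozenset(rng.choice(nodes, size=2, replace=False))
             for _ in range(rng.integers(1, 300))}
    pairs = {p for p in pairs if len(p) == 2}
    fams = single_linkage_clusters(pairs)
    uf = _UnionFind()
    for p in pairs:
        a, b = p
        uf.union(a, b)
    roots = {}
    for p in pairs:
        for x in p:
            roots.setdefault(uf.find(x), set()).add(x)
    assert sorted(map(sorted, fams.clusters.values())) == \
        sorted(map(sorted, roots.values()))


def _famset(clusters):
    membership = {p: "ortholog" for c in clusters.values() for p in c}
    return FamilySet(clusters={k: set(v) for k, v in clusters.items()},
                     singletons=[], membership_type=membership)


def _score_hits(scores):
    """scores: dict[(a, b)] = score; emits symmetric directed hits."""
    rows = []
    for (a, b), s in scores.items():
        rows.append((a, b, "gA", "gA", s))
        rows.append((b, a, "gA", "gA", s))
    return _hits_frame(rows)


def test_inparalog_joins_single_member_cluster():
    fams = _famset({"CL0": {"m"}})
    hits = _score_hits({("p", "m"): 50.0})
    out = assign_inparalogs(fams, hits, ["m", "p"])
    assert out.clusters["CL0"] == {"m", "p"}
    assert out.membership_type["p"] == "inparalog"


def test_inparalog_rejected_when_within_cluster_score_higher():
    fams = _famset({"CL0": {"m1", "m2"}})
    hits = _score_hits({("m1", "m2"): 100.0, ("p", "m1"): 80.0})
    out = assign_inparalogs(fams, hits, ["m1", "m2", "p"])
    assert out.clusters["CL0"] == {"m1", "m2"}
    assert out.singletons == ["p"]


def _inparalog_oracle(clusters, scores, unassigned):
    """Literal re-evaluation of the score-margin rule."""
    out = {}
    for p in sorted(unassigned):
        best = None
        for fid, members in clusters.items():
            for m in members:
                s_pm = scores.get(frozenset((p, m)))
                if s_pm is None:
                    continue
                others = [scores.get(frozenset((m, x)), float("-inf"))
                          for x in members if x != m]
                thr = max(others) if others else float("-inf")
                if s_pm > thr:
                    margin = s_pm - thr
                    cand = (margin, fid)
                    if best is None or margin > best[0] or \
                            (margin == best[0] and fid < best[1]):
                        best = cand
        if best is not None:
            out[p] = best[1]
    return out


@pytest.mark.parametrize("seed", range(15))
def test_inparalog_assignment_matches_rule_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    n_clusters = int(rng.integers(1, 4))
    clusters = {}
    idx = 0
    for c in range(n_clusters):
        size = int(rng.integers(1, 4))
        clusters[f"CL{c}"] = {f"m{idx + i}" for i in range(size)}
        idx += size
    members = sorted({m for c in clusters.values() for m in c})
    extras = [f"p{i}" for i in range(int(rng.integers(1, 4)))]
    scores = {}
    everyone = members + extras
    for a, b in itertools.combinations(everyone, 2):
        if rng.random() < 0.7:
            scores[frozenset((a, b))] = float(rng.integers(10, 200))
    fams = _famset(clusters)
    hits = _score_hits({tuple(sorted(k)): v for k, v in scores.items()})
    out = assign_inparalogs(fams, hits, everyone)
    oracle = _inparalog_oracle(clusters, scores, extras)
    assert out.inparalog_assignments == oracle
    assert set(out.singletons) == set(extras) - set(oracle)


def test_pipeline_partitions_the_proteome(small_family_run):
    genomes, truth, proteomes, famset, hits = small_family_run
    all_proteins = {p for prots in proteomes.values() for p in prots}
    sizes = sum(len(m) for m in famset.clusters.values())
    assert sizes + len(famset.singletons) == len(all_proteins)
    assert famset.all_proteins() == all_proteins
    for members in famset.clusters.values():
        assert len(members) >= 2 or any(
            t == "inparalog" for p, t in famset.membership_type.items()
            if p in members)


def test_recovered_partition_equals_truth(small_family_run):
    genomes, truth, proteomes, famset, hits = small_family_run
    truthmap = dict(zip(truth.genes["gene_id"], truth.genes["family_id"]))
    recov = famset.family_of()
    ids = sorted(truthmap)
    for a, b in itertools.combinations(ids, 2):
        assert (truthmap[a] == truthmap[b]) == (recov[a] == recov[b])


def test_clustering_is_order_invariant(small_family_run):
    genomes, truth, proteomes, famset, hits = small_family_run
    shuffled_hits = hits.sample(frac=1.0, random_state=4).reset_index(drop=True)
    pairs = reciprocal_best_hits(shuffled_hits)
    fams2 = single_linkage_clusters(pairs)
    fams2 = assign_inparalogs(
        fams2, shuffled_hits,
        [p for prots in reversed(list(proteomes.values())) for p in prots])
    assert sorted(map(sorted, famset.clusters.values())) == \
        sorted(map(sorted, fams2.clusters.values()))
    assert sorted(famset.singletons) == sorted(fams2.singletons)


def test_outgroup_members_never_become_focal_singletons():
    seq1 = "MSTLKEQAGHWVNDCRIPYFE" * 5
    rng = np.random.default_rng(2)
    seq2 = "".join(rng.choice(list(AA), size=90))
    proteomes = {"focal1": {"f1": seq1}, "focal2": {"f2": seq1},
                 "og": {"o1": seq2}}
    famset, _ = cluster_proteomes(proteomes, outgroup={"og"})
    assert "o1" not in famset.singletons
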