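"""Family classification, parsimony ancestry, ORFan null, gene locations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chlorocomp import ancestry
from chlorocomp.ancestry import (ConfigurationError, FamilyMatrix,
                                 ancestral_families, build_matrix,
                                 classify_families, count_chance_orfs,
                                 nonancestral_location_distribution,
                                 orfan_chance_null, select_single_copy_core)
from chlorocomp.families import FamilySet
from chlorocomp.genome_io import AnnotatedGenome, GeneRecord, translate_cds


def _matrix(counts, groups):
    df = pd.DataFrame(counts)
    df.index = [f"F{i}" for i in range(len(df))]
    return FamilyMatrix(counts=df, host_group=groups)


GROUPS6 = {"n1": "NC64A", "n2": "NC64A", "p1": "Pbi", "p2": "Pbi",
           "s1": "SAG", "s2": "SAG"}
COLS6 = list(GROUPS6)


def _mat6(rows):
    df = pd.DataFrame(rows, columns=COLS6)
    df.index = [f"F{i}" for i in range(len(rows))]
    return FamilyMatrix(counts=df, host_group=GROUPS6)


def test_build_matrix_counts_members_per_genome():
    fams = FamilySet(clusters={"CL0": {"a1", "a2", "b1"}},
                     singletons=["c1"],
                     membership_type={"a1": "ortholog", "a2": "inparalog",
                                      "b1": "ortholog", "c1": "singleton"})
    genome_of = {"a1": "gA", "a2": "gA", "b1": "gB", "c1": "gC"}
    matrix = build_matrix(fams, genome_of,
                          {"gA": "NC64A", "gB": "Pbi", "gC": "SAG"})
    assert matrix.counts.loc["CL0", "gA"] == 2  # in-paralog adds to the count
    assert matrix.counts.loc["CL0", "gB"] == 1
    assert matrix.counts.loc["CL0"].sum() == 3
    assert matrix.counts.loc["singleton:c1"].sum() == 1


def test_build_matrix_row_sums_equal_cluster_sizes(small_family_run):
    genomes, truth, proteomes, famset, hits = small_family_run
    genome_of = {p: g for g, prots in proteomes.items() for p in prots}
    matrix = build_matrix(famset, genome_of,
                          {g.genome_id: g.host_group for g in genomes})
    for fid, members in famset.clusters.items():
        assert matrix.counts.loc[fid].sum() == len(members)


def test_build_matrix_unknown_genome_raises():
    fams = FamilySet(clusters={"CL0": {"a", "b"}}, singletons=[],
                     membership_type={"a": "ortholog", "b": "ortholog"})
    with pytest.raises(KeyError):
        build_matrix(fams, {"a": "gA"}, {"gA": "NC64A"})


def test_classification_rules_on_hand_patterns():
    matrix = _mat6([
        [1, 1, 1, 1, 1, 1],   # core
        [1, 1, 0, 0, 0, 0],   # host_specific:NC64A
        [0, 0, 1, 1, 1, 1],   # opposite:NC64A
        [1, 0, 1, 0, 0, 0],   # scattered
        [0, 0, 0, 1, 0, 0],   # singleton
        [2, 1, 1, 1, 1, 1],   # core with an in-paralog
    ])
    classify_families(matrix)
    assert list(matrix.category) == [
        "core", "host_specific:NC64A", "opposite:NC64A", "scattered",
        "singleton", "core"]


def _classify_oracle(row_present, counts_total, groups):
    """Literal re-evaluation of the five classification rules."""
    genomes = list(row_present.index)
    if all(row_present):
        return "core"
    for g in sorted(set(groups.values())):
        mine = [x for x in genomes if groups[x] == g]
        rest = [x for x in genomes if groups[x] != g]
        if all(row_present[m] for m in mine) and not any(row_present[r] for r in rest):
            return f"host_specific:{g}"
        if not any(row_present[m] for m in mine) and all(row_present[r] for r in rest):
            return f"opposite:{g}"
    if counts_total == 1:
        return "singleton"
    return "scattered"


@pytest.mark.parametrize("seed", range(10))
def test_classification_matches_rule_oracle(seed):
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, 3, size=(30, 6))
    matrix = _mat6(rows.tolist())
    classify_families(matrix)
    for fid in matrix.counts.index:
        row = matrix.counts.loc[fid]
        expected = _classify_oracle(row > 0, row.sum(), GROUPS6)
        got = matrix.category[fid]
        # the oracle checks groups in sorted order; several host_specific /
        # opposite labels can never hold simultaneously, so labels agree
        assert got == expected


def test_category_counts_sum_to_total_families():
    rng = np.random.default_rng(3)
    matrix = _mat6(rng.integers(0, 2, size=(50, 6)).tolist())
    classify_families(matrix)
    assert matrix.category.notna().all()
    assert matrix.category.value_counts().sum() == 50


def test_ancestral_rule_two_clades():
    matrix = _mat6([
        [1, 0, 0, 0, 1, 0],   # NC64A + SAG -> ancestral
        [0, 0, 1, 1, 0, 0],   # only Pbi -> not ancestral
        [1, 1, 0, 0, 0, 0],   # only NC64A -> not ancestral
    ])
    flags = ancestral_families(matrix)
    assert list(flags) == [True, False, False]


def test_extra_evidence_families_are_flagged():
    matrix = _mat6([[0, 0, 1, 1, 0, 0]])
    flags = ancestral_families(matrix, extra_evidence=["F0"])
    assert flags["F0"]


def test_missing_group_labels_raise():
    matrix = _matrix({"gA": [1], "gB": [1]}, {"gA": "X", "gB": "Y"})
    with pytest.raises(ConfigurationError):
        ancestral_families(matrix)


def test_core_families_are_always_ancestral():
    rng = np.random.default_rng(8)
    matrix = _mat6(rng.integers(0, 2, size=(60, 6)).tolist())
    classify_families(matrix)
    flags = ancestral_families(matrix)
    assert flags[matrix.category == "core"].all()


def test_ancestral_flag_is_monotone_in_membership():
    rng = np.random.default_rng(9)
    base = _mat6(rng.integers(0, 2, size=(40, 6)).tolist())
    flags = ancestral_families(base)
    grown = FamilyMatrix(counts=base.counts + 1, host_group=GROUPS6)
    grown_flags = ancestral_families(grown)
    assert (grown_flags | ~flags).all()  # adding members never clears the flag


def test_single_copy_core_selection():
    matrix = _mat6([
        [1, 1, 1, 1, 1, 1],
        [1, 1, 2, 1, 1, 1],   # a duplicate anywhere excludes the family
        [1, 1, 1, 1, 1, 0],
    ])
    assert select_single_copy_core(matrix) == ["F0"]


def test_single_copy_core_recovered_from_truth(small_family_run):
    genomes, truth, proteomes, famset, hits = small_family_run
    genome_of = {p: g for g, prots in proteomes.items() for p in prots}
    matrix = build_matrix(famset, genome_of,
                          {g.genome_id: g.host_group for g in genomes})
    selected = select_single_copy_core(matrix)
    fam_of = famset.family_of()
    truthmap = dict(zip(truth.genes["gene_id"], truth.genes["family_id"]))
    truth_core = {f for f, sub in truth.genes.groupby("family_id")
                  if set(sub["genome_id"]) == {g.genome_id for g in genomes}
                  and len(sub) == len(genomes)}
    recovered_truth_ids = {truthmap[next(iter(famset.clusters[f]))]
                           for f in selected}
    assert recovered_truth_ids == truth_core


# ---------------------------------------------------------------------------
# ORFan chance null
# ---------------------------------------------------------------------------

def test_tandem_stop_sequence_has_no_orfs():
    assert count_chance_orfs("TAA" * 300, min_len_bp=300) == 0


def test_chance_orf_count_matches_geometric_expectation():
    """On iid uniform sequence the expected count per frame-strand is
    n_codons * P(ATG) * P(no stop within the qualifying span)."""
    rng = np.random.default_rng(12)
    L = 120_000
    min_len = 150
    counts = [count_chance_orfs(
        "".join(rng.choice(list("ACGT"), size=L)), min_len_bp=min_len)
        for _ in range(8)]
    p_stop, p_atg = 3 / 64, 1 / 64
    m = min_len // 3  # codons that must be stop-free after the ATG
    expected = 6 * (L // 3) * p_atg * (1 - p_stop) ** m
    mean, sd = np.mean(counts), np.std(counts, ddof=1)
    assert abs(mean - expected) < 2 * sd / np.sqrt(len(counts)) + 2 * sd


def _genome_with_orfans():
    rng = np.random.default_rng(21)
    parts, genes, pos = [], [], 0
    for i in range(8):
        spacer = "".join(rng.choice(list("ACGT"), size=150))
        parts.append(spacer)
        pos += len(spacer)
        cds = "ATG" + "".join(rng.choice(list("ACGT"), size=450)) + "TAA"
        gid = f"g{i}"
        genes.append(GeneRecord(gid, "c1", pos, pos + len(cds), "+", cds,
                                translate_cds(cds, gid)))
        parts.append(cds)
        pos += len(cds)
    parts.append("".join(rng.choice(list("ACGT"), size=150)))
    return AnnotatedGenome("sim", [("c1", "".join(parts))], genes)


def test_orfan_null_is_deterministic_and_reports_sd():
    genome = _genome_with_orfans()
    orfans = {"g0", "g1"}
    out1 = orfan_chance_null([genome], orfans, replicates=5, seed=42)
    out2 = orfan_chance_null([genome], orfans, replicates=5, seed=42)
    pd.testing.assert_frame_equal(out1, out2)
    assert out1.loc[0, "mean_chance_orfs"] >= 0
    with pytest.raises(ValueError):
        orfan_chance_null([genome], orfans, replicates=0)


def test_orfan_null_small_for_gene_dense_genome():
    # intergenic gaps are far shorter than the 300 bp ORF floor, so chance
    # ORFs outside the non-ORFan gene spans are rare
    genome = _genome_with_orfans()
    out = orfan_chance_null([genome], set(), min_len_bp=300, replicates=5,
                            seed=1)
    assert out.loc[0, "mean_chance_orfs"] < 1.0


# ---------------------------------------------------------------------------
# Genomic location distribution
# ---------------------------------------------------------------------------

def _location_setup(midpoints, length=10_000):
    genes, rows = [], []
    for i, mid in enumerate(midpoints):
        start = int(mid * length) - 150
        cds = "ATG" + "A" * 294 + "TAA"
        gid = f"g{i}"
        genes.append(GeneRecord(gid, "c1", start, start + 300, "+", cds,
                                translate_cds(cds, gid)))
        rows.append({"family_id": f"F{i}", "protein_id": gid,
                     "genome_id": "G"})
    genome = AnnotatedGenome("G", [("c1", "A" * length)], genes)
    counts = pd.DataFrame(0, index=[f"F{i}" for i in range(len(midpoints))],
                          columns=["G"])
    counts["G"] = 1
    matrix = FamilyMatrix(counts=counts, host_group={"G": "NC64A"})
    matrix.ancestral = pd.Series(False, index=counts.index)
    return matrix, pd.DataFrame(rows), [genome]


def test_relative_position_of_centered_and_origin_genes():
    matrix, membership, genomes = _location_setup([0.5, 0.02])
    out = nonancestral_location_distribution(matrix, membership, genomes)
    pos = dict(zip(out["family_id"], out["mean_relative_position"]))
    assert pos["F0"] == pytest.approx(0.5, abs=0.01)
    assert pos["F1"] == pytest.approx(0.02, abs=0.01)


def test_uniform_placement_passes_ks_against_uniform():
    rng = np.random.default_rng(33)
    mids = rng.uniform(0.03, 0.97, size=200)
    matrix, membership, genomes = _location_setup(mids, length=100_000)
    out = nonancestral_location_distribution(matrix, membership, genomes)
    stat, p = stats.kstest(out["mean_relative_position"], "uniform",
                           args=(0.03, 0.94))
    assert p > 0.01
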