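"""Family classification, ancestral gene-content reconstruction and nulls.

Families are classified by their presence/absence pattern across host
groups (core, host-specific, opposite-pattern, scattered, singleton).  The
ancestral repertoire is reconstructed by a two-clade parsimony rule: a
family is inferred present in the last common ancestor when it spans the
NC64A clade and at least one of the Pbi/SAG clades, the deepest split of
the virus phylogeny.  Families supported by external phylogenetic evidence
(e.g., sister groups to homologs in other giant-virus lineages, read from
manually curated trees) can be supplied as an extra list; identifying them
is out of scope here.

ORFan status (no detectable homolog outside the genus) is an *input*
annotation: it requires external database searches and is consumed as a
boolean flag, never computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .families import FamilySet
from .genome_io import AnnotatedGenome, reverse_complement


class ConfigurationError(ValueError):
    pass


@dataclass
class FamilyMatrix:
    """Protein families x genomes member-count matrix with family labels."""

    counts: pd.DataFrame          # index family_id, columns genome_id, int counts
    host_group: dict[str, str]    # genome_id -> group
    category: pd.Series | None = None
    ancestral: pd.Series | None = None
    orfan: pd.Series | None = None
    median_len_bp: pd.Series | None = None

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for genome in self.counts.columns:
            out.setdefault(self.host_group[genome], []).append(genome)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        for name in ("category", "ancestral", "orfan", "median_len_bp"):
            col = getattr(self, name)
            if col is not None:
                df[name] = col
        return df


def build_matrix(families: FamilySet, genome_of: Mapping[str, str],
                 host_group: Mapping[str, str],
                 genomes: Sequence[str] | None = None) -> FamilyMatrix:
    """Count family members per genome; cell (f, g) = members of f in g."""
    fam_of: dict[str, str] = {}
    for fid, members in families.clusters.items():
        for p in members:
            fam_of[p] = fid
    for p in families.singletons:
        fam_of[p] = f"singleton:{p}"
    unknown = [p for p in fam_of if p not in genome_of]
    if unknown:
        raise KeyError(f"proteins with unknown genome: {unknown[:5]}")
    if genomes is None:
        genomes = sorted(set(genome_of[p] for p in fam_of))
    counts = pd.DataFrame(0, index=sorted(set(fam_of.values())),
                          columns=list(genomes), dtype=int)
    for p, fid in fam_of.items():
        counts.loc[fid, genome_of[p]] += 1
    missing = set(genomes) - set(host_group)
    if missing:
        raise ConfigurationError(f"genomes without host group: {sorted(missing)}")
    return FamilyMatrix(counts=counts,
                        host_group={g: host_group[g] for g in genomes})


def classify_families(matrix: FamilyMatrix,
                      focal_genomes: Sequence[str] | None = None,
                      ) -> FamilyMatrix:
    """Label each family core / host_specific:g / opposite:g / singleton / scattered.

    core: present in every focal genome.  host_specific:g: present in every
    genome of group g and absent elsewhere.  opposite:g: absent from every
    genome of g, present in all other genomes.  singleton: exactly one
    member overall.  scattered: everything else.
    """
    counts = matrix.counts if focal_genomes is None else \
        matrix.counts[list(focal_genomes)]
    groups = {}
    for genome in counts.columns:
        groups.setdefault(matrix.host_group[genome], []).append(genome)
    if len(groups) < 2:
        raise ConfigurationError("classification needs >=2 host groups")
    present = counts > 0
    labels = {}
    for fid, row in present.iterrows():
        total_members = int(matrix.counts.loc[fid].sum())
        if row.all():
            labels[fid] = "core"
            continue
        label = None
        for g, members in groups.items():
            others = [c for c in counts.columns if c not in members]
            if row[members].all() and not row[others].any():
                label = f"host_specific:{g}"
                break
            if not row[members].any() and row[others].all():
                label = f"opposite:{g}"
                break
        if label is None:
            label = "singleton" if total_members == 1 else "scattered"
        labels[fid] = label
    matrix.category = pd.Series(labels).reindex(matrix.counts.index)
    return matrix


def ancestral_families(matrix: FamilyMatrix,
                       extra_evidence: Iterable[str] | None = None,
                       primary_group: str = "NC64A",
                       secondary_groups: Sequence[str] = ("Pbi", "SAG"),
                       ) -> pd.Series:
    """Two-clade parsimony flag for presence in the last common ancestor.

    True iff the family has >=1 member in a ``primary_group`` genome and
    >=1 member in a genome of any ``secondary_groups``; families named in
    ``extra_evidence`` (externally supplied phylogenetic support) are
    additionally flagged.
    """
    groups = matrix.groups()
    if primary_group not in groups or not any(g in groups
                                              for g in secondary_groups):
        raise ConfigurationError(
            f"host groups must include {primary_group} and one of "
            f"{secondary_groups}; have {sorted(groups)}")
    primary = matrix.counts[groups[primary_group]].sum(axis=1) > 0
    secondary_cols = [c for g in secondary_groups
                      for c in groups.get(g, [])]
    secondary = matrix.counts[secondary_cols].sum(axis=1) > 0
    flag = primary & secondary
    if extra_evidence is not None:
        extra = [f for f in extra_evidence if f in flag.index]
        flag.loc[extra] = True
    matrix.ancestral = flag
    return flag


def select_single_copy_core(matrix: FamilyMatrix,
                            outgroup: Sequence[str] | None = None,
                            ) -> list[str]:
    """Families with exactly one member in every genome (incl. outgroup)."""
    cols = list(matrix.counts.columns)
    if outgroup:
        missing = set(outgroup) - set(cols)
        if missing:
            raise ConfigurationError(f"outgroup genomes not in matrix: {missing}")
    ok = (matrix.counts[cols] == 1).all(axis=1)
    return sorted(matrix.counts.index[ok])


# ---------------------------------------------------------------------------
# ORFan chance null
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def count_chance_orfs(seq: str, min_len_bp: int = 300,
                      both_strands: bool = True) -> int:
    """Count ATG-initiated, stop-terminated ORFs longer than ``min_len_bp``.

    Every qualifying ATG opens an ORF ending at the next in-frame stop
    (nested ORFs are counted separately); ORF length includes the stop
    codon.  All three frames are scanned, on both strands by default.
    """
    total = 0
    strands = (seq, reverse_complement(seq)) if both_strands else (seq,)
    min_codons = min_len_bp // 3  # non-stop codons required after which > holds
    for strand in strands:
        for frame in range(3):
            codons = [strand[i:i + 3]
                      for i in range(frame, len(strand) - 2, 3)]
            stop_after = np.full(len(codons), -1)
            next_stop = -1
            for i in range(len(codons) - 1, -1, -1):
                if codons[i] in _STOPS:
                    next_stop = i
                stop_after[i] = next_stop
            for i, codon in enumerate(codons):
                if codon == "ATG" and stop_after[i] >= 0:
                    length_bp = 3 * (stop_after[i] - i + 1)
                    if length_bp > min_len_bp:
                        total += 1
    return total


def _gene_spans(genome: AnnotatedGenome) -> dict[str, list[tuple[int, int, str]]]:
    spans: dict[str, list[tuple[int, int, str]]] = {c: [] for c, _ in genome.contigs}
    for g in genome.genes:
        spans[g.contig_id].append((g.start, g.end, g.gene_id))
    return spans


def orfan_chance_null(genomes: Sequence[AnnotatedGenome],
                      orfan_genes: set[str],
                      min_len_bp: int = 300,
                      replicates: int = 10,
                      seed: int = 0) -> pd.DataFrame:
    """Chance-ORF null for ORFan gene predictions.

    Per replicate, the sequence lying *between* the non-ORFan genes of a
    genome (intergenic DNA plus the spans of ORFan-flagged genes) is
    shuffled as a single mononucleotide pool and written back into the same
    spans; the six frames of the resulting genome are then scanned and
    ATG-initiated, stop-terminated ORFs longer than ``min_len_bp`` that
    fall entirely outside the non-ORFan gene spans are counted.  Returns
    the mean and SD of that count per genome over replicates.

    Assumptions surfaced to the caller (the procedure admits several
    readings): the shuffle unit is the single nucleotide; starts must be
    ATG; nested ORFs are each counted; both strands are scanned.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for genome in genomes:
        counts = []
        for _ in range(replicates):
            n_orfs = 0
            for contig_id, seq in genome.contigs:
                keep = [(s, e) for (s, e, gid) in _gene_spans(genome)[contig_id]
                        if gid not in orfan_genes]
                keep.sort()
                # complement of the non-ORFan spans
                free: list[tuple[int, int]] = []
                pos = 0
                for s, e in keep:
                    if s > pos:
                        free.append((pos, s))
                    pos = max(pos, e)
                if pos < len(seq):
                    free.append((pos, len(seq)))
                pool = list("".join(seq[s:e] for s, e in free))
                if not pool:
                    continue
                pool = rng.permutation(pool)
                rebuilt = list(seq)
                cursor = 0
                for s, e in free:
                    rebuilt[s:e] = pool[cursor:cursor + (e - s)]
                    cursor += e - s
                shuffled = "".join(rebuilt)
                # count chance ORFs wholly outside non-ORFan gene spans
                for s, e in free:
                    if e - s > min_len_bp:
                        n_orfs += count_chance_orfs(shuffled[s:e], min_len_bp)
            counts.append(n_orfs)
        arr = np.asarray(counts, dtype=float)
        rows.append({"genome_id": genome.genome_id,
                     "mean_chance_orfs": float(arr.mean()),
                     "sd_chance_orfs": float(arr.std(ddof=1)) if len(arr) > 1
                     else 0.0,
                     "replicates": replicates})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genomic location of non-ancestral families
# ---------------------------------------------------------------------------

def nonancestral_location_distribution(matrix: FamilyMatrix,
                                       membership: pd.DataFrame,
                                       genomes: Sequence[AnnotatedGenome],
                                       ) -> pd.DataFrame:
    """Mean relative genomic position per non-ancestral family.

    For each family not flagged ancestral, averages (gene midpoint /
    genome length) over its members, with contigs concatenated in given
    order.  ``membership`` has columns family_id, protein_id, genome_id.
    """
    if matrix.ancestral is None:
        raise ConfigurationError("run ancestral_families first")
    by_id = {g.genome_id: g for g in genomes}
    gene_lookup = {(g.genome_id, gene.gene_id): g.gene_absolute_midpoint(gene)
                   for g in genomes for gene in g.genes}
    rows = []
    nonanc = set(matrix.ancestral.index[~matrix.ancestral])
    for fid, sub in membership.groupby("family_id"):
        if fid not in nonanc:
            continue
        rel = []
        for row in sub.itertuples(index=False):
            key = (row.genome_id, row.protein_id)
            if key not in gene_lookup:
                continue
            rel.append(gene_lookup[key] / by_id[row.genome_id].length)
        if rel:
            rows.append({"family_id": fid,
                         "mean_relative_position": float(np.mean(rel)),
                         "n_members": len(rel)})
    return pd.DataFrame(rows)
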