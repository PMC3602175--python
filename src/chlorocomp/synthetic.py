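"""Synthetic chlorovirus-like genome sets with known ground truth.

The generator emulates the structure of a multi-host-group virus collection:

* host groups of genomes with group-specific nucleotide composition
  (defaults 40 / 45 / 49 %GC, mirroring NC64A / Pbi / SAG viruses);
* protein families with designed presence/absence patterns (core,
  group-specific, opposite-pattern, scattered, singleton);
* conserved gene order within a group (up to a configurable number of
  inversions) and shuffled order between groups;
* a designated fraction of genes per genome whose nucleotides are emitted
  through a compositionally distinct "alien" model - the ground truth for
  compositional HGT detection.

Each family has a single ancestor protein; members are derived from it by
per-site amino-acid substitution so that reciprocal-best-hit clustering can
recover the family partition.  Nucleotide sequences are produced by
back-translating proteins through a codon-frequency table parameterised
only by a target GC (position-wise nucleotide bias), since the downstream
compositional signal is nucleotide frequency, not codon optimality.

All randomness flows from the single design seed through named
``numpy`` seed-sequence substreams, so the same design yields byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genome_io import (AnnotatedGenome, GeneRecord, reverse_complement,
                        translate_cds, write_fasta_gff)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Standard genetic code, sense codons grouped by amino acid.
_CODONS_BY_AA: dict[str, list[str]] = {}
_BASES = "TCAG"
_CODE = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
         "VVVVAAAADDEEGGGG")
for _i, (_b1, _b2, _b3) in enumerate(
        (a, b, c) for a in _BASES for b in _BASES for c in _BASES):
    _aa = _CODE[_i]
    if _aa != "*":
        _CODONS_BY_AA.setdefault(_aa, []).append(_b1 + _b2 + _b3)
STOP_CODONS = ("TAA", "TAG", "TGA")


class DesignError(ValueError):
    """Raised when a synthetic design is internally inconsistent."""


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_genomes: int
    gc: float  # target genomic GC fraction in (0, 1)


@dataclass(frozen=True)
class FamilySpec:
    family_id: str
    category: str  # core | group_specific:<g> | opposite:<g> | scattered | singleton
    copy_number: int = 1
    presence: tuple[str, ...] | None = None  # explicit genome ids (scattered/singleton)


@dataclass
class SyntheticDesign:
    groups: list[GroupSpec]
    families: list[FamilySpec]
    seed: int
    alien_fraction: float = 0.0
    alien_gc: float | None = None  # default: group GC + alien_gc_offset
    alien_gc_offset: float = 0.10
    substitution_rate: float = 0.10  # per-site amino-acid substitution per genome
    inparalog_extra_rate: float = 0.05
    mean_gene_length_codons: float = 200.0
    sigma_gene_length: float = 0.35  # log-normal sigma
    min_gene_length_codons: int = 60
    max_gene_length_codons: int = 2000
    n_inversions: int = 0
    spacer_range: tuple[int, int] = (20, 200)

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise DesignError("duplicate group names")
        for g in self.groups:
            if not 0.0 < g.gc < 1.0:
                raise DesignError(f"group {g.name}: GC target must be in (0,1)")
        for f in self.families:
            cat = f.category
            if cat.startswith(("group_specific:", "opposite:")):
                target = cat.split(":", 1)[1]
                if target not in names:
                    raise DesignError(f"family {f.family_id}: unknown group {target}")
                if cat.startswith("group_specific:") and \
                        next(g for g in self.groups if g.name == target).n_genomes == 0:
                    raise DesignError(
                        f"family {f.family_id}: group-specific in empty group {target}")
            elif cat not in ("core", "scattered", "singleton"):
                raise DesignError(f"family {f.family_id}: unknown category {cat!r}")
        if not 0.0 <= self.alien_fraction < 1.0:
            raise DesignError("alien_fraction must be in [0, 1)")

    def genome_ids(self) -> list[str]:
        return [f"{g.name}_{i:02d}" for g in self.groups for i in range(g.n_genomes)]

    def group_of(self) -> dict[str, str]:
        return {f"{g.name}_{i:02d}": g.name
                for g in self.groups for i in range(g.n_genomes)}

    @classmethod
    def simple(cls, seed: int, n_per_group: int = 3, n_core: int = 20,
               n_group_specific: int = 2, n_opposite: int = 1,
               n_scattered: int = 5, n_singleton: int = 2,
               group_gc: Sequence[float] = (0.40, 0.45, 0.49),
               group_names: Sequence[str] = ("NC64A", "Pbi", "SAG"),
               **kwargs) -> "SyntheticDesign":
        """Convenience constructor building a family plan from counts."""
        groups = [GroupSpec(n, n_per_group, gc)
                  for n, gc in zip(group_names, group_gc)]
        fams: list[FamilySpec] = []
        fid = 0

        def add(cat: str) -> None:
            nonlocal fid
            fams.append(FamilySpec(f"F{fid:04d}", cat))
            fid += 1

        for _ in range(n_core):
            add("core")
        for g in group_names:
            for _ in range(n_group_specific):
                add(f"group_specific:{g}")
        for i in range(n_opposite):
            add(f"opposite:{group_names[i % len(group_names)]}")
        for _ in range(n_scattered):
            add("scattered")
        for _ in range(n_singleton):
            add("singleton")
        return cls(groups=groups, families=fams, seed=seed, **kwargs)


@dataclass
class TruthTables:
    genes: pd.DataFrame      # gene_id, genome_id, family_id, is_alien, length_nt
    families: pd.DataFrame   # family_id, category, presence (comma-joined ids)
    groups: pd.DataFrame     # group, gc, theta, alien_gc


# ---------------------------------------------------------------------------
# GC-parameterised codon emission
# ---------------------------------------------------------------------------

def _codon_weights(theta: float) -> dict[str, np.ndarray]:
    """Per-amino-acid codon probabilities under nucleotide bias theta.

    Each codon is weighted by the product of per-nucleotide probabilities
    p(G) = p(C) = theta/2, p(A) = p(T) = (1-theta)/2, renormalised within
    the synonymous codon set.
    """
    p = {nt: (theta / 2 if nt in "GC" else (1 - theta) / 2) for nt in "ACGT"}
    out = {}
    for aa, codons in _CODONS_BY_AA.items():
        w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in codons])
        out[aa] = w / w.sum()
    return out


def _expected_gc(theta: float) -> float:
    """Expected coding GC under uniform amino-acid usage at bias theta."""
    weights = _codon_weights(theta)
    total = 0.0
    for aa in AMINO_ACIDS:
        w = weights[aa]
        gc = np.array([sum(nt in "GC" for nt in c) for c in _CODONS_BY_AA[aa]])
        total += float((w * gc).sum()) / 3.0
    return total / len(AMINO_ACIDS)


def calibrate_theta(target_gc: float) -> float:
    """Nucleotide bias theta whose expected coding GC equals ``target_gc``.

    The genetic code constrains achievable coding GC (roughly 0.26-0.83 for
    uniform amino-acid usage); targets outside that range raise.
    """
    lo, hi = 1e-3, 1 - 1e-3
    if not _expected_gc(lo) < target_gc < _expected_gc(hi):
        raise DesignError(f"coding GC target {target_gc} unreachable")
    return float(brentq(lambda t: _expected_gc(t) - target_gc, lo, hi, xtol=1e-6))


class CodonEmitter:
    """Back-translates proteins and emits background sequence at one GC."""

    def __init__(self, gc: float):
        self.gc = gc
        self.theta = calibrate_theta(gc)
        self._weights = _codon_weights(self.theta)
        p = self.theta / 2
        q = (1 - self.theta) / 2
        stop_w = np.array([q * q * q, q * q * p, q * p * q])  # TAA, TAG, TGA
        self._stop_w = stop_w / stop_w.sum()
        # intergenic background at the genomic GC target itself
        self._bg_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    def back_translate(self, protein: str, rng: np.random.Generator) -> str:
        codons = []
        for aa in protein:
            opts = _CODONS_BY_AA[aa]
            codons.append(opts[rng.choice(len(opts), p=self._weights[aa])])
        codons.append(STOP_CODONS[rng.choice(3, p=self._stop_w)])
        return "".join(codons)

    def background(self, length: int, rng: np.random.Generator) -> str:
        return "".join(np.array(list("ACGT"))[
            rng.choice(4, size=length, p=self._bg_p)])


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution to a uniformly chosen different residue.

    The initial methionine is preserved so every gene keeps its start codon.
    """
    chars = list(protein)
    for i in range(1, len(chars)):
        if rng.random() < rate:
            alternatives = AMINO_ACIDS.replace(chars[i], "")
            chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _resolve_presence(design: SyntheticDesign,
                      rng: np.random.Generator) -> dict[str, list[str]]:
    """Map family_id -> list of genome ids carrying it."""
    ids = design.genome_ids()
    group_of = design.group_of()
    by_group = {g.name: [i for i in ids if group_of[i] == g.name]
                for g in design.groups}
    presence: dict[str, list[str]] = {}
    for fam in design.families:
        if fam.presence is not None:
            unknown = set(fam.presence) - set(ids)
            if unknown:
                raise DesignError(f"family {fam.family_id}: unknown genomes {unknown}")
            presence[fam.family_id] = list(fam.presence)
            continue
        cat = fam.category
        if cat == "core":
            chosen = list(ids)
        elif cat.startswith("group_specific:"):
            chosen = list(by_group[cat.split(":", 1)[1]])
        elif cat.startswith("opposite:"):
            g = cat.split(":", 1)[1]
            chosen = [i for i in ids if group_of[i] != g]
            if not chosen:
                raise DesignError(f"family {fam.family_id}: opposite set empty")
        elif cat == "singleton":
            chosen = [ids[rng.integers(len(ids))]]
        else:  # scattered: a random proper subset of size 2..n-1
            size = int(rng.integers(2, max(3, len(ids))))
            chosen = list(rng.choice(ids, size=min(size, len(ids) - 1),
                                     replace=False))
        presence[fam.family_id] = chosen
    return presence


def generate_genome_set(design: SyntheticDesign,
                        ) -> tuple[list[AnnotatedGenome], TruthTables]:
    """Generate an annotated genome set plus truth tables from a design."""
    root = np.random.SeedSequence(design.seed)
    plan_rng, anc_rng, order_rng, *genome_seeds = [
        np.random.default_rng(s)
        for s in root.spawn(3 + len(design.genome_ids()))]

    ids = design.genome_ids()
    group_of = design.group_of()
    presence = _resolve_presence(design, plan_rng)

    emitters = {g.name: CodonEmitter(g.gc) for g in design.groups}
    alien_emitters = {
        g.name: CodonEmitter(design.alien_gc if design.alien_gc is not None
                             else g.gc + design.alien_gc_offset)
        for g in design.groups}

    # one ancestor protein per family
    lengths = np.exp(anc_rng.normal(np.log(design.mean_gene_length_codons),
                                    design.sigma_gene_length,
                                    size=len(design.families)))
    lengths = np.clip(np.round(lengths), design.min_gene_length_codons,
                      design.max_gene_length_codons).astype(int)
    ancestors = {}
    for fam, L in zip(design.families, lengths):
        body = "".join(np.array(list(AMINO_ACIDS))[
            anc_rng.integers(len(AMINO_ACIDS), size=L - 1)])
        ancestors[fam.family_id] = "M" + body

    # family order: conserved within a group, shuffled between groups;
    # per-(group, family) strand is likewise conserved within the group
    fam_ids = [f.family_id for f in design.families]
    group_order = {}
    group_strand = {}
    for g in design.groups:
        group_order[g.name] = list(order_rng.permutation(fam_ids))
        group_strand[g.name] = {
            f: ("+" if order_rng.random() < 0.5 else "-") for f in fam_ids}

    genomes: list[AnnotatedGenome] = []
    gene_rows = []
    for gid, rng in zip(ids, genome_seeds):
        group = group_of[gid]
        emitter = emitters[group]
        alien_emitter = alien_emitters[group]

        fams_here = [f for f in group_order[group] if gid in presence[f]]
        # gene-order divergence within the group: segment inversions
        for _ in range(design.n_inversions):
            if len(fams_here) > 2:
                a, b = sorted(rng.choice(len(fams_here), size=2, replace=False))
                fams_here[a:b + 1] = fams_here[a:b + 1][::-1]

        copy_of = {f.family_id: f.copy_number for f in design.families}
        entries = []  # (family_id, copy_index)
        for f in fams_here:
            for c in range(copy_of[f]):
                entries.append((f, c))

        n_alien = int(round(design.alien_fraction * len(entries)))
        alien_idx = set(rng.choice(len(entries), size=n_alien, replace=False)
                        ) if n_alien else set()

        seq_parts = []
        genes = []
        pos = 0
        lo, hi = design.spacer_range
        for idx, (fam, copy) in enumerate(entries):
            spacer = emitter.background(int(rng.integers(lo, hi + 1)), rng)
            seq_parts.append(spacer)
            pos += len(spacer)

            rate = design.substitution_rate + copy * design.inparalog_extra_rate
            protein = _mutate_protein(ancestors[fam], rate, rng)
            is_alien = idx in alien_idx
            cds = (alien_emitter if is_alien else emitter).back_translate(
                protein, rng)
            strand = group_strand[group][fam]
            placed = cds if strand == "+" else reverse_complement(cds)
            gene_id = f"{gid}|{fam}" + (f".{copy + 1}" if copy else "")
            genes.append(GeneRecord(
                gene_id, gid, pos, pos + len(cds), strand, cds,
                translate_cds(cds, gene_id), annotation=fam))
            gene_rows.append({"gene_id": gene_id, "genome_id": gid,
                              "family_id": fam, "is_alien": is_alien,
                              "length_nt": len(cds)})
            seq_parts.append(placed)
            pos += len(cds)
        seq_parts.append(emitter.background(int(rng.integers(lo, hi + 1)), rng))
        genome = AnnotatedGenome(gid, [(gid, "".join(seq_parts))], genes,
                                 host_group=group)
        genomes.append(genome)

    truth = TruthTables(
        genes=pd.DataFrame(gene_rows),
        families=pd.DataFrame([
            {"family_id": f.family_id, "category": f.category,
             "presence": ",".join(presence[f.family_id])}
            for f in design.families]),
        groups=pd.DataFrame([
            {"group": g.name, "gc": g.gc, "theta": emitters[g.name].theta,
             "alien_gc": alien_emitters[g.name].gc}
            for g in design.groups]),
    )
    return genomes, truth


def emit_files(genomes: Sequence[AnnotatedGenome], truth: TruthTables,
               outdir: str | Path) -> None:
    """Write FASTA+GFF3 per genome plus metadata and truth TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        write_fasta_gff(g, out / f"{g.genome_id}.fasta", out / f"{g.genome_id}.gff3")
    pd.DataFrame({"genome_id": [g.genome_id for g in genomes],
                  "host_group": [g.host_group for g in genomes]}
                 ).to_csv(out / "metadata.tsv", sep="\t", index=False)
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    truth.families.to_csv(out / "truth_families.tsv", sep="\t", index=False)
    truth.groups.to_csv(out / "truth_groups.tsv", sep="\t", index=False)
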