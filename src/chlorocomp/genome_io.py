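"""Reading, writing and summarising annotated chlorovirus genomes.

Genomes are held as :class:`AnnotatedGenome` objects: an ordered list of
contigs plus an ordered list of protein-coding gene records.  Coordinates are
0-based half-open internally; GenBank and GFF3 use 1-based inclusive
coordinates, and the conversion happens exactly once at the file boundary.

Host-group labels (NC64A / Pbi / SAG for the real data) are never inferred
from sequence; they come from an explicit metadata table mapping genome ids
to host groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

HOST_GROUPS = ("NC64A", "Pbi", "SAG", "other")

_COMPLEMENT = str.maketrans("ACGTUacgtuRYKMSWBDHVNrykmswbdhvn",
                            "TGCAAtgcaaYRMKSWVHDBNyrmkswvhdbn")


class GenomeFormatError(ValueError):
    """Raised when an input file does not parse under the named standard."""


class CoordinateError(ValueError):
    """Raised when a feature's coordinates fall outside its contig."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand of ``contig_id``; ``coding_sequence`` is strand-resolved
    (5'->3' of the coding strand).
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    coding_sequence: str
    protein_sequence: str
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise CoordinateError(f"gene {self.gene_id}: end <= start")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class AnnotatedGenome:
    """Ordered contigs plus gene records for one virus."""

    genome_id: str
    contigs: list[tuple[str, str]]
    genes: list[GeneRecord]
    host_group: str = "other"

    def __post_init__(self) -> None:
        lengths = {cid: len(seq) for cid, seq in self.contigs}
        for g in self.genes:
            if g.contig_id not in lengths:
                raise CoordinateError(
                    f"gene {g.gene_id} references unknown contig {g.contig_id}")
            if g.end > lengths[g.contig_id]:
                raise CoordinateError(
                    f"gene {g.gene_id} extends past end of contig {g.contig_id}")
        order = {cid: i for i, (cid, _) in enumerate(self.contigs)}
        self.genes = sorted(self.genes, key=lambda g: (order[g.contig_id], g.start))

    @property
    def length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    def contig_sequence(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    def contig_offsets(self) -> dict[str, int]:
        """Cumulative start offset of each contig when concatenated in order."""
        offsets, pos = {}, 0
        for cid, seq in self.contigs:
            offsets[cid] = pos
            pos += len(seq)
        return offsets

    def gene_absolute_midpoint(self, gene: GeneRecord) -> float:
        return self.contig_offsets()[gene.contig_id] + gene.midpoint

    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein_sequence for g in self.genes}


def translate_cds(nt: str, gene_id: str = "?") -> str:
    """Translate a coding sequence with the standard code.

    Trailing partial codons are dropped; a terminal stop is stripped;
    internal stops are tolerated with a warning (deposited viral ORFs may
    contain them) and rendered as ``*``.
    """
    trimmed = nt[: len(nt) - len(nt) % 3]
    prot = str(Seq(trimmed).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        warnings.warn(f"gene {gene_id}: internal stop codon(s) in translation")
    return prot


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _gene_from_feature(feat: SeqFeature, contig_id: str, contig_seq: str,
                       index: int) -> GeneRecord:
    quals = feat.qualifiers
    gene_id = (quals.get("locus_tag") or quals.get("protein_id")
               or quals.get("gene") or [f"{contig_id}_CDS{index}"])[0]
    start, end = int(feat.location.start), int(feat.location.end)
    if end > len(contig_seq):
        raise CoordinateError(
            f"CDS {gene_id} extends past end of contig {contig_id}")
    strand = "-" if feat.location.strand == -1 else "+"
    cds = contig_seq[start:end]
    if strand == "-":
        cds = reverse_complement(cds)
    prot = quals.get("translation", [None])[0] or translate_cds(cds, gene_id)
    annotation = (quals.get("product") or quals.get("note") or [""])[0]
    return GeneRecord(gene_id, contig_id, start, end, strand, cds, prot, annotation)


def read_genbank(path: str | Path, genome_id: str | None = None) -> AnnotatedGenome:
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # pragma: no cover - biopython raises many types
        raise GenomeFormatError(f"{path}: not a parseable GenBank file: {exc}")
    if not records:
        raise GenomeFormatError(f"{path}: no GenBank records found")
    contigs, genes = [], []
    for rec in records:
        contig_id = rec.id
        seq = str(rec.seq).upper()
        contigs.append((contig_id, seq))
        idx = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            idx += 1
            genes.append(_gene_from_feature(feat, contig_id, seq, idx))
    gid = genome_id or Path(path).stem
    return AnnotatedGenome(gid, contigs, genes)


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if "=" in item:
            key, val = item.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def read_fasta_gff(fasta_path: str | Path, gff_path: str | Path,
                   genome_id: str | None = None) -> AnnotatedGenome:
    """Read a FASTA genome plus GFF3 annotation (CDS features only)."""
    contigs = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(str(fasta_path), "fasta")]
    if not contigs:
        raise GenomeFormatError(f"{fasta_path}: no FASTA records found")
    seqs = dict(contigs)
    genes = []
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeFormatError(
                    f"{gff_path}:{lineno}: expected 9 tab-separated columns")
            contig_id, _src, ftype, start1, end1, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            if contig_id not in seqs:
                raise CoordinateError(
                    f"{gff_path}:{lineno}: unknown contig {contig_id}")
            # GFF3 is 1-based inclusive.
            start, end = int(start1) - 1, int(end1)
            attrd = _parse_gff_attributes(attrs)
            gene_id = attrd.get("ID") or attrd.get("Name") or f"{contig_id}_l{lineno}"
            if end > len(seqs[contig_id]):
                raise CoordinateError(
                    f"CDS {gene_id} extends past end of contig {contig_id}")
            cds = seqs[contig_id][start:end]
            if strand == "-":
                cds = reverse_complement(cds)
            genes.append(GeneRecord(gene_id, contig_id, start, end, strand, cds,
                                    translate_cds(cds, gene_id),
                                    attrd.get("product", "")))
    gid = genome_id or Path(fasta_path).stem
    return AnnotatedGenome(gid, contigs, genes)


def read_genome(path: str | Path, format: str = "genbank",
                gff_path: str | Path | None = None,
                genome_id: str | None = None) -> AnnotatedGenome:
    """Read an annotated genome from disk.

    ``format`` is ``"genbank"`` or ``"fasta+gff"``; for the latter either
    pass ``gff_path`` or place a ``.gff3`` file next to the FASTA.
    """
    if format == "genbank":
        return read_genbank(path, genome_id)
    if format == "fasta+gff":
        gff = Path(gff_path) if gff_path else Path(path).with_suffix(".gff3")
        return read_fasta_gff(path, gff, genome_id)
    raise GenomeFormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    records = []
    for contig_id, seq in genome.contigs:
        rec = SeqRecord(Seq(seq), id=contig_id, name=contig_id[:16],
                        description=genome.genome_id,
                        annotations={"molecule_type": "DNA"})
        for g in genome.genes:
            if g.contig_id != contig_id:
                continue
            loc = FeatureLocation(g.start, g.end, strand=1 if g.strand == "+" else -1)
            feat = SeqFeature(loc, type="CDS", qualifiers={
                "locus_tag": [g.gene_id],
                "translation": [g.protein_sequence],
                "product": [g.annotation or "hypothetical protein"],
            })
            rec.features.append(feat)
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def write_fasta_gff(genome: AnnotatedGenome, fasta_path: str | Path,
                    gff_path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=cid, description="")
               for cid, seq in genome.contigs]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, seq in genome.contigs:
            fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id}"
            if g.annotation:
                attrs += f";product={g.annotation}"
            fh.write("\t".join([
                g.contig_id, "chlorocomp", "CDS",
                str(g.start + 1), str(g.end),  # back to 1-based inclusive
                ".", g.strand, "0", attrs,
            ]) + "\n")


def write_genome(genome: AnnotatedGenome, path: str | Path,
                 format: str = "genbank",
                 gff_path: str | Path | None = None) -> None:
    if format == "genbank":
        write_genbank(genome, path)
    elif format == "fasta+gff":
        gff = Path(gff_path) if gff_path else Path(path).with_suffix(".gff3")
        write_fasta_gff(genome, path, gff)
    else:
        raise GenomeFormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Metadata and summaries
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> dict[str, str]:
    """Read the genome_id -> host_group TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"genome_id", "host_group"} <= set(df.columns):
        raise GenomeFormatError(
            f"{path}: metadata needs columns genome_id, host_group")
    return dict(zip(df["genome_id"], df["host_group"]))


def apply_metadata(genomes: Iterable[AnnotatedGenome],
                   meta: dict[str, str]) -> list[AnnotatedGenome]:
    out = []
    for g in genomes:
        if g.genome_id not in meta:
            raise KeyError(f"no host group for genome {g.genome_id}")
        g.host_group = meta[g.genome_id]
        out.append(g)
    return out


def gc_content(genome: AnnotatedGenome | str) -> float:
    """GC fraction over all contigs, ignoring ambiguity codes entirely."""
    if isinstance(genome, AnnotatedGenome):
        seq = "".join(s for _, s in genome.contigs)
    else:
        seq = genome
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T") + seq.count("U")
    if gc + at == 0:
        raise ValueError("gc_content undefined: no unambiguous bases")
    return gc / (gc + at)


def genome_summary(genomes: Sequence[AnnotatedGenome]) -> pd.DataFrame:
    rows = [{
        "genome_id": g.genome_id,
        "host_group": g.host_group,
        "n_contigs": g.n_contigs,
        "genome_size_bp": g.length,
        "pct_gc": 100.0 * gc_content(g),
        "n_protein_genes": len(g.genes),
    } for g in genomes]
    return pd.DataFrame(rows)


def group_gc_summary(genomes: Sequence[AnnotatedGenome] | pd.DataFrame,
                     ) -> pd.DataFrame:
    """Median and SD of %GC per host group.

    Accepts either genomes or a DataFrame with columns ``host_group`` and
    ``pct_gc`` (e.g., a published genome-feature table).  Empty groups are
    omitted with a warning.  SD is the population SD for single-genome
    groups (0) and the sample SD otherwise.
    """
    if isinstance(genomes, pd.DataFrame):
        df = genomes
    else:
        df = genome_summary(genomes)
    if df.empty:
        warnings.warn("no genomes supplied; empty summary")
        return pd.DataFrame(columns=["host_group", "median_pct_gc", "sd_pct_gc",
                                     "n_genomes"])
    rows = []
    for group, sub in df.groupby("host_group", sort=True):
        vals = sub["pct_gc"].astype(float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append({"host_group": group,
                     "median_pct_gc": float(vals.median()),
                     "sd_pct_gc": sd,
                     "n_genomes": len(vals)})
    return pd.DataFrame(rows)
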