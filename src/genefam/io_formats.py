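"""Readers and writers for the external formats the pipeline touches.

Every downstream stage consumes only the domain types defined here:
:class:`GenomeAssembly`, :class:`GeneModel`, :class:`ProteinRecord`,
:class:`DomainHit` and :class:`FamilyTableRow`.

Coordinate conventions
----------------------
GFF3 coordinates (1-based, inclusive) are used internally everywhere.
BED output converts to 0-based half-open on write, per the BED standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class FormatError(ValueError):
    """A file violated the expectations of its format or an invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeAssembly:
    """A genome as a mapping of chromosome id -> uppercase nucleotide string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"chromosome {chrom!r} has an empty sequence")
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise FormatError(
                    f"chromosome {chrom!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]


@dataclass
class GeneModel:
    """One annotated gene: location, strand and exon blocks (1-based inclusive)."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.start > self.end:
            raise FormatError(f"gene {self.gene_id}: start > end")
        if not self.exons:
            raise FormatError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise FormatError(f"gene {self.gene_id}: exon start > end")
            if s < self.start or e > self.end:
                raise FormatError(f"gene {self.gene_id}: exon outside gene span")
            if prev_end is not None and s <= prev_end:
                raise FormatError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1


@dataclass
class ProteinRecord:
    """A protein sequence over the 20-letter alphabet (X allowed for ambiguity)."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.protein_id}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS - {"X"}
        if bad:
            raise FormatError(
                f"protein {self.protein_id}: illegal characters {sorted(bad)}"
            )


@dataclass
class DomainHit:
    """One domain match on a protein (HMMER per-domain row)."""

    protein_id: str
    domain_accession: str
    evalue: float
    ali_start: int
    ali_end: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"hit on {self.protein_id}: negative E-value")
        if self.ali_start > self.ali_end:
            raise FormatError(f"hit on {self.protein_id}: ali_start > ali_end")


@dataclass
class FamilyTableRow:
    """One row of a family characterization table (Table-1-style)."""

    name: str
    protein_id: str
    exon_count: int
    intron_count: int
    location: tuple[int, int]
    chromosome: str
    aa: int
    mw_kda: float
    pi: float
    subfamily: str = ""
    strand_hint: str = "+"  # "-" when the source printed start > end

    def __post_init__(self) -> None:
        if self.intron_count != self.exon_count - 1:
            raise FormatError(
                f"row {self.name}: intron count {self.intron_count} != "
                f"exon count {self.exon_count} - 1"
            )
        if self.aa < 1:
            raise FormatError(f"row {self.name}: aa < 1")
        if self.mw_kda <= 0:
            raise FormatError(f"row {self.name}: non-positive MW")
        if not 0 < self.pi < 14:
            raise FormatError(f"row {self.name}: pI outside (0, 14)")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA; ids are headers up to the first whitespace.

    Raises :class:`FormatError` on duplicate ids or an empty file.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def read_genome_fasta(path: str | Path) -> GenomeAssembly:
    """Read a nucleotide FASTA as a :class:`GenomeAssembly`."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate chromosome id {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeAssembly(sequences)


def write_fasta(records: Iterable[ProteinRecord] | Mapping[str, str],
                path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA (60-column wrap; byte-stable round trip)."""
    if isinstance(records, Mapping):
        items = records.items()
    else:
        items = ((r.protein_id, r.sequence) for r in records)
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 into one :class:`GeneModel` per gene.

    When a gene has several mRNA isoforms the exons of the longest one
    (greatest summed exon length, ties broken by exon count then id) are
    retained, so every gene maps to a single deterministic transcript.
    Exons are stored in ascending genomic order regardless of strand.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.strand not in {"+", "-"}:
            raise FormatError(f"gene {gene.id}: unknown strand {gene.strand!r}")
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if mrnas:
            def isoform_key(m):
                ex = list(db.children(m, featuretype="exon"))
                return (sum(e.end - e.start + 1 for e in ex), len(ex), m.id)
            best = max(mrnas, key=isoform_key)
            exon_feats = list(db.children(best, featuretype="exon", order_by="start"))
            protein_id = best.attributes.get("protein_id", [None])[0]
        else:
            exon_feats = list(db.children(gene, featuretype="exon", order_by="start"))
            protein_id = gene.attributes.get("protein_id", [None])[0]
        if exon_feats:
            exons = sorted((e.start, e.end) for e in exon_feats)
        else:
            exons = [(gene.start, gene.end)]
        for s, e in exons:
            if s < gene.start or e > gene.end:
                raise FormatError(f"gene {gene.id}: exon outside parent gene span")
        genes.append(GeneModel(
            gene_id=gene.id, chromosome=gene.seqid, strand=gene.strand,
            start=gene.start, end=gene.end, exons=exons, protein_id=protein_id,
        ))
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal GFF3 (gene/mRNA/exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.chromosome}\tgenefam\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            mrna_id = f"{g.gene_id}.t1"
            mattrs = f"ID={mrna_id};Parent={g.gene_id}"
            if g.protein_id:
                mattrs += f";protein_id={g.protein_id}"
            fh.write(f"{g.chromosome}\tgenefam\tmRNA\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{mattrs}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chromosome}\tgenefam\texon\t{s}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={mrna_id}.exon{i};Parent={mrna_id}\n")


# ---------------------------------------------------------------------------
# HMMER domtblout
# ---------------------------------------------------------------------------

def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output (``--domtblout``).

    One :class:`DomainHit` per domain row.  The full-sequence
    (independent) E-value column is used; the alignment coordinates are
    the ``ali from``/``ali to`` columns.  Comment lines start with ``#``.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 22 domtblout columns, "
                    f"got {len(fields)}"
                )
            try:
                evalue = float(fields[6])
                ali_start = int(fields[17])
                ali_end = int(fields[18])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            accession = fields[4] if fields[4] != "-" else fields[3]
            # strip Pfam accession version (PF00011.23 -> PF00011)
            accession = accession.split(".")[0]
            hits.append(DomainHit(
                protein_id=fields[0], domain_accession=accession,
                evalue=evalue, ali_start=ali_start, ali_end=ali_end,
            ))
    return hits


_DOMTBL_HEADER = (
    "#%-19s %10s %5s %-20s %10s %5s %9s %6s %5s %3s %3s %9s %9s %6s %5s "
    "%5s %5s %5s %5s %5s %5s %4s %s\n"
)


def write_domtblout(hits: Sequence[DomainHit], path: str | Path,
                    protein_lengths: Mapping[str, int] | None = None) -> None:
    """Write hits in HMMER3 domtblout layout (round-trips via read_domtblout)."""
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name           "
                 "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                 "i-Evalue  score  bias  from    to  from    to  from    to  "
                 "acc description of target\n")
        for h in hits:
            tlen = (protein_lengths or {}).get(h.protein_id, h.ali_end)
            qlen = h.ali_end - h.ali_start + 1
            fh.write(
                f"{h.protein_id:<20s} -          {tlen:5d} "
                f"{h.domain_accession:<20s} {h.domain_accession:<11s} {qlen:5d} "
                f"{h.evalue:9.3g} {50.0:6.1f} {0.1:5.1f}   1   1 "
                f"{h.evalue:9.3g} {h.evalue:9.3g} {50.0:6.1f} {0.1:5.1f} "
                f"{1:5d} {qlen:5d} {h.ali_start:5d} {h.ali_end:5d} "
                f"{h.ali_start:5d} {h.ali_end:5d} 0.95 -\n"
            )


# ---------------------------------------------------------------------------
# Family characterization table (Table-1-style TSV)
# ---------------------------------------------------------------------------

def read_family_table(path: str | Path) -> list[FamilyTableRow]:
    """Load a family table TSV, validating the intron = exon - 1 invariant.

    A printed location with start > end is normalized to (min, max) and the
    original order is kept as a strand hint ("-").
    """
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    required = {"name", "protein_id", "exon", "intron", "loc_start",
                "loc_end", "chr", "aa", "mw_kda", "pi"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    rows: list[FamilyTableRow] = []
    for _, r in df.iterrows():
        s, e = int(r["loc_start"]), int(r["loc_end"])
        try:
            rows.append(FamilyTableRow(
                name=str(r["name"]), protein_id=str(r["protein_id"]),
                exon_count=int(r["exon"]), intron_count=int(r["intron"]),
                location=(min(s, e), max(s, e)), chromosome=str(r["chr"]),
                aa=int(r["aa"]), mw_kda=float(r["mw_kda"]), pi=float(r["pi"]),
                subfamily=str(r.get("subfamily", "")),
                strand_hint="-" if s > e else "+",
            ))
        except FormatError as exc:
            raise FormatError(f"{path}: invalid row {r['name']!r}: {exc}") from exc
    return rows


def load_table1_fixture() -> list[FamilyTableRow]:
    """Load the packaged 34-row shiitake HSP family table."""
    with resources.as_file(
        resources.files("genefam").joinpath("data/table1_lehsp.tsv")
    ) as p:
        return read_family_table(p)


# ---------------------------------------------------------------------------
# Newick / BED / TSV
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Write a tree (anything with ``to_newick()``, or a Newick string)."""
    text = tree if isinstance(tree, str) else tree.to_newick()
    if not text.endswith(";"):
        text += ";"
    with open(path, "w") as fh:
        fh.write(text + "\n")


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) 1-based inclusive
    intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end, *rest = iv
            if start > end:
                raise FormatError(f"interval on {chrom}: start > end")
            fields = [str(chrom), str(start - 1), str(end)] + [str(x) for x in rest]
            fh.write("\t".join(fields) + "\n")


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a DataFrame as TSV (round-trip stable with read_tsv)."""
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
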