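"""Promoter extraction and heat-shock-element (HSE) scanning.

Promoters are the 1 kb of sequence immediately upstream of the translation
start (the gene's 5' end on its own strand): for a plus-strand gene the
block ending just before the gene start, read as-is; for a minus-strand
gene the block starting just after the gene end, reverse-complemented.
Promoters truncated by a chromosome edge are returned shorter, with a
warning.

The HSE motif scanned is 5'-nGAAC-3': any real base (A/C/G/T, never N)
followed by the literal GAAC.  Overlapping occurrences are counted, and by
default only the sense (promoter) strand is scanned; ``both_strands=True``
adds reverse-strand matches with positions reported in promoter
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GeneModel, GenomeAssembly

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterScan:
    """HSE occurrences in one promoter; offsets point at the 'n' base."""

    gene_id: str
    promoter_seq: str
    hse_positions: list[int]
    strands: list[str] = field(default_factory=list)

    @property
    def hse_count(self) -> int:
        return len(self.hse_positions)


def extract_promoter(gene: GeneModel, genome: GenomeAssembly,
                     length: int = 1000) -> str:
    """Strand-aware upstream sequence of a gene, 5'->3', up to `length` bp."""
    chrom_seq = genome[gene.chromosome]
    if gene.strand == "+":
        end = gene.start - 1          # last upstream base, 1-based
        start = max(1, end - length + 1)
        promoter = chrom_seq[start - 1:end]
    else:
        start = gene.end + 1
        end = min(len(chrom_seq), gene.end + length)
        promoter = reverse_complement(chrom_seq[start - 1:end])
    if len(promoter) < length:
        warnings.warn(
            f"promoter of {gene.gene_id} truncated to {len(promoter)} bp "
            f"at chromosome edge", stacklevel=2)
    return promoter


def scan_hse(promoter: str, gene_id: str = "", pattern: str = "GAAC",
             both_strands: bool = False) -> PromoterScan:
    """Count nGAAC occurrences (overlaps allowed; N never matches 'n')."""
    positions: list[int] = []
    strands: list[str] = []
    plen = len(pattern)
    for o in range(len(promoter) - plen):
        if promoter[o] in "ACGT" and promoter[o + 1:o + 1 + plen] == pattern:
            positions.append(o)
            strands.append("+")
    if both_strands:
        rc = reverse_complement(promoter)
        L = len(promoter)
        for o in range(len(rc) - plen):
            if rc[o] in "ACGT" and rc[o + 1:o + 1 + plen] == pattern:
                # map the motif's n-base back to promoter coordinates
                positions.append(L - 1 - o)
                strands.append("-")
    order = sorted(range(len(positions)), key=lambda i: positions[i])
    return PromoterScan(gene_id, promoter,
                        [positions[i] for i in order],
                        [strands[i] for i in order])


def hse_report(genes: Sequence[GeneModel], genome: GenomeAssembly,
               length: int = 1000, pattern: str = "GAAC",
               both_strands: bool = False,
               ) -> tuple[pd.DataFrame, list[tuple]]:
    """Scan every gene's promoter; return a count table and BED intervals.

    BED intervals are in genome coordinates (1-based inclusive tuples, as
    expected by :func:`genefam.io_formats.write_bed`), covering the full
    5-base motif.
    """
    rows = []
    bed: list[tuple] = []
    motif_len = len(pattern) + 1
    for gene in genes:
        promoter = extract_promoter(gene, genome, length)
        scan = scan_hse(promoter, gene.gene_id, pattern, both_strands)
        rows.append({"gene_id": gene.gene_id, "strand": gene.strand,
                     "promoter_len": len(promoter),
                     "hse_count": scan.hse_count})
        for o, s in zip(scan.hse_positions, scan.strands):
            if gene.strand == "+":
                g_start = gene.start - len(promoter) + o
            else:
                g_start = gene.end + len(promoter) - o - motif_len + 1
            bed.append((gene.chromosome, g_start, g_start + motif_len - 1,
                        gene.gene_id, scan.hse_count, s))
    return pd.DataFrame(rows).set_index("gene_id"), bed
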