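"""Seeded generators for every input the pipeline consumes.

The generators fabricate a small multi-chromosome genome with strand-mixed
gene models, six protein subfamilies carrying distinguishable sequence
signatures (each member is a mutated copy of a subfamily template, with a
40-residue window emitted as a domain hit), decoy proteins with no hits,
planted tandem/segmental duplicate pairs at a controlled similarity,
promoters with exact planted heat-shock-element counts, negative-binomial
count matrices with known log2 fold changes, and qPCR Ct tables with known
induction ratios.  Every product is deterministic in (seed, parameters)
and ships with a ground-truth record for recovery tests.

What this emulates — and what it does not: gene placement, strand mixing,
promoter context and domain-hit statistics mirror the shape of real
annotation data, but there is no codon structure, no splice signals, and
domain E-values are sampled rather than computed from a profile HMM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import QPCR_COLUMNS
from .io_formats import (DomainHit, GeneModel, GenomeAssembly, ProteinRecord,
                         write_domtblout, write_fasta, write_gff3)
from .promoter_hse import reverse_complement

AA20 = "ACDEFGHIKLMNPQRSTVWY"
DNA4 = "ACGT"

SUBFAMILY_ACCESSIONS = {
    "SHSP": ["PF00011"],
    "HSP40": ["PF00226", "PF01556"],
    "HSP60": ["PF00118"],
    "HSP70": ["PF00012"],
    "HSP90": ["PF00183"],
    "HSP100": ["PF02861", "PF10431"],
}
SUBFAMILY_ORDER = list(SUBFAMILY_ACCESSIONS)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(DNA4))[rng.integers(0, 4, n)])


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(AA20))[rng.integers(0, 20, n)])


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _overwrite(seq: str, pos0: int, block: str) -> str:
    """Replace seq[pos0:pos0+len(block)] keeping total length."""
    return seq[:pos0] + block + seq[pos0 + len(block):]


@dataclass
class SyntheticWorld:
    """A generated genome plus annotation, proteins, hits and ground truth."""

    genome: GenomeAssembly
    genes: list[GeneModel]
    proteins: list[ProteinRecord]
    hits: list[DomainHit]
    truth: dict
    params: dict

    @property
    def gene_of(self) -> dict[str, GeneModel]:
        return {g.protein_id: g for g in self.genes if g.protein_id}

    @property
    def protein_seqs(self) -> dict[str, str]:
        return {p.protein_id: p.sequence for p in self.proteins}

    def write(self, outdir: str | Path) -> None:
        """Write standard-format files plus a truth.json sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome.sequences, outdir / "genome.fasta")
        write_gff3(self.genes, outdir / "annotation.gff3")
        write_fasta(self.proteins, outdir / "proteins.faa")
        write_domtblout(self.hits, outdir / "hits.domtblout",
                        {p.protein_id: len(p.sequence) for p in self.proteins})
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"truth": self.truth, "params": self.params}, fh,
                      indent=1, sort_keys=True)


def make_genome(n_chromosomes: int = 3,
                genes_per_chr: int = 10,
                n_members: int = 18,
                member_length: int = 140,
                domain_block: int = 40,
                mutation_rate: float = 0.35,
                gap_range: tuple[int, int] = (5000, 8000),
                seed: int = 0) -> SyntheticWorld:
    """Generate a genome with family members (cycling through the six
    subfamilies) and decoy proteins.

    Members are mutated copies of per-subfamily templates; a 40-residue
    window of each is reported as a domain hit with a log-uniform E-value
    in [1e-30, 1e-6].  Decoys are unrelated random proteins with no hits.

    The default mutation rate (0.35) keeps subfamily members clearly
    homologous to each other while their pairwise similarity stays well
    below the 75% paralog threshold, mirroring real families where only a
    handful of member pairs qualify as duplicates; lower the rate to
    emulate tight, recently expanded families.
    """
    rng = np.random.default_rng(seed)
    n_genes = n_chromosomes * genes_per_chr
    if n_members > n_genes:
        raise ValueError("more members than genes")

    templates = {label: _random_protein(rng, member_length)
                 for label in SUBFAMILY_ORDER}
    block_start = (member_length - domain_block) // 2

    # decide which gene slots are members, cycling subfamilies
    member_slots = sorted(rng.choice(n_genes, size=n_members, replace=False))
    slot_subfamily = {slot: SUBFAMILY_ORDER[i % len(SUBFAMILY_ORDER)]
                      for i, slot in enumerate(member_slots)}

    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    truth_subfamily: dict[str, str] = {}
    truth_interval: dict[str, list[int]] = {}
    decoys: list[str] = []

    slot = 0
    for c in range(1, n_chromosomes + 1):
        chrom = f"chr{c}"
        pos = 1
        chunks: list[str] = []
        for _ in range(genes_per_chr):
            gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
            chunks.append(_random_dna(rng, gap))
            pos += gap
            n_exons = int(rng.integers(1, 4))
            exon_lens = rng.integers(100, 351, n_exons)
            intron_lens = rng.integers(50, 151, max(0, n_exons - 1))
            exons = []
            p = pos
            for i, el in enumerate(exon_lens):
                exons.append((p, p + int(el) - 1))
                p += int(el)
                if i < n_exons - 1:
                    p += int(intron_lens[i])
            gene_len = p - pos
            chunks.append(_random_dna(rng, gene_len))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g{slot + 1:03d}"
            pid = f"p{slot + 1:03d}"
            genes.append(GeneModel(gid, chrom, strand, pos, p - 1, exons, pid))
            if slot in slot_subfamily:
                label = slot_subfamily[slot]
                seq = _mutate_protein(rng, templates[label], mutation_rate)
                proteins.append(ProteinRecord(pid, seq))
                truth_subfamily[pid] = label
                accs = SUBFAMILY_ACCESSIONS[label]
                acc = accs[int(rng.integers(0, len(accs)))]
                evalue = float(10.0 ** rng.uniform(-30, -6))
                hits.append(DomainHit(pid, acc, evalue, block_start + 1,
                                      block_start + domain_block))
                truth_interval[pid] = [block_start + 1,
                                       block_start + domain_block]
            else:
                length = int(rng.integers(100, 201))
                proteins.append(ProteinRecord(pid, _random_protein(rng, length)))
                decoys.append(pid)
            pos = p
            slot += 1
        chunks.append(_random_dna(rng, 3000))  # tail margin
        sequences[chrom] = "".join(chunks)

    params = dict(n_chromosomes=n_chromosomes, genes_per_chr=genes_per_chr,
                  n_members=n_members, member_length=member_length,
                  domain_block=domain_block, mutation_rate=mutation_rate,
                  gap_range=list(gap_range), seed=seed)
    truth = {"subfamily": truth_subfamily, "domain_interval": truth_interval,
             "decoys": decoys, "pairs": [], "hse_offsets": {}}
    return SyntheticWorld(GenomeAssembly(sequences), genes, proteins, hits,
                          truth, params)


def _mutate_to_similarity(rng: np.random.Generator, seq: str,
                          target: float, matrix) -> str:
    """Mutated copy whose column similarity equals the target (+-2%).

    Changed positions receive residues scoring <= 0 against the original
    under the substitution matrix, so each changed column is non-similar
    and similarity is (L - m) / L by construction.
    """
    L = len(seq)
    m = round((1.0 - target) * L)
    pos = rng.choice(L, size=m, replace=False)
    out = list(seq)
    for i in pos:
        bad = [a for a in AA20 if a != out[i] and matrix[(a, out[i])] <= 0]
        out[i] = bad[int(rng.integers(0, len(bad)))]
    return "".join(out)


def plant_duplicates(world: SyntheticWorld,
                     n_tandem: int = 2,
                     n_segmental: int = 2,
                     target_similarity: float = 0.9,
                     seed: int = 0) -> SyntheticWorld:
    """Insert duplicate gene copies with a controlled protein similarity.

    Tandem copies land in the intergenic gap right after their source gene
    (zero intervening genes, well under 100 kb); segmental copies are
    appended to a different chromosome.  The world is modified in place
    and returned.
    """
    from .pairwise_dup import _default_matrix, global_align

    rng = np.random.default_rng(seed)
    matrix = _default_matrix()
    member_pids = sorted(world.truth["subfamily"])
    sources = [member_pids[i] for i in
               rng.choice(len(member_pids), size=n_tandem + n_segmental,
                          replace=False)]
    gene_of = world.gene_of
    chrom_names = list(world.genome.sequences)

    for idx, src_pid in enumerate(sources):
        kind = "tandem" if idx < n_tandem else "segmental"
        src_gene = gene_of[src_pid]
        src_seq = world.protein_seqs[src_pid]
        for _ in range(50):
            new_seq = _mutate_to_similarity(rng, src_seq, target_similarity,
                                            matrix)
            sim = global_align(src_seq, new_seq, matrix=matrix).similarity
            if abs(sim - target_similarity) <= 0.02:
                break
        else:
            raise RuntimeError("could not reach target similarity")

        gene_len = src_gene.end - src_gene.start + 1
        if kind == "tandem":
            chrom = src_gene.chromosome
            start = src_gene.end + 600
        else:
            others = [c for c in chrom_names if c != src_gene.chromosome]
            chrom = others[int(rng.integers(0, len(others)))]
            last_end = max([g.end for g in world.genes
                            if g.chromosome == chrom], default=0)
            start = last_end + 3000
        end = start + gene_len - 1
        seq = world.genome.sequences[chrom]
        if end + 1500 > len(seq):
            seq += _random_dna(rng, end + 1500 - len(seq))
        seq = _overwrite(seq, start - 1, _random_dna(rng, gene_len))
        world.genome.sequences[chrom] = seq

        gid = f"gdup{idx + 1}"
        pid = f"pdup{idx + 1}"
        offset = start - src_gene.start
        exons = [(s + offset, e + offset) for s, e in src_gene.exons]
        world.genes.append(GeneModel(gid, chrom, src_gene.strand,
                                     start, end, exons, pid))
        world.proteins.append(ProteinRecord(pid, new_seq))
        label = world.truth["subfamily"][src_pid]
        world.truth["subfamily"][pid] = label
        acc = SUBFAMILY_ACCESSIONS[label][0]
        src_hit = next(h for h in world.hits if h.protein_id == src_pid)
        world.hits.append(DomainHit(pid, acc, float(10.0 ** rng.uniform(-30, -6)),
                                    src_hit.ali_start, src_hit.ali_end))
        world.truth["pairs"].append({
            "a": src_pid, "b": pid, "type": kind,
            "target_similarity": target_similarity,
        })
        world.genes.sort(key=lambda g: (g.chromosome, g.start))
    world.params.update(n_tandem=n_tandem, n_segmental=n_segmental,
                        target_similarity=target_similarity, dup_seed=seed)
    return world


def _promoter_window(gene: GeneModel, chrom_len: int,
                     length: int) -> tuple[int, int]:
    """Genomic (1-based inclusive) window holding the gene's promoter."""
    if gene.strand == "+":
        return max(1, gene.start - length), gene.start - 1
    return gene.end + 1, min(chrom_len, gene.end + length)


def plant_promoter_sites(world: SyntheticWorld,
                         counts: Mapping[str, int],
                         length: int = 1000,
                         seed: int = 0) -> SyntheticWorld:
    """Scrub each requested promoter of accidental GAAC text, then insert
    exactly the requested number of nGAAC sites at non-overlapping offsets.

    Raises if two requested promoter windows overlap (the planted counts
    would not be independent).
    """
    rng = np.random.default_rng(seed)
    gene_by_id = {g.gene_id: g for g in world.genes}
    windows = []
    for gid in counts:
        g = gene_by_id[gid]
        w = _promoter_window(g, len(world.genome.sequences[g.chromosome]),
                             length)
        windows.append((g.chromosome, *w, gid))
    windows.sort()
    for (c1, s1, e1, g1), (c2, s2, e2, g2) in zip(windows, windows[1:]):
        if c1 == c2 and s2 <= e1:
            raise ValueError(f"promoter windows of {g1} and {g2} overlap")

    for gid in sorted(counts):
        gene = gene_by_id[gid]
        n_sites = counts[gid]
        chrom_seq = world.genome.sequences[gene.chromosome]
        w_start, w_end = _promoter_window(gene, len(chrom_seq), length)
        block = chrom_seq[w_start - 1:w_end]
        promoter = reverse_complement(block) if gene.strand == "-" else block
        plen = len(promoter)
        if n_sites and plen < 6 * n_sites:
            raise ValueError(f"promoter of {gid} too short for {n_sites} sites")

        for _ in range(50):
            scrubbed = promoter
            while "GAAC" in scrubbed:
                i = scrubbed.index("GAAC")
                scrubbed = _overwrite(scrubbed, i, "T")
            offsets: list[int] = []
            if n_sites:
                slots = np.arange(0, plen - 5, 6)
                pick = rng.choice(len(slots), size=n_sites, replace=False)
                offsets = sorted(int(slots[i]) for i in pick)
                for o in offsets:
                    n_base = DNA4[int(rng.integers(0, 4))]
                    scrubbed = _overwrite(scrubbed, o, n_base + "GAAC")
            # verify: planting must not create accidental extra matches
            found = [o for o in range(plen - 4)
                     if scrubbed[o] in "ACGT"
                     and scrubbed[o + 1:o + 5] == "GAAC"]
            if found == offsets:
                break
        else:
            raise RuntimeError(f"could not plant sites cleanly in {gid}")

        new_block = (reverse_complement(scrubbed) if gene.strand == "-"
                     else scrubbed)
        world.genome.sequences[gene.chromosome] = _overwrite(
            chrom_seq, w_start - 1, new_block)
        world.truth["hse_offsets"][gid] = offsets
    world.params.update(hse_counts=dict(counts), hse_seed=seed,
                        promoter_length=length)
    return world


def make_counts(gene_lengths: Mapping[str, int],
                lfc: pd.DataFrame,
                dispersion: float = 0.02,
                base_mean: float = 200.0,
                library_size: float = 1e6,
                seed: int = 0) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Negative-binomial count matrix with planted log2 fold changes.

    Mean of gene g in sample s is ``base_mean * (length_g / 1 kb) *
    2**lfc(g, s)``; variance is ``mu + dispersion * mu**2``.  The matrix
    models a gene-family slice of a transcriptome sequenced to a fixed
    per-sample depth, so the truth record carries ``library_size`` as the
    per-sample mapped-fragment total to normalize FPKM against (the
    family's own column sums are a negligible, composition-biased part of
    a real library).  Returns (counts, lengths, truth).
    """
    rng = np.random.default_rng(seed)
    genes = list(lfc.index)
    lengths = pd.Series({g: gene_lengths[g] for g in genes}, name="length")
    counts = pd.DataFrame(index=genes, columns=lfc.columns, dtype=int)
    for s in lfc.columns:
        mu = base_mean * (lengths.to_numpy() / 1000.0) \
            * np.power(2.0, lfc[s].to_numpy())
        if dispersion > 0:
            n = 1.0 / dispersion
            counts[s] = rng.negative_binomial(n, n / (n + mu))
        else:
            counts[s] = rng.poisson(mu)
    truth = {"lfc": {g: {s: float(lfc.loc[g, s]) for s in lfc.columns}
                     for g in genes},
             "dispersion": dispersion, "base_mean": base_mean,
             "library_size": library_size, "seed": seed}
    return counts, lengths, truth


def make_ct(fold_changes: Mapping[str, Mapping[str, float]],
            control: str = "0h",
            efficiency: float = 2.0,
            noise_sd: float = 0.2,
            replicates: int = 3,
            baseline_ct: float = 25.0,
            seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """qPCR Ct table with planted induction ratios.

    Ct = baseline - log_E(expression) + Normal(0, noise_sd); the control
    sample has expression 1 for every gene, and two reference genes (ref1,
    ref2) have expression 1 in every sample.
    """
    rng = np.random.default_rng(seed)
    samples = sorted({s for fc in fold_changes.values() for s in fc} - {control})
    rows = []

    def emit(gene: str, sample: str, expr: float, role: str) -> None:
        for rep in range(1, replicates + 1):
            ct = baseline_ct - math.log(expr, efficiency) \
                + float(rng.normal(0.0, noise_sd))
            rows.append({"gene": gene, "sample": sample, "replicate": rep,
                         "ct": round(ct, 4), "role": role,
                         "efficiency": efficiency})

    for gene in sorted(fold_changes):
        emit(gene, control, 1.0, "target")
        for s in samples:
            emit(gene, s, float(fold_changes[gene][s]), "target")
    for ref in ("ref1", "ref2"):
        emit(ref, control, 1.0, "reference")
        for s in samples:
            emit(ref, s, 1.0, "reference")

    table = pd.DataFrame(rows, columns=QPCR_COLUMNS)
    truth = {"fold_changes": {g: dict(fc) for g, fc in fold_changes.items()},
             "control": control, "efficiency": efficiency,
             "noise_sd": noise_sd, "replicates": replicates, "seed": seed}
    return table, truth


def default_world(seed: int = 0) -> SyntheticWorld:
    """The standard test world: 3 chromosomes, 30 genes (18 members cycling
    the six subfamilies, 12 decoys), 2 tandem + 2 segmental duplicate pairs
    at 90% similarity, and planted promoter HSE counts spanning 0-9."""
    world = make_genome(seed=seed)
    world = plant_duplicates(world, seed=seed + 1)
    counts = {}
    hse_grid = [9, 1, 0, 2, 3, 5, 7, 4]
    originals = [g for g in world.genes if not g.gene_id.startswith("gdup")]
    for i, gene in enumerate(originals[:len(hse_grid)]):
        counts[gene.gene_id] = hse_grid[i]
    world = plant_promoter_sites(world, counts, seed=seed + 2)
    return world
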