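"""Generator determinism, structural invariants and planted-truth fidelity."""

import json

import numpy as np
import pandas as pd
import pytest

from genefam import io_formats as io
from genefam import synthetic_data as syn
from genefam.family_identify import identify_members
from genefam.pairwise_dup import detect_paralogs, global_align
from genefam.promoter_hse import extract_promoter, scan_hse


class TestDeterminism:
    def test_make_genome_reproducible(self):
        w1 = syn.make_genome(seed=5)
        w2 = syn.make_genome(seed=5)
        assert w1.genome.sequences == w2.genome.sequences
        assert [(g.gene_id, g.start, g.exons) for g in w1.genes] == \
            [(g.gene_id, g.start, g.exons) for g in w2.genes]
        assert [(p.protein_id, p.sequence) for p in w1.proteins] == \
            [(p.protein_id, p.sequence) for p in w2.proteins]
        assert w1.truth == w2.truth

    def test_default_world_files_byte_identical(self, tmp_path):
        syn.default_world(seed=3).write(tmp_path / "a")
        syn.default_world(seed=3).write(tmp_path / "b")
        for name in ("genome.fasta", "annotation.gff3", "proteins.faa",
                     "hits.domtblout", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        assert syn.make_genome(seed=1).genome.sequences != \
            syn.make_genome(seed=2).genome.sequences


class TestStructuralInvariants:
    def test_genes_never_overlap(self, world):
        by_chrom = {}
        for g in world.genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                assert a.end < b.start

    def test_exons_inside_genes(self, world):
        for g in world.genes:
            for s, e in g.exons:
                assert g.start <= s <= e <= g.end

    def test_genome_alphabet_and_gene_fit(self, world):
        for chrom, seq in world.genome.sequences.items():
            assert set(seq) <= set("ACGT")
        for g in world.genes:
            assert g.end <= len(world.genome[g.chromosome])


class TestClassificationTruth:
    def test_all_members_no_decoys_recovered(self):
        w = syn.make_genome(n_chromosomes=2, genes_per_chr=6, n_members=12,
                            seed=11)
        members = identify_members(w.hits)
        assert len(members) == 12
        assert {m.protein_id: m.subfamily for m in members} == \
            w.truth["subfamily"]

    def test_domain_hits_within_protein(self, world):
        lengths = {p.protein_id: len(p.sequence) for p in world.proteins}
        for h in world.hits:
            assert 1 <= h.ali_start <= h.ali_end <= lengths[h.protein_id]
            assert h.evalue < 1e-4


class TestPlantedDuplicates:
    def test_target_similarity_reached(self, world):
        seqs = world.protein_seqs
        for pair in world.truth["pairs"]:
            aln = global_align(seqs[pair["a"]], seqs[pair["b"]])
            assert aln.similarity == pytest.approx(
                pair["target_similarity"], abs=0.02)
            assert aln.coverage > 0.95

    def test_low_similarity_pair_rejected_by_criteria(self):
        w = syn.make_genome(seed=21)
        w = syn.plant_duplicates(w, n_tandem=1, n_segmental=0,
                                 target_similarity=0.60, seed=22)
        (pair,) = w.truth["pairs"]
        seqs = w.protein_seqs
        found = detect_paralogs({k: seqs[k] for k in (pair["a"], pair["b"])})
        assert found == []

    def test_tandem_and_segmental_geometry(self, world):
        gene_of = world.gene_of
        for pair in world.truth["pairs"]:
            ga, gb = gene_of[pair["a"]], gene_of[pair["b"]]
            if pair["type"] == "tandem":
                assert ga.chromosome == gb.chromosome
                assert abs(ga.start - gb.start) <= 100_000
            else:
                assert ga.chromosome != gb.chromosome


class TestPlantedPromoterSites:
    def test_requested_counts_recovered_exactly(self, world):
        gene_by_id = {g.gene_id: g for g in world.genes}
        requested = world.params["hse_counts"]
        assert set(requested.values()) >= {0, 1, 9}
        for gid, n in requested.items():
            promoter = extract_promoter(gene_by_id[gid], world.genome)
            scan = scan_hse(promoter)
            assert scan.hse_count == n
            assert scan.hse_positions == world.truth["hse_offsets"][gid]

    def test_single_planted_site_reported_at_scanned_offset(self):
        w = syn.make_genome(n_chromosomes=1, genes_per_chr=2, n_members=2,
                            seed=31)
        gid = w.genes[0].gene_id
        w = syn.plant_promoter_sites(w, {gid: 1}, seed=32)
        promoter = extract_promoter(w.gene_of[w.genes[0].protein_id],
                                    w.genome)
        assert scan_hse(promoter).hse_positions == \
            w.truth["hse_offsets"][gid]

    def test_overlapping_windows_rejected(self):
        from genefam.io_formats import GeneModel

        w = syn.make_genome(n_chromosomes=1, genes_per_chr=2, n_members=2,
                            seed=41)
        anchor = w.genes[0]
        # a second plus-strand gene 500 bp downstream shares upstream context
        s = anchor.start + 500
        intruder = GeneModel("gx", anchor.chromosome, "+", s, s + 200,
                             [(s, s + 200)], "px")
        w.genes.append(intruder)
        a = GeneModel(anchor.gene_id, anchor.chromosome, "+", anchor.start,
                      anchor.end, anchor.exons, anchor.protein_id)
        w.genes[0] = a
        with pytest.raises(ValueError, match="overlap"):
            syn.plant_promoter_sites(w, {a.gene_id: 2, "gx": 2}, seed=43)


class TestCountAndCtTruth:
    def test_planted_lfc_two_recovered(self):
        lfc = pd.DataFrame({"ctrl": 0.0, "heat": 2.0},
                           index=[f"g{i}" for i in range(200)])
        counts, lengths, truth = syn.make_counts(
            {g: 1500 for g in lfc.index}, lfc, seed=51)
        ratio = (counts["heat"] / counts["ctrl"]).replace([np.inf], np.nan)
        est = float(np.log2(ratio).mean())
        assert est == pytest.approx(2.0, abs=0.2)

    def test_replicates_share_truth_differ_by_noise(self):
        table, truth = syn.make_ct({"t": {"4h": 8.0}}, seed=61)
        target = table[(table["gene"] == "t") & (table["sample"] == "4h")]
        assert len(target) == truth["replicates"]
        assert target["ct"].nunique() == len(target)  # noise differs
        assert truth["fold_changes"]["t"]["4h"] == 8.0

    def test_reference_genes_present_and_flat(self):
        table, _ = syn.make_ct({"t": {"4h": 400.0}}, noise_sd=0.0, seed=62)
        refs = table[table["role"] == "reference"]
        assert set(refs["gene"]) == {"ref1", "ref2"}
        for _, grp in refs.groupby("gene"):
            assert grp["ct"].nunique() == 1  # expression 1 everywhere


class TestRoundTrip:
    def test_world_files_parse_back_consistently(self, world, tmp_path):
        world.write(tmp_path)
        genome = io.read_genome_fasta(tmp_path / "genome.fasta")
        genes = io.read_gff3(tmp_path / "annotation.gff3")
        proteins = io.read_fasta(tmp_path / "proteins.faa")
        hits = io.read_domtblout(tmp_path / "hits.domtblout")
        truth = json.loads((tmp_path / "truth.json").read_text())["truth"]
        assert genome.sequences == world.genome.sequences
        assert len(genes) == len(world.genes)
        assert {p.protein_id for p in proteins} == \
            {p.protein_id for p in world.proteins}
        assert {h.protein_id for h in hits} == set(truth["subfamily"])
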