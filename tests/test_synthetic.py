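"""Generator invariants: determinism, planted features, recoverability."""

import numpy as np
import pandas as pd
import pytest

from chronotopo import asmqc, io, phylostrat, polya, synthetic
from chronotopo.synthetic import SyntheticConfig


class TestConfigValidation:
    def test_overlapping_gaps_rejected(self):
        cfg = SyntheticConfig(gap_runs=[(0, 500_000, 100), (0, 500_050, 100)])
        with pytest.raises(ValueError, match="overlapping"):
            cfg.validate()

    def test_gap_past_end_rejected(self):
        cfg = SyntheticConfig(gap_runs=[(0, 1_499_990, 100)])
        with pytest.raises(ValueError, match="past chromosome"):
            cfg.validate()

    def test_nonpositive_effect_rejected(self):
        with pytest.raises(ValueError, match="effect"):
            SyntheticConfig(sRNA_effect=0.0).validate()

    def test_proportions_over_one_rejected(self):
        with pytest.raises(ValueError, match="proportions"):
            SyntheticConfig(hexamer_proportions={"AAUAAA": 0.8, "AUUAAA": 0.4}).validate()

    def test_too_many_genes_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            SyntheticConfig(n_genes_per_chrom=10_000).validate()


class TestMakeGenome:
    def test_no_telomeres_no_gaps(self):
        cfg = SyntheticConfig(telomere_copies_per_end=0, gap_runs=[], young_blocks=[],
                              n_chrom=1, chrom_length_bp=50_000, n_genes_per_chrom=20)
        chroms, _ = synthetic.make_genome(cfg)
        seq = chroms["chr1"]
        assert "N" not in seq
        assert not seq.startswith("CCCTAA") and not seq.endswith("TTAGGG")

    def test_planted_telomeres_and_gap(self):
        cfg = SyntheticConfig(
            telomere_copies_per_end=10, gap_runs=[(0, 5000, 15)], young_blocks=[],
            n_chrom=1, chrom_length_bp=50_000, n_genes_per_chrom=20,
        )
        chroms, manifest = synthetic.make_genome(cfg)
        seq = chroms["chr1"]
        assert seq.startswith("CCCTAA" * 10) and seq.endswith("TTAGGG" * 10)
        # exactly one N run of 15 at position 5000
        assert seq[5000:5015] == "N" * 15
        assert seq.count("N") == 15
        assert len(seq) == 50_000

    def test_same_seed_identical(self):
        cfg = SyntheticConfig(n_chrom=1, chrom_length_bp=30_000, gap_runs=[],
                              young_blocks=[], n_genes_per_chrom=15)
        a, _ = synthetic.make_genome(cfg)
        b, _ = synthetic.make_genome(cfg)
        assert a == b


class TestMakeGeneAges:
    def test_block_covering_chromosome_zero_dispersion(self):
        cfg = SyntheticConfig(
            n_chrom=1, chrom_length_bp=200_000, gap_runs=[], n_genes_per_chrom=50,
            young_blocks=[(0, 0, 200_000, 9.0)], rank_dispersion=0.0,
        )
        genes = synthetic.make_gene_ages(cfg)
        assert (genes.true_rank == 9).all()

    def test_no_blocks_zero_dispersion_all_rank_one(self):
        cfg = SyntheticConfig(
            n_chrom=1, chrom_length_bp=200_000, gap_runs=[], n_genes_per_chrom=50,
            young_blocks=[], rank_dispersion=0.0, background_mean_rank=1.0,
        )
        genes = synthetic.make_gene_ages(cfg)
        assert (genes.true_rank == 1).all()

    def test_block_contrast_matches_configured_gap(self):
        cfg = SyntheticConfig(
            seed=5, n_chrom=2, chrom_length_bp=2_000_000, gap_runs=[],
            n_genes_per_chrom=400, young_blocks=[(0, 0, 1_000_000, 7.0)],
            background_mean_rank=1.5, rank_dispersion=0.5,
        )
        genes = synthetic.make_gene_ages(cfg)
        inside = genes[(genes.chrom == "chr1") & (genes.start < 1_000_000)]
        outside = genes[~genes.index.isin(inside.index)]
        assert len(inside) >= 150 and len(outside) >= 500
        # clipping at rank 1 raises the background mean slightly above 1.5
        assert inside.true_rank.mean() - outside.true_rank.mean() == pytest.approx(
            7.0 - 1.5, abs=0.3
        )

    def test_genes_within_bounds(self):
        cfg = SyntheticConfig()
        genes = synthetic.make_gene_ages(cfg)
        assert (genes.start >= 0).all() and (genes.end <= cfg.chrom_length_bp).all()
        assert genes.true_rank.between(1, cfg.n_phyloranks).all()


class TestMakeTracks:
    def test_unit_effects_no_group_difference(self):
        cfg = SyntheticConfig(seed=2, sRNA_effect=1.0, longRNA_effect=1.0,
                              srna_loci_per_chrom=300)
        genes = synthetic.make_gene_ages(cfg)
        srna, cov, _ = synthetic.make_tracks(cfg, genes)
        from scipy import stats

        blocks = {(c, s, e) for c, s, e, _ in [
            (synthetic.chrom_name(b[0]), b[1], b[2], b[3]) for b in cfg.young_blocks
        ]}

        def inside(row):
            return any(row.chrom == c and s <= row.start < e for c, s, e in blocks)

        mask = srna.apply(inside, axis=1)
        _, p = stats.ttest_ind(srna[mask].rpkm, srna[~mask].rpkm)
        assert p > 0.05

    def test_methylation_range(self):
        cfg = SyntheticConfig(seed=3)
        genes = synthetic.make_gene_ages(cfg)
        _, _, meth = synthetic.make_tracks(cfg, genes)
        assert meth.meth_pct.between(0, 100).all()

    def test_srna_effect_ratio_recovered(self):
        cfg = SyntheticConfig(seed=4, sRNA_effect=8.0, srna_loci_per_chrom=400,
                              n_chrom=2)
        genes = synthetic.make_gene_ages(cfg)
        srna, _, _ = synthetic.make_tracks(cfg, genes)
        in_block = srna[(srna.chrom == "chr1") & (srna.start >= 400_000) & (srna.start < 900_000)]
        out_block = srna[~srna.index.isin(in_block.index)]
        ratio = in_block.rpkm.mean() / out_block.rpkm.mean()
        assert ratio == pytest.approx(8.0, rel=0.25)

    def test_longrna_elevated_outside_blocks(self):
        cfg = SyntheticConfig(seed=5, longRNA_effect=4.0, n_chrom=2)
        genes = synthetic.make_gene_ages(cfg)
        _, cov, _ = synthetic.make_tracks(cfg, genes)
        inb = cov[(cov.chrom == "chr1") & (cov.start >= 400_000) & (cov.start < 900_000)]
        outb = cov[~cov.index.isin(inb.index)]
        assert outb.value.mean() / inb.value.mean() == pytest.approx(4.0, rel=0.25)


class TestMakeHomologyHits:
    def test_species_restricted_gene_has_no_outside_hits(self):
        cfg = SyntheticConfig()
        ages = pd.DataFrame({"gene_id": ["gA"], "true_rank": [cfg.n_phyloranks]})
        hits, taxon_map, _, _ = synthetic.make_homology_hits(cfg, ages)
        taxa = dict(zip(taxon_map.subject_id, taxon_map.taxon_id))
        assert all(taxa[s] == synthetic.FOCAL_TAXON_ID for s in hits.sseqid)

    def test_noise_free_scores_exact(self):
        cfg = SyntheticConfig(bitscore_noise_sd=0.0)
        ages = pd.DataFrame({"gene_id": ["gA"], "true_rank": [1]})
        hits, taxon_map, _, newick = synthetic.make_homology_hits(cfg, ages)
        tree = phylostrat.TreeDistances.from_newick_string(newick)
        taxa = dict(zip(taxon_map.subject_id, taxon_map.taxon_id))
        for r in hits.itertuples():
            t = taxa[r.sseqid]
            d = tree.distance(synthetic.FOCAL_TAXON_ID, t)
            assert r.bitscore == pytest.approx(cfg.decay_a * np.exp(-cfg.decay_b * d), abs=0.05)

    def test_assignment_recovers_true_ranks(self):
        """End-to-end recovery: >= 95% of simulated genes get their planted
        rank back from the assignment pipeline."""
        cfg = SyntheticConfig(seed=8, n_chrom=2, n_genes_per_chrom=150)
        genes = synthetic.make_gene_ages(cfg)
        true_ages = genes[["gene_id", "true_rank"]]
        hits, taxon_map, lineages_df, newick = synthetic.make_homology_hits(cfg, true_ages)
        lineages = {
            int(r.taxon_id): phylostrat.TaxonLineage(
                int(r.taxon_id), r.lineage.split(";")
            )
            for r in lineages_df.itertuples()
        }
        merged = hits.rename(columns={"qseqid": "gene_id"}).merge(
            taxon_map.rename(columns={"subject_id": "sseqid"}), on="sseqid"
        )
        merged = merged.rename(columns={"taxon_id": "subject_taxon_id"})
        assignments = phylostrat.assign_all(
            merged[["gene_id", "subject_taxon_id", "evalue", "bitscore"]],
            lineages, synthetic.FOCAL_TAXON_ID,
        )
        check = assignments.merge(true_ages, on="gene_id")
        recovery = (check.phylorank == check.true_rank).mean()
        assert recovery >= 0.95


class TestMakePolyAReads:
    def test_single_variant_manifest(self):
        cfg = SyntheticConfig(hexamer_proportions={"AAUAAA": 1.0}, n_polya_reads=50)
        _, manifest = synthetic.make_polya_reads(cfg)
        assert all(m["value"].split(",")[0] == "AAUAAA" for m in manifest)

    def test_tail_floor(self):
        cfg = SyntheticConfig(n_polya_reads=200)
        _, manifest = synthetic.make_polya_reads(cfg)
        lens = [int(m["value"].split(",")[1]) for m in manifest]
        assert min(lens) >= cfg.min_tail

    def test_planted_tails_and_signals_recovered_exactly(self):
        cfg = SyntheticConfig(seed=6, n_polya_reads=150)
        reads, manifest = synthetic.make_polya_reads(cfg)
        truth = {m["key"]: m["value"].split(",") for m in manifest}
        for rid, seq in reads:
            variant, tail_len = truth[rid][0], int(truth[rid][1])
            tc = polya.detect_tail(rid, seq)
            assert tc is not None and tc.tail_length_nt == tail_len
            window = seq[len(seq) - tail_len - 50 : len(seq) - tail_len]
            assert polya.call_signal(window) == variant


class TestBundle:
    def test_determinism_hash_equal(self, small_cfg, tmp_path):
        import hashlib

        b1 = synthetic.generate_bundle(small_cfg, tmp_path / "a")
        b2 = synthetic.generate_bundle(small_cfg, tmp_path / "b")
        for name in ("genome", "genes", "true_ages", "hits", "srna_loci",
                     "coverage", "methylation", "reads", "manifest", "tree"):
            h1 = hashlib.sha256(getattr(b1, name).read_bytes()).hexdigest()
            h2 = hashlib.sha256(getattr(b2, name).read_bytes()).hexdigest()
            assert h1 == h2, name

    def test_files_round_trip_through_readers(self, small_bundle, small_cfg):
        scaffolds = asmqc.read_fasta(small_bundle.genome)
        assert len(scaffolds) == small_cfg.n_chrom
        assert all(len(s) == small_cfg.chrom_length_bp for s in scaffolds.values())

        genes = io.read_gff3_genes(small_bundle.genes)
        ages = io.read_true_ages(small_bundle.true_ages)
        assert set(genes.gene_id) == set(ages.gene_id)  # every gene has an age

        hits = phylostrat.read_hits_table(small_bundle.hits, small_bundle.taxon_map)
        lineages = phylostrat.load_lineages(small_bundle.lineages, synthetic.FOCAL_TAXON_ID)
        assert set(hits.subject_taxon_id) <= set(lineages)  # taxa all known

        tree = phylostrat.TreeDistances.from_newick(small_bundle.tree)
        for tid in lineages:
            assert tree.distance(synthetic.FOCAL_TAXON_ID, tid) >= 0.0

        srna = io.read_bed(small_bundle.srna_loci)
        assert (srna.end > srna.start).all()
        meth = io.read_methylation(small_bundle.methylation)
        assert meth.meth_pct.between(0, 100).all()
        reads = asmqc.read_fastq_ids_seqs(small_bundle.reads)
        assert len(reads) == small_cfg.n_polya_reads
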