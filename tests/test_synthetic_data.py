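"""Ground-truth generator: sequence, count, read and truth-table contracts."""

import numpy as np
import pandas as pd
import pytest

from hebkit.synthetic_data import (
    SimDesign,
    generate_counts,
    generate_genomes,
    generate_homoeolog_counts,
    generate_reads,
)


class TestDesignValidation:
    def test_bad_mixture_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimDesign(category_mix={"conserved": 0.5}).validate()

    def test_bad_snp_rate_rejected(self):
        with pytest.raises(ValueError):
            SimDesign(snp_rate=1.5).validate()

    def test_unsatisfiable_mixture_names_genes(self):
        # every gene is category I (parents R>C) but the HEB mixture has no
        # transition with parental state R>C
        design = SimDesign(
            n_genes=5,
            category_mix={"I": 1.0},
            heb_mix={("R=C", "R=C"): 1.0},
            silencing_fraction=0,
            novel_fraction=0,
        )
        genomes = generate_genomes(design)
        with pytest.raises(ValueError, match="gene0000"):
            generate_counts(design, genomes)


class TestGenomes:
    def test_zero_snp_rate_gives_identical_orthologues(self):
        design = SimDesign(n_genes=5, snp_rate=0.0, seed=1)
        g = generate_genomes(design)
        assert g.snps == []
        assert all(g.seq_r[x] == g.seq_c[x] for x in g.genes)

    def test_saturating_snp_rate_diverges_every_base(self):
        design = SimDesign(
            n_genes=2, snp_rate=1.0, gene_length_range=(100, 100), seed=1
        )
        g = generate_genomes(design)
        per_gene = pd.Series([s.pair_id for s in g.snps]).value_counts()
        assert (per_gene == 100).all()
        for x in g.genes:
            assert all(a != b for a, b in zip(g.seq_r[x], g.seq_c[x]))

    def test_snp_count_matches_binomial_expectation(self):
        design = SimDesign(
            n_genes=500, snp_rate=0.01, gene_length_range=(1000, 1000), seed=7
        )
        g = generate_genomes(design)
        expected = 500 * 1000 * 0.01
        sd = np.sqrt(500 * 1000 * 0.01 * 0.99)
        assert abs(len(g.snps) - expected) <= 3 * sd

    def test_fasta_round_trip(self, tmp_path):
        from Bio import SeqIO

        design = SimDesign(n_genes=3, seed=2)
        g = generate_genomes(design)
        g.write_fasta(tmp_path / "R.fa", tmp_path / "C.fa")
        back = {r.id: str(r.seq) for r in SeqIO.parse(tmp_path / "R.fa", "fasta")}
        assert back == g.seq_r


class TestCounts:
    def test_seeded_determinism(self):
        design = SimDesign(n_genes=50, depth=5e4, seed=3)
        runs = []
        for _ in range(2):
            g = generate_genomes(design)
            b = generate_counts(design, g)
            runs.append(b)
        assert runs[0].count_matrix.counts.equals(runs[1].count_matrix.counts)
        assert runs[0].truth.equals(runs[1].truth)

    def test_library_size_equals_column_sum(self, small_sim):
        _, _, bundle, _ = small_sim
        cm = bundle.count_matrix
        assert (cm.library_sizes == cm.counts.sum(axis=0)).all()

    def test_conserved_genes_have_equal_programmed_means(self, small_sim):
        _, _, bundle, _ = small_sim
        t = bundle.truth
        cons = t[(t["category"] == "conserved") & ~t["novel_expression"]]
        assert np.allclose(cons["mean_R"], cons["mean_C"])
        assert np.allclose(cons["mean_R"], cons["mean_hybrid"])

    def test_silenced_homoeologue_component_is_zero(self, small_sim):
        _, _, bundle, _ = small_sim
        t = bundle.truth
        r_sil = t.index[t["r_silencing"]]
        assert len(r_sil) > 0
        for sample, comp in bundle.components.items():
            assert (comp.loc[r_sil, "r_component"] == 0).all()

    def test_truth_flags_consistent_with_mixing_proportion(self, small_sim):
        _, _, bundle, _ = small_sim
        t = bundle.truth
        assert t["rho"].between(0, 1).all()
        assert (t.loc[t["r_silencing"], "rho"] == 0).all()
        assert (t.loc[t["c_silencing"], "rho"] == 1).all()

    def test_poisson_limit_recovers_programmed_fold(self):
        """Zero dispersion, 4-fold programmed parental difference: the
        sample-mean ratio is within 10% of 4 at mean counts >= 200."""
        design = SimDesign(
            n_genes=200,
            depth=1e6,
            nb_dispersion=0.0,
            category_mix={"X": 1.0},         # R = 4x C, hybrid at R level
            heb_mix={("R>C", "R>C"): 1.0},
            silencing_fraction=0,
            novel_fraction=0,
            seed=5,
        )
        g = generate_genomes(design)
        b = generate_counts(design, g)
        cm = b.count_matrix
        mean_r = cm.counts[[s for s in cm.samples if s.startswith("R_")]].mean(axis=1)
        mean_c = cm.counts[[s for s in cm.samples if s.startswith("C_")]].mean(axis=1)
        big = b.truth["mean_C"] >= 200
        assert big.sum() > 20
        ratios = mean_r[big] / mean_c[big]
        assert ((ratios > 3.6) & (ratios < 4.4)).mean() > 0.95


class TestReads:
    def test_read_longer_than_gene_is_rejected_by_name(self):
        design = SimDesign(
            n_genes=3, gene_length_range=(80, 90), read_length=100, depth=1e3, seed=1
        )
        g = generate_genomes(design)
        b = generate_counts(design, g)
        with pytest.raises(ValueError, match="gene00000"):
            generate_reads(design, g, b, "unused")

    def test_origin_counts_match_mixing_proportion(self, tmp_path):
        design = SimDesign(n_genes=30, depth=3e4, seed=21)
        g = generate_genomes(design)
        b = generate_counts(design, g)
        paths = generate_reads(design, g, b, tmp_path, samples=["F18_1"])
        names = [
            line[1:].strip()
            for line in open(paths["F18_1"]["fastq"])
            if line.startswith("@")
        ]
        origins = pd.DataFrame(
            [n.split(":")[1:] for n in names], columns=["gene", "serial", "origin"]
        )
        comp = b.components["F18_1"]
        per_gene = origins.groupby("gene")["origin"].value_counts().unstack(fill_value=0)
        for gene, row in per_gene.iterrows():
            assert row.get("R", 0) == comp.loc[gene, "r_component"]
            assert row.get("C", 0) == comp.loc[gene, "c_component"]

    def test_fully_r_gene_yields_only_r_reads(self, tmp_path):
        design = SimDesign(
            n_genes=10, depth=1e4,
            category_mix={"conserved": 1.0},
            heb_mix={("R=C", "R=C"): 1.0},
            silencing_fraction=0.4, novel_fraction=0.0, seed=2,
        )
        g = generate_genomes(design)
        b = generate_counts(design, g)
        c_sil = b.truth.index[b.truth["c_silencing"]]  # mixing proportion 1
        assert len(c_sil) > 0
        paths = generate_reads(design, g, b, tmp_path, samples=["F1_1"])
        for line in open(paths["F1_1"]["fastq"]):
            if line.startswith("@"):
                _, gene, _, origin = line[1:].strip().split(":")
                if gene in c_sil:
                    assert origin == "R"


class TestHomoeologCounts:
    def test_bins_conserve_component_totals(self, small_sim):
        _, _, bundle, homoeolog = small_sim
        for sample, comp in bundle.components.items():
            sub = homoeolog[homoeolog["sample"] == sample].set_index("pair_id")
            total = sub[["r_count", "c_count", "ambiguous"]].sum(axis=1)
            expected = comp["r_component"] + comp["c_component"]
            assert total.reindex(expected.index).equals(expected)

    def test_gene_without_snps_is_fully_ambiguous(self):
        design = SimDesign(n_genes=40, depth=2e4, snp_rate=0.002, seed=23)
        genomes = generate_genomes(design)
        bundle = generate_counts(design, genomes)
        homoeolog = generate_homoeolog_counts(design, genomes, bundle)
        no_snp = bundle.truth.index[bundle.truth["n_snps"] == 0]
        assert len(no_snp) > 0  # at this SNP rate some genes carry none
        sub = homoeolog[homoeolog["pair_id"].isin(no_snp)]
        assert (sub[["r_count", "c_count"]] == 0).all().all()
        assert (sub["ambiguous"] > 0).any()

    def test_binomial_split_tracks_mixing_proportion(self, small_sim):
        _, _, bundle, homoeolog = small_sim
        t = bundle.truth
        agg = homoeolog.groupby("pair_id")[["r_count", "c_count"]].sum()
        informative = agg.sum(axis=1)
        strong = informative[informative >= 200].index
        rho_hat = agg.loc[strong, "r_count"] / informative[strong]
        rho_true = t.loc[strong, "rho"]
        sd = np.sqrt(rho_true * (1 - rho_true) / informative[strong])
        # 3-sigma binomial envelope, elementwise
        assert ((rho_hat - rho_true).abs() <= 3 * sd + 1e-9).mean() > 0.98
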