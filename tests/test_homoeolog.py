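"""Orthologue pairing, SNP discovery, read binning and HEB states."""

import itertools

import numpy as np
import pandas as pd
import pysam
import pytest

from hebkit.homoeolog import (
    DiagnosticSnp,
    bin_reads,
    call_expression_status,
    classify_heb,
    find_diagnostic_snps,
    find_orthologues,
    heb_transition,
    read_snp_table,
    write_snp_table,
)

HIT = "{q}\t{s}\t98.0\t{ln}\t2\t0\t1\t{ln}\t1\t{ln}\t{e}\t500"


def _write_hits(path, rows):
    path.write_text("\n".join(rows) + "\n")
    return path


class TestOrthologues:
    def test_reciprocal_best_pair_retained(self, tmp_path):
        fwd = _write_hits(tmp_path / "f.tsv", [HIT.format(q="A", s="B", ln=400, e=1e-30)])
        rev = _write_hits(tmp_path / "r.tsv", [HIT.format(q="B", s="A", ln=400, e=1e-30)])
        pairs = find_orthologues(fwd, rev)
        assert len(pairs) == 1 and pairs[0].r_id == "A" and pairs[0].c_id == "B"

    def test_short_alignment_dropped(self, tmp_path):
        fwd = _write_hits(tmp_path / "f.tsv", [HIT.format(q="A", s="B", ln=250, e=1e-30)])
        rev = _write_hits(tmp_path / "r.tsv", [HIT.format(q="B", s="A", ln=250, e=1e-30)])
        assert find_orthologues(fwd, rev) == []

    def test_weak_evalue_dropped(self, tmp_path):
        fwd = _write_hits(tmp_path / "f.tsv", [HIT.format(q="A", s="B", ln=400, e=1e-10)])
        rev = _write_hits(tmp_path / "r.tsv", [HIT.format(q="B", s="A", ln=400, e=1e-10)])
        assert find_orthologues(fwd, rev) == []

    def test_non_reciprocal_dropped(self, tmp_path):
        fwd = _write_hits(tmp_path / "f.tsv", [HIT.format(q="A", s="B", ln=400, e=1e-30)])
        rev = _write_hits(
            tmp_path / "r.tsv",
            [
                HIT.format(q="B", s="A2", ln=400, e=1e-40),
                HIT.format(q="B", s="A", ln=400, e=1e-30),
            ],
        )
        assert find_orthologues(fwd, rev) == []

    def test_malformed_row_reports_line_number(self, tmp_path):
        fwd = tmp_path / "f.tsv"
        fwd.write_text("A\tB\tnot-enough-columns\n")
        rev = _write_hits(tmp_path / "r.tsv", [HIT.format(q="B", s="A", ln=400, e=1e-30)])
        with pytest.raises(ValueError, match=":1"):
            find_orthologues(fwd, rev)


class TestDiagnosticSnps:
    def test_perfect_concordance_retained(self):
        snps = find_diagnostic_snps(
            "p1", "AAG", "ACG",
            pileups={("R", 1): {"A": 20}, ("C", 1): {"C": 18}},
        )
        assert [(s.pos_r, s.allele_r, s.allele_c) for s in snps] == [(1, "A", "C")]

    def test_half_concordance_dropped(self):
        snps = find_diagnostic_snps(
            "p1", "AAG", "ACG",
            pileups={("R", 1): {"A": 10, "C": 10}},
        )
        assert snps == []

    def test_identical_column_not_candidate(self):
        assert find_diagnostic_snps("p1", "AAGT", "AAGT") == []

    def test_gap_columns_skipped_and_coordinates_track_gaps(self):
        # R has an insertion; the site after it maps to different coordinates
        snps = find_diagnostic_snps("p1", "ATTG", "A-TC")
        assert len(snps) == 1
        s = snps[0]
        assert (s.pos_r, s.pos_c, s.allele_r, s.allele_c) == (3, 2, "G", "C")

    def test_table_round_trip_is_one_based(self, tmp_path):
        snps = [DiagnosticSnp("p1", 0, 0, "A", "G")]
        path = tmp_path / "snps.tsv"
        write_snp_table(snps, path)
        assert pd.read_csv(path, sep="\t")["pos_r"].iloc[0] == 1
        assert read_snp_table(path)[0].pos_r == 0


def _make_sam(path, reads, ref_len=60):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "p1", "LN": ref_len}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for name, start, seq, cigar in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = name
            a.query_sequence = seq
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = cigar or [(0, len(seq))]
            fh.write(a)


class TestBinReads:
    # diagnostic sites at 0-based positions 10 (R=A/C=G) and 20 (R=T/C=C)
    SNPS = [DiagnosticSnp("p1", 10, 10, "A", "G"), DiagnosticSnp("p1", 20, 20, "T", "C")]

    def test_vote_assignment_and_conservation(self, tmp_path):
        sam = tmp_path / "t.sam"
        _make_sam(
            sam,
            [
                ("r_allele", 8, "CCACC", None),       # covers site 10 with A -> R
                ("c_allele", 8, "CCGCC", None),       # covers site 10 with G -> C
                ("no_snp", 0, "CCCCC", None),         # overlaps no site -> ambiguous
                ("tie", 8, "CCACCCCCCCCCCC", None),   # A at 10 (R) but C at 20 (C)
                ("unknown_base", 8, "CCNCC", None),   # N at the site -> no vote
            ],
        )
        table = bin_reads(sam, self.SNPS, "s1")
        row = table.set_index("pair_id").loc["p1"]
        assert (row["r_count"], row["c_count"], row["ambiguous"]) == (1, 1, 3)
        assert row[["r_count", "c_count", "ambiguous"]].sum() == 5

    def test_deletion_over_site_is_ambiguous(self, tmp_path):
        sam = tmp_path / "t.sam"
        # read spans site 10 but deletes it: 4M3D4M starting at 8
        _make_sam(sam, [("del", 8, "CCCCCCCC", [(0, 2), (2, 3), (0, 6)])])
        table = bin_reads(sam, self.SNPS, "s1")
        assert table.set_index("pair_id").loc["p1", "ambiguous"] == 1

    def test_unknown_reference_counted_unpaired(self, tmp_path):
        sam = tmp_path / "t.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "px", "LN": 60}]}
        with pysam.AlignmentFile(str(sam), "wh", header=header) as fh:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = "r1"
            a.query_sequence = "CCCCC"
            a.reference_id = 0
            a.reference_start = 0
            a.mapping_quality = 60
            a.cigartuples = [(0, 5)]
            fh.write(a)
        table = bin_reads(sam, self.SNPS, "s1")
        assert table.set_index("pair_id").loc["__unpaired__", "ambiguous"] == 1

    def test_per_read_assignments_match_true_origin(self, tmp_path):
        """Zero-error synthetic reads: every assigned read matches its origin."""
        from hebkit.synthetic_data import (
            SimDesign, generate_counts, generate_genomes, generate_reads,
        )

        design = SimDesign(n_genes=40, depth=2e4, seed=17)
        genomes = generate_genomes(design)
        bundle = generate_counts(design, genomes)
        paths = generate_reads(design, genomes, bundle, tmp_path, samples=["F1_1"])
        _, assigned = bin_reads(
            paths["F1_1"]["sam"], genomes.snps, "F1_1", return_assignments=True
        )
        informative = assigned[assigned["bin"] != "ambiguous"]
        origins = informative["read"].str.rsplit(":", n=1).str[-1]
        assert len(informative) > 0
        assert (informative["bin"] == origins).all()


class TestExpressionStatus:
    PARENTAL = pd.DataFrame({"R": [50.0, 30.0, 2.0], "C": [40.0, 30.0, 3.0]},
                            index=["p1", "p2", "p3"])

    def _hybrid(self, rows):
        return pd.DataFrame(
            rows, columns=["pair_id", "r_per_million", "c_per_million"]
        )

    def test_r_silencing(self):
        out = call_expression_status(
            self._hybrid([("p1", 2.0, 50.0)]), self.PARENTAL
        )
        assert bool(out.iloc[0]["r_silencing"]) is True
        assert bool(out.iloc[0]["novel_expression"]) is False

    def test_no_flags_when_both_expressed(self):
        out = call_expression_status(
            self._hybrid([("p1", 20.0, 50.0)]), self.PARENTAL
        )
        assert not out.iloc[0][["r_silencing", "c_silencing", "novel_expression"]].any()

    def test_novel_expression_when_parents_silent(self):
        out = call_expression_status(
            self._hybrid([("p3", 25.0, 15.0)]), self.PARENTAL
        )
        assert bool(out.iloc[0]["novel_expression"]) is True
        assert not out.iloc[0][["r_silencing", "c_silencing"]].any()

    def test_flags_mutually_exclusive(self, small_sim):
        design, _, bundle, homoeolog = small_sim
        cm = bundle.count_matrix
        parental = pd.DataFrame(
            {
                "R": cm.pooled_counts("R") * 1e6 / cm.pooled_library_size("R"),
                "C": cm.pooled_counts("C") * 1e6 / cm.pooled_library_size("C"),
            }
        )
        f1 = homoeolog[homoeolog["sample"].str.startswith("F1")]
        lib = cm.library_sizes[[s for s in cm.samples if s.startswith("F1")]].sum()
        agg = f1.groupby("pair_id")[["r_count", "c_count"]].sum().reset_index()
        agg["r_per_million"] = 1e6 * agg["r_count"] / lib
        agg["c_per_million"] = 1e6 * agg["c_count"] / lib
        out = call_expression_status(agg, parental)
        both = out["novel_expression"] & (out["r_silencing"] | out["c_silencing"])
        assert not both.any()


class TestHebStates:
    def test_transition_grid_partition(self):
        tally = {"parental-condition": 0, "no-bias-in-progeny": 0,
                 "novel-bias-in-progeny": 0}
        for pa, pr in itertools.product(("R>C", "R=C", "R<C"), repeat=2):
            tally[heb_transition(pa, pr)] += 1
        assert tally == {
            "parental-condition": 3,
            "no-bias-in-progeny": 2,
            "novel-bias-in-progeny": 4,
        }

    @pytest.mark.parametrize(
        "parental_call,r,c,expected",
        [
            ("up", 400, 100, "parental-condition"),
            ("up", 250, 250, "no-bias-in-progeny"),
            ("up", 100, 400, "novel-bias-in-progeny"),
        ],
    )
    def test_table_rows(self, parental_call, r, c, expected):
        rec = classify_heb(parental_call, r, c, lib_assigned=100000)
        assert rec["transition"] == expected

    def test_equal_bins_are_potential_c(self):
        rec = classify_heb("ns", 100, 100, lib_assigned=100000)
        assert rec["potential_bias"] == "C"  # ratio exactly 1 is not > 1
        assert rec["overall_bias"] == "none"

    def test_zero_bins_flagged_no_data(self):
        rec = classify_heb("ns", 0, 0)
        assert rec["progeny_state"] == "R=C" and rec["no_data"]

    def test_overall_bias_requires_significance(self):
        rec = classify_heb("ns", 6, 4, lib_assigned=100000)
        assert rec["overall_bias"] == "none"
        assert rec["potential_bias"] == "R"
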