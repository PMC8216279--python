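"""Stockholm I/O, conservation, covariation and junction/helix analytics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import entropy

from permuzyme.alignment import (
    Alignment,
    AlignmentError,
    conservation_profile,
    covariation_mip,
    covariation_significance,
    helix_extension_analysis,
    junction_length_distribution,
    mutual_information,
    pair_joint_counts,
    perfectly_conserved_positions,
    read_stockholm,
    unique_sequences,
    write_stockholm,
)
from permuzyme.simulate import simulate_alignment


def _toy(rows, structure=None, ids=None):
    structure = structure or "." * len(rows[0])
    ids = ids or [f"r{i}" for i in range(len(rows))]
    return Alignment(ids=ids, rows=rows, structure=structure)


class TestStockholmIO:
    def test_round_trip(self, tmp_path):
        aln = _toy(["ACGU-", "AC-UU", "ACGUA"], structure="<<.>>")
        p = tmp_path / "toy.sto"
        write_stockholm(aln, p)
        back = read_stockholm(p)
        assert back.ids == aln.ids
        assert back.rows == aln.rows
        assert back.structure == aln.structure

    def test_interleaved_blocks(self, tmp_path):
        p = tmp_path / "multi.sto"
        p.write_text(
            "# STOCKHOLM 1.0\n"
            "s1 ACG\ns2 ACG\n#=GC SS_cons <.>\n\n"
            "s1 UAC\ns2 UAC\n#=GC SS_cons ...\n//\n"
        )
        aln = read_stockholm(p)
        assert aln.rows == ["ACGUAC", "ACGUAC"]
        assert aln.structure == "<.>..."

    def test_length_mismatch_fails(self, tmp_path):
        p = tmp_path / "bad.sto"
        p.write_text("# STOCKHOLM 1.0\ns1 ACGU\ns2 ACG\n#=GC SS_cons ....\n//\n")
        with pytest.raises((AlignmentError, ValueError)):
            read_stockholm(p)

    def test_missing_ss_cons_fails(self, tmp_path):
        p = tmp_path / "noss.sto"
        p.write_text("# STOCKHOLM 1.0\ns1 ACGU\ns2 ACGU\n//\n")
        with pytest.raises(AlignmentError, match="SS_cons"):
            read_stockholm(p)

    def test_unbalanced_structure_fails(self):
        with pytest.raises(AlignmentError, match="unbalanced"):
            _toy(["ACGU", "ACGU"], structure="<<.>")


class TestUniqueSequences:
    def test_duplicate_rows_collapse(self):
        aln = _toy(["AC-GU", "ACG-U", "ACGUU"])
        n, dedup = unique_sequences(aln)  # first two rows identical ungapped
        assert n == 2
        assert dedup.ids == ["r0", "r2"]

    def test_idempotent(self):
        aln = _toy(["ACGU", "ACGU", "AGGU"])
        n1, d1 = unique_sequences(aln)
        n2, d2 = unique_sequences(d1)
        assert n1 == n2 == 2
        assert d1.rows == d2.rows


class TestConservation:
    def test_two_row_toy_counts(self):
        aln = _toy(["AG", "AU"])
        prof = conservation_profile(aln, {"pos1": 0, "pos2": 1})
        assert prof.counts["pos1"] == {"A": 2, "C": 0, "G": 0, "U": 0, "gap": 0}
        assert prof.counts["pos2"] == {"A": 0, "C": 0, "G": 1, "U": 1, "gap": 0}

    def test_counts_conserve_row_totals(self):
        aln = _toy(["A-GU", "ACG-", "NCGU"])
        prof = conservation_profile(aln, {f"c{i}": i for i in range(4)})
        for pos, tally in prof.counts.items():
            assert sum(tally.values()) == aln.n_rows

    def test_unmapped_column_fails(self):
        aln = _toy(["ACGU", "ACGU"])
        with pytest.raises(AlignmentError):
            conservation_profile(aln, {"x": 9})

    def test_perfectly_conserved_brute_force_agreement(self, rng):
        rows = ["".join(rng.choice(list("ACGU-"), size=12)) for _ in range(20)]
        rows.append("A" * 12)
        aln = _toy(rows)
        colmap = {f"c{i}": i for i in range(12)}
        prof = conservation_profile(aln, colmap)
        got = set(perfectly_conserved_positions(prof))
        expect = set()
        for name, col in colmap.items():
            column = [r[col] for r in aln.rows]
            if len(set(column)) == 1 and column[0] in "ACGU":
                expect.add(name)
        assert got == expect

    def test_identical_rows_all_conserved(self):
        aln = _toy(["ACGU"] * 5)
        prof = conservation_profile(aln, {f"c{i}": i for i in range(4)})
        assert len(perfectly_conserved_positions(prof)) == 4

    def test_conserved_positions_have_no_gaps(self):
        aln = _toy(["ACGU", "-CGU", "ACGU"])
        prof = conservation_profile(aln, {f"c{i}": i for i in range(4)})
        assert "c0" not in perfectly_conserved_positions(prof)


class TestMutualInformation:
    def test_uniform_wc_coupling_is_two_bits(self):
        counts = np.zeros((4, 4))
        for a, b in ((0, 3), (3, 0), (1, 2), (2, 1)):  # AU/UA/CG/GC
            counts[a, b] = 10
        assert mutual_information(counts) == pytest.approx(2.0)

    def test_independent_constant_columns_zero(self):
        counts = np.zeros((4, 4))
        counts[0, 2] = 50
        assert mutual_information(counts) == pytest.approx(0.0)

    def test_relabeling_invariance(self, rng):
        counts = rng.integers(0, 6, size=(4, 4)).astype(float)
        counts[0, 0] += 1
        perm = rng.permutation(4)
        relabeled = counts[perm][:, perm]
        assert mutual_information(counts) == pytest.approx(
            mutual_information(relabeled)
        )

    @settings(max_examples=150, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=5), min_size=16,
                    max_size=16))
    def test_small_table_entropy_oracle(self, flat):
        """MI equals H(X) + H(Y) - H(X,Y) computed with scipy.stats.entropy
        on every hypothesis-generated small table."""
        counts = np.array(flat, dtype=float).reshape(4, 4)
        if counts.sum() < 2:
            return
        p = counts / counts.sum()
        expect = (
            entropy(p.sum(axis=1), base=2)
            + entropy(p.sum(axis=0), base=2)
            - entropy(p.ravel(), base=2)
        )
        assert mutual_information(counts) == pytest.approx(max(expect, 0.0),
                                                           abs=1e-9)

    def test_joint_counts_respect_gaps(self):
        aln = _toy(["AU", "A-", "GC", "GC"])
        counts = pair_joint_counts(aln, (0, 1))
        assert counts.sum() == 3  # the gapped row drops out
        with pytest.raises(AlignmentError):
            pair_joint_counts(_toy(["-U", "-C"]), (0, 1))


class TestCovariationSignificance:
    def test_planted_pairs_flagged_controls_not(self):
        aln, pairs = simulate_alignment(200, 0.3, 0.05, seed=7)
        loop_cols = [c for c in range(aln.n_cols)
                     if aln.structure[c] == "."][:4]
        fake = [(loop_cols[0], loop_cols[2]), (loop_cols[1], loop_cols[3])]
        stats = covariation_significance(aln, pairs=pairs + fake,
                                         n_shuffles=300, seed=3)
        by_pair = {s.columns: s for s in stats}
        for pr in pairs:
            assert by_pair[tuple(sorted(pr))].significant, pr
        for pr in fake:
            assert not by_pair[tuple(sorted(pr))].significant, pr

    def test_reproducible_under_seed(self):
        aln, pairs = simulate_alignment(60, 0.3, 0.05, seed=1)
        a = covariation_significance(aln, pairs=pairs, n_shuffles=150, seed=5)
        b = covariation_significance(aln, pairs=pairs, n_shuffles=150, seed=5)
        assert [s.p_value for s in a] == [s.p_value for s in b]

    def test_pvalues_in_unit_interval_and_qvalues_ordered(self):
        aln, pairs = simulate_alignment(50, 0.2, 0.1, seed=2)
        stats = covariation_significance(aln, pairs=pairs, n_shuffles=120, seed=4)
        for s in stats:
            assert 0.0 <= s.p_value <= 1.0
            assert 0.0 <= s.q_value <= 1.0
            assert s.q_value >= s.p_value - 1e-12

    def test_too_few_shuffles_rejected(self):
        aln, pairs = simulate_alignment(20, 0.3, 0.05, seed=1)
        with pytest.raises(AlignmentError):
            covariation_significance(aln, pairs=pairs, n_shuffles=10, seed=0)


class TestJunctionAnalytics:
    # layout: h2 = cols (0,1) x (8,9); junction cols 2..3; h3 = (4,5) x (6,7)
    H2 = [(0, 9), (1, 8)]
    H3 = [(4, 7), (5, 6)]

    def test_junction_lengths_counted(self):
        #       h2 jj h3 h3 h2
        rows = ["GC--AUAUGC",   # junction 0
                "GCA-AUAUGC",   # junction 1
                "GCAGAUAUGC"]   # junction 2
        aln = _toy(rows)
        hist, lengths = junction_length_distribution(
            aln, [c for pr in self.H2 for c in pr],
            [c for pr in self.H3 for c in pr])
        assert lengths == [0, 1, 2]
        assert sum(hist.values()) == aln.n_rows

    def test_overlapping_helix_sets_rejected(self):
        aln = _toy(["ACGUACGUAC"])
        with pytest.raises(AlignmentError):
            junction_length_distribution(aln, [0, 1], [1, 2])

    def test_mismatch_and_indel_rows_excluded(self):
        rows = ["GC--AUAUGC",   # clean
                "GA--AUAUGC",   # G-A mismatch closes h2 col1/col8? (A vs U ok) ->
                "GC--A-AUGC"]   # indel in h3
        # row1: h2 pairs (0,9)=G/C ok, (1,8)=A/G not a pair -> excluded
        aln = _toy(rows)
        rep = helix_extension_analysis(aln, self.H2, self.H3)
        assert [r.excluded for r in rep.rows] == [False, True, True]
        assert "mismatch" in rep.rows[1].exclusion_reason
        assert "indel" in rep.rows[2].exclusion_reason

    def test_junction_nt_extends_helix(self):
        # layout: cols 0,1 h2a; 2 junction strand a; 3,4 h3a; 5,6 h3b;
        # 7 junction strand b; 8,9 h2b
        h2 = [(0, 9), (1, 8)]
        h3 = [(3, 6), (4, 5)]
        rows = ["GCGAUAUCGC",  # junction G (col2) / C (col7): pairable -> extend
                "GCAAUAUGGC"]  # junction A (col2) / G (col7): unpairable
        aln = _toy(rows)
        rep = helix_extension_analysis(aln, h2, h3)
        r0, r1 = rep.rows
        assert not r0.excluded and not r1.excluded
        assert r0.helix2_len == 3  # 2 predicted + 1 junction extension
        assert r0.helix3_len == 2
        assert r0.junction_len == 0
        assert r1.helix2_len == 2 and r1.helix3_len == 2
        assert r1.junction_len == 2  # one leftover nucleotide per strand

    def test_ambiguous_extension_records_alternates(self):
        h2 = [(0, 9), (1, 8)]
        h3 = [(3, 6), (4, 5)]
        # a single junction pair G (col2) / C (col7) stacks equally well on
        # helix 2 or helix 3: both alternatives recorded, helix 2 primary
        rows = ["GCGAUAUCGC"]
        aln = _toy(rows)
        rep = helix_extension_analysis(aln, h2, h3)
        r = rep.rows[0]
        assert r.alternates
        assert r.helix2_len == 3

    def test_histogram_bins_sum_to_rows(self, rng):
        rows = []
        for _ in range(15):
            j = rng.integers(0, 3)
            junk = "".join(rng.choice(list("ACGU"), size=j)) + "-" * (2 - j)
            rows.append("GC" + junk + "AUAUGC")
        aln = _toy(rows)
        hist, lengths = junction_length_distribution(
            aln, [0, 1, 8, 9], [4, 5, 6, 7])
        assert sum(hist.values()) == 15
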