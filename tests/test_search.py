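"""Scanner correctness: oracle equivalence, strand/rotation symmetry, mapping."""

import numpy as np
import pytest

from permuzyme.motif import (
    CleavageSite,
    HelixClose,
    HelixOpen,
    MotifDescriptor,
    SingleStrand,
)
from permuzyme.search import (
    SearchError,
    collapse_by_cleavage,
    dedupe_matches,
    iupac_compatible,
    map_to_standard_positions,
    pairs_allowed,
    revcomp,
    scan_sequence,
)
from permuzyme.simulate import realize_descriptor

from .oracles import brute_force_matches, match_key


class TestPrimitives:
    @pytest.mark.parametrize(
        "pattern,base,expected",
        [
            ("R", "A", True), ("R", "G", True), ("R", "C", False),
            ("N", "G", True), ("Y", "U", True), ("Y", "A", False),
            ("A", "T", False), ("U", "T", True), ("N", "N", True),
            ("A", "N", False),
        ],
    )
    def test_iupac_compatible(self, pattern, base, expected):
        assert iupac_compatible(pattern, base) is expected

    def test_iupac_invalid_characters_fail_loudly(self):
        with pytest.raises(SearchError):
            iupac_compatible("X", "A")
        with pytest.raises(SearchError):
            iupac_compatible("N", "Z")

    @pytest.mark.parametrize(
        "a,b,gu,expected",
        [
            ("G", "C", False, True), ("C", "G", False, True),
            ("A", "U", False, True), ("U", "A", True, True),
            ("G", "U", True, True), ("G", "U", False, False),
            ("U", "G", True, True), ("A", "C", True, False),
            ("A", "A", True, False), ("N", "A", True, False),
        ],
    )
    def test_pairs_allowed(self, a, b, gu, expected):
        assert pairs_allowed(a, b, allow_gu=gu) is expected


def _tiny_descriptor():
    """Small two-helix descriptor for exhaustive oracle comparison."""
    return MotifDescriptor(
        elements=(
            HelixOpen("p", 3, 5),
            SingleStrand("AG", 2, 2, ("-1", "+1")),  # placeholder labels
            CleavageSite(),
            SingleStrand("GAAC", 4, 4),
            HelixOpen("q", 3, 4),
            SingleStrand("N", 3, 5),
            HelixClose("q"),
            SingleStrand("RYN", 3, 3),
            HelixClose("p"),
        ),
        permutation="tiny",
    )


class TestOracleEquivalence:
    def test_tiny_descriptor_random_suite(self, rng):
        """Exhaustive brute force equals the anchored matcher on short
        random sequences with planted instances."""
        desc = _tiny_descriptor()
        for trial in range(12):
            seq = "".join(rng.choice(list("ACGU"), size=120))
            if trial % 2 == 0:  # plant an instance so matches exist
                real = realize_descriptor(desc, rng, gu_prob=0.0)
                at = int(rng.integers(0, 120 - len(real.seq)))
                seq = seq[:at] + real.seq + seq[at + len(real.seq):]
            got = {match_key(m) for m in scan_sequence(desc, seq)}
            expect = brute_force_matches(desc, seq)
            assert got == expect

    def test_narrowed_hairpin_descriptor_suite(self, model, rng):
        """Brute force equals the matcher for a narrowed four-helix hairpin
        descriptor (full element mix, tractable enumeration) on
        realization-plus-flank sequences (seeded)."""
        from permuzyme.motif import (
            HairpinCoreModel,
            HelixSpec,
            PermutationSpec,
            descriptor_from_permutation,
        )

        narrow = HairpinCoreModel(
            helices=(
                HelixSpec("h1", 3, 4),
                HelixSpec("h2", 3, 4),
                HelixSpec("h3", 4, 5),
                HelixSpec("h4", 3, 4),
            ),
            loop_a=model.loop_a,
            loop_b=model.loop_b,
            junction_min=0,
            junction_max=1,
            terminal_loop_min=3,
            terminal_loop_max=4,
            invariant_positions=model.invariant_positions,
        )
        for arrangement in ("A_nests_B", "B_then_A"):
            desc = descriptor_from_permutation(
                narrow, PermutationSpec(arrangement, False, True)
            )
            real = realize_descriptor(desc, rng, gu_prob=0.1)
            flank = "".join(rng.choice(list("ACGU"), size=12))
            seq = flank + real.seq + flank
            got = {match_key(m) for m in scan_sequence(desc, seq)}
            expect = brute_force_matches(desc, seq)
            assert got, "planted instance must be found"
            assert got == expect


class TestLongRandomSequence:
    def test_10kb_random_clean_and_planted_recovered(self, default_descriptor):
        """A 10 kb uniform-random sequence yields no matches with the default
        stringent descriptor; planting one instance yields exactly one locus."""
        rng = np.random.default_rng(1001)
        seq = "".join(rng.choice(list("ACGU"), size=10_000))
        assert scan_sequence(default_descriptor, seq) == []
        real = realize_descriptor(default_descriptor, rng, gu_prob=0.0)
        planted = seq[:4000] + real.seq + seq[4000 + len(real.seq):]
        hits = collapse_by_cleavage(scan_sequence(default_descriptor, planted))
        assert len(hits) == 1
        assert hits[0].strand == "+"
        assert hits[0].cleavage_pos == 4000 + real.cleavage_offset


class TestPlantedInstances:
    def test_exact_recovery_all_permutations(self, descriptors, rng):
        for label, desc in descriptors.items():
            real = realize_descriptor(desc, rng)
            ms = collapse_by_cleavage(scan_sequence(desc, real.seq, strands=("+",)))
            assert len(ms) == 1, label
            m = ms[0]
            assert (m.start, m.end) == (0, len(real.seq))
            assert m.cleavage_offset == real.cleavage_offset

    def test_strand_symmetry(self, default_descriptor, rng):
        real = realize_descriptor(default_descriptor, rng)
        fwd = collapse_by_cleavage(scan_sequence(default_descriptor, real.seq))
        rc = collapse_by_cleavage(scan_sequence(default_descriptor, revcomp(real.seq)))
        assert [m.strand for m in fwd] == ["+"]
        assert [m.strand for m in rc] == ["-"]
        assert (rc[0].start, rc[0].end) == (fwd[0].start, fwd[0].end)
        assert (
            map_to_standard_positions(fwd[0]).nucleotides
            == map_to_standard_positions(rc[0]).nucleotides
        )

    def test_empty_and_too_short_sequences(self, default_descriptor):
        assert scan_sequence(default_descriptor, "") == []
        assert scan_sequence(default_descriptor, "ACGUACGU") == []

    def test_monotonicity_loosening_never_removes_matches(self, model, rng):
        """Widening a length range preserves every existing match."""
        from permuzyme.motif import descriptor_from_permutation, HairpinCoreModel, HelixSpec
        from permuzyme.motif import PermutationSpec

        perm = PermutationSpec("A_nests_B", False, False)
        tight = descriptor_from_permutation(model, perm)
        loose_model = HairpinCoreModel(
            helices=(
                HelixSpec("h1", 3, 16),
                HelixSpec("h2", 2, 7),
                HelixSpec("h3", 3, 8),
                HelixSpec("h4", 3, 16),
            ),
            loop_a=model.loop_a,
            loop_b=model.loop_b,
            junction_min=0,
            junction_max=4,
            invariant_positions=model.invariant_positions,
        )
        loose = descriptor_from_permutation(loose_model, perm)
        real = realize_descriptor(tight, rng)
        flank = "".join(rng.choice(list("ACGU"), size=10))
        seq = flank + real.seq + flank
        tight_keys = {match_key(m) for m in scan_sequence(tight, seq)}
        loose_keys = {match_key(m) for m in scan_sequence(loose, seq)}
        assert tight_keys <= loose_keys

    def test_n_policy_blocks_informative_positions(self, default_descriptor, rng):
        real = realize_descriptor(default_descriptor, rng, gu_prob=0.0)
        # overwrite the invariant +1 G with N: no match survives
        ms = scan_sequence(default_descriptor, real.seq, strands=("+",))
        full = [m for m in ms if m.start == 0 and m.end == len(real.seq)]
        assert full
        off = next(
            sp.offset for sp in full[0].spans
            if sp.kind == "ss"
            and full[0].descriptor.elements[sp.index].labels
            and full[0].descriptor.elements[sp.index].labels[0] == "+1"
        )
        broken = real.seq[:off] + "N" + real.seq[off + 1:]
        assert scan_sequence(default_descriptor, broken, strands=("+",)) == []


class TestCircularScanning:
    def test_rotation_invariance(self, default_descriptor, rng):
        from permuzyme.simulate import generate_circle

        circle, _ = generate_circle(500, [(default_descriptor, "+")], rng)
        base = scan_sequence(default_descriptor, circle, circular=True)
        base_nts = sorted(
            tuple(sorted(map_to_standard_positions(m).nucleotides.items()))
            for m in collapse_by_cleavage(base)
        )
        for origin in (1, 137, 499):
            rot = circle[origin:] + circle[:origin]
            ms = scan_sequence(default_descriptor, rot, circular=True)
            nts = sorted(
                tuple(sorted(map_to_standard_positions(m).nucleotides.items()))
                for m in collapse_by_cleavage(ms)
            )
            assert nts == base_nts

    def test_wrap_around_match_found(self, default_descriptor, rng):
        from permuzyme.simulate import realize_descriptor as rd

        real = rd(default_descriptor, rng, gu_prob=0.0)
        pad = "".join(rng.choice(list("ACGU"), size=300))
        circle = real.seq + pad
        # rotate so the motif spans the origin
        cut = 30
        rot = circle[cut:] + circle[:cut]
        ms = collapse_by_cleavage(
            scan_sequence(default_descriptor, rot, strands=("+",), circular=True)
        )
        assert any(m.end > len(circle) >= m.start for m in ms)
        linear = scan_sequence(default_descriptor, rot, strands=("+",), circular=False)
        assert not any(m.start == len(circle) - cut for m in linear)


class TestStandardPositionMap:
    def test_planted_positions(self, default_descriptor, rng):
        real = realize_descriptor(default_descriptor, rng)
        m = collapse_by_cleavage(
            scan_sequence(default_descriptor, real.seq, strands=("+",))
        )[0]
        spm = map_to_standard_positions(m)
        assert spm.nucleotides["+1"] == "G"
        assert spm.nucleotides["8"] == "G"
        assert spm.nucleotides["25"] == "C"
        for lab, off in real.label_offsets.items():
            assert spm.positions[lab] == off
        # -1/+1 flank the cleavage position
        assert spm.positions["-1"] == m.cleavage_pos - 1
        assert spm.positions["+1"] == m.cleavage_pos
        # helix-embedded positions adjacent to the loop
        assert spm.positions["-3"] == spm.positions["-2"] - 1
        assert spm.positions["+4"] == spm.positions["+3"] + 1

    def test_every_model_position_mapped(self, descriptors, rng):
        labels = (
            [str(i) for i in range(-5, 0)]
            + ["+1", "+2", "+3", "+4"]
            + [str(i) for i in range(7, 12)]
            + [str(i) for i in range(20, 27)]
            + [str(i) for i in range(36, 45)]
        )
        for label, desc in descriptors.items():
            real = realize_descriptor(desc, rng)
            m = collapse_by_cleavage(scan_sequence(desc, real.seq, strands=("+",)))[0]
            spm = map_to_standard_positions(m)
            for lab in labels:
                assert lab in spm.positions, (label, lab)
            assert set(spm.helix_pairs) == {"h1", "h2", "h3", "h4"}

    def test_spans_tile_match(self, default_descriptor, rng):
        real = realize_descriptor(default_descriptor, rng)
        for m in scan_sequence(default_descriptor, real.seq):
            offsets = sorted((sp.offset, sp.length) for sp in m.spans)
            pos = 0
            for off, ln in offsets:
                assert off == pos
                pos += ln
            assert pos == m.length


class TestDeduplication:
    def test_dedupe_is_deterministic_and_maximal(self, default_descriptor, rng):
        real = realize_descriptor(default_descriptor, rng, gu_prob=0.0)
        ms = scan_sequence(default_descriptor, real.seq, strands=("+",))
        d1 = dedupe_matches(ms)
        d2 = dedupe_matches(list(reversed(ms)))
        assert [match_key(m) for m in d1] == [match_key(m) for m in d2]
        best = collapse_by_cleavage(ms)[0]
        helix_total = sum(sp.length for sp in best.spans if sp.kind == "helix5")
        for m in ms:
            assert helix_total >= sum(
                sp.length for sp in m.spans if sp.kind == "helix5"
            )
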