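"""Ground-truth synthetic data for every pipeline stage.

Emulates the study conditions end to end: circular ssRNA molecules of
381-5170 nt carrying a planted permuted hairpin core sampled from the
consensus model, optional second ribozyme on the opposite strand,
assembler-style linearization with an exact terminal repeat (123 nt by
default, detectable down to 75 nt), i.i.d. substitution errors, non-ribozyme
decoy contigs, and simulated structural alignments with planted compensatory
base pairs.

Two *synthetic stand-ins* for reference objects that cannot be shipped are
also provided: :func:`synthetic_reference_alignment` (a designed 941-row
alignment embodying the published conservation statistics of the real
941-sequence alignment) and :func:`synthetic_hpr1_construct` (an 87-nt
self-cleaving transcript whose cleavage site lies 12 nt from the 5' end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alignment import Alignment
from .circular import Contig
from .motif import (
    IUPAC,
    CleavageSite,
    HairpinCoreModel,
    HelixClose,
    HelixOpen,
    MotifDescriptor,
    PermutationSpec,
    SingleStrand,
    build_default_hairpin_core,
    descriptor_from_permutation,
)
from .search import revcomp

_NTS = "ACGU"
_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WC_PAIRS = (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"))


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# motif realization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreRealization:
    seq: str
    cleavage_offset: int                  # inter-nucleotide, from realization start
    element_spans: Tuple[Tuple[int, int, int], ...]  # (element index, offset, length)
    descriptor: MotifDescriptor
    label_offsets: Dict[str, int]         # standard position -> offset in seq


def realize_descriptor(
    descriptor: MotifDescriptor,
    rng: np.random.Generator,
    lengths: Optional[Dict[int, int]] = None,
    gu_prob: float = 0.1,
    helix_cap: int = 8,
) -> CoreRealization:
    """Draw one concrete sequence satisfying ``descriptor``.

    Helices are sampled exactly complementary (G-U wobble with probability
    ``gu_prob`` per pair); degenerate pattern positions are drawn uniformly
    from their IUPAC expansion.  ``lengths`` pins chosen element lengths by
    element index (helix open and variable single-strand elements).
    """
    lengths = lengths or {}
    parts: List[str] = []
    spans: List[Tuple[int, int, int]] = []
    labels: Dict[str, int] = {}
    open_seqs: Dict[str, str] = {}
    cleave = None
    pos = 0
    for idx, el in enumerate(descriptor.elements):
        if isinstance(el, HelixOpen):
            cap = max(el.min_len, min(el.max_len, helix_cap))
            k = lengths.get(idx, int(rng.integers(el.min_len, cap + 1)))
            if not (el.min_len <= k <= el.max_len):
                raise SimulationError(f"pinned length {k} outside helix range")
            s = "".join(rng.choice(list(_NTS)) for _ in range(k))
            open_seqs[el.label] = s
            parts.append(s)
            spans.append((idx, pos, k))
            pos += k
        elif isinstance(el, HelixClose):
            s = open_seqs[el.label]
            comp = []
            for ch in s:
                if ch == "G" and rng.random() < gu_prob:
                    comp.append("U")
                elif ch == "U" and rng.random() < gu_prob:
                    comp.append("G")
                else:
                    comp.append(_WC_PARTNER[ch])
            closing = "".join(reversed(comp))
            parts.append(closing)
            spans.append((idx, pos, len(closing)))
            pos += len(closing)
        elif isinstance(el, CleavageSite):
            cleave = pos
            spans.append((idx, pos, 0))
        elif isinstance(el, SingleStrand):
            if el.fixed:
                s = "".join(
                    str(rng.choice(sorted(IUPAC[c]))) for c in el.pattern
                )
                if el.labels:
                    for j, lab in enumerate(el.labels):
                        labels[lab] = pos + j
            else:
                k = lengths.get(idx, int(rng.integers(el.min_len, el.max_len + 1)))
                if not (el.min_len <= k <= el.max_len):
                    raise SimulationError("pinned length outside ss range")
                choices = sorted(IUPAC[el.pattern])
                s = "".join(str(rng.choice(choices)) for _ in range(k))
            parts.append(s)
            spans.append((idx, pos, len(s)))
            pos += len(s)
        else:  # pragma: no cover
            raise SimulationError(f"unknown element {el!r}")
    if cleave is None:
        raise SimulationError("descriptor has no cleavage site")
    return CoreRealization(
        seq="".join(parts),
        cleavage_offset=cleave,
        element_spans=tuple(spans),
        descriptor=descriptor,
        label_offsets=labels,
    )


def sample_core_sequence(
    model: HairpinCoreModel,
    perm: PermutationSpec,
    seed: int,
    gu_prob: float = 0.1,
) -> CoreRealization:
    """Realized motif sequence for one permutation of the core model."""
    rng = np.random.default_rng(seed)
    desc = descriptor_from_permutation(model, perm)
    return realize_descriptor(desc, rng, gu_prob=gu_prob)


# ---------------------------------------------------------------------------
# circles, linearization, datasets
# ---------------------------------------------------------------------------

@dataclass
class PlantTruth:
    start: int
    end: int
    strand: str
    permutation: str
    ribozyme_class: str
    cleavage_pos: int


@dataclass
class TruthRecord:
    molecule_id: str
    circle_len: int
    plants: List[PlantTruth] = field(default_factory=list)
    origin: Optional[int] = None
    repeat_len: Optional[int] = None
    error_positions: Tuple[int, ...] = ()


@dataclass
class SyntheticDatasetConfig:
    n_molecules: int
    seed: int
    circle_len_range: Tuple[int, int] = (381, 5170)
    end_repeat_len: int = 123
    min_detect_repeat: int = 75
    error_rate: float = 0.0
    decoy_fraction: float = 0.0
    planted_permutations: Optional[Sequence[str]] = None
    opposite_strand: Optional[str] = None  # None | "hairpin" | "hammerhead" | "twister"
    gu_prob: float = 0.1

    def __post_init__(self):
        lo, hi = self.circle_len_range
        if lo <= 0 or hi < lo:
            raise SimulationError("circle length range must be positive and ordered")
        if not (0.0 <= self.error_rate <= 0.2):
            raise SimulationError("error rate must lie in [0, 0.2]")
        if self.seed is None:
            raise SimulationError("seed is mandatory")


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_NTS), size=n, p=p))


def generate_circle(
    length: int,
    plants: Sequence[Tuple[MotifDescriptor, str]],
    rng: np.random.Generator,
    molecule_id: str = "mol",
    gu_prob: float = 0.1,
) -> Tuple[str, TruthRecord]:
    """Uniform-random circle with the given motifs spliced in.

    ``plants`` is a sequence of (descriptor, strand); each realization
    replaces a background segment of equal length at a random, non-overlapping
    position.  Fails loudly when the motifs cannot be placed.
    """
    seq = list(_random_seq(rng, length))
    truth = TruthRecord(molecule_id=molecule_id, circle_len=length)
    taken: List[Tuple[int, int]] = []
    for desc, strand in plants:
        real = realize_descriptor(desc, rng, gu_prob=gu_prob)
        m = len(real.seq)
        if m + 50 > length:
            raise SimulationError(
                f"circle length {length} too short for a {m}-nt motif"
            )
        placed = False
        for _ in range(200):
            start = int(rng.integers(0, length - m))
            if any(start < e and start + m > s for s, e in taken):
                continue
            ins = real.seq if strand == "+" else revcomp(real.seq)
            seq[start:start + m] = list(ins)
            taken.append((start, start + m))
            cleav = (
                start + real.cleavage_offset
                if strand == "+"
                else start + m - real.cleavage_offset
            )
            rz_class = (
                desc.permutation
                if desc.permutation.endswith("-like")
                else "hairpin"
            )
            truth.plants.append(
                PlantTruth(
                    start=start,
                    end=start + m,
                    strand=strand,
                    permutation=desc.permutation,
                    ribozyme_class=rz_class,
                    cleavage_pos=cleav,
                )
            )
            placed = True
            break
        if not placed:
            raise SimulationError("could not place motif without overlap")
    return "".join(seq), truth


def linearize(
    circle: str,
    origin: int,
    repeat_len: int,
    error_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[str, Tuple[int, ...]]:
    """Assembler-style linear contig: rotation + exact terminal repeat + errors.

    contig = rotation(circle, origin) + first ``repeat_len`` nt of that
    rotation, then i.i.d. substitutions at ``error_rate``.
    """
    L = len(circle)
    if not (0 <= origin < L):
        raise SimulationError("origin out of range")
    if not (0 <= repeat_len <= L):
        raise SimulationError("repeat length out of range")
    rot = circle[origin:] + circle[:origin]
    contig = rot + rot[:repeat_len]
    errors: List[int] = []
    if error_rate > 0:
        if rng is None:
            raise SimulationError("error simulation needs an rng")
        chars = list(contig)
        hits = np.nonzero(rng.random(len(chars)) < error_rate)[0]
        for i in hits:
            alts = [c for c in _NTS if c != chars[i]]
            chars[i] = str(rng.choice(alts))
            errors.append(int(i))
        contig = "".join(chars)
    return contig, tuple(errors)


def generate_dataset(
    config: SyntheticDatasetConfig,
    model: Optional[HairpinCoreModel] = None,
) -> Tuple[List[Contig], List[str], Dict[str, TruthRecord]]:
    """Full synthetic dataset: contigs, the underlying circles, and truth.

    Positives are circular molecules linearized with the configured exact end
    repeat; decoys are plain linear contigs without motif or repeat.
    """
    model = model or build_default_hairpin_core()
    rng = np.random.default_rng(config.seed)
    perms = list(
        config.planted_permutations
        or [PermutationSpec("A_nests_B", False, False).canonical_label]
    )
    descs = {
        lab: descriptor_from_permutation(model, PermutationSpec.from_label(lab))
        for lab in perms
    }
    n_decoys = int(round(config.n_molecules * config.decoy_fraction))
    n_pos = config.n_molecules - n_decoys

    contigs: List[Contig] = []
    circles: List[str] = []
    truths: Dict[str, TruthRecord] = {}
    lo, hi = config.circle_len_range
    for i in range(n_pos):
        mid = f"mol{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        lab = perms[i % len(perms)]
        plants = [(descs[lab], "+")]
        if config.opposite_strand == "hairpin":
            plants.append((descs[lab], "-"))
        elif config.opposite_strand in ("hammerhead", "twister"):
            from .annotate import default_opposite_descriptors

            plants.append(
                (default_opposite_descriptors()[config.opposite_strand], "-")
            )
        circle, truth = generate_circle(
            length, plants, rng, molecule_id=mid, gu_prob=config.gu_prob
        )
        origin = int(rng.integers(0, length))
        contig, errs = linearize(
            circle, origin, config.end_repeat_len, config.error_rate, rng
        )
        truth.origin = origin
        truth.repeat_len = config.end_repeat_len
        truth.error_positions = errs
        circles.append(circle)
        truths[mid] = truth
        contigs.append(Contig(id=mid, seq=contig))
    for i in range(n_decoys):
        mid = f"decoy{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        contigs.append(Contig(id=mid, seq=_random_seq(rng, length)))
        truths[mid] = TruthRecord(molecule_id=mid, circle_len=0)
    return contigs, circles, truths


# ---------------------------------------------------------------------------
# simulated structural alignments
# ---------------------------------------------------------------------------

def simulate_alignment(
    n_rows: int,
    compensatory_rate: float,
    noise_rate: float,
    seed: int,
    n_pairs: int = 9,
    n_unpaired: int = 12,
) -> Tuple[Alignment, List[Tuple[int, int]]]:
    """Rows evolved from a consensus with planted compensatory base pairs.

    Paired columns jointly mutate to a different Watson-Crick pair at
    ``compensatory_rate``; unpaired columns mutate independently at
    ``noise_rate``.  Returns the alignment (SS_cons marks the planted pairs)
    and the planted pair list.
    """
    if n_rows < 10:
        raise SimulationError("need at least 10 rows")
    rng = np.random.default_rng(seed)
    # layout: u pairs as a single stem with unpaired flanks/loop
    left = list(range(n_pairs))
    loop = list(range(n_pairs, n_pairs + n_unpaired))
    right = list(range(n_pairs + n_unpaired, 2 * n_pairs + n_unpaired))
    n_cols = 2 * n_pairs + n_unpaired
    pairs = [(left[i], right[-1 - i]) for i in range(n_pairs)]

    cons_pairs = [list(_WC_PAIRS[rng.integers(0, 4)]) for _ in range(n_pairs)]
    cons_loop = [str(rng.choice(list(_NTS))) for _ in loop]
    rows = []
    for _ in range(n_rows):
        row = [""] * n_cols
        for k, (i, j) in enumerate(pairs):
            a, b = cons_pairs[k]
            if rng.random() < compensatory_rate:
                alts = [p for p in _WC_PAIRS if p != (a, b)]
                a, b = alts[rng.integers(0, len(alts))]
            row[i], row[j] = a, b
        for c, base in zip(loop, cons_loop):
            if rng.random() < noise_rate:
                base = str(rng.choice([x for x in _NTS if x != base]))
            row[c] = base
        rows.append("".join(row))
    structure = "".join(
        "<" if c in {i for i, _ in pairs}
        else ">" if c in {j for _, j in pairs}
        else "." for c in range(n_cols)
    )
    aln = Alignment(
        ids=[f"row{r}" for r in range(n_rows)], rows=rows, structure=structure
    )
    return aln, pairs


def shuffle_alignment(aln: Alignment, seed: int) -> Alignment:
    """Independent within-column permutation of rows (covariation destroyed)."""
    rng = np.random.default_rng(seed)
    cols = [list(col) for col in zip(*aln.rows)]
    for col in cols:
        rng.shuffle(col)
    rows = ["".join(chars) for chars in zip(*cols)]
    return Alignment(ids=list(aln.ids), rows=rows, structure=aln.structure)


# ---------------------------------------------------------------------------
# synthetic stand-ins for unavailable reference objects
# ---------------------------------------------------------------------------

# fixed column layout of the stand-in alignment (nested arrangement, helix
# lengths h1=4, h2=4, h3=5, h4=4, one-sided 3-column junction)
_REF_COLMAP = {
    "-5": 1, "-4": 2, "-3": 3,
    "-2": 4, "-1": 5, "+1": 6, "+2": 7, "+3": 8, "+4": 9,
    "7": 58, "8": 59, "9": 60, "10": 61, "11": 62,
    "20": 21, "21": 22, "22": 23, "23": 24, "24": 25, "25": 26, "26": 27,
    "36": 40, "37": 41, "38": 42, "39": 43, "40": 44,
    "41": 45, "42": 46, "43": 47, "44": 48,
}
_REF_H2_PAIRS = ((9, 57), (10, 56), (11, 55), (12, 54))
_REF_H3_PAIRS = ((16, 53), (17, 52), (18, 51), (19, 50), (20, 49))
_REF_N_COLS = 67


def _ref_structure() -> str:
    ss = ["."] * _REF_N_COLS
    for a, b in [(c, 66 - c + 0) for c in range(0, 4)]:
        pass
    for i, j in [(0, 66), (1, 65), (2, 64), (3, 63)]:
        ss[i], ss[j] = "(", ")"
    for i, j in _REF_H2_PAIRS:
        ss[i], ss[j] = "<", ">"
    for i, j in _REF_H3_PAIRS:
        ss[i], ss[j] = "[", "]"
    for i, j in [(28, 39), (29, 38), (30, 37), (31, 36)]:
        ss[i], ss[j] = "{", "}"
    return "".join(ss)


def synthetic_reference_alignment(seed: int = 20210607):
    """SYNTHETIC stand-in for the real 941-sequence reference alignment.

    The real supplementary alignment cannot be redistributed here; this
    designed alignment embodies its published marginal statistics so that the
    analytics can be exercised end to end:

    - 941 unique sequences;
    - exactly seven perfectly conserved core positions (+1, 8, 22, 23, 24,
      25, 38);
    - A at position 9 in 940 of 941 rows;
    - exactly 4 rows with a G-G combination at positions 20/44;
    - 364 rows with a mismatch or indel in helix 2 or 3 (excluded from the
      helix-extension analysis);
    - junction-length mode of 0, lengths ranging 0-3;
    - one alternate row at U42 and two at U41.

    Returns (Alignment, meta) where meta holds the standard-position column
    map, helix 2/3 pair columns, and the core-region position list.
    """
    rng = np.random.default_rng(seed)
    n_rows = 941
    rows: List[str] = []
    seen = set()

    def wc(s: str) -> str:
        return "".join(_WC_PARTNER[c] for c in reversed(s))

    def rand(n: int) -> str:
        return "".join(rng.choice(list(_NTS), size=n))

    r = 0
    while r < n_rows:
        h1, h2, h3, h4 = rand(4), rand(4), rand(5), rand(4)
        near_a = f"{rand(1)}{rand(1)}G{rand(1)}{rand(1)}"
        j = int(rng.choice([0, 1, 2, 3], p=[0.85, 0.08, 0.05, 0.02]))
        junction = rand(j) + "-" * (3 - j)
        p20 = "G" if r < 4 else str(rng.choice(["A", "G"]))
        p21 = "A" if 35 <= r <= 40 else "G"
        p26 = rand(1)
        near_b = f"{p20}{p21}AAAC{p26}"
        tloop = rand(4)
        p9 = "G" if r == 500 else "A"
        p10 = "G" if 45 <= r <= 50 else "A"
        p11 = "A" if 55 <= r <= 57 else "G"
        far_a = f"{rng.choice(['A', 'G'])}G{p9}{p10}{p11}"
        p39 = str(rng.choice(["C", "U", "A", "G"], p=[0.5, 0.25, 0.2, 0.05]))
        p41 = {20: "C", 21: "A"}.get(r, "U")
        p42 = "C" if r == 22 else "U"
        p43 = "G" if 30 <= r <= 32 else "A"
        if r < 4:
            p44 = "G"
        elif p20 == "G":
            p44 = str(rng.choice(["A", "C", "U"]))
        else:
            p44 = str(rng.choice(["A", "C", "U"]))
        far_b = f"{rand(1)}{rand(1)}A{p39}{rand(1)}{p41}{p42}{p43}{p44}"

        h3b = wc(h3)
        if 577 <= r <= 800:
            # planted mismatch in helix 3: identical bases never pair
            h3b = h3[-1] + h3b[1:]
        elif r > 800:
            h3b = "-" + h3b[1:]  # planted indel in helix 3
        row = (
            h1 + near_a + h2 + junction + h3 + near_b + h4 + tloop
            + wc(h4) + far_b + h3b + wc(h2) + far_a + wc(h1)
        )
        key = row.replace("-", "")
        if key in seen:
            continue  # redraw this row
        seen.add(key)
        rows.append(row)
        r += 1

    aln = Alignment(
        ids=[f"syn{r:04d}" for r in range(n_rows)],
        rows=rows,
        structure=_ref_structure(),
    )
    # guarantee variation at every non-invariant core position (keeps the
    # perfectly-conserved set at exactly the seven designed positions)
    invariant = {"+1", "8", "22", "23", "24", "25", "38"}
    helix_partner = {i: j for i, j in _REF_H2_PAIRS + _REF_H3_PAIRS}
    helix_partner.update({j: i for i, j in _REF_H2_PAIRS + _REF_H3_PAIRS})
    helix_partner.update({0: 66, 1: 65, 2: 64, 3: 63, 66: 0, 65: 1, 64: 2, 63: 3})
    helix_partner.update({28: 39, 29: 38, 30: 37, 31: 36, 39: 28, 38: 29, 37: 30, 36: 31})
    grid = [list(row) for row in aln.rows]
    for pos, col in _REF_COLMAP.items():
        if pos in invariant:
            continue
        vals = {grid[i][col] for i in range(5, n_rows)} - {"-"}
        if len({grid[i][col] for i in range(n_rows)} - {"-"}) >= 2:
            continue
        cur = grid[5][col]
        alt = "A" if cur != "A" else "C"
        grid[5][col] = alt
        if col in helix_partner:
            grid[5][helix_partner[col]] = _WC_PARTNER.get(alt, "U")
    aln = Alignment(ids=aln.ids, rows=["".join(g) for g in grid],
                    structure=aln.structure)
    meta = {
        "colmap": dict(_REF_COLMAP),
        "helix2_pairs": list(_REF_H2_PAIRS),
        "helix3_pairs": list(_REF_H3_PAIRS),
        "core_region": list(_REF_COLMAP.keys()),
    }
    return aln, meta


def synthetic_hpr1_construct(seed: int = 1) -> Tuple[str, int]:
    """SYNTHETIC stand-in for the HPR 1 in vitro transcription construct.

    An 87-nt transcript carrying the default hairpin core (nested, unflipped
    arrangement) with the cleavage site 12 nt from the 5' end, so that
    self-cleavage yields 12-nt (5') and 75-nt (3') products.  Returns
    (sequence, cleavage offset).
    """
    rng = np.random.default_rng(seed)
    model = build_default_hairpin_core()
    desc = descriptor_from_permutation(
        model, PermutationSpec("A_nests_B", False, False)
    )
    # element indices in the nested unflipped descriptor:
    # 0 h1open, 1 ss(-2,-1), 2 cleave, 3 ss(+1..+3), 4 h2open, 5 junction,
    # 6 h3open, 7 nearB, 8 h4open, 9 tloop, 10 h4close, 11 farB, 12 h3close,
    # 13 junction, 14 h2close, 15 farA, 16 h1close
    lengths = {0: 10, 4: 4, 5: 3, 6: 5, 8: 5, 9: 8, 13: 2}
    real = realize_descriptor(desc, rng, lengths=lengths, gu_prob=0.0)
    if len(real.seq) != 87 or real.cleavage_offset != 12:
        raise SimulationError("construct realization violated its design")
    return real.seq, real.cleavage_offset
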