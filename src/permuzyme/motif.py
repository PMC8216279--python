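"""Hairpin-ribozyme core model and its circular permutations.

The hairpin ribozyme core consists of two internal loops (A and B), each
flanked by two helices (loop A by helices 1 and 2, loop B by helices 3 and
4).  Loop A carries the cleavage site between standard positions -1 and +1;
loop B carries the general acid A38.  Because the natural host molecules are
circular ssRNAs, the core can occur in several circularly permuted linear
arrangements: the two loop units may appear in either order, one may nest
inside the other, and each unit may be "flipped" so that its two unpaired
strands occur in the opposite order.  4 arrangements x 2 flip states per
loop = 16 theoretical permutations, each rendered here as a searchable
descriptor.

Standard hairpin numbering is used throughout: substrate strand -5..+4
(cleavage between -1/+1), loop A far strand 7-11, loop B strands 20-26 and
36-44.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

ARRANGEMENTS = ("A_nests_B", "A_then_B", "B_nests_A", "B_then_A")


class MotifModelError(ValueError):
    """Raised for invalid motif-model construction or descriptor text."""


# ---------------------------------------------------------------------------
# descriptor elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixOpen:
    label: str
    min_len: int
    max_len: int
    mismatches: int = 0

    def __post_init__(self):
        if not (1 <= self.min_len <= self.max_len):
            raise MotifModelError(
                f"helix {self.label}: need 1 <= min <= max, got "
                f"[{self.min_len}, {self.max_len}]"
            )
        if self.mismatches < 0:
            raise MotifModelError(f"helix {self.label}: negative mismatch count")


@dataclass(frozen=True)
class HelixClose:
    label: str


@dataclass(frozen=True)
class SingleStrand:
    """Unpaired element.

    A fixed-length element carries an IUPAC ``pattern`` whose characters may
    be annotated with standard hairpin position labels; a variable-length
    element has a single repeated pattern character with ``min_len`` /
    ``max_len`` bounds.
    """

    pattern: str
    min_len: int
    max_len: int
    labels: Optional[Tuple[str, ...]] = None

    def __post_init__(self):
        if not self.pattern:
            raise MotifModelError("empty single-strand pattern")
        for ch in self.pattern:
            if ch not in IUPAC:
                raise MotifModelError(f"invalid IUPAC code {ch!r} in pattern")
        if self.min_len < 0 or self.min_len > self.max_len:
            raise MotifModelError("bad single-strand length range")
        if self.fixed:
            if self.min_len != len(self.pattern):
                raise MotifModelError("fixed-length pattern length mismatch")
            if self.labels is not None and len(self.labels) != len(self.pattern):
                raise MotifModelError("labels length mismatch")
        elif len(self.pattern) != 1:
            raise MotifModelError("variable-length element needs a 1-char pattern")

    @property
    def fixed(self) -> bool:
        return self.min_len == self.max_len and (
            len(self.pattern) == self.min_len
        )


@dataclass(frozen=True)
class CleavageSite:
    """Inter-nucleotide cleavage marker (zero-width)."""


Element = object  # HelixOpen | HelixClose | SingleStrand | CleavageSite


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixSpec:
    label: str
    min_len: int
    max_len: int
    mismatches: int = 0

    def __post_init__(self):
        if not (1 <= self.min_len <= self.max_len):
            raise MotifModelError(f"helix {self.label}: min <= max and min >= 1 required")

    def open_element(self) -> HelixOpen:
        return HelixOpen(self.label, self.min_len, self.max_len, self.mismatches)


@dataclass(frozen=True)
class LoopUnit:
    """One internal-loop unit with its two unpaired strands.

    ``segment_near`` is the strand closer to the cleavage site (for loop A it
    contains the cleavage marker between -1 and +1; for loop B it is the
    20-26 strand); ``segment_far`` is the opposite strand (7-11 for loop A,
    36-44 for loop B).  ``outer_helix`` / ``inner_helix`` are the flanking
    helix labels in the unflipped orientation.
    """

    identity: str  # "A" or "B"
    segment_near: str
    segment_far: str
    near_labels: Tuple[str, ...]
    far_labels: Tuple[str, ...]
    outer_helix: str
    inner_helix: str
    cleavage_after: Optional[int] = None  # index in segment_near after which cleavage occurs

    def __post_init__(self):
        if self.identity not in ("A", "B"):
            raise MotifModelError("loop identity must be A or B")
        if not self.segment_near or not self.segment_far:
            raise MotifModelError("loop segments must be non-empty")
        for seg in (self.segment_near, self.segment_far):
            for ch in seg:
                if ch not in IUPAC:
                    raise MotifModelError(f"invalid IUPAC code {ch!r} in loop segment")
        if self.identity == "A":
            if self.cleavage_after is None:
                raise MotifModelError("loop A must carry the cleavage-site marker")
            if not (0 < self.cleavage_after < len(self.segment_near)):
                raise MotifModelError("cleavage marker must be internal to segment_near")
            # marker must sit between standard positions -1 and +1
            left = self.near_labels[self.cleavage_after - 1]
            right = self.near_labels[self.cleavage_after]
            if (left, right) != ("-1", "+1"):
                raise MotifModelError(
                    f"cleavage marker must lie between -1 and +1, found {left}/{right}"
                )
        elif self.cleavage_after is not None:
            raise MotifModelError("only loop A carries the cleavage site")

    def near_elements(self) -> Tuple[Element, ...]:
        """Render segment_near as descriptor elements (cleavage marker included)."""
        if self.cleavage_after is None:
            return (
                SingleStrand(
                    self.segment_near,
                    len(self.segment_near),
                    len(self.segment_near),
                    self.near_labels,
                ),
            )
        k = self.cleavage_after
        return (
            SingleStrand(self.segment_near[:k], k, k, self.near_labels[:k]),
            CleavageSite(),
            SingleStrand(
                self.segment_near[k:],
                len(self.segment_near) - k,
                len(self.segment_near) - k,
                self.near_labels[k:],
            ),
        )

    def far_elements(self) -> Tuple[Element, ...]:
        return (
            SingleStrand(
                self.segment_far,
                len(self.segment_far),
                len(self.segment_far),
                self.far_labels,
            ),
        )


@dataclass(frozen=True)
class HairpinCoreModel:
    """Parametric description of the conserved hairpin-ribozyme core."""

    helices: Tuple[HelixSpec, HelixSpec, HelixSpec, HelixSpec]
    loop_a: LoopUnit
    loop_b: LoopUnit
    junction_min: int
    junction_max: int
    terminal_loop_min: int = 3
    terminal_loop_max: int = 8
    invariant_positions: frozenset = frozenset()

    REQUIRED_INVARIANTS = frozenset(
        {("+1", "G"), ("8", "G"), ("25", "C"), ("38", "A"),
         ("22", "A"), ("23", "A"), ("24", "A")}
    )

    def __post_init__(self):
        labels = sorted(h.label for h in self.helices)
        if labels != ["h1", "h2", "h3", "h4"]:
            raise MotifModelError("model needs helices h1..h4 exactly once each")
        if self.junction_min < 0 or self.junction_min > self.junction_max:
            raise MotifModelError("junction min must satisfy 0 <= min <= max")
        if not self.REQUIRED_INVARIANTS <= self.invariant_positions:
            missing = self.REQUIRED_INVARIANTS - self.invariant_positions
            raise MotifModelError(f"missing required invariant positions: {missing}")

    def helix(self, label: str) -> HelixSpec:
        for h in self.helices:
            if h.label == label:
                return h
        raise MotifModelError(f"no helix {label!r}")


@dataclass(frozen=True)
class PermutationSpec:
    """One linear arrangement of the two internal-loop units."""

    arrangement: str
    flip_a: bool
    flip_b: bool

    def __post_init__(self):
        if self.arrangement not in ARRANGEMENTS:
            raise MotifModelError(f"unknown arrangement {self.arrangement!r}")

    @property
    def canonical_label(self) -> str:
        return f"{self.arrangement}/{int(self.flip_a)}/{int(self.flip_b)}"

    @classmethod
    def from_label(cls, label: str) -> "PermutationSpec":
        try:
            arr, fa, fb = label.split("/")
            if fa not in ("0", "1") or fb not in ("0", "1"):
                raise ValueError("flip digits must be 0 or 1")
            return cls(arr, fa == "1", fb == "1")
        except (ValueError, MotifModelError) as exc:
            raise MotifModelError(f"bad permutation label {label!r}") from exc


@dataclass(frozen=True)
class MotifDescriptor:
    """Ordered element list for one permutation, scannable against sequence."""

    elements: Tuple[Element, ...]
    permutation: str  # canonical permutation label (provenance)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        stack = []
        seen_open, seen_close = set(), set()
        n_cleave = 0
        for el in self.elements:
            if isinstance(el, HelixOpen):
                if el.label in seen_open:
                    raise MotifModelError(f"helix {el.label} opened twice")
                seen_open.add(el.label)
                stack.append(el.label)
            elif isinstance(el, HelixClose):
                if not stack or stack[-1] != el.label:
                    raise MotifModelError(
                        f"helix {el.label} closes out of nesting order"
                    )
                stack.pop()
                seen_close.add(el.label)
            elif isinstance(el, CleavageSite):
                n_cleave += 1
        if stack:
            raise MotifModelError(f"unclosed helices: {stack}")
        if seen_open != seen_close:
            raise MotifModelError("helix open/close label mismatch")
        if n_cleave != 1:
            raise MotifModelError(f"descriptor needs exactly 1 cleavage site, got {n_cleave}")

    @property
    def min_length(self) -> int:
        n = 0
        for el in self.elements:
            if isinstance(el, HelixOpen):
                n += 2 * el.min_len
            elif isinstance(el, SingleStrand):
                n += el.min_len
        return n

    def to_dot_bracket(self) -> str:
        """Minimal-length dot-bracket rendering (helices as <>, ss as dots)."""
        out = []
        for el in self.elements:
            if isinstance(el, HelixOpen):
                out.append("<" * el.min_len)
            elif isinstance(el, HelixClose):
                out.append(">" * self._min_of(el.label))
            elif isinstance(el, SingleStrand):
                out.append("." * el.min_len)
        return "".join(out)

    def _min_of(self, label: str) -> int:
        for el in self.elements:
            if isinstance(el, HelixOpen) and el.label == label:
                return el.min_len
        raise MotifModelError(f"no helix {label!r}")


# ---------------------------------------------------------------------------
# default model (reconstructed consensus)
# ---------------------------------------------------------------------------

def build_default_hairpin_core() -> HairpinCoreModel:
    """Default core model.

    Invariant positions: G+1, G8, C25, A38 and A22-A24 (the seven positions
    perfectly conserved across the 941-sequence phylogeny).  Helix 2 and 3
    length ranges are centred on the modal natural lengths (4 and 5 bp);
    helices 1 and 4 vary greatly in nature and get broad ranges.  The
    junction between helices 2 and 3 carries 0-3 unpaired nucleotides.
    Degenerate letters at the variable core positions: R7, R20, Y39, N-1,
    N+2, N26, N36, N40, N44 (and N at -2, +3, 37, where no consensus
    nucleotide is established).
    """
    loop_a = LoopUnit(
        identity="A",
        segment_near="NNGNN",
        near_labels=("-2", "-1", "+1", "+2", "+3"),
        segment_far="RGAAG",
        far_labels=("7", "8", "9", "10", "11"),
        outer_helix="h1",
        inner_helix="h2",
        cleavage_after=2,
    )
    loop_b = LoopUnit(
        identity="B",
        segment_near="RGAAACN",
        near_labels=("20", "21", "22", "23", "24", "25", "26"),
        segment_far="NNAYNUUAN",
        far_labels=("36", "37", "38", "39", "40", "41", "42", "43", "44"),
        outer_helix="h3",
        inner_helix="h4",
    )
    invariants = frozenset(
        {("+1", "G"), ("8", "G"), ("25", "C"), ("38", "A"),
         ("22", "A"), ("23", "A"), ("24", "A")}
    )
    return HairpinCoreModel(
        helices=(
            HelixSpec("h1", 3, 15),
            HelixSpec("h2", 3, 6),
            HelixSpec("h3", 4, 7),
            HelixSpec("h4", 3, 15),
        ),
        loop_a=loop_a,
        loop_b=loop_b,
        junction_min=0,
        junction_max=3,
        invariant_positions=invariants,
    )


# ---------------------------------------------------------------------------
# permutation enumeration and descriptor construction
# ---------------------------------------------------------------------------

def enumerate_permutations(
    model: HairpinCoreModel, allow_flips: bool = True
) -> Tuple[PermutationSpec, ...]:
    """All theoretical permutations, sorted by canonical label.

    16 with flips allowed (4 arrangements x 2 x 2), 4 without.
    """
    flips = (False, True) if allow_flips else (False,)
    specs = {
        PermutationSpec(arr, fa, fb).canonical_label: PermutationSpec(arr, fa, fb)
        for arr in ARRANGEMENTS
        for fa in flips
        for fb in flips
    }
    return tuple(specs[k] for k in sorted(specs))


def _unit_halves(model: HairpinCoreModel, unit: LoopUnit, flipped: bool):
    """(prefix, suffix) element tuples for one loop unit.

    Unflipped: outer-helix open, near strand, inner-helix open ... inner
    close, far strand, outer close.  Flipping the unit exchanges the order
    of the two unpaired strands (the far strand now comes first) and swaps
    the outer/inner roles of the two flanking helices, as a circular
    permutation cut on the other side of the unit produces.
    """
    outer = model.helix(unit.outer_helix)
    inner = model.helix(unit.inner_helix)
    if not flipped:
        prefix = (outer.open_element(), *unit.near_elements(), inner.open_element())
        suffix = (HelixClose(inner.label), *unit.far_elements(), HelixClose(outer.label))
    else:
        prefix = (inner.open_element(), *unit.far_elements(), outer.open_element())
        suffix = (HelixClose(outer.label), *unit.near_elements(), HelixClose(inner.label))
    return prefix, suffix


def descriptor_from_permutation(
    model: HairpinCoreModel, perm: PermutationSpec
) -> MotifDescriptor:
    """Render one permutation as a well-formed searchable descriptor."""
    if perm.canonical_label not in {
        p.canonical_label for p in enumerate_permutations(model, True)
    }:
        raise MotifModelError(f"unknown permutation {perm.canonical_label!r}")

    junction = SingleStrand("N", model.junction_min, model.junction_max)
    tloop = SingleStrand("N", model.terminal_loop_min, model.terminal_loop_max)
    pre_a, suf_a = _unit_halves(model, model.loop_a, perm.flip_a)
    pre_b, suf_b = _unit_halves(model, model.loop_b, perm.flip_b)

    if perm.arrangement == "A_nests_B":
        elems = (*pre_a, junction, *pre_b, tloop, *suf_b, junction, *suf_a)
    elif perm.arrangement == "B_nests_A":
        elems = (*pre_b, junction, *pre_a, tloop, *suf_a, junction, *suf_b)
    elif perm.arrangement == "A_then_B":
        elems = (*pre_a, tloop, *suf_a, junction, *pre_b, tloop, *suf_b)
    else:  # B_then_A
        elems = (*pre_b, tloop, *suf_b, junction, *pre_a, tloop, *suf_a)
    return MotifDescriptor(elements=elems, permutation=perm.canonical_label)


def default_descriptors(model: Optional[HairpinCoreModel] = None):
    """Canonical-label -> descriptor for all 16 permutations of a model."""
    model = model or build_default_hairpin_core()
    return {
        p.canonical_label: descriptor_from_permutation(model, p)
        for p in enumerate_permutations(model, True)
    }


# ---------------------------------------------------------------------------
# descriptor text format (round-trippable)
# ---------------------------------------------------------------------------
#
# one element per line:
#   helix5 <label> <min> <max> <mismatches>
#   helix3 <label>
#   ss <pattern-with-optional-{min,max}-quantifier> [comma-separated labels]
#   cleave
# '#' starts a comment; the header comment carries the permutation label.

def render_descriptor(desc: MotifDescriptor) -> str:
    lines = [f"# permutation: {desc.permutation}"]
    for el in desc.elements:
        if isinstance(el, HelixOpen):
            lines.append(f"helix5 {el.label} {el.min_len} {el.max_len} {el.mismatches}")
        elif isinstance(el, HelixClose):
            lines.append(f"helix3 {el.label}")
        elif isinstance(el, CleavageSite):
            lines.append("cleave")
        elif isinstance(el, SingleStrand):
            if el.fixed:
                lab = f" {','.join(el.labels)}" if el.labels else ""
                lines.append(f"ss {el.pattern}{lab}")
            else:
                lines.append(f"ss {el.pattern}{{{el.min_len},{el.max_len}}}")
        else:  # pragma: no cover
            raise MotifModelError(f"unknown element {el!r}")
    return "\n".join(lines) + "\n"


def parse_descriptor(text: str) -> MotifDescriptor:
    permutation = "unknown"
    elements: list = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("permutation:"):
                permutation = body.split(":", 1)[1].strip()
            continue
        parts = line.split()
        kind = parts[0]
        if kind == "helix5":
            if len(parts) != 5:
                raise MotifModelError(f"bad helix5 line: {line!r}")
            elements.append(HelixOpen(parts[1], int(parts[2]), int(parts[3]), int(parts[4])))
        elif kind == "helix3":
            if len(parts) != 2:
                raise MotifModelError(f"bad helix3 line: {line!r}")
            elements.append(HelixClose(parts[1]))
        elif kind == "cleave":
            elements.append(CleavageSite())
        elif kind == "ss":
            if len(parts) not in (2, 3):
                raise MotifModelError(f"bad ss line: {line!r}")
            pat = parts[1]
            labels = tuple(parts[2].split(",")) if len(parts) == 3 else None
            if "{" in pat:
                base, _, quant = pat.partition("{")
                lo, hi = quant.rstrip("}").split(",")
                elements.append(SingleStrand(base, int(lo), int(hi)))
            else:
                elements.append(SingleStrand(pat, len(pat), len(pat), labels))
        else:
            raise MotifModelError(f"unknown descriptor line kind {kind!r}")
    return MotifDescriptor(elements=tuple(elements), permutation=permutation)
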