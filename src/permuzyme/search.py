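"""Descriptor scanning of nucleotide sequences.

Scans contigs (both strands, optionally circular) for matches to a
:class:`~permuzyme.motif.MotifDescriptor` and maps hits onto standard
hairpin-ribozyme position numbering.

The matcher enumerates *every* assignment of element lengths that satisfies
all constraints (exhaustive over the descriptor's length ranges).  To avoid
trying every start position, candidate starts are generated from occurrences
of the most informative fixed single-strand element (an exact filter: any
true match must place those letters verbatim), then verified by
backtracking.  Per-locus tie-breaking is a separate, explicit step
(:func:`dedupe_matches`).

Coordinates are 0-based half-open internally, on the plus strand; for
circular scans a match may wrap, in which case ``end`` exceeds the sequence
length and coordinates are taken modulo the circle length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .motif import (
    IUPAC,
    CleavageSite,
    HelixClose,
    HelixOpen,
    MotifDescriptor,
    SingleStrand,
)

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")
_WC_GU = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")})
_WC = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})


class SearchError(ValueError):
    """Raised on invalid sequence characters or inconsistent matches."""


def normalize_rna(seq: str) -> str:
    """Uppercase, DNA->RNA alphabet; rejects non-nucleotide characters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGUN")
    if bad:
        raise SearchError(f"invalid sequence characters: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_compatible(pattern_char: str, seq_char: str) -> bool:
    """True iff the subject nucleotide is in the pattern code's expansion.

    T is treated as U.  A subject 'N' (ambiguous base call) matches only
    pattern 'N', so degenerate assemblies cannot satisfy informative
    pattern positions.
    """
    p = pattern_char.upper()
    s = seq_char.upper().replace("T", "U")
    if p not in IUPAC:
        raise SearchError(f"invalid IUPAC pattern code {p!r}")
    if s not in "ACGUN":
        raise SearchError(f"invalid sequence character {s!r}")
    if s == "N":
        return p == "N"
    return s in IUPAC[p]


def pairs_allowed(a: str, b: str, allow_gu: bool = True) -> bool:
    """Watson-Crick pair, or G-U wobble when ``allow_gu``; N never pairs."""
    x = a.upper().replace("T", "U")
    y = b.upper().replace("T", "U")
    if x not in "ACGUN" or y not in "ACGUN":
        raise SearchError(f"invalid nucleotides {a!r}/{b!r}")
    return (x, y) in (_WC_GU if allow_gu else _WC)


# ---------------------------------------------------------------------------
# match records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementSpan:
    """Span of one descriptor element within a match (oriented offsets)."""

    index: int          # element index within the descriptor
    kind: str           # "helix5" | "helix3" | "ss" | "cleave"
    label: Optional[str]  # helix label, or None
    offset: int         # offset from match start, in ribozyme orientation
    length: int


@dataclass(frozen=True)
class MotifMatch:
    contig_id: str
    strand: str                      # "+" or "-"
    start: int                       # plus-strand, 0-based
    end: int                         # half-open; > circle length if wrapped
    spans: Tuple[ElementSpan, ...]
    cleavage_offset: int             # inter-nucleotide offset from match start (oriented)
    cleavage_pos: int                # inter-nucleotide plus-strand coordinate
    permutation: str
    score: int
    contains_n: bool
    oriented_seq: str                # matched sequence, 5'->3' in ribozyme orientation
    descriptor: MotifDescriptor
    seq_length: int                  # subject length (circle length if circular)
    circular: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    def helix_length(self, label: str) -> int:
        for sp in self.spans:
            if sp.kind == "helix5" and sp.label == label:
                return sp.length
        raise SearchError(f"no helix {label!r} in match")


@dataclass(frozen=True)
class StandardPositionMap:
    """Standard hairpin position -> (plus-strand coordinate, nucleotide)."""

    positions: Dict[str, int]
    nucleotides: Dict[str, str]
    helix_pairs: Dict[str, Tuple[Tuple[int, int], ...]]  # label -> ((coord5, coord3), ...)

    def nucleotide(self, label: str) -> str:
        return self.nucleotides[label]


# ---------------------------------------------------------------------------
# matcher core
# ---------------------------------------------------------------------------

def _char_ok(p: str, s: str) -> bool:
    # hot path: inputs already normalized/validated
    if s == "N":
        return p == "N"
    return s in IUPAC[p]


def _match_at(desc: MotifDescriptor, seq: str, start: int, allow_gu: bool,
              max_len: Optional[int] = None) -> List[Tuple[Tuple[ElementSpan, ...], int]]:
    """All satisfying element-length assignments of ``desc`` at ``start``.

    Returns (spans, cleavage_offset) per assignment.  ``max_len`` bounds the
    total match length (used to forbid >1 wrap on circular scans).
    """
    elements = desc.elements
    n = len(elements)
    L = len(seq)
    out: List[Tuple[Tuple[ElementSpan, ...], int]] = []

    def recurse(i: int, pos: int, open_spans: dict, acc: list, cleave: Optional[int]):
        if max_len is not None and pos - start > max_len:
            return
        if i == n:
            if cleave is not None:
                out.append((tuple(acc), cleave))
            return
        el = elements[i]
        if isinstance(el, CleavageSite):
            acc.append(ElementSpan(i, "cleave", None, pos - start, 0))
            recurse(i + 1, pos, open_spans, acc, pos - start)
            acc.pop()
        elif isinstance(el, SingleStrand):
            if el.fixed:
                k = el.min_len
                if pos + k > L:
                    return
                for j, p in enumerate(el.pattern):
                    if not _char_ok(p, seq[pos + j]):
                        return
                acc.append(ElementSpan(i, "ss", None, pos - start, k))
                recurse(i + 1, pos + k, open_spans, acc, cleave)
                acc.pop()
            else:
                p = el.pattern
                if pos + el.min_len > L:
                    return
                ok_upto = 0  # chars [pos, pos+ok_upto) verified against p
                for k in range(el.min_len, el.max_len + 1):
                    if pos + k > L:
                        break
                    while ok_upto < k:
                        if not _char_ok(p, seq[pos + ok_upto]):
                            ok_upto = -1
                            break
                        ok_upto += 1
                    if ok_upto < 0:
                        break  # a bad char kills this and all longer k
                    acc.append(ElementSpan(i, "ss", None, pos - start, k))
                    recurse(i + 1, pos + k, open_spans, acc, cleave)
                    acc.pop()
        elif isinstance(el, HelixOpen):
            for k in range(el.min_len, el.max_len + 1):
                if pos + k > L:
                    break
                open_spans[el.label] = (pos, k, el.mismatches)
                acc.append(ElementSpan(i, "helix5", el.label, pos - start, k))
                recurse(i + 1, pos + k, open_spans, acc, cleave)
                acc.pop()
            open_spans.pop(el.label, None)
        elif isinstance(el, HelixClose):
            o_pos, k, mm_budget = open_spans[el.label]
            if pos + k > L:
                return
            mm = 0
            for j in range(k):
                a, b = seq[o_pos + j], seq[pos + k - 1 - j]
                pr = (a, b) in (_WC_GU if allow_gu else _WC)
                if not pr:
                    mm += 1
                    if mm > mm_budget:
                        return
            acc.append(ElementSpan(i, "helix3", el.label, pos - start, k))
            recurse(i + 1, pos + k, open_spans, acc, cleave)
            acc.pop()
        else:  # pragma: no cover
            raise SearchError(f"unknown element {el!r}")

    recurse(0, start, {}, [], None)
    return out


_CLASS = {c: "[" + "".join(sorted(IUPAC[c] | ({"N"} if c == "N" else set()))) + "]"
          for c in IUPAC}


def _anchor(desc: MotifDescriptor):
    """(regex, min_offset, max_offset) for the most informative fixed element.

    Any true match places this element's letters exactly at
    start + offset for some offset in [min_offset, max_offset]; scanning for
    the element therefore yields a complete candidate-start set.
    """
    bits = {"A": 2, "C": 2, "G": 2, "U": 2, "R": 1, "Y": 1, "S": 1, "W": 1,
            "K": 1, "M": 1, "B": 0.4, "D": 0.4, "H": 0.4, "V": 0.4, "N": 0}
    best = None
    lo = hi = 0
    for el in desc.elements:
        if isinstance(el, SingleStrand) and el.fixed:
            info = sum(bits[c] for c in el.pattern)
            if best is None or info > best[0]:
                best = (info, el.pattern, lo, hi)
        if isinstance(el, HelixOpen):
            lo += el.min_len
            hi += el.max_len
        elif isinstance(el, HelixClose):
            # closing span length equals its open span length; bounds are the same
            o = next(e for e in desc.elements
                     if isinstance(e, HelixOpen) and e.label == el.label)
            lo += o.min_len
            hi += o.max_len
        elif isinstance(el, SingleStrand):
            lo += el.min_len
            hi += el.max_len
    if best is None:
        return None
    _, pat, mn, mx = best
    rx = re.compile("(?=" + "".join(_CLASS[c] for c in pat) + ")")
    return rx, mn, mx


def _candidate_starts(desc: MotifDescriptor, seq: str) -> Iterable[int]:
    anch = _anchor(desc)
    if anch is None:
        return range(len(seq))
    rx, mn, mx = anch
    starts = set()
    for m in rx.finditer(seq):
        o = m.start()
        for off in range(mn, mx + 1):
            s = o - off
            if s >= 0:
                starts.add(s)
    return sorted(starts)


def _score(spans: Sequence[ElementSpan], desc: MotifDescriptor) -> int:
    """Count of preferred features: modal helix 2/3 lengths, empty junction."""
    h2 = h3 = None
    junction = 0
    for sp in spans:
        if sp.kind == "helix5" and sp.label == "h2":
            h2 = sp.length
        elif sp.kind == "helix5" and sp.label == "h3":
            h3 = sp.length
        elif sp.kind == "ss":
            el = desc.elements[sp.index]
            if not el.fixed and el.labels is None and el.max_len <= 3:
                junction += sp.length
    return int(h2 == 4) + int(h3 == 5) + int(junction == 0)


def scan_sequence(
    descriptor: MotifDescriptor,
    seq: str,
    contig_id: str = "seq",
    strands: Sequence[str] = ("+", "-"),
    circular: bool = False,
    allow_gu: bool = True,
) -> List[MotifMatch]:
    """All matches of ``descriptor`` in ``seq``.

    For circular sequences the doubled sequence (seq + first L-1 nt) is
    scanned and matches are reported once, with start in [0, L); minus-strand
    hits are reported in plus-strand coordinates with strand "-".
    """
    s = normalize_rna(seq)
    L = len(s)
    if L == 0 or L < descriptor.min_length and not circular:
        return []
    matches: List[MotifMatch] = []
    for strand in strands:
        if strand not in ("+", "-"):
            raise SearchError(f"bad strand {strand!r}")
        oriented = s if strand == "+" else revcomp(s)
        subject = oriented + oriented[: L - 1] if circular else oriented
        max_len = L if circular else None
        for a in _candidate_starts(descriptor, subject):
            if circular and a >= L:
                continue  # duplicate of a - L
            for spans, cleave in _match_at(descriptor, subject, a, allow_gu, max_len):
                mlen = sum(sp.length for sp in spans)
                b = a + mlen
                oriented_seq = subject[a:b]
                if strand == "+":
                    start = a
                else:
                    start = (L - b) % L if circular else L - b
                end = start + mlen
                cpos = start + cleave if strand == "+" else start + mlen - cleave
                if circular:
                    cpos %= L
                matches.append(
                    MotifMatch(
                        contig_id=contig_id,
                        strand=strand,
                        start=start,
                        end=end,
                        spans=spans,
                        cleavage_offset=cleave,
                        cleavage_pos=cpos,
                        permutation=descriptor.permutation,
                        score=_score(spans, descriptor),
                        contains_n="N" in oriented_seq,
                        oriented_seq=oriented_seq,
                        descriptor=descriptor,
                        seq_length=L,
                        circular=circular,
                    )
                )
    matches.sort(key=lambda m: (m.strand, m.start, m.end, m.permutation))
    return matches


def dedupe_matches(matches: Iterable[MotifMatch]) -> List[MotifMatch]:
    """One match per (contig, strand, start, permutation) locus.

    Tie-break: maximal total helix length, then lexicographically smallest
    span tuple — deterministic output for overlapping length assignments.
    """
    best: Dict[tuple, MotifMatch] = {}
    for m in matches:
        key = (m.contig_id, m.strand, m.start, m.permutation)
        helix_total = sum(sp.length for sp in m.spans if sp.kind == "helix5")
        rank = (-helix_total, tuple((sp.offset, sp.length) for sp in m.spans))
        prev = best.get(key)
        if prev is None:
            best[key] = m
        else:
            prev_total = sum(sp.length for sp in prev.spans if sp.kind == "helix5")
            prev_rank = (-prev_total, tuple((sp.offset, sp.length) for sp in prev.spans))
            if rank < prev_rank:
                best[key] = m
    return sorted(best.values(), key=lambda m: (m.contig_id, m.strand, m.start, m.permutation))


def collapse_by_cleavage(matches: Iterable[MotifMatch]) -> List[MotifMatch]:
    """One match per (contig, strand, cleavage site, permutation).

    Alternative length assignments of one ribozyme locus (e.g. a shortened
    outer helix) all share the cleavage position, which identifies the
    ribozyme; the representative is the assignment with maximal total helix
    length, then lexicographically smallest spans.
    """
    best: Dict[tuple, MotifMatch] = {}
    for m in matches:
        key = (m.contig_id, m.strand, m.cleavage_pos, m.permutation)
        helix_total = sum(sp.length for sp in m.spans if sp.kind == "helix5")
        rank = (-helix_total, tuple((sp.offset, sp.length) for sp in m.spans))
        prev = best.get(key)
        if prev is None:
            best[key] = m
            continue
        prev_total = sum(sp.length for sp in prev.spans if sp.kind == "helix5")
        prev_rank = (-prev_total, tuple((sp.offset, sp.length) for sp in prev.spans))
        if rank < prev_rank:
            best[key] = m
    return sorted(
        best.values(),
        key=lambda m: (m.contig_id, m.strand, m.cleavage_pos, m.permutation),
    )


# ---------------------------------------------------------------------------
# standard-position mapping
# ---------------------------------------------------------------------------

def _oriented_to_plus(match: MotifMatch, offset: int) -> int:
    """Plus-strand coordinate of oriented offset within the match."""
    if match.strand == "+":
        c = match.start + offset
    else:
        c = match.start + match.length - 1 - offset
    if match.circular:
        c %= match.seq_length
    return c


def map_to_standard_positions(match: MotifMatch) -> StandardPositionMap:
    """Map a match onto standard hairpin numbering.

    Labelled single-strand positions come from the descriptor; helix-embedded
    standard positions (-5..-3 extend 5'-ward of -2, +4 extends 3'-ward of
    +3) are derived by adjacency.  Fails loudly if spans are inconsistent
    with the descriptor or the invariant G at +1 is violated.
    """
    desc = match.descriptor
    positions: Dict[str, int] = {}
    nucleotides: Dict[str, str] = {}
    offsets: Dict[str, int] = {}

    total = sum(sp.length for sp in match.spans)
    if total != match.length:
        raise SearchError("match spans do not tile the match interval")

    for sp in match.spans:
        el = desc.elements[sp.index]
        if sp.kind == "ss" and isinstance(el, SingleStrand) and el.labels:
            if sp.length != len(el.labels):
                raise SearchError("span length inconsistent with labelled element")
            for j, lab in enumerate(el.labels):
                offsets[lab] = sp.offset + j

    # helix-embedded standard positions by adjacency
    if "-2" in offsets:
        for d, lab in ((1, "-3"), (2, "-4"), (3, "-5")):
            offsets[lab] = offsets["-2"] - d
    if "+3" in offsets:
        offsets["+4"] = offsets["+3"] + 1

    for lab, off in offsets.items():
        if not (0 <= off < match.length):
            raise SearchError(f"standard position {lab} falls outside the match")
        positions[lab] = _oriented_to_plus(match, off)
        nucleotides[lab] = match.oriented_seq[off]

    if nucleotides.get("+1") != "G":
        raise SearchError("invariant violated: position +1 is not G")

    helix_pairs: Dict[str, Tuple[Tuple[int, int], ...]] = {}
    opens = {sp.label: sp for sp in match.spans if sp.kind == "helix5"}
    closes = {sp.label: sp for sp in match.spans if sp.kind == "helix3"}
    for lab, osp in opens.items():
        csp = closes.get(lab)
        if csp is None or csp.length != osp.length:
            raise SearchError(f"helix {lab} spans inconsistent")
        pairs = []
        for j in range(osp.length):
            pairs.append(
                (
                    _oriented_to_plus(match, osp.offset + j),
                    _oriented_to_plus(match, csp.offset + csp.length - 1 - j),
                )
            )
        helix_pairs[lab] = tuple(pairs)

    return StandardPositionMap(positions=positions, nucleotides=nucleotides,
                               helix_pairs=helix_pairs)
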