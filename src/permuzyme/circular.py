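"""Circular-molecule inference from linear contigs.

Assemblers that force circular templates into linear contigs duplicate the
region around the (arbitrary) first position: the contig's 5' prefix recurs
exactly at its 3' end.  Detecting that terminal repeat identifies a complete
circular molecule whose length is the contig length minus the repeat length
(e.g. a 735-nt contig with a 123-nt end repeat implies a 612-nt circle).
Matching is exact (case- and U/T-insensitive; 'N' never matches), mirroring
the conservative detection rule; tandem-repeat artifacts are screened by a
k-mer-seeded self-similarity scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .search import normalize_rna


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str
    sample: Optional[str] = None

    def __post_init__(self):
        if not self.seq:
            raise ValueError("empty contig sequence")
        normalize_rna(self.seq)  # validates alphabet


@dataclass(frozen=True)
class EndRepeatResult:
    repeat_len: int
    prefix_span: Tuple[int, int]   # [0, repeat_len)
    suffix_span: Tuple[int, int]   # [L - repeat_len, L)
    circle_len: int                # contig length - repeat length

    def __post_init__(self):
        if self.repeat_len < 1:
            raise ValueError("repeat length must be >= 1")


@dataclass(frozen=True)
class CircularMolecule:
    seq: str                       # rotation-normalized (lexicographically minimal)
    length: int
    source_contig: str
    complete: bool = True

    def __post_init__(self):
        if len(self.seq) != self.length:
            raise ValueError("length field inconsistent with sequence")


@dataclass(frozen=True)
class SelfMatch:
    span_a: Tuple[int, int]
    span_b: Tuple[int, int]
    length: int
    identity: float


def detect_end_repeat(contig: Contig, min_len: int = 75) -> Optional[EndRepeatResult]:
    """Longest exact prefix == suffix match with length in [min_len, L//2].

    Returns None when no qualifying repeat exists.  'N' positions never
    match, so gap-filled assemblies do not produce spurious repeats.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    s = normalize_rna(contig.seq)
    L = len(s)
    for k in range(L // 2, min_len - 1, -1):
        pre = s[:k]
        if pre == s[L - k:] and "N" not in pre:
            return EndRepeatResult(
                repeat_len=k,
                prefix_span=(0, k),
                suffix_span=(L - k, L),
                circle_len=L - k,
            )
    return None


def canonical_rotation(seq: str) -> str:
    """Lexicographically smallest rotation (Booth's algorithm)."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq + seq
    n = len(seq)
    f = [-1] * len(s)  # failure function
    k = 0
    for j in range(1, len(s)):
        sj = s[j]
        i = f[j - k - 1]
        while i != -1 and sj != s[k + i + 1]:
            if sj < s[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s[k + i + 1]:
            if sj < s[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return s[k:k + n]


def infer_circle(contig: Contig, min_len: int = 75) -> Optional[CircularMolecule]:
    """Strip the terminal repeat copy and rotation-normalize, if a repeat exists."""
    rep = detect_end_repeat(contig, min_len)
    if rep is None:
        return None
    s = normalize_rna(contig.seq)[: rep.circle_len]
    return CircularMolecule(
        seq=canonical_rotation(s),
        length=rep.circle_len,
        source_contig=contig.id,
        complete=True,
    )


def self_similarity_scan(
    contig: Contig,
    min_len: int = 50,
    max_mismatch_frac: float = 0.1,
    kmer: int = 12,
    end_repeat_min: int = 75,
) -> Tuple[List[SelfMatch], bool]:
    """Internal (off-diagonal) self-matches; flags putative tandem artifacts.

    k-mer-seeded, ungapped-extended matches of length >= min_len are
    reported, excluding the trivial self-diagonal and the diagonal of the
    detected end repeat.  The artifact flag is set when a non-end-repeat
    match covers >= 50% of the contig.
    """
    if min_len < 12:
        raise ValueError("min_len must be >= 12")
    s = normalize_rna(contig.seq)
    L = len(s)
    rep = detect_end_repeat(contig, end_repeat_min)
    # a repeat of exactly half the contig IS a perfect tandem duplication;
    # only a shorter terminal repeat is excused as assembler linearization
    excluded_diag = (
        (L - rep.repeat_len) if rep and 2 * rep.repeat_len < L else None
    )

    seeds: Dict[str, List[int]] = {}
    for i in range(L - kmer + 1):
        w = s[i:i + kmer]
        if "N" in w:
            continue
        seeds.setdefault(w, []).append(i)

    # group seed pairs by diagonal (j - i), extend the best run per diagonal
    diag_pairs: Dict[int, List[int]] = {}
    for pos_list in seeds.values():
        if len(pos_list) < 2:
            continue
        for ai in range(len(pos_list) - 1):
            for bi in range(ai + 1, len(pos_list)):
                i, j = pos_list[ai], pos_list[bi]
                diag_pairs.setdefault(j - i, []).append(i)

    matches: List[SelfMatch] = []
    for diag, starts in diag_pairs.items():
        if diag == 0 or diag == excluded_diag:
            continue
        starts = sorted(set(starts))
        covered_until = -1
        for i0 in starts:
            if i0 <= covered_until:
                continue
            # ungapped extension around the seed on this diagonal
            lo = i0
            while lo > 0 and lo - 1 + diag < L and s[lo - 1] == s[lo - 1 + diag] != "N":
                lo -= 1
            hi = i0 + kmer
            mism = 0
            best_hi = hi
            budget = max_mismatch_frac
            while hi + diag < L and hi < L:
                if s[hi] == s[hi + diag] and s[hi] != "N":
                    hi += 1
                    if mism / max(1, hi - lo) <= budget:
                        best_hi = hi
                else:
                    mism += 1
                    if mism / max(1, hi + 1 - lo) > budget:
                        break
                    hi += 1
            length = best_hi - lo
            covered_until = best_hi
            if length >= min_len:
                ident = 1.0 - mism / length
                matches.append(
                    SelfMatch(
                        span_a=(lo, best_hi),
                        span_b=(lo + diag, best_hi + diag),
                        length=length,
                        identity=round(ident, 4),
                    )
                )
    artifact = any(m.length >= 0.5 * L for m in matches)
    return matches, artifact


def end_repeat_enrichment(
    with_motif: Sequence[Contig],
    without_motif: Sequence[Contig],
    min_len: int = 75,
) -> Dict[str, float]:
    """End-repeat frequency in motif-containing vs other contigs, and ratio."""
    if not with_motif or not without_motif:
        raise ValueError("both contig sets must be non-empty")
    n_with = sum(detect_end_repeat(c, min_len) is not None for c in with_motif)
    n_without = sum(detect_end_repeat(c, min_len) is not None for c in without_motif)
    f_with = n_with / len(with_motif)
    f_without = n_without / len(without_motif)
    ratio = float("inf") if f_without == 0 and f_with > 0 else (
        1.0 if f_with == f_without == 0 else f_with / f_without
    )
    return {
        "n_with_motif": len(with_motif),
        "n_without_motif": len(without_motif),
        "repeats_with_motif": n_with,
        "repeats_without_motif": n_without,
        "fraction_with_motif": f_with,
        "fraction_without_motif": f_without,
        "ratio": ratio,
    }
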