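"""Comparative analyses over structural alignments.

Implements the conservation / covariation analytics applied to the hairpin
ribozyme alignment: per-position nucleotide counts, perfectly conserved
positions, covariation support for the proposed base pairs (APC-corrected
mutual information with a within-column shuffle null — a deliberately simple,
seedable stand-in for phylogeny-aware tests such as R-scape), the
junction-length distribution between helices 2 and 3, and the helix-extension
accounting that reassigns pairable junction nucleotides to an adjacent helix.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import AlignIO

from .search import pairs_allowed

GAP_CHARS = set(".-~_:,")
_OPEN = "<([{"
_CLOSE = ">)]}"
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


class AlignmentError(ValueError):
    """Raised on malformed alignments or inconsistent requests."""


def _norm_char(c: str) -> str:
    c = c.upper()
    if c == "T":
        return "U"
    if c in GAP_CHARS or c == "-":
        return "-"
    return c


@dataclass
class Alignment:
    """Gapped rows plus a consensus secondary-structure line."""

    ids: List[str]
    rows: List[str]          # gapped, normalized to upper RNA with '-' gaps
    structure: str           # WUSS/dot-bracket consensus, same length

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids/rows length mismatch")
        if not self.rows:
            raise AlignmentError("empty alignment")
        ncol = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != ncol:
                raise AlignmentError(
                    f"row {rid!r} has length {len(row)}, expected {ncol}"
                )
        if len(self.structure) != ncol:
            raise AlignmentError("structure line length mismatch")
        self.paired_columns()  # validates bracket nesting

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def paired_columns(self) -> List[Tuple[int, int]]:
        """(i, j) column pairs from the consensus structure, i < j."""
        stacks: Dict[int, list] = {k: [] for k in range(len(_OPEN))}
        pairs = []
        for i, c in enumerate(self.structure):
            if c in _OPEN:
                stacks[_OPEN.index(c)].append(i)
            elif c in _CLOSE:
                k = _CLOSE.index(c)
                if not stacks[k]:
                    raise AlignmentError(
                        f"unbalanced structure: stray {c!r} at column {i}"
                    )
                pairs.append((stacks[k].pop(), i))
        for k, st in stacks.items():
            if st:
                raise AlignmentError(
                    f"unbalanced structure: unclosed {_OPEN[k]!r} at column {st[-1]}"
                )
        return sorted(pairs)

    def ungapped(self, r: int) -> str:
        return self.rows[r].replace("-", "")

    def to_array(self) -> np.ndarray:
        """(rows, cols) int8 array: A,C,G,U -> 0..3; gap/other -> -1."""
        arr = np.full((self.n_rows, self.n_cols), -1, dtype=np.int8)
        for r, row in enumerate(self.rows):
            for c, ch in enumerate(row):
                arr[r, c] = _NT_INDEX.get(ch, -1)
        return arr


def read_stockholm(path) -> Alignment:
    """Read a Stockholm 1.0 alignment (multi-block supported) with #=GC SS_cons."""
    try:
        aln = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise AlignmentError(f"cannot parse Stockholm file {path}: {exc}") from exc
    ss = aln.column_annotations.get("secondary_structure")
    if ss is None:
        raise AlignmentError(f"{path}: missing #=GC SS_cons line")
    ids = [rec.id for rec in aln]
    rows = ["".join(_norm_char(c) for c in str(rec.seq)) for rec in aln]
    return Alignment(ids=ids, rows=rows, structure=ss)


def write_stockholm(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        width = max(len(i) for i in aln.ids + ["#=GC SS_cons"]) + 2
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f"{rid:<{width}}{row}\n")
        fh.write(f"{'#=GC SS_cons':<{width}}{aln.structure}\n")
        fh.write("//\n")


def unique_sequences(aln: Alignment) -> Tuple[int, Alignment]:
    """Deduplicate rows by ungapped sequence (U/T- and case-normalized).

    Returns (unique count, first-occurrence-retained alignment).
    """
    seen = {}
    keep = []
    for r in range(aln.n_rows):
        key = aln.ungapped(r)
        if key not in seen:
            seen[key] = r
            keep.append(r)
    dedup = Alignment(
        ids=[aln.ids[r] for r in keep],
        rows=[aln.rows[r] for r in keep],
        structure=aln.structure,
    )
    return len(keep), dedup


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

@dataclass
class ConservationProfile:
    counts: Dict[str, Dict[str, int]]   # standard position -> {A,C,G,U,gap: n}
    colmap: Dict[str, int]
    n_rows: int

    def consensus_count(self, position: str) -> Tuple[str, int]:
        c = self.counts[position]
        nt = max("ACGU", key=lambda x: c[x])
        return nt, c[nt]


def conservation_profile(
    aln: Alignment, colmap: Mapping[str, int]
) -> ConservationProfile:
    """Exact per-position nucleotide counts at the mapped columns."""
    counts: Dict[str, Dict[str, int]] = {}
    for pos, col in colmap.items():
        if not (0 <= col < aln.n_cols):
            raise AlignmentError(f"position {pos!r} maps to invalid column {col}")
        tally = {"A": 0, "C": 0, "G": 0, "U": 0, "gap": 0}
        for row in aln.rows:
            ch = row[col]
            if ch in tally:
                tally[ch] += 1
            else:
                tally["gap"] += 1  # gaps and ambiguity codes
        counts[pos] = tally
    return ConservationProfile(counts=counts, colmap=dict(colmap), n_rows=aln.n_rows)


def perfectly_conserved_positions(
    profile: ConservationProfile, region: Optional[Iterable[str]] = None
) -> List[str]:
    """Positions where a single nucleotide accounts for every row."""
    region = set(region) if region is not None else set(profile.counts)
    out = []
    for pos in profile.counts:
        if pos not in region:
            continue
        tally = profile.counts[pos]
        if any(tally[nt] == profile.n_rows for nt in "ACGU"):
            out.append(pos)
    return sorted(out, key=lambda p: profile.colmap.get(p, 0))


# ---------------------------------------------------------------------------
# covariation
# ---------------------------------------------------------------------------

def pair_joint_counts(aln: Alignment, colpair: Tuple[int, int]) -> np.ndarray:
    """4x4 joint nucleotide counts over rows non-gapped at both columns."""
    i, j = colpair
    arr = aln.to_array()
    x, y = arr[:, i], arr[:, j]
    mask = (x >= 0) & (y >= 0)
    if mask.sum() < 2:
        raise AlignmentError(f"columns {colpair}: fewer than 2 ungapped rows")
    return np.bincount(
        (4 * x[mask] + y[mask]).astype(np.int64), minlength=16
    ).reshape(4, 4).astype(float)


def mutual_information(counts: np.ndarray) -> float:
    """Raw MI (bits) of a 4x4 joint count table."""
    n = counts.sum()
    if n == 0:
        raise AlignmentError("empty joint count table")
    p = counts / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for a in range(4):
        for b in range(4):
            if p[a, b] > 0:
                mi += p[a, b] * math.log2(p[a, b] / (px[a] * py[b]))
    return max(mi, 0.0)


def _mi_from_arrays(x: np.ndarray, y: np.ndarray) -> float:
    mask = (x >= 0) & (y >= 0)
    n = int(mask.sum())
    if n < 2:
        return float("nan")
    joint = np.bincount((4 * x[mask] + y[mask]).astype(np.int64), minlength=16)
    joint = joint.reshape(4, 4) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    indep = np.outer(px, py)
    nz = joint > 0
    mi = float((joint[nz] * np.log2(joint[nz] / indep[nz])).sum())
    return max(mi, 0.0)


def _mip_over_columns(
    col_data: Mapping[int, np.ndarray]
) -> Dict[Tuple[int, int], float]:
    """APC-corrected MI for every unordered pair among the given columns.

    The average-product correction uses the full MI matrix over the column
    set (mean MI of column i times mean MI of column j over the grand mean),
    so a genuinely covarying pair is corrected against the background of its
    columns' other pairings rather than against itself.
    """
    cols = sorted(col_data)
    mi: Dict[Tuple[int, int], float] = {}
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            i, j = cols[a], cols[b]
            mi[(i, j)] = _mi_from_arrays(col_data[i], col_data[j])
    vals = [v for v in mi.values() if not math.isnan(v)]
    grand = sum(vals) / len(vals) if vals else 0.0
    col_sum: Dict[int, float] = {c: 0.0 for c in cols}
    col_n: Dict[int, int] = {c: 0 for c in cols}
    for (i, j), v in mi.items():
        if not math.isnan(v):
            col_sum[i] += v
            col_n[i] += 1
            col_sum[j] += v
            col_n[j] += 1
    mean_col = {c: (col_sum[c] / col_n[c] if col_n[c] else 0.0) for c in cols}
    out: Dict[Tuple[int, int], float] = {}
    for (i, j), v in mi.items():
        if math.isnan(v) or grand <= 0:
            out[(i, j)] = v
        else:
            out[(i, j)] = v - mean_col[i] * mean_col[j] / grand
    return out


def covariation_mip(
    aln: Alignment, pairs: Optional[Sequence[Tuple[int, int]]] = None
) -> Dict[Tuple[int, int], float]:
    """APC-corrected MI (bits) for the structure's paired columns."""
    pairs = [tuple(sorted(pr)) for pr in (pairs if pairs is not None
                                          else aln.paired_columns())]
    arr = aln.to_array()
    cols = sorted({c for pr in pairs for c in pr})
    full = _mip_over_columns({c: arr[:, c] for c in cols})
    return {pr: full[pr] for pr in pairs}


@dataclass(frozen=True)
class PairStats:
    columns: Tuple[int, int]
    joint_counts: tuple            # 4x4 nested tuple
    statistic: float               # APC-corrected MI, bits
    p_value: float                 # empirical, column-shuffle null
    q_value: float                 # Benjamini-Hochberg across tested pairs
    significant: bool              # p <= alpha


def covariation_significance(
    aln: Alignment,
    pairs: Optional[Sequence[Tuple[int, int]]] = None,
    n_shuffles: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> List[PairStats]:
    """Empirical covariation test for each proposed base pair.

    Null model: independent within-column permutation of rows (destroys the
    pairing signal, preserves per-column composition); the statistic
    (APC-corrected MI) is recomputed over the full pair set per replicate.
    p = fraction of replicates with statistic >= observed.
    """
    if n_shuffles < 100:
        raise AlignmentError("n_shuffles must be >= 100")
    pairs = [tuple(sorted(pr)) for pr in (pairs if pairs is not None
                                          else aln.paired_columns())]
    if not pairs:
        return []
    arr = aln.to_array()
    observed = covariation_mip(aln, pairs)

    rng = np.random.default_rng(seed)
    cols = sorted({c for pr in pairs for c in pr})
    exceed = {pr: 0 for pr in pairs}
    n_eff = {pr: 0 for pr in pairs}
    col_arr = {c: arr[:, c].copy() for c in cols}
    for _ in range(n_shuffles):
        shuffled = {c: rng.permutation(col_arr[c]) for c in cols}
        mi = _mip_over_columns(shuffled)
        for pr in pairs:
            if math.isnan(mi[pr]) or math.isnan(observed[pr]):
                continue
            n_eff[pr] += 1
            if mi[pr] >= observed[pr]:
                exceed[pr] += 1

    pvals = {
        pr: (exceed[pr] / n_eff[pr]) if n_eff[pr] else float("nan") for pr in pairs
    }
    qvals = _benjamini_hochberg(pvals)
    out = []
    for pr in pairs:
        counts = pair_joint_counts(aln, pr)
        out.append(
            PairStats(
                columns=pr,
                joint_counts=tuple(tuple(int(x) for x in row) for row in counts),
                statistic=observed[pr],
                p_value=pvals[pr],
                q_value=qvals[pr],
                significant=(not math.isnan(pvals[pr])) and pvals[pr] <= alpha,
            )
        )
    return out


def _benjamini_hochberg(pvals: Dict, ) -> Dict:
    items = [(k, v) for k, v in pvals.items() if not math.isnan(v)]
    m = len(items)
    if m == 0:
        return dict(pvals)
    items.sort(key=lambda kv: kv[1])
    q = {}
    prev = 1.0
    for rank in range(m, 0, -1):
        k, p = items[rank - 1]
        val = min(prev, p * m / rank)
        q[k] = val
        prev = val
    for k, v in pvals.items():
        if math.isnan(v):
            q[k] = v
    return q


# ---------------------------------------------------------------------------
# junction / helix extension
# ---------------------------------------------------------------------------

def junction_length_distribution(
    aln: Alignment,
    helix2_cols: Sequence[int],
    helix3_cols: Sequence[int],
) -> Tuple[Counter, List[int]]:
    """Per-row count of non-gap characters strictly between helices 2 and 3.

    Junction columns are the non-helix columns inside maximal gaps flanked by
    one helix-2 and one helix-3 column (covers both strands of a nested
    layout).  Ignores non-canonical pairs/indels inside the helices.
    """
    h2, h3 = set(helix2_cols), set(helix3_cols)
    if h2 & h3:
        raise AlignmentError("helix 2 and 3 column sets overlap")
    jcols = _junction_columns(h2, h3)
    lengths = [
        sum(1 for c in jcols if aln.rows[r][c] != "-") for r in range(aln.n_rows)
    ]
    return Counter(lengths), lengths


def _junction_columns(h2: set, h3: set) -> List[int]:
    """Columns lying strictly between adjacent helix-2 / helix-3 columns."""
    marks = sorted((c, 2) for c in h2) + sorted((c, 3) for c in h3)
    marks.sort()
    out = []
    for (c1, t1), (c2, t2) in zip(marks, marks[1:]):
        if t1 != t2 and c2 - c1 > 1:
            out.extend(range(c1 + 1, c2))
    return out


@dataclass
class HelixJunctionRow:
    row_id: str
    excluded: bool
    exclusion_reason: Optional[str]
    junction_len: Optional[int]
    helix2_len: Optional[int]
    helix3_len: Optional[int]
    alternates: Tuple[str, ...] = ()   # e.g. ("junction nt could extend h2 or h3",)


@dataclass
class HelixJunctionReport:
    rows: List[HelixJunctionRow]

    @property
    def n_excluded(self) -> int:
        return sum(r.excluded for r in self.rows)

    @property
    def length_table(self) -> Counter:
        return Counter(
            (r.helix2_len, r.helix3_len) for r in self.rows if not r.excluded
        )


def helix_extension_analysis(
    aln: Alignment,
    helix2_pairs: Sequence[Tuple[int, int]],
    helix3_pairs: Sequence[Tuple[int, int]],
    allow_gu: bool = True,
) -> HelixJunctionReport:
    """Per-row helix 2/3 lengths after junction-nucleotide extension.

    Rows with any non-WC/GU pair or indel inside predicted helix 2 or 3 are
    excluded (counted, not analyzed).  For the remaining rows, junction
    nucleotides are greedily added to whichever adjacent helix they extend
    via a WC/GU pair with the opposite-strand junction nucleotide; when a
    nucleotide could extend either helix, both alternatives are recorded and
    helix 2 takes the primary assignment.
    """
    h2cols = {c for pr in helix2_pairs for c in pr}
    h3cols = {c for pr in helix3_pairs for c in pr}
    jcols = _junction_columns(h2cols, h3cols)
    # split junction columns by strand side: those flanked h2->h3 (strand a)
    # and those flanked h3->h2 (strand b)
    side_a, side_b = [], []
    marks = sorted([(c, "h2") for c in h2cols] + [(c, "h3") for c in h3cols])
    for c in jcols:
        left = max((m for m in marks if m[0] < c), key=lambda m: m[0])
        side = side_a if left[1] == "h2" else side_b
        side.append(c)
    side_a.sort()
    side_b.sort()

    report_rows: List[HelixJunctionRow] = []
    for r in range(aln.n_rows):
        row = aln.rows[r]
        reason = None
        for name, prs in (("helix 2", helix2_pairs), ("helix 3", helix3_pairs)):
            for i, j in prs:
                a, b = row[i], row[j]
                if a == "-" or b == "-":
                    reason = f"indel in {name}"
                    break
                if not pairs_allowed(a, b, allow_gu):
                    reason = f"mismatch in {name}"
                    break
            if reason:
                break
        if reason:
            report_rows.append(
                HelixJunctionRow(aln.ids[r], True, reason, None, None, None)
            )
            continue

        ja = [c for c in side_a if row[c] != "-"]
        jb = [c for c in side_b if row[c] != "-"]
        h2_len = len(helix2_pairs)
        h3_len = len(helix3_pairs)
        alternates: List[str] = []
        # greedy extension from each helix end toward the junction middle
        while ja and jb:
            # candidate pair stacking on helix 2: first of side a, last of side b
            can_h2 = pairs_allowed(row[ja[0]], row[jb[-1]], allow_gu)
            can_h3 = pairs_allowed(row[ja[-1]], row[jb[0]], allow_gu)
            if can_h2 and can_h3 and len(ja) == 1 and len(jb) == 1:
                alternates.append(
                    f"junction pair ({ja[0]},{jb[0]}) could extend helix 2 or helix 3"
                )
                h2_len += 1  # primary assignment
                ja.pop(0)
                jb.pop(-1)
            elif can_h2:
                h2_len += 1
                ja.pop(0)
                jb.pop(-1)
            elif can_h3:
                h3_len += 1
                ja.pop(-1)
                jb.pop(0)
            else:
                break
        junction_left = len(ja) + len(jb)
        report_rows.append(
            HelixJunctionRow(
                aln.ids[r], False, None, junction_left, h2_len, h3_len,
                tuple(alternates),
            )
        )
    return HelixJunctionReport(rows=report_rows)
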