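"""Per-molecule annotation: ribozyme content, cleavage products, ORFs, summary.

Assembles molecule-level reports for inferred circular ssRNAs: hairpin
ribozyme matches on both strands, a both-strand-hairpin flag, simplified
opposite-strand hammerhead/twister patterns, predicted cleavage-product
sizes, a coarse longest-ORF coding heuristic (deliberately NOT a
phylogenetic coding test), and the size/content summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .circular import CircularMolecule
from .motif import (
    CleavageSite,
    HelixClose,
    HelixOpen,
    MotifDescriptor,
    SingleStrand,
    build_default_hairpin_core,
    default_descriptors,
)
from .search import (MotifMatch, collapse_by_cleavage, normalize_rna, revcomp,
                     scan_sequence)

_STOPS = {"UAA", "UAG", "UGA"}


class AnnotationError(ValueError):
    pass


def predict_cleavage_products(
    transcript_length: int, cleavage_pos: int
) -> Tuple[int, int]:
    """5'/3' product lengths for self-cleavage at an inter-nucleotide offset.

    The 5' product spans the transcript start up to the cleavage site; the
    two products always sum to the transcript length.
    """
    if not (0 < cleavage_pos < transcript_length):
        raise AnnotationError(
            f"cleavage at {cleavage_pos} outside transcript of "
            f"{transcript_length} nt (boundary cleavage is not a cleavage)"
        )
    return cleavage_pos, transcript_length - cleavage_pos


# ---------------------------------------------------------------------------
# simplified opposite-strand ribozyme patterns (plumbing for synthetic tests;
# no sensitivity claim on real data)
# ---------------------------------------------------------------------------

def default_opposite_descriptors() -> Dict[str, MotifDescriptor]:
    """Simplified type-III-hammerhead-like and type-P1-twister-like patterns."""
    hammerhead = MotifDescriptor(
        elements=(
            HelixOpen("s1", 3, 6),
            SingleStrand("CUGANGA", 7, 7),
            HelixOpen("s2", 3, 6),
            SingleStrand("N", 3, 8),
            HelixClose("s2"),
            SingleStrand("GAAAY", 5, 5),
            HelixOpen("s3", 3, 6),
            SingleStrand("N", 3, 8),
            HelixClose("s3"),
            SingleStrand("NUH", 3, 3),
            CleavageSite(),
            HelixClose("s1"),
        ),
        permutation="hammerhead-III-like",
    )
    twister = MotifDescriptor(
        elements=(
            HelixOpen("p1", 3, 6),
            SingleStrand("UAAUA", 5, 5),
            HelixOpen("p2", 3, 6),
            SingleStrand("N", 4, 8),
            HelixClose("p2"),
            SingleStrand("GCUGC", 5, 5),
            CleavageSite(),
            SingleStrand("AAAU", 4, 4),
            HelixClose("p1"),
        ),
        permutation="twister-P1-like",
    )
    return {"hammerhead": hammerhead, "twister": twister}


# ---------------------------------------------------------------------------
# ORF heuristic
# ---------------------------------------------------------------------------

def longest_orf(circle_seq: str) -> int:
    """Longest AUG-to-stop ORF (nt, stop excluded) over 6 frames of the circle.

    Scans the doubled sequence so ORFs spanning the rotation origin are seen;
    lengths are capped at the circle length.  Deterministic; returns 0 when
    no AUG-initiated ORF closes with a stop codon.
    """
    s = normalize_rna(circle_seq)
    L = len(s)
    best = 0
    for strand_seq in (s, revcomp(s)):
        doubled = strand_seq + strand_seq
        for frame in range(3):
            starts: List[int] = []
            for i in range(frame, len(doubled) - 2, 3):
                codon = doubled[i:i + 3]
                if codon == "AUG":
                    starts.append(i)
                elif codon in _STOPS:
                    for a in starts:
                        best = max(best, min(i - a, L))
                    starts = []
    return best


# ---------------------------------------------------------------------------
# molecule reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RibozymeAnnotation:
    molecule_id: str
    ribozyme_class: str   # "hairpin" | "hammerhead-III-like" | "twister-P1-like"
    strand: str
    match: MotifMatch


@dataclass
class MoleculeReport:
    molecule_id: str
    length: int
    annotations: List[RibozymeAnnotation]
    both_strand_hairpin: bool
    longest_orf_nt: int
    coding_heuristic: bool        # longest ORF >= threshold; NOT a coding test
    size_bin: Tuple[int, int]

    def class_counts(self) -> Dict[Tuple[str, str], int]:
        out: Dict[Tuple[str, str], int] = {}
        for a in self.annotations:
            key = (a.ribozyme_class, a.strand)
            out[key] = out.get(key, 0) + 1
        return out


def _size_bin(length: int, bin_width: int) -> Tuple[int, int]:
    lo = (length // bin_width) * bin_width
    return (lo, lo + bin_width)


def annotate_molecule(
    circle: CircularMolecule,
    hairpin_descriptors: Optional[Sequence[MotifDescriptor]] = None,
    opposite_descriptors: Optional[Mapping[str, MotifDescriptor]] = None,
    orf_threshold: int = 300,
    bin_width: int = 500,
) -> MoleculeReport:
    """Scan a canonical circle on both strands and assemble its report.

    Scanning is circular, so the report is invariant under rotation of the
    input circle.
    """
    if hairpin_descriptors is None:
        hairpin_descriptors = list(default_descriptors().values())
    if opposite_descriptors is None:
        opposite_descriptors = default_opposite_descriptors()

    hairpin_matches = []
    for desc in hairpin_descriptors:
        hairpin_matches.extend(
            scan_sequence(desc, circle.seq, contig_id=circle.source_contig,
                          circular=True)
        )
    annotations: List[RibozymeAnnotation] = [
        RibozymeAnnotation(circle.source_contig, "hairpin", m.strand, m)
        for m in collapse_by_cleavage(hairpin_matches)
    ]
    for cls, desc in opposite_descriptors.items():
        for m in collapse_by_cleavage(
            scan_sequence(desc, circle.seq, contig_id=circle.source_contig,
                          circular=True)
        ):
            annotations.append(
                RibozymeAnnotation(circle.source_contig, desc.permutation, m.strand, m)
            )

    hairpin_strands = {a.strand for a in annotations if a.ribozyme_class == "hairpin"}
    orf = longest_orf(circle.seq)
    return MoleculeReport(
        molecule_id=circle.source_contig,
        length=circle.length,
        annotations=annotations,
        both_strand_hairpin=hairpin_strands == {"+", "-"},
        longest_orf_nt=orf,
        coding_heuristic=orf >= orf_threshold,
        size_bin=_size_bin(circle.length, bin_width),
    )


def size_content_summary(
    reports: Sequence[MoleculeReport],
) -> pd.DataFrame:
    """Binned size/content table over molecule reports.

    One row per occupied size bin with molecule counts, opposite-strand
    ribozyme class counts, both-strand-hairpin counts and coding-heuristic
    counts; min/max sizes carried as DataFrame attrs.
    """
    if not reports:
        raise AnnotationError("need at least one molecule report")
    rows = []
    for rep in reports:
        counts = rep.class_counts()
        rows.append(
            {
                "bin_lo": rep.size_bin[0],
                "bin_hi": rep.size_bin[1],
                "n": 1,
                "hairpin_plus": counts.get(("hairpin", "+"), 0) > 0,
                "hairpin_minus": counts.get(("hairpin", "-"), 0) > 0,
                "both_strand_hairpin": rep.both_strand_hairpin,
                "opp_hammerhead": counts.get(("hammerhead-III-like", "-"), 0) > 0
                or counts.get(("hammerhead-III-like", "+"), 0) > 0,
                "opp_twister": counts.get(("twister-P1-like", "-"), 0) > 0
                or counts.get(("twister-P1-like", "+"), 0) > 0,
                "coding": rep.coding_heuristic,
            }
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["bin_lo", "bin_hi"], as_index=False)
        .agg(
            n=("n", "sum"),
            hairpin_plus=("hairpin_plus", "sum"),
            hairpin_minus=("hairpin_minus", "sum"),
            both_strand_hairpin=("both_strand_hairpin", "sum"),
            opp_hammerhead=("opp_hammerhead", "sum"),
            opp_twister=("opp_twister", "sum"),
            coding=("coding", "sum"),
        )
        .sort_values("bin_lo")
        .reset_index(drop=True)
    )
    out.attrs["min_size"] = min(r.length for r in reports)
    out.attrs["max_size"] = max(r.length for r in reports)
    return out
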