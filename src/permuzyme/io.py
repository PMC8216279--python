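"""FASTA and tabular I/O for the pipeline (Biopython-backed)."""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .circular import CircularMolecule, Contig
from .search import MotifMatch


def read_fasta(path) -> List[Contig]:
    """Multi-record FASTA -> contigs (T/U tolerant; alphabet validated)."""
    return [Contig(id=rec.id, seq=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[Tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def write_circles_fasta(circles: Iterable[CircularMolecule], path) -> None:
    """Canonical circles, headers tagged |circular."""
    write_fasta(((f"{c.source_contig}|circular", c.seq) for c in circles), path)


def matches_to_frame(matches: Sequence[MotifMatch]) -> pd.DataFrame:
    """Match table; user-facing coordinates are 1-based inclusive."""
    rows = [
        {
            "contig": m.contig_id,
            "strand": m.strand,
            "start": m.start + 1,
            "end": m.end,
            "permutation": m.permutation,
            "cleavage_pos": m.cleavage_pos,
            "score": m.score,
            "contains_n": m.contains_n,
        }
        for m in matches
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "strand", "start", "end", "permutation",
            "cleavage_pos", "score", "contains_n",
        ],
    )
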