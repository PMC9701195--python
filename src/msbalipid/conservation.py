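"""Residue-conservation statistics for alignment columns, plus an N-terminal
Met-His motif survey.

Workflow mirrors a common structure-guided conservation analysis: given a
multiple sequence alignment containing a reference sequence (e.g. E. coli
MsbA), map reference residue positions (1-based, reference numbering such as
R188) to alignment columns by skipping reference gaps, extract those
columns, and compute per-column amino-acid frequencies and information
content in bits — the matrix behind a sequence logo.  Separately, a motif
scan counts sequences whose mature N-terminus begins Met-His, the copper(II)
chelating motif.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment

__all__ = [
    "AMINO_ACIDS",
    "MAX_IC_BITS",
    "SiteProfile",
    "map_reference_positions",
    "site_frequencies",
    "profiles_to_frame",
    "scan_nterm_histidine",
    "read_alignment",
    "read_sequences",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
MAX_IC_BITS = math.log2(20)
_GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class SiteProfile:
    """Amino-acid frequencies and information content of one alignment column.

    Frequencies are normalised over the 20 standard residues only; gaps and
    ambiguous characters (X, B, Z, ...) are tallied as separate fractions of
    the column and excluded from the entropy.  IC = log2(20) - H, in bits.
    """

    position: int          # 1-based reference residue number (0 if unmapped)
    column: int            # 1-based alignment column
    frequencies: tuple[float, ...]  # ordered as AMINO_ACIDS
    gap_fraction: float
    other_fraction: float
    information_bits: float
    n_sequences: int
    empty: bool = False    # column carried no standard residues

    def frequency(self, residue: str) -> float:
        return self.frequencies[AMINO_ACIDS.index(residue.upper())]


def read_alignment(path: str | Path) -> MultipleSeqAlignment:
    return AlignIO.read(str(path), "fasta")


def read_sequences(path: str | Path) -> list:
    return list(SeqIO.parse(str(path), "fasta"))


def _reference_row(alignment: MultipleSeqAlignment, ref_id: str) -> str:
    for rec in alignment:
        if rec.id == ref_id or rec.name == ref_id:
            return str(rec.seq)
    raise KeyError(f"reference id {ref_id!r} not found in alignment")


def map_reference_positions(alignment: MultipleSeqAlignment, ref_id: str,
                            positions: Sequence[int]) -> list[int]:
    """Alignment columns (1-based) of the given reference residue positions.

    Column c hosts reference position p iff the reference row's p-th non-gap
    character sits at column c; the map is a bijection on non-gap reference
    positions, so reference numbering (R188 etc.) carries over directly.
    """
    ref = _reference_row(alignment, ref_id)
    col_of_pos: list[int] = []  # col_of_pos[p-1] = 1-based column of position p
    for col, ch in enumerate(ref, start=1):
        if ch not in _GAP_CHARS:
            col_of_pos.append(col)
    out = []
    for p in positions:
        if not (1 <= p <= len(col_of_pos)):
            raise IndexError(
                f"reference position {p} outside the ungapped reference "
                f"length {len(col_of_pos)}")
        out.append(col_of_pos[p - 1])
    return out


def site_frequencies(alignment: MultipleSeqAlignment,
                     columns: Sequence[int],
                     positions: Sequence[int] | None = None,
                     ) -> list[SiteProfile]:
    """Per-column residue frequencies and information content (bits).

    ``columns`` are 1-based alignment columns (as returned by
    :func:`map_reference_positions`); ``positions`` optionally carries the
    matching reference numbering for labelling.  Residues are matched
    case-insensitively; a column with no standard residues at all is
    returned flagged ``empty`` with zero IC.
    """
    n_seq = len(alignment)
    n_col = alignment.get_alignment_length()
    positions = list(positions) if positions is not None else [0] * len(columns)
    if len(positions) != len(columns):
        raise ValueError("positions and columns must have equal length")
    profiles = []
    for pos, col in zip(positions, columns):
        if not (1 <= col <= n_col):
            raise IndexError(f"column {col} outside alignment width {n_col}")
        chars = [str(rec.seq[col - 1]).upper() for rec in alignment]
        n_gap = sum(c in _GAP_CHARS for c in chars)
        counts = {aa: 0 for aa in AMINO_ACIDS}
        n_other = 0
        for c in chars:
            if c in _GAP_CHARS:
                continue
            if c in counts:
                counts[c] += 1
            else:
                n_other += 1
        n_res = sum(counts.values())
        if n_res == 0:
            profiles.append(SiteProfile(
                position=pos, column=col,
                frequencies=(0.0,) * 20, gap_fraction=n_gap / n_seq,
                other_fraction=n_other / n_seq, information_bits=0.0,
                n_sequences=n_seq, empty=True))
            continue
        freqs = tuple(counts[aa] / n_res for aa in AMINO_ACIDS)
        entropy = -sum(f * math.log2(f) for f in freqs if f > 0)
        profiles.append(SiteProfile(
            position=pos, column=col, frequencies=freqs,
            gap_fraction=n_gap / n_seq, other_fraction=n_other / n_seq,
            information_bits=MAX_IC_BITS - entropy, n_sequences=n_seq))
    return profiles


def profiles_to_frame(profiles: Iterable[SiteProfile]) -> pd.DataFrame:
    """Tidy per-site table (one row per column) for TSV export / logo tools."""
    rows = []
    for p in profiles:
        row = {"position": p.position, "column": p.column}
        row.update({aa: f for aa, f in zip(AMINO_ACIDS, p.frequencies)})
        row.update({
            "gap_fraction": p.gap_fraction,
            "other_fraction": p.other_fraction,
            "information_bits": p.information_bits,
            "n_sequences": p.n_sequences,
            "empty": p.empty,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def scan_nterm_histidine(sequences, motif: str = "MH") -> tuple[list[str], int]:
    """Identifiers (and count) of sequences whose N-terminus matches ``motif``.

    The default motif MH flags a histidine in the second position — the
    arrangement that lets the free alpha-amine and His side chain chelate
    copper(II), as in the GHK plasma peptide.  An extended motif (e.g.
    ``MHK``) can be supplied.  Sequences may be plain strings or SeqRecords;
    empty sequences are skipped with a warning.
    """
    motif = motif.upper()
    matches = []
    for i, seq in enumerate(sequences):
        ident = getattr(seq, "id", None) or f"seq{i + 1}"
        text = str(getattr(seq, "seq", seq)).upper()
        if not text:
            warnings.warn(f"skipping empty sequence {ident!r}", stacklevel=2)
            continue
        if text.startswith(motif):
            matches.append(ident)
    return matches, len(matches)
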