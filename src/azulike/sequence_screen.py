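"""Peptide-level screening by hydrophobic percentage (HPP).

The hydrophobic percentage of a peptide is the percent of its residues that
belong to the fixed nine-letter hydrophobic alphabet {F, I, L, M, V, W, G, C,
A}.  Candidates are retained when their integer-rounded HPP falls inside a
window anchored on two reference values (full-length azurin and its p28
fragment) widened by a symmetric tolerance, by default 2 percentage points,
giving the canonical [44, 51] window.

All rounding in this module is round-half-up, applied to exact rational
arithmetic so that boundary cases (e.g. a raw HPP of 51.22 rounding into a
window that ends at 51) are reproducible and independent of binary floating
point representation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "HYDROPHOBIC_RESIDUES",
    "STANDARD_AMINO_ACIDS",
    "PeptideRecord",
    "HppResult",
    "HppWindow",
    "read_peptide_fasta",
    "hydrophobic_percentage",
    "extract_reference_subpeptide",
    "derive_window",
    "hpp_window_filter",
    "write_hpp_report",
]

#: The nine residues counted as hydrophobic: Phe, Ile, Leu, Met, Val, Trp,
#: Gly, Cys, Ala.  This binary alphabet is the package's only hydrophobicity
#: scale; no continuous scale (GRAVY etc.) is used.
HYDROPHOBIC_RESIDUES = frozenset("FILMVWGCA")

#: The 20 standard one-letter amino-acid codes.  Ambiguity/rare codes
#: (B, Z, X, U, O) are rejected rather than silently classified.
STANDARD_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

assert len(HYDROPHOBIC_RESIDUES) == 9


@dataclass(frozen=True)
class PeptideRecord:
    """One candidate sequence with its provenance labels."""

    seq_id: str
    sequence: str
    bagel_id: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, self.seq_id)
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HppResult:
    """Hydrophobic-percentage breakdown for one sequence."""

    seq_id: str
    length: int
    hydrophobic_count: int
    hpp_raw: float  # percent, un-rounded
    hpp: int  # percent, rounded half-up


@dataclass(frozen=True)
class HppWindow:
    """Inclusive integer-percent retention window around reference HPPs."""

    low: int
    high: int
    tolerance: int = 2
    reference_hpps: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"empty window [{self.low}, {self.high}]")

    def contains(self, hpp: int) -> bool:
        return self.low <= hpp <= self.high


def validate_sequence(sequence: str, seq_id: str = "<anonymous>") -> None:
    """Raise ``ValueError`` unless *sequence* is a non-empty standard-residue string."""
    if not sequence:
        raise ValueError(f"record {seq_id!r}: empty sequence")
    bad = set(sequence) - STANDARD_AMINO_ACIDS
    if bad:
        raise ValueError(
            f"record {seq_id!r}: non-standard amino-acid character(s) "
            f"{sorted(bad)!r} in sequence"
        )


def _round_half_up(value: Fraction) -> int:
    """Round a non-negative rational half-up to the nearest integer."""
    num, den = value.numerator, value.denominator
    return (2 * num + den) // (2 * den)


def read_peptide_fasta(path: str | Path) -> list[PeptideRecord]:
    """Read peptides from FASTA with ``seq_id|bagel_id|species`` headers.

    Only ``seq_id`` is mandatory; trailing header fields may be absent or
    empty.  Sequences are uppercased and whitespace-stripped.  Duplicate ids,
    empty sequences and non-standard residues raise ``ValueError``.
    """
    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        fields = entry.description.split("|")
        seq_id = fields[0].strip()
        bagel_id = fields[1].strip() or None if len(fields) > 1 else None
        species = fields[2].strip() or None if len(fields) > 2 else None
        if seq_id in seen:
            raise ValueError(f"duplicate seq_id {seq_id!r} in {path}")
        seen.add(seq_id)
        sequence = re.sub(r"\s", "", str(entry.seq)).upper()
        records.append(
            PeptideRecord(seq_id=seq_id, sequence=sequence,
                          bagel_id=bagel_id, species=species)
        )
    return records


def hydrophobic_percentage(sequence: str, seq_id: str = "") -> HppResult:
    """Compute the hydrophobic percentage of *sequence*.

    ``hpp_raw`` is ``100 * hydrophobic_count / length``; ``hpp`` is its
    half-up integer rounding, computed in exact rational arithmetic.
    """
    validate_sequence(sequence, seq_id or "<anonymous>")
    count = sum(residue in HYDROPHOBIC_RESIDUES for residue in sequence)
    raw = Fraction(100 * count, len(sequence))
    return HppResult(
        seq_id=seq_id,
        length=len(sequence),
        hydrophobic_count=count,
        hpp_raw=float(raw),
        hpp=_round_half_up(raw),
    )


def extract_reference_subpeptide(parent: str, documented_sub: str) -> tuple[str, int]:
    """Locate a documented subpeptide inside its parent sequence.

    Returns ``(matched_substring, start)`` with a 1-based start position.
    Anchoring by exact substring search makes the result independent of
    whether *parent* uses precursor or mature numbering (the azurin precursor
    carries a 20-residue offset relative to mature numbering).  An absent or
    ambiguous (multiply occurring) subpeptide is an error.
    """
    if not documented_sub:
        raise ValueError("documented subpeptide must be non-empty")
    first = parent.find(documented_sub)
    if first < 0:
        raise ValueError(
            f"subpeptide {documented_sub[:12]!r}... not found in parent sequence"
        )
    if parent.find(documented_sub, first + 1) >= 0:
        raise ValueError(
            f"subpeptide {documented_sub[:12]!r}... occurs more than once; "
            "anchor is ambiguous"
        )
    return documented_sub, first + 1


def derive_window(
    reference_hpps: Sequence[int], tolerance: int = 2
) -> HppWindow:
    """Build the retention window ``[min(refs) - tol, max(refs) + tol]``."""
    if not reference_hpps:
        raise ValueError("need at least one reference HPP")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    refs = tuple(sorted(int(h) for h in reference_hpps))
    return HppWindow(
        low=min(refs) - tolerance,
        high=max(refs) + tolerance,
        tolerance=tolerance,
        reference_hpps=refs,
    )


def hpp_window_filter(
    records: Iterable[PeptideRecord], window: HppWindow
) -> tuple[list[PeptideRecord], list[tuple[HppResult, bool]]]:
    """Filter records by integer-rounded HPP against an inclusive window.

    Returns ``(retained_records, report)`` where *report* pairs every input
    record's :class:`HppResult` with its retained/rejected flag, in input
    order.
    """
    retained: list[PeptideRecord] = []
    report: list[tuple[HppResult, bool]] = []
    for record in records:
        result = hydrophobic_percentage(record.sequence, record.seq_id)
        keep = window.contains(result.hpp)
        report.append((result, keep))
        if keep:
            retained.append(record)
    return retained, report


def write_hpp_report(
    path: str | Path, report: list[tuple[HppResult, bool]], window: HppWindow
) -> None:
    """Write the per-record HPP report as TSV."""
    header = (
        "seq_id\tlength\thydrophobic_count\thpp_raw\thpp\tretained"
        "\twindow_low\twindow_high"
    )
    lines = [header]
    for result, keep in report:
        lines.append(
            f"{result.seq_id}\t{result.length}\t{result.hydrophobic_count}"
            f"\t{result.hpp_raw:.4f}\t{result.hpp}\t{str(keep).lower()}"
            f"\t{window.low}\t{window.high}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
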