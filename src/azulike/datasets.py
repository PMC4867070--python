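"""Bundled reference data for the azurin-like screen.

Ships the published screening panel as plain-text package data: the 14
candidate bacteriocin sequences with their BAGEL provenance, the azurin and
p28 reference sequences, the published per-sequence hydrophobic percentages,
and the published binding-interface comparison table (per-candidate shared
receptor-residue counts against the p28 and azurin reference interfaces plus
polar/nonpolar interface atom percentages).

The reference interfaces themselves are not redistributable, but their sizes
are implied by the published overlap percentages; :func:`recover_reference_sizes`
recovers them by exhaustive search for the unique integer denominators
consistent with every printed percentage.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .sequence_screen import PeptideRecord, read_peptide_fasta

__all__ = [
    "candidate_peptides",
    "reference_peptides",
    "azurin_sequence",
    "p28_sequence",
    "published_hpp",
    "published_interface_table",
    "recover_reference_sizes",
]


def _data_path(name: str):
    return resources.files("azulike.data") / name


def candidate_peptides() -> list[PeptideRecord]:
    """The 14 screened candidate bacteriocins, in published panel order."""
    with resources.as_file(_data_path("candidates.fasta")) as path:
        return read_peptide_fasta(path)


def reference_peptides() -> list[PeptideRecord]:
    """The reference sequences: full-length azurin and its p28 fragment."""
    with resources.as_file(_data_path("references.fasta")) as path:
        return read_peptide_fasta(path)


def azurin_sequence() -> str:
    return next(r.sequence for r in reference_peptides() if r.seq_id == "azurin")


def p28_sequence() -> str:
    return next(r.sequence for r in reference_peptides() if r.seq_id == "p28-azurin")


def published_hpp() -> dict[str, int]:
    """Published integer hydrophobic percentages, keyed by seq_id."""
    with resources.as_file(_data_path("table1_hpp.tsv")) as path:
        frame = pd.read_csv(path, sep="\t")
    return dict(zip(frame["seq_id"], frame["hpp"].astype(int)))


def published_interface_table() -> pd.DataFrame:
    """Published per-candidate binding-interface comparison table."""
    with resources.as_file(_data_path("table2_interface.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def recover_reference_sizes(
    table: pd.DataFrame | None = None,
    max_size: int = 400,
    tolerance: float = 0.005,
) -> dict[str, int]:
    """Recover the p28/azurin reference-interface sizes from overlap percentages.

    For each reference column, searches all integer denominators d in
    [1, max_size] such that 100 * shared / d reproduces every non-zero
    printed percentage to within *tolerance* (half a unit in the last
    printed decimal place).  Raises if no denominator, or more than one,
    is consistent.
    """
    if table is None:
        table = published_interface_table()
    sizes: dict[str, int] = {}
    for name, count_col, pct_col in (
        ("p28", "shared_p28", "pct_p28"),
        ("azurin", "shared_azurin", "pct_azurin"),
    ):
        rows = [
            (int(c), float(p))
            for c, p in zip(table[count_col], table[pct_col])
            if int(c) > 0
        ]
        candidates = [
            d
            for d in range(1, max_size + 1)
            if all(abs(100.0 * c / d - p) <= tolerance + 1e-12 for c, p in rows)
        ]
        if len(candidates) != 1:
            raise ValueError(
                f"reference {name!r}: {len(candidates)} consistent interface "
                f"sizes found ({candidates[:5]}...), expected exactly one"
            )
        sizes[name] = candidates[0]
    return sizes
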