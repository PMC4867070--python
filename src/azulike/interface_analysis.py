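"""Binding-interface extraction and comparison for docked two-chain complexes.

A docked pose is a receptor chain (the p53 DNA-binding domain in the
screening application) plus a ligand chain (a candidate bacteriocin, or the
p28/azurin reference).  The binding interface is defined by a heavy-atom
contact criterion: every (receptor atom, ligand atom) pair at Euclidean
distance <= cutoff (default 5.0 A, inclusive) is a contact, and the residues
owning contacting atoms form the per-side interface residue sets.

Candidate poses are compared against reference interfaces by intersecting
receptor-side residue sets (residues are matched by chain id, residue number
and insertion code — all compared complexes share the receptor numbering, so
no alignment is attempted).  A candidate binds "in the same region" as the
references when it shares at least one receptor residue with each reference
interface.

Interface atom composition is summarised as percent polar vs nonpolar unique
heavy atoms per side, with the minimal element-based rule N/O polar and C/S
nonpolar; other heavy elements count as polar with a logged warning.  The
rule is isolated in :func:`atom_polarity` so an alternative convention can be
substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ComplexModel",
    "InterfaceParams",
    "BindingInterface",
    "OverlapResult",
    "CompositionResult",
    "read_complex_pdb",
    "compute_interface",
    "atom_polarity",
    "interface_composition",
    "overlap_with_reference",
    "classify_azurin_like",
    "comparison_report",
    "save_interface_residues",
    "load_interface_residues",
]

#: residue identifier: (chain id, residue number, insertion code)
ResidueId = tuple[str, int, str]
#: atom identifier: (chain id, residue number, insertion code, atom name)
AtomId = tuple[str, int, str, str]


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    resseq: int
    icode: str
    resname: str
    name: str
    element: str
    coord: tuple[float, float, float]

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain, self.resseq, self.icode)

    @property
    def atom_id(self) -> AtomId:
        return (self.chain, self.resseq, self.icode, self.name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class ComplexModel:
    """Atoms of a two-chain docked pose with designated receptor/ligand."""

    atoms: list[AtomRecord]
    receptor_chain: str
    ligand_chain: str

    def __post_init__(self) -> None:
        chains = {a.chain for a in self.atoms}
        for label, chain in (("receptor", self.receptor_chain),
                             ("ligand", self.ligand_chain)):
            if chain not in chains:
                raise ValueError(f"{label} chain {chain!r} absent from model")
        for a in self.atoms:
            if not all(np.isfinite(a.coord)):
                raise ValueError(f"non-finite coordinates on atom {a.atom_id}")

    def heavy_atoms(self, chain: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain == chain and not a.is_hydrogen]

    def atom_by_id(self, atom_id: AtomId) -> AtomRecord:
        for a in self.atoms:
            if a.atom_id == atom_id:
                return a
        raise KeyError(atom_id)


@dataclass(frozen=True)
class InterfaceParams:
    """Contact criterion: heavy-atom distance cutoff in Angstrom, inclusive."""

    cutoff: float = 5.0
    heavy_atoms_only: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass(frozen=True)
class BindingInterface:
    receptor_residues: frozenset[ResidueId]
    ligand_residues: frozenset[ResidueId]
    contact_pairs: frozenset[tuple[AtomId, AtomId]]
    params: InterfaceParams = field(default=InterfaceParams())


@dataclass(frozen=True)
class OverlapResult:
    """Receptor-residue intersection of a query interface with a reference."""

    shared_count: int
    reference_size: int
    overlap_percent: float  # 100 * shared / reference_size, 2 d.p. half-up


@dataclass(frozen=True)
class CompositionResult:
    """Percent polar/nonpolar unique interface heavy atoms, per side."""

    ligand_polar: float
    ligand_nonpolar: float
    receptor_polar: float
    receptor_nonpolar: float


def _pct(numerator: int, denominator: int) -> float:
    """Exact percentage rounded half-up to 2 decimal places."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    value = Fraction(10000 * numerator, denominator)
    num, den = value.numerator, value.denominator
    return ((2 * num + den) // (2 * den)) / 100.0


def read_complex_pdb(
    path: str | Path, receptor_chain: str, ligand_chain: str
) -> ComplexModel:
    """Load the two designated chains of a PDB file into a :class:`ComplexModel`.

    Only the first model of multi-model files is read.  Alternate locations
    are resolved to the highest-occupancy conformer (falling back to the
    first-encountered altloc on occupancy ties, i.e. normally 'A').
    Hydrogens are retained in the model but ignored by all interface
    operations.
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("complex", str(path))
    except Exception as exc:  # PDBConstructionException carries the line no.
        raise ValueError(f"{path}: unparseable PDB record ({exc})") from exc
    models = list(structure.get_models())
    if not models:
        raise ValueError(f"{path}: no coordinate models found")
    model = models[0]
    atoms: list[AtomRecord] = []
    wanted = {receptor_chain, ligand_chain}
    for chain in model:
        if chain.id not in wanted:
            continue
        for residue in chain:
            _, resseq, icode = residue.id
            for atom in residue.get_atoms():
                # disordered atoms yield their selected (highest-occupancy) child
                element = (atom.element or "").strip().upper()
                x, y, z = (float(v) for v in atom.coord)
                atoms.append(
                    AtomRecord(
                        chain=chain.id,
                        resseq=int(resseq),
                        icode=icode.strip(),
                        resname=residue.resname.strip(),
                        name=atom.get_name().strip(),
                        element=element,
                        coord=(x, y, z),
                    )
                )
    present = {a.chain for a in atoms}
    for label, chain_id in (("receptor", receptor_chain), ("ligand", ligand_chain)):
        if chain_id not in present:
            raise ValueError(f"{path}: {label} chain {chain_id!r} not found")
    return ComplexModel(atoms=atoms, receptor_chain=receptor_chain,
                        ligand_chain=ligand_chain)


def compute_interface(
    model: ComplexModel, params: InterfaceParams | None = None
) -> BindingInterface:
    """Extract the binding interface at the given contact cutoff.

    The contract is defined by the brute-force all-pairs distance scan; a
    k-d tree is used for the neighbour search but returns the identical
    inclusive-boundary contact set.
    """
    params = params or InterfaceParams()
    rec = model.heavy_atoms(model.receptor_chain)
    lig = model.heavy_atoms(model.ligand_chain)
    pairs: set[tuple[AtomId, AtomId]] = set()
    if rec and lig:
        rec_xyz = np.array([a.coord for a in rec])
        lig_xyz = np.array([a.coord for a in lig])
        tree = cKDTree(lig_xyz)
        for i, neighbours in enumerate(
            tree.query_ball_point(rec_xyz, r=params.cutoff)
        ):
            for j in neighbours:
                pairs.add((rec[i].atom_id, lig[j].atom_id))
    receptor_residues = frozenset(p[0][:3] for p in pairs)
    ligand_residues = frozenset(p[1][:3] for p in pairs)
    return BindingInterface(
        receptor_residues=receptor_residues,
        ligand_residues=ligand_residues,
        contact_pairs=frozenset(pairs),
        params=params,
    )


def atom_polarity(element: str, atom_name: str = "") -> str:
    """Classify one heavy atom as ``"polar"`` or ``"nonpolar"``.

    N and O are polar; C and S nonpolar; any other heavy element is counted
    polar with a logged warning.  Hydrogens must be filtered out by the
    caller and raise ``ValueError`` here.
    """
    element = element.strip().upper()
    if element in ("H", "D"):
        raise ValueError(f"hydrogen atom {atom_name!r} passed to atom_polarity")
    if element in ("N", "O"):
        return "polar"
    if element in ("C", "S"):
        return "nonpolar"
    logger.warning("element %r (atom %r): no polarity rule, counting as polar",
                   element, atom_name)
    return "polar"


def interface_composition(
    interface: BindingInterface, model: ComplexModel
) -> CompositionResult:
    """Percent polar vs nonpolar unique interface heavy atoms per side."""
    if not interface.contact_pairs:
        raise ValueError("empty interface has no atom composition")
    sides = {
        "receptor": {p[0] for p in interface.contact_pairs},
        "ligand": {p[1] for p in interface.contact_pairs},
    }
    percents: dict[str, tuple[float, float]] = {}
    for side, atom_ids in sides.items():
        polar = 0
        for atom_id in atom_ids:
            atom = model.atom_by_id(atom_id)
            if atom_polarity(atom.element, atom.name) == "polar":
                polar += 1
        total = len(atom_ids)
        percents[side] = (_pct(polar, total), _pct(total - polar, total))
    return CompositionResult(
        ligand_polar=percents["ligand"][0],
        ligand_nonpolar=percents["ligand"][1],
        receptor_polar=percents["receptor"][0],
        receptor_nonpolar=percents["receptor"][1],
    )


def _receptor_residues(
    interface: "BindingInterface | frozenset[ResidueId] | set[ResidueId]",
) -> frozenset[ResidueId]:
    if isinstance(interface, BindingInterface):
        return interface.receptor_residues
    return frozenset(interface)


def overlap_with_reference(
    query: BindingInterface | frozenset[ResidueId],
    reference: BindingInterface | frozenset[ResidueId],
) -> OverlapResult:
    """Count receptor residues the query interface shares with a reference.

    The percentage is taken over the reference interface size.  Residues
    must be identified on the same receptor numbering.
    """
    query_res = _receptor_residues(query)
    ref_res = _receptor_residues(reference)
    if not ref_res:
        raise ValueError("reference interface is empty")
    shared = len(query_res & ref_res)
    return OverlapResult(
        shared_count=shared,
        reference_size=len(ref_res),
        overlap_percent=_pct(shared, len(ref_res)),
    )


def classify_azurin_like(
    overlap_p28: OverlapResult, overlap_azurin: OverlapResult
) -> bool:
    """A candidate binds "in the same region" as the references when it
    shares >= 1 receptor interface residue with both of them."""
    return overlap_p28.shared_count > 0 and overlap_azurin.shared_count > 0


def comparison_report(
    rows: Sequence[Mapping[str, object]], path: str | Path | None = None
) -> pd.DataFrame:
    """Assemble (and optionally write as TSV) the per-candidate comparison table.

    Each row mapping must carry: seq_id, size, shared_p28, pct_p28,
    shared_azurin, pct_azurin, polar_pct_ligand, nonpolar_pct_ligand,
    polar_pct_receptor, nonpolar_pct_receptor, selected.
    """
    columns = [
        "seq_id", "size", "shared_p28", "pct_p28", "shared_azurin",
        "pct_azurin", "polar_pct_ligand", "nonpolar_pct_ligand",
        "polar_pct_receptor", "nonpolar_pct_receptor", "selected",
    ]
    frame = pd.DataFrame(list(rows), columns=columns)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False, float_format="%.2f")
    return frame


def save_interface_residues(
    path: str | Path, interface: BindingInterface | frozenset[ResidueId]
) -> None:
    """Store an interface's receptor residue identifiers as TSV."""
    residues = sorted(_receptor_residues(interface))
    lines = ["chain\tresseq\ticode"]
    lines += [f"{c}\t{r}\t{i}" for c, r, i in residues]
    Path(path).write_text("\n".join(lines) + "\n")


def load_interface_residues(path: str | Path) -> frozenset[ResidueId]:
    """Load receptor residue identifiers stored by :func:`save_interface_residues`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["chain", "resseq", "icode"]:
        raise ValueError(f"{path}: bad interface-residue header")
    residues = set()
    for line in lines[1:]:
        if not line.strip():
            continue
        chain, resseq, *rest = line.split("\t")
        icode = rest[0] if rest else ""
        residues.add((chain, int(resseq), icode))
    return frozenset(residues)
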