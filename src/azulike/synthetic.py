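"""Seeded synthetic inputs with planted ground truth for every pipeline stage.

Real counterparts of two pipeline inputs are not redistributable: the
per-sequence functional-annotation odds of the original 81-candidate screen,
and the docked candidate/p53 poses.  This module generates stand-ins whose
ground truth is known by construction, so every stage can be tested for
exact recovery:

* peptides with an exact planted hydrophobic count per sequence;
* annotation tables with a planted azurin-like subset whose three-category
  odds product exceeds 1 (background products below 1), and probabilities
  set to odds times a fixed per-group prior so odds- and probability-scores
  are exactly collinear;
* two-chain PDB complexes built from single-atom pseudo-residues, with
  planted contacts at cutoff - 0.5 A and decoys beyond 2 x cutoff, so the
  interface detector must recover the planted receptor residue set exactly.

The geometry is deliberately unphysical (no rotamers, no sterics): it
isolates the contact arithmetic from everything a docking engine does.
All generators are deterministic given a spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .function_score import GROUPS, AnnotationEntry, AnnotationSet
from .interface_analysis import AtomRecord, ComplexModel
from .sequence_screen import HYDROPHOBIC_RESIDUES, STANDARD_AMINO_ACIDS, PeptideRecord

__all__ = [
    "SyntheticSpec",
    "ComplexGroundTruth",
    "generate_peptides",
    "generate_annotation_table",
    "generate_complex",
    "write_annotation_tsv",
    "write_peptide_fasta",
    "complex_to_pdb",
    "generate_overlap_scenario",
    "REFERENCE_PRIORS",
]

_NONHYDROPHOBIC = "".join(sorted(STANDARD_AMINO_ACIDS - HYDROPHOBIC_RESIDUES))
_HYDROPHOBIC = "".join(sorted(HYDROPHOBIC_RESIDUES))

#: Fixed per-group priors linking synthetic probabilities to odds
#: (probability = odds * prior).  Chosen so probability <= 1 for any odds the
#: generator can draw (max 10).
REFERENCE_PRIORS = {"F": 0.05, "EZ": 0.08, "GO": 0.1}

#: The control's reference categories used by all synthetic annotation sets.
_REF_CATEGORIES = {"F": "Cell_envelope", "EZ": "Nonenzyme", "GO": "Immune_response"}

#: Control odds emulating a cupredoxin-like annotation profile.
_CONTROL_ODDS = {"F": 9.71, "EZ": 1.147, "GO": 5.877}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults mirror the screening study's conditions: 81 annotated
    candidates of which 28 are planted azurin-like, planted odds above 1.1
    and background odds below 0.9 per category, and a 5.0 A contact cutoff.
    """

    seed: int = 0
    n_peptides: int = 20
    length_range: tuple[int, int] = (30, 80)
    target_hpp: int | str = 49  # integer percent, or "random"
    n_annotated: int = 81
    n_planted: int = 28
    planted_odds_range: tuple[float, float] = (1.1, 10.0)
    background_odds_range: tuple[float, float] = (0.1, 0.9)
    receptor_residues: int = 20
    planted_contacts: frozenset[int] = frozenset({3, 7, 9})
    cutoff: float = 5.0

    def __post_init__(self) -> None:
        if self.planted_odds_range[0] <= 1.0:
            raise ValueError("planted odds range must lie strictly above 1")
        if self.background_odds_range[1] >= 1.0:
            raise ValueError("background odds range must lie strictly below 1")
        if self.n_planted > self.n_annotated:
            raise ValueError("n_planted exceeds n_annotated")
        if not set(self.planted_contacts) <= set(range(1, self.receptor_residues + 1)):
            raise ValueError("planted contacts outside receptor residue range")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _planted_hydro_count(length: int, target_hpp: int) -> int:
    """Half-up rounding of length * target / 100, exactly."""
    value = Fraction(length * target_hpp, 100)
    num, den = value.numerator, value.denominator
    return (2 * num + den) // (2 * den)


def generate_peptides(
    spec: SyntheticSpec,
) -> tuple[list[PeptideRecord], list[dict]]:
    """Generate peptides with an exactly planted hydrophobic count.

    Each sequence of length L carries round(L * target_hpp / 100) residues
    drawn from the hydrophobic alphabet and the rest from the 11 remaining
    letters, uniformly shuffled.  Returns the records and a ground-truth
    table (one dict per record: seq_id, length, hydrophobic_count, hpp).
    """
    rng = spec.rng()
    lo, hi = spec.length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad length range {spec.length_range}")
    records: list[PeptideRecord] = []
    truth: list[dict] = []
    for i in range(spec.n_peptides):
        length = int(rng.integers(lo, hi + 1))
        if spec.target_hpp == "random":
            n_hydro = int(rng.integers(0, length + 1))
        else:
            target = int(spec.target_hpp)
            if not 0 <= target <= 100:
                raise ValueError(f"target HPP {target} not achievable")
            n_hydro = _planted_hydro_count(length, target)
        letters = [
            _HYDROPHOBIC[k] for k in rng.integers(0, len(_HYDROPHOBIC), n_hydro)
        ] + [
            _NONHYDROPHOBIC[k]
            for k in rng.integers(0, len(_NONHYDROPHOBIC), length - n_hydro)
        ]
        order = rng.permutation(length)
        sequence = "".join(letters[k] for k in order)
        seq_id = f"syn{i + 1:03d}"
        records.append(PeptideRecord(seq_id=seq_id, sequence=sequence))
        hpp_fraction = Fraction(100 * n_hydro, length)
        truth.append(
            {
                "seq_id": seq_id,
                "length": length,
                "hydrophobic_count": n_hydro,
                "hpp": (2 * hpp_fraction.numerator + hpp_fraction.denominator)
                // (2 * hpp_fraction.denominator),
            }
        )
    return records, truth


def generate_annotation_table(
    spec: SyntheticSpec, control_id: str = "azurin"
) -> tuple[AnnotationSet, list[str]]:
    """Generate an annotation table with a planted azurin-like subset.

    Planted ids draw all three category odds from ``planted_odds_range``
    (product > 1 guaranteed); background ids draw from
    ``background_odds_range`` (product < 1).  Probabilities equal odds times
    the fixed per-group prior, so probability scores are an exact affine
    shift of odds scores (Pearson r = 1).  The control receives its
    canonical odds plus one lower-odds decoy category per group.

    Returns the set and the sorted planted id list.
    """
    rng = spec.rng()
    ids = [f"seq{i + 1:03d}" for i in range(spec.n_annotated)]
    planted = sorted(
        rng.choice(spec.n_annotated, size=spec.n_planted, replace=False).tolist()
    )
    planted_ids = [ids[k] for k in planted]
    planted_set = set(planted_ids)

    annotations = AnnotationSet()
    for group in GROUPS:
        category = _REF_CATEGORIES[group]
        prior = REFERENCE_PRIORS[group]
        odds = _CONTROL_ODDS[group]
        annotations.add(
            AnnotationEntry(control_id, group, category, round(odds * prior, 6), odds)
        )
        # a decoy category keeps reference_categories from being vacuous
        annotations.add(
            AnnotationEntry(control_id, group, f"Decoy_{group}", 0.01, 0.05)
        )
    for seq_id in ids:
        lo, hi = (
            spec.planted_odds_range
            if seq_id in planted_set
            else spec.background_odds_range
        )
        for group in GROUPS:
            odds = float(rng.uniform(lo, hi))
            prior = REFERENCE_PRIORS[group]
            annotations.add(
                AnnotationEntry(
                    seq_id, group, _REF_CATEGORIES[group],
                    round(odds * prior, 9), round(odds, 9),
                )
            )
    return annotations, sorted(planted_ids)


def generate_screen_annotations(
    planted_ids: Sequence[str],
    background_ids: Sequence[str],
    seed: int = 0,
    control_id: str = "azurin",
    planted_odds_range: tuple[float, float] = (1.1, 10.0),
    background_odds_range: tuple[float, float] = (0.1, 0.9),
) -> AnnotationSet:
    """Like :func:`generate_annotation_table` but with caller-chosen ids.

    Used to plant a known azurin-like subset among a mixed panel (e.g. real
    candidate ids plus synthetic background ids).
    """
    if set(planted_ids) & set(background_ids):
        raise ValueError("planted and background id sets overlap")
    rng = np.random.default_rng(seed)
    annotations = AnnotationSet()
    for group in GROUPS:
        category = _REF_CATEGORIES[group]
        prior = REFERENCE_PRIORS[group]
        odds = _CONTROL_ODDS[group]
        annotations.add(
            AnnotationEntry(control_id, group, category, round(odds * prior, 6), odds)
        )
        annotations.add(
            AnnotationEntry(control_id, group, f"Decoy_{group}", 0.01, 0.05)
        )
    for seq_id in list(planted_ids) + list(background_ids):
        lo, hi = (
            planted_odds_range if seq_id in set(planted_ids)
            else background_odds_range
        )
        for group in GROUPS:
            odds = float(rng.uniform(lo, hi))
            prior = REFERENCE_PRIORS[group]
            annotations.add(
                AnnotationEntry(
                    seq_id, group, _REF_CATEGORIES[group],
                    round(odds * prior, 9), round(odds, 9),
                )
            )
    return annotations


@dataclass(frozen=True)
class ComplexGroundTruth:
    """Planted truth for one generated complex."""

    receptor_residues: frozenset[int]  # planted contact residues (chain A)
    ligand_interface_elements: tuple[str, ...]  # elements of contact ligand atoms
    cutoff: float


def generate_complex(
    spec: SyntheticSpec,
    n_decoy_ligand: int = 5,
    ligand_interface_elements: Sequence[str] | None = None,
    receptor_element: str = "C",
) -> tuple[ComplexModel, ComplexGroundTruth]:
    """Build a two-chain complex with an exactly planted interface.

    The receptor (chain A) is a line of single-atom pseudo-residues spaced
    2.5 x cutoff apart, so no two receptor positions can share a ligand
    contact.  Each planted contact residue gets one ligand atom at distance
    cutoff - 0.5 A; decoy ligand atoms sit 5 x cutoff away from the receptor
    axis.  Elements of the contact ligand atoms can be prescribed to realise
    a requested polar/nonpolar interface composition (default: all N, i.e.
    fully polar ligand side).
    """
    if not spec.planted_contacts:
        raise ValueError("planted contact set must be non-empty")
    cutoff = spec.cutoff
    spacing = 2.5 * cutoff
    if cutoff <= 0.5:
        raise ValueError("cutoff too small to place contacts at cutoff - 0.5")
    planted = sorted(spec.planted_contacts)
    if ligand_interface_elements is None:
        ligand_interface_elements = ["N"] * len(planted)
    if len(ligand_interface_elements) != len(planted):
        raise ValueError(
            "need one ligand interface element per planted contact residue"
        )
    atoms: list[AtomRecord] = []
    for r in range(1, spec.receptor_residues + 1):
        atoms.append(
            AtomRecord(
                chain="A", resseq=r, icode="", resname="ALA", name="CA",
                element=receptor_element, coord=(spacing * r, 0.0, 0.0),
            )
        )
    lig_resseq = 0
    for r, element in zip(planted, ligand_interface_elements):
        lig_resseq += 1
        atoms.append(
            AtomRecord(
                chain="B", resseq=lig_resseq, icode="", resname="GLY", name="X1",
                element=element, coord=(spacing * r, cutoff - 0.5, 0.0),
            )
        )
    for d in range(n_decoy_ligand):
        lig_resseq += 1
        atoms.append(
            AtomRecord(
                chain="B", resseq=lig_resseq, icode="", resname="GLY", name="X1",
                element="C", coord=(spacing * (d + 1), 5.0 * cutoff, 0.0),
            )
        )
    model = ComplexModel(atoms=atoms, receptor_chain="A", ligand_chain="B")
    truth = ComplexGroundTruth(
        receptor_residues=frozenset(planted),
        ligand_interface_elements=tuple(ligand_interface_elements),
        cutoff=cutoff,
    )
    return model, truth


def complex_to_pdb(model: ComplexModel, path: str | Path) -> None:
    """Serialise a :class:`ComplexModel` as minimal standard PDB coordinates."""
    lines = []
    serial = 0
    last_chain = None
    for atom in model.atoms:
        if last_chain is not None and atom.chain != last_chain:
            lines.append("TER")
        last_chain = atom.chain
        serial += 1
        x, y, z = atom.coord
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {name}{'':1s}{atom.resname:>3s} {atom.chain:1s}"
            f"{atom.resseq:4d}{atom.icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{atom.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_peptide_fasta(records: Sequence[PeptideRecord], path: str | Path) -> None:
    """Serialise peptides in the pipe-delimited FASTA header dialect."""
    lines = []
    for rec in records:
        lines.append(f">{rec.seq_id}|{rec.bagel_id or ''}|{rec.species or ''}")
        seq = rec.sequence
        lines += [seq[i:i + 60] for i in range(0, len(seq), 60)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_annotation_tsv(annotations: AnnotationSet, path: str | Path) -> None:
    """Serialise an annotation set in the parser's TSV dialect (sorted keys)."""
    lines = ["seq_id\tgroup\tcategory\tprobability\todds"]
    for entry in sorted(annotations, key=lambda e: (e.seq_id, e.group, e.category)):
        lines.append(
            f"{entry.seq_id}\t{entry.group}\t{entry.category}"
            f"\t{entry.probability:.9g}\t{entry.odds:.9g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Whole-screen scenario with a planted interface-overlap pattern
# ---------------------------------------------------------------------------

#: Receptor-side regions used to plant overlap patterns (residue numbers on
#: a 60-residue pseudo-receptor).  The p28 reference interface is residues
#: 1-30 (size 30) and the azurin reference 20-44 (size 25) — the reference
#: sizes implied by the published overlap percentages.
_P28_REFERENCE = frozenset(range(1, 31))
_AZURIN_REFERENCE = frozenset(range(20, 45))
_SCENARIO_RECEPTOR = 60


def _plant_contacts(shared_p28: int, shared_azurin: int) -> frozenset[int]:
    """Choose a contact set with prescribed intersections with both references."""
    both = sorted(_P28_REFERENCE & _AZURIN_REFERENCE)          # 20..30
    p28_only = sorted(_P28_REFERENCE - _AZURIN_REFERENCE)      # 1..19
    az_only = sorted(_AZURIN_REFERENCE - _P28_REFERENCE)       # 31..44
    neither = sorted(
        set(range(1, _SCENARIO_RECEPTOR + 1)) - _P28_REFERENCE - _AZURIN_REFERENCE
    )
    b = min(shared_p28, shared_azurin, len(both))
    x = shared_p28 - b
    y = shared_azurin - b
    if x > len(p28_only) or y > len(az_only):
        raise ValueError(
            f"overlap pattern ({shared_p28}, {shared_azurin}) infeasible on "
            "the scenario receptor"
        )
    contacts = set(p28_only[:x]) | set(both[:b]) | set(az_only[:y])
    if not contacts:
        contacts = set(neither[:3])  # non-empty interface overlapping nothing
    return frozenset(contacts)


def generate_overlap_scenario(
    targets: Mapping[str, tuple[int, int]],
    out_dir: str | Path,
    seed: int = 0,
    cutoff: float = 5.0,
) -> dict[str, Path]:
    """Generate reference and candidate complexes with planted overlaps.

    *targets* maps candidate seq_id to the desired (shared-with-p28,
    shared-with-azurin) receptor residue counts.  Writes
    ``p28-azurin.pdb``, ``azurin.pdb`` and one ``<seq_id>.pdb`` per
    candidate into *out_dir* and returns the path map.  Interface extraction
    on the generated poses yields exactly the planted overlap counts against
    the two reference interfaces (sizes 30 and 25).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _emit(name: str, contacts: frozenset[int]) -> None:
        spec = SyntheticSpec(
            seed=seed, receptor_residues=_SCENARIO_RECEPTOR,
            planted_contacts=contacts, cutoff=cutoff,
        )
        elements = tuple("N" if i % 2 == 0 else "C" for i in range(len(contacts)))
        model, _ = generate_complex(spec, ligand_interface_elements=elements)
        path = out / f"{name}.pdb"
        complex_to_pdb(model, path)
        paths[name] = path

    _emit("p28-azurin", _P28_REFERENCE)
    _emit("azurin", _AZURIN_REFERENCE)
    for seq_id, (shared_p28, shared_azurin) in targets.items():
        _emit(seq_id, _plant_contacts(shared_p28, shared_azurin))
    return paths


# ---------------------------------------------------------------------------
# End-to-end demonstration screen
# ---------------------------------------------------------------------------

def generate_demo_screen(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Assemble a complete, runnable screening input set.

    Combines the bundled 14-candidate sequence panel with synthetic stages
    whose ground truth mirrors the published screen's structure: an
    81-sequence annotation table in which the 14 real candidates plus 14
    synthetic high-hydrophobicity peptides are planted azurin-like (28
    selected of 81), and docked pseudo-complexes planting the published
    per-candidate interface-overlap counts.  The synthetic planted peptides
    carry a 70% hydrophobic percentage so the window filter removes them,
    leaving the 14 real candidates, of which the interface stage classifies
    the published 8 as azurin-like.

    Writes sequences.fasta, annotations.tsv, complexes/ and config.yaml
    into *out_dir*; returns the path map.
    """
    from . import datasets  # local import: datasets does not import synthetic

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    candidates = datasets.candidate_peptides()
    references = datasets.reference_peptides()

    pep_spec = SyntheticSpec(seed=seed, n_peptides=14, target_hpp=70,
                             length_range=(30, 80))
    decoys, _ = generate_peptides(pep_spec)
    sequences_path = out / "sequences.fasta"
    write_peptide_fasta(list(candidates) + decoys, sequences_path)
    references_path = out / "references.fasta"
    write_peptide_fasta(references, references_path)

    planted_ids = [r.seq_id for r in candidates] + [r.seq_id for r in decoys]
    background_ids = [f"bg{i + 1:03d}" for i in range(81 - len(planted_ids))]
    annotations = generate_screen_annotations(
        planted_ids, background_ids, seed=seed
    )
    annotations_path = out / "annotations.tsv"
    write_annotation_tsv(annotations, annotations_path)

    table = datasets.published_interface_table()
    targets = {
        str(row.seq_id): (int(row.shared_p28), int(row.shared_azurin))
        for row in table.itertuples()
    }
    complex_paths = generate_overlap_scenario(
        targets, out / "complexes", seed=seed
    )

    config_path = out / "config.yaml"
    config_path.write_text(
        "\n".join(
            [
                f"sequences: {sequences_path}",
                f"reference_sequences: {references_path}",
                f"annotations: {annotations_path}",
                f"complexes_dir: {out / 'complexes'}",
                f"p28_complex: {complex_paths['p28-azurin']}",
                f"azurin_complex: {complex_paths['azurin']}",
                "control_id: azurin",
                "tolerance: 2",
                "cutoff: 5.0",
                "receptor_chain: A",
                "ligand_chain: B",
            ]
        )
        + "\n"
    )
    return {
        "sequences": sequences_path,
        "reference_sequences": references_path,
        "annotations": annotations_path,
        "complexes_dir": out / "complexes",
        "config": config_path,
        **complex_paths,
    }
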