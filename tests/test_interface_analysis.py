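"""Binding-interface extraction, overlap arithmetic and classification."""

import numpy as np
import pytest

from azulike import datasets
from azulike.interface_analysis import (
    AtomRecord,
    BindingInterface,
    ComplexModel,
    InterfaceParams,
    atom_polarity,
    classify_azurin_like,
    comparison_report,
    compute_interface,
    interface_composition,
    load_interface_residues,
    overlap_with_reference,
    read_complex_pdb,
    save_interface_residues,
)
from azulike.synthetic import SyntheticSpec, complex_to_pdb, generate_complex

from conftest import brute_force_interface, random_complex


def two_chain_model(contact_distance=4.0):
    """Minimal complex: one receptor atom near one ligand atom plus a decoy."""
    atoms = [
        AtomRecord("A", 1, "", "ALA", "CA", "C", (0.0, 0.0, 0.0)),
        AtomRecord("B", 1, "", "GLY", "N1", "N", (contact_distance, 0.0, 0.0)),
        AtomRecord("B", 2, "", "GLY", "C1", "C", (100.0, 0.0, 0.0)),
    ]
    return ComplexModel(atoms=atoms, receptor_chain="A", ligand_chain="B")


class TestPdbReading:
    def test_synthetic_fixture_round_trip(self, tmp_path):
        """A generated 2-chain pose reloads with identical residues and coords."""
        spec = SyntheticSpec(seed=3, receptor_residues=10,
                             planted_contacts=frozenset({2, 5}))
        model, _ = generate_complex(spec, n_decoy_ligand=3)
        path = tmp_path / "pose.pdb"
        complex_to_pdb(model, path)
        reloaded = read_complex_pdb(path, "A", "B")
        assert len(reloaded.atoms) == len(model.atoms)
        assert {a.residue_id for a in reloaded.atoms} == {
            a.residue_id for a in model.atoms
        }
        for a, b in zip(
            sorted(model.atoms, key=lambda x: x.atom_id),
            sorted(reloaded.atoms, key=lambda x: x.atom_id),
        ):
            assert a.element == b.element
            assert np.allclose(a.coord, b.coord, atol=1e-3)

    def test_missing_chain_is_error(self, tmp_path):
        spec = SyntheticSpec(seed=3, receptor_residues=5,
                             planted_contacts=frozenset({2}))
        model, _ = generate_complex(spec)
        path = tmp_path / "pose.pdb"
        complex_to_pdb(model, path)
        with pytest.raises(ValueError, match="chain 'C'"):
            read_complex_pdb(path, "A", "C")

    def test_multi_model_reads_first_model_only(self, tmp_path):
        spec = SyntheticSpec(seed=3, receptor_residues=4,
                             planted_contacts=frozenset({1}))
        model, _ = generate_complex(spec, n_decoy_ligand=1)
        single = tmp_path / "single.pdb"
        complex_to_pdb(model, single)
        body = [
            line for line in single.read_text().splitlines() if line != "END"
        ]
        multi = tmp_path / "multi.pdb"
        multi.write_text(
            "MODEL        1\n" + "\n".join(body) + "\nENDMDL\n"
            "MODEL        2\n" + "\n".join(body) + "\nENDMDL\nEND\n"
        )
        n_model1_atoms = sum(line.startswith("ATOM") for line in body)
        reloaded = read_complex_pdb(multi, "A", "B")
        assert len(reloaded.atoms) == n_model1_atoms


class TestInterfaceExtraction:
    def test_matches_brute_force_oracle_on_random_complexes(self):
        """KD-tree contact search equals the all-pairs scan on 100 random
        complexes of up to 500 atoms, exactly."""
        rng = np.random.default_rng(20260929)
        for trial in range(100):
            model = random_complex(rng)
            cutoff = float(rng.uniform(1.0, 8.0))
            iface = compute_interface(model, InterfaceParams(cutoff=cutoff))
            rec, lig, pairs = brute_force_interface(model, cutoff)
            assert iface.receptor_residues == rec, trial
            assert iface.ligand_residues == lig, trial
            assert iface.contact_pairs == pairs, trial

    def test_planted_contacts_recovered_exactly(self):
        spec = SyntheticSpec(seed=11, receptor_residues=12,
                             planted_contacts=frozenset({3, 7, 9}))
        model, truth = generate_complex(spec)
        iface = compute_interface(model, InterfaceParams(cutoff=spec.cutoff))
        assert {r[1] for r in iface.receptor_residues} == truth.receptor_residues

    def test_planted_recovery_straddles_cutoff(self):
        """Contacts planted at cutoff - 0.5 appear at the nominal cutoff and
        vanish when the cutoff shrinks below the planted distance."""
        spec = SyntheticSpec(seed=11, planted_contacts=frozenset({3, 7, 9}))
        model, _ = generate_complex(spec)
        at_cutoff = compute_interface(model, InterfaceParams(cutoff=spec.cutoff))
        assert len(at_cutoff.receptor_residues) == 3
        below = compute_interface(
            model, InterfaceParams(cutoff=spec.cutoff - 0.6)
        )
        assert not below.contact_pairs

    def test_exact_cutoff_boundary_is_inclusive(self):
        model = two_chain_model(contact_distance=5.0)
        iface = compute_interface(model, InterfaceParams(cutoff=5.0))
        assert len(iface.contact_pairs) == 1

    def test_distant_ligand_gives_empty_interface(self):
        model = two_chain_model(contact_distance=100.0)
        iface = compute_interface(model, InterfaceParams(cutoff=5.0))
        assert not iface.contact_pairs
        assert not iface.receptor_residues and not iface.ligand_residues

    def test_residue_sets_follow_from_contact_pairs(self):
        """Interface residue sets are exactly the owners of contacting atoms."""
        rng = np.random.default_rng(5)
        model = random_complex(rng, max_atoms=200)
        iface = compute_interface(model, InterfaceParams(cutoff=6.0))
        assert iface.receptor_residues == frozenset(
            p[0][:3] for p in iface.contact_pairs
        )
        assert iface.ligand_residues == frozenset(
            p[1][:3] for p in iface.contact_pairs
        )

    def test_rigid_motion_invariance(self):
        """Rotating + translating the whole complex leaves the interface fixed."""
        rng = np.random.default_rng(8)
        model = random_complex(rng, max_atoms=150)
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        shift = np.array([12.0, -7.0, 3.0])
        moved = ComplexModel(
            atoms=[
                AtomRecord(
                    a.chain, a.resseq, a.icode, a.resname, a.name, a.element,
                    tuple(rot @ np.array(a.coord) + shift),
                )
                for a in model.atoms
            ],
            receptor_chain="A",
            ligand_chain="B",
        )
        params = InterfaceParams(cutoff=6.0 - 1e-9)
        before = compute_interface(model, params)
        after = compute_interface(moved, params)
        assert before.contact_pairs == after.contact_pairs

    def test_hydrogens_ignored(self):
        atoms = [
            AtomRecord("A", 1, "", "ALA", "CA", "C", (0.0, 0.0, 0.0)),
            AtomRecord("B", 1, "", "GLY", "H1", "H", (1.0, 0.0, 0.0)),
            AtomRecord("B", 1, "", "GLY", "N1", "N", (90.0, 0.0, 0.0)),
        ]
        model = ComplexModel(atoms=atoms, receptor_chain="A", ligand_chain="B")
        iface = compute_interface(model, InterfaceParams(cutoff=5.0))
        assert not iface.contact_pairs


class TestPolarityAndComposition:
    @pytest.mark.parametrize(
        "element, name, expected",
        [("O", "O", "polar"), ("N", "ND1", "polar"), ("C", "CB", "nonpolar"),
         ("S", "SD", "nonpolar")],
    )
    def test_element_rule(self, element, name, expected):
        assert atom_polarity(element, name) == expected

    def test_unusual_heavy_element_counts_polar(self, caplog):
        assert atom_polarity("SE", "SE") == "polar"

    def test_hydrogen_rejected(self):
        with pytest.raises(ValueError, match="hydrogen"):
            atom_polarity("H", "HA")

    def test_all_polar_interface(self):
        spec = SyntheticSpec(seed=2, planted_contacts=frozenset({1, 2, 3}))
        model, _ = generate_complex(
            spec, ligand_interface_elements=["N", "O", "N"],
            receptor_element="N",
        )
        iface = compute_interface(model, InterfaceParams(cutoff=spec.cutoff))
        comp = interface_composition(iface, model)
        assert (comp.ligand_polar, comp.ligand_nonpolar) == (100.00, 0.00)
        assert (comp.receptor_polar, comp.receptor_nonpolar) == (100.00, 0.00)

    def test_planted_three_polar_one_nonpolar(self):
        spec = SyntheticSpec(seed=2, planted_contacts=frozenset({1, 2, 3, 4}))
        model, _ = generate_complex(
            spec, ligand_interface_elements=["N", "O", "N", "C"]
        )
        iface = compute_interface(model, InterfaceParams(cutoff=spec.cutoff))
        comp = interface_composition(iface, model)
        assert (comp.ligand_polar, comp.ligand_nonpolar) == (75.00, 25.00)

    def test_matches_brute_force_recount(self):
        """Composition equals an element recount over the oracle interface."""
        rng = np.random.default_rng(17)
        model = random_complex(rng, max_atoms=200)
        iface = compute_interface(model, InterfaceParams(cutoff=6.0))
        if not iface.contact_pairs:
            pytest.skip("degenerate draw: no contacts")
        _, _, pairs = brute_force_interface(model, 6.0)
        for side, idx in (("ligand", 1), ("receptor", 0)):
            atom_ids = {p[idx] for p in pairs}
            polar = sum(
                model.atom_by_id(a).element in ("N", "O") for a in atom_ids
            )
            comp = interface_composition(iface, model)
            got = getattr(comp, f"{side}_polar")
            assert got == pytest.approx(100 * polar / len(atom_ids), abs=0.005)

    def test_percent_sides_sum_to_100(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            model = random_complex(rng, max_atoms=120)
            iface = compute_interface(model, InterfaceParams(cutoff=7.0))
            if not iface.contact_pairs:
                continue
            comp = interface_composition(iface, model)
            assert comp.ligand_polar + comp.ligand_nonpolar == pytest.approx(
                100.0, abs=0.01
            )
            assert comp.receptor_polar + comp.receptor_nonpolar == pytest.approx(
                100.0, abs=0.01
            )

    def test_empty_interface_is_error(self):
        model = two_chain_model(contact_distance=100.0)
        iface = compute_interface(model, InterfaceParams(cutoff=5.0))
        with pytest.raises(ValueError, match="empty"):
            interface_composition(iface, model)


class TestOverlap:
    def test_self_overlap_is_100(self):
        residues = frozenset({("A", i, "") for i in range(1, 11)})
        result = overlap_with_reference(residues, residues)
        assert result.shared_count == result.reference_size == 10
        assert result.overlap_percent == 100.00

    def test_disjoint_sets(self):
        q = frozenset({("A", 1, "")})
        r = frozenset({("A", 2, ""), ("A", 3, "")})
        assert overlap_with_reference(q, r).overlap_percent == 0.00

    def test_consistency_oracle_azurin_case(self):
        """4 shared residues over the recovered azurin reference size = 16.00%."""
        sizes = datasets.recover_reference_sizes()
        assert sizes == {"p28": 30, "azurin": 25}
        reference = frozenset({("A", i, "") for i in range(1, sizes["azurin"] + 1)})
        query = frozenset({("A", i, "") for i in range(1, 5)})
        result = overlap_with_reference(query, reference)
        assert result.shared_count == 4
        assert result.overlap_percent == 16.00

    def test_published_percentages_all_consistent(self, interface_table):
        """Every printed overlap percentage reproduces from its count and the
        recovered reference size."""
        sizes = datasets.recover_reference_sizes(interface_table)
        for row in interface_table.itertuples():
            for count, pct, ref in (
                (row.shared_p28, row.pct_p28, sizes["p28"]),
                (row.shared_azurin, row.pct_azurin, sizes["azurin"]),
            ):
                reference = frozenset({("A", i, "") for i in range(1, ref + 1)})
                query = frozenset({("A", i, "") for i in range(1, int(count) + 1)})
                got = overlap_with_reference(query, reference)
                assert got.overlap_percent == pytest.approx(float(pct), abs=0.005)

    def test_overlap_monotone_in_query(self):
        reference = frozenset({("A", i, "") for i in range(1, 21)})
        shared = 0
        for k in range(0, 25):
            query = frozenset({("A", i, "") for i in range(1, k + 1)})
            result = overlap_with_reference(query, reference)
            assert result.shared_count >= shared
            shared = result.shared_count

    def test_empty_reference_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_with_reference(frozenset({("A", 1, "")}), frozenset())


class TestClassification:
    def test_published_rows_select_eight(self, interface_table):
        """Applying the shared->=1-with-both rule to the published counts
        selects exactly the 8 highlighted candidates."""
        sizes = datasets.recover_reference_sizes(interface_table)
        selected = []
        for row in interface_table.itertuples():
            ref_p28 = frozenset({("A", i, "") for i in range(1, sizes["p28"] + 1)})
            ref_az = frozenset({("A", i, "") for i in range(1, sizes["azurin"] + 1)})
            ov_p28 = overlap_with_reference(
                frozenset({("A", i, "") for i in range(1, int(row.shared_p28) + 1)}),
                ref_p28,
            )
            ov_az = overlap_with_reference(
                frozenset({("A", i, "") for i in range(1, int(row.shared_azurin) + 1)}),
                ref_az,
            )
            if classify_azurin_like(ov_p28, ov_az):
                selected.append(row.seq_id)
        assert selected == [
            "p1seq09", "p1seq16", "p2seq05", "p2seq08",
            "p2seq20", "p3seq02", "p3seq17", "p3seq24",
        ]

    def test_one_sided_overlap_is_not_azurin_like(self):
        """Sharing residues with azurin only (the p2seq33 pattern) fails."""
        ref = frozenset({("A", i, "") for i in range(1, 26)})
        none = overlap_with_reference(frozenset(), ref)
        some = overlap_with_reference(
            frozenset({("A", i, "") for i in range(1, 5)}), ref
        )
        assert classify_azurin_like(some, some)
        assert not classify_azurin_like(none, some)
        assert not classify_azurin_like(some, none)
        assert not classify_azurin_like(none, none)


class TestReports:
    def test_report_round_trip(self, tmp_path):
        rows = [
            {"seq_id": "a", "size": 35, "shared_p28": 16, "pct_p28": 53.33,
             "shared_azurin": 7, "pct_azurin": 28.00, "polar_pct_ligand": 50.0,
             "nonpolar_pct_ligand": 50.0, "polar_pct_receptor": 60.0,
             "nonpolar_pct_receptor": 40.0, "selected": True},
            {"seq_id": "b", "size": 10, "shared_p28": 0, "pct_p28": 0.0,
             "shared_azurin": 0, "pct_azurin": 0.0, "polar_pct_ligand": 0.0,
             "nonpolar_pct_ligand": 0.0, "polar_pct_receptor": 0.0,
             "nonpolar_pct_receptor": 0.0, "selected": False},
        ]
        path = tmp_path / "report.tsv"
        frame = comparison_report(rows, path)
        import pandas as pd

        reparsed = pd.read_csv(path, sep="\t")
        assert list(reparsed.seq_id) == ["a", "b"]
        assert reparsed.pct_p28.tolist() == [53.33, 0.0]
        assert bool(reparsed.selected[0]) and not bool(reparsed.selected[1])
        assert list(frame.columns) == list(reparsed.columns)

    def test_interface_residue_tsv_round_trip(self, tmp_path):
        residues = frozenset({("A", 5, ""), ("A", 7, "B"), ("A", 12, "")})
        path = tmp_path / "iface.tsv"
        save_interface_residues(path, residues)
        assert load_interface_residues(path) == residues
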