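import numpy as np
import pytest

from cgap.coarse_grain import (
    CONTACT_CUTOFF,
    NativeContactSet,
    TopologyError,
    assign_charges,
    build_psite_groups,
    coarse_grain,
    detect_native_contacts,
    histidine_charge,
)

from conftest import annotated, backbone_residue, make_atoms


def chain_structure(n, chain="A", label="structured", spacing=3.8, resnames=None):
    records = []
    for k in range(1, n + 1):
        name = resnames[k - 1] if resnames else "ALA"
        records += backbone_residue(chain, k, name, (spacing * k, 0.1 * k**2, 0.0))
    return annotated(records, label)


def nucleotide_records(chain="N", resid=1, origin=(0.0, 0.0, 0.0)):
    ox, oy, oz = origin
    atoms = [
        ("C2", "C"), ("C6", "C"), ("N9", "N"), ("C4'", "C"),
        ("PA", "P"), ("PB", "P"), ("PG", "P"),
    ]
    recs = [
        (chain, resid, "ANP", nm, el, (ox + 1.5 * k, oy + 0.3 * k, oz))
        for k, (nm, el) in enumerate(atoms)
    ]
    recs += [
        (chain, resid + 1, "MG", "MG", "MG", (ox + 2.0, oy + 2.0, oz + 1.0)),
        (chain, resid + 2, "MG", "MG", "MG", (ox + 4.0, oy + 2.0, oz + 1.0)),
    ]
    return recs


class TestCoarseGrain:
    def test_single_chain_counts(self):
        top = coarse_grain(chain_structure(10))
        assert top.n_beads == 10
        assert len(top.bonds) == 9
        assert len(top.angles) == 8
        assert len(top.dihedrals) == 7
        assert np.allclose(top.radius, 5.3)

    def test_bead_positions_are_calpha(self):
        s = chain_structure(4)
        top = coarse_grain(s)
        ca = s.atoms.coord[s.atoms.atom_name == "CA"]
        assert np.allclose(top.positions, ca, atol=1e-5)

    def test_nucleotide_complex_nine_beads_fully_bonded(self):
        atoms = make_atoms(nucleotide_records())
        atoms.set_annotation("region", np.full(atoms.array_length(), "nucleotide-complex", dtype="U20"))
        from cgap.structure_io import AnnotatedStructure

        top = coarse_grain(AnnotatedStructure(atoms))
        assert top.n_beads == 9
        assert len(top.bonds) == 36  # C(9,2): every pseudo-atom pair
        assert np.allclose(top.radius, 3.5)
        assert len(top.dihedrals) == 0  # harmonic cage only

    def test_chain_break_has_no_bond(self):
        records = []
        records += backbone_residue("A", 1, "ALA", (0, 0, 0))
        records += backbone_residue("A", 2, "ALA", (3.8, 0, 0))
        records += backbone_residue("B", 1, "ALA", (7.6, 0, 0))
        top = coarse_grain(annotated(records))
        assert len(top.bonds) == 1

    def test_missing_calpha_names_residue(self):
        records = backbone_residue("A", 1, "ALA", (0, 0, 0))
        records += [("A", 2, "ALA", "N", "N", (3.8, 0.0, 0.0))]
        with pytest.raises(TopologyError, match="A:2"):
            coarse_grain(annotated(records))

    def test_reference_geometry_from_input(self):
        top = coarse_grain(chain_structure(5))
        d = np.linalg.norm(top.positions[top.bonds[:, 0]] - top.positions[top.bonds[:, 1]], axis=1)
        assert np.allclose(top.bond_req, d)


class TestNativeContacts:
    def test_cutoff_boundary(self):
        # two residues with closest atoms at 5.4 vs 5.6 A
        for gap, expect in [(5.4, 1), (5.6, 0)]:
            records = backbone_residue("A", 1, "ALA", (0, 0, 0))
            records += backbone_residue("A", 5, "ALA", (0, 100, 0))  # spacer far away
            # pure z offset of an identical template: min atom distance == gap
            records += backbone_residue("A", 9, "ALA", (0, 0, gap))
            s = annotated(records)
            top = coarse_grain(s)
            contacts = detect_native_contacts(s, top, eligible=lambda r: True)
            got = {(top.resid[i], top.resid[j]) for i, j in zip(contacts.i, contacts.j)}
            assert ((1, 9) in got or (9, 1) in got) == bool(expect)

    def test_sequence_separation_rule(self):
        records = backbone_residue("A", 1, "ALA", (0, 0, 0))
        records += backbone_residue("A", 3, "ALA", (0, 4.0, 0))  # i, i+2 at 4 A
        s = annotated(records)
        top = coarse_grain(s)
        contacts = detect_native_contacts(s, top, eligible=lambda r: True)
        assert len(contacts) == 0

    def test_matches_brute_force_oracle(self, helix_structure):
        s = helix_structure
        top = coarse_grain(s)
        contacts = detect_native_contacts(s, top)
        got = {(min(a, b), max(a, b)) for a, b in zip(contacts.i, contacts.j)}
        # independent O(N^2) oracle over residue atom groups
        atoms = s.atoms
        expected = set()
        for i in range(1, 9):
            for j in range(i + 3, 9):
                ai = atoms.coord[atoms.res_id == i]
                aj = atoms.coord[atoms.res_id == j]
                dmin = np.linalg.norm(ai[:, None] - aj[None], axis=-1).min()
                if dmin <= CONTACT_CUTOFF:
                    expected.add((i - 1, j - 1))
        assert got == expected
        # sigma is the pseudo-atom (C-alpha) separation
        for i, j, sg in zip(contacts.i, contacts.j, contacts.sigma):
            assert sg == pytest.approx(np.linalg.norm(top.positions[i] - top.positions[j]))

    def test_eligibility_predicate(self, helix_structure):
        top = coarse_grain(helix_structure)
        none = detect_native_contacts(helix_structure, top, eligible=lambda r: r == "modeled")
        assert len(none) == 0

    def test_duplicate_pairs_rejected_silently(self):
        cs = NativeContactSet()
        cs.add(0, 5, 6.0, 0.6, "fold")
        cs.add(5, 0, 6.5, 0.6, "fold")
        assert len(cs) == 1

    def test_sigma_must_be_positive(self):
        cs = NativeContactSet()
        with pytest.raises(ValueError):
            cs.add(0, 1, -1.0, 0.6, "fold")


class TestCharges:
    def test_psite_window_sequence(self):
        # DADEYLIPQ: D-1, A0, D-1, E-1, Y0, L0, I0, P0, Q0 (no termini)
        resnames = ["ASP", "ALA", "ASP", "GLU", "TYR", "LEU", "ILE", "PRO", "GLN"]
        top = coarse_grain(chain_structure(9, resnames=resnames))
        top = assign_charges(top, pH=7.6, include_termini=False)
        assert list(top.charge) == [-1, 0, -1, -1, 0, 0, 0, 0, 0]

    def test_histidine_zeroed_at_ph76(self):
        frac = histidine_charge(7.6)
        assert frac == pytest.approx(10 ** (6.0 - 7.6) / (1 + 10 ** (6.0 - 7.6)))
        assert frac < 0.1
        top = coarse_grain(chain_structure(3, resnames=["HIS", "HIS", "HIS"]))
        top = assign_charges(top, include_termini=False)
        assert np.all(top.charge == 0)

    def test_histidine_charged_at_low_ph(self):
        top = coarse_grain(chain_structure(3, resnames=["HIS", "HIS", "HIS"]))
        top = assign_charges(top, pH=4.0, include_termini=False)
        assert np.all(top.charge > 0.9)

    def test_termini(self):
        top = coarse_grain(chain_structure(4))
        top = assign_charges(top, include_termini=True)
        assert top.charge[0] == 1.0 and top.charge[-1] == -1.0

    def test_nucleotide_complex_net_neutral(self):
        from cgap.structure_io import AnnotatedStructure

        atoms = make_atoms(nucleotide_records())
        atoms.set_annotation("region", np.full(atoms.array_length(), "nucleotide-complex", dtype="U20"))
        top = assign_charges(coarse_grain(AnnotatedStructure(atoms)))
        assert top.charge.sum() == pytest.approx(0.0)
        assert sorted(top.charge)[:3] == pytest.approx([-4 / 3] * 3)
        assert sorted(top.charge)[-2:] == pytest.approx([2.0, 2.0])

    def test_unknown_residue_warns_and_zeroes(self):
        top = coarse_grain(chain_structure(3, resnames=["ALA", "XXX", "ALA"]))
        with pytest.warns(UserWarning, match="XXX"):
            top = assign_charges(top, include_termini=False)
        assert top.charge[1] == 0.0


class TestPSiteGroups:
    def _dimer_topology(self):
        records = []
        for chain in ("A", "B"):
            for k in range(1, 31):
                records += backbone_residue(chain, k, "ALA", (3.8 * k, 0 if chain == "A" else 30, 0))
        s = annotated(records, "modeled")
        return coarse_grain(s)

    def _definition(self):
        pairs = [
            {"psite_resid": 25, "partner_resid": p, "sigma": 6.0 + 0.1 * p}
            for p in range(1, 10)
        ]
        pairs.append({"psite_resid": 24, "partner_resid": 5, "sigma": 7.0, "trigger": False})
        return {"site_id": "25", "tyr_resid": 25, "window": list(range(21, 30)), "contact_pairs": pairs}

    def test_groups_built_for_both_chains_and_sites(self):
        top = self._dimer_topology()
        groups, contacts = build_psite_groups(top, [self._definition()], NativeContactSet(), "A", "B")
        assert len(groups) == 4  # 2 copies x 2 active sites
        productive = [g for g in groups if g.productive]
        assert {g.site_id for g in productive} == {"25A", "25B"}
        assert all(g.trigger_size == 9 for g in groups)
        # mirrored copies share sigma but differ in bead indices
        a, b = productive
        assert np.allclose(a.trigger_sigma, b.trigger_sigma)
        assert not np.array_equal(a.trigger_pairs, b.trigger_pairs)
        assert len(contacts) == 4 * 10

    def test_cis_trans_classification(self):
        top = self._dimer_topology()
        groups, _ = build_psite_groups(top, [self._definition()], NativeContactSet(), "A", "B")
        for g in groups:
            assert g.cis == (g.psite_chain == g.target_chain)

    def test_wrong_trigger_count_rejected_and_overridable(self):
        top = self._dimer_topology()
        bad = self._definition()
        bad["contact_pairs"] = bad["contact_pairs"][:5]
        with pytest.raises(ValueError, match="trigger"):
            build_psite_groups(top, [bad], NativeContactSet(), "A", "B")
        groups, _ = build_psite_groups(
            top, [bad], NativeContactSet(), "A", "B", validate_trigger=False
        )
        assert groups[0].trigger_size == 5

    def test_strip_psite_attractions(self):
        from cgap.coarse_grain import CGSystem

        top = self._dimer_topology()
        groups, contacts = build_psite_groups(top, [self._definition()], NativeContactSet(), "A", "B")
        system = CGSystem(top, contacts, groups)
        stripped = system.strip_psite_attractions()
        assert len(stripped.contacts) == 0
        assert len(system.contacts) == 40  # original untouched
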