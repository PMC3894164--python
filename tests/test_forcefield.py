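import dataclasses

import numpy as np
import pytest

from cgap.coarse_grain import NativeContactSet, PseudoAtomTopology, _angle, _dihedral
from cgap.forcefield import (
    GoForceField,
    bonded_energy,
    build_schedule,
    contact_energy,
    electrostatic_energy,
    membrane_energy,
    nonbonded_candidate_pairs,
    repulsive_energy,
    total_energy,
)


def random_chain_topology(n, seed, charged=True, membrane=False):
    rng = np.random.default_rng(seed)
    pos = np.cumsum(rng.normal(scale=2.0, size=(n, 3)) + [3.0, 0, 0], axis=0)
    bonds = np.array([[i, i + 1] for i in range(n - 1)]).reshape(-1, 2)
    angles = np.array([[i, i + 1, i + 2] for i in range(max(n - 2, 0))]).reshape(-1, 3)
    dihedrals = np.array([[i, i + 1, i + 2, i + 3] for i in range(max(n - 3, 0))]).reshape(-1, 4)
    side = rng.choice([-1, 0, 1], n).astype(np.int8) if membrane else np.full(n, -1, np.int8)
    pos[:, 2] -= 40.0  # intracellular by default
    top = PseudoAtomTopology(
        positions=pos.copy(),
        chain=np.array(["A"] * n),
        resid=np.arange(1, n + 1),
        resname=np.array(["GLY"] * n),
        kind=np.array(["residue"] * n),
        region=np.array(["modeled"] * n),
        charge=rng.choice([-1.0, 0.0, 1.0], n) if charged else np.zeros(n),
        radius=np.full(n, 5.3),
        bonds=bonds,
        bond_req=np.linalg.norm(pos[bonds[:, 0]] - pos[bonds[:, 1]], axis=1) * rng.uniform(0.9, 1.1, len(bonds)),
        angles=angles,
        angle_eq=np.array([_angle(*pos[t]) for t in angles]) * rng.uniform(0.9, 1.1, len(angles)),
        dihedrals=dihedrals,
        dihedral_native=np.array([_dihedral(*pos[q]) for q in dihedrals]) + rng.uniform(-0.5, 0.5, len(dihedrals)),
        membrane_side=side,
        tm_z0=np.where(side == 0, pos[:, 2], np.nan),
    )
    return top


def numeric_force(fn, coords, h=1e-6):
    num = np.zeros_like(coords)
    for a in range(len(coords)):
        for d in range(3):
            cp = coords.copy(); cp[a, d] += h
            cm = coords.copy(); cm[a, d] -= h
            num[a, d] = -(fn(cp) - fn(cm)) / (2 * h)
    return num


FF = GoForceField()


class TestPointValues:
    def test_bond_at_equilibrium_and_stretched(self):
        top = random_chain_topology(2, 0, charged=False)
        top.bond_req[:] = 3.8
        coords = np.array([[0.0, 0, -40], [3.8, 0, -40]])
        e, f = bonded_energy(coords, top, FF)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(f, 0.0)
        coords[1, 0] = 4.8  # stretched 1 A -> k_bond acts as printed: 20 kcal/mol
        e, _ = bonded_energy(coords, top, FF)
        assert e == pytest.approx(20.0)

    def test_contact_minimum_depth_and_zero_slope(self):
        cs = NativeContactSet()
        cs.add(0, 1, 5.0, 0.6, "fold")
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        e, f = contact_energy(coords, cs, FF)
        assert e == pytest.approx(-0.6)
        assert np.allclose(f, 0.0, atol=1e-10)  # dU/dr = 0 at the minimum
        coords[1, 0] = 50.0
        e, _ = contact_energy(coords, cs, FF)
        assert abs(e) < 1e-5

    def test_contact_12_10_variant(self):
        ff = dataclasses.replace(FF, contact_form="12-10")
        cs = NativeContactSet()
        cs.add(0, 1, 5.0, 0.6, "fold")
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        e, f = contact_energy(coords, cs, ff)
        assert e == pytest.approx(-0.6)
        assert np.allclose(f, 0.0, atol=1e-10)

    def test_repulsion_printed_values(self):
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        e, _ = repulsive_energy(coords, [[0, 1]], FF)
        assert e == pytest.approx(0.6)
        coords[1, 0] = 8.0
        e, _ = repulsive_energy(coords, [[0, 1]], FF)
        assert e == pytest.approx(0.6 / 4096)

    def test_repulsion_monotone(self):
        rs = np.linspace(3.0, 20.0, 50)
        es = [repulsive_energy(np.array([[0.0, 0, 0], [r, 0, 0]]), [[0, 1]], FF)[0] for r in rs]
        assert np.all(np.diff(es) < 0)
        assert min(es) > 0

    def test_electrostatics_zero_charge_and_coulomb_limit(self):
        coords = np.array([[0.0, 0, 0], [7.0, 0, 0]])
        e, _ = electrostatic_energy(coords, np.array([0.0, 1.0]), FF)
        assert e == 0.0
        ff0 = dataclasses.replace(FF, ionic_strength=0.0)
        e, _ = electrostatic_energy(coords, np.array([1.0, 1.0]), ff0)
        assert e == pytest.approx(332.0637 / (78.4 * 7.0))

    def test_electrostatics_scalar_oracle(self):
        rng = np.random.default_rng(4)
        lam = FF.debye_length
        for _ in range(100):
            r = rng.uniform(3, 60)
            qi, qj = rng.choice([-1.0, 1.0], 2)
            coords = np.array([[0.0, 0, 0], [r, 0, 0]])
            e, _ = electrostatic_energy(coords, np.array([qi, qj]), FF)
            expected = 332.0637 * qi * qj * np.exp(-r / lam) / (78.4 * r)
            assert e == pytest.approx(expected, abs=1e-12)

    def test_debye_length_at_physiological_strength(self):
        assert FF.debye_length == pytest.approx(7.9, abs=0.15)

    def test_membrane_wall_values(self):
        top = random_chain_topology(3, 1, charged=False)
        top.membrane_side = np.array([1, 1, 0], dtype=np.int8)
        top.tm_z0 = np.array([np.nan, np.nan, 0.0])
        coords = top.positions.copy()
        coords[:, 2] = [20.0, 15.5, 2.0]
        e, f = membrane_energy(coords, top, FF)
        # outside bead free; 1 A penetration costs k_wall = 5; TM 2 A costs 20
        assert e == pytest.approx(5.0 * 1.0**2 + 5.0 * 2.0**2)
        assert f[0, 2] == 0.0

    def test_plane_separation_is_33(self):
        assert FF.plane_separation == pytest.approx(33.0)


class TestForceConsistency:
    @pytest.mark.parametrize("seed", range(6))
    def test_every_term_matches_finite_differences(self, seed):
        top = random_chain_topology(8, seed, membrane=(seed % 2 == 0))
        cs = NativeContactSet()
        cs.add(0, 4, 6.0, 0.6, "fold")
        cs.add(1, 7, 8.0, 0.6, "fold")
        rng = np.random.default_rng(100 + seed)
        coords = top.positions + rng.normal(scale=0.5, size=top.positions.shape)
        pairs = nonbonded_candidate_pairs(top, cs)
        cases = {
            "bonded": lambda c: bonded_energy(c, top, FF),
            "contact": lambda c: contact_energy(c, cs, FF),
            "repulsive": lambda c: repulsive_energy(c, pairs, FF),
            "electrostatic": lambda c: electrostatic_energy(c, top.charge, FF),
            "membrane": lambda c: membrane_energy(c, top, FF),
        }
        for name, fn in cases.items():
            e, f = fn(coords)
            num = numeric_force(lambda c: fn(c)[0], coords)
            scale = np.abs(num).max()
            if scale == 0:
                continue
            assert np.abs(f - num).max() / scale < 1e-5, name

    @pytest.mark.parametrize("seed", range(3))
    def test_net_force_zero_except_membrane(self, seed):
        top = random_chain_topology(10, seed)
        top.membrane_side = np.full(10, -1, np.int8)
        cs = NativeContactSet()
        cs.add(0, 5, 6.0, 0.6, "fold")
        coords = top.positions + np.random.default_rng(seed).normal(scale=0.4, size=(10, 3))
        for fn in (
            lambda c: bonded_energy(c, top, FF),
            lambda c: contact_energy(c, cs, FF),
            lambda c: repulsive_energy(c, nonbonded_candidate_pairs(top, cs), FF),
            lambda c: electrostatic_energy(c, top.charge, FF),
        ):
            _, f = fn(coords)
            assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)


class TestSchedule:
    def test_two_bead_classification(self):
        for r, cls in [(10.0, "short"), (20.0, "medium"), (30.0, "neither")]:
            top = random_chain_topology(2, 0, charged=True)
            top.chain = np.array(["A", "B"])  # inter-chain: no seq exclusion
            coords = np.array([[0.0, 0, -40], [r, 0, -40]])
            top.bonds = np.zeros((0, 2), dtype=np.int64)
            top.bond_req = np.zeros(0)
            sched = build_schedule(coords, top, FF, NativeContactSet())
            short = len(sched.short_pairs)
            med = len(sched.medium_pairs)
            assert (short, med) == {"short": (1, 0), "medium": (0, 1), "neither": (0, 0)}[cls]
            if top.charge[0] * top.charge[1] != 0:
                assert len(sched.elec_pairs) == 1  # electrostatics unrestricted

    def test_random_gas_matches_brute_force(self):
        rng = np.random.default_rng(7)
        n = 50
        top = random_chain_topology(n, 3, charged=False)
        coords = rng.uniform(0, 40, size=(n, 3))
        cs = NativeContactSet()
        cs.add(0, 10, 6.0, 0.6, "fold")
        sched = build_schedule(coords, top, FF, cs)
        got_short = {tuple(p) for p in sched.short_pairs}
        got_med = {tuple(p) for p in sched.medium_pairs}
        exp_short, exp_med = set(), set()
        bonded = {tuple(sorted(b)) for b in top.bonds}
        for i in range(n):
            for j in range(i + 1, n):
                if abs(i - j) < 3 or (i, j) in bonded or (i, j) == (0, 10):
                    continue
                r = np.linalg.norm(coords[i] - coords[j])
                if r <= 12.5:
                    exp_short.add((i, j))
                elif r < 25.0:
                    exp_med.add((i, j))
        assert got_short == exp_short
        assert got_med == exp_med

    def test_breakdown_sums_to_total(self):
        top = random_chain_topology(12, 5)
        cs = NativeContactSet()
        cs.add(0, 6, 7.0, 0.6, "fold")
        coords = top.positions
        e, breakdown, _ = total_energy(coords, top, FF, cs)
        assert e == pytest.approx(sum(breakdown.values()), rel=1e-12)

    def test_overlapping_beads_rejected(self):
        top = random_chain_topology(4, 0)
        coords = top.positions.copy()
        coords[3] = coords[0]
        from cgap.forcefield import SingularGeometryError

        with pytest.raises(SingularGeometryError):
            build_schedule(coords, top, FF, NativeContactSet())


class TestValidation:
    def test_nonpositive_constants_rejected(self):
        with pytest.raises(ValueError):
            GoForceField(contact_eps=-0.1)
        with pytest.raises(ValueError):
            GoForceField(k_bond=0.0)

    def test_unknown_contact_form_rejected(self):
        with pytest.raises(ValueError):
            GoForceField(contact_form="10-6")
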