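"""Deterministic synthetic toy systems.

The toy dimer emulates the architecture the method assumes without
reproducing any real receptor quantitatively: two compact pseudo-kinase
folds (beads on a serpentine path through a cubic template) joined by a
glued interface into an asymmetric dimer, membrane-spanning helices
confined between the two walls, short extracellular stubs, and long
disordered C-terminal tails carrying phosphorylation-site (P-site) beads
tethered at configurable sequence distances from the fold.  Each P-site
gets a nine-contact trigger group against the catalytic patch of each
monomer, built through the same machinery production systems use.

Fixture native contacts are defined at the pseudo-atom level (7.5 A
C-alpha cutoff) because generated toys have no all-atom reference; real
structures use the 5.5 A all-atom rule instead.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np

from .coarse_grain import (
    CGSystem,
    NativeContactSet,
    PSiteContactGroup,
    PseudoAtomTopology,
    _angle,
    _dihedral,
)

BOND_LENGTH = 3.8  # A, C-alpha virtual bond (helices, tails)
FOLD_SPACING = 5.0  # A, fold-template lattice constant: typical nonbonded
#   C-alpha neighbor distance; keeps per-bead contact stiffness inside the
#   overdamped-Euler stability margin at the 125 fs step
FOLD_CONTACT_CUTOFF = 7.5  # A, pseudo-atom contact rule for generated toys
DOCK_HEIGHT = 4.5  # A, docked tyrosine above the patch face


class FixtureError(ValueError):
    """Toy-system specification cannot be realized."""


@dataclasses.dataclass
class ToyDimerSpec:
    """Parameters of the generated toy dimer.

    ``psite_tethers`` maps chain id to the tether distances (in residues
    from the fold exit) of that chain's P-sites; the tyrosine sits at the
    tether position and its nine-residue window spans +/-4 residues.
    """

    fold_dim: tuple = (3, 2, 3)  # x, y, z extent; the 3x3 y-face is the patch
    tm_length: int = 22  # helical TM anchor; 1.5 A rise/residue spans the 33 A slab
    ecto_length: int = 2
    psite_tethers: dict = dataclasses.field(default_factory=lambda: {"A": [10], "B": [10]})
    tail_extra: int = 4
    trigger_size: int = 9
    aux_flank: int = 4  # window residues +/-k of the tyrosine carry aux contacts
    aux_cutoff: float = 10.0  # A, docked window position to patch bead
    tail_charge_spacing: int = 5  # every k-th tail bead carries -1 (0 disables)
    receiver_chain: str = "A"
    seed: int = 0

    def __post_init__(self):
        min_tether = 5  # window needs +/-4 residues around the tyrosine
        for chain, tethers in self.psite_tethers.items():
            for t in tethers:
                if t < min_tether:
                    raise FixtureError(
                        f"tether {t} on chain {chain} too short; the nine-residue "
                        f"window requires at least {min_tether}"
                    )
        nx, ny, nz = self.fold_dim
        if ny < 2 or nx * ny * nz < 8:
            raise FixtureError("fold template too small for a 3x3 catalytic patch face")

    def tail_length(self, chain: str) -> int:
        tethers = self.psite_tethers.get(chain, [])
        return (max(tethers) if tethers else 0) + 4 + self.tail_extra


def _serpentine_grid(nx: int, ny: int, nz: int, flip_y: bool) -> list:
    """Grid index path visiting y-layers last so the exit lies on the patch face."""
    order = []
    ys = range(ny) if not flip_y else range(ny - 1, -1, -1)
    for yi, y in enumerate(ys):
        for zi in range(nz):
            z = zi if yi % 2 == 0 else nz - 1 - zi
            for xi in range(nx):
                x = xi if (yi + zi) % 2 == 0 else nx - 1 - xi
                order.append((x, y, z))
    return order


def _fold_coords(spec: ToyDimerSpec, center: np.ndarray, patch_normal: int) -> tuple:
    """Fold bead coordinates plus patch-face bead offsets (local indices)."""
    nx, ny, nz = spec.fold_dim
    flip = patch_normal < 0
    path = _serpentine_grid(nx, ny, nz, flip_y=flip)
    half = (np.array([nx, ny, nz]) - 1) / 2.0
    coords = np.array([(np.array(p) - half) * FOLD_SPACING + center for p in path])
    face_y = ny - 1 if patch_normal > 0 else 0
    face = [k for k, p in enumerate(path) if p[1] == face_y]
    # central 3x3 patch of the face, ordered by distance to the face center
    face_center = center + np.array([0.0, patch_normal * half[1] * FOLD_SPACING, 0.0])
    face.sort(key=lambda k: np.linalg.norm(coords[k] - face_center))
    patch = face[:9]
    return coords, patch, face_center


def _random_tail(rng: np.random.Generator, anchor: np.ndarray, n: int, existing: np.ndarray) -> np.ndarray:
    """Downward-biased self-avoiding random walk below the membrane."""
    coords = []
    pos = anchor.copy()
    for k in range(n):
        for attempt in range(200):
            d = rng.normal(size=3)
            d[2] -= 0.05  # slight bias away from the membrane wall
            d /= np.linalg.norm(d)
            cand = pos + BOND_LENGTH * d
            if cand[2] > -18.0:
                continue
            obstacles = np.vstack([existing] + ([np.array(coords)] if coords else []))
            if np.linalg.norm(obstacles - cand, axis=1).min() < 3.5:
                continue
            break
        else:
            raise FixtureError(f"could not grow tail bead {k}: geometry too crowded")
        coords.append(cand)
        pos = cand
    return np.array(coords)


def make_toy_dimer(spec: ToyDimerSpec) -> CGSystem:
    """Generate the toy dimer system (topology, contacts, P-site groups).

    Deterministic given ``spec.seed``.  Folds carry intra- and
    interface native contacts (7.5 A, separation >= 3); tails carry none
    except the P-site trigger groups, each mirrored onto both catalytic
    patches.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.fold_dim
    fold_half_x = (nx - 1) / 2.0 * FOLD_SPACING
    gap = 5.5  # A between facing fold faces: glues the dimer interface
    offset = fold_half_x + gap / 2.0
    fold_z_center = -19.0 - (nz - 1) / 2.0 * FOLD_SPACING

    chains, all_coords, regions, sides = [], [], [], []
    fold_slices, patch_beads, face_centers, tail_slices = {}, {}, {}, {}

    # both monomer cores first, so tails see every obstacle while growing
    cores = {}
    rise, radius, turn = 1.5, 2.3, np.deg2rad(100.0)  # coarse alpha-helix
    for chain, sign in (("A", -1.0), ("B", 1.0)):
        center = np.array([sign * offset, 0.0, fold_z_center])
        patch_normal = 1 if chain == spec.receiver_chain else -1
        fold, patch_local, face_center = _fold_coords(spec, center, patch_normal)
        entry = fold[0]
        # TM helix spans the membrane slab, continued upward by the ecto stub;
        # helical geometry keeps backbone triples well away from collinearity
        z_bottom = -0.5 * (spec.tm_length - 1) * rise
        n_helix = spec.ecto_length + spec.tm_length
        helix = np.array(
            [
                [
                    entry[0] + radius * np.cos(turn * k),
                    entry[1] + radius * np.sin(turn * k),
                    z_bottom + rise * (n_helix - 1 - k),
                ]
                for k in range(n_helix)
            ]
        )
        ecto, tm = helix[: spec.ecto_length], helix[spec.ecto_length :]
        cores[chain] = (ecto, tm, fold, patch_local, face_center)

    tails = {}
    core_coords = np.vstack([np.vstack(cores[c][:3]) for c in ("A", "B")])
    for chain in ("A", "B"):
        fold = cores[chain][2]
        obstacles = (
            np.vstack([core_coords] + [tails[c] for c in tails]) if tails else core_coords
        )
        tails[chain] = _random_tail(rng, fold[-1], spec.tail_length(chain), obstacles)

    for chain in ("A", "B"):
        ecto, tm, fold, patch_local, face_center = cores[chain]
        tail = tails[chain]
        n_tail = len(tail)
        start = sum(len(c) for c in all_coords)
        coords = np.vstack([ecto, tm, fold, tail])
        all_coords.append(coords)
        chains.extend([chain] * len(coords))
        regions.extend(
            ["extracellular"] * spec.ecto_length
            + ["transmembrane"] * spec.tm_length
            + ["structured"] * len(fold)
            + ["modeled"] * n_tail
        )
        sides.extend(
            [1] * spec.ecto_length + [0] * spec.tm_length + [-1] * (len(fold) + n_tail)
        )
        fold_start = start + spec.ecto_length + spec.tm_length
        fold_slices[chain] = (fold_start, fold_start + len(fold))
        patch_beads[chain] = [fold_start + k for k in patch_local]
        face_centers[chain] = face_center
        tail_slices[chain] = (fold_start + len(fold), fold_start + len(fold) + n_tail)

    positions = np.vstack(all_coords)
    n = len(positions)
    chains_arr = np.array(chains)
    resid = np.zeros(n, dtype=np.int64)
    for chain in ("A", "B"):
        mask = chains_arr == chain
        resid[mask] = np.arange(1, mask.sum() + 1)

    charge = np.zeros(n)
    if spec.tail_charge_spacing:
        for chain in ("A", "B"):
            t0, t1 = tail_slices[chain]
            for k in range(t0, t1, spec.tail_charge_spacing):
                charge[k] = -1.0

    bonds, angles, dihedrals = [], [], []
    for chain in ("A", "B"):
        idx = np.flatnonzero(chains_arr == chain)
        bonds.extend([(int(a), int(b)) for a, b in zip(idx[:-1], idx[1:])])
        angles.extend([(int(a), int(b), int(c)) for a, b, c in zip(idx[:-2], idx[1:-1], idx[2:])])
        dihedrals.extend(
            [(int(a), int(b), int(c), int(d)) for a, b, c, d in zip(idx[:-3], idx[1:-2], idx[2:-1], idx[3:])]
        )
    bonds = np.asarray(bonds, dtype=np.int64)
    angles = np.asarray(angles, dtype=np.int64)
    dihedrals = np.asarray(dihedrals, dtype=np.int64)

    topology = PseudoAtomTopology(
        positions=positions,
        chain=chains_arr,
        resid=resid,
        resname=np.full(n, "GLY"),
        kind=np.full(n, "residue"),
        region=np.array(regions),
        charge=charge,
        radius=np.full(n, 5.3),
        bonds=bonds,
        bond_req=np.linalg.norm(positions[bonds[:, 0]] - positions[bonds[:, 1]], axis=1),
        angles=angles,
        angle_eq=np.array([_angle(*positions[t]) for t in angles]),
        dihedrals=dihedrals,
        dihedral_native=np.array([_dihedral(*positions[q]) for q in dihedrals]),
        membrane_side=np.array(sides, dtype=np.int8),
        tm_z0=np.where(np.array(sides, dtype=np.int8) == 0, positions[:, 2], np.nan),
    )

    # fold native contacts: pseudo-atom rule, folds only (intra + interface)
    contacts = NativeContactSet()
    fold_idx = np.concatenate([np.arange(*fold_slices[c]) for c in ("A", "B")])
    for ai in range(len(fold_idx)):
        for bi in range(ai + 1, len(fold_idx)):
            a, b = int(fold_idx[ai]), int(fold_idx[bi])
            if topology.sequence_separation(a, b) < 3:
                continue
            d = float(np.linalg.norm(positions[a] - positions[b]))
            if d <= FOLD_CONTACT_CUTOFF:
                contacts.add(a, b, d, 0.6, "fold")

    # P-site groups: docked-pose sigma template shared by all groups
    groups = []
    for psite_chain in ("A", "B"):
        t0, _ = tail_slices[psite_chain]
        for tether in spec.psite_tethers.get(psite_chain, []):
            tyr = t0 + tether - 1
            window = np.arange(tyr - 4, tyr + 5)
            site_resid = int(resid[tyr])
            site_id = f"{site_resid}{psite_chain}"
            for target_chain in ("A", "B"):
                patch = patch_beads[target_chain]
                normal = 1 if target_chain == spec.receiver_chain else -1
                pose = face_centers[target_chain] + np.array([0.0, normal * DOCK_HEIGHT, 0.0])
                sig = np.array([np.linalg.norm(pose - positions[p]) for p in patch])
                # window residues flank the docked tyrosine along the face
                # tangent; their contacts widen and deepen the docking funnel
                # without joining the trigger
                tangent = np.array([1.0, 0.0, 0.0])
                aux_pairs, aux_sigma = [], []
                for koff in range(-spec.aux_flank, spec.aux_flank + 1):
                    if koff == 0:
                        continue
                    wpos = pose + tangent * BOND_LENGTH * koff
                    for p in patch:
                        d = float(np.linalg.norm(wpos - positions[p]))
                        if d <= spec.aux_cutoff:
                            aux_pairs.append((int(tyr + koff), int(p)))
                            aux_sigma.append(d)
                group = PSiteContactGroup(
                    site_id=site_id,
                    psite_chain=psite_chain,
                    target_chain=target_chain,
                    productive=(target_chain == spec.receiver_chain),
                    tyr_bead=int(tyr),
                    window_beads=window,
                    trigger_pairs=np.array([(int(tyr), int(p)) for p in patch], dtype=np.int64),
                    trigger_sigma=sig,
                    aux_pairs=np.asarray(aux_pairs, dtype=np.int64).reshape(-1, 2),
                    aux_sigma=np.asarray(aux_sigma),
                    trigger_size=len(patch),
                )
                if group.trigger_size != spec.trigger_size:
                    raise FixtureError(
                        f"patch yields {group.trigger_size} trigger contacts, "
                        f"spec demands {spec.trigger_size}"
                    )
                groups.append(group)
                for (a, b), s in zip(group.trigger_pairs, group.trigger_sigma):
                    contacts.add(int(a), int(b), float(s), 0.6, group.tag())
                for (a, b), s in zip(group.aux_pairs, group.aux_sigma):
                    contacts.add(int(a), int(b), float(s), 0.6, group.tag())

    system = CGSystem(topology, contacts, groups)
    system.metadata = {
        "patch_beads": patch_beads,
        "catalytic_asp_bead": {c: patch_beads[c][0] for c in patch_beads},
        "gamma_phosphate_bead": {c: patch_beads[c][1] for c in patch_beads},
        "fold_slices": fold_slices,
        "tail_slices": tail_slices,
        "spec": spec,
    }
    return system


def topology_hash(system: CGSystem) -> str:
    """Stable content hash of a generated system (reproducibility check)."""
    h = hashlib.sha256()
    top = system.topology
    for arr in (top.positions, top.charge, top.bonds, top.angles, top.dihedrals,
                system.contacts.i, system.contacts.j, system.contacts.sigma):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def make_tether_series(base: ToyDimerSpec, tether_lengths) -> list:
    """Specs identical to ``base`` except for the (single) P-site tether."""
    out = []
    for length in tether_lengths:
        out.append(
            dataclasses.replace(
                base,
                psite_tethers={c: [length] for c in base.psite_tethers},
            )
        )
    return out


# ---------------------------------------------------------------------------
# Docked/near-docked starting coordinates
# ---------------------------------------------------------------------------


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def docked_coordinates(system: CGSystem, group: PSiteContactGroup, ff=None) -> np.ndarray:
    """Start coordinates with the group's tyrosine bound in the docked pose.

    The whole tail is rigidly rotated about its anchor (preserving every
    internal angle and dihedral, hence introducing no elastic strain), then
    the tyrosine is pulled onto the pose by a steered minimization and the
    state relaxed freely.  The result has all trigger contacts formed and
    is locally stable under the force field.
    """
    from .dynamics import minimize
    from .forcefield import GoForceField, total_energy

    ff = ff or GoForceField()
    top = system.topology
    pos = top.positions.copy()
    patch = group.trigger_pairs[:, 1]
    centers = pos[patch]
    from scipy.optimize import least_squares

    x0 = centers.mean(axis=0) + np.array([0.0, 0.0, DOCK_HEIGHT])
    pose = least_squares(
        lambda x: np.linalg.norm(centers - x, axis=1) - group.trigger_sigma, x0
    ).x

    t0, t1 = system.metadata["tail_slices"][group.psite_chain]
    anchor = pos[t0 - 1]  # fold exit bead
    tyr = group.tyr_bead
    contour = (tyr - t0 + 1) * BOND_LENGTH
    dist = float(np.linalg.norm(pose - anchor))
    if contour < dist:
        raise FixtureError(
            f"tether too short to reach the docked pose (contour {contour:.1f} A "
            f"< distance {dist:.1f} A); needs >= {int(np.ceil(dist / BOND_LENGTH))} residues"
        )
    # rigid rotation of the tail about the anchor: tyr direction -> pose direction
    v_nat = pos[tyr] - anchor
    rot = _rotation_between(v_nat / np.linalg.norm(v_nat), (pose - anchor) / dist)
    pos[t0:t1] = (pos[t0:t1] - anchor) @ rot.T + anchor

    # steered descent: spring drags the tyrosine the remaining distance;
    # the pose target tracks the current patch geometry (the fold may drift)
    k_pull = 5.0
    for it in range(4000):
        if it % 50 == 0:
            pose = least_squares(
                lambda x: np.linalg.norm(pos[patch] - x, axis=1) - group.trigger_sigma,
                pose,
            ).x
        _, _, forces = total_energy(pos, top, ff, system.contacts)
        forces[tyr] += k_pull * (pose - pos[tyr])
        norms = np.linalg.norm(forces, axis=1)
        disp = forces * (0.1 / max(norms.max(), 1e-12))
        pos += disp
        if np.linalg.norm(pos[tyr] - pose) < 0.3 and norms.max() < 60.0:
            break
    pos = minimize(system, ff, pos, n_steps=300)
    if group.formed_count(pos) < group.trigger_size:
        raise FixtureError(
            f"steered docking of {group.site_id} did not settle into the pose"
        )
    return pos


def near_docked_system(system: CGSystem, start: np.ndarray) -> tuple:
    """System + start pinned at trigger_size - 1 formed contacts, forever.

    One trigger pair of the (first) productive group gets a reference
    separation far below the excluded-volume contact distance, so that
    contact can never register as formed: the state sits at eight of nine
    contacts and the strict all-contacts-simultaneous trigger never fires.
    The pair's attractive term is dropped alongside.
    """
    mod = system.copy()
    grp = mod.productive_groups()[0]
    a, b = (int(x) for x in grp.trigger_pairs[0])
    grp.trigger_sigma = grp.trigger_sigma.copy()
    grp.trigger_sigma[0] = 2.0  # formed would need r <= ~2.7 A: sterically excluded
    keep = ~(((mod.contacts.i == a) & (mod.contacts.j == b))
             | ((mod.contacts.i == b) & (mod.contacts.j == a)))
    mod.contacts = NativeContactSet(
        mod.contacts.i[keep], mod.contacts.j[keep],
        mod.contacts.sigma[keep], mod.contacts.eps[keep],
        [t for t, k in zip(mod.contacts.tag, keep) if k],
    )
    if grp.formed_count(start) != grp.trigger_size - 1:
        raise FixtureError("near-docked construction failed to pin at trigger-1")
    return mod, start


# ---------------------------------------------------------------------------
# Micro-fixtures with analytic reference behaviour
# ---------------------------------------------------------------------------


def _bare_topology(positions, bonds=(), angles=(), dihedrals=(), charge=None, side=None, chains=None, resids=None):
    positions = np.asarray(positions, dtype=np.float64)
    n = len(positions)
    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    angles = np.asarray(angles, dtype=np.int64).reshape(-1, 3)
    dihedrals = np.asarray(dihedrals, dtype=np.int64).reshape(-1, 4)
    side_arr = np.asarray(side if side is not None else [-1] * n, dtype=np.int8)
    return PseudoAtomTopology(
        positions=positions,
        chain=np.asarray(chains if chains is not None else ["A"] * n),
        resid=np.asarray(resids if resids is not None else np.arange(1, n + 1), dtype=np.int64),
        resname=np.full(n, "GLY"),
        kind=np.full(n, "residue"),
        region=np.full(n, "modeled"),
        charge=np.asarray(charge if charge is not None else np.zeros(n), dtype=np.float64),
        radius=np.full(n, 5.3),
        bonds=bonds,
        bond_req=np.linalg.norm(positions[bonds[:, 0]] - positions[bonds[:, 1]], axis=1) if len(bonds) else np.zeros(0),
        angles=angles,
        angle_eq=np.array([_angle(*positions[t]) for t in angles]) if len(angles) else np.zeros(0),
        dihedrals=dihedrals,
        dihedral_native=np.array([_dihedral(*positions[q]) for q in dihedrals]) if len(dihedrals) else np.zeros(0),
        membrane_side=side_arr,
        tm_z0=np.where(side_arr == 0, positions[:, 2], np.nan),
    )


def make_unit_systems() -> dict:
    """Library of micro-fixtures with analytic reference behaviour.

    Keys: ``bond``, ``angle``, ``dihedral``, ``charged_pair``, ``free_bead``,
    ``wall_bead``, ``pre_docked``, ``near_docked``.  The docked fixtures are
    (system, start_coords) pairs on a small toy dimer.
    """
    out = {}
    out["bond"] = CGSystem(_bare_topology([[0, 0, -30], [3.8, 0, -30]], bonds=[[0, 1]]), NativeContactSet())
    out["angle"] = CGSystem(
        _bare_topology([[0, 0, -30], [3.8, 0, -30], [5.5, 3.0, -30]], bonds=[[0, 1], [1, 2]], angles=[[0, 1, 2]]),
        NativeContactSet(),
    )
    out["dihedral"] = CGSystem(
        _bare_topology(
            [[0, 0, -30], [3.8, 0, -30], [5.5, 3.0, -30], [8.0, 3.5, -27.0]],
            bonds=[[0, 1], [1, 2], [2, 3]],
            angles=[[0, 1, 2], [1, 2, 3]],
            dihedrals=[[0, 1, 2, 3]],
        ),
        NativeContactSet(),
    )
    out["charged_pair"] = CGSystem(
        _bare_topology([[0, 0, -30], [8.0, 0, -30]], charge=[1.0, -1.0], chains=["A", "B"], resids=[1, 1]),
        NativeContactSet(),
    )
    out["free_bead"] = CGSystem(_bare_topology([[0.0, 0.0, -30.0]]), NativeContactSet())
    out["wall_bead"] = CGSystem(_bare_topology([[0.0, 0.0, 25.0]], side=[1]), NativeContactSet())

    spec = ToyDimerSpec(psite_tethers={"A": [8]}, seed=7)
    toy = make_toy_dimer(spec)
    grp = toy.productive_groups()[0]
    out["pre_docked"] = (toy, docked_coordinates(toy, grp))
    out["near_docked"] = near_docked_system(toy, out["pre_docked"][1])
    return out
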