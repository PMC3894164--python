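"""Go-model energy terms, forces, and the non-bonded pair schedule.

All terms are vectorized NumPy reference implementations returning
``(energy, forces)`` with forces the exact negative gradient; the dynamics
module carries numba-compiled equivalents for production runs, validated
against these.  Conventions (documented prominently because the printed
constants are ambiguous about them):

* harmonic terms are ``k * (delta)**2`` -- no factor 1/2 -- so a bond
  stretched 1 A at k_bond = 20 kcal/mol/A^2 costs exactly 20 kcal/mol;
* the attractive well defaults to the 12-10-6 form
  ``eps * (13 s^12 - 18 s^10 + 4 s^6)`` with ``s = sigma_ij/r``, whose
  minimum is ``-eps`` at ``r = sigma_ij``; a 12-10 form
  ``eps * (5 s^12 - 6 s^10)`` is selectable;
* dihedral phases put the native dihedral at the energy minimum:
  ``phi1 = phi_native + pi`` and ``phi3 = 3 phi_native + pi``;
* the Debye screening length is derived from the ionic strength and
  temperature, and electrostatics carry no distance cutoff.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import constants
from .coarse_grain import MIN_SEQ_SEPARATION, NativeContactSet, PseudoAtomTopology

#: regularization added to sin(theta) in angle gradients near collinearity
ANGLE_EPSILON = 1e-8


class SingularGeometryError(ValueError):
    """Beads are (nearly) coincident."""


@dataclasses.dataclass
class GoForceField:
    """All energy-term parameters (defaults are the published values)."""

    k_bond: float = 20.0  # kcal/mol/A^2
    k_angle: float = 10.0  # kcal/mol/rad^2
    v1: float = 0.5  # kcal/mol, 1-fold dihedral barrier
    v3: float = 0.25  # kcal/mol, 3-fold dihedral barrier
    contact_eps: float = 0.6  # kcal/mol
    sigma_vdw: float = 4.0  # A
    repulsive_eps: float = 0.6  # kcal/mol
    ionic_strength: float = 0.15  # M
    dielectric: float = 78.4
    temperature: float = 298.0  # K
    z_wall: float = 16.5  # A (membrane planes at +/- z_wall; separation 33 A)
    k_restraint: float = 5.0  # kcal/mol/A^2 (TM z restraint)
    k_wall: float = 5.0  # kcal/mol/A^2 (half-harmonic walls)
    short_cutoff: float = 12.5  # A
    medium_cutoff: float = 25.0  # A
    contact_form: str = "12-10-6"  # or "12-10"

    def __post_init__(self):
        for name in (
            "k_bond", "k_angle", "v1", "v3", "contact_eps", "sigma_vdw",
            "repulsive_eps", "dielectric", "temperature", "z_wall",
            "k_restraint", "k_wall", "short_cutoff", "medium_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic_strength must be non-negative")
        if self.contact_form not in ("12-10-6", "12-10"):
            raise ValueError("contact_form must be '12-10-6' or '12-10'")

    @property
    def kbt(self) -> float:
        return constants.KB * self.temperature

    @property
    def debye_length(self) -> float:
        return constants.debye_length(self.ionic_strength, self.dielectric, self.temperature)

    @property
    def plane_separation(self) -> float:
        return 2.0 * self.z_wall


# ---------------------------------------------------------------------------
# Bonded terms
# ---------------------------------------------------------------------------


def bonded_energy(coords: np.ndarray, topology: PseudoAtomTopology, ff: GoForceField):
    """Bond + angle + dihedral energy and forces."""
    f = np.zeros_like(coords)
    e = 0.0

    if len(topology.bonds):
        ri = coords[topology.bonds[:, 0]]
        rj = coords[topology.bonds[:, 1]]
        dv = rj - ri
        r = np.linalg.norm(dv, axis=1)
        if np.any(r < 1e-6):
            raise SingularGeometryError("bonded beads coincide")
        delta = r - topology.bond_req
        e += ff.k_bond * np.sum(delta**2)
        # dE/dr = 2 k delta; force on j is -dE/dr * unit(j-i)
        coef = (2.0 * ff.k_bond * delta / r)[:, None]
        np.add.at(f, topology.bonds[:, 0], coef * dv)
        np.add.at(f, topology.bonds[:, 1], -coef * dv)

    if len(topology.angles):
        i, j, k = topology.angles.T
        v1 = coords[i] - coords[j]
        v2 = coords[k] - coords[j]
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        cos_t = np.clip(np.sum(v1 * v2, axis=1) / (n1 * n2), -1.0, 1.0)
        theta = np.arccos(cos_t)
        delta = theta - topology.angle_eq
        e += ff.k_angle * np.sum(delta**2)
        dedt = 2.0 * ff.k_angle * delta
        sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, ANGLE_EPSILON**2))
        u1 = v1 / n1[:, None]
        u2 = v2 / n2[:, None]
        dthi = (cos_t[:, None] * u1 - u2) / (n1 * sin_t)[:, None]
        dthk = (cos_t[:, None] * u2 - u1) / (n2 * sin_t)[:, None]
        fi = -dedt[:, None] * dthi
        fk = -dedt[:, None] * dthk
        np.add.at(f, i, fi)
        np.add.at(f, k, fk)
        np.add.at(f, j, -(fi + fk))

    if len(topology.dihedrals):
        ii, jj, kk, ll = topology.dihedrals.T
        b1 = coords[jj] - coords[ii]
        b2 = coords[kk] - coords[jj]
        b3 = coords[ll] - coords[kk]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = np.linalg.norm(b2, axis=1)
        # near-collinear quadruplets: dihedral ill-conditioned (grad ~ 1/sin);
        # contribution zeroed below sin(theta) = 0.02 (matches the kernel)
        b1sq = np.sum(b1 * b1, axis=1)
        b3sq = np.sum(b3 * b3, axis=1)
        ok = (np.sum(n1 * n1, axis=1) >= 4e-4 * b1sq * b2n**2) & (
            np.sum(n2 * n2, axis=1) >= 4e-4 * b2n**2 * b3sq
        )
        native = topology.dihedral_native
        if not ok.all():
            ii, jj, kk, ll = ii[ok], jj[ok], kk[ok], ll[ok]
            b1, b2, b3, n1, n2, b2n = b1[ok], b2[ok], b3[ok], n1[ok], n2[ok], b2n[ok]
            native = native[ok]
        if not len(b1):
            return float(e), f
        m1 = np.cross(n1, b2 / b2n[:, None])
        x = np.sum(n1 * n2, axis=1)
        y = np.sum(m1 * n2, axis=1)
        phi = np.arctan2(y, x)
        phi1 = native + np.pi
        phi3 = 3.0 * native + np.pi
        e += np.sum(
            0.5 * ff.v1 * (1.0 + np.cos(phi - phi1))
            + 0.5 * ff.v3 * (1.0 + np.cos(3.0 * phi - phi3))
        )
        dedphi = -0.5 * ff.v1 * np.sin(phi - phi1) - 1.5 * ff.v3 * np.sin(3.0 * phi - phi3)
        n1sq = np.sum(n1 * n1, axis=1)
        n2sq = np.sum(n2 * n2, axis=1)
        # dphi/dri = +|b2| n1/|n1|^2 ; dphi/drl = -|b2| n2/|n2|^2 (this phi
        # convention); middle atoms follow from translational invariance
        gi = (b2n / n1sq)[:, None] * n1
        gl = -(b2n / n2sq)[:, None] * n2
        t1 = (np.sum(b1 * b2, axis=1) / b2n**2)[:, None]
        t2 = (np.sum(b3 * b2, axis=1) / b2n**2)[:, None]
        gj = -gi - t1 * gi + t2 * gl
        gk = -gl + t1 * gi - t2 * gl
        fi = -dedphi[:, None] * gi
        fj = -dedphi[:, None] * gj
        fk2 = -dedphi[:, None] * gk
        fl = -dedphi[:, None] * gl
        np.add.at(f, ii, fi)
        np.add.at(f, jj, fj)
        np.add.at(f, kk, fk2)
        np.add.at(f, ll, fl)

    return float(e), f


# ---------------------------------------------------------------------------
# Non-bonded terms
# ---------------------------------------------------------------------------


def contact_energy(coords: np.ndarray, contacts: NativeContactSet, ff: GoForceField):
    """Native-contact attractive wells: minimum -eps at r = sigma_ij."""
    f = np.zeros_like(coords)
    if not len(contacts):
        return 0.0, f
    dv = coords[contacts.j] - coords[contacts.i]
    r = np.linalg.norm(dv, axis=1)
    if np.any(r < 1e-6):
        raise SingularGeometryError("contact pair beads coincide")
    s = contacts.sigma / r
    eps = contacts.eps
    if ff.contact_form == "12-10-6":
        u = eps * (13.0 * s**12 - 18.0 * s**10 + 4.0 * s**6)
        dudr = eps * (-12.0 * 13.0 * s**12 + 10.0 * 18.0 * s**10 - 6.0 * 4.0 * s**6) / r
    else:
        u = eps * (5.0 * s**12 - 6.0 * s**10)
        dudr = eps * (-60.0 * s**12 + 60.0 * s**10) / r
    coef = (dudr / r)[:, None]
    np.add.at(f, contacts.i, coef * dv)
    np.add.at(f, contacts.j, -coef * dv)
    return float(np.sum(u)), f


def repulsive_energy(coords: np.ndarray, pairs: np.ndarray, ff: GoForceField):
    """Strictly repulsive excluded-volume term eps*(sigma_vdw/r)^12."""
    f = np.zeros_like(coords)
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if not len(pairs):
        return 0.0, f
    dv = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    r = np.linalg.norm(dv, axis=1)
    if np.any(r < 1e-6):
        raise SingularGeometryError("repulsive pair beads coincide")
    s12 = (ff.sigma_vdw / r) ** 12
    u = ff.repulsive_eps * s12
    dudr = -12.0 * u / r
    coef = (dudr / r)[:, None]
    np.add.at(f, pairs[:, 0], coef * dv)
    np.add.at(f, pairs[:, 1], -coef * dv)
    return float(np.sum(u)), f


def electrostatic_energy(coords: np.ndarray, charges: np.ndarray, ff: GoForceField, pairs: np.ndarray | None = None):
    """Debye-Hueckel screened Coulomb energy over the given pairs (no cutoff).

    ``pairs`` defaults to every i<j pair with a non-zero charge product.
    """
    charges = np.asarray(charges, dtype=np.float64)
    f = np.zeros_like(coords)
    if pairs is None:
        nz = np.flatnonzero(charges != 0)
        pairs = np.array([(a, b) for ai, a in enumerate(nz) for b in nz[ai + 1:]], dtype=np.int64).reshape(-1, 2)
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if not len(pairs):
        return 0.0, f
    qq = charges[pairs[:, 0]] * charges[pairs[:, 1]]
    keep = qq != 0
    pairs, qq = pairs[keep], qq[keep]
    if not len(pairs):
        return 0.0, f
    dv = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    r = np.linalg.norm(dv, axis=1)
    if np.any(r < 1e-6):
        raise SingularGeometryError("charged pair beads coincide")
    lam = ff.debye_length
    screen = np.exp(-r / lam) if np.isfinite(lam) else 1.0
    u = constants.COULOMB * qq * screen / (ff.dielectric * r)
    dudr = -u / r - (u / lam if np.isfinite(lam) else 0.0)
    coef = (dudr / r)[:, None]
    np.add.at(f, pairs[:, 0], coef * dv)
    np.add.at(f, pairs[:, 1], -coef * dv)
    return float(np.sum(u)), f


def membrane_energy(coords: np.ndarray, topology: PseudoAtomTopology, ff: GoForceField):
    """Membrane slab: TM z-restraints plus half-harmonic walls.

    TM beads: ``k_restraint (z - z0)^2``.  Extracellular beads are penalized
    only below the outer plane (z < z_wall); intracellular and nucleotide
    beads only above the inner plane (z > -z_wall).
    """
    f = np.zeros_like(coords)
    z = coords[:, 2]
    e = 0.0

    tm = topology.membrane_side == 0
    if tm.any():
        dz = z[tm] - topology.tm_z0[tm]
        e += ff.k_restraint * np.sum(dz**2)
        f[tm, 2] -= 2.0 * ff.k_restraint * dz

    ext = topology.membrane_side == 1
    if ext.any():
        pen = np.minimum(z[ext] - ff.z_wall, 0.0)
        e += ff.k_wall * np.sum(pen**2)
        f[ext, 2] -= 2.0 * ff.k_wall * pen

    intr = topology.membrane_side == -1
    if intr.any():
        pen = np.maximum(z[intr] + ff.z_wall, 0.0)
        e += ff.k_wall * np.sum(pen**2)
        f[intr, 2] -= 2.0 * ff.k_wall * pen

    return float(e), f


# ---------------------------------------------------------------------------
# Pair schedule
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PairSchedule:
    """Non-bonded pair classification at build time.

    Short-range pairs (<= short cutoff) are evaluated every step; medium
    pairs (short..medium cutoff) at their slower cadence with forces held in
    between; electrostatic pairs are listed separately and unrestricted by
    distance.
    """

    short_pairs: np.ndarray
    medium_pairs: np.ndarray
    elec_pairs: np.ndarray
    rebuild_interval_ps: float = 6.0
    medium_interval_ps: float = 1.0


def nonbonded_candidate_pairs(topology: PseudoAtomTopology, contacts: NativeContactSet) -> np.ndarray:
    """All pairs eligible for the repulsive term.

    Excluded: same-chain residue pairs closer than three in sequence, bonded
    pairs (including the fully bonded nucleotide cage) and native-contact
    pairs (which carry the attractive well instead).
    """
    n = topology.n_beads
    ii, jj = np.triu_indices(n, k=1)
    same_chain = topology.chain[ii] == topology.chain[jj]
    both_res = (topology.kind[ii] == "residue") & (topology.kind[jj] == "residue")
    near_seq = same_chain & both_res & (
        np.abs(topology.resid[ii] - topology.resid[jj]) < MIN_SEQ_SEPARATION
    )
    keep = ~near_seq
    if len(topology.bonds) or len(contacts):
        keys = ii.astype(np.int64) * n + jj
        excl = []
        if len(topology.bonds):
            b = np.sort(topology.bonds, axis=1)
            excl.append(b[:, 0].astype(np.int64) * n + b[:, 1])
        if len(contacts):
            ci = np.minimum(contacts.i, contacts.j).astype(np.int64)
            cj = np.maximum(contacts.i, contacts.j).astype(np.int64)
            excl.append(ci * n + cj)
        keep &= ~np.isin(keys, np.concatenate(excl))
    return np.column_stack([ii[keep], jj[keep]]).astype(np.int64)


def electrostatic_pairs(topology: PseudoAtomTopology) -> np.ndarray:
    """Charged non-bonded pairs (sequence separation >= 3; no cutoff)."""
    n = topology.n_beads
    nz = np.flatnonzero(topology.charge != 0)
    if len(nz) < 2:
        return np.zeros((0, 2), dtype=np.int64)
    ai, bi = np.triu_indices(len(nz), k=1)
    ii, jj = nz[ai], nz[bi]
    same_chain = topology.chain[ii] == topology.chain[jj]
    both_res = (topology.kind[ii] == "residue") & (topology.kind[jj] == "residue")
    keep = ~(
        same_chain & both_res
        & (np.abs(topology.resid[ii] - topology.resid[jj]) < MIN_SEQ_SEPARATION)
    )
    if len(topology.bonds):
        b = np.sort(topology.bonds, axis=1)
        keys = np.minimum(ii, jj).astype(np.int64) * n + np.maximum(ii, jj)
        keep &= ~np.isin(keys, b[:, 0].astype(np.int64) * n + b[:, 1])
    return np.column_stack([ii[keep], jj[keep]]).astype(np.int64)


def build_schedule(
    coords: np.ndarray,
    topology: PseudoAtomTopology,
    ff: GoForceField,
    contacts: NativeContactSet,
    candidates: np.ndarray | None = None,
) -> PairSchedule:
    """Classify repulsive candidates into short/medium lists by distance."""
    if candidates is None:
        candidates = nonbonded_candidate_pairs(topology, contacts)
    if len(candidates):
        r = np.linalg.norm(coords[candidates[:, 0]] - coords[candidates[:, 1]], axis=1)
        if np.any(r < 1e-6):
            raise SingularGeometryError("overlapping beads at schedule build")
        short = candidates[r <= ff.short_cutoff]
        medium = candidates[(r > ff.short_cutoff) & (r < ff.medium_cutoff)]
    else:
        short = medium = np.zeros((0, 2), dtype=np.int64)
    return PairSchedule(
        short_pairs=short,
        medium_pairs=medium,
        elec_pairs=electrostatic_pairs(topology),
    )


def total_energy(
    coords: np.ndarray,
    topology: PseudoAtomTopology,
    ff: GoForceField,
    contacts: NativeContactSet,
    schedule: PairSchedule | None = None,
):
    """Full energy with per-term breakdown and forces.

    The breakdown sums to the total exactly; with a fresh schedule this is
    the exact instantaneous energy (no held medium-range values).
    """
    if schedule is None:
        schedule = build_schedule(coords, topology, ff, contacts)
    breakdown = {}
    forces = np.zeros_like(coords)
    e, f = bonded_energy(coords, topology, ff)
    breakdown["bonded"] = e
    forces += f
    e, f = contact_energy(coords, contacts, ff)
    breakdown["contact"] = e
    forces += f
    rep_pairs = (
        np.vstack([schedule.short_pairs, schedule.medium_pairs])
        if len(schedule.medium_pairs)
        else schedule.short_pairs
    )
    e, f = repulsive_energy(coords, rep_pairs, ff)
    breakdown["repulsive"] = e
    forces += f
    e, f = electrostatic_energy(coords, topology.charge, ff, schedule.elec_pairs)
    breakdown["electrostatic"] = e
    forces += f
    e, f = membrane_energy(coords, topology, ff)
    breakdown["membrane"] = e
    forces += f
    return sum(breakdown.values()), breakdown, forces
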