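"""Pseudo-atom topology and Go-model interaction assignment.

Each amino-acid residue maps to a single bead centered on its C-alpha atom;
a bound nucleotide-substrate complex (AMPPNP plus two Mg2+) maps to nine
finer-grained beads centered on named atoms and fully interconnected by
harmonic bonds.  Native contacts are residue pairs whose all-atom minimum
distance falls within a cutoff (5.5 A) in the reference structure, with the
attractive-well minimum placed at the reference pseudo-atom separation.
P-site contact groups carry the tyrosine/active-site contacts whose
simultaneous formation defines a productive binding event.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Iterable, Sequence

import numpy as np

from .structure_io import AnnotatedStructure

RESIDUE_RADIUS = 5.3  # A, hydrodynamic radius of an amino-acid bead
NUCLEOTIDE_RADIUS = 3.5  # A, nucleotide-complex beads
CONTACT_CUTOFF = 5.5  # A, all-atom native-contact detection
CONTACT_EPS = 0.6  # kcal/mol, well depth
MIN_SEQ_SEPARATION = 3  # residues; pairs closer in sequence are bonded/excluded

#: atom names defining the nine nucleotide-complex beads (synonyms allowed)
NUCLEOTIDE_BEAD_ATOMS = [
    ("C2",),
    ("C6",),
    ("N9",),
    ("C4'", "C4*"),
    ("PA", "P1"),
    ("PB", "P2"),
    ("PG", "P3"),
    ("MG", "MG1"),
    ("MG", "MG2"),
]

PHOSPHATE_CHARGE = -4.0 / 3.0
MG_CHARGE = 2.0

NEGATIVE_RESIDUES = {"ASP", "GLU"}
POSITIVE_RESIDUES = {"LYS", "ARG"}
STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

HIS_PKA = 6.0
CHARGE_SIGNIFICANCE = 0.1  # |q| below this is zeroed ("significant" charge)

MEMBRANE_TM = 0
MEMBRANE_EXTRACELLULAR = 1
MEMBRANE_INTRACELLULAR = -1


class TopologyError(ValueError):
    """Structure cannot be coarse-grained."""


@dataclasses.dataclass
class PseudoAtomTopology:
    """The coarse-grained system: beads, bonded terms, charges, membrane roles.

    Reference geometry (``bond_req``, ``angle_eq``, ``dihedral_native``) is
    measured on the structure the topology was built from; the force field
    treats it as the energy minimum.
    """

    positions: np.ndarray  # (N, 3) A
    chain: np.ndarray  # (N,) chain id
    resid: np.ndarray  # (N,) parent residue index
    resname: np.ndarray  # (N,)
    kind: np.ndarray  # (N,) 'residue' | 'nucleotide'
    region: np.ndarray  # (N,) region label
    charge: np.ndarray  # (N,) e
    radius: np.ndarray  # (N,) A
    bonds: np.ndarray  # (B, 2) int
    bond_req: np.ndarray  # (B,) A
    angles: np.ndarray  # (A, 3) int
    angle_eq: np.ndarray  # (A,) rad
    dihedrals: np.ndarray  # (D, 4) int
    dihedral_native: np.ndarray  # (D,) rad
    membrane_side: np.ndarray  # (N,) {0: TM, +1: extracellular, -1: intracellular}
    tm_z0: np.ndarray  # (N,) reference z for TM beads (nan elsewhere)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def copy(self) -> "PseudoAtomTopology":
        return PseudoAtomTopology(
            **{
                f.name: getattr(self, f.name).copy()
                for f in dataclasses.fields(self)
            }
        )

    def bead_index(self, chain: str, resid: int) -> int:
        hits = np.flatnonzero((self.chain == chain) & (self.resid == resid) & (self.kind == "residue"))
        if len(hits) != 1:
            raise KeyError(f"no unique bead for {chain}:{resid}")
        return int(hits[0])

    def sequence_separation(self, i: int, j: int) -> float:
        """Residue separation, inf across chains or for nucleotide beads."""
        if (
            self.kind[i] != "residue"
            or self.kind[j] != "residue"
            or self.chain[i] != self.chain[j]
        ):
            return np.inf
        return abs(int(self.resid[i]) - int(self.resid[j]))


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m = np.cross(n1, b1 / np.linalg.norm(b1))
    return float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


def _angle(p0, p1, p2) -> float:
    v1 = p0 - p1
    v2 = p2 - p1
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _membrane_side(region: str, z: float, z_wall: float) -> int:
    if region == "transmembrane":
        return MEMBRANE_TM
    if region in ("extracellular", "ligand"):
        return MEMBRANE_EXTRACELLULAR
    if region in ("intracellular", "nucleotide-complex"):
        return MEMBRANE_INTRACELLULAR
    # structured/modeled segments sit on whichever side their reference
    # coordinates place them
    return MEMBRANE_EXTRACELLULAR if z >= 0 else MEMBRANE_INTRACELLULAR


def coarse_grain(structure: AnnotatedStructure, z_wall: float = 16.5) -> PseudoAtomTopology:
    """Map an annotated all-atom structure to the pseudo-atom topology.

    One bead per protein residue (on the C-alpha); nine beads per
    nucleotide-complex (adenine C2/C6/N9, deoxyribose C4', the three
    phosphorus atoms and the two Mg), the latter fully interconnected by
    harmonic bonds.  Chain-sequential residue beads get bond, angle and
    dihedral terms whose reference values are measured on the input
    coordinates.
    """
    atoms = structure.atoms
    positions, chain, resid, resname, kind, region = [], [], [], [], [], []

    import biotite.structure as struc

    starts = struc.get_residue_starts(atoms)
    stops = list(starts[1:]) + [atoms.array_length()]
    # protein (and ligand) residues -> CA beads
    nuc_atoms_by_chain: dict[str, list[int]] = {}
    for s, e in zip(starts, stops):
        reg = str(atoms.region[s])
        ch = str(atoms.chain_id[s])
        if reg == "nucleotide-complex":
            nuc_atoms_by_chain.setdefault(ch, []).extend(range(s, e))
            continue
        names = list(atoms.atom_name[s:e])
        if "CA" not in names:
            raise TopologyError(
                f"residue {ch}:{int(atoms.res_id[s])} ({atoms.res_name[s]}) has no CA atom"
            )
        positions.append(atoms.coord[s + names.index("CA")])
        chain.append(ch)
        resid.append(int(atoms.res_id[s]))
        resname.append(str(atoms.res_name[s]))
        kind.append("residue")
        region.append(reg)

    # nucleotide complexes: nine named beads per chain carrying the label
    for ch, idxs in sorted(nuc_atoms_by_chain.items()):
        names = [str(atoms.atom_name[i]) for i in idxs]
        used: set[int] = set()
        for bead_no, synonyms in enumerate(NUCLEOTIDE_BEAD_ATOMS):
            hit = None
            for k, nm in enumerate(names):
                if k in used:
                    continue
                if nm in synonyms:
                    hit = k
                    break
            if hit is None:
                raise TopologyError(
                    f"nucleotide complex in chain {ch} lacks atom {'/'.join(synonyms)}"
                )
            used.add(hit)
            i = idxs[hit]
            positions.append(atoms.coord[i])
            chain.append(ch)
            resid.append(int(atoms.res_id[i]))
            resname.append(str(atoms.res_name[i]))
            kind.append("nucleotide")
            region.append("nucleotide-complex")

    positions = np.asarray(positions, dtype=np.float64)
    chain = np.asarray(chain)
    resid = np.asarray(resid, dtype=np.int64)
    resname = np.asarray(resname)
    kind = np.asarray(kind)
    region = np.asarray(region)
    n = len(positions)

    radius = np.where(kind == "residue", RESIDUE_RADIUS, NUCLEOTIDE_RADIUS)
    charge = np.zeros(n)

    bonds, angles, dihedrals = [], [], []
    # protein chains: consecutive residues
    res_mask = kind == "residue"
    for ch in np.unique(chain[res_mask]):
        order = np.flatnonzero(res_mask & (chain == ch))
        order = order[np.argsort(resid[order])]
        for a, b in zip(order[:-1], order[1:]):
            if resid[b] - resid[a] == 1:
                bonds.append((int(a), int(b)))
        for a, b, c in zip(order[:-2], order[1:-1], order[2:]):
            if resid[c] - resid[a] == 2:
                angles.append((int(a), int(b), int(c)))
        for a, b, c, d in zip(order[:-3], order[1:-2], order[2:-1], order[3:]):
            if resid[d] - resid[a] == 3:
                dihedrals.append((int(a), int(b), int(c), int(d)))
    # nucleotide complexes: every bead pair bonded (rigid harmonic cage)
    for ch in sorted(nuc_atoms_by_chain):
        beads = np.flatnonzero((kind == "nucleotide") & (chain == ch))
        for x in range(len(beads)):
            for y in range(x + 1, len(beads)):
                bonds.append((int(beads[x]), int(beads[y])))

    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    angles = np.asarray(angles, dtype=np.int64).reshape(-1, 3)
    dihedrals = np.asarray(dihedrals, dtype=np.int64).reshape(-1, 4)

    bond_req = np.linalg.norm(positions[bonds[:, 0]] - positions[bonds[:, 1]], axis=1) if len(bonds) else np.zeros(0)
    angle_eq = np.array([_angle(*positions[t]) for t in angles]) if len(angles) else np.zeros(0)
    dihedral_native = np.array([_dihedral(*positions[q]) for q in dihedrals]) if len(dihedrals) else np.zeros(0)

    side = np.array([_membrane_side(r, z, z_wall) for r, z in zip(region, positions[:, 2])], dtype=np.int8)
    tm_z0 = np.where(side == MEMBRANE_TM, positions[:, 2], np.nan)

    return PseudoAtomTopology(
        positions=positions, chain=chain, resid=resid, resname=resname,
        kind=kind, region=region, charge=charge, radius=radius,
        bonds=bonds, bond_req=bond_req, angles=angles, angle_eq=angle_eq,
        dihedrals=dihedrals, dihedral_native=dihedral_native,
        membrane_side=side, tm_z0=tm_z0,
    )


# ---------------------------------------------------------------------------
# Native contacts
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class NativeContactSet:
    """Attractive-pair list: (i, j, sigma_ij, eps, tag).

    ``sigma_ij`` is the reference pseudo-atom separation (the well minimum);
    tags classify pairs as ``fold``, ``nucleotide-site`` or ``psite:<id>``.
    """

    i: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    j: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    sigma: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(0))
    eps: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(0))
    tag: list = dataclasses.field(default_factory=list)

    def __post_init__(self):
        if np.any(self.sigma <= 0) and len(self.sigma):
            raise ValueError("sigma_ij must be positive")

    def __len__(self) -> int:
        return len(self.i)

    def pairs(self) -> set:
        return {(min(a, b), max(a, b)) for a, b in zip(self.i, self.j)}

    def add(self, i: int, j: int, sigma: float, eps: float, tag: str) -> None:
        if sigma <= 0:
            raise ValueError("sigma_ij must be positive")
        if (min(i, j), max(i, j)) in self.pairs():
            return
        self.i = np.append(self.i, i)
        self.j = np.append(self.j, j)
        self.sigma = np.append(self.sigma, sigma)
        self.eps = np.append(self.eps, eps)
        self.tag.append(tag)

    def merged(self, other: "NativeContactSet") -> "NativeContactSet":
        out = self.copy()
        for k in range(len(other)):
            out.add(int(other.i[k]), int(other.j[k]), float(other.sigma[k]), float(other.eps[k]), other.tag[k])
        return out

    def copy(self) -> "NativeContactSet":
        return NativeContactSet(self.i.copy(), self.j.copy(), self.sigma.copy(), self.eps.copy(), list(self.tag))

    def select(self, predicate: Callable[[str], bool]) -> "NativeContactSet":
        keep = np.array([predicate(t) for t in self.tag], dtype=bool)
        return NativeContactSet(
            self.i[keep], self.j[keep], self.sigma[keep], self.eps[keep],
            [t for t, k in zip(self.tag, keep) if k],
        )

    def without_psite_terms(self) -> "NativeContactSet":
        return self.select(lambda t: not t.startswith("psite:"))


def default_contact_eligibility(region: str) -> bool:
    """Only elements of known structure form native contacts."""
    return region in ("structured", "ligand", "nucleotide-complex")


def detect_native_contacts(
    structure: AnnotatedStructure,
    topology: PseudoAtomTopology,
    cutoff: float = CONTACT_CUTOFF,
    eligible: Callable[[str], bool] = default_contact_eligibility,
    eps: float = CONTACT_EPS,
) -> NativeContactSet:
    """All-atom native-contact detection mapped onto pseudo-atom pairs.

    A residue pair is a contact iff the minimum over its atom pairs is within
    ``cutoff``, both residues are eligible by region, and the sequence
    separation is at least three.  Nucleotide-complex beads contact a residue
    iff their defining atom is within ``cutoff`` of any atom of that residue.
    ``sigma_ij`` is the pseudo-atom separation in the reference.
    """
    import biotite.structure as struc

    atoms = structure.atoms
    starts = struc.get_residue_starts(atoms)
    stops = list(starts[1:]) + [atoms.array_length()]

    res_keys, res_coords, res_regions = [], [], []
    for s, e in zip(starts, stops):
        reg = str(atoms.region[s])
        if reg == "nucleotide-complex":
            continue
        res_keys.append((str(atoms.chain_id[s]), int(atoms.res_id[s])))
        res_coords.append(atoms.coord[s:e].astype(np.float64))
        res_regions.append(reg)

    contacts = NativeContactSet()
    n = len(res_keys)
    for a in range(n):
        if not eligible(res_regions[a]):
            continue
        for b in range(a + 1, n):
            if not eligible(res_regions[b]):
                continue
            ca, cb = res_keys[a], res_keys[b]
            if ca[0] == cb[0] and abs(ca[1] - cb[1]) < MIN_SEQ_SEPARATION:
                continue
            d = np.linalg.norm(res_coords[a][:, None, :] - res_coords[b][None, :, :], axis=-1)
            if d.min() <= cutoff:
                try:
                    bi = topology.bead_index(*ca)
                    bj = topology.bead_index(*cb)
                except KeyError:
                    continue
                sigma = float(np.linalg.norm(topology.positions[bi] - topology.positions[bj]))
                contacts.add(bi, bj, sigma, eps, "fold")

    # nucleotide beads vs eligible residues
    nuc = np.flatnonzero(topology.kind == "nucleotide")
    for bead in nuc:
        p = topology.positions[bead]
        for b in range(n):
            if not eligible(res_regions[b]):
                continue
            d = np.linalg.norm(res_coords[b] - p, axis=-1)
            if d.min() <= cutoff:
                bj = topology.bead_index(*res_keys[b])
                sigma = float(np.linalg.norm(p - topology.positions[bj]))
                if sigma > 0:
                    contacts.add(int(bead), bj, sigma, eps, "nucleotide-site")
    return contacts


# ---------------------------------------------------------------------------
# Charges
# ---------------------------------------------------------------------------


def histidine_charge(pH: float, pKa: float = HIS_PKA) -> float:
    """Henderson-Hasselbalch fractional protonation of the imidazole."""
    x = 10.0 ** (pKa - pH)
    return x / (1.0 + x)


def assign_charges(
    topology: PseudoAtomTopology,
    pH: float = 7.6,
    include_termini: bool = True,
    titrate_his: bool = True,
    significance: float = CHARGE_SIGNIFICANCE,
) -> PseudoAtomTopology:
    """Assign per-bead charges at the simulation pH.

    Asp/Glu carry -1, Lys/Arg +1; His is titrated by Henderson-Hasselbalch
    and zeroed when below the significance threshold (side chains with pKa
    well above the simulation pH -- Cys, Tyr -- are treated as neutral).
    Free N-/C-termini add +1/-1.  Nucleotide-complex phosphate beads carry
    -4/3 each and Mg beads +2, making the complex net-neutral.
    """
    top = topology.copy()
    q = np.zeros(top.n_beads)
    for idx in range(top.n_beads):
        if top.kind[idx] == "nucleotide":
            continue
        rn = top.resname[idx]
        if rn in NEGATIVE_RESIDUES:
            q[idx] = -1.0
        elif rn in POSITIVE_RESIDUES:
            q[idx] = +1.0
        elif rn == "HIS" and titrate_his:
            q[idx] = histidine_charge(pH)
        elif rn not in STANDARD_RESIDUES:
            warnings.warn(f"unknown residue name {rn!r}: assigned zero charge")

    # nucleotide complexes: bead order within each complex is fixed
    for ch in np.unique(top.chain[top.kind == "nucleotide"]):
        beads = np.flatnonzero((top.kind == "nucleotide") & (top.chain == ch))
        # order matches NUCLEOTIDE_BEAD_ATOMS: 4..6 phosphates, 7..8 Mg
        for off, bead in enumerate(beads):
            if 4 <= off <= 6:
                q[bead] = PHOSPHATE_CHARGE
            elif off >= 7:
                q[bead] = MG_CHARGE

    if include_termini:
        res_mask = top.kind == "residue"
        for ch in np.unique(top.chain[res_mask]):
            order = np.flatnonzero(res_mask & (top.chain == ch))
            order = order[np.argsort(top.resid[order])]
            q[order[0]] += 1.0
            q[order[-1]] -= 1.0

    q[np.abs(q) < significance] = 0.0
    top.charge = q
    return top


# ---------------------------------------------------------------------------
# P-site contact groups
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PSiteContactGroup:
    """One P-site copy monitored against one active site.

    ``trigger_pairs`` are the tyrosine/active-site contacts whose simultaneous
    formation defines a binding event (count == ``trigger_size``);
    ``aux_pairs`` are additional window-residue contacts that stabilize the
    docked pose but do not gate the trigger.  ``productive`` marks groups
    monitoring the catalytic (receiver) site; only those terminate trials.
    """

    site_id: str  # e.g. "992A"
    psite_chain: str
    target_chain: str
    productive: bool
    tyr_bead: int
    window_beads: np.ndarray
    trigger_pairs: np.ndarray  # (m, 2) bead indices
    trigger_sigma: np.ndarray
    aux_pairs: np.ndarray
    aux_sigma: np.ndarray
    trigger_size: int
    enabled: bool = True

    def __post_init__(self):
        if len(self.trigger_pairs) != self.trigger_size:
            raise ValueError(
                f"group {self.site_id}: {len(self.trigger_pairs)} trigger contacts, "
                f"declared trigger size {self.trigger_size}"
            )
        w = np.sort(np.asarray(self.window_beads))
        if len(w) > 1 and not np.all(np.diff(w) == 1):
            raise ValueError(f"group {self.site_id}: window beads are not contiguous")

    @property
    def cis(self) -> bool:
        return self.psite_chain == self.target_chain

    def tag(self) -> str:
        return f"psite:{self.site_id}->{self.target_chain}"

    def formed_count(self, positions: np.ndarray, form_ratio: float = 1.35) -> int:
        d = np.linalg.norm(
            positions[self.trigger_pairs[:, 0]] - positions[self.trigger_pairs[:, 1]], axis=1
        )
        return int(np.sum(d <= form_ratio * self.trigger_sigma))


def build_psite_groups(
    topology: PseudoAtomTopology,
    psite_definitions: Sequence[dict],
    contacts: NativeContactSet,
    receiver_chain: str,
    activator_chain: str,
    eps: float = CONTACT_EPS,
    trigger_size: int = 9,
    validate_trigger: bool = True,
) -> tuple[list[PSiteContactGroup], NativeContactSet]:
    """Instantiate P-site groups on both receptor copies and both active sites.

    Each definition supplies the docked-complex contact pairs once; they are
    mirrored onto the P-site copy of each chain and onto both the catalytic
    (receiver) and the activator active site, with identical ``sigma_ij``.
    Attractive terms for every pair are appended to the contact set under the
    group's tag.  Definitions are dicts with keys ``site_id``, ``tyr_resid``,
    ``window`` (list of resids) and ``contact_pairs`` (list of dicts with
    ``psite_resid``, ``partner_resid``, ``sigma`` and optional ``trigger``
    flag, default True for tyrosine pairs).
    """
    out_contacts = contacts.copy()
    groups: list[PSiteContactGroup] = []
    chains = (receiver_chain, activator_chain)
    for spec in psite_definitions:
        tyr_resid = int(spec["tyr_resid"])
        window = [int(r) for r in spec["window"]]
        for psite_chain in chains:
            copy_id = f"{spec['site_id']}{psite_chain}"
            for target_chain in chains:
                trig_pairs, trig_sigma, aux_pairs, aux_sigma = [], [], [], []
                for cp in spec["contact_pairs"]:
                    p_bead = topology.bead_index(psite_chain, int(cp["psite_resid"]))
                    t_bead = topology.bead_index(target_chain, int(cp["partner_resid"]))
                    sig = float(cp["sigma"])
                    is_trigger = bool(cp.get("trigger", int(cp["psite_resid"]) == tyr_resid))
                    if is_trigger:
                        trig_pairs.append((p_bead, t_bead))
                        trig_sigma.append(sig)
                    else:
                        aux_pairs.append((p_bead, t_bead))
                        aux_sigma.append(sig)
                if validate_trigger and len(trig_pairs) != trigger_size:
                    raise ValueError(
                        f"P-site {copy_id}->{target_chain}: {len(trig_pairs)} tyrosine "
                        f"contacts, expected trigger size {trigger_size}"
                    )
                group = PSiteContactGroup(
                    site_id=copy_id,
                    psite_chain=psite_chain,
                    target_chain=target_chain,
                    productive=(target_chain == receiver_chain),
                    tyr_bead=topology.bead_index(psite_chain, tyr_resid),
                    window_beads=np.array([topology.bead_index(psite_chain, r) for r in window]),
                    trigger_pairs=np.asarray(trig_pairs, dtype=np.int64).reshape(-1, 2),
                    trigger_sigma=np.asarray(trig_sigma),
                    aux_pairs=np.asarray(aux_pairs, dtype=np.int64).reshape(-1, 2),
                    aux_sigma=np.asarray(aux_sigma),
                    trigger_size=len(trig_pairs),
                )
                groups.append(group)
                for (a, b), s in zip(group.trigger_pairs, group.trigger_sigma):
                    out_contacts.add(int(a), int(b), float(s), eps, group.tag())
                for (a, b), s in zip(group.aux_pairs, group.aux_sigma):
                    out_contacts.add(int(a), int(b), float(s), eps, group.tag())
    return groups, out_contacts


def contacts_from_docked(
    docked: AnnotatedStructure,
    psite_chain: str,
    kinase_chain: str,
    cutoff: float = CONTACT_CUTOFF,
) -> list[dict]:
    """Extract P-site/active-site contact pairs from an all-atom docked model.

    Returns contact-pair dicts usable in a P-site definition; ``sigma`` is
    the C-alpha separation in the docked structure.
    """
    import biotite.structure as struc

    atoms = docked.atoms
    starts = struc.get_residue_starts(atoms)
    stops = list(starts[1:]) + [atoms.array_length()]
    pep, kin = [], []
    for s, e in zip(starts, stops):
        entry = (int(atoms.res_id[s]), atoms.coord[s:e].astype(np.float64), list(atoms.atom_name[s:e]))
        if str(atoms.chain_id[s]) == psite_chain:
            pep.append(entry)
        elif str(atoms.chain_id[s]) == kinase_chain:
            kin.append(entry)
    pairs = []
    for prid, pcoord, pnames in pep:
        for krid, kcoord, knames in kin:
            d = np.linalg.norm(pcoord[:, None, :] - kcoord[None, :, :], axis=-1)
            if d.min() <= cutoff:
                ca_p = pcoord[pnames.index("CA")]
                ca_k = kcoord[knames.index("CA")]
                pairs.append(
                    {
                        "psite_resid": prid,
                        "partner_resid": krid,
                        "sigma": float(np.linalg.norm(ca_p - ca_k)),
                    }
                )
    return pairs


# ---------------------------------------------------------------------------
# System bundle
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CGSystem:
    """Topology + contact set + P-site groups: everything dynamics needs."""

    topology: PseudoAtomTopology
    contacts: NativeContactSet
    psite_groups: list = dataclasses.field(default_factory=list)
    metadata: dict = dataclasses.field(default_factory=dict)

    def copy(self) -> "CGSystem":
        return CGSystem(
            self.topology.copy(),
            self.contacts.copy(),
            [dataclasses.replace(g) for g in self.psite_groups],
            dict(self.metadata),
        )

    def productive_groups(self) -> list:
        return [g for g in self.psite_groups if g.productive and g.enabled]

    def activator_groups(self) -> list:
        return [g for g in self.psite_groups if not g.productive and g.enabled]

    def strip_psite_attractions(self) -> "CGSystem":
        out = self.copy()
        out.contacts = out.contacts.without_psite_terms()
        return out
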