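"""All-atom structure input/output with per-residue region annotations.

Structures are carried as :class:`biotite.structure.AtomArray` objects with a
custom ``region`` annotation.  Region labels classify each residue as one of
``structured``, ``modeled``, ``transmembrane``, ``extracellular``,
``intracellular``, ``ligand`` or ``nucleotide-complex``; the label controls
native-contact eligibility and membrane-side assignment downstream.

The module also implements the dipeptide-library terminal-extension
algorithm used to grow disordered N-/C-terminal segments (e.g. a receptor
C-terminal tail) onto a chain: the terminal residue is repeatedly replaced
by a randomly drawn two-residue backbone fragment whose first residue is
superposed onto the residue replaced, subject to a clash check against all
pre-existing atoms.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

REGION_LABELS = frozenset(
    [
        "structured",
        "modeled",
        "transmembrane",
        "extracellular",
        "intracellular",
        "ligand",
        "nucleotide-complex",
    ]
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureError(ValueError):
    """Malformed structure or inconsistent annotation."""


class ExtensionError(RuntimeError):
    """Terminal extension could not be completed."""

    def __init__(self, message: str, step_index: int):
        super().__init__(message)
        self.step_index = step_index


@dataclasses.dataclass
class AnnotatedStructure:
    """All-atom structure plus per-residue region labels.

    ``atoms`` carries a ``region`` annotation category (one label per atom,
    uniform within a residue).  ``provenance`` maps segment descriptions to
    free-text notes.
    """

    atoms: struc.AtomArray
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if "region" not in self.atoms.get_annotation_categories():
            raise StructureError("atoms must carry a 'region' annotation")
        if not np.all(np.isfinite(self.atoms.coord)):
            raise StructureError("coordinates must be finite")
        self._check_labels()

    def _check_labels(self):
        bad = set(self.atoms.region) - REGION_LABELS
        if bad:
            raise StructureError(f"unknown region labels: {sorted(bad)}")
        # one label per residue
        for chain, resid in zip(*self._residue_keys()):
            mask = (self.atoms.chain_id == chain) & (self.atoms.res_id == resid)
            if len(set(self.atoms.region[mask])) != 1:
                raise StructureError(f"residue {chain}:{resid} has multiple region labels")
        # transmembrane runs must be contiguous per chain
        for chain in np.unique(self.atoms.chain_id):
            cmask = self.atoms.chain_id == chain
            resids = []
            for rid in np.unique(self.atoms.res_id[cmask]):
                reg = self.atoms.region[cmask & (self.atoms.res_id == rid)][0]
                if reg == "transmembrane":
                    resids.append(int(rid))
            if resids and (max(resids) - min(resids) + 1 != len(resids)):
                raise StructureError(f"transmembrane residues of chain {chain} are not contiguous")

    def _residue_keys(self):
        starts = struc.get_residue_starts(self.atoms)
        return self.atoms.chain_id[starts], self.atoms.res_id[starts]

    @property
    def n_residues(self) -> int:
        return len(struc.get_residue_starts(self.atoms))

    def residue_region(self, chain: str, resid: int) -> str:
        mask = (self.atoms.chain_id == chain) & (self.atoms.res_id == resid)
        if not mask.any():
            raise KeyError(f"no residue {chain}:{resid}")
        return str(self.atoms.region[mask][0])


def _apply_region_map(atoms: struc.AtomArray, region_map: Iterable[tuple]) -> np.ndarray:
    """Resolve a (chain, first, last, label) range map to a per-atom label array."""
    labels = np.full(atoms.array_length(), "", dtype="U20")
    claimed: dict[tuple, str] = {}
    for entry in region_map:
        chain, first, last, label = entry
        if label not in REGION_LABELS:
            raise StructureError(f"unknown region label {label!r}")
        for rid in range(int(first), int(last) + 1):
            key = (str(chain), rid)
            if key in claimed and claimed[key] != label:
                raise StructureError(
                    f"region map overlap at residue {chain}:{rid}: "
                    f"{claimed[key]!r} vs {label!r}"
                )
            claimed[key] = label
        mask = (atoms.chain_id == str(chain)) & (atoms.res_id >= int(first)) & (atoms.res_id <= int(last))
        labels[mask] = label
    missing = sorted(
        {(str(c), int(r)) for c, r in zip(atoms.chain_id[labels == ""], atoms.res_id[labels == ""])}
    )
    if missing:
        raise StructureError(f"region map does not cover residues: {missing}")
    return labels


def read_structure(path, region_map: Iterable[tuple], provenance: dict | None = None) -> AnnotatedStructure:
    """Read a PDB file and attach region labels.

    ``region_map`` is an iterable of ``(chain_id, first_resid, last_resid,
    label)`` tuples that must cover every residue in the file exactly once.
    Insertion codes are rejected; residue numbering is taken as-is.
    """
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises various parse errors
        raise StructureError(f"failed to parse PDB file {path}: {exc}") from exc
    if "ins_code" in atoms.get_annotation_categories() and np.any(atoms.ins_code != ""):
        bad = np.unique(atoms.res_id[atoms.ins_code != ""])
        raise StructureError(f"insertion codes are not supported (residues {bad.tolist()})")
    labels = _apply_region_map(atoms, region_map)
    atoms.set_annotation("region", labels)
    return AnnotatedStructure(atoms, provenance=dict(provenance or {}))


def write_structure(structure: AnnotatedStructure, path) -> None:
    """Write the all-atom coordinates back out as PDB (labels go to a sidecar JSON)."""
    pdb = PDBFile()
    pdb.set_structure(structure.atoms)
    pdb.write(str(path))
    sidecar = str(path) + ".regions.json"
    starts = struc.get_residue_starts(structure.atoms)
    records = [
        {
            "chain": str(structure.atoms.chain_id[s]),
            "res_id": int(structure.atoms.res_id[s]),
            "region": str(structure.atoms.region[s]),
        }
        for s in starts
    ]
    with open(sidecar, "w") as fh:
        json.dump({"residues": records, "provenance": structure.provenance}, fh, indent=1)


def read_structure_with_sidecar(path) -> AnnotatedStructure:
    """Re-read a structure written by :func:`write_structure`."""
    with open(str(path) + ".regions.json") as fh:
        sidecar = json.load(fh)
    region_map = [
        (rec["chain"], rec["res_id"], rec["res_id"], rec["region"]) for rec in sidecar["residues"]
    ]
    out = read_structure(path, region_map)
    out.provenance = sidecar.get("provenance", {})
    return out


# ---------------------------------------------------------------------------
# Dipeptide fragment library and terminal extension
# ---------------------------------------------------------------------------

# idealized backbone internal coordinates (Engh-Huber-like)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = np.deg2rad(111.2)
_A_CA_C_N = np.deg2rad(116.2)
_A_C_N_CA = np.deg2rad(121.7)
_A_CA_C_O = np.deg2rad(120.8)

#: (phi, psi) pairs sampled by the default library: alpha helix, beta strand,
#: polyproline II and a few bridging conformers.
_DEFAULT_PHI_PSI = [
    (-57.0, -47.0),
    (-63.0, -42.0),
    (-120.0, 120.0),
    (-135.0, 135.0),
    (-75.0, 145.0),
    (-90.0, 0.0),
    (-140.0, 70.0),
]


def _place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF placement of atom d given positions a-b-c and internal coordinates."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_dipeptide(phi2: float, psi1: float, omega: float = 180.0) -> np.ndarray:
    """Backbone coordinates (N,CA,C,O per residue; shape (8, 3)) of a dipeptide.

    ``psi1`` is the psi of residue 1 and ``phi2`` the phi of residue 2; the
    peptide bond is trans by default.
    """
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.pi - _A_N_CA_C
    c1 = ca1 + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    psi1r, omegar, phi2r = map(np.deg2rad, (psi1, omega, phi2))
    n2 = _place_atom(n1, ca1, c1, _B_C_N, _A_CA_C_N, psi1r)
    o1 = _place_atom(n1, ca1, c1, _B_C_O, _A_CA_C_O, psi1r + np.pi)
    ca2 = _place_atom(ca1, c1, n2, _B_N_CA, _A_C_N_CA, omegar)
    c2 = _place_atom(c1, n2, ca2, _B_CA_C, _A_N_CA_C, phi2r)
    # psi of residue 2 fixed extended for O placement; it is re-set on the next step
    o2 = _place_atom(n2, ca2, c2, _B_C_O, _A_CA_C_O, np.deg2rad(140.0) + np.pi)
    return np.stack([n1, ca1, c1, o1, n2, ca2, c2, o2])


@dataclasses.dataclass
class DipeptideLibrary:
    """Library of two-residue backbone fragments keyed by residue-type pair.

    Fragments are arrays of shape (8, 3): N, CA, C, O for each of the two
    residues.  A ``("*", "*")`` key acts as the type-agnostic fallback pool;
    the default library is entirely type-agnostic.
    """

    fragments: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not self.fragments.get(("*", "*")):
            raise StructureError("library must provide a non-empty ('*', '*') fallback pool")
        for key, frags in self.fragments.items():
            for frag in frags:
                if np.asarray(frag).shape != (8, 3):
                    raise StructureError(f"fragment under {key} lacks complete backbone atoms")

    def pool(self, res1: str, res2: str) -> list:
        return self.fragments.get((res1, res2)) or self.fragments[("*", "*")]

    @classmethod
    def default(cls) -> "DipeptideLibrary":
        frags = [
            _build_dipeptide(phi2, psi1)
            for psi1 in (p[1] for p in _DEFAULT_PHI_PSI)
            for phi2 in (p[0] for p in _DEFAULT_PHI_PSI)
        ]
        return cls({("*", "*"): frags})


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation/translation superposing ``mobile`` onto ``target`` (rows paired)."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


def _terminal_residue_mask(atoms: struc.AtomArray, chain: str, direction: str) -> np.ndarray:
    cmask = atoms.chain_id == chain
    if not cmask.any():
        raise StructureError(f"no chain {chain!r}")
    resids = atoms.res_id[cmask]
    rid = int(resids.max() if direction == "C" else resids.min())
    return cmask & (atoms.res_id == rid)


def extend_terminus(
    structure: AnnotatedStructure,
    chain: str,
    direction: str,
    sequence: Sequence[str],
    library: DipeptideLibrary | None = None,
    clash_radius: float = 2.5,
    max_retries: int = 200,
    seed: int = 0,
) -> AnnotatedStructure:
    """Grow ``sequence`` onto the given chain terminus by dipeptide build-up.

    Each step draws a dipeptide fragment at random, superposes its first
    residue's backbone (N, CA, C) onto the current terminal residue and, if no
    atom of the newly placed residue falls within ``clash_radius`` of any
    pre-existing atom (the residue it extends excepted), appends the
    fragment's second residue as the new terminus.  New residues are labeled
    ``modeled``.  Raises :class:`ExtensionError` naming the step at which the
    retry budget was exhausted.  Pre-existing coordinates are never moved.
    """
    if direction not in ("N", "C"):
        raise ValueError("direction must be 'N' or 'C'")
    if len(sequence) == 0:
        return structure
    library = library or DipeptideLibrary.default()
    rng = np.random.default_rng(seed)
    atoms = structure.atoms.copy()

    for step, resname in enumerate(sequence):
        term_mask = _terminal_residue_mask(atoms, chain, direction)
        term = atoms[term_mask]
        names = list(term.atom_name)
        try:
            anchor = np.stack([term.coord[names.index(a)] for a in ("N", "CA", "C")])
        except ValueError:
            raise StructureError(
                f"terminal residue {chain}:{int(term.res_id[0])} lacks a full backbone"
            )
        term_resname = str(term.res_name[0])
        pool = (
            library.pool(term_resname, resname)
            if direction == "C"
            else library.pool(resname, term_resname)
        )
        other_coord = atoms.coord[~term_mask]

        placed = None
        for _ in range(max_retries):
            frag = np.asarray(pool[rng.integers(len(pool))])
            if direction == "C":
                mob = frag[[0, 1, 2]]  # res1 N, CA, C
                new_res = frag[4:8]
            else:
                mob = frag[[4, 5, 6]]  # res2 N, CA, C
                new_res = frag[0:4]
            rot, trans = _kabsch(mob, anchor)
            cand = new_res @ rot.T + trans
            if other_coord.size:
                d = np.linalg.norm(other_coord[:, None, :] - cand[None, :, :], axis=-1)
                if d.min() < clash_radius:
                    continue
            placed = cand
            break
        if placed is None:
            raise ExtensionError(
                f"terminal extension failed at step {step} ({resname}): "
                f"{max_retries} fragment draws all clashed",
                step_index=step,
            )

        new_rid = int(term.res_id[0]) + (1 if direction == "C" else -1)
        new_atoms = struc.AtomArray(4)
        new_atoms.coord = placed.astype(np.float32)
        new_atoms.atom_name = np.array(BACKBONE_ATOMS)
        new_atoms.element = np.array(["N", "C", "C", "O"])
        new_atoms.res_id = np.full(4, new_rid)
        new_atoms.res_name = np.full(4, resname, dtype="U5")
        new_atoms.chain_id = np.full(4, chain, dtype="U4")
        for cat in atoms.get_annotation_categories():
            if cat not in new_atoms.get_annotation_categories():
                fill = "modeled" if cat == "region" else np.zeros(1, atoms.get_annotation(cat).dtype)[0]
                new_atoms.set_annotation(cat, np.full(4, fill, dtype=atoms.get_annotation(cat).dtype))
        atoms = atoms + new_atoms if direction == "C" else new_atoms + atoms

    out = AnnotatedStructure(atoms, provenance=dict(structure.provenance))
    out.provenance[f"extension:{chain}:{direction}"] = f"{len(sequence)} residues, seed {seed}"
    return out


# ---------------------------------------------------------------------------
# Event tables and trajectories
# ---------------------------------------------------------------------------

EVENT_COLUMNS = [
    "trial",
    "seed",
    "site",
    "chain",
    "cis",
    "elapsed_ns",
    "initial_structure",
]


def write_event_table(table, path) -> None:
    """Write a binding-event table as TSV with the fixed column order."""
    df = table.to_frame() if hasattr(table, "to_frame") else table
    df = df.reindex(columns=EVENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_event_table(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")


def write_trajectory(frames, path, units: str = "A,ns") -> None:
    """Write frames as a self-describing binary container (compressed npz).

    ``frames`` is an iterable of (time_ns, coords) pairs; time stamps must be
    strictly increasing.
    """
    times = []
    coords = []
    for t, c in frames:
        times.append(float(t))
        coords.append(np.asarray(c, dtype=np.float64))
    times = np.asarray(times)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("frame time stamps must be strictly increasing")
    np.savez_compressed(
        path,
        times_ns=times,
        coords_A=np.stack(coords) if coords else np.zeros((0, 0, 3)),
        header=np.array([f"cgap trajectory; units={units}"]),
    )


def read_trajectory(path):
    data = np.load(path, allow_pickle=False)
    return data["times_ns"], data["coords_A"]
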