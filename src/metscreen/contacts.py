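"""Per-residue contact-frequency analysis over docked ligand pose ensembles.

A residue is *contacted* by a ligand when any ligand heavy atom lies within
the cutoff (default 5 Å) of any residue heavy atom; its contact frequency is
the fraction of ligands in the ensemble contacting it, and residues with
frequency > 0.5 are categorised high-contact.  Non-protein residues — in
particular pore-adjacent phospholipids such as POPC, each lipid one residue —
participate like any other residue.  All distances are heavy-atom only,
since docked poses commonly omit or misplace hydrogens.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 5.0  # Å
HIGH_CONTACT = 0.5  # strict >; exactly 0.5 is low-contact

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass
class Receptor:
    """Heavy-atom macromolecular structure, lipids included as residues."""

    coords: np.ndarray  # (n, 3) Å
    elements: np.ndarray  # str
    atom_names: np.ndarray  # str
    chain_ids: np.ndarray  # str
    res_ids: np.ndarray  # int
    res_names: np.ndarray  # str

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("receptor coordinates must be finite")
        for name in ("elements", "atom_names", "chain_ids", "res_names"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.res_ids = np.asarray(self.res_ids, dtype=int)

    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    def residue_keys(self) -> np.ndarray:
        """Per-atom residue label, e.g. 'D569:A' or 'POPC801:M'."""
        out = np.empty(len(self.res_ids), dtype=object)
        for i in range(len(self.res_ids)):
            rn = str(self.res_names[i])
            short = _AA3TO1.get(rn, rn)
            out[i] = f"{short}{self.res_ids[i]}:{self.chain_ids[i]}"
        return out

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Receptor":
        return Receptor(self.coords @ R.T + t, self.elements, self.atom_names,
                        self.chain_ids, self.res_ids, self.res_names)


def receptor_from_pdb(path, model: int = 1) -> Receptor:
    """Read a receptor (protein + lipids/heteroatoms) from a PDB file."""
    from biotite.structure.io import pdb

    arr = pdb.PDBFile.read(str(path)).get_structure(model=model)
    return Receptor(
        arr.coord, arr.element.astype(object), arr.atom_name.astype(object),
        arr.chain_id.astype(object), arr.res_id, arr.res_name.astype(object),
    )


@dataclass
class Pose:
    """One docked ligand pose: heavy-atom coordinates + formal charges."""

    ligand_id: str
    coords: np.ndarray  # (m, 3)
    elements: np.ndarray
    charges: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.elements = np.asarray(self.elements, dtype=object)
        self.charges = np.asarray(self.charges, dtype=int)

    def heavy(self) -> "Pose":
        m = self.elements != "H"
        return Pose(self.ligand_id, self.coords[m], self.elements[m], self.charges[m])


def poses_from_sdf(path) -> list[Pose]:
    """Read a multi-record SDF of docked poses (one pose per record)."""
    from rdkit import Chem

    poses = []
    for i, m in enumerate(Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)):
        if m is None:
            warnings.warn(f"unreadable SDF record {i} in {path}")
            continue
        conf = m.GetConformer()
        name = m.GetProp("_Name") if m.HasProp("_Name") and m.GetProp("_Name") else f"pose{i}"
        poses.append(
            Pose(
                name,
                np.array([conf.GetAtomPosition(a.GetIdx()) for a in m.GetAtoms()]),
                np.array([a.GetSymbol() for a in m.GetAtoms()], dtype=object),
                np.array([a.GetFormalCharge() for a in m.GetAtoms()]),
            )
        )
    return poses


@dataclass
class PoseSet:
    receptor: Receptor
    poses: list[Pose]
    grid_center: np.ndarray | None = None  # docking-box metadata, Å
    grid_edge: float | None = None


@dataclass
class ContactProfile:
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: residue, count, frequency, category

    def high_contact(self) -> list[str]:
        return list(self.frame.loc[self.frame["category"] == "high", "residue"])


def contact_frequency(ps: PoseSet, cutoff: float = DEFAULT_CUTOFF) -> ContactProfile:
    """Fraction of ligands with any heavy atom within ``cutoff`` of each
    residue's heavy atoms; frequency > 0.5 ⇒ high-contact."""
    if not ps.poses:
        raise ValueError("pose set is empty")
    heavy = ps.receptor.heavy_mask()
    keys = ps.receptor.residue_keys()[heavy]
    coords = ps.receptor.coords[heavy]
    tree = cKDTree(coords)
    all_res = list(dict.fromkeys(keys))  # receptor order
    counts = {r: 0 for r in all_res}
    for pose in ps.poses:
        p = pose.heavy()
        if p.coords.shape[0] == 0:
            raise ValueError(f"pose {pose.ligand_id!r} has no heavy atoms")
        idx = tree.query_ball_point(p.coords, r=cutoff)
        touched = {keys[j] for row in idx for j in row}
        for r in touched:
            counts[r] += 1
    n = len(ps.poses)
    rows = [
        {
            "residue": r,
            "count": counts[r],
            "frequency": counts[r] / n,
            "category": "high" if counts[r] / n > HIGH_CONTACT else "low",
        }
        for r in all_res
    ]
    return ContactProfile(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# interaction typing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionRules:
    """Heavy-atom distance criteria for typed contacts (configurable)."""

    salt_bridge: float = 4.0  # opposite formal charges
    hbond: float = 3.5  # donor-acceptor N/O pair
    cation_pi: float = 4.5  # cation to aromatic ring centroid
    hydrophobic: float = 4.5  # apolar C-C


# charged / aromatic atom templates for common residues; unknown residues
# are skipped with a warning
_TEMPLATES: dict[str, dict] = {
    "ASP": {"neg": {"OD1", "OD2"}, "rings": []},
    "GLU": {"neg": {"OE1", "OE2"}, "rings": []},
    "LYS": {"pos": {"NZ"}, "rings": []},
    "ARG": {"pos": {"NE", "NH1", "NH2"}, "rings": []},
    "HIS": {"rings": [("CG", "ND1", "CD2", "CE1", "NE2")]},
    "PHE": {"rings": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")]},
    "TYR": {"rings": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")]},
    "TRP": {"rings": [("CG", "CD1", "NE1", "CE2", "CD2"),
                      ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")]},
}
_STANDARD_AA = set(_AA3TO1)
_POLAR_ELEMENTS = {"N", "O"}


def _residue_annotation(res_names, atom_names, elements, coords):
    """Per-atom charge annotation (+1/-1/0) from residue templates.

    Lipids (POPC and relatives): choline N is cationic; phosphate oxygens
    (O within 1.9 Å of a P) are treated as the anionic acceptors.
    """
    charge = np.zeros(len(atom_names), dtype=int)
    name = np.asarray(atom_names)
    for rn in set(str(r) for r in res_names):
        mask = np.asarray([str(r) == rn for r in res_names])
        tpl = _TEMPLATES.get(rn)
        if tpl:
            charge[mask & np.isin(name, list(tpl.get("pos", ())))] = 1
            charge[mask & np.isin(name, list(tpl.get("neg", ())))] = -1
        elif rn not in _STANDARD_AA:
            # lipid-like: geometric phosphate rule + choline nitrogen
            sub = np.where(mask)[0]
            p_idx = [i for i in sub if elements[i] == "P"]
            for i in sub:
                if elements[i] == "N":
                    charge[i] = 1
                if elements[i] == "O" and any(
                    np.linalg.norm(coords[i] - coords[j]) < 1.9 for j in p_idx
                ):
                    charge[i] = -1
            if not p_idx and not any(elements[i] in ("N", "O") for i in sub):
                logger.warning("no template for residue %s; treated as apolar", rn)
    return charge


def annotate_interactions(
    ps: PoseSet, rules: InteractionRules | None = None
) -> pd.DataFrame:
    """Typed ligand–residue contacts: salt bridges, hydrogen bonds,
    cation-π and hydrophobic, one row per (ligand, residue, type) with the
    minimum heavy-atom distance."""
    rules = rules or InteractionRules()
    rec = ps.receptor
    heavy = rec.heavy_mask()
    idx = np.where(heavy)[0]
    coords = rec.coords[idx]
    elements = rec.elements[idx]
    names = rec.atom_names[idx]
    res_names = rec.res_names[idx]
    keys = rec.residue_keys()[idx]
    rcharge = _residue_annotation(res_names, names, elements, coords)
    tree = cKDTree(coords)
    max_cut = max(rules.salt_bridge, rules.hbond, rules.cation_pi, rules.hydrophobic)

    # aromatic ring centroids per residue (for cation-pi)
    ring_centroids: list[tuple[str, np.ndarray]] = []
    for key in dict.fromkeys(keys):
        mask = keys == key
        rn = str(res_names[mask][0])
        tpl = _TEMPLATES.get(rn)
        if not tpl:
            continue
        for ring in tpl.get("rings", []):
            sel = mask & np.isin(names, list(ring))
            if sel.sum() == len(ring):
                ring_centroids.append((key, coords[sel].mean(axis=0)))

    found: dict[tuple[str, str, str], float] = {}

    def record(lig, res, itype, dist):
        k = (lig, res, itype)
        if k not in found or dist < found[k]:
            found[k] = dist

    for pose in ps.poses:
        p = pose.heavy()
        near = tree.query_ball_point(p.coords, r=max_cut)
        for ai, rec_idx in enumerate(near):
            le, lq = p.elements[ai], int(p.charges[ai])
            for j in rec_idx:
                d = float(np.linalg.norm(p.coords[ai] - coords[j]))
                rq = int(rcharge[j])
                if lq * rq < 0 and d <= rules.salt_bridge:
                    record(pose.ligand_id, keys[j], "salt-bridge", d)
                elif (
                    le in _POLAR_ELEMENTS
                    and elements[j] in _POLAR_ELEMENTS
                    and d <= rules.hbond
                ):
                    record(pose.ligand_id, keys[j], "H-bond", d)
                elif le == "C" and elements[j] == "C" and d <= rules.hydrophobic:
                    record(pose.ligand_id, keys[j], "hydrophobic", d)
        for ai in range(len(p.coords)):
            if int(p.charges[ai]) > 0:
                for key, cen in ring_centroids:
                    d = float(np.linalg.norm(p.coords[ai] - cen))
                    if d <= rules.cation_pi:
                        record(pose.ligand_id, key, "cation-pi", d)

    rows = [
        {"ligand_id": l, "residue": r, "type": t, "distance": round(d, 3)}
        for (l, r, t), d in sorted(found.items())
    ]
    return pd.DataFrame(rows, columns=["ligand_id", "residue", "type", "distance"])


def assign_zone(position, zones: dict[str, tuple[float, float]]) -> str:
    """Binding-site zone (top/middle/bottom) of a point from its axial
    coordinate; 'outside' when beyond the pore span."""
    intervals = sorted(zones.items(), key=lambda kv: kv[1][0])
    for (n1, (a1, b1)), (n2, (a2, b2)) in zip(intervals, intervals[1:]):
        if b1 > a2:
            raise ValueError(f"zones {n1!r} and {n2!r} overlap")
    z = float(np.asarray(position, dtype=float).reshape(3)[2])
    for name, (lo, hi) in zones.items():
        if lo <= z <= hi:
            return name
    return "outside"
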