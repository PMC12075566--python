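"""3D pharmacophore feature perception.

Features are assigned from a declarative, versioned rule table (SMARTS
patterns plus a placement mode, see ``data/feature_rules.tsv``) applied to
molecules with explicit hydrogens and resolved aromaticity.  Placement:

* ``atom``     — feature at the first matched atom (A/D/P); A carries an
  idealised lone-pair direction, D the mean X–H direction;
* ``centroid`` — feature at the centroid of the matched atoms (charged
  groups such as carboxylates);
* ``ring``     — one feature per aromatic ring at its centroid, direction
  along the ring normal;
* ``cluster``  — one feature per maximal connected cluster (size ≥ 2) of
  apolar carbons/halogens, at the cluster centroid.

Overlapping same-type features closer than 1 Å are merged to their centroid
so fused-ring and tautomer artifacts are not double counted.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .mol import DIRECTIONAL_TYPES, FEATURE_TYPES, FeatureSet, Molecule3D, PharmacophoreFeature

MERGE_RADIUS = 1.0  # Å; same-type features closer than this collapse to one

_BOND_ORDERS = {
    1.0: Chem.BondType.SINGLE,
    1.5: Chem.BondType.AROMATIC,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
}


class InputError(ValueError):
    """Unparsable or invalid input record."""


@dataclass(frozen=True)
class FeatureRule:
    ftype: str
    pattern: str
    placement: str  # atom | centroid | ring | cluster


def load_rules(path=None) -> list[FeatureRule]:
    """Read the feature-rule table (tab-separated; '#' comments)."""
    if path is None:
        ref = importlib.resources.files("metscreen.data") / "feature_rules.tsv"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rules = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise InputError(f"malformed rule line: {line!r}")
        ftype, pattern, placement = (p.strip() for p in parts)
        if ftype not in FEATURE_TYPES:
            raise InputError(f"unknown feature type in rule: {ftype!r}")
        if placement not in ("atom", "centroid", "ring", "cluster"):
            raise InputError(f"unknown placement mode: {placement!r}")
        rules.append(FeatureRule(ftype, pattern, placement))
    return rules


# ---------------------------------------------------------------------------
# Molecule3D <-> RDKit
# ---------------------------------------------------------------------------

def to_rdkit(mol: Molecule3D) -> Chem.Mol:
    """Build a sanitised RDKit molecule (with conformer) from a Molecule3D."""
    rw = Chem.RWMol()
    for elem, _, q in mol.atoms:
        a = Chem.Atom(elem)
        a.SetFormalCharge(q)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j, order in mol.bonds:
        bt = _BOND_ORDERS.get(float(order))
        if bt is None:
            raise InputError(f"molecule {mol.id}: unsupported bond order {order}")
        rw.AddBond(int(i), int(j), bt)
    conf = Chem.Conformer(rw.GetNumAtoms())
    for idx, (_, xyz, _) in enumerate(mol.atoms):
        conf.SetAtomPosition(idx, xyz.tolist())
    m = rw.GetMol()
    m.AddConformer(conf, assignId=True)
    try:
        Chem.SanitizeMol(m)
    except Exception as exc:  # rdkit raises various Boost exceptions
        raise InputError(f"molecule {mol.id}: sanitisation failed: {exc}") from exc
    return m


def from_rdkit(rdmol: Chem.Mol, mol_id: str, conformer_id: int = 0) -> Molecule3D:
    if rdmol.GetNumConformers() == 0:
        raise InputError(f"molecule {mol_id}: no 3D conformer")
    conf = rdmol.GetConformer()
    atoms = [
        (a.GetSymbol(), np.array(conf.GetAtomPosition(a.GetIdx())), a.GetFormalCharge())
        for a in rdmol.GetAtoms()
    ]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in rdmol.GetBonds()
    ]
    return Molecule3D(mol_id, atoms, bonds, conformer_id)


def molecule_from_smiles(mol_id: str, smiles: str, seed: int = 2024,
                         conformer_id: int = 0) -> Molecule3D:
    """Parse SMILES, add explicit hydrogens, embed one 3D conformer (ETKDG)."""
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise InputError(f"molecule {mol_id}: unparsable SMILES {smiles!r}")
    rd = Chem.AddHs(rd)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(rd, params) != 0:
        raise InputError(f"molecule {mol_id}: 3D embedding failed")
    AllChem.MMFFOptimizeMolecule(rd, maxIters=200)
    return from_rdkit(rd, mol_id, conformer_id)


def molecule_from_molblock(mol_id: str, block: str, conformer_id: int = 0) -> Molecule3D:
    rd = Chem.MolFromMolBlock(block, removeHs=False)
    if rd is None:
        raise InputError(f"molecule {mol_id}: unparsable SDF/MOL block")
    return from_rdkit(rd, mol_id, conformer_id)


# ---------------------------------------------------------------------------
# perception
# ---------------------------------------------------------------------------

_APOLAR_HALOGENS = {"F", "Cl", "Br", "I"}
_POLAR_NEIGHBOURS = {"N", "O", "S", "P"}


def _lone_pair_direction(rdmol, conf, idx) -> np.ndarray | None:
    """Idealised lone-pair direction: opposite the mean bond vector."""
    atom = rdmol.GetAtomWithIdx(idx)
    p = np.array(conf.GetAtomPosition(idx))
    vecs = []
    for nb in atom.GetNeighbors():
        v = np.array(conf.GetAtomPosition(nb.GetIdx())) - p
        n = np.linalg.norm(v)
        if n > 1e-9:
            vecs.append(v / n)
    if not vecs:
        return None
    d = -np.sum(vecs, axis=0)
    n = np.linalg.norm(d)
    return None if n < 1e-6 else d / n


def _donor_direction(rdmol, conf, idx) -> np.ndarray | None:
    """Mean heteroatom -> H bond direction."""
    atom = rdmol.GetAtomWithIdx(idx)
    p = np.array(conf.GetAtomPosition(idx))
    vecs = []
    for nb in atom.GetNeighbors():
        if nb.GetSymbol() == "H":
            v = np.array(conf.GetAtomPosition(nb.GetIdx())) - p
            n = np.linalg.norm(v)
            if n > 1e-9:
                vecs.append(v / n)
    if not vecs:
        return None
    d = np.sum(vecs, axis=0)
    n = np.linalg.norm(d)
    return None if n < 1e-6 else d / n


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of a (near-)planar ring via SVD; deterministic sign."""
    centred = coords - coords.mean(axis=0)
    _, _, Vt = np.linalg.svd(centred)
    n = Vt[-1]
    for c in n:
        if abs(c) > 1e-9:
            if c < 0:
                n = -n
            break
    return n / np.linalg.norm(n)


def _aromatic_ring_features(rdmol, conf) -> list[PharmacophoreFeature]:
    feats = []
    for ring in rdmol.GetRingInfo().AtomRings():
        if all(rdmol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            coords = np.array([conf.GetAtomPosition(i) for i in ring])
            feats.append(
                PharmacophoreFeature("R", coords.mean(axis=0), _ring_normal(coords), ring)
            )
    return feats


def _apolar_cluster_features(rdmol, conf, min_size: int = 2) -> list[PharmacophoreFeature]:
    def is_apolar(atom) -> bool:
        sym = atom.GetSymbol()
        if sym in _APOLAR_HALOGENS:
            return True
        if sym != "C" or atom.GetIsAromatic():
            return False
        return not any(nb.GetSymbol() in _POLAR_NEIGHBOURS for nb in atom.GetNeighbors())

    apolar = {a.GetIdx() for a in rdmol.GetAtoms() if is_apolar(a)}
    seen: set[int] = set()
    feats = []
    for start in sorted(apolar):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            for nb in rdmol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in apolar and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(comp) >= min_size:
            coords = np.array([conf.GetAtomPosition(i) for i in comp])
            feats.append(PharmacophoreFeature("H", coords.mean(axis=0), None, tuple(sorted(comp))))
    return feats


def _merge_overlapping(feats: list[PharmacophoreFeature]) -> list[PharmacophoreFeature]:
    """Collapse same-type features within MERGE_RADIUS to a single centroid."""
    out: list[PharmacophoreFeature] = []
    for f in feats:
        merged = False
        for k, g in enumerate(out):
            if g.ftype == f.ftype and np.linalg.norm(g.position - f.position) < MERGE_RADIUS:
                pos = (g.position + f.position) / 2.0
                d = g.direction
                if d is not None and f.direction is not None:
                    s = g.direction + f.direction
                    n = np.linalg.norm(s)
                    d = g.direction if n < 1e-6 else s / n
                out[k] = PharmacophoreFeature(
                    f.ftype, pos, d, tuple(sorted(set(g.source_atoms) | set(f.source_atoms)))
                )
                merged = True
                break
        if not merged:
            out.append(f)
    return out


def perceive_features(mol: Molecule3D, rules: list[FeatureRule] | None = None) -> FeatureSet:
    """Assign A/D/H/N/P/R features to a prepared molecule.

    A molecule in which no rule fires yields an empty FeatureSet (not an
    error); an unparsable molecule raises :class:`InputError`.
    """
    if rules is None:
        rules = load_rules()
    rdmol = to_rdkit(mol)
    conf = rdmol.GetConformer()

    feats: list[PharmacophoreFeature] = []
    for rule in rules:
        if rule.placement == "ring":
            feats.extend(_aromatic_ring_features(rdmol, conf))
            continue
        if rule.placement == "cluster":
            feats.extend(_apolar_cluster_features(rdmol, conf))
            continue
        patt = Chem.MolFromSmarts(rule.pattern)
        if patt is None:
            raise InputError(f"invalid SMARTS in rule table: {rule.pattern!r}")
        for match in rdmol.GetSubstructMatches(patt, uniquify=True):
            coords = np.array([conf.GetAtomPosition(i) for i in match])
            if rule.placement == "atom":
                idx = match[0]
                direction = None
                if rule.ftype == "A":
                    direction = _lone_pair_direction(rdmol, conf, idx)
                elif rule.ftype == "D":
                    direction = _donor_direction(rdmol, conf, idx)
                feats.append(
                    PharmacophoreFeature(rule.ftype, coords[0], direction, (idx,))
                )
            else:  # centroid
                feats.append(
                    PharmacophoreFeature(rule.ftype, coords.mean(axis=0), None, match)
                )

    order = {t: k for k, t in enumerate(FEATURE_TYPES)}
    feats = _merge_overlapping(feats)
    feats.sort(key=lambda f: (order[f.ftype], tuple(np.round(f.position, 6))))
    return FeatureSet(mol.id, mol.conformer_id, feats)


def enumerate_protomer_inputs(
    records: list[tuple[str, str, str]], seed: int = 2024
) -> tuple[list[Molecule3D], list[tuple[str, str, str]]]:
    """Build one Molecule3D per (id, structure, protomer-tag) record.

    ``structure`` is a SMILES string or an SDF/MOL block (detected by the
    V2000/V3000 counts line).  Returns ``(molecules, failures)`` where each
    failure is ``(id, tag, reason)``; duplicate (id, tag) keys raise.
    """
    seen: set[tuple[str, str]] = set()
    mols: list[Molecule3D] = []
    failures: list[tuple[str, str, str]] = []
    for rec_id, structure, tag in records:
        key = (rec_id, tag)
        if key in seen:
            raise InputError(f"duplicate record key {key}")
        seen.add(key)
        full_id = f"{rec_id}|{tag}" if tag else rec_id
        try:
            if "V2000" in structure or "V3000" in structure:
                mols.append(molecule_from_molblock(full_id, structure))
            else:
                mols.append(molecule_from_smiles(full_id, structure, seed=seed))
        except InputError as exc:
            failures.append((rec_id, tag, str(exc)))
    return mols, failures


def compound_id(molecule_id: str) -> str:
    """Base compound id of a protomer-tagged molecule id (``'x|2plus'`` -> ``'x'``)."""
    return molecule_id.split("|", 1)[0]
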