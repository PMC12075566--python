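"""Core ligand-side data containers.

A :class:`Molecule3D` is a prepared small molecule: elements, one conformer of
3D coordinates (Å), formal charges and bonds.  Protonation-state enumeration
is upstream of this package — each protomer/tautomer arrives as its own
record and its own ``Molecule3D``.

A :class:`PharmacophoreFeature` is one of the six classic feature types

* ``A`` hydrogen-bond acceptor, ``D`` hydrogen-bond donor,
* ``H`` hydrophobic group, ``N`` negatively charged group,
* ``P`` positively charged group, ``R`` aromatic ring,

with a position and, for A/D/R, an optional unit direction vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

FEATURE_TYPES = ("A", "D", "H", "N", "P", "R")

#: feature types that carry a direction (projection vector / ring normal)
DIRECTIONAL_TYPES = frozenset({"A", "D", "R"})


@dataclass(frozen=True)
class PharmacophoreFeature:
    ftype: str
    position: np.ndarray  # (3,) Å
    direction: np.ndarray | None = None  # unit vector, A/D/R only
    source_atoms: tuple[int, ...] = ()

    def __post_init__(self):
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("feature position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            if d.shape != (3,) or abs(np.linalg.norm(d) - 1.0) > 1e-6:
                raise ValueError("feature direction must be a unit 3-vector")
            object.__setattr__(self, "direction", d)
        object.__setattr__(self, "source_atoms", tuple(int(i) for i in self.source_atoms))

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "PharmacophoreFeature":
        """Apply the rigid motion x -> R x + t."""
        d = None if self.direction is None else R @ self.direction
        return PharmacophoreFeature(self.ftype, R @ self.position + t, d, self.source_atoms)


@dataclass
class Molecule3D:
    """A prepared organic small molecule with one 3D conformer."""

    id: str
    atoms: list[tuple[str, np.ndarray, int]]  # (element, xyz Å, formal charge)
    bonds: list[tuple[int, int, float]]  # (i, j, order)
    conformer_id: int = 0

    def __post_init__(self):
        atoms = []
        for elem, xyz, q in self.atoms:
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise ValueError(f"molecule {self.id}: non-finite coordinates")
            atoms.append((elem, xyz, int(q)))
        self.atoms = atoms
        n = len(atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"molecule {self.id}: bond ({i},{j}) out of range")
        if not any(elem != "H" for elem, _, _ in atoms):
            raise ValueError(f"molecule {self.id}: no heavy atom")

    @property
    def coords(self) -> np.ndarray:
        return np.array([xyz for _, xyz, _ in self.atoms])


@dataclass
class FeatureSet:
    """Perceived pharmacophore features of one molecule conformer."""

    molecule_id: str
    conformer_id: int
    features: list[PharmacophoreFeature] = field(default_factory=list)

    def by_type(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, f in enumerate(self.features):
            out.setdefault(f.ftype, []).append(i)
        return out

    @property
    def signature(self) -> str:
        return "".join(sorted(f.ftype for f in self.features))

    def positions(self, idx=None) -> np.ndarray:
        feats = self.features if idx is None else [self.features[i] for i in idx]
        return np.array([f.position for f in feats]).reshape(-1, 3)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "FeatureSet":
        return FeatureSet(
            self.molecule_id, self.conformer_id, [f.transformed(R, t) for f in self.features]
        )

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "molecule_id": self.molecule_id,
            "conformer_id": self.conformer_id,
            "features": [
                {
                    "ftype": f.ftype,
                    "position": f.position.tolist(),
                    "direction": None if f.direction is None else f.direction.tolist(),
                    "source_atoms": list(f.source_atoms),
                }
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        feats = [
            PharmacophoreFeature(
                f["ftype"],
                np.asarray(f["position"]),
                None if f.get("direction") is None else np.asarray(f["direction"]),
                tuple(f.get("source_atoms", ())),
            )
            for f in d["features"]
        ]
        return cls(d["molecule_id"], d["conformer_id"], feats)


def save_feature_sets(sets: list[FeatureSet], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in sets], fh, indent=1)


def load_feature_sets(path) -> list[FeatureSet]:
    with open(path) as fh:
        return [FeatureSet.from_dict(d) for d in json.load(fh)]
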