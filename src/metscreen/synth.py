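"""Seed-deterministic synthetic fixtures with built-in ground truth.

Every generator returns its own ground truth alongside the data so tests
can close the loop without external files:

* :func:`gen_planted_set` — feature sets of "actives" sharing a planted
  3D arrangement (a known pharmacophore plus per-molecule coordinate noise
  and distractor features) and geometry-randomised decoys guaranteed not to
  match, standing in for a training set of known channel blockers with
  property-matched decoys (decoy matching here is geometric, not
  physicochemical);
* :func:`gen_toy_pore` — a cylinder of pseudo-atoms with an analytically
  known radius profile;
* :func:`gen_toy_poseset` — a receptor + pose ensemble realising a
  prescribed contact-frequency map exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactProfile, Pose, PoseSet, Receptor
from .geometry import best_correspondence
from .hypotheses import Hypothesis
from .mol import DIRECTIONAL_TYPES, FEATURE_TYPES, FeatureSet, PharmacophoreFeature

#: default planted four-point arrangement: acceptor, cation, two rings
#: (the archetypal blocker motif: protonatable nitrogen + aromatic rings)
DEFAULT_SIGNATURE = "APRR"
DEFAULT_POSITIONS = {
    "APRR": np.array(
        [[0.0, 0.0, 0.0], [4.0, 0.0, 0.0], [2.0, 3.0, 0.5], [6.5, 2.5, -0.5]]
    )
}


@dataclass
class PlantedSpec:
    """Study conditions for the planted-pharmacophore generator."""

    signature: str = DEFAULT_SIGNATURE
    positions: np.ndarray | None = None  # (k, 3); default geometry per signature
    sigma: float = 0.2  # Å coordinate noise on planted features
    n_actives: int = 6
    n_decoys_per_active: int = 40
    n_distractors: int = 2  # extra non-planted features per molecule
    seed: int = 0
    min_decoy_rmsd: float = 2.0  # rejection radius from the planted arrangement

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if any(t not in FEATURE_TYPES for t in self.signature):
            raise ValueError(f"bad signature {self.signature!r}")
        if self.positions is None:
            if self.signature not in DEFAULT_POSITIONS:
                raise ValueError(
                    f"no default geometry for {self.signature!r}; give positions"
                )
            self.positions = DEFAULT_POSITIONS[self.signature].copy()
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.signature), 3):
            raise ValueError("positions must be (len(signature), 3)")
        # sanity: pairwise distances must be realisable (they are, being 3D
        # coordinates already) and non-degenerate
        d = np.linalg.norm(self.positions[:, None] - self.positions[None, :], axis=-1)
        if np.any(d[~np.eye(len(d), dtype=bool)] < 1e-6):
            raise ValueError("planted features must not coincide")


def _random_rotation(rng) -> np.ndarray:
    """Haar-uniform rotation matrix via QR of a Gaussian matrix."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _unit(v):
    return v / np.linalg.norm(v)


def _planted_features(spec: PlantedSpec, rng) -> list[PharmacophoreFeature]:
    dirs = {}
    for i, t in enumerate(spec.signature):
        if t in DIRECTIONAL_TYPES:
            dirs[i] = _unit(np.random.default_rng(spec.seed + 101 + i).normal(size=3))
    return [
        PharmacophoreFeature(t, spec.positions[i], dirs.get(i))
        for i, t in enumerate(spec.signature)
    ]


def gen_planted_set(
    spec: PlantedSpec,
) -> tuple[list[FeatureSet], list[FeatureSet], Hypothesis]:
    """Actives sharing the planted arrangement, decoys that provably do not.

    Actives: planted features + N(0, σ²) coordinate noise + distractor
    features, then a random rigid motion per molecule.  Decoys: the same
    feature-type inventory with fully randomised geometry, rejection-sampled
    until the best type-preserving superposition onto the planted
    arrangement has RMSD > ``min_decoy_rmsd``.
    """
    rng = np.random.default_rng(spec.seed)
    truth_feats = _planted_features(spec, rng)
    truth = Hypothesis("truth-" + spec.signature, truth_feats)
    k = len(spec.signature)
    ref_types = list(spec.signature)

    def distractors(n):
        out = []
        for _ in range(n):
            t = FEATURE_TYPES[rng.integers(len(FEATURE_TYPES))]
            pos = rng.uniform(-8.0, 8.0, size=3)
            d = _unit(rng.normal(size=3)) if t in DIRECTIONAL_TYPES else None
            out.append(PharmacophoreFeature(t, pos, d))
        return out

    actives = []
    for i in range(spec.n_actives):
        noisy = [
            PharmacophoreFeature(
                f.ftype, f.position + rng.normal(scale=spec.sigma, size=3), f.direction
            )
            for f in truth_feats
        ]
        feats = noisy + distractors(spec.n_distractors)
        R, t = _random_rotation(rng), rng.uniform(-20, 20, size=3)
        fs = FeatureSet(f"active-{i}", 0, feats).transformed(R, t)
        actives.append(fs)

    n_decoys = spec.n_actives * spec.n_decoys_per_active
    decoys = []
    attempts = 0
    while len(decoys) < n_decoys:
        attempts += 1
        if attempts > 100 * n_decoys:
            raise RuntimeError("decoy rejection sampling failed to converge")
        feats = []
        for t in spec.signature:
            pos = rng.uniform(-6.0, 6.0, size=3)
            d = _unit(rng.normal(size=3)) if t in DIRECTIONAL_TYPES else None
            feats.append(PharmacophoreFeature(t, pos, d))
        feats += distractors(spec.n_distractors)
        fs = FeatureSet(f"decoy-{len(decoys)}", 0, feats)
        _, rmsd, _, _ = best_correspondence(
            truth.positions(), ref_types, fs.positions(), fs.by_type()
        )
        if rmsd > spec.min_decoy_rmsd:
            decoys.append(fs)
    return actives, decoys, truth


# ---------------------------------------------------------------------------
# toy pore
# ---------------------------------------------------------------------------

@dataclass
class ToyPore:
    coords: np.ndarray
    elements: np.ndarray
    vdw_table: dict[str, float]
    ring_radii: list[tuple[float, float]]  # (z, ring radius)
    atom_vdw: float

    def analytic_radius(self, z: float) -> float:
        """On-axis probe radius: min over rings of √(R² + Δz²) − vdW."""
        return min(
            float(np.sqrt(R**2 + (z - zr) ** 2)) - self.atom_vdw
            for zr, R in self.ring_radii
        )

    def to_pdb(self, path) -> None:
        import biotite.structure as struc
        from biotite.structure.io import pdb

        n = len(self.coords)
        arr = struc.AtomArray(n)
        arr.coord = self.coords
        arr.element = np.array(["C"] * n)
        arr.atom_name = np.array(["C"] * n)
        arr.res_name = np.array(["PSE"] * n)
        arr.res_id = np.arange(1, n + 1)
        arr.chain_id = np.array(["A"] * n)
        f = pdb.PDBFile()
        f.set_structure(arr)
        f.write(str(path))


def gen_toy_pore(
    ring_radii: list[tuple[float, float]],
    atom_vdw: float = 1.5,
    atoms_per_ring: int = 24,
    seed: int = 0,
) -> ToyPore:
    """Stacked rings of pseudo-atoms forming a pore of known radius.

    At a ring of radius R the true pore radius is R − atom_vdw (up to the
    angular discretisation of the ring, which shrinks with
    ``atoms_per_ring``).
    """
    if len(ring_radii) < 2:
        raise ValueError("need at least 2 rings")
    if any(R <= atom_vdw for _, R in ring_radii):
        raise ValueError("ring radius must exceed the atom vdW radius")
    rng = np.random.default_rng(seed)
    # one phase for the whole stack: keeps the angular gap structure of the
    # discretisation consistent along z
    phase = rng.uniform(0, 2 * np.pi)
    coords = []
    for z, R in ring_radii:
        ang = phase + 2 * np.pi * np.arange(atoms_per_ring) / atoms_per_ring
        ring = np.stack([R * np.cos(ang), R * np.sin(ang), np.full_like(ang, z)], axis=1)
        coords.append(ring)
    coords = np.concatenate(coords)
    elements = np.array(["X"] * len(coords), dtype=object)
    return ToyPore(coords, elements, {"X": atom_vdw}, list(ring_radii), atom_vdw)


# ---------------------------------------------------------------------------
# toy pose sets
# ---------------------------------------------------------------------------

def gen_toy_poseset(
    n_residues: int,
    n_poses: int,
    planted_contact_map: np.ndarray | None = None,
    seed: int = 0,
    cutoff: float = 5.0,
) -> tuple[PoseSet, ContactProfile]:
    """Receptor + pose ensemble realising a prescribed contact map exactly.

    Residues are single-atom and spaced far apart (≥ 4×cutoff); each pose
    places one atom within 1 Å of every residue it is planted to contact,
    so the true contact frequency of residue j is the column mean of the
    planted boolean map.
    """
    if n_poses < 1:
        raise ValueError("need at least one pose")
    rng = np.random.default_rng(seed)
    if planted_contact_map is None:
        planted_contact_map = rng.random((n_poses, n_residues)) < 0.5
    cmap = np.asarray(planted_contact_map, dtype=bool)
    if cmap.shape != (n_poses, n_residues):
        raise ValueError("contact map must be (n_poses, n_residues)")

    spacing = 4.0 * cutoff
    res_pos = np.stack(
        [np.arange(n_residues) * spacing, np.zeros(n_residues), np.zeros(n_residues)],
        axis=1,
    )
    receptor = Receptor(
        res_pos,
        np.array(["C"] * n_residues, dtype=object),
        np.array(["CA"] * n_residues, dtype=object),
        np.array(["A"] * n_residues, dtype=object),
        np.arange(1, n_residues + 1),
        np.array(["GLY"] * n_residues, dtype=object),
    )
    poses = []
    for p in range(n_poses):
        pts = []
        for j in range(n_residues):
            if cmap[p, j]:
                offset = rng.normal(size=3)
                pts.append(res_pos[j] + _unit(offset) * rng.uniform(0.5, 1.0))
        if not pts:
            pts.append(np.array([-10.0 * spacing - p * spacing, 0.0, 0.0]))
        pts = np.array(pts)
        poses.append(
            Pose(f"lig-{p}", pts, np.array(["C"] * len(pts), dtype=object),
                 np.zeros(len(pts), dtype=int))
        )
    freqs = cmap.mean(axis=0)
    rows = [
        {
            "residue": f"G{j + 1}:A",
            "count": int(cmap[:, j].sum()),
            "frequency": float(freqs[j]),
            "category": "high" if freqs[j] > 0.5 else "low",
        }
        for j in range(n_residues)
    ]
    return PoseSet(receptor, poses), ContactProfile(pd.DataFrame(rows))


def gen_score_table(
    n_molecules: int, n_hypotheses: int, mean: float = 1.0, sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-form nonnegative score table with known mean/SD structure."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_molecules):
        for j in range(n_hypotheses):
            rows.append(
                {
                    "molecule_id": f"mol-{i:04d}",
                    "hypothesis_id": f"hypo-{j}",
                    "score": max(0.0, rng.normal(mean, sd)),
                }
            )
    return pd.DataFrame(rows)
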