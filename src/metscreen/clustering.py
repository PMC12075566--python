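"""Structural-diversity triage of screening hits.

Hits are encoded as radius-2 circular (Morgan) fingerprints, compared with
the Tanimoto coefficient, clustered by average-linkage hierarchical
clustering on Tanimoto distance (1 − similarity), and cut at a *normalized*
threshold — a fraction of the maximum merge height of the dendrogram
(0.75 and 0.85 are the library-specific defaults of the study design; an
absolute-height cut is available behind a flag).  Within each cluster of at
least ``min_cluster_size`` members, representatives are the compounds with
the lowest docking-rescoring binding energy ΔG_bind (kcal/mol, without
phospholipids), cross-checked against the ΔG_bind values recomputed in the
presence of phospholipids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs import BulkTanimotoSimilarity
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

FP_RADIUS = 2
FP_NBITS = 2048


@dataclass
class FingerprintSet:
    ids: list[str]
    fingerprints: list  # rdkit ExplicitBitVect, one per id

    def __post_init__(self):
        if not self.ids or len(self.ids) != len(self.fingerprints):
            raise ValueError("need one fingerprint per id, nonempty")


def fingerprints_from_smiles(records: list[tuple[str, str]]) -> FingerprintSet:
    """Radius-2 hashed circular fingerprints (2048 bits, achiral)."""
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=FP_RADIUS, fpSize=FP_NBITS, includeChirality=False
    )
    ids, fps = [], []
    for cid, smi in records:
        m = Chem.MolFromSmiles(smi)
        if m is None:
            raise ValueError(f"unparsable SMILES for {cid!r}")
        ids.append(cid)
        fps.append(gen.GetFingerprint(m))
    return FingerprintSet(ids, fps)


def tanimoto_matrix(fps: FingerprintSet) -> pd.DataFrame:
    """Pairwise Tanimoto similarity (1 = identical environments)."""
    n = len(fps.ids)
    if n < 2:
        raise ValueError("need at least 2 fingerprints")
    S = np.eye(n)
    for i in range(n):
        if i + 1 < n:
            S[i, i + 1:] = BulkTanimotoSimilarity(fps.fingerprints[i], fps.fingerprints[i + 1:])
            S[i + 1:, i] = S[i, i + 1:]
    return pd.DataFrame(S, index=fps.ids, columns=fps.ids)


@dataclass
class ClusterAssignment:
    labels: dict[str, int]  # id -> contiguous cluster label, 1-based
    linkage: np.ndarray  # scipy linkage matrix (average method)
    threshold: float  # normalized threshold as given
    cut_height: float  # absolute height actually used
    n_clusters: int = field(init=False)

    def __post_init__(self):
        self.n_clusters = len(set(self.labels.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for cid, lab in self.labels.items():
            out.setdefault(lab, []).append(cid)
        return {k: sorted(v) for k, v in out.items()}


def cluster_cut(
    dist: pd.DataFrame, normalized_threshold: float, absolute: bool = False
) -> ClusterAssignment:
    """Average-linkage tree on a distance matrix, cut at
    ``normalized_threshold × max merge height`` (or at the absolute height
    when ``absolute=True``)."""
    if not (0.0 < normalized_threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    ids = [str(i) for i in dist.index] if isinstance(dist, pd.DataFrame) else [
        str(i) for i in range(D.shape[0])
    ]
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    max_height = float(Z[:, 2].max()) if len(Z) else 0.0
    cut = normalized_threshold if absolute else normalized_threshold * max_height
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")
    # relabel contiguously in order of first appearance
    remap: dict[int, int] = {}
    labels = {}
    for cid, lab in zip(ids, raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[cid] = remap[lab]
    return ClusterAssignment(labels, Z, normalized_threshold, cut)


@dataclass
class EnergyTable:
    """Per-compound MM-GBSA rescoring energies, consumed as input.

    Columns: ``dg_no_lipid`` and ``dg_lipid`` — ΔG_bind (kcal/mol)
    without / with membrane phospholipids in the complex.
    """

    frame: pd.DataFrame  # index: compound id

    def __post_init__(self):
        need = {"dg_no_lipid", "dg_lipid"}
        if not need <= set(self.frame.columns):
            raise ValueError(f"energy table needs columns {sorted(need)}")
        if not np.all(np.isfinite(self.frame[list(need)].to_numpy())):
            raise ValueError("energies must be finite")

    def dg(self, cid: str, with_lipid: bool = False) -> float:
        col = "dg_lipid" if with_lipid else "dg_no_lipid"
        return float(self.frame.loc[cid, col])


def select_representatives(
    ca: ClusterAssignment,
    e: EnergyTable,
    min_cluster_size: int = 3,
    reps_per_cluster: int | dict[int, int] = 1,
) -> pd.DataFrame:
    """Diversity-aware hit picking: from each cluster with at least
    ``min_cluster_size`` members, take the ``reps_per_cluster`` compounds
    with the lowest ΔG_bind (without phospholipids); ties break by id."""
    rows = []
    for lab, members in sorted(ca.members().items()):
        if len(members) < min_cluster_size:
            continue
        missing = [m for m in members if m not in e.frame.index]
        if missing:
            raise KeyError(f"no binding energy for compound(s): {missing}")
        n_reps = reps_per_cluster if isinstance(reps_per_cluster, int) else \
            reps_per_cluster.get(lab, 1)
        ranked = sorted(members, key=lambda m: (e.dg(m), m))
        for m in ranked[:n_reps]:
            rows.append({"id": m, "cluster": lab, "dg_no_lipid": e.dg(m),
                         "dg_lipid": e.dg(m, with_lipid=True)})
    return pd.DataFrame(rows, columns=["id", "cluster", "dg_no_lipid", "dg_lipid"])


def consistency_check(hits: pd.DataFrame, e: EnergyTable) -> pd.DataFrame:
    """Verify hits remain thermodynamically favorable when phospholipids are
    included in the rescoring: per hit, both-column favorability flags, rank
    percentiles in each column, and the sign of the lipid-induced shift."""
    frame = e.frame
    pct_no = frame["dg_no_lipid"].rank(pct=True)
    pct_li = frame["dg_lipid"].rank(pct=True)
    rows = []
    for cid in hits["id"]:
        dg0, dg1 = e.dg(cid), e.dg(cid, with_lipid=True)
        rows.append(
            {
                "id": cid,
                "dg_no_lipid": dg0,
                "dg_lipid": dg1,
                "favorable_no_lipid": dg0 < 0,
                "favorable_lipid": dg1 < 0,
                "pct_no_lipid": float(pct_no.loc[cid]),
                "pct_lipid": float(pct_li.loc[cid]),
                "weaker_with_lipid": dg1 > dg0,
            }
        )
    return pd.DataFrame(rows)
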