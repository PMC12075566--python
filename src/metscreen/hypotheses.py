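"""Common-feature 3D pharmacophore hypothesis generation.

A hypothesis is an arrangement of 3–5 features (e.g. signature ``APRR``:
acceptor, positive charge, two aromatic rings) that at least half of a
training set of known actives can superpose onto within a tolerance.

Search strategy: feature k-tuples are enumerated on each training molecule
in turn as reference arrangements, verified against every other molecule by
type-preserving correspondence + rigid superposition, deduplicated by
signature and geometry, and ranked by a bounded quality score.  This is
exhaustive at training-set scale (tens of molecules, tens of features).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .geometry import best_correspondence
from .mol import FeatureSet, PharmacophoreFeature
from .screening import ConfigError, match_to_hypothesis

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 1.0  # Å, per-feature match radius (same as the RMSD gate)
DEFAULT_MAX_HYPOTHESES = 10


@dataclass
class Hypothesis:
    """A ranked common-feature pharmacophore arrangement."""

    id: str
    features: list[PharmacophoreFeature]
    tolerance: float = DEFAULT_TOLERANCE
    coverage: float = 0.0
    hypo_score: float = 0.0
    distance_matrix: np.ndarray = field(init=False)

    def __post_init__(self):
        if not (3 <= len(self.features) <= 5):
            raise ConfigError("hypothesis must have 3-5 features")
        P = self.positions()
        self.distance_matrix = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=-1)

    @property
    def signature(self) -> str:
        return "".join(sorted(f.ftype for f in self.features))

    def positions(self, idx=None) -> np.ndarray:
        feats = self.features if idx is None else [self.features[i] for i in idx]
        return np.array([f.position for f in feats]).reshape(-1, 3)

    def by_type(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, f in enumerate(self.features):
            out.setdefault(f.ftype, []).append(i)
        return out

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "tolerance": self.tolerance,
            "coverage": self.coverage,
            "hypo_score": self.hypo_score,
            "features": [
                {
                    "ftype": f.ftype,
                    "position": f.position.tolist(),
                    "direction": None if f.direction is None else f.direction.tolist(),
                }
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Hypothesis":
        feats = [
            PharmacophoreFeature(
                f["ftype"],
                np.asarray(f["position"]),
                None if f.get("direction") is None else np.asarray(f["direction"]),
            )
            for f in d["features"]
        ]
        h = cls(d["id"], feats, d.get("tolerance", DEFAULT_TOLERANCE))
        h.coverage = d.get("coverage", 0.0)
        h.hypo_score = d.get("hypo_score", 0.0)
        return h


def save_hypotheses(hs: list[Hypothesis], path) -> None:
    with open(path, "w") as fh:
        json.dump([h.to_dict() for h in hs], fh, indent=1)


def load_hypotheses(path) -> list[Hypothesis]:
    with open(path) as fh:
        return [Hypothesis.from_dict(d) for d in json.load(fh)]


def _group_by_molecule(training: list[FeatureSet]) -> dict[str, list[FeatureSet]]:
    groups: dict[str, list[FeatureSet]] = {}
    for fs in training:
        groups.setdefault(fs.molecule_id, []).append(fs)
    return groups


def _best_molecule_match(h: Hypothesis, conformers: list[FeatureSet]):
    """Best complete match of any conformer of one molecule; None if none."""
    best = None
    for fs in conformers:
        m = match_to_hypothesis(fs, h, rmsd_max=h.tolerance, allow_partial=False)
        if m is not None and (best is None or m.rmsd < best.rmsd):
            best = m
    return best


def score_hypothesis(
    h: Hypothesis, training: list[FeatureSet], max_features: int = 5
) -> float:
    """Quality score in [0, 1], a defined analog of commercial hypothesis
    scores (site + alignment + vector terms, scaled by coverage):

        coverage × mean over matched molecules of
            (k/k_max + (1 − RMSD/RMSD_max) + vector_alignment) / 3

    with k the hypothesis feature count, k_max = 5 and RMSD_max =
    2·tolerance.  The site term k/k_max rewards more specific (larger)
    arrangements, so a complete planted arrangement outranks its own
    sub-arrangements; without it every 3-feature subset of a good 4-point
    hypothesis would win on RMSD alone.  Not numerically comparable to any
    published hypothesis scores.
    """
    groups = _group_by_molecule(training)
    if not groups:
        raise ConfigError("empty training set")
    rmsd_max = 2.0 * h.tolerance
    site = len(h.features) / max_features
    terms = []
    for conformers in groups.values():
        m = _best_molecule_match(h, conformers)
        if m is not None:
            align = max(0.0, 1.0 - m.rmsd / rmsd_max)
            terms.append((site + align + m.vector_alignment) / 3.0)
    if not terms:
        return 0.0
    coverage = len(terms) / len(groups)
    return float(np.mean(terms) * coverage)


def _is_duplicate(cand: Hypothesis, accepted: list[Hypothesis]) -> bool:
    """Same signature and geometry (best-correspondence RMSD ≤ tolerance)."""
    for h in accepted:
        if h.signature != cand.signature:
            continue
        _, rmsd, _, _ = best_correspondence(
            h.positions(),
            [f.ftype for f in h.features],
            cand.positions(),
            cand.by_type(),
        )
        if rmsd <= h.tolerance:
            return True
    return False


def generate_hypotheses(
    training: list[FeatureSet],
    min_features: int = 3,
    max_features: int = 5,
    min_coverage: float = 0.5,
    tolerance: float = DEFAULT_TOLERANCE,
    max_hypotheses: int = DEFAULT_MAX_HYPOTHESES,
) -> list[Hypothesis]:
    """Enumerate and rank common-feature hypotheses from a training set.

    Every k-tuple (``min_features ≤ k ≤ max_features``) of features on each
    training molecule is a candidate arrangement; a candidate is kept when
    the fraction of training molecules with a complete match within
    ``tolerance`` reaches ``min_coverage`` (the 50% matching-threshold
    default).  Candidates are ranked by :func:`score_hypothesis`, ties by
    id then feature count descending; the best ``max_hypotheses`` return.
    """
    if min_features > max_features:
        raise ConfigError("min_features > max_features")
    if not (3 <= min_features and max_features <= 5):
        raise ConfigError("feature counts must lie in [3, 5]")
    groups = _group_by_molecule(training)
    if len(groups) < 2:
        raise ConfigError("need at least 2 training molecules")

    accepted: list[Hypothesis] = []
    sig_counter: dict[str, int] = {}
    for mol_id in sorted(groups):
        for fs in groups[mol_id]:
            n = len(fs.features)
            for k in range(min_features, min(max_features, n) + 1):
                for subset in combinations(range(n), k):
                    feats = [fs.features[i] for i in subset]
                    cand = Hypothesis("cand", feats, tolerance)
                    if _is_duplicate(cand, accepted):
                        continue
                    matched = sum(
                        _best_molecule_match(cand, confs) is not None
                        for confs in groups.values()
                    )
                    coverage = matched / len(groups)
                    if coverage + 1e-12 < min_coverage:
                        continue
                    sig = cand.signature
                    sig_counter[sig] = sig_counter.get(sig, 0) + 1
                    cand.id = f"{sig}-{sig_counter[sig]}"
                    cand.coverage = coverage
                    cand.hypo_score = score_hypothesis(cand, training)
                    accepted.append(cand)

    if not accepted:
        logger.warning("no common arrangement reaches coverage %.2f", min_coverage)
        return []
    accepted.sort(key=lambda h: (-h.hypo_score, h.id, -len(h.features)))
    return accepted[:max_hypotheses]
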