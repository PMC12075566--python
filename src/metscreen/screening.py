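"""Pharmacophore-based virtual screening.

Two-pass protocol mirroring the study design:

1. a geometric gate — a molecule matches a hypothesis when some
   type-preserving feature correspondence superposes onto the hypothesis
   with RMSD ≤ 1 Å (compounds above the gate are discarded); per hypothesis
   the ``top_n`` lowest-RMSD molecules are kept and only molecules matching
   ≥ ``min_hypotheses`` hypotheses advance;
2. a screen score per (molecule, hypothesis) combining site matching,
   alignment quality and feature-vector agreement, summed across hypotheses
   into the total screen score TPS_S.

Compounds whose TPS_S reaches the docking threshold

    D_T = X̄ + 2·δ

(mean plus two sample standard deviations of TPS_S over the library)
advance to docking.  Protomers/conformers of one compound are collapsed by
taking the best score per hypothesis before summation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import compound_id
from .geometry import kabsch, iter_type_assignments
from .mol import DIRECTIONAL_TYPES, FeatureSet

DEFAULT_RMSD_MAX = 1.0  # Å, first-pass geometric gate
PARTIAL_MIN_FRACTION = 0.75  # minimum fraction of hypothesis features in a partial match


class ConfigError(ValueError):
    pass


@dataclass
class MatchResult:
    molecule_id: str
    hypothesis_id: str
    correspondence: tuple[tuple[int, int], ...]  # (hypothesis feature, molecule feature)
    rmsd: float
    matched_fraction: float
    vector_alignment: float  # mean direction-cosine over matched directional pairs
    screen_score: float = 0.0


def _vector_alignment(h, fs: FeatureSet, pairs, R: np.ndarray) -> float:
    """Mean cosine between hypothesis feature vectors and the superposed
    molecule feature vectors; ring normals compare up to sign."""
    cosines = []
    for hi, fi in pairs:
        dh = h.features[hi].direction
        dm = fs.features[fi].direction
        if dh is None or dm is None:
            continue
        c = float(np.dot(dh, R @ dm))
        if h.features[hi].ftype == "R":
            c = abs(c)
        cosines.append(max(0.0, c))
    return float(np.mean(cosines)) if cosines else 1.0


def _candidate_matches(fs: FeatureSet, h, allow_partial: bool):
    """Yield (pairs, rmsd, matched_fraction, R) over subset sizes/assignments."""
    nh = len(h.features)
    min_k = nh if not allow_partial else max(3, math.ceil(PARTIAL_MIN_FRACTION * nh))
    cand_by_type = fs.by_type()
    cand_pos = fs.positions()
    from itertools import combinations

    for k in range(nh, min_k - 1, -1):
        for subset in combinations(range(nh), k):
            ref_types = [h.features[i].ftype for i in subset]
            ref_pos = h.positions(subset)
            for assign in iter_type_assignments(ref_types, cand_by_type):
                pts = cand_pos[list(assign)]
                R, t, rmsd = kabsch(pts, ref_pos)
                pairs = tuple(zip(subset, assign))
                yield pairs, rmsd, k / nh, R


def match_to_hypothesis(
    fs: FeatureSet,
    h,
    rmsd_max: float = DEFAULT_RMSD_MAX,
    allow_partial: bool = False,
) -> MatchResult | None:
    """Best geometric match of a feature set against a hypothesis.

    Among all type-preserving correspondences within the RMSD gate, the
    match covering the most hypothesis features wins; RMSD breaks ties
    (so a complete match is preferred over a cheaper partial one).
    Returns ``None`` when no correspondence passes the gate.
    """
    if len(h.features) < 3:
        raise ConfigError("hypothesis must have at least 3 features")
    if not fs.features:
        return None
    best = None
    for pairs, rmsd, frac, R in _candidate_matches(fs, h, allow_partial):
        if rmsd > rmsd_max:
            continue
        key = (-frac, rmsd)
        if best is None or key < best[0]:
            best = (key, pairs, rmsd, frac, R)
    if best is None:
        return None
    _, pairs, rmsd, frac, R = best
    valign = _vector_alignment(h, fs, pairs, R)
    m = MatchResult(fs.molecule_id, h.id, pairs, rmsd, frac, valign)
    m.screen_score = screen_score(m, h, rmsd_max=rmsd_max)
    return m


def screen_score(
    m: MatchResult,
    h,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    scale: float = 1.0,
    rmsd_max: float = DEFAULT_RMSD_MAX,
) -> float:
    """Alignment-quality score for a valid match.

    ``scale * (w_site·matched_fraction + w_align·(1 − rmsd/rmsd_max)
    + w_vec·vector_alignment) / Σw`` — a defined analog of commercial
    screen scores (site match + alignment + vector terms), bounded by
    ``scale`` and not numerically comparable to any published values.
    """
    w_site, w_align, w_vec = weights
    total = w_site + w_align + w_vec
    align = max(0.0, 1.0 - m.rmsd / rmsd_max)
    raw = w_site * m.matched_fraction + w_align * align + w_vec * m.vector_alignment
    return scale * raw / total


@dataclass
class ScreenMatrix:
    """Molecules × hypotheses best-score table with TPS_S and D_T."""

    table: pd.DataFrame  # index: compound id; columns: hypothesis ids; 0 = unmatched
    tpss: pd.Series = field(init=False)
    mean_tpss: float = field(init=False)
    sd_tpss: float = field(init=False)
    d_threshold: float = field(init=False)
    selected: list[str] = field(init=False)

    def __post_init__(self):
        self.tpss = self.table.sum(axis=1)
        if len(self.tpss) < 2:
            raise ConfigError("need TPS_S for at least 2 molecules")
        self.mean_tpss = float(self.tpss.mean())
        self.sd_tpss = float(self.tpss.std(ddof=1))  # sample SD in the threshold rule
        self.d_threshold = self.mean_tpss + 2.0 * self.sd_tpss
        self.selected = [
            str(i) for i in self.tpss.index if self.tpss[i] >= self.d_threshold - 1e-12
        ]

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["tpss"] = self.tpss
        out["selected"] = [i in set(self.selected) for i in out.index]
        return out


def aggregate_tpss(scores: pd.DataFrame, collapse_protomers: bool = True) -> ScreenMatrix:
    """Build the screening matrix from long-form (molecule, hypothesis, score) rows.

    ``scores`` columns: ``molecule_id``, ``hypothesis_id``, ``score``.
    Protomer/conformer ids of the form ``"compound|tag"`` are collapsed to
    the compound by the per-hypothesis maximum; TPS_S is the row sum over
    hypotheses with unmatched entries contributing 0.
    """
    df = scores.copy()
    if (df["score"] < 0).any():
        raise ValueError("screen scores must be nonnegative")
    if collapse_protomers:
        df["molecule_id"] = df["molecule_id"].map(compound_id)
        df = (
            df.groupby(["molecule_id", "hypothesis_id"], as_index=False)["score"].max()
        )
    dup = df.duplicated(subset=["molecule_id", "hypothesis_id"])
    if dup.any():
        raise ValueError("duplicated (molecule, hypothesis) entries after collapsing")
    table = (
        df.pivot(index="molecule_id", columns="hypothesis_id", values="score")
        .fillna(0.0)
        .sort_index()
    )
    table.columns.name = None
    table.index.name = "molecule_id"
    return ScreenMatrix(table)


def docking_threshold(sm: ScreenMatrix) -> tuple[float, list[str]]:
    """Eq.-style selection: D_T = X̄ + 2δ; compounds with TPS_S ≥ D_T pass."""
    return sm.d_threshold, list(sm.selected)


def first_pass_filter(
    matches: pd.DataFrame, top_n: int = 5000, min_hypotheses: int = 2
) -> list[str]:
    """RMSD-gate triage: per hypothesis keep the ``top_n`` lowest-RMSD
    molecules (ties broken by molecule id), then keep molecules that appear
    under at least ``min_hypotheses`` hypotheses.

    ``matches`` columns: ``molecule_id``, ``hypothesis_id``, ``rmsd``.
    """
    if top_n <= 0:
        raise ConfigError("top_n must be positive")
    if not np.all(np.isfinite(matches["rmsd"])):
        raise ValueError("non-finite RMSD values")
    kept: dict[str, int] = {}
    for _, grp in matches.groupby("hypothesis_id"):
        grp = grp.sort_values(["rmsd", "molecule_id"], kind="mergesort").head(top_n)
        for mid in grp["molecule_id"]:
            kept[mid] = kept.get(mid, 0) + 1
    return sorted(m for m, c in kept.items() if c >= min_hypotheses)
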