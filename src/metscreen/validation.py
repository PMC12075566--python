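"""Decoy-based model validation: ROC/AUC and the Güner–Henry metric family.

A pharmacophore model is screened against known actives plus presumed
inactive decoys (the study design uses 40 decoys per active) and judged by
retrieval statistics computed from the counts

    D   total compounds screened,      A   total actives,
    Ht  total hits retrieved,          Ha  active hits retrieved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ValidationCounts:
    D: int
    A: int
    Ht: int
    Ha: int

    def __post_init__(self):
        if not (0 <= self.Ha <= min(self.A, self.Ht)):
            raise ValueError("need 0 <= Ha <= min(A, Ht)")
        if self.Ht > self.D or self.A > self.D:
            raise ValueError("Ht and A cannot exceed D")


def roc_auc(active_scores, decoy_scores) -> float:
    """AUC of the ROC curve in the rank formulation,
    P(active > decoy) + 0.5·P(tie); higher score = more active."""
    a = np.asarray(active_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    if a.size == 0 or d.size == 0:
        raise ValueError("both score lists must be nonempty")
    # Mann-Whitney U equals the pairwise win count with half credit for ties
    ranks = stats.rankdata(np.concatenate([a, d]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * d.size))


def gh_metrics(c: ValidationCounts) -> dict[str, float]:
    """%Yield, Ya, Se, Sp, EF and the Güner–Henry score.

    GH = [Ha·(3A + Ht) / (4·Ht·A)] · [1 − (Ht − Ha)/(D − A)], in [0, 1];
    EF = (Ha/Ht)/(A/D) is the active-concentration enrichment of the hit
    list over the screened set.
    """
    if c.Ht == 0:
        raise ValueError("Ht = 0: retrieval metrics undefined")
    if c.A == 0 or c.D <= c.A:
        raise ValueError("need A > 0 and D > A (decoys present)")
    ya = c.Ha / c.Ht
    se = c.Ha / c.A
    sp = ((c.D - c.A) - (c.Ht - c.Ha)) / (c.D - c.A)
    ef = ya / (c.A / c.D)
    gh = (c.Ha * (3 * c.A + c.Ht) / (4 * c.Ht * c.A)) * (1 - (c.Ht - c.Ha) / (c.D - c.A))
    return {
        "yield_pct": 100.0 * ya,
        "Ya": ya,
        "Se": se,
        "Sp": sp,
        "EF": ef,
        "GH": gh,
    }


def classify_model_quality(
    gh: float, thresholds: dict[str, float] | None = None
) -> str:
    """Label a model from its GH score: > 0.7 good, > 0.5 acceptable
    (both strict), else poor."""
    if thresholds is None:
        thresholds = {"good": 0.7, "acceptable": 0.5}
    if not (0.0 <= gh <= 1.0):
        raise ValueError("GH score must lie in [0, 1]")
    if gh > thresholds["good"]:
        return "good"
    if gh > thresholds["acceptable"]:
        return "acceptable"
    return "poor"


def counts_from_scores(
    active_scores, decoy_scores, threshold: float
) -> ValidationCounts:
    """Hit counts at a score cutoff (score ≥ threshold ⇒ hit)."""
    a = np.asarray(active_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    ha = int((a >= threshold).sum())
    ht = ha + int((d >= threshold).sum())
    return ValidationCounts(D=a.size + d.size, A=a.size, Ht=ht, Ha=ha)
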