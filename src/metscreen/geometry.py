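"""Rigid-body superposition and feature-correspondence search.

The matcher used throughout hypothesis generation and screening reduces to:
given two same-length point sets (hypothesis feature positions and candidate
molecule feature positions, paired type-by-type), find the proper rotation +
translation minimising RMSD (Kabsch), and search over all type-preserving
assignments for the correspondence with the lowest such RMSD.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of P onto Q (both (n,3)).

    Returns ``(R, t, rmsd)`` such that ``P @ R.T + t`` best fits ``Q`` in the
    least-squares sense, with ``R`` a proper rotation.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


def iter_type_assignments(
    ref_types: list[str], cand_by_type: dict[str, list[int]]
):
    """Yield index tuples assigning each reference slot a distinct candidate
    feature of the same type.

    ``ref_types`` is the type letter of each reference slot; the yielded tuple
    gives, per slot, the candidate feature index.  Candidates are drawn
    without replacement within each type.
    """
    slots_by_type: dict[str, list[int]] = {}
    for i, t in enumerate(ref_types):
        slots_by_type.setdefault(t, []).append(i)

    per_type_choices = []
    for t, slots in slots_by_type.items():
        pool = cand_by_type.get(t, [])
        if len(pool) < len(slots):
            return  # a type is under-supplied: no assignment exists
        per_type_choices.append((slots, list(permutations(pool, len(slots)))))

    def rec(k, current):
        if k == len(per_type_choices):
            yield tuple(current)
            return
        slots, perms = per_type_choices[k]
        for perm in perms:
            for s, c in zip(slots, perm):
                current[s] = c
            yield from rec(k + 1, current)

    yield from rec(0, [None] * len(ref_types))


def best_correspondence(
    ref_positions: np.ndarray,
    ref_types: list[str],
    cand_positions: np.ndarray,
    cand_by_type: dict[str, list[int]],
) -> tuple[tuple[int, ...] | None, float, np.ndarray | None, np.ndarray | None]:
    """Minimum-RMSD type-preserving correspondence.

    Returns ``(assignment, rmsd, R, t)`` where ``assignment[i]`` is the
    candidate feature index matched to reference slot ``i`` and ``(R, t)``
    superposes the candidate onto the reference.  ``(None, inf, None, None)``
    when no assignment exists.
    """
    best = (None, np.inf, None, None)
    for assign in iter_type_assignments(ref_types, cand_by_type):
        pts = cand_positions[list(assign)]
        R, t, rmsd = kabsch(pts, ref_positions)
        if rmsd < best[1]:
            best = (assign, rmsd, R, t)
    return best
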