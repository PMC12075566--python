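"""Independent brute-force oracles for the production algorithms.

Deliberately different implementation routes: superposition via Horn's
quaternion method (the production matcher uses Kabsch/SVD), correspondence
enumeration via itertools, pairwise-count ROC, a from-scratch agglomerative
average-linkage clusterer, and all-pairs distance scans.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


def horn_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD superposing P onto Q via Horn's quaternion method."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    Sxx, Sxy, Sxz = (P0[:, 0] * Q0[:, 0]).sum(), (P0[:, 0] * Q0[:, 1]).sum(), (P0[:, 0] * Q0[:, 2]).sum()
    Syx, Syy, Syz = (P0[:, 1] * Q0[:, 0]).sum(), (P0[:, 1] * Q0[:, 1]).sum(), (P0[:, 1] * Q0[:, 2]).sum()
    Szx, Szy, Szz = (P0[:, 2] * Q0[:, 0]).sum(), (P0[:, 2] * Q0[:, 1]).sum(), (P0[:, 2] * Q0[:, 2]).sum()
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    sq = ((P0**2).sum() + (Q0**2).sum() - 2.0 * lam) / len(P)
    return float(np.sqrt(max(sq, 0.0)))


def brute_force_match(ref_positions, ref_types, cand_positions, cand_types,
                      rmsd_max=np.inf, min_fraction=1.0):
    """Exhaustive correspondence search mirroring the matcher's preference
    rule (most features matched first, then lowest RMSD).

    Returns (rmsd, n_matched) of the winning correspondence or None.
    """
    ref_positions = np.asarray(ref_positions, float)
    cand_positions = np.asarray(cand_positions, float)
    n = len(ref_types)
    min_k = max(3, int(np.ceil(min_fraction * n)))
    cand_idx_by_type = {}
    for i, t in enumerate(cand_types):
        cand_idx_by_type.setdefault(t, []).append(i)

    best = None
    for k in range(n, min_k - 1, -1):
        for subset in combinations(range(n), k):
            choices = []

            def rec(slot, used, chosen):
                nonlocal best
                if slot == len(subset):
                    rmsd = horn_rmsd(
                        cand_positions[list(chosen)], ref_positions[list(subset)]
                    )
                    if rmsd <= rmsd_max:
                        key = (-len(subset), rmsd)
                        if best is None or key < best[0]:
                            best = (key, rmsd, len(subset))
                    return
                t = ref_types[subset[slot]]
                for c in cand_idx_by_type.get(t, []):
                    if c not in used:
                        rec(slot + 1, used | {c}, chosen + [c])

            rec(0, frozenset(), choices)
    if best is None:
        return None
    return best[1], best[2]


def pairwise_auc(active_scores, decoy_scores) -> float:
    wins = ties = 0
    for a in active_scores:
        for d in decoy_scores:
            if a > d:
                wins += 1
            elif a == d:
                ties += 1
    return (wins + 0.5 * ties) / (len(active_scores) * len(decoy_scores))


def naive_average_linkage(D: np.ndarray):
    """From-scratch UPGMA: returns merge heights and a label function.

    ``labels_at(t)``: cluster labels from merging every pair of clusters
    whose average inter-point distance is <= t, replayed from the recorded
    merge sequence (cut above height t).
    """
    D = np.asarray(D, float)
    n = len(D)
    clusters = {i: [i] for i in range(n)}
    merges = []  # (height, members_a, members_b)
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            h = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        merges.append((h, list(clusters[a]), list(clusters[b])))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]

    def labels_at(t: float) -> list[int]:
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for h, ma, mb in merges:
            if h <= t:
                ra, rb = find(ma[0]), find(mb[0])
                parent[rb] = ra
        roots = {}
        out = []
        for i in range(n):
            r = find(i)
            if r not in roots:
                roots[r] = len(roots) + 1
            out.append(roots[r])
        return out

    heights = [m[0] for m in merges]
    return heights, labels_at


def all_pairs_contact_freq(rec_coords, rec_residue_keys, pose_coord_list, cutoff):
    """Triple-loop contact frequencies; returns {residue: frequency}."""
    residues = list(dict.fromkeys(rec_residue_keys))
    counts = {r: 0 for r in residues}
    for pose in pose_coord_list:
        touched = set()
        for pc in pose:
            for rc, key in zip(rec_coords, rec_residue_keys):
                if np.linalg.norm(np.asarray(pc) - np.asarray(rc)) <= cutoff:
                    touched.add(key)
        for r in touched:
            counts[r] += 1
    n = len(pose_coord_list)
    return {r: counts[r] / n for r in residues}
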