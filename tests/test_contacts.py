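"""Pose-ensemble contact frequencies, interaction typing, zone assignment."""

import numpy as np
import pandas as pd
import pytest

from metscreen.contacts import (
    ContactProfile,
    Pose,
    PoseSet,
    Receptor,
    annotate_interactions,
    assign_zone,
    contact_frequency,
)
from metscreen.synth import gen_toy_poseset
from oracles import all_pairs_contact_freq


def one_atom_receptor(positions, res_names=None, elements=None, atom_names=None):
    n = len(positions)
    return Receptor(
        np.asarray(positions, float),
        np.array(elements or ["C"] * n, dtype=object),
        np.array(atom_names or ["CA"] * n, dtype=object),
        np.array(["A"] * n, dtype=object),
        np.arange(1, n + 1),
        np.array(res_names or ["GLY"] * n, dtype=object),
    )


def carbon_pose(pid, positions, charges=None):
    pts = np.asarray(positions, float).reshape(-1, 3)
    return Pose(pid, pts, np.array(["C"] * len(pts), dtype=object),
                np.array(charges if charges is not None else [0] * len(pts)))


class TestContactFrequency:
    def test_residue_near_both_poses_is_high(self):
        rec = one_atom_receptor([[0, 0, 0]])
        ps = PoseSet(rec, [carbon_pose("l1", [[0, 0, 3]]), carbon_pose("l2", [[0, 3, 0]])])
        prof = contact_frequency(ps)
        assert prof.frame.iloc[0]["frequency"] == 1.0
        assert prof.frame.iloc[0]["category"] == "high"

    def test_exactly_half_is_low_contact(self):
        rec = one_atom_receptor([[0, 0, 0]])
        ps = PoseSet(rec, [carbon_pose("l1", [[0, 0, 3]]), carbon_pose("l2", [[0, 0, 30]])])
        row = contact_frequency(ps).frame.iloc[0]
        assert row["frequency"] == 0.5
        assert row["category"] == "low"  # the >0.5 rule is strict

    def test_three_residue_distance_arithmetic(self):
        rec = one_atom_receptor([[0, 0, 0], [0, 0, 6], [0, 0, 12]])
        ps = PoseSet(rec, [carbon_pose("l1", [[0, 0, 4]])])
        freqs = dict(zip(contact_frequency(ps).frame["residue"],
                         contact_frequency(ps).frame["frequency"]))
        assert freqs == {"G1:A": 1.0, "G2:A": 1.0, "G3:A": 0.0}

    def test_empty_pose_rejected(self):
        rec = one_atom_receptor([[0, 0, 0]])
        hpose = Pose("h", np.array([[0.0, 0, 0]]), np.array(["H"], dtype=object),
                     np.array([0]))
        with pytest.raises(ValueError):
            contact_frequency(PoseSet(rec, [hpose]))

    def test_rigid_motion_invariance(self, rng):
        ps, _ = gen_toy_poseset(6, 4, seed=9)
        base = contact_frequency(ps).frame
        theta = 1.1
        R = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                      [-np.sin(theta), 0, np.cos(theta)]])
        t = np.array([5.0, -3.0, 2.0])
        moved = PoseSet(
            ps.receptor.transformed(R, t),
            [Pose(p.ligand_id, p.coords @ R.T + t, p.elements, p.charges)
             for p in ps.poses],
        )
        assert contact_frequency(moved).frame.equals(base)

    def test_adding_a_pose_shifts_frequencies_by_at_most_one_over_n1(self):
        ps, _ = gen_toy_poseset(8, 5, seed=3)
        f1 = contact_frequency(ps).frame.set_index("residue")["frequency"]
        extra, _ = gen_toy_poseset(8, 1, seed=4)
        bigger = PoseSet(ps.receptor, ps.poses + extra.poses)
        f2 = contact_frequency(bigger).frame.set_index("residue")["frequency"]
        n = len(ps.poses)
        assert np.all(np.abs(f2 - f1) <= 1.0 / (n + 1) + 1e-12)

    def test_matches_all_pairs_brute_force(self):
        """KD-tree path equals a triple-loop distance scan."""
        ps, truth = gen_toy_poseset(50, 36, seed=11)
        got = contact_frequency(ps).frame.set_index("residue")["frequency"]
        heavy = ps.receptor.heavy_mask()
        want = all_pairs_contact_freq(
            ps.receptor.coords[heavy],
            list(ps.receptor.residue_keys()[heavy]),
            [p.heavy().coords for p in ps.poses],
            cutoff=5.0,
        )
        for res, f in want.items():
            assert got[res] == pytest.approx(f, abs=1e-12)
        # and both agree with the generator's planted ground truth
        truth_f = truth.frame.set_index("residue")["frequency"]
        assert np.allclose(got[truth_f.index], truth_f)


def aspartate_fragment():
    """Side-chain carboxylate of an aspartate at the origin."""
    return Receptor(
        np.array([[0.0, 0, 0], [1.3, 0.6, 0], [1.3, -0.6, 0]]),
        np.array(["C", "O", "O"], dtype=object),
        np.array(["CG", "OD1", "OD2"], dtype=object),
        np.array(["A"] * 3, dtype=object),
        np.array([569] * 3),
        np.array(["ASP"] * 3, dtype=object),
    )


def popc_headgroup():
    """Phosphate head: P with two bonded oxygens, plus choline N."""
    return Receptor(
        np.array([[0.0, 0, 0], [1.5, 0, 0], [-0.8, 1.2, 0], [3.5, 2.0, 0]]),
        np.array(["P", "O", "O", "N"], dtype=object),
        np.array(["P", "O13", "O14", "N"], dtype=object),
        np.array(["M"] * 4, dtype=object),
        np.array([801] * 4),
        np.array(["POPC"] * 4, dtype=object),
    )


class TestInteractionTyping:
    def test_cation_to_carboxylate_is_salt_bridge(self):
        # ligand N+ 2.82 Å from a carboxylate oxygen
        lig = Pose("lig", np.array([[1.3, 0.6, 2.82]]),
                   np.array(["N"], dtype=object), np.array([1]))
        out = annotate_interactions(PoseSet(aspartate_fragment(), [lig]))
        row = out[out["type"] == "salt-bridge"].iloc[0]
        assert row["residue"] == "D569:A"
        assert row["distance"] == pytest.approx(2.82, abs=1e-6)

    def test_neutral_donor_to_phosphate_is_hbond(self):
        lig = Pose("lig", np.array([[1.5, 0, 3.1]]),
                   np.array(["N"], dtype=object), np.array([0]))
        out = annotate_interactions(PoseSet(popc_headgroup(), [lig]))
        row = out[out["type"] == "H-bond"].iloc[0]
        assert row["residue"] == "POPC801:M"
        assert row["distance"] == pytest.approx(3.1, abs=1e-6)

    def test_distant_apolar_pair_not_recorded(self):
        rec = one_atom_receptor([[0, 0, 0]])
        lig = carbon_pose("lig", [[0, 0, 6.0]])
        assert annotate_interactions(PoseSet(rec, [lig])).empty


class TestZones:
    ZONES = {"bottom": (-10.0, -3.0), "middle": (-3.0, 3.0), "top": (3.0, 10.0)}

    @pytest.mark.parametrize(
        "point,label",
        [([0, 0, 0], "middle"), ([1, 1, -5], "bottom"), ([0, 0, 8], "top"),
         ([0, 0, 15], "outside")],
    )
    def test_axial_lookup(self, point, label):
        assert assign_zone(point, self.ZONES) == label

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            assign_zone([0, 0, 0], {"a": (0.0, 5.0), "b": (4.0, 9.0)})
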