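"""Pore-radius profiling of a channel structure along an axis.

At each plane normal to the channel axis the profiler reports the radius of
the largest probe sphere that fits: the maximised value of

    f(c) = min over atoms i of ( |c - x_i| - vdW_i )

over probe centres ``c`` in the plane, where ``vdW_i`` is the van der Waals
radius of atom *i*.  This is the classic sphere-fitting pore analysis of
channel biophysics; the maximiser here is a seeded, restarted Nelder–Mead
search bounded to a cylinder around the axis, warm-started from the
previous plane's centre.  The narrowest constriction is reported as a
minimum radius and diameter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

#: Bondi-style element van der Waals radii (Å); table-dependent results —
#: the reported pore diameter depends on the radii in use.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}
VDW_DEFAULT = 1.70

MAX_RADIUS = 15.0  # Å, cap + search-cylinder bound
N_RESTARTS = 8


@dataclass
class PoreProfile:
    z: np.ndarray  # axial grid (Å)
    radius: np.ndarray  # pore radius per plane (Å)
    centers: np.ndarray  # (n, 3) probe centres in lab coordinates
    capped: np.ndarray  # bool flag: no atoms near the plane, radius capped
    min_radius: float = field(init=False)
    min_diameter: float = field(init=False)
    z_at_min: float = field(init=False)

    def __post_init__(self):
        valid = ~self.capped
        sel = np.where(valid)[0] if valid.any() else np.arange(len(self.z))
        k = sel[np.argmin(self.radius[sel])]
        self.min_radius = float(self.radius[k])
        self.min_diameter = 2.0 * self.min_radius
        self.z_at_min = float(self.z[k])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "z": self.z, "radius": self.radius,
                "cx": self.centers[:, 0], "cy": self.centers[:, 1],
                "cz": self.centers[:, 2], "capped": self.capped,
            }
        )


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(a, helper)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    return u, v


def profile_pore(
    coords: np.ndarray,
    elements,
    axis=(0.0, 0.0, 1.0),
    anchor=(0.0, 0.0, 0.0),
    z_range: tuple[float, float] | None = None,
    step: float = 0.5,
    seed: int = 0,
    vdw_table: dict[str, float] | None = None,
    max_radius: float = MAX_RADIUS,
    n_restarts: int = N_RESTARTS,
) -> PoreProfile:
    """Radius-vs-axial-coordinate profile of a channel structure.

    ``coords``/``elements`` are the heavy atoms of the structure; ``axis``
    (unit vector) and ``anchor`` define the channel axis, ``z_range`` the
    axial span (default: the structure's own span along the axis).  Planes
    with no atoms inside the search cylinder are reported at ``max_radius``
    and flagged.  Fully reproducible for a fixed ``seed``.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if coords.shape[0] == 0:
        raise ValueError("structure has no atoms")
    table = dict(VDW_RADII if vdw_table is None else vdw_table)
    radii = np.array([table.get(str(e), VDW_DEFAULT) for e in elements], dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    anchor = np.asarray(anchor, dtype=float)
    u, v = _orthonormal_frame(axis)

    zproj = (coords - anchor) @ axis
    if z_range is None:
        z_range = (float(zproj.min()), float(zproj.max()))
    zgrid = np.arange(z_range[0], z_range[1] + 0.5 * step, step)

    rng = np.random.default_rng(seed)
    out_r = np.empty(len(zgrid))
    out_c = np.empty((len(zgrid), 3))
    out_flag = np.zeros(len(zgrid), dtype=bool)
    prev_xy = np.zeros(2)

    for k, z in enumerate(zgrid):
        plane_origin = anchor + z * axis
        # atoms that could limit a probe of radius <= max_radius at this plane
        dz = zproj - z
        near = np.abs(dz) <= (max_radius + radii + 2.0)
        if not near.any():
            out_r[k] = max_radius
            out_c[k] = plane_origin + prev_xy[0] * u + prev_xy[1] * v
            out_flag[k] = True
            continue
        acoords = coords[near]
        aradii = radii[near]

        def objective(xy):
            if np.hypot(xy[0], xy[1]) > max_radius:
                return 1e6 + np.hypot(xy[0], xy[1])
            c = plane_origin + xy[0] * u + xy[1] * v
            return -(np.linalg.norm(acoords - c, axis=1) - aradii).min()

        starts = [prev_xy] + [
            prev_xy + rng.normal(scale=1.5, size=2) for _ in range(n_restarts)
        ]
        results = []
        for s in starts:
            res = minimize(
                objective, s, method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
            )
            results.append(res)
        # keep the probe inside the pore: accept the best optimum reachable
        # from the previous centre without the path crossing a wall
        results.sort(key=lambda r: r.fun)
        best = None
        for res in results:
            seg = prev_xy + np.linspace(0, 1, 25)[:, None] * (res.x - prev_xy)
            if all(objective(p) <= 0.0 for p in seg):
                best = res
                break
        if best is None:  # previous centre sits in a blocked plane
            best = min(results, key=lambda r: np.linalg.norm(r.x - prev_xy))
        r = min(-best.fun, max_radius)
        prev_xy = best.x
        out_r[k] = max(r, 0.0)
        out_c[k] = plane_origin + best.x[0] * u + best.x[1] * v
        out_flag[k] = -best.fun >= max_radius

    return PoreProfile(zgrid, out_r, out_c, out_flag)


def profile_pore_receptor(receptor, **kw) -> PoreProfile:
    """Profile a :class:`~metscreen.contacts.Receptor` (heavy atoms)."""
    m = receptor.heavy_mask()
    return profile_pore(receptor.coords[m], receptor.elements[m], **kw)


def zone_boundaries_from_profile(
    p: PoreProfile,
    rel_width: float = 0.5,
    min_halfwidth: float = 2.0,
    min_relief: float = 0.5,
) -> dict[str, tuple[float, float]]:
    """Axial top/middle/bottom intervals from a pore profile.

    The middle site covers the central constriction: the contiguous region
    around the narrowest plane where the radius stays below
    ``r_min + rel_width·(r_max − r_min)``, at least ``min_halfwidth`` Å to
    each side (so a V-shaped constriction still yields a finite middle
    zone); the expanded flanks become the bottom (low z) and top (high z)
    sites.  A profile with less than ``min_relief`` Å of radius variation
    has no constriction: a single-zone fallback is returned with a warning.
    """
    z, r = p.z, p.radius
    rmin, rmax = float(r.min()), float(r.max())
    if rmax - rmin < min_relief:
        warnings.warn("profile has no constriction; single-zone fallback")
        return {"pore": (float(z.min()), float(z.max()))}
    cut = rmin + rel_width * (rmax - rmin)
    k = int(np.argmin(r))
    lo = k
    while lo > 0 and r[lo - 1] <= cut:
        lo -= 1
    hi = k
    while hi < len(r) - 1 and r[hi + 1] <= cut:
        hi += 1
    m_lo, m_hi = float(z[lo]), float(z[hi])
    if m_hi - m_lo < 2.0 * min_halfwidth:  # V-shaped: widen around the segment
        mid = 0.5 * (m_lo + m_hi)
        m_lo, m_hi = mid - min_halfwidth, mid + min_halfwidth
    m_lo = max(m_lo, float(z.min()))
    m_hi = min(m_hi, float(z.max()))
    zones = {}
    if m_lo > z.min():
        zones["bottom"] = (float(z.min()), m_lo)
    zones["middle"] = (m_lo, m_hi)
    if m_hi < z.max():
        zones["top"] = (m_hi, float(z.max()))
    return zones
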