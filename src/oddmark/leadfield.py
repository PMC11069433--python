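"""Analytic spherical-head EEG forward model.

Current-dipole potentials in a homogeneous conducting sphere, evaluated from
the Legendre-series solution of the Neumann boundary problem (no current
leaves the scalp).  Exact to machine precision for sources away from the
surface; used both to build voxel-grid leadfields for the inverse solution
and to forward-simulate single sources in tests.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .montage import SensorMontage

__all__ = ["Leadfield", "spherical_leadfield", "dipole_potential"]

logger = logging.getLogger(__name__)


@dataclass
class Leadfield:
    """Forward gain: voxels x orientations x channels.

    ``gain`` maps a dipole moment of 1 nA*m along each orientation to
    electrode potentials in microvolts.  ``orientations`` holds the unit
    moment vectors (radial for fixed mode; x/y/z for free mode).
    """

    gain: np.ndarray
    voxel_positions: np.ndarray  # (n_voxels, 3) in mm, head-centered
    orientations: np.ndarray  # (n_voxels, n_orientations, 3)
    head_radius_mm: float
    orientation_mode: str  # "fixed" or "free"
    conductivity_s_m: float = 0.33

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("leadfield gain must be finite")
        r = np.linalg.norm(self.voxel_positions, axis=1)
        if np.any(r >= self.head_radius_mm):
            raise ValueError("voxels must lie strictly inside the sphere")

    @property
    def n_voxels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_orientations(self) -> int:
        return self.gain.shape[1]

    @property
    def n_channels(self) -> int:
        return self.gain.shape[2]

    def hemisphere_labels(self, midline_mm: float = 1.0) -> np.ndarray:
        """'left' / 'right' / 'both' per voxel by the sign of x."""
        x = self.voxel_positions[:, 0]
        out = np.where(x < 0, "left", "right").astype(object)
        out[np.abs(x) < midline_mm] = "both"
        return out


def _series_terms(cosg: np.ndarray, b_over_R: np.ndarray, n_terms: int):
    """Yield (n, P_n(c), P_n^1(c), (b/R)^(n-1)) using stable recurrences.

    P_n^1 follows the Condon-Shortley convention (P_1^1 = -sqrt(1-c^2)).
    """
    sing = np.sqrt(np.clip(1.0 - cosg ** 2, 0.0, None))
    P_prev = np.ones_like(cosg)  # P_0
    P = cosg.copy()  # P_1
    Q_prev = np.zeros_like(cosg)  # P_0^1
    Q = -sing  # P_1^1
    pw = np.ones_like(b_over_R)  # (b/R)^0
    for n in range(1, n_terms + 1):
        yield n, P, Q, pw
        # advance to n+1
        P_next = ((2 * n + 1) * cosg * P - n * P_prev) / (n + 1)
        Q_next = ((2 * n + 1) * cosg * Q - (n + 1) * Q_prev) / n
        P_prev, P = P, P_next
        Q_prev, Q = Q, Q_next
        pw = pw * b_over_R


def dipole_potential(electrode_pos: np.ndarray, dipole_pos: np.ndarray,
                     moment: np.ndarray, radius: float,
                     conductivity: float = 0.33, n_terms: int = 200
                     ) -> np.ndarray:
    """Surface potential (volts) of one dipole in a homogeneous sphere.

    ``electrode_pos`` (n_elec, 3) on the sphere surface, ``dipole_pos`` (3,)
    strictly inside, ``moment`` (3,) in A*m; all positions in meters.
    """
    e = np.asarray(electrode_pos, float)
    r0 = np.asarray(dipole_pos, float)
    q = np.asarray(moment, float)
    R = float(radius)
    b = float(np.linalg.norm(r0))
    if b >= R:
        raise ValueError("dipole must lie strictly inside the sphere")
    eh = e / np.linalg.norm(e, axis=1, keepdims=True)
    if b < 1e-12 * R:
        # only the n=1 term survives: uniform-field solution
        return 3.0 * (eh @ q) / (4.0 * np.pi * conductivity * R ** 2)
    r0h = r0 / b
    cosg = np.clip(eh @ r0h, -1.0, 1.0)
    sing = np.sqrt(np.clip(1.0 - cosg ** 2, 0.0, None))
    q_r = float(q @ r0h)
    # tangential moment component along the great circle toward each electrode
    t_vec = eh - cosg[:, None] * r0h
    t_norm = np.linalg.norm(t_vec, axis=1)
    safe = t_norm > 1e-12
    q_t = np.zeros(len(e))
    q_t[safe] = (t_vec[safe] @ q) / t_norm[safe]
    total = np.zeros(len(e))
    bR = np.full(len(e), b / R)
    # b^(n-1)/R^(n+1) = (b/R)^(n-1) / R^2, with (b/R)^(n-1) tracked as pw
    for n, P, Q, pw in _series_terms(cosg, bR, n_terms):
        total += ((2 * n + 1) / n) * pw * (n * q_r * P - q_t * Q)
    return total / (4.0 * np.pi * conductivity * R ** 2)


def _potential_many(eh: np.ndarray, voxels: np.ndarray, moments: np.ndarray,
                    R: float, sigma: float, n_terms: int) -> np.ndarray:
    """Series evaluation vectorized over voxels and electrodes.

    eh: (E, 3) unit electrode directions; voxels: (V, 3) positions; moments:
    (V, 3) unit moments.  Returns (V, E) potentials for 1 A*m moments.
    """
    b = np.linalg.norm(voxels, axis=1)
    out = np.zeros((len(voxels), len(eh)))
    central = b < 1e-12 * R
    if central.any():
        out[central] = 3.0 * (moments[central] @ eh.T) / (4 * np.pi * sigma * R ** 2)
    idx = np.flatnonzero(~central)
    if len(idx) == 0:
        return out
    vox = voxels[idx]
    mom = moments[idx]
    bv = b[idx]
    r0h = vox / bv[:, None]
    cosg = np.clip(r0h @ eh.T, -1.0, 1.0)  # (V, E)
    q_r = np.einsum("vi,vi->v", mom, r0h)  # (V,)
    t_vec = eh[None, :, :] - cosg[:, :, None] * r0h[:, None, :]  # (V, E, 3)
    t_norm = np.linalg.norm(t_vec, axis=2)
    q_t = np.einsum("vei,vi->ve", t_vec, mom)
    with np.errstate(invalid="ignore", divide="ignore"):
        q_t = np.where(t_norm > 1e-12, q_t / t_norm, 0.0)
    bR = (bv / R)[:, None] * np.ones((1, eh.shape[0]))
    total = np.zeros_like(cosg)
    for n, P, Q, pw in _series_terms(cosg, bR, n_terms):
        total += ((2 * n + 1) / n) * pw * (n * q_r[:, None] * P - q_t * Q)
    out[idx] = total / (4.0 * np.pi * sigma * R ** 2)
    return out


def spherical_leadfield(montage: SensorMontage, grid_spacing_mm: float = 5.0,
                        orientation_mode: str = "fixed",
                        head_radius_mm: float = 85.0,
                        conductivity_s_m: float = 0.33,
                        max_radius_fraction: float = 0.9,
                        n_terms: int | None = None) -> Leadfield:
    """Leadfield on a cubic source grid inside a homogeneous sphere.

    Electrodes are the montage positions scaled to the head radius.  Voxels
    on or outside ``max_radius_fraction`` of the radius are excluded (the
    series converges slowly near the surface); gains are in microvolts per
    nA*m of dipole moment.
    """
    if orientation_mode not in ("fixed", "free"):
        raise ValueError("orientation_mode must be 'fixed' or 'free'")
    R = head_radius_mm
    half = int(np.floor(R / grid_spacing_mm))
    axis = float(grid_spacing_mm) * np.arange(-half, half + 1, dtype=float)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    r = np.linalg.norm(grid, axis=1)
    inside = r < max_radius_fraction * R
    n_excluded = int((r < R).sum() - inside.sum())
    if n_excluded:
        logger.warning("excluded %d voxels on or near the sphere surface "
                       "(beyond %.0f%% of the radius)", n_excluded,
                       100 * max_radius_fraction)
    voxels = grid[inside]
    if n_terms is None:
        frac = max(max_radius_fraction, 1e-3)
        n_terms = int(min(400, max(60, np.ceil(np.log(1e-12) / np.log(frac)))))
    eh = montage.positions  # unit sphere
    sigma = conductivity_s_m
    R_m = R / 1000.0
    vox_m = voxels / 1000.0
    if orientation_mode == "fixed":
        rn = np.linalg.norm(voxels, axis=1)
        ori = np.zeros_like(voxels)
        nz = rn > 0
        ori[nz] = voxels[nz] / rn[nz, None]
        gains = _potential_many(eh, vox_m, ori, R_m, sigma, n_terms)[:, None, :]
        orientations = ori[:, None, :]
    else:
        gain_list = []
        ori_list = []
        for ax in np.eye(3):
            mom = np.tile(ax, (len(voxels), 1))
            gain_list.append(_potential_many(eh, vox_m, mom, R_m, sigma, n_terms))
            ori_list.append(mom)
        gains = np.stack(gain_list, axis=1)
        orientations = np.stack(ori_list, axis=1)
    # volts per A*m -> microvolts per nA*m: 1e6 uV/V * 1e-9 A*m = 1e-3
    gains = gains * 1e-3
    return Leadfield(gain=gains, voxel_positions=voxels,
                     orientations=orientations, head_radius_mm=R,
                     orientation_mode=orientation_mode,
                     conductivity_s_m=conductivity_s_m)
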