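"""TMS-induced E-field of a figure-of-eight coil in a spherical conductor.

The coil is approximated by two mirrored clusters of magnetic dipoles (one
per wing, opposite winding sense).  The primary field is the magnetostatic
vector-potential rate of change,

    E_p(r) = -(mu0 / 4 pi) * dI/dt * sum_k  m_k x (r - r_k) / |r - r_k|^3 ,

with m_k the dipole moments per unit coil current.  Inside a spherically
symmetric conductor the charge-redistribution (secondary) field is the
gradient of the interior harmonic function phi solving the Neumann problem
d(phi)/dr = E_p . r_hat on the scalp sphere; phi is expanded in spherical
harmonics up to order ``L`` (default 60) and the total field E = E_p -
grad(phi) is purely tangential with respect to the head center.  No
conductivity value enters the solution.

Units: positions mm, dI/dt A/s, fields mV/mm (identical to V/m).  The
device convention 1 %MSO == 1.49 A/us of coil-current rate of change is
used throughout; field maps are computed at 1 %MSO and scaled linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import sph_harm_y_all

from .headmodel import CoilPlacement, CorticalSurface, HeadModel, build_head, nearest_vertex, place_coil

__all__ = [
    "CoilModel",
    "EFieldMap",
    "RoiStats",
    "build_figure8_coil",
    "default_coil",
    "primary_field",
    "total_field",
    "field_map",
    "decompose",
    "roi_stats",
    "nearest_rank_percentile",
    "angle_sweep",
    "scale_to_intensity",
    "match_efield_intensity",
    "export_field_map_ply",
    "export_field_map_csv",
    "DIDT_PER_PCT_MSO",
    "DEFAULT_ANGLES",
    "REFERENCE_ROI_MEAN",
]

MU0_4PI = 1e-7            # T m / A
DIDT_PER_PCT_MSO = 1.49e6  # A/s per %MSO (MagPro-class device convention)
DEFAULT_ANGLES = tuple(range(0, 180, 15))

#: the coil calibration anchors the reference head's M1 ROI mean at the
#: 45-degree placement to this value (mV/mm per %MSO)
REFERENCE_ROI_MEAN = 2.0


@dataclass(frozen=True)
class CoilModel:
    """Dipole-cluster figure-of-eight coil (coil frame: z = plane normal,
    x = wing-separation axis)."""

    positions_mm: np.ndarray     # (n, 3) coil frame
    moments: np.ndarray          # (n, 3) A m^2 per A of coil current
    calibration_constant: float  # dimensionless field scale


@dataclass
class EFieldMap:
    """Per-vertex field vectors and surface decomposition at a given drive."""

    vectors: np.ndarray   # (n, 3) mV/mm
    e_total: np.ndarray   # |E|
    e_t: np.ndarray       # tangential magnitude
    e_perp: np.ndarray    # signed normal component
    pct_mso: float


@dataclass(frozen=True)
class RoiStats:
    roi_center_index: int
    roi_radius_mm: float
    n_vertices: int
    mean_e_total: float
    mean_e_t: float
    mean_e_perp: float
    robust_max_e_total: float


def build_figure8_coil(wing_radius_mm: float = 27.0, wing_separation_mm: float = 40.0,
                       dipoles_per_wing: int = 8, rings_per_wing: int = 4,
                       calibration_constant: float = 1.0) -> CoilModel:
    """Dipole-cluster figure-of-eight coil.

    A flat current loop is magnetically identical to a uniformly
    magnetized disc (its magnetization currents reduce to the boundary
    loop), so each wing is tiled by ``rings_per_wing`` equal-area
    concentric circles carrying ``dipoles_per_wing`` dipoles each, with
    total moment equal to the loop area per unit current.  The two wings
    are mirrored with opposite winding sense, which makes the summed
    moment vanish and the cluster antisymmetric under a 180-degree
    in-plane rotation.
    """
    if wing_radius_mm <= 0 or wing_separation_mm <= 0:
        raise ValueError("coil geometry parameters must be positive")
    if dipoles_per_wing < 1 or rings_per_wing < 1:
        raise ValueError("dipole counts must be >= 1")
    area_m2 = np.pi * (wing_radius_mm * 1e-3) ** 2
    n = dipoles_per_wing * rings_per_wing
    radii = wing_radius_mm * np.sqrt((np.arange(rings_per_wing) + 0.5) / rings_per_wing)
    pos, mom = [], []
    for side in (+1.0, -1.0):
        cx = side * wing_separation_mm / 2.0
        for i, rr in enumerate(radii):
            ang = 2 * np.pi * (np.arange(dipoles_per_wing) + 0.5 * (i % 2)) / dipoles_per_wing
            for a in ang:
                pos.append([cx + rr * np.cos(a), rr * np.sin(a), 0.0])
                mom.append([0.0, 0.0, side * area_m2 / n])
    return CoilModel(
        positions_mm=np.asarray(pos),
        moments=np.asarray(mom),
        calibration_constant=float(calibration_constant),
    )


def _coil_frame(placement: CoilPlacement) -> np.ndarray:
    """Rows: coil-frame axes in head coordinates."""
    z = placement.normal
    x = np.cross(z, placement.handle_direction)  # wing-separation axis
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return np.stack([x, y, z])


def _world_dipoles(coil: CoilModel, placement: CoilPlacement) -> tuple[np.ndarray, np.ndarray]:
    R = _coil_frame(placement)
    pos = placement.center + coil.positions_mm @ R
    mom = coil.moments @ R
    return pos, mom


def primary_field(coil: CoilModel, placement: CoilPlacement, dIdt: float,
                  points_mm: np.ndarray) -> np.ndarray:
    """Primary (magnetic vector potential) E-field, in mV/mm, at the points."""
    pts = np.atleast_2d(np.asarray(points_mm, float)) * 1e-3
    pos, mom = _world_dipoles(coil, placement)
    pos = pos * 1e-3
    d = pts[:, None, :] - pos[None, :, :]          # (p, k, 3)
    r3 = np.linalg.norm(d, axis=2) ** 3
    if np.any(r3 < 1e-27):
        raise ValueError("evaluation point coincides with a coil dipole")
    cross = np.cross(np.broadcast_to(mom, d.shape), d)
    E = -MU0_4PI * dIdt * np.sum(cross / r3[:, :, None], axis=1)
    return E * coil.calibration_constant


# ---------------------------------------------------------------------------
# secondary field: interior Neumann problem on the scalp sphere
# ---------------------------------------------------------------------------

DEFAULT_L = 60


def _legendre_norm_all(L: int, x: np.ndarray) -> np.ndarray:
    """Orthonormalized associated Legendre P~_l^m(x) for 0 <= m <= l <= L,
    including the Condon-Shortley phase, so that
    Y_l^m = P~_l^m(cos(theta)) * exp(i m phi).

    Stable three-term recurrence (Holmes & Featherstone style); returns an
    array of shape (L+1, L+1, len(x)) indexed [l, m].
    """
    x = np.asarray(x, float)
    s = np.sqrt(np.maximum(0.0, 1.0 - x * x))
    P = np.zeros((L + 1, L + 1, x.size))
    P[0, 0] = 1.0 / np.sqrt(4.0 * np.pi)
    for m in range(L):
        P[m + 1, m + 1] = -np.sqrt((2 * m + 3) / (2.0 * m + 2)) * s * P[m, m]
        P[m + 1, m] = np.sqrt(2 * m + 3.0) * x * P[m, m]
    for m in range(L + 1):
        for l in range(m + 2, L + 1):
            a = np.sqrt((4.0 * l * l - 1.0) / (l * l - m * m))
            b = np.sqrt(((2.0 * l + 1.0) * ((l - 1.0) ** 2 - m * m)) / ((2.0 * l - 3.0) * (l * l - m * m)))
            P[l, m] = a * x * P[l - 1, m] - b * P[l - 2, m]
    return P


@lru_cache(maxsize=4)
def _quadrature(L: int):
    """Gauss-Legendre nodes/weights in cos(theta) plus uniform azimuths and
    the precomputed Legendre basis at the nodes (exact through degree 2L+1
    for the theta integral)."""
    ntheta, nphi = L + 1, 2 * L + 2
    x, w = np.polynomial.legendre.leggauss(ntheta)
    theta = np.arccos(x)
    phi = 2 * np.pi * np.arange(nphi) / nphi
    P = _legendre_norm_all(L, x)  # (L+1, L+1, ntheta)
    return theta, phi, w, P


def _sph_angles(pts: np.ndarray):
    r = np.linalg.norm(pts, axis=1)
    theta = np.arccos(np.clip(pts[:, 2] / np.where(r > 0, r, 1.0), -1, 1))
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    return r, theta, phi


def _neumann_coefficients(coil: CoilModel, placement: CoilPlacement, dIdt: float,
                          scalp_radius_mm: float, L: int) -> np.ndarray:
    """Coefficients b_lm with phi(r) = sum b_lm (r/R)^l Y_lm, from the
    boundary condition d(phi)/dr|_R = E_p . r_hat.

    Projection is FFT in azimuth plus Gauss-Legendre summation in
    colatitude, using the cached Legendre basis (cost O(L^2) per node set
    rather than a dense Y evaluation on the grid).
    """
    theta, phi, w, P = _quadrature(L)
    nphi = phi.size
    th, ph = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)], axis=-1)
    Ep = primary_field(coil, placement, dIdt, scalp_radius_mm * dirs.reshape(-1, 3))
    g = np.einsum("ij,ij->i", Ep, dirs.reshape(-1, 3)).reshape(th.shape)
    # azimuthal transform: gm[i, m] = sum_j g[i, j] exp(-i m phi_j) * 2 pi / nphi
    gm = np.fft.fft(g, axis=1) * (2.0 * np.pi / nphi)
    blm = np.zeros((L + 1, 2 * L + 1), dtype=complex)
    ls = np.arange(L + 1, dtype=float)
    for m in range(-L, L + 1):
        col = gm[:, m % nphi]
        # conj(Y)_l^m integrand; P~ carries |m|, with Y_l^{-m} = (-1)^m conj(Y_l^m)
        Pm = P[:, abs(m)] * ((-1) ** m if m < 0 else 1)
        glm = Pm @ (w * col)
        with np.errstate(divide="ignore", invalid="ignore"):
            blm[:, m] = np.where(ls > 0, scalp_radius_mm / np.maximum(ls, 1), 0.0) * glm
    return blm


def _phi_eval(blm: np.ndarray, scalp_radius_mm: float, pts: np.ndarray,
              chunk: int = 20000) -> np.ndarray:
    """Evaluate the interior harmonic potential at interior points (mm).
    Used by the finite-difference cross-check of the spectral gradient."""
    L = blm.shape[0] - 1
    out = np.empty(len(pts))
    ls = np.arange(L + 1)
    for a in range(0, len(pts), chunk):
        p = pts[a:a + chunk]
        r, th, ph = _sph_angles(p)
        Y = sph_harm_y_all(L, L, th, ph)
        radial = (r[None, :] / scalp_radius_mm) ** ls[:, None]
        out[a:a + chunk] = np.einsum("lmp,lm,lp->p", Y, blm, radial).real
    return out


def _shift_m(c: np.ndarray, shift: int) -> np.ndarray:
    """Return d with d[l, m] = c[l, m - shift] (zero where out of range)."""
    L = c.shape[0] - 1
    d = np.zeros_like(c)
    for m in range(-L, L + 1):
        src = m - shift
        if -L <= src <= L:
            d[:, m] = c[:, src]
    return d


def _grad_phi(blm: np.ndarray, scalp_radius_mm: float, pts: np.ndarray,
              chunk: int = 20000) -> np.ndarray:
    """Cartesian gradient of the interior potential via pole-safe spectral
    identities (one spherical-harmonic evaluation per chunk).

    Uses
      d(Y_lm)/d(theta) = 1/2 [ A_lm e^{-i phi} Y_l^{m+1} - B_lm e^{i phi} Y_l^{m-1} ]
      m/sin(theta) Y_lm = -1/2 sqrt((2l+1)/(2l-1)) [ C_lm e^{i phi} Y_{l-1}^{m-1}
                                                   + D_lm e^{-i phi} Y_{l-1}^{m+1} ]
    with A=sqrt((l-m)(l+m+1)), B=sqrt((l+m)(l-m+1)), C=sqrt((l+m)(l+m-1)),
    D=sqrt((l-m)(l-m-1)); both are regular at the poles.
    """
    L = blm.shape[0] - 1
    R = scalp_radius_mm
    ls = np.arange(L + 1, dtype=float)[:, None]
    ms = np.concatenate([np.arange(0, L + 1), np.arange(-L, 0)]).astype(float)[None, :]
    valid = np.abs(ms) <= ls

    A = np.where(valid, np.sqrt(np.maximum((ls - ms) * (ls + ms + 1), 0.0)), 0.0)
    B = np.where(valid, np.sqrt(np.maximum((ls + ms) * (ls - ms + 1), 0.0)), 0.0)
    C = np.where(valid, np.sqrt(np.maximum((ls + ms) * (ls + ms - 1), 0.0)), 0.0)
    D = np.where(valid, np.sqrt(np.maximum((ls - ms) * (ls - ms - 1), 0.0)), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lower = np.where(ls > 0, np.sqrt((2 * ls + 1) / np.maximum(2 * ls - 1, 1)), 0.0)

    # radial derivative: coefficients l * blm / R on (r/R)^(l-1) Y_lm
    c_r = blm * ls / R
    # theta: same-degree sums with azimuth phase e^{-+ i phi} factored out
    c_th_plus = _shift_m(blm * A, +1) * 0.5          # pairs with e^{-i phi} Y_l^{m'}
    c_th_minus = _shift_m(blm * B, -1) * (-0.5)      # pairs with e^{+i phi} Y_l^{m'}
    # phi: degree-lowered sums; push l -> l-1 by rolling the degree axis
    t1 = np.roll(_shift_m(blm * C * lower, -1), -1, axis=0) * (-0.5)
    t2 = np.roll(_shift_m(blm * D * lower, +1), -1, axis=0) * (-0.5)
    t1[-1] = 0.0
    t2[-1] = 0.0

    out = np.empty((len(pts), 3))
    for a in range(0, len(pts), chunk):
        p = pts[a:a + chunk]
        r, th, ph = _sph_angles(p)
        Y = sph_harm_y_all(L, L, th, ph)                    # (L+1, 2L+1, n)
        rad_lo = (r[None, :] / R) ** np.maximum(ls - 1, 0)  # (r/R)^(l-1); l=0 unused
        rad_lo[0] = 0.0
        rad = (r[None, :] / R) ** ls                        # (r/R)^l
        eip = np.exp(1j * ph)

        dphi_dr = np.einsum("lmp,lm,lp->p", Y, c_r, rad_lo).real
        # 1/r d(phi)/d(theta): radial factor (r/R)^l / r = rad_lo / R
        dphi_th = (np.einsum("lmp,lm,lp->p", Y, c_th_plus, rad_lo) * np.conj(eip)
                   + np.einsum("lmp,lm,lp->p", Y, c_th_minus, rad_lo) * eip).real / R
        # 1/(r sin th) d(phi)/d(phi): the identity lowers the degree, so the
        # surviving radial factor against Y_lambda is (r/R)^lambda / R
        dphi_ph = (1j * (np.einsum("lmp,lm,lp->p", Y, t1, rad) * eip
                         + np.einsum("lmp,lm,lp->p", Y, t2, rad) * np.conj(eip))).real / R

        st, ct = np.sin(th), np.cos(th)
        cp, sp = np.cos(ph), np.sin(ph)
        r_hat = np.stack([st * cp, st * sp, ct], axis=1)
        th_hat = np.stack([ct * cp, ct * sp, -st], axis=1)
        ph_hat = np.stack([-sp, cp, np.zeros_like(sp)], axis=1)
        out[a:a + chunk] = (dphi_dr[:, None] * r_hat
                            + dphi_th[:, None] * th_hat
                            + dphi_ph[:, None] * ph_hat)
    return out


def total_field(coil: CoilModel, placement: CoilPlacement, head: HeadModel,
                points_mm: np.ndarray, dIdt: float = DIDT_PER_PCT_MSO,
                L: int = DEFAULT_L) -> np.ndarray:
    """Total interior field E = E_p - grad(phi), in mV/mm, at the points.

    Exactly linear in ``dIdt``; independent of any conductivity value.
    """
    if L < 1:
        raise ValueError("expansion order L must be >= 1")
    pts = np.atleast_2d(np.asarray(points_mm, float))
    R = head.scalp_radius_mm
    if np.any(np.linalg.norm(pts, axis=1) >= R):
        raise ValueError("evaluation points must lie strictly inside the scalp sphere")
    # solve at unit drive and scale once, so linearity in dIdt holds to the
    # last bit for power-of-two factors and to 1 ulp otherwise
    blm = _neumann_coefficients(coil, placement, 1.0, R, L)
    E_unit = primary_field(coil, placement, 1.0, pts) - _grad_phi(blm, R, pts)
    return E_unit * dIdt


def decompose(E: np.ndarray, normals: np.ndarray):
    """Split field vectors into (E_total, E_T, E_perp) w.r.t. unit normals."""
    normals = np.atleast_2d(np.asarray(normals, float))
    if np.any(np.abs(np.linalg.norm(normals, axis=1) - 1.0) > 1e-6):
        raise ValueError("surface normals must be unit length (within 1e-6)")
    E = np.atleast_2d(np.asarray(E, float))
    e_perp = np.einsum("ij,ij->i", E, normals)
    tang = E - e_perp[:, None] * normals
    return np.linalg.norm(E, axis=1), np.linalg.norm(tang, axis=1), e_perp


def field_map(coil: CoilModel, placement: CoilPlacement, head: HeadModel,
              surface: CorticalSurface, pct_mso: float = 1.0, L: int = DEFAULT_L,
              vertex_indices: np.ndarray | None = None) -> EFieldMap:
    """Field map over (a subset of) the cortical surface at ``pct_mso``."""
    idx = np.arange(surface.n_vertices) if vertex_indices is None else np.asarray(vertex_indices)
    E = total_field(coil, placement, head, surface.vertices[idx],
                    dIdt=DIDT_PER_PCT_MSO * pct_mso, L=L)
    et, etan, eperp = decompose(E, surface.outward_normals[idx])
    return EFieldMap(vectors=E, e_total=et, e_t=etan, e_perp=eperp, pct_mso=float(pct_mso))


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q/100 * n)-th order statistic."""
    v = np.sort(np.asarray(values))
    if v.size == 0:
        raise ValueError("empty sample")
    # tiny slack so e.g. ceil(0.999 * 1000) is 999, not 1000, despite
    # floating-point representation of q/100
    k = max(1, int(np.ceil(q / 100.0 * v.size - 1e-9)))
    return float(v[min(k, v.size) - 1])


def roi_members(surface: CorticalSurface, roi_center_index: int, radius_mm: float) -> np.ndarray:
    center = surface.vertices[roi_center_index]
    return np.flatnonzero(np.linalg.norm(surface.vertices - center, axis=1) <= radius_mm)


def roi_stats(efmap: EFieldMap, surface: CorticalSurface, roi_center_index: int,
              radius_mm: float = 10.0, percentile: float = 99.9,
              vertex_indices: np.ndarray | None = None) -> RoiStats:
    """ROI summary: mean of each component plus the robust maximum of E_total.

    ``vertex_indices`` maps rows of ``efmap`` to surface vertices when the
    map was evaluated on a subset; by default the map covers all vertices.
    """
    if radius_mm <= 0:
        raise ValueError("ROI radius must be > 0")
    rows = np.arange(surface.n_vertices) if vertex_indices is None else np.asarray(vertex_indices)
    member = roi_members(surface, roi_center_index, radius_mm)
    sel = np.flatnonzero(np.isin(rows, member))
    if sel.size == 0:
        raise ValueError("empty ROI: no evaluated vertex within radius")
    return RoiStats(
        roi_center_index=int(roi_center_index),
        roi_radius_mm=float(radius_mm),
        n_vertices=int(sel.size),
        mean_e_total=float(efmap.e_total[sel].mean()),
        mean_e_t=float(efmap.e_t[sel].mean()),
        mean_e_perp=float(efmap.e_perp[sel].mean()),
        robust_max_e_total=nearest_rank_percentile(efmap.e_total[sel], percentile),
    )


def angle_sweep(coil: CoilModel, head: HeadModel, region: str, target: np.ndarray,
                angles=DEFAULT_ANGLES, roi_radius_mm: float = 10.0,
                percentile: float = 99.9, L: int = DEFAULT_L) -> tuple[pd.DataFrame, float]:
    """Sweep the coil rotation angle; report ROI stats per angle and the
    angle with the strongest ROI-mean E_total.

    The ROI center (cortical vertex nearest the coil center) is fixed
    across angles because rotation does not move the coil center.
    """
    surface = head.surfaces[region]
    rows = []
    placement0 = place_coil(head, target, 0.0)
    roi_center = nearest_vertex(surface, placement0.center)
    members = roi_members(surface, roi_center, roi_radius_mm)
    for a in angles:
        placement = place_coil(head, target, a)
        em = field_map(coil, placement, head, surface, pct_mso=1.0, L=L,
                       vertex_indices=members)
        st = roi_stats(em, surface, roi_center, roi_radius_mm, percentile,
                       vertex_indices=members)
        rows.append({
            "angle_deg": float(a),
            "mean_e_total": st.mean_e_total,
            "mean_e_t": st.mean_e_t,
            "mean_e_perp": st.mean_e_perp,
            "robust_max": st.robust_max_e_total,
            "n_roi_vertices": st.n_vertices,
        })
    df = pd.DataFrame(rows)
    optimal = float(df.loc[df["mean_e_total"].idxmax(), "angle_deg"])
    return df, optimal


def scale_to_intensity(efmap: EFieldMap, pct_mso: float) -> EFieldMap:
    """Linearly scale a 1 %MSO field map to ``pct_mso`` (0 < pct <= 100)."""
    if not 0 < pct_mso <= 100:
        raise ValueError("intensity must be in (0, 100] %MSO")
    k = pct_mso / efmap.pct_mso
    return EFieldMap(
        vectors=efmap.vectors * k,
        e_total=efmap.e_total * k,
        e_t=efmap.e_t * k,
        e_perp=efmap.e_perp * k,
        pct_mso=float(pct_mso),
    )


def match_efield_intensity(roi_mean_at_1pct: float, target_mv_per_mm: float) -> float:
    """Real-valued %MSO that makes the ROI mean hit the target exactly."""
    if target_mv_per_mm <= 0:
        raise ValueError("target field strength must be > 0")
    if roi_mean_at_1pct <= 0:
        raise ValueError("ROI mean at 1 %MSO must be > 0")
    return target_mv_per_mm / roi_mean_at_1pct


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _default_calibration() -> float:
    """Field scale that puts the reference head's M1 ROI mean at the
    45-degree placement at REFERENCE_ROI_MEAN mV/mm per %MSO.

    The absolute output of the dipole model (single-turn winding, no
    anatomy) is arbitrary; this single constant anchors it so RMT-scaled
    doses land in a physiologically sensible range.
    """
    head = build_head()
    surface = head.surfaces["M1"]
    target = surface.vertices[nearest_vertex(surface, head.scalp_radius_mm * np.array([0.0, 0.0, 1.0]))]
    coil = build_figure8_coil(calibration_constant=1.0)
    placement = place_coil(head, target, 45.0)
    roi_center = nearest_vertex(surface, placement.center)
    members = roi_members(surface, roi_center, 10.0)
    em = field_map(coil, placement, head, surface, pct_mso=1.0, vertex_indices=members)
    st = roi_stats(em, surface, roi_center, 10.0, vertex_indices=members)
    return REFERENCE_ROI_MEAN / st.mean_e_total


def export_field_map_ply(efmap: EFieldMap, surface: CorticalSurface, path) -> None:
    """Write the surface with per-vertex e_total / e_t / e_perp properties
    (binary little-endian PLY)."""
    if len(efmap.e_total) != surface.n_vertices:
        raise ValueError("field map must cover every surface vertex for PLY export")
    mesh = surface.as_trimesh()
    mesh.vertex_attributes["e_total"] = efmap.e_total.astype(np.float32)
    mesh.vertex_attributes["e_t"] = efmap.e_t.astype(np.float32)
    mesh.vertex_attributes["e_perp"] = efmap.e_perp.astype(np.float32)
    with open(path, "wb") as fh:
        fh.write(mesh.export(file_type="ply", encoding="binary"))


def export_field_map_csv(efmap: EFieldMap, surface: CorticalSurface, path,
                         vertex_indices: np.ndarray | None = None) -> None:
    """Per-vertex table: id, position, field vector and decomposition."""
    idx = (np.arange(surface.n_vertices) if vertex_indices is None
           else np.asarray(vertex_indices))
    df = pd.DataFrame({
        "vertex_id": idx,
        "x_mm": surface.vertices[idx, 0],
        "y_mm": surface.vertices[idx, 1],
        "z_mm": surface.vertices[idx, 2],
        "ex_mv_mm": efmap.vectors[:, 0],
        "ey_mv_mm": efmap.vectors[:, 1],
        "ez_mv_mm": efmap.vectors[:, 2],
        "e_total": efmap.e_total,
        "e_t": efmap.e_t,
        "e_perp": efmap.e_perp,
    })
    df.to_csv(path, index=False, float_format="%.10g")


def default_coil(calibrated: bool = True, **kwargs) -> CoilModel:
    """The package's default figure-of-eight coil, optionally calibrated
    against the reference head (see ``_default_calibration``)."""
    coil = build_figure8_coil(**kwargs)
    if calibrated:
        return replace(coil, calibration_constant=coil.calibration_constant * _default_calibration())
    return coil
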