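"""Cell placement over the cortical ROI and activation-threshold maps.

One reduced pyramidal cell is placed rigidly at sampled surface vertices:
the soma sits 1.25 mm beneath the vertex along the inward normal, the
somato-dendritic axis is perpendicular to the local surface (apical
toward the pia), and the azimuthal orientation of the arbors about that
axis is randomized per placement.  For every placement the local E-field
at 1 %MSO is sampled at all compartment midpoints from the analytic
spherical-conductor solution, line-integrated into quasipotentials, and
the activation threshold is the smallest integer %MSO whose single pulse
evokes a time-locked somatic action potential (censored above 100 %MSO).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import efield as ef
from . import neuron as nr
from .headmodel import CorticalSurface, HeadModel

__all__ = [
    "CellPlacement",
    "ThresholdMap",
    "place_cells",
    "estimate_threshold",
    "estimate_synaptic_threshold",
    "threshold_map_for_participant",
    "weak_synapse_for",
    "SOMATIC_DEPTH_MM",
    "POPULATION_ROI_MM",
]

SOMATIC_DEPTH_MM = 1.25
POPULATION_ROI_MM = 15.0
#: synaptic events are scheduled this long before each pulse so the weak
#: input's conductance is active at pulse time
SYNAPSE_LEAD_MS = 2.0


@dataclass(frozen=True)
class CellPlacement:
    vertex_index: int
    vertex_mm: np.ndarray
    soma_mm: np.ndarray          # vertex - depth * outward normal
    axis: np.ndarray             # inward unit normal (somato-dendritic line)
    azimuth_rad: float
    depth_class: str

    def rotation(self) -> np.ndarray:
        """Map morphology frame (apical +z) to head frame: +z -> -axis
        (outward normal), then spin by the azimuth about that axis."""
        out = -self.axis
        # orthonormal frame around the outward normal
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, out)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - np.dot(ref, out) * out
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(out, e1)
        c, s = np.cos(self.azimuth_rad), np.sin(self.azimuth_rad)
        u1 = c * e1 + s * e2
        u2 = -s * e1 + c * e2
        return np.column_stack([u1, u2, out])


@dataclass
class ThresholdMap:
    """Per-placement integer activation thresholds with censoring flags."""

    placements: list
    threshold_pct_mso: np.ndarray   # int; meaningless where censored
    censored: np.ndarray            # bool
    with_synapse: bool
    region: str
    participant_id: str = ""

    @property
    def n(self) -> int:
        return len(self.censored)

    @property
    def fraction_censored(self) -> float:
        return float(np.mean(self.censored))

    def valid_thresholds(self) -> np.ndarray:
        return self.threshold_pct_mso[~self.censored]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.placements):
            rows.append({
                "participant": self.participant_id,
                "region": self.region,
                "cell_id": i,
                "x_mm": p.vertex_mm[0], "y_mm": p.vertex_mm[1], "z_mm": p.vertex_mm[2],
                "depth_class": p.depth_class,
                "with_synapse": self.with_synapse,
                "threshold_pct_mso": (int(self.threshold_pct_mso[i])
                                      if not self.censored[i] else ""),
                "censored": bool(self.censored[i]),
            })
        return pd.DataFrame(rows)


def place_cells(head: HeadModel, region: str, roi_center_index: int,
                radius_mm: float = POPULATION_ROI_MM, target_count: int = 150,
                seed: int = 0) -> list[CellPlacement]:
    """Sample ``target_count`` vertices within the population ROI by
    farthest-point subsampling (deterministic given the seed)."""
    surface = head.surfaces[region]
    center = surface.vertices[roi_center_index]
    cand = np.flatnonzero(np.linalg.norm(surface.vertices - center, axis=1) <= radius_mm)
    if target_count > cand.size:
        raise ValueError(
            f"requested {target_count} cells but only {cand.size} vertices lie "
            f"within {radius_mm} mm; use a finer surface mesh")
    rng = np.random.default_rng(seed)
    pts = surface.vertices[cand]
    chosen = [int(rng.integers(cand.size))]
    d = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    while len(chosen) < target_count:
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    placements = []
    for c in chosen:
        vi = int(cand[c])
        nrm = surface.outward_normals[vi]
        placements.append(CellPlacement(
            vertex_index=vi,
            vertex_mm=surface.vertices[vi].copy(),
            soma_mm=surface.vertices[vi] - SOMATIC_DEPTH_MM * nrm,
            axis=-nrm,
            azimuth_rad=float(rng.uniform(0.0, 2 * np.pi)),
            depth_class=str(surface.depth_class[vi]),
        ))
    return placements


def _placed_tree(tree: nr.CompartmentTree, placement: CellPlacement) -> nr.CompartmentTree:
    return tree.transformed(placement.rotation(), placement.soma_mm * 1e3)


def estimate_threshold(tree: nr.CompartmentTree, biophys: nr.BiophysSpec,
                       psi: nr.QuasiPotentialProfile, waveform: nr.PulseWaveform,
                       synapse: nr.SynapseSpec | None = None,
                       precision_pct: int = 1, max_pct: int = 100,
                       duration_ms: float = 12.0, pulse_onset_ms: float = 5.0,
                       **sim_kw) -> int | None:
    """Smallest integer %MSO evoking a time-locked AP; None if censored.

    Geometric bracketing followed by integer bisection under the monotone
    assumption; the returned bracket (s - 1 silent, s firing) is verified
    and a linear scan is used as fallback if it fails.
    """
    syn = synapse
    if syn is not None:
        syn = nr.SynapseSpec(
            tau1_ms=syn.tau1_ms, tau2_ms=syn.tau2_ms, weight_us=syn.weight_us,
            e_rev_mv=syn.e_rev_mv, attach_path_dist_um=syn.attach_path_dist_um,
            event_times_ms=(pulse_onset_ms - SYNAPSE_LEAD_MS,),
        )
    cache: dict[int, bool] = {}

    def fires(s):
        s = int(s)
        if s not in cache:
            try:
                tr = nr.simulate(tree, biophys, psi, waveform, float(s),
                                 synapse=syn, duration_ms=duration_ms,
                                 pulse_onsets_ms=(pulse_onset_ms,), **sim_kw)
                cache[s] = bool(tr.time_locked_flags.any())
            except nr.SolverDivergence:
                # a drive strong enough to blow past the voltage guard is
                # certainly suprathreshold
                cache[s] = True
        return cache[s]

    # geometric bracketing
    s = precision_pct
    hi = None
    while True:
        if fires(s):
            hi = s
            break
        if s >= max_pct:
            return None
        s = min(2 * s, max_pct)
    lo = hi // 2 if hi > precision_pct else 0
    while hi - lo > precision_pct:
        mid = (lo + hi) // 2
        if fires(mid):
            hi = mid
        else:
            lo = mid
    # verify the bracket; fall back to a linear scan on non-monotonicity
    if hi > precision_pct and fires(hi - precision_pct):
        warnings.warn("non-monotone activation around the bisection bracket; "
                      "falling back to linear scan")
        for s in range(precision_pct, max_pct + 1, precision_pct):
            if fires(s):
                return s
        return None
    return int(hi)


def estimate_synaptic_threshold(tree: nr.CompartmentTree, biophys: nr.BiophysSpec,
                                w_max_us: float = 2.0, rel_precision: float = 0.01,
                                duration_ms: float = 30.0,
                                event_ms: float = 5.0) -> float | None:
    """Minimum synaptic weight (uS) that makes the cell fire without TMS;
    None (censored) if even ``w_max_us`` stays subthreshold."""
    def fires(w):
        syn = nr.SynapseSpec(weight_us=float(w), event_times_ms=(event_ms,))
        tr = nr.simulate(tree, biophys, None, None, 0.0, synapse=syn,
                         duration_ms=duration_ms)
        return len(tr.ap_times_ms) > 0
    if not fires(w_max_us):
        return None
    lo, hi = 0.0, w_max_us
    while hi - lo > rel_precision * hi:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


def weak_synapse_for(tree: nr.CompartmentTree, biophys: nr.BiophysSpec,
                     fraction: float = 0.1) -> nr.SynapseSpec:
    """The weak background input: ``fraction`` (default 10%) of the
    synaptic threshold weight."""
    w_star = estimate_synaptic_threshold(tree, biophys)
    if w_star is None:
        raise RuntimeError("synaptic threshold not found below the search bound")
    return nr.SynapseSpec(weight_us=fraction * w_star)


def threshold_map_for_participant(participant_id: str, head: HeadModel, region: str,
                                  placements: list[CellPlacement],
                                  coil: ef.CoilModel, placement_coil,
                                  tree: nr.CompartmentTree,
                                  biophys: nr.BiophysSpec,
                                  waveform: nr.PulseWaveform,
                                  with_synapse: bool = False,
                                  synapse: nr.SynapseSpec | None = None,
                                  L: int | None = None) -> ThresholdMap:
    """Estimate one activation threshold per placement at the 45-degree
    coil placement, with the E-field map computed at 1 %MSO.

    The field is sampled at every compartment midpoint of every placed
    cell in a single batched evaluation of the spherical-conductor
    solution, then split per cell for the quasipotential line integrals.
    """
    L = ef.DEFAULT_L if L is None else L
    if with_synapse and synapse is None:
        synapse = weak_synapse_for(tree, biophys)

    placed = [_placed_tree(tree, p) for p in placements]
    # batched field evaluation at all segment midpoints of all cells
    seg_mids = []
    for pt in placed:
        pos_mm = pt.midpoint_um * 1e-3
        seg_mids.append(0.5 * (pos_mm[1:] + pos_mm[pt.parent[1:]]))
    all_pts = np.concatenate(seg_mids)
    E_all = ef.total_field(coil, placement_coil, head, all_pts,
                           dIdt=ef.DIDT_PER_PCT_MSO, L=L)
    thresholds = np.zeros(len(placements), dtype=int)
    censored = np.zeros(len(placements), dtype=bool)
    off = 0
    for i, pt in enumerate(placed):
        k = pt.n - 1
        E = E_all[off:off + k]
        off += k
        pos_mm = pt.midpoint_um * 1e-3
        psi = np.zeros(pt.n)
        for j in range(1, pt.n):
            dx = pos_mm[j] - pos_mm[pt.parent[j]]
            psi[j] = psi[pt.parent[j]] - float(np.dot(E[j - 1], dx))
        prof = nr.QuasiPotentialProfile(psi_mv=psi)
        thr = estimate_threshold(pt, biophys, prof, waveform,
                                 synapse=synapse if with_synapse else None)
        if thr is None:
            censored[i] = True
        else:
            thresholds[i] = thr
    return ThresholdMap(
        placements=list(placements), threshold_pct_mso=thresholds,
        censored=censored, with_synapse=with_synapse, region=region,
        participant_id=participant_id,
    )
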