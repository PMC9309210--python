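"""Reduced layer-5 pyramidal cell and its coupling to the TMS field.

The cell is a surrogate morphology (soma, axon with initial segment,
apical trunk + tuft, four basal dendrites) stored as a standard SWC node
table and discretized into coupled cylindrical compartments.  Membrane
dynamics are Hodgkin-Huxley-type: transient Na (m^3 h), delayed-rectifier
K (n^4), leak, and a high-voltage-activated Ca current (m^2 h, apical and
somatic) feeding a first-order intracellular Ca pool

    d[Ca]/dt = -k * I_Ca - ([Ca] - Ca_rest) / tau_Ca .

The extracellular TMS drive enters through quasipotentials: the field is
line-integrated along the tree (psi_child = psi_parent - E . dx, psi = 0
at the root) and the axial term of the cable equation uses
(V_i + psi_i * s * w(t)) differences, where s is the stimulation
intensity in %MSO and w(t) the normalized biphasic pulse waveform.
Depolarization therefore appears where psi decreases along the path away
from the soma: for a two-compartment cable (soma -> terminal) in a field
pointing from soma to terminal, psi_terminal < psi_soma and the terminal
is depolarized during the positive phase of w.

Integration is backward Euler with tree-ordered (Hines) elimination,
unconditionally stable for the stiff pulse drive; gates use staggered
exponential updates.  Time steps refine automatically during pulses.

Units: lengths um (positions exposed in mm where stated), potentials mV,
conductances uS (densities mS/cm^2), currents nA, capacitance nF,
concentration mM, time ms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "Morphology",
    "CompartmentTree",
    "BiophysSpec",
    "PulseWaveform",
    "QuasiPotentialProfile",
    "SynapseSpec",
    "SimTrace",
    "generate_reduced_l5_morphology",
    "read_swc",
    "write_swc",
    "discretize",
    "quasipotentials",
    "biphasic_waveform",
    "simulate",
    "detect_aps",
    "time_locked",
    "detect_ca_events",
    "synapse_conductance",
    "save_trace_csv",
    "default_biophys",
]

SWC_SOMA, SWC_AXON, SWC_BASAL, SWC_APICAL = 1, 2, 3, 4
# compartment region codes (separate AIS entry so it can carry higher gNa)
R_SOMA, R_AIS, R_AXON, R_BASAL, R_APICAL = 0, 1, 2, 3, 4


@dataclass
class Morphology:
    """SWC node table: one tree, radii > 0, parent precedes child."""

    ids: np.ndarray       # (n,) int
    types: np.ndarray     # (n,) int SWC type codes
    xyz: np.ndarray       # (n, 3) um
    radius: np.ndarray    # (n,) um
    parent: np.ndarray    # (n,) int id of parent, -1 for root

    def __post_init__(self):
        if np.any(self.radius <= 0):
            raise ValueError("all radii must be > 0")
        if np.sum(self.parent == -1) != 1:
            raise ValueError("morphology must have exactly one root")

    @property
    def n_nodes(self) -> int:
        return len(self.ids)


@dataclass
class CompartmentTree:
    """Cylindrical compartments; parent index always precedes child."""

    parent: np.ndarray       # (n,) int, -1 for root compartment
    length_um: np.ndarray
    diam_um: np.ndarray
    midpoint_um: np.ndarray  # (n, 3)
    area_cm2: np.ndarray
    g_axial_uS: np.ndarray   # coupling conductance to parent (0 at root)
    region: np.ndarray       # (n,) int region codes R_*
    path_dist_um: np.ndarray  # path distance from soma center

    @property
    def n(self) -> int:
        return len(self.parent)

    @property
    def total_area_cm2(self) -> float:
        return float(self.area_cm2.sum())

    def transformed(self, rotation: np.ndarray, translation_um: np.ndarray) -> "CompartmentTree":
        """Rigid placement of the cell; lengths, areas and couplings are
        invariant, only midpoints move."""
        return replace(self, midpoint_um=self.midpoint_um @ rotation.T + translation_um)


@dataclass(frozen=True)
class BiophysSpec:
    """Channel densities (mS/cm^2) per region code and passive/Ca settings."""

    g_na: tuple = (80.0, 1500.0, 1000.0, 10.0, 10.0)   # soma, ais, axon, basal, apical
    g_kdr: tuple = (60.0, 150.0, 60.0, 5.0, 5.0)
    g_km: tuple = (3.0, 3.0, 3.0, 0.5, 0.5)
    g_leak: tuple = (0.04, 0.04, 0.02, 0.04, 0.04)
    g_ca_hva: tuple = (0.3, 0.0, 0.0, 0.0, 0.3)
    # effective axonal capacitance is reduced so that brief pulses can
    # polarize terminals the way fast-initiating real axons do; the early
    # cable response scales as sqrt(1 / Cm)
    cm_uf_cm2: tuple = (1.0, 1.0, 0.01, 1.0, 1.0)
    ra_ohm_cm: float = 150.0
    e_na_mv: float = 60.0
    e_k_mv: float = -90.0
    e_ca_mv: float = 130.0
    v_rest_mv: float = -70.0
    ca_rest_mm: float = 1e-4
    tau_ca_ms: float = 80.0
    ca_influx_factor: float = 0.4   # mM cm^2 / (mA ms)
    temperature_c: float = 36.0     # folded into the rate constants

    def __post_init__(self):
        for dens in (self.g_na, self.g_kdr, self.g_km, self.g_leak, self.g_ca_hva):
            if any(g < 0 for g in dens):
                raise ValueError("channel densities must be >= 0")
        if self.tau_ca_ms <= 0:
            raise ValueError("tau_Ca must be > 0")


def default_biophys() -> BiophysSpec:
    return BiophysSpec()


@dataclass(frozen=True)
class PulseWaveform:
    """Normalized biphasic pulse: w(t) = cos(2 pi f t) exp(-t / tau_d) on
    one full carrier period, peak |w| = 1."""

    times_ms: np.ndarray
    values: np.ndarray
    carrier_khz: float
    damping_ms: float

    @property
    def duration_ms(self) -> float:
        return float(self.times_ms[-1])

    def __call__(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, float)
        inside = (t >= 0) & (t <= self.duration_ms)
        tc = np.where(inside, t, 0.0)
        w = np.cos(2 * np.pi * self.carrier_khz * tc) * np.exp(-tc / self.damping_ms)
        return np.where(inside, w / self._peak, 0.0)

    @property
    def _peak(self) -> float:
        return float(np.max(np.abs(np.cos(2 * np.pi * self.carrier_khz * self.times_ms)
                                   * np.exp(-self.times_ms / self.damping_ms))))


def biphasic_waveform(dt_ms: float = 0.005, carrier_khz: float = 3.4,
                      damping_ms: float = 0.4) -> PulseWaveform:
    """One damped-cosine carrier period (about 294 us at 3.4 kHz)."""
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    if carrier_khz <= 0:
        raise ValueError("carrier frequency must be > 0")
    period = 1.0 / carrier_khz
    t = np.arange(0.0, period + dt_ms / 2, dt_ms)
    t[-1] = period
    w = np.cos(2 * np.pi * carrier_khz * t) * np.exp(-t / damping_ms)
    w = w / np.max(np.abs(w))
    return PulseWaveform(times_ms=t, values=w, carrier_khz=carrier_khz, damping_ms=damping_ms)


@dataclass
class QuasiPotentialProfile:
    """Extracellular potential per compartment per unit intensity (1 %MSO)."""

    psi_mv: np.ndarray


@dataclass(frozen=True)
class SynapseSpec:
    """Two-exponential conductance synapse on the proximal apical dendrite."""

    tau1_ms: float = 0.2
    tau2_ms: float = 2.5
    weight_us: float = 0.0
    e_rev_mv: float = 0.0
    attach_path_dist_um: float = 20.0
    event_times_ms: tuple = ()

    def __post_init__(self):
        if not self.tau2_ms > self.tau1_ms > 0:
            raise ValueError("require tau2 > tau1 > 0")
        if self.weight_us < 0:
            raise ValueError("synaptic weight must be >= 0")


@dataclass
class SimTrace:
    t_ms: np.ndarray
    vm_mv: np.ndarray
    ca_mm: np.ndarray
    pulse_onsets_ms: np.ndarray
    ap_times_ms: np.ndarray
    ca_event_times_ms: np.ndarray
    time_locked_flags: np.ndarray


class SolverDivergence(RuntimeError):
    def __init__(self, t_ms: float):
        super().__init__(f"membrane solver diverged (|Vm| > 200 mV) at t = {t_ms:.3f} ms")
        self.t_ms = t_ms


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def generate_reduced_l5_morphology(seed: int = 0, apical_trunk_um: float = 600.0,
                                   tuft_branch_um: float = 250.0, n_tuft: int = 2,
                                   basal_um: float = 200.0, n_basal: int = 4,
                                   axon_um: float = 1000.0, step_um: float = 20.0,
                                   n_collateral: int = 2, collateral_um: float = 300.0,
                                   max_extent_um: float = 1200.0) -> Morphology:
    """Deterministic surrogate pyramidal cell.

    Soma (single node, ~25 um cylinder), ~1 mm axon with initial segment
    and ``n_collateral`` near-horizontal collaterals, apical trunk along
    +z with a spread tuft, and ``n_basal`` obliquely descending basal
    dendrites.  The horizontal collaterals matter for field coupling: they
    are what lets a cell whose somato-dendritic axis is perpendicular to
    the (largely tangential) induced field still be excitable, as real
    pyramidal cells are.  The apical tip must stay within
    ``max_extent_um`` of the soma so that a cell at 1.25 mm somatic depth
    keeps all compartments inside gray matter.
    """
    if apical_trunk_um + tuft_branch_um > max_extent_um:
        raise ValueError(
            f"apical extent {apical_trunk_um + tuft_branch_um:.0f} um exceeds the "
            f"{max_extent_um:.0f} um budget set by the somatic depth")
    rng = np.random.default_rng(seed)
    ids, types, xyz, rad, par = [], [], [], [], []

    def add(t, p, r, parent_id):
        nid = len(ids) + 1
        ids.append(nid)
        types.append(t)
        xyz.append(p)
        rad.append(r)
        par.append(parent_id)
        return nid

    soma = add(SWC_SOMA, np.zeros(3), 12.5, -1)

    def grow(t, start_id, direction, length, r0, r1, wiggle=0.02):
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        n = max(1, int(round(length / step_um)))
        pos = np.array(xyz[start_id - 1], float)
        last = start_id
        for i in range(n):
            d_i = d + wiggle * rng.normal(size=3)
            d_i /= np.linalg.norm(d_i)
            pos = pos + d_i * (length / n)
            r = r0 + (r1 - r0) * (i + 1) / n
            last = add(t, pos.copy(), r, last)
        return last

    # axon: 50 um initial segment then the main axon, descending (-z),
    # with near-horizontal collaterals branching off at depth
    ais_end = grow(SWC_AXON, soma, (0, 0, -1.0), 50.0, 0.75, 0.75, wiggle=0.0)
    main_len = axon_um - 50.0
    branch_at = np.linspace(0.35, 0.75, max(n_collateral, 1)) * main_len
    cur = ais_end
    done = 0.0
    for k in range(n_collateral):
        seg = branch_at[k] - done
        cur = grow(SWC_AXON, cur, (0, 0, -1.0), seg, 0.75, 0.75)
        az = 2 * np.pi * (k / max(n_collateral, 1) + rng.uniform(-0.1, 0.1))
        tilt = np.deg2rad(80.0)   # nearly horizontal
        d = (np.sin(tilt) * np.cos(az), np.sin(tilt) * np.sin(az), -np.cos(tilt))
        grow(SWC_AXON, cur, d, collateral_um, 0.6, 0.5)
        done = branch_at[k]
    grow(SWC_AXON, cur, (0, 0, -1.0), main_len - done, 0.75, 0.5)

    # apical trunk (+z) and tuft
    trunk_end = grow(SWC_APICAL, soma, (0, 0, 1.0), apical_trunk_um, 1.3, 0.9)
    for k in range(n_tuft):
        az = 2 * np.pi * (k + rng.uniform(-0.1, 0.1)) / n_tuft
        tilt = np.deg2rad(35.0)
        d = (np.sin(tilt) * np.cos(az), np.sin(tilt) * np.sin(az), np.cos(tilt))
        grow(SWC_APICAL, trunk_end, d, tuft_branch_um, 0.6, 0.5)

    # basal dendrites, descending obliquely
    for k in range(n_basal):
        az = 2 * np.pi * (k + rng.uniform(-0.15, 0.15)) / n_basal
        elev = np.deg2rad(-35.0 + rng.uniform(-5, 5))
        d = (np.cos(elev) * np.cos(az), np.cos(elev) * np.sin(az), np.sin(elev))
        grow(SWC_BASAL, soma, d, basal_um, 0.75, 0.6)

    return Morphology(
        ids=np.asarray(ids), types=np.asarray(types), xyz=np.asarray(xyz),
        radius=np.asarray(rad), parent=np.asarray(par),
    )


def read_swc(path) -> Morphology:
    """Standard 7-column SWC; raises on cycles or unknown type codes with
    the offending line number."""
    ids, types, xyz, rad, par = [], [], [], [], []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{ln}: expected 7 columns, got {len(parts)}")
            try:
                nid, t = int(parts[0]), int(parts[1])
                x, y, z, r = map(float, parts[2:6])
                p = int(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
            if t not in (SWC_SOMA, SWC_AXON, SWC_BASAL, SWC_APICAL):
                raise ValueError(f"{path}:{ln}: unknown SWC type code {t}")
            ids.append(nid)
            types.append(t)
            xyz.append((x, y, z))
            rad.append(r)
            par.append(p)
    id_to_line = {nid: ln for ln, nid in enumerate(ids)}
    # cycle check by walking to root
    index = {nid: i for i, nid in enumerate(ids)}
    for i, nid in enumerate(ids):
        seen = set()
        cur = nid
        while cur != -1:
            if cur in seen:
                raise ValueError(f"{path}: cyclic parent links at node id {nid}")
            seen.add(cur)
            if cur not in index:
                raise ValueError(f"{path}: node {nid} references missing parent {cur}")
            cur = par[index[cur]]
    return Morphology(
        ids=np.asarray(ids), types=np.asarray(types), xyz=np.asarray(xyz),
        radius=np.asarray(rad), parent=np.asarray(par),
    )


def write_swc(morph: Morphology, path) -> None:
    """Write sorted ids, parent before child, fixed 6-decimal precision."""
    order = np.argsort(morph.ids)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in order:
            x, y, z = morph.xyz[i]
            fh.write(f"{morph.ids[i]} {morph.types[i]} {x:.6f} {y:.6f} {z:.6f} "
                     f"{morph.radius[i]:.6f} {morph.parent[i]}\n")


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def discretize(morph: Morphology, max_seg_len_um: float = 20.0,
               ra_ohm_cm: float = 150.0) -> CompartmentTree:
    """Split each SWC edge into cylinders no longer than ``max_seg_len_um``.

    The coupling conductance between adjacent compartment centers is the
    series half-resistance rule with R_c = 4 Ra L_c / (pi d_c^2).  The
    single-node soma becomes a cylinder with length = diameter = 2 r
    (lateral area 4 pi r^2, the usual single-point-soma convention).
    """
    if max_seg_len_um <= 0:
        raise ValueError("max segment length must be > 0")
    index = {nid: i for i, nid in enumerate(morph.ids)}

    parent, length, diam, mid, area, region, pdist = [], [], [], [], [], [], []
    half_r = []  # axial half-resistance (MOhm) of each compartment

    def ra_mohm(l_um, d_um):
        # 4 Ra L / (pi d^2); Ra Ohm cm = 1e-2 Ohm m; result in MOhm
        return 4.0 * ra_ohm_cm * 1e4 * l_um / (np.pi * d_um**2) * 1e-6

    # soma compartment
    ri = index[morph.ids[np.flatnonzero(morph.parent == -1)[0]]]
    r_soma = morph.radius[ri]
    soma_len = 2 * r_soma
    parent.append(-1)
    length.append(soma_len)
    diam.append(2 * r_soma)
    mid.append(morph.xyz[ri].copy())
    area.append(np.pi * (2 * r_soma) * soma_len * 1e-8)   # um^2 -> cm^2
    region.append(R_SOMA)
    pdist.append(0.0)
    half_r.append(ra_mohm(soma_len, 2 * r_soma) / 2.0)

    node_comp = {morph.ids[ri]: 0}   # SWC node id -> compartment holding its end

    swc_to_region = {SWC_SOMA: R_SOMA, SWC_AXON: R_AXON, SWC_BASAL: R_BASAL,
                     SWC_APICAL: R_APICAL}
    order = np.argsort(morph.ids)
    for i in order:
        pid = morph.parent[i]
        if pid == -1:
            continue
        pi = index[pid]
        p0, p1 = morph.xyz[pi], morph.xyz[i]
        r0, r1 = morph.radius[pi], morph.radius[i]
        if morph.types[pi] == SWC_SOMA and morph.types[i] != SWC_SOMA:
            r0 = r1   # neurites emerge at their own caliber, not the soma's
        seg_len = np.linalg.norm(p1 - p0)
        if seg_len == 0:
            continue
        nseg = max(1, int(np.ceil(seg_len / max_seg_len_um)))
        pc = node_comp[pid]
        reg = swc_to_region[morph.types[i]]
        if reg == R_AXON and pdist[pc] < 50.0:
            reg = R_AIS
        for k in range(nseg):
            f0, f1 = k / nseg, (k + 1) / nseg
            a0, a1 = p0 + (p1 - p0) * f0, p0 + (p1 - p0) * f1
            rr0, rr1 = r0 + (r1 - r0) * f0, r0 + (r1 - r0) * f1
            l = seg_len / nseg
            d = rr0 + rr1
            slant = np.hypot(l, rr1 - rr0)
            parent.append(pc)
            length.append(l)
            diam.append(d)
            mid.append((a0 + a1) / 2.0)
            area.append(np.pi * (rr0 + rr1) * slant * 1e-8)
            region.append(reg)
            pdist.append(pdist[pc] + length[pc] / 2.0 + l / 2.0)
            half_r.append(ra_mohm(l, d) / 2.0)
            pc = len(parent) - 1
        node_comp[morph.ids[i]] = pc

    parent = np.asarray(parent)
    half_r = np.asarray(half_r)
    g_ax = np.zeros(len(parent))
    for i in range(1, len(parent)):
        r_series = half_r[i] + half_r[parent[i]]   # MOhm
        g_ax[i] = 1.0 / r_series                   # uS
    return CompartmentTree(
        parent=parent,
        length_um=np.asarray(length),
        diam_um=np.asarray(diam),
        midpoint_um=np.asarray(mid),
        area_cm2=np.asarray(area),
        g_axial_uS=g_ax,
        region=np.asarray(region),
        path_dist_um=np.asarray(pdist),
    )


# ---------------------------------------------------------------------------
# quasipotentials
# ---------------------------------------------------------------------------

def quasipotentials(tree: CompartmentTree, efield_sampler) -> QuasiPotentialProfile:
    """Line-integrate the field along the tree (root psi = 0).

    ``efield_sampler`` maps positions in mm, shape (n, 3), to field
    vectors in mV/mm.  psi_child = psi_parent - E(segment midpoint) . dx.
    """
    pos_mm = tree.midpoint_um * 1e-3
    seg_mid = np.zeros_like(pos_mm)
    for i in range(1, tree.n):
        seg_mid[i] = 0.5 * (pos_mm[i] + pos_mm[tree.parent[i]])
    E = np.asarray(efield_sampler(seg_mid[1:]))
    if E.shape != (tree.n - 1, 3) or not np.all(np.isfinite(E)):
        bad = "unknown"
        if E.shape == (tree.n - 1, 3):
            bad = seg_mid[1:][~np.all(np.isfinite(E), axis=1)][:1]
        raise ValueError(f"E-field sampler undefined at position {bad}")
    psi = np.zeros(tree.n)
    for i in range(1, tree.n):
        dx = pos_mm[i] - pos_mm[tree.parent[i]]
        psi[i] = psi[tree.parent[i]] - float(np.dot(E[i - 1], dx))
    return QuasiPotentialProfile(psi_mv=psi)


# ---------------------------------------------------------------------------
# membrane solver
# ---------------------------------------------------------------------------

@njit(cache=True)
def _vtrap(x, y):
    # x / (1 - exp(-x/y)) with the removable singularity handled
    if abs(x / y) < 1e-6:
        return y + x / 2.0
    return x / (1.0 - np.exp(-x / y))


@njit(cache=True)
def _rates(v, out):
    # Na activation (Traub-Miles-style kinetics, ~36 C)
    am = 0.32 * _vtrap(v + 54.0, 4.0)
    bm = 0.28 * _vtrap(-(v + 27.0), 5.0)
    ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    an = 0.032 * _vtrap(v + 52.0, 5.0)
    bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
    # high-voltage-activated Ca (Reuveni-style)
    amc = 0.055 * _vtrap(v + 27.0, 3.8)
    bmc = 0.94 * np.exp(-(v + 75.0) / 17.0)
    ahc = 0.000457 * np.exp(-(v + 13.0) / 50.0)
    bhc = 0.0065 / (np.exp(-(v + 15.0) / 28.0) + 1.0)
    # slow (M-type) K: gives spike-frequency adaptation and the
    # post-spike hyperpolarization that prevents tonic re-firing
    akm = 0.0033 * np.exp((v + 35.0) / 20.0)
    bkm = 0.0033 * np.exp(-(v + 35.0) / 20.0)
    out[0] = am
    out[1] = bm
    out[2] = ah
    out[3] = bh
    out[4] = an
    out[5] = bn
    out[6] = amc
    out[7] = bmc
    out[8] = ahc
    out[9] = bhc
    out[10] = akm
    out[11] = bkm


@njit(cache=True)
def _gate_tables(v_lo, dv, nbin, dts_unique):
    """xinf and exp(-dt/tau) lookup tables for the five gates."""
    ndt = dts_unique.shape[0]
    xinf = np.empty((6, nbin))
    q = np.empty((ndt, 6, nbin))
    rates = np.empty(12)
    for b in range(nbin):
        v = v_lo + b * dv
        _rates(v, rates)
        for g in range(6):
            a = rates[2 * g]
            bb = rates[2 * g + 1]
            tau = 1.0 / (a + bb)
            xinf[g, b] = a * tau
            for k in range(ndt):
                q[k, g, b] = np.exp(-dts_unique[k] / tau)
    return xinf, q


@njit(cache=True)
def _run_kernel(parent, g_ax, cm_nf, gna, gk, gkm, gl, gca, eleak,
                ena, ek, eca, area_cm2,
                psi_q, drive, dts, dt_idx, xinf, qtab, v_lo, inv_dv,
                gsyn_t, syn_idx, esyn,
                iclamp_t, iclamp_idx,
                v0, m0, h0, n0, mc0, hc0, km0,
                ca_rest, tau_ca, k_ca,
                rec_vm, rec_ca):
    n = parent.shape[0]
    nsteps = dts.shape[0]
    nbin = xinf.shape[1]
    v = v0.copy()
    gates = np.empty((6, n))
    for i in range(n):
        gates[0, i] = m0[i]
        gates[1, i] = h0[i]
        gates[2, i] = n0[i]
        gates[3, i] = mc0[i]
        gates[4, i] = hc0[i]
        gates[5, i] = km0[i]
    ca = np.full(n, ca_rest)
    d = np.empty(n)
    rhs = np.empty(n)
    rec_vm[0] = v[0]
    rec_ca[0] = ca[0]
    t = 0.0
    for step in range(nsteps):
        dt = dts[step]
        k_dt = dt_idx[step]
        t += dt
        # gate update via table lookup (linear interpolation in V)
        for i in range(n):
            x = (v[i] - v_lo) * inv_dv
            if x < 0.0:
                x = 0.0
            elif x > nbin - 1.001:
                x = nbin - 1.001
            b = int(x)
            f = x - b
            for g in range(6):
                xi = xinf[g, b] * (1.0 - f) + xinf[g, b + 1] * f
                qq = qtab[k_dt, g, b] * (1.0 - f) + qtab[k_dt, g, b + 1] * f
                gates[g, i] = xi + (gates[g, i] - xi) * qq
        ca_q = np.exp(-dt / tau_ca)
        # assemble diagonal and rhs
        for i in range(n):
            g_na_i = gna[i] * gates[0, i] ** 3 * gates[1, i]
            g_k_i = gk[i] * gates[2, i] ** 4 + gkm[i] * gates[5, i]
            g_ca_i = gca[i] * gates[3, i] ** 2 * gates[4, i]
            g_tot = g_na_i + g_k_i + gl[i] + g_ca_i
            b_i = g_na_i * ena + g_k_i * ek + gl[i] * eleak[i] + g_ca_i * eca
            d[i] = cm_nf[i] / dt + g_tot
            rhs[i] = cm_nf[i] / dt * v[i] + b_i + drive[step] * psi_q[i]
        if syn_idx >= 0:
            gs = gsyn_t[step]
            d[syn_idx] += gs
            rhs[syn_idx] += gs * esyn
        if iclamp_idx >= 0:
            rhs[iclamp_idx] += iclamp_t[step]
        for i in range(1, n):
            d[i] += g_ax[i]
            d[parent[i]] += g_ax[i]
        # Hines elimination (children stored after parents)
        for i in range(n - 1, 0, -1):
            k = g_ax[i] / d[i]
            d[parent[i]] -= g_ax[i] * k
            rhs[parent[i]] += rhs[i] * k
        v[0] = rhs[0] / d[0]
        for i in range(1, n):
            v[i] = (rhs[i] + g_ax[i] * v[parent[i]]) / d[i]
        # calcium pool (exponential update toward the instantaneous target)
        for i in range(n):
            if gca[i] > 0.0:
                ica = gca[i] * gates[3, i] ** 2 * gates[4, i] * (v[i] - eca) / area_cm2[i] * 1e-6
                target = ca_rest - k_ca * tau_ca * ica
                if target < 0.0:
                    target = 0.0
                ca[i] = target + (ca[i] - target) * ca_q
        rec_vm[step + 1] = v[0]
        rec_ca[step + 1] = ca[0]
        amax = 0.0
        for i in range(n):
            if np.abs(v[i]) > amax:
                amax = np.abs(v[i])
        if amax > 200.0 or not np.isfinite(amax):
            return t
    return -1.0


# gate lookup tables span the physiological voltage range at 0.05 mV
# resolution; interpolation error is far below the solver tolerance
_V_TABLE_LO, _V_TABLE_HI, _V_TABLE_DV = -150.0, 80.0, 0.05
_TABLE_CACHE: dict = {}


def _cached_gate_tables(dts_key: tuple):
    if dts_key not in _TABLE_CACHE:
        nbin = int(round((_V_TABLE_HI - _V_TABLE_LO) / _V_TABLE_DV)) + 1
        _TABLE_CACHE[dts_key] = _gate_tables(
            _V_TABLE_LO, _V_TABLE_DV, nbin, np.asarray(dts_key))
    return _TABLE_CACHE[dts_key]


def _steady_gates(v):
    out = np.empty(12)
    _rates(v, out)
    am, bm, ah, bh, an, bn, amc, bmc, ahc, bhc, akm, bkm = out
    return (am / (am + bm), ah / (ah + bh), an / (an + bn),
            amc / (amc + bmc), ahc / (ahc + bhc), akm / (akm + bkm))


def _density_arrays(tree: CompartmentTree, bio: BiophysSpec):
    reg = tree.region
    a = tree.area_cm2
    def per(dens):
        return np.asarray(dens)[reg] * a * 1e3   # mS -> uS
    gna, gk, gkm = per(bio.g_na), per(bio.g_kdr), per(bio.g_km)
    gl, gca = per(bio.g_leak), per(bio.g_ca_hva)
    cm = np.asarray(bio.cm_uf_cm2)[reg] * a * 1e3     # uF -> nF
    # leak reversal balancing all steady currents at rest (exact fixed point)
    m, h, n, mc, hc, km = _steady_gates(bio.v_rest_mv)
    v = bio.v_rest_mv
    with np.errstate(divide="ignore", invalid="ignore"):
        eleak = np.where(
            gl > 0,
            v + (gna * m**3 * h * (v - bio.e_na_mv)
                 + (gk * n**4 + gkm * km) * (v - bio.e_k_mv)
                 + gca * mc**2 * hc * (v - bio.e_ca_mv)) / np.maximum(gl, 1e-30),
            v,
        )
    return gna, gk, gkm, gl, gca, cm, eleak


def _time_grid(duration_ms, dt_ms, fine_dt_ms, pulse_onsets, pulse_dur_ms):
    """Piecewise time grid: fine steps during pulses (plus 1 ms tail)."""
    fine = []
    for on in sorted(pulse_onsets):
        fine.append((max(0.0, on - 2 * dt_ms), min(duration_ms, on + pulse_dur_ms + 1.0)))
    dts = []
    t = 0.0
    fi = 0
    while t < duration_ms - 1e-9:
        in_fine = False
        for a, b in fine:
            if a - 1e-12 <= t < b - 1e-12:
                in_fine = True
                break
        dt = fine_dt_ms if in_fine else dt_ms
        dt = min(dt, duration_ms - t)
        dts.append(dt)
        t += dt
    return np.asarray(dts)


def synapse_conductance(spec: SynapseSpec, t_ms) -> np.ndarray:
    """Summed two-exponential conductance (uS), peak-normalized to weight."""
    if not spec.tau2_ms > spec.tau1_ms:
        raise ValueError("require tau2 > tau1")
    t = np.atleast_1d(np.asarray(t_ms, float))
    tp = (spec.tau1_ms * spec.tau2_ms / (spec.tau2_ms - spec.tau1_ms)
          * np.log(spec.tau2_ms / spec.tau1_ms))
    norm = 1.0 / (np.exp(-tp / spec.tau2_ms) - np.exp(-tp / spec.tau1_ms))
    g = np.zeros_like(t)
    for t0 in spec.event_times_ms:
        dt = t - t0
        act = dt >= 0
        g[act] += spec.weight_us * norm * (np.exp(-dt[act] / spec.tau2_ms)
                                           - np.exp(-dt[act] / spec.tau1_ms))
    return g if np.ndim(t_ms) else float(g[0])


def simulate(tree: CompartmentTree, biophys: BiophysSpec,
             psi: QuasiPotentialProfile | None, waveform: PulseWaveform | None,
             intensity_pct_mso: float = 0.0, synapse: SynapseSpec | None = None,
             duration_ms: float = 100.0, dt_ms: float = 0.025,
             fine_dt_ms: float = 0.005, pulse_onsets_ms=(5.0,),
             iclamp: tuple | None = None,
             ap_threshold_mv: float = 0.0, ap_refractory_ms: float = 2.0,
             ca_event_delta: float | None = None,
             ca_event_separation_ms: float = 20.0,
             time_lock_window_ms: float = 5.0) -> SimTrace:
    """Integrate the cell and return somatic voltage/calcium with events.

    ``iclamp`` is an optional (compartment_index, amplitude_nA, t_on_ms,
    t_off_ms) somatic/dendritic current step, used for passive validation
    and synaptic threshold searches.
    """
    n = tree.n
    gna, gk, gkm, gl, gca, cm, eleak = _density_arrays(tree, biophys)

    pulse_onsets = tuple(pulse_onsets_ms) if (waveform is not None and intensity_pct_mso != 0) else ()
    pulse_dur = waveform.duration_ms if waveform is not None else 0.0
    dts = _time_grid(duration_ms, dt_ms, fine_dt_ms, pulse_onsets, pulse_dur)
    tgrid = np.concatenate([[0.0], np.cumsum(dts)])

    drive = np.zeros(len(dts))
    if pulse_onsets:
        tend = tgrid[1:]
        for on in pulse_onsets:
            drive += waveform(tend - on)
        drive *= intensity_pct_mso

    psi_q = np.zeros(n)
    if psi is not None and intensity_pct_mso != 0:
        # rhs contribution q_i = sum_j g_ij (psi_j - psi_i), per unit drive
        p = psi.psi_mv
        q = np.zeros(n)
        for i in range(1, n):
            q[i] += tree.g_axial_uS[i] * (p[tree.parent[i]] - p[i])
            q[tree.parent[i]] += tree.g_axial_uS[i] * (p[i] - p[tree.parent[i]])
        psi_q = q

    syn_idx = -1
    gsyn_t = np.zeros(len(dts))
    if synapse is not None and synapse.weight_us > 0 and synapse.event_times_ms:
        apical = np.flatnonzero(tree.region == R_APICAL)
        if apical.size == 0:
            raise ValueError("no apical compartment to attach the synapse")
        syn_idx = int(apical[np.argmin(np.abs(tree.path_dist_um[apical]
                                              - synapse.attach_path_dist_um))])
        gsyn_t = synapse_conductance(synapse, tgrid[1:])

    iclamp_idx = -1
    iclamp_t = np.zeros(len(dts))
    if iclamp is not None:
        iclamp_idx, amp, t_on, t_off = int(iclamp[0]), *map(float, iclamp[1:])
        iclamp_t = np.where((tgrid[1:] > t_on) & (tgrid[1:] <= t_off), amp, 0.0)

    m, h, nn, mc, hc, km = _steady_gates(biophys.v_rest_mv)
    v0 = np.full(n, biophys.v_rest_mv)
    rec_vm = np.empty(len(dts) + 1)
    rec_ca = np.empty(len(dts) + 1)
    dts_unique, dt_idx = np.unique(np.round(dts, 12), return_inverse=True)
    xinf, qtab = _cached_gate_tables(tuple(dts_unique))
    t_fail = _run_kernel(
        tree.parent.astype(np.int64), tree.g_axial_uS, cm,
        gna, gk, gkm, gl, gca, eleak,
        biophys.e_na_mv, biophys.e_k_mv, biophys.e_ca_mv, tree.area_cm2,
        psi_q, drive, dts, dt_idx.astype(np.int64),
        xinf, qtab, _V_TABLE_LO, 1.0 / _V_TABLE_DV,
        gsyn_t, syn_idx, 0.0 if synapse is None else synapse.e_rev_mv,
        iclamp_t, iclamp_idx,
        v0, np.full(n, m), np.full(n, h), np.full(n, nn), np.full(n, mc), np.full(n, hc),
        np.full(n, km),
        biophys.ca_rest_mm, biophys.tau_ca_ms, biophys.ca_influx_factor,
        rec_vm, rec_ca,
    )
    if t_fail >= 0:
        raise SolverDivergence(t_fail)

    ap_times = detect_aps(tgrid, rec_vm, ap_threshold_mv, ap_refractory_ms)
    delta = (ca_event_delta if ca_event_delta is not None
             else 5.0 * biophys.ca_rest_mm)
    ca_events = detect_ca_events(tgrid, rec_ca, biophys.ca_rest_mm, delta,
                                 ca_event_separation_ms)
    flags = time_locked(ap_times, np.asarray(pulse_onsets, float), time_lock_window_ms)
    return SimTrace(
        t_ms=tgrid, vm_mv=rec_vm, ca_mm=rec_ca,
        pulse_onsets_ms=np.asarray(pulse_onsets, float),
        ap_times_ms=ap_times, ca_event_times_ms=ca_events,
        time_locked_flags=flags,
    )


def save_trace_csv(trace: SimTrace, path) -> None:
    """Write the somatic trace (time_ms, vm_mv, ca_mm) plus a companion
    <path stem>_events.csv with AP and Ca event times."""
    import pandas as pd
    from pathlib import Path
    path = Path(path)
    pd.DataFrame({"time_ms": trace.t_ms, "vm_mv": trace.vm_mv,
                  "ca_mm": trace.ca_mm}).to_csv(path, index=False,
                                                float_format="%.10g")
    events = ([("ap", t) for t in trace.ap_times_ms]
              + [("ca", t) for t in trace.ca_event_times_ms])
    pd.DataFrame(events, columns=["event", "time_ms"]).to_csv(
        path.with_name(path.stem + "_events.csv"), index=False,
        float_format="%.10g")


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def detect_aps(t_ms: np.ndarray, vm_mv: np.ndarray, threshold_mv: float = 0.0,
               refractory_ms: float = 2.0) -> np.ndarray:
    """Upward threshold crossings with a refractory merge window."""
    above = vm_mv >= threshold_mv
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    for i in idx:
        if not times or t_ms[i] - times[-1] >= refractory_ms:
            times.append(float(t_ms[i]))
    return np.asarray(times)


def time_locked(ap_times: np.ndarray, pulse_onsets: np.ndarray,
                window_ms: float = 5.0) -> np.ndarray:
    """Flag per pulse: any AP in (onset, onset + window]."""
    flags = np.zeros(len(pulse_onsets), dtype=bool)
    for k, on in enumerate(pulse_onsets):
        flags[k] = bool(np.any((ap_times > on) & (ap_times <= on + window_ms)))
    return flags


def detect_ca_events(t_ms: np.ndarray, ca_mm: np.ndarray, ca_rest_mm: float,
                     delta_mm: float, min_separation_ms: float = 20.0) -> np.ndarray:
    """Upward crossings of rest + delta, separated by the refractory gap."""
    thr = ca_rest_mm + delta_mm
    above = ca_mm >= thr
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    for i in idx:
        if not times or t_ms[i] - times[-1] >= min_separation_ms:
            times.append(float(t_ms[i]))
    return np.asarray(times)
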