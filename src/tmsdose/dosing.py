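"""Stimulation-intensity selection strategies and rTMS scenarios.

Four ways of choosing the pulse intensity are compared per participant
and region:

* ``RMT_FRACTION`` — a fraction (default 1.2, i.e. 120%) of the
  participant's resting motor threshold, the clinical standard;
* ``FXD`` — one fixed %MSO for everyone (default 60);
* ``EFIELD_MATCHED`` — the intensity that makes the ROI-mean E_total hit
  a common target (default 140 mV/mm), exact under the linear model;
* ``MEDIAN_THRESHOLD`` — the participant's own median cellular
  activation threshold in that region (lower median, so the dose is an
  attained threshold).

Outcomes are summarized as the percentage of activated cells among the
cells with thresholds at or below 100 %MSO (censored cells are excluded
from the denominator).  The rTMS protocol applies trains of biphasic
pulses (default 20 pulses at 10 Hz) to cells whose thresholds sit just
below, at, or just above the applied intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import neuron as nr
from .population import ThresholdMap

__all__ = [
    "STRATEGIES",
    "DoseResult",
    "RtmsScenario",
    "dose_rmt",
    "dose_fxd",
    "dose_efield_matched",
    "dose_median_threshold",
    "pct_activated",
    "compare_strategies",
    "select_scenario_cells",
    "run_rtms_protocol",
]

STRATEGIES = ("RMT_FRACTION", "FXD", "EFIELD_MATCHED", "MEDIAN_THRESHOLD")


@dataclass(frozen=True)
class DoseResult:
    participant: str
    region: str
    strategy: str
    applied_pct_mso: float
    achieved_roi_mean_mv_mm: float
    pct_activated: float


@dataclass
class RtmsScenario:
    scenario: str                 # below | at | above
    intensity_pct_mso: float
    cell_index: int
    threshold_pct_mso: int
    n_pulses: int
    freq_hz: float
    trace: nr.SimTrace

    @property
    def ap_count(self) -> int:
        return len(self.trace.ap_times_ms)

    @property
    def time_locked_count(self) -> int:
        return int(self.trace.time_locked_flags.sum())

    @property
    def ca_event_count(self) -> int:
        return len(self.trace.ca_event_times_ms)


def dose_rmt(rmt_pct_mso: float, fraction: float = 1.2) -> float:
    """Fraction of the resting motor threshold (e.g. 1.2 for 120% RMT)."""
    if fraction <= 0:
        raise ValueError("RMT fraction must be > 0")
    return float(fraction * rmt_pct_mso)


def dose_fxd(mso: float = 60.0) -> float:
    """One fixed intensity for every participant and region."""
    if not 0 < mso <= 100:
        raise ValueError("fixed intensity must be in (0, 100] %MSO")
    return float(mso)


def dose_efield_matched(roi_mean_at_1pct: float, target_mv_per_mm: float = 140.0) -> float:
    """Intensity that reaches the target ROI-mean E_total exactly."""
    from .efield import match_efield_intensity
    return match_efield_intensity(roi_mean_at_1pct, target_mv_per_mm)


def dose_median_threshold(threshold_map: ThresholdMap) -> float:
    """Lower median of the non-censored activation thresholds."""
    v = np.sort(threshold_map.valid_thresholds())
    if v.size == 0:
        raise ValueError("all thresholds censored; median dose undefined")
    return float(v[(v.size - 1) // 2])


def pct_activated(threshold_map: ThresholdMap, intensity_pct_mso: float) -> float:
    """Percent of eligible (non-censored) cells with threshold <= intensity."""
    if intensity_pct_mso <= 0:
        raise ValueError("intensity must be > 0")
    v = threshold_map.valid_thresholds()
    if v.size == 0:
        raise ValueError("no eligible cells (all thresholds censored)")
    return float(100.0 * np.count_nonzero(v <= intensity_pct_mso) / v.size)


def compare_strategies(cohort, roi_means_1pct: dict, threshold_maps: dict,
                       strategies=STRATEGIES, rmt_fraction: float = 1.2,
                       fxd_mso: float = 60.0, efield_target: float = 140.0,
                       regions=("M1", "DLPFC")) -> pd.DataFrame:
    """One row per participant x region x strategy.

    ``roi_means_1pct[(participant_id, region)]`` is the ROI-mean E_total
    at 1 %MSO; ``threshold_maps[(participant_id, region)]`` the
    (with-synapse) threshold map used for activation percentages.
    """
    rows = []
    for p in cohort:
        for region in regions:
            roi1 = roi_means_1pct[(p.id, region)]
            tmap = threshold_maps[(p.id, region)]
            for strat in strategies:
                if strat == "RMT_FRACTION":
                    dose = dose_rmt(p.rmt_pct_mso, rmt_fraction)
                elif strat == "FXD":
                    dose = dose_fxd(fxd_mso)
                elif strat == "EFIELD_MATCHED":
                    dose = dose_efield_matched(roi1, efield_target)
                elif strat == "MEDIAN_THRESHOLD":
                    dose = dose_median_threshold(tmap)
                else:
                    raise ValueError(f"unknown strategy {strat!r}")
                rows.append(DoseResult(
                    participant=p.id, region=region, strategy=strat,
                    applied_pct_mso=dose,
                    achieved_roi_mean_mv_mm=roi1 * dose,
                    pct_activated=pct_activated(tmap, dose),
                ).__dict__)
    return pd.DataFrame(rows)


def select_scenario_cells(threshold_map: ThresholdMap, intensity_pct_mso: float):
    """Indices of the cells with thresholds nearest 95%, 100% and 105% of
    the intensity (ties resolved toward the lower threshold)."""
    v = threshold_map.threshold_pct_mso.astype(float).copy()
    v[threshold_map.censored] = np.inf
    if not np.isfinite(v).any():
        raise ValueError("threshold map has no usable cells")
    out = {}
    for name, fac in (("below", 0.95), ("at", 1.00), ("above", 1.05)):
        target = fac * intensity_pct_mso
        dist = np.abs(v - target)
        # ties -> lower threshold
        best = np.flatnonzero(dist == dist.min())
        out[name] = int(best[np.argmin(v[best])])
    return out


def run_rtms_protocol(tree: nr.CompartmentTree, biophys: nr.BiophysSpec,
                      psi: nr.QuasiPotentialProfile, waveform: nr.PulseWaveform,
                      intensity_pct_mso: float, n_pulses: int = 20,
                      freq_hz: float = 10.0, start_ms: float = 100.0,
                      tail_ms: float = 200.0, **sim_kw) -> nr.SimTrace:
    """Simulate a pulse train (default 20 pulses at 10 Hz) plus a tail
    that captures late Ca dynamics; no synaptic input."""
    if n_pulses < 1 or freq_hz <= 0:
        raise ValueError("need n_pulses >= 1 and freq_hz > 0")
    period = 1000.0 / freq_hz
    onsets = start_ms + period * np.arange(n_pulses)
    duration = onsets[-1] + tail_ms
    return nr.simulate(tree, biophys, psi, waveform, intensity_pct_mso,
                       duration_ms=float(duration),
                       pulse_onsets_ms=tuple(onsets), **sim_kw)
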