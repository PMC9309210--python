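"""End-to-end pipeline: cohort -> E-field -> thresholds -> dosing -> stats.

Runs are driven by a ``RunConfig`` that collects every tunable parameter
in one serializable place (YAML round-trip).  All stages are
deterministic functions of (config, seed): re-running a stage into a
fresh directory reproduces byte-identical CSV outputs.  The threshold
stage caches per-cell results on disk keyed by a content hash of the
relevant config slice, so interrupted runs resume without recomputing
completed cells.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dosing as ds
from . import efield as ef
from . import headmodel as hm
from . import neuron as nr
from . import population as pop
from . import stats as st
from . import synthdata as sd

__all__ = ["RunConfig", "default_config", "load_config", "save_config",
           "run_cohort_stage", "run_efield_stage", "run_threshold_stage",
           "run_dosing_stage", "run_all", "write_report"]

log = logging.getLogger("tmsdose")

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    # cohort
    n_participants: int = 4
    seed: int = 1
    use_table1_rmts: bool = False
    # geometry / field
    mesh_edge_mm: float = 1.0
    expansion_order: int = ef.DEFAULT_L
    angles_deg: tuple = (45.0,)
    roi_radius_mm: float = 10.0
    robust_percentile: float = 99.9
    coil_standoff_mm: float = 4.0
    # population
    population_roi_mm: float = 15.0
    cells_per_region: int = 150
    cell_seed: int = 12345
    # dosing
    rmt_fraction: float = 1.2
    fxd_mso: float = 60.0
    efield_target_mv_mm: float = 140.0
    rtms_n_pulses: int = 20
    rtms_freq_hz: float = 10.0
    rtms_participant: str = ""   # default: first participant
    # stats
    depth_test: str = "t"            # paired t for depths
    activation_test: str = "wilcoxon"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["angles_deg"] = list(self.angles_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "angles_deg" in d:
            d["angles_deg"] = tuple(float(a) for a in d["angles_deg"])
        return cls(**d)


def default_config() -> RunConfig:
    return RunConfig()


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _cfg_hash(cfg: RunConfig, keys: tuple) -> str:
    d = cfg.to_dict()
    blob = json.dumps({k: d[k] for k in keys}, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _update_manifest(outdir: Path, stage: str, entry: dict) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest[stage] = entry
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _cohort(cfg: RunConfig):
    cohort = sd.sample_cohort(cfg.n_participants, cfg.seed)
    if cfg.use_table1_rmts:
        table = sd.load_table1_fixture()
        cohort = [dataclasses.replace(p, rmt_pct_mso=table[i % 16].rmt_pct_mso)
                  for i, p in enumerate(cohort)]
    return cohort


def _targets_and_placements(head, cfg: RunConfig):
    """M1 target above the patch center; DLPFC target via the 5-cm rule."""
    out = {}
    surf = head.surfaces[sd.M1]
    center_dir = np.asarray(surf.spec.patch_center_direction, float)
    tgt_m1 = surf.vertices[hm.nearest_vertex(surf, head.scalp_radius_mm * center_dir)]
    pl_m1 = hm.place_coil(head, tgt_m1, 45.0, cfg.coil_standoff_mm)
    out[sd.M1] = tgt_m1
    out[sd.DLPFC] = hm.apply_5cm_rule(head, pl_m1)
    return out


def run_cohort_stage(cfg: RunConfig, outdir: Path) -> list:
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = _cohort(cfg)
    sd.cohort_to_csv(cohort, outdir / "cohort.csv")
    _update_manifest(outdir, "cohort", {
        "n": len(cohort), "seed": cfg.seed, "file": "cohort.csv"})
    log.info("cohort stage: %d participants", len(cohort))
    return cohort


def run_efield_stage(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    """Angle sweeps and ROI statistics per participant and region."""
    cohort = _cohort(cfg)
    coil = ef.default_coil()
    rows = []
    for p in cohort:
        t0 = time.monotonic()
        head = hm.build_head(p.head_params, cfg.mesh_edge_mm)
        targets = _targets_and_placements(head, cfg)
        for region in (sd.M1, sd.DLPFC):
            df, optimal = ef.angle_sweep(
                coil, head, region, targets[region], angles=cfg.angles_deg,
                roi_radius_mm=cfg.roi_radius_mm, percentile=cfg.robust_percentile,
                L=cfg.expansion_order)
            for _, r in df.iterrows():
                rows.append({"participant": p.id, "region": region,
                             "angle_deg": r.angle_deg,
                             "mean_e_total": r.mean_e_total,
                             "mean_e_t": r.mean_e_t,
                             "mean_e_perp": r.mean_e_perp,
                             "robust_max": r.robust_max,
                             "optimal_angle_deg": optimal})
        log.info("efield stage: participant %s elapsed %.1fs", p.id,
                 time.monotonic() - t0)
    out = pd.DataFrame(rows)
    outdir.mkdir(parents=True, exist_ok=True)
    out.to_csv(outdir / "efield_roi_stats.csv", index=False, float_format=FLOAT_FMT)
    _update_manifest(outdir, "efield", {
        "rows": len(out), "angles": list(cfg.angles_deg), "file": "efield_roi_stats.csv"})
    return out


THRESHOLD_CFG_KEYS = ("seed", "n_participants", "mesh_edge_mm", "expansion_order",
                      "population_roi_mm", "cells_per_region", "cell_seed",
                      "coil_standoff_mm")


def run_threshold_stage(cfg: RunConfig, outdir: Path, resume: bool = False) -> pd.DataFrame:
    """Per-cell activation thresholds, with and without the weak synapse."""
    efield_file = outdir / "efield_roi_stats.csv"
    if not efield_file.exists():
        raise FileNotFoundError(
            f"threshold stage requires the E-field stage output at {efield_file}")
    cohort = _cohort(cfg)
    coil = ef.default_coil()
    tree = nr.discretize(nr.generate_reduced_l5_morphology(seed=1))
    bio = nr.default_biophys()
    wf = nr.biphasic_waveform()
    weak_syn = pop.weak_synapse_for(tree, bio)

    cache_dir = outdir / "cache"
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = _cfg_hash(cfg, THRESHOLD_CFG_KEYS)

    frames = []
    for p in cohort:
        head = hm.build_head(p.head_params, cfg.mesh_edge_mm)
        targets = _targets_and_placements(head, cfg)
        for region in (sd.M1, sd.DLPFC):
            plc = hm.place_coil(head, targets[region], 45.0, cfg.coil_standoff_mm)
            surf = head.surfaces[region]
            rc = hm.nearest_vertex(surf, plc.center)
            cells = pop.place_cells(head, region, rc, cfg.population_roi_mm,
                                    cfg.cells_per_region, seed=cfg.cell_seed + p.seed)
            for with_syn in (False, True):
                tag = f"{key}_{p.id}_{region}_{'syn' if with_syn else 'nosyn'}"
                cached = cache_dir / f"{tag}.csv"
                if resume and cached.exists():
                    frames.append(pd.read_csv(cached, keep_default_na=False))
                    log.info("threshold stage: %s cached", tag)
                    continue
                t0 = time.monotonic()
                tm = pop.threshold_map_for_participant(
                    p.id, head, region, cells, coil, plc, tree, bio, wf,
                    with_synapse=with_syn, synapse=weak_syn if with_syn else None,
                    L=cfg.expansion_order)
                df = tm.to_dataframe()
                df.to_csv(cached, index=False, float_format=FLOAT_FMT)
                frames.append(pd.read_csv(cached, keep_default_na=False))
                log.info("threshold stage: %s %s %s done in %.1fs "
                         "(censored %.0f%%, %d bisection runs)",
                         p.id, region, "syn" if with_syn else "nosyn",
                         time.monotonic() - t0, 100 * tm.fraction_censored, tm.n)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(outdir / "thresholds.csv", index=False, float_format=FLOAT_FMT)
    _update_manifest(outdir, "thresholds", {
        "rows": len(out), "cache_key": key, "file": "thresholds.csv"})
    return out


def _maps_from_frame(df: pd.DataFrame):
    maps = {}
    for (pid, region, wsyn), g in df.groupby(["participant", "region", "with_synapse"]):
        thr = pd.to_numeric(g["threshold_pct_mso"], errors="coerce").fillna(0).to_numpy(int)
        maps[(str(pid), str(region), bool(wsyn))] = pop.ThresholdMap(
            placements=[None] * len(g), threshold_pct_mso=thr,
            censored=g["censored"].astype(bool).to_numpy(),
            with_synapse=bool(wsyn), region=str(region), participant_id=str(pid))
    return maps


def run_dosing_stage(cfg: RunConfig, outdir: Path, strategies=ds.STRATEGIES) -> dict:
    """Strategy comparison, paired statistics and the rTMS scenarios."""
    thr_file = outdir / "thresholds.csv"
    ef_file = outdir / "efield_roi_stats.csv"
    for f in (thr_file, ef_file):
        if not f.exists():
            raise FileNotFoundError(f"dosing stage requires upstream output {f}")
    cohort = _cohort(cfg)
    thr = pd.read_csv(thr_file, keep_default_na=False)
    efd = pd.read_csv(ef_file)
    maps = _maps_from_frame(thr)

    roi_means = {}
    sel = efd[efd.angle_deg == 45.0]
    for _, r in sel.iterrows():
        roi_means[(str(r.participant), str(r.region))] = float(r.mean_e_total)

    syn_maps = {(pid, region): m for (pid, region, wsyn), m in maps.items() if wsyn}
    table = ds.compare_strategies(
        cohort, roi_means, syn_maps, strategies=strategies,
        rmt_fraction=cfg.rmt_fraction, fxd_mso=cfg.fxd_mso,
        efield_target=cfg.efield_target_mv_mm)
    table.to_csv(outdir / "dose_results.csv", index=False, float_format=FLOAT_FMT)

    # paired comparisons per strategy (M1 vs DLPFC percent activated)
    stat_rows = []
    pvals = []
    for strat in strategies:
        x = table[(table.strategy == strat) & (table.region == sd.M1)].sort_values(
            "participant").pct_activated.to_numpy()
        y = table[(table.strategy == strat) & (table.region == sd.DLPFC)].sort_values(
            "participant").pct_activated.to_numpy()
        try:
            if cfg.activation_test == "wilcoxon":
                res = st.wilcoxon_signed_rank(x, y)
            else:
                res = st.paired_t(x, y)
            stat_rows.append({"comparison": f"pct_activated_m1_vs_dlpfc[{strat}]",
                              "test": res.test, "statistic": res.statistic,
                              "df": res.df if res.df is not None else "",
                              "p_raw": res.p_two_sided, "n": res.n})
            pvals.append(res.p_two_sided)
        except ValueError as exc:   # identical pairs (e.g. exact matching)
            stat_rows.append({"comparison": f"pct_activated_m1_vs_dlpfc[{strat}]",
                              "test": cfg.activation_test, "statistic": np.nan,
                              "df": "", "p_raw": np.nan, "n": len(x)})
            log.info("dosing stage: %s comparison degenerate (%s)", strat, exc)
    adj = st.holm_adjust([p for p in pvals])
    it = iter(adj)
    for row in stat_rows:
        row["p_holm"] = next(it) if np.isfinite(row["p_raw"]) else np.nan

    if cfg.use_table1_rmts:
        t1 = sd.load_table1_fixture()
        res = st.paired_t([r.depth_m1_mm for r in t1], [r.depth_dlpfc_mm for r in t1])
        stat_rows.append({"comparison": "scalp_to_cortex_depth_m1_vs_dlpfc[table1]",
                          "test": res.test, "statistic": res.statistic, "df": res.df,
                          "p_raw": res.p_two_sided, "p_holm": res.p_two_sided,
                          "n": res.n})
    stats_df = pd.DataFrame(stat_rows)
    stats_df.to_csv(outdir / "stats.csv", index=False, float_format=FLOAT_FMT)

    # rTMS scenarios on the designated participant, DLPFC target, no synapse
    rtms_pid = cfg.rtms_participant or cohort[0].id
    part = next(p for p in cohort if p.id == rtms_pid)
    head = hm.build_head(part.head_params, cfg.mesh_edge_mm)
    targets = _targets_and_placements(head, cfg)
    region = sd.DLPFC
    plc = hm.place_coil(head, targets[region], 45.0, cfg.coil_standoff_mm)
    surf = head.surfaces[region]
    rc = hm.nearest_vertex(surf, plc.center)
    cells = pop.place_cells(head, region, rc, cfg.population_roi_mm,
                            cfg.cells_per_region, seed=cfg.cell_seed + part.seed)
    tmap = maps[(part.id, region, False)]
    coil = ef.default_coil()
    tree = nr.discretize(nr.generate_reduced_l5_morphology(seed=1))
    bio = nr.default_biophys()
    wf = nr.biphasic_waveform()
    intensity = ds.dose_rmt(part.rmt_pct_mso, cfg.rmt_fraction)
    chosen = ds.select_scenario_cells(tmap, intensity)
    scen_summary = []
    for name, idx in chosen.items():
        cell = cells[idx]
        placed = pop._placed_tree(tree, cell)
        sampler = lambda pts: ef.total_field(coil, plc, head, pts,
                                             dIdt=ef.DIDT_PER_PCT_MSO,
                                             L=cfg.expansion_order)
        psi = nr.quasipotentials(placed, sampler)
        trace = ds.run_rtms_protocol(placed, bio, psi, wf, intensity,
                                     n_pulses=cfg.rtms_n_pulses,
                                     freq_hz=cfg.rtms_freq_hz)
        nr.save_trace_csv(trace, outdir / f"rtms_trace_{name}.csv")
        scen_summary.append({
            "scenario": name, "participant": part.id, "region": region,
            "intensity_pct_mso": intensity, "cell_index": idx,
            "threshold_pct_mso": (int(tmap.threshold_pct_mso[idx])
                                  if not tmap.censored[idx] else ""),
            "ap_count": len(trace.ap_times_ms),
            "time_locked_count": int(trace.time_locked_flags.sum()),
            "ca_event_count": len(trace.ca_event_times_ms),
        })
        log.info("dosing stage: rTMS scenario %s cell %d done", name, idx)
    pd.DataFrame(scen_summary).to_csv(outdir / "rtms_scenarios.csv", index=False,
                                      float_format=FLOAT_FMT)
    _update_manifest(outdir, "dosing", {
        "strategies": list(strategies), "rtms_participant": rtms_pid,
        "files": ["dose_results.csv", "stats.csv", "rtms_scenarios.csv"]})
    return {"dose_results": table, "stats": stats_df,
            "rtms": pd.DataFrame(scen_summary)}


def run_all(cfg: RunConfig, outdir: Path, resume: bool = False) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, outdir / "config.yaml")
    run_cohort_stage(cfg, outdir)
    run_efield_stage(cfg, outdir)
    run_threshold_stage(cfg, outdir, resume=resume)
    out = run_dosing_stage(cfg, outdir)
    write_report(cfg, outdir)
    return out


def write_report(cfg: RunConfig, outdir: Path) -> dict:
    """Aggregate the stage outputs into one JSON summary."""
    outdir = Path(outdir)
    report = {}
    ef_file = outdir / "efield_roi_stats.csv"
    if ef_file.exists():
        efd = pd.read_csv(ef_file)
        at45 = efd[efd.angle_deg == 45.0]
        report["roi_mean_e_total_at_45deg_1pct"] = {
            region: float(at45[at45.region == region].mean_e_total.mean())
            for region in at45.region.unique()
        }
    thr_file = outdir / "thresholds.csv"
    if thr_file.exists():
        thr = pd.read_csv(thr_file, keep_default_na=False)
        summ = {}
        for (region, wsyn), g in thr.groupby(["region", "with_synapse"]):
            v = pd.to_numeric(g.loc[~g.censored.astype(bool), "threshold_pct_mso"],
                              errors="coerce").dropna()
            summ[f"{region}_{'syn' if wsyn else 'nosyn'}"] = {
                "median_threshold": float(v.median()) if len(v) else None,
                "fraction_censored": float(g.censored.astype(bool).mean()),
            }
        report["thresholds"] = summ
    dose_file = outdir / "dose_results.csv"
    if dose_file.exists():
        d = pd.read_csv(dose_file)
        report["mean_pct_activated"] = {
            f"{r.strategy}_{r.region}": float(r.pct_activated)
            for _, r in d.groupby(["strategy", "region"]).pct_activated.mean()
                         .reset_index().iterrows()
        }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
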