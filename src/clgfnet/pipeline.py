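"""End-to-end orchestration: cohort -> spectra -> switching -> PLV ->
feedback networks -> motif census -> group report (+ optional circuit
sweep), with a single global seed fanned out per stage and subject.

The run configuration defaults to the study conditions used throughout
the package (wavelet width 7, 1000/200 ms PLV windows, four-window
network consistency, 13-30 / 30-80 Hz bands, alpha = 0.05).  A config
file is a YAML mapping with the same structure as :class:`RunConfig`;
unknown keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortSpec, make_cohort
from .feedback import consistent_network
from .motifs import classify_edges, count_clgf, group_motif_stats
from .spectral import band_power, mean_spectrum, morlet_tf
from .stats import group_report
from .switching import detect_switching, group_switching_stats
from .synchrony import bandpass, hilbert_phase, plv, plv_topography
from .wilson_cowan import sweep_local_coupling

log = logging.getLogger("clgfnet")

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results/run"
    # stage toggles
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "spectral", "switching", "plv", "infer", "motifs", "report"])
    # cohort spec overrides (see CohortSpec for the full parameter set)
    cohort: dict = field(default_factory=dict)
    # spectral
    wavelet_width: float = 7.0
    # synchrony
    plv_window_ms: float = 1000.0
    plv_slide_ms: float = 200.0
    topography_thresholds: tuple[float, float] = (0.01, 0.001)
    # feedback inference
    ir_max_lag_ms: float = 50.0
    ir_surrogates: int = 100
    n_windows: int = 4
    # Wilson-Cowan sweep
    sweep_grid: list[float] = field(default_factory=lambda: list(np.arange(0.0, 4.01, 0.5)))
    sweep_global_strength: float = 2.6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        cohort_keys = {f.name for f in dataclasses.fields(CohortSpec)}
        bad = set(raw.get("cohort", {})) - cohort_keys
        if bad:
            raise KeyError(f"unknown cohort config key(s): {sorted(bad)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep_grid"] = [float(x) for x in d["sweep_grid"]]
        d["topography_thresholds"] = list(d["topography_thresholds"])
        return d


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def run(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Execute the configured stages; returns the run directory.

    Deterministic given (config, seed).  Every stage logs its timing; a
    stage failure aborts with the stage name in the exception message.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__ as _version

    provenance = {"version": _version, "config": config.to_dict(),
                  "config_hash": _config_hash(config), "timings_s": {}}
    state: dict = {}
    for stage in config.stages:
        fn = _STAGES.get(stage)
        if fn is None:
            raise KeyError(f"unknown stage {stage!r}; choose from {sorted(_STAGES)}")
        t0 = time.perf_counter()
        log.info("stage %s ...", stage)
        try:
            fn(config, state, out)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        provenance["timings_s"][stage] = round(time.perf_counter() - t0, 3)
    if "cohort" in state:
        state["cohort"].table.to_csv(out / "cohort_table.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out


# --------------------------------------------------------------------- stages

def _stage_simulate(cfg: RunConfig, state: dict, out: Path) -> None:
    spec = CohortSpec(**{**cfg.cohort, "seed": cfg.seed})
    cohort: Cohort = make_cohort(spec)
    state["cohort"] = cohort
    topo_dir = out / "topologies"
    topo_dir.mkdir(exist_ok=True)
    for s in cohort.subjects:
        s.topology.to_text(topo_dir / f"{s.subject_id}_truth.tsv")


def _require_cohort(state: dict) -> Cohort:
    if "cohort" not in state:
        raise RuntimeError("run the 'simulate' stage first")
    return state["cohort"]


def _stage_spectral(cfg: RunConfig, state: dict, out: Path) -> None:
    cohort = _require_cohort(state)
    spectra, beta, gamma, bps = [], [], [], {}
    for s in cohort.subjects:
        tf = morlet_tf(s.signals, width=cfg.wavelet_width)
        bp = band_power(tf)
        bps[s.subject_id] = bp
        beta.append(bp.beta_scalar)
        gamma.append(bp.gamma_scalar)
        spec = mean_spectrum(tf)
        spec["subject_id"] = s.subject_id
        spectra.append(spec)
    cohort.table["beta_power"] = beta
    cohort.table["gamma_power"] = gamma
    state["band_powers"] = bps
    pd.concat(spectra).to_csv(out / "mean_spectra.csv", index=False)


def _stage_switching(cfg: RunConfig, state: dict, out: Path) -> None:
    cohort = _require_cohort(state)
    if "band_powers" not in state:
        raise RuntimeError("run the 'spectral' stage first")
    traces = [detect_switching(state["band_powers"][s.subject_id])
              for s in cohort.subjects]
    cohort.table["switch_duration_ms"] = [t.duration for t in traces]
    cohort.table["switch_events"] = [t.n_events for t in traces]
    stats = group_switching_stats(traces, [s.group for s in cohort.subjects])
    (out / "switching_stats.json").write_text(json.dumps(stats, indent=2))


def _stage_plv(cfg: RunConfig, state: dict, out: Path) -> None:
    cohort = _require_cohort(state)
    results = {"beta": [], "gamma": []}
    for s in cohort.subjects:
        for band, lims in (("beta", (13.0, 30.0)), ("gamma", (30.0, 80.0))):
            ph = hilbert_phase(bandpass(s.signals, lims), band=band)
            results[band].append(plv(ph, cfg.plv_window_ms, cfg.plv_slide_ms))
    for band in results:
        cohort.table[f"{band}_plv"] = [r.subject_mean for r in results[band]]
    groups = np.array([s.group for s in cohort.subjects])
    edges = []
    for thr in cfg.topography_thresholds:
        df = plv_topography(
            [r for r, g in zip(results["beta"], groups) if g == "control"],
            [r for r, g in zip(results["beta"], groups) if g == "patient"],
            thr, labels=("control", "patient"))
        df["threshold"] = thr
        edges.append(df)
    pd.concat(edges).to_csv(out / "plv_topography_edges.csv", index=False)
    state["plv"] = results


def _stage_infer(cfg: RunConfig, state: dict, out: Path) -> None:
    cohort = _require_cohort(state)
    rng_children = np.random.SeedSequence(cfg.seed + 7_777).spawn(
        len(cohort.subjects))
    nets = {}
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    for s, child in zip(cohort.subjects, rng_children):
        net = consistent_network(
            s.signals, n_windows=cfg.n_windows,
            max_lag_ms=cfg.ir_max_lag_ms, n_surrogates=cfg.ir_surrogates,
            rng=np.random.default_rng(child))
        nets[s.subject_id] = net
        net.to_text(net_dir / f"{s.subject_id}_network.tsv")
    state["networks"] = nets


def _stage_motifs(cfg: RunConfig, state: dict, out: Path) -> None:
    cohort = _require_cohort(state)
    if "networks" not in state:
        raise RuntimeError("run the 'infer' stage first")
    censuses = {}
    for s in cohort.subjects:
        labeled = classify_edges(state["networks"][s.subject_id],
                                 s.topology.region_map)
        censuses[s.subject_id] = count_clgf(labeled)
    for key in ("n_pos_fb_total", "n_pos_fb_local", "n_pos_fb_global", "n_clgf"):
        cohort.table[key] = [censuses[s.subject_id].as_row()[key]
                             for s in cohort.subjects]
    stats = group_motif_stats(
        [censuses[s.subject_id] for s in cohort.subjects if s.group == "control"],
        [censuses[s.subject_id] for s in cohort.subjects if s.group == "patient"])
    (out / "motif_stats.json").write_text(json.dumps(stats, indent=2))


def _stage_sweep(cfg: RunConfig, state: dict, out: Path) -> None:
    df = sweep_local_coupling(np.asarray(cfg.sweep_grid),
                              w_global=cfg.sweep_global_strength)
    df.to_csv(out / "wc_sweep.csv", index=False)
    (out / "wc_sweep_crossover.json").write_text(
        json.dumps({"crossover_strength": df.attrs.get("crossover")}))


def _stage_report(cfg: RunConfig, state: dict, out: Path) -> None:
    cohort = _require_cohort(state)
    measures = [m for m in (
        "beta_power", "gamma_power", "beta_plv", "gamma_plv",
        "switch_duration_ms", "switch_events",
        "n_pos_fb_total", "n_pos_fb_local", "n_pos_fb_global", "n_clgf",
    ) if m in cohort.table.columns]
    report = group_report(cohort.table, measures=measures)
    (out / "group_report.json").write_text(json.dumps(report, indent=2))
    lines = [f"clgfnet group report ({len(cohort.subjects)} subjects)"]
    for m, d in report["measures"].items():
        lines.append(
            f"  {m:20s} control {d['control']['mean']:10.4f} +/- {d['control']['se']:8.4f}"
            f"  patient {d['patient']['mean']:10.4f} +/- {d['patient']['se']:8.4f}"
            f"  t={d['t']:7.3f} p={d['p']:.4g}")
    for s, d in report.get("correlations", {}).items():
        lines.append(f"  r(n_clgf, {s}) = {d.get('r', float('nan')):.4f}"
                     f"  p={d.get('p', float('nan')):.4g}")
    (out / "group_report.txt").write_text("\n".join(lines) + "\n")


_STAGES = {
    "simulate": _stage_simulate,
    "spectral": _stage_spectral,
    "switching": _stage_switching,
    "plv": _stage_plv,
    "infer": _stage_infer,
    "motifs": _stage_motifs,
    "sweep": _stage_sweep,
    "report": _stage_report,
}
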