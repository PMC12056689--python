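"""End-to-end orchestration of the analysis stages.

A run config (YAML mapping) names the materials and the input files for
whichever stages apply; :func:`run_pipeline` executes the stages in
dependency order, writes one JSON report plus a run manifest to the
output directory, and returns the report.  Stages are independent: a
config may declare any subset.

Config schema (all sections optional except ``materials`` when a stage
needs specs)::

    materials:
      silicas:    [{name, surface_area, pore_diameter, pore_volume, particle_diameter}, ...]
      substances: [{name, molar_mass, glass_density, cp_glass, cp_liquid, tg_onset}, ...]
    loading:
      pairs: [{silica, substance, ms_fraction_full_rigid: optional}, ...]
    fractions:
      observations: <csv path>
      pure_delta_cp: <J/(g·K)>
      pure_cc_enthalpy: <J/g>
    crr:
      thermogram: <csv path>
      substance: <name>
      search_window: [lo_C, hi_C]
    bds:
      spectra: [<csv path>, ...]
      n_processes: 1
      fit_vft: true
      fit_kww: true
    kinetics:
      traces: [<csv path>, ...]
      eps0 / eps_inf: (bds-kind traces only)
"""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .bds import fit_hn, fit_kww_beta, fit_vft, normalize_loss, tau_alpha
from .crr import crr_size_from_transition
from .dsc import detect_glass_transition
from .fractions import decompose, extrapolate_full_rigid_load
from .io import (
    RunManifest,
    read_observations_csv,
    read_spectrum_csv,
    read_trace_csv,
    read_thermogram_csv,
)
from .kinetics import epsilon_n, fit_avrami, t_half, t_half_empirical, terminal_conversion
from .loading import loading_report
from .materials import (
    BUILTIN_SILICAS,
    BUILTIN_SUBSTANCES,
    ConfigError,
    GlassSubstanceSpec,
    MesoporousSilicaSpec,
)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the manifest records the failure point."""


def _materials(cfg: dict):
    silicas = dict(BUILTIN_SILICAS)
    substances = dict(BUILTIN_SUBSTANCES)
    mat = cfg.get("materials") or {}
    for entry in mat.get("silicas") or []:
        spec = MesoporousSilicaSpec(**entry)
        silicas[spec.name] = spec
    for entry in mat.get("substances") or []:
        spec = GlassSubstanceSpec(**entry)
        substances[spec.name] = spec
    return silicas, substances


def _stage_loading(cfg, silicas, substances):
    out = []
    for pair in cfg.get("pairs") or []:
        sil = silicas.get(pair["silica"])
        sub = substances.get(pair["substance"])
        if sil is None or sub is None:
            raise ConfigError(f"unknown silica/substance in loading pair: {pair}")
        rep = loading_report(sil, sub, pair.get("ms_fraction_full_rigid"))
        out.append(rep.as_dict())
    return out


def _stage_fractions(cfg, base: Path):
    obs = read_observations_csv(base / cfg["observations"])
    dcp0 = float(cfg["pure_delta_cp"])
    dh0 = float(cfg["pure_cc_enthalpy"])
    profiles = [asdict(decompose(o, dcp0, dh0)) | {"ms_mass_fraction": o.ms_mass_fraction}
                for o in obs]
    result = {"profiles": profiles}
    try:
        result["full_rigid_extrapolation"] = asdict(extrapolate_full_rigid_load(obs))
    except ValueError as exc:
        result["full_rigid_extrapolation"] = {"error": str(exc)}
    return result


def _stage_crr(cfg, base: Path, substances):
    tg = read_thermogram_csv(base / cfg["thermogram"])
    sub = substances[cfg["substance"]]
    window = tuple(cfg["search_window"])
    gt = detect_glass_transition(tg, window)
    return {
        "glass_transition": asdict(gt),
        "crr_nm": crr_size_from_transition(gt, sub),
    }


def _stage_bds(cfg, base: Path, seed: int):
    n_proc = int(cfg.get("n_processes", 1))
    results, tau_pairs = [], []
    for path in cfg.get("spectra") or []:
        spec = read_spectrum_csv(base / path)
        fit = fit_hn(spec, n_processes=n_proc, seed=seed)
        taus = [tau_alpha(p) for p in fit.processes]
        entry = {
            "path": str(path),
            "temperature_K": spec.temperature,
            "processes": [asdict(p) for p in fit.processes],
            "eps_inf": fit.eps_inf,
            "sigma_dc": fit.sigma_dc,
            "residual": fit.residual,
            "tau_alpha_s": taus,
        }
        if cfg.get("fit_kww", True):
            norm = normalize_loss(spec, fit)
            if not norm.boundary_peak:
                kww = fit_kww_beta(norm)
                entry["kww"] = asdict(kww)
        results.append(entry)
        tau_pairs.append((spec.temperature, taus[0]))
    out = {"spectra": results}
    if cfg.get("fit_vft", True) and len(tau_pairs) >= 3:
        out["vft"] = asdict(fit_vft(tau_pairs))
    return out


def _stage_kinetics(cfg, base: Path):
    results = []
    for path in cfg.get("traces") or []:
        trace = read_trace_csv(base / path)
        if trace.kind == "bds":
            eps0 = float(cfg.get("eps0", trace.observable[0]))
            eps_inf = float(cfg["eps_inf"])
            conv = epsilon_n(eps0, eps_inf, trace.observable)
            trace = type(trace)(
                time=trace.time, observable=conv, kind="bds",
                temperature=trace.temperature,
            )
        fit = fit_avrami(trace, fit_plateau=bool(cfg.get("fit_plateau", False)))
        plateau_mean, settled = terminal_conversion(trace)
        entry = {
            "path": str(path),
            "avrami": asdict(fit),
            "rate_constant_per_s": fit.rate_constant_per_s,
            "terminal_conversion": plateau_mean,
            "plateaued": settled,
        }
        try:
            entry["t_half_analytic_s"] = t_half(fit)
            entry["t_half_empirical_s"] = t_half_empirical(trace)
        except ValueError as exc:
            entry["t_half_error"] = str(exc)
        results.append(entry)
    return {"traces": results}


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    seed: int = 0,
    base_dir: Optional[Path] = None,
) -> dict:
    """Run every configured stage; write report + manifest to ``out_dir``.

    ``config`` is a mapping or a path to a YAML file.  Relative input
    paths resolve against the config file's directory (or ``base_dir``).
    On a stage failure the manifest records the failing stage and a
    :class:`PipelineError` is raised; prior stage outputs are retained.
    """
    config_path = None
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        with open(config_path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        base = config_path.parent
    else:
        cfg = dict(config)
        base = Path(".")
    if base_dir is not None:
        base = Path(base_dir)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    silicas, substances = _materials(cfg)
    report: dict = {"seed": seed, "version": __version__}
    inputs: dict = {}
    stage = None
    try:
        if "loading" in cfg:
            stage = "loading"
            report["loading"] = _stage_loading(cfg["loading"], silicas, substances)
        if "fractions" in cfg:
            stage = "fractions"
            inputs[str(cfg["fractions"]["observations"])] = RunManifest.hash_file(
                base / cfg["fractions"]["observations"])
            report["fractions"] = _stage_fractions(cfg["fractions"], base)
        if "crr" in cfg:
            stage = "crr"
            inputs[str(cfg["crr"]["thermogram"])] = RunManifest.hash_file(
                base / cfg["crr"]["thermogram"])
            report["crr"] = _stage_crr(cfg["crr"], base, substances)
        if "bds" in cfg:
            stage = "bds"
            for p in cfg["bds"].get("spectra") or []:
                inputs[str(p)] = RunManifest.hash_file(base / p)
            report["bds"] = _stage_bds(cfg["bds"], base, seed)
        if "kinetics" in cfg:
            stage = "kinetics"
            for p in cfg["kinetics"].get("traces") or []:
                inputs[str(p)] = RunManifest.hash_file(base / p)
            report["kinetics"] = _stage_kinetics(cfg["kinetics"], base)
        status = "ok"
    except Exception as exc:
        status = f"failed at stage '{stage}': {exc}"
        raise PipelineError(status) from exc
    finally:
        with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        RunManifest(
            command="run",
            config=str(config_path) if config_path else None,
            inputs=inputs,
            seed=seed,
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
            status=status,
        ).write(out_dir / "manifest.json")
    return report
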