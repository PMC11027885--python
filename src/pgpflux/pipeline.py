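"""Config-driven orchestration: generate -> fit -> compare -> report.

A run is described by one YAML document (stages, seeds, paths,
generator and fit settings).  Stages execute in order, each writing its
outputs under ``out_dir``; a manifest records inputs, outputs, seeds,
package version and wall time.  Re-running a completed pipeline with an
unchanged config is a no-op unless forced.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import yaml

from . import __version__, reference
from .atpase import fit_atpase, select_kinetic_model
from .fitting import FitSpec, compare_topologies, global_fit, rate_table
from .synth import (ATPaseDataset, SensorgramNoiseModel, SensorgramSet,
                    generate_atpase_dataset, generate_sensorgram_set,
                    make_paired_condition_set)
from .transport import ObservableParams, ReactionRates
from .assay import transport_ratio

__all__ = ["RunConfig", "run_pipeline", "ConfigError"]

log = logging.getLogger("pgpflux")

KNOWN_STAGES = ("simulate-atpase", "fit-atpase", "simulate-spr",
                "fit-transport", "compare-models", "transport-ratio")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: Path
    seed: int
    stages: list[str]
    sections: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        stages = raw.get("stages", [])
        if not isinstance(stages, list):
            raise ConfigError("stages must be a list")
        for s in stages:
            if s not in KNOWN_STAGES:
                raise ConfigError(f"unknown stage {s!r}; known: {KNOWN_STAGES}")
        if stages and "seed" not in raw:
            raise ConfigError("a seed is mandatory for stochastic pipelines")
        # every stage must be able to find its inputs
        produced = set()
        for s in stages:
            needs = _STAGE_INPUTS.get(s, ())
            sect = raw.get(s.replace("-", "_"), {}) or {}
            for need in needs:
                if need not in produced and "data" not in sect and "data_atp" not in sect:
                    raise ConfigError(
                        f"stage {s!r} needs {need!r} from an earlier stage "
                        "or an explicit data path in its section")
            produced.add(s)
        sections = {k: (v or {}) for k, v in raw.items()
                    if k not in ("out_dir", "seed", "stages")}
        return cls(out_dir=Path(raw.get("out_dir", "pgpflux_run")),
                   seed=int(raw.get("seed", 0)), stages=list(stages),
                   sections=sections)


_STAGE_INPUTS = {
    "fit-atpase": ("simulate-atpase",),
    "fit-transport": ("simulate-spr",),
    "compare-models": ("simulate-spr",),
    "transport-ratio": ("simulate-spr",),
}


def _rates_by_name(name: str) -> ReactionRates:
    if name == "demo":
        return reference.DEMO_RATES
    if name == "discrimination":
        return reference.DISCRIMINATION_RATES
    if name in reference.VACUUM_RATES:
        return reference.VACUUM_RATES[name]
    raise ConfigError(f"unknown rate set {name!r}")


def _fit_spec(section: dict, topology: str, seed: int) -> FitSpec:
    kwargs: dict[str, Any] = {"topology": topology, "seed": seed}
    for key in ("optimizer", "population", "generations", "refine",
                "fit_stride", "rate_convention"):
        if key in section:
            kwargs[key] = section[key]
    if "free_parameters" in section:
        kwargs["free_parameters"] = tuple(section["free_parameters"])
    if "fit_window" in section:
        kwargs["fit_window"] = tuple(section["fit_window"])
    if "baseline_rates" in section:
        kwargs["baseline_rates"] = _rates_by_name(section["baseline_rates"])
    return FitSpec(**kwargs)


# -- stage implementations ---------------------------------------------------


def _stage_simulate_atpase(cfg: RunConfig, ctx: dict) -> dict:
    sect = cfg.sections.get("simulate_atpase", {})
    drug = sect.get("drug", "methadone")
    params = reference.ATPASE_PARAMS[drug]
    model = sect.get("model", params.model_kind)
    conc = sect.get("concentrations",
                    [0.0] + [500.0 / 2**k for k in reversed(range(11))])
    ds = generate_atpase_dataset(params, model, np.sort(np.asarray(conc, float)),
                                 noise_sd=float(sect.get("noise_sd",
                                                         reference.ATPASE_NOISE_SD)),
                                 replicates=int(sect.get("replicates", 1)),
                                 seed=cfg.seed, drug_label=drug)
    path = cfg.out_dir / f"atpase_{drug}.csv"
    ds.to_csv(path)
    ctx["atpase_csv"] = path
    return {"outputs": [str(path), str(path.with_suffix(".json"))],
            "drug": drug, "model": model}


def _stage_fit_atpase(cfg: RunConfig, ctx: dict) -> dict:
    sect = cfg.sections.get("fit_atpase", {})
    path = Path(sect.get("data", ctx.get("atpase_csv")))
    ds = ATPaseDataset.from_csv(path)
    sel = select_kinetic_model(ds, n_starts=int(sect.get("n_starts", 16)),
                               seed=cfg.seed)
    winner = sel.biphasic if sel.selected == "biphasic" else sel.monophasic
    out_json = cfg.out_dir / f"atpase_fit_{ds.drug_label}.json"
    out_json.write_text(json.dumps({"selected": sel.selected,
                                    "delta_aicc": sel.delta_aicc,
                                    "fit": winner.as_dict()}, indent=2))
    row = winner.as_dict()
    tsv = cfg.out_dir / "atpase_fits.tsv"
    header = "drug\tmodel\tvmax\tkm\tki\tvbasal\trss\taicc\n"
    line = (f"{ds.drug_label}\t{row['model']}\t{row['vmax']:.6g}\t{row['km']:.6g}\t"
            f"{'' if row['ki'] is None else format(row['ki'], '.6g')}\t"
            f"{row['vbasal']:.6g}\t{row['rss']:.6g}\t{row['aicc']:.6g}\n")
    mode = "a" if tsv.exists() else "w"
    with tsv.open(mode) as fh:
        if mode == "w":
            fh.write(header)
        fh.write(line)
    return {"outputs": [str(out_json), str(tsv)], "selected": sel.selected}


def _stage_simulate_spr(cfg: RunConfig, ctx: dict) -> dict:
    sect = cfg.sections.get("simulate_spr", {})
    rates = _rates_by_name(sect.get("rates", "demo"))
    topology = sect.get("topology", "vacuum")
    conc = sect.get("concentrations_um", [500.0, 250.0, 125.0, 62.5, 31.25])
    obs = ObservableParams(k=float(sect.get("observable_k", 1e6)),
                           c=float(sect.get("observable_c", 0.0)))
    noise = SensorgramNoiseModel(sigma=float(sect.get("noise_sigma", 0.0)),
                                 drift_per_second=float(sect.get("drift", 0.0)),
                                 seed=cfg.seed)
    dt = float(sect.get("dt", 0.5))
    outputs = []
    for active, tag in ((True, "atp"), (False, "apo")):
        s = make_paired_condition_set(rates, transport_active=active,
                                      topology=topology, concentrations_um=conc,
                                      observable=obs, noise=noise, dt=dt,
                                      phases=reference.DEFAULT_PHASES)
        path = cfg.out_dir / f"sensorgrams_{tag}.csv"
        s.to_csv(path)
        ctx[f"spr_{tag}_csv"] = path
        outputs += [str(path), str(path.with_suffix(".json"))]
    return {"outputs": outputs, "topology": topology}


def _stage_fit_transport(cfg: RunConfig, ctx: dict) -> dict:
    sect = cfg.sections.get("fit_transport", {})
    path = Path(sect.get("data", ctx.get("spr_atp_csv")))
    data = SensorgramSet.from_csv(path)
    spec = _fit_spec(sect, sect.get("topology", "vacuum"), cfg.seed)
    result = global_fit(data, spec)
    out_json = cfg.out_dir / "transport_fit.json"
    out_json.write_text(json.dumps(result.as_dict(), indent=2))
    resid = cfg.out_dir / "transport_fit_residuals.csv"
    import pandas as pd
    pd.DataFrame(result.residual_traces.T, index=result.residual_times,
                 columns=[f"resid_{c:g}uM" for c in data.concentrations_um]
                 ).rename_axis("time_s").to_csv(resid)
    table = cfg.out_dir / "transport_fit_rates.tsv"
    rate_table(result, force=True).to_csv(table, sep="\t", index=False)
    ctx["transport_fit_json"] = out_json
    return {"outputs": [str(out_json), str(resid), str(table)],
            "rss": result.rss, "aicc": result.aicc}


def _stage_compare_models(cfg: RunConfig, ctx: dict) -> dict:
    sect = cfg.sections.get("compare_models", {})
    path = Path(sect.get("data", ctx.get("spr_atp_csv")))
    data = SensorgramSet.from_csv(path)
    cmp = compare_topologies(data,
                             _fit_spec(sect, "vacuum", cfg.seed),
                             _fit_spec(sect, "flippase", cfg.seed))
    out = cfg.out_dir / "model_comparison.json"
    out.write_text(json.dumps({
        "preferred": cmp.preferred, "delta_aicc": cmp.delta_aicc,
        "rss_relative_difference": cmp.rss_relative_difference,
        "vacuum": cmp.vacuum.as_dict(), "flippase": cmp.flippase.as_dict(),
    }, indent=2))
    return {"outputs": [str(out)], "preferred": cmp.preferred}


def _stage_transport_ratio(cfg: RunConfig, ctx: dict) -> dict:
    sect = cfg.sections.get("transport_ratio", {})
    atp = SensorgramSet.from_csv(Path(sect.get("data_atp", ctx.get("spr_atp_csv"))))
    apo = SensorgramSet.from_csv(Path(sect.get("data_apo", ctx.get("spr_apo_csv"))))
    tr = transport_ratio(atp, apo, method=sect.get("method", "mean-of-ratios"),
                         drug_label=sect.get("drug", "synthetic"))
    out = cfg.out_dir / "transport_ratio.tsv"
    out.write_text("drug\tratio\tsd\tn\n"
                   f"{tr.drug_label}\t{tr.ratio:.6g}\t{tr.sd:.6g}\t{tr.n}\n")
    return {"outputs": [str(out)], "ratio": tr.ratio}


_STAGE_FN: dict[str, Callable[[RunConfig, dict], dict]] = {
    "simulate-atpase": _stage_simulate_atpase,
    "fit-atpase": _stage_fit_atpase,
    "simulate-spr": _stage_simulate_spr,
    "fit-transport": _stage_fit_transport,
    "compare-models": _stage_compare_models,
    "transport-ratio": _stage_transport_ratio,
}


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute the configured stages in order and write a manifest.

    When a manifest from an identical config already exists in
    ``out_dir`` and all its outputs are present, the run is skipped
    unless ``force``.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = config.out_dir / "manifest.json"
    fingerprint = {"seed": config.seed, "stages": config.stages,
                   "sections": config.sections, "version": __version__}
    if manifest_path.exists() and not force:
        old = json.loads(manifest_path.read_text())
        if old.get("config") == json.loads(json.dumps(fingerprint)) and all(
                Path(p).exists() for st in old.get("stages", [])
                for p in st.get("outputs", [])):
            log.info("pipeline up to date; skipping (use force to re-run)")
            old["skipped"] = True
            return old

    manifest: dict = {"config": fingerprint, "stages": [], "skipped": False}
    ctx: dict = {}
    t_start = time.time()
    for stage in config.stages:
        log.info("running stage %s", stage)
        t0 = time.time()
        try:
            info = _STAGE_FN[stage](config, ctx)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        info.update({"stage": stage, "wall_time_s": round(time.time() - t0, 3)})
        manifest["stages"].append(info)
    manifest["wall_time_s"] = round(time.time() - t_start, 3)
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
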