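"""YAML configuration loading for the command-line pipeline.

A single config file carries acquisition metadata, contrast-agent
properties, fitting options, reconstruction knobs and simulation settings.
All keys are optional; omitted ones fall back to the protocol defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .kinetics import FitConfig, KineticParams
from .phantom import PhantomConfig
from .reconstruction import ReconConfig
from .signal_model import AcquisitionParams, ContrastAgentSpec
from .simulation import (ACQ_HS, ACQ_HT, NL_HS_DEFAULT, NL_HT_DEFAULT,
                         NoiseSpec, PopulationVIFModel, SamplingScheme,
                         SimulationConfig)

__all__ = ["load_config", "PipelineConfig", "config_hash"]


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    acq_ht: AcquisitionParams = ACQ_HT
    acq_hs: AcquisitionParams = ACQ_HS
    agent: ContrastAgentSpec = ContrastAgentSpec()
    fit: FitConfig = FitConfig()
    recon: ReconConfig = ReconConfig()
    simulation: SimulationConfig = SimulationConfig()
    phantom: PhantomConfig = PhantomConfig()
    n_select_vif: int = 10
    first_pass_window_s: float = 60.0


def _build_noise(defaults: NoiseSpec, section: dict) -> NoiseSpec:
    section = dict(section)
    if "nl" in section and "baseline_sd" not in section:
        # an overridden level invalidates the default baseline SD
        section["baseline_sd"] = None
    return _build(NoiseSpec, defaults, section)


def _build(cls, defaults, section: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return dataclasses.replace(defaults, **section)


def load_config(path=None) -> PipelineConfig:
    """Load a pipeline configuration from YAML (None -> all defaults).

    Recognized top-level sections: ``acq_ht``, ``acq_hs``, ``agent``,
    ``fit``, ``recon``, ``simulation`` (with optional ``truth``, ``scheme``,
    ``vif``, ``noise_ht``, ``noise_hs`` subsections), ``phantom`` and the
    scalar keys ``n_select_vif`` / ``first_pass_window_s``.
    """
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    base = PipelineConfig()
    kw = {}
    if "acq_ht" in raw:
        kw["acq_ht"] = _build(AcquisitionParams, base.acq_ht, raw.pop("acq_ht"))
    if "acq_hs" in raw:
        kw["acq_hs"] = _build(AcquisitionParams, base.acq_hs, raw.pop("acq_hs"))
    if "agent" in raw:
        kw["agent"] = _build(ContrastAgentSpec, base.agent, raw.pop("agent"))
    if "fit" in raw:
        sec = raw.pop("fit")
        for key in ("ktrans_bounds", "vp_bounds", "ve_bounds", "bat_grid_s"):
            if key in sec and sec[key] is not None:
                sec[key] = tuple(sec[key])
        kw["fit"] = _build(FitConfig, base.fit, sec)
    if "recon" in raw:
        kw["recon"] = _build(ReconConfig, base.recon, raw.pop("recon"))
    if "simulation" in raw:
        sec = dict(raw.pop("simulation"))
        sim_kw = {}
        if "truth" in sec:
            sim_kw["truth"] = _build(KineticParams, base.simulation.truth, sec.pop("truth"))
        if "scheme" in sec:
            sim_kw["scheme"] = _build(SamplingScheme, base.simulation.scheme, sec.pop("scheme"))
        if "vif" in sec:
            sim_kw["vif_model"] = _build(PopulationVIFModel, base.simulation.vif_model, sec.pop("vif"))
        if "noise_ht" in sec:
            sim_kw["noise_ht"] = _build_noise(base.simulation.noise_ht, sec.pop("noise_ht"))
        if "noise_hs" in sec:
            sim_kw["noise_hs"] = _build_noise(base.simulation.noise_hs, sec.pop("noise_hs"))
        sim_kw.update(sec)
        kw["simulation"] = dataclasses.replace(base.simulation, **sim_kw)
    if "phantom" in raw:
        sec = dict(raw.pop("phantom"))
        ph_kw = {}
        if "tumour_params" in sec:
            ph_kw["tumour_params"] = _build(KineticParams, base.phantom.tumour_params,
                                            sec.pop("tumour_params"))
        if "scheme" in sec:
            ph_kw["scheme"] = _build(SamplingScheme, base.phantom.scheme, sec.pop("scheme"))
        if "vif" in sec:
            ph_kw["vif_model"] = _build(PopulationVIFModel, base.phantom.vif_model,
                                        sec.pop("vif"))
        for key in ("tumour_center_frac", "tumour_radii_frac", "vessel_center_frac"):
            if key in sec:
                sec[key] = tuple(sec[key])
        if "noise_ht" in sec:
            ph_kw["noise_ht"] = _build_noise(base.phantom.noise_ht, sec.pop("noise_ht"))
        if "noise_hs" in sec:
            ph_kw["noise_hs"] = _build_noise(base.phantom.noise_hs, sec.pop("noise_hs"))
        ph_kw.update(sec)
        kw["phantom"] = dataclasses.replace(base.phantom, **ph_kw)
    for key in ("n_select_vif", "first_pass_window_s"):
        if key in raw:
            kw[key] = raw.pop(key)
    if raw:
        raise ValueError(f"unknown config sections: {sorted(raw)}")
    return dataclasses.replace(base, **kw)


def config_hash(cfg) -> str:
    """Stable short hash of a (nested) dataclass configuration."""
    from .phantom import _config_to_jsonable
    blob = json.dumps(_config_to_jsonable(cfg), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
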