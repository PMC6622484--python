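"""Run configuration: YAML loading with validated defaults, result writing.

The configuration file is a YAML document with sections mirroring the
model components::

    fibers:
      abeta: {n_fibers: 90, baseline_rate: 1.0, stim_rate: 40.0,
              stim_duration: 0.010, velocity_range: [30, 70]}
      adelta: {...}
      c: {...}
    circuit:
      weights: {g_abeta_p: ..., g_adelta_p: ..., ...}
      taus: {tau_p: 0.001, tau_e: 0.01, tau_i: 0.02, tau_nmda: 1.0}
      response:
        p: {max_rate: ..., alpha: ..., beta: ...}
        e: {...}
        i: {...}
        m: {...}
    diurnal: {mean_abeta: 40.0, amp_abeta: 6.0, ...}
    seed: 0

Every key is optional; omitted keys take the package defaults (the
standard 1000-fiber afferent population, the calibrated circuit
parameters, and the standard diurnal modulation).  Unknown keys are
rejected with the list of valid keys for their section.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from .afferents import (
    DiurnalParams,
    FiberClass,
    FiberClassConfig,
    default_fiber_configs,
)
from .circuit import CircuitParams, ResponseFunctionParams, default_circuit_params

__all__ = ["RunConfig", "load_config", "save_config", "write_result"]

_WEIGHT_KEYS = (
    "g_abeta_p", "g_adelta_p", "g_c_p", "g_e_p",
    "g_i_p", "g_c_e", "g_i_e", "g_abeta_i",
)
_TAU_KEYS = ("tau_p", "tau_e", "tau_i", "tau_nmda")
_RESPONSE_KEYS = ("max_rate", "alpha", "beta")
_FIBER_KEYS = (
    "n_fibers", "baseline_rate", "stim_rate", "stim_duration", "velocity_range",
)
_DIURNAL_KEYS = tuple(f.name for f in dataclasses.fields(DiurnalParams))
_TOP_KEYS = ("fibers", "circuit", "diurnal", "seed", "output_dir")


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    fiber_configs: dict[FiberClass, FiberClassConfig] = field(
        default_factory=default_fiber_configs
    )
    circuit: CircuitParams = field(default_factory=default_circuit_params)
    diurnal: DiurnalParams = field(default_factory=DiurnalParams)
    seed: int = 0
    output_dir: Optional[str] = None

    def to_dict(self) -> dict[str, Any]:
        fibers = {}
        for cls, cfg in self.fiber_configs.items():
            fibers[cls.value] = {
                "n_fibers": cfg.n_fibers,
                "baseline_rate": cfg.baseline_rate,
                "stim_rate": cfg.stim_rate,
                "stim_duration": cfg.stim_duration,
                "velocity_range": list(cfg.velocity_range),
            }
        circuit = {
            "weights": {k: getattr(self.circuit, k) for k in _WEIGHT_KEYS},
            "taus": {k: getattr(self.circuit, k) for k in _TAU_KEYS},
            "response": {
                pop: {
                    k: getattr(getattr(self.circuit, f"response_{pop}"), k)
                    for k in _RESPONSE_KEYS
                }
                for pop in ("p", "e", "i", "m")
            },
        }
        out: dict[str, Any] = {
            "fibers": fibers,
            "circuit": circuit,
            "diurnal": {k: getattr(self.diurnal, k) for k in _DIURNAL_KEYS},
            "seed": self.seed,
        }
        if self.output_dir is not None:
            out["output_dir"] = self.output_dir
        return out


def _reject_unknown(section: dict, valid: tuple[str, ...], where: str) -> None:
    unknown = set(section) - set(valid)
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in {where}; "
            f"valid keys: {sorted(valid)}"
        )


def _build_fibers(data: dict) -> dict[FiberClass, FiberClassConfig]:
    defaults = default_fiber_configs()
    _reject_unknown(data, tuple(c.value for c in FiberClass), "fibers")
    out = {}
    for cls in FiberClass:
        base = defaults[cls]
        section = data.get(cls.value, {})
        _reject_unknown(section, _FIBER_KEYS, f"fibers.{cls.value}")
        kwargs = {k: section.get(k, getattr(base, k)) for k in _FIBER_KEYS}
        kwargs["velocity_range"] = tuple(kwargs["velocity_range"])
        out[cls] = FiberClassConfig(class_name=cls, **kwargs)
    return out


def _build_circuit(data: dict) -> CircuitParams:
    base = default_circuit_params()
    _reject_unknown(data, ("weights", "taus", "response"), "circuit")
    weights = data.get("weights", {})
    _reject_unknown(weights, _WEIGHT_KEYS, "circuit.weights")
    taus = data.get("taus", {})
    _reject_unknown(taus, _TAU_KEYS, "circuit.taus")
    response = data.get("response", {})
    _reject_unknown(response, ("p", "e", "i", "m"), "circuit.response")
    kwargs: dict[str, Any] = {}
    for k in _WEIGHT_KEYS:
        kwargs[k] = weights.get(k, getattr(base, k))
    for k in _TAU_KEYS:
        kwargs[k] = taus.get(k, getattr(base, k))
    for pop in ("p", "e", "i", "m"):
        section = response.get(pop, {})
        _reject_unknown(section, _RESPONSE_KEYS, f"circuit.response.{pop}")
        base_resp = getattr(base, f"response_{pop}")
        kwargs[f"response_{pop}"] = ResponseFunctionParams(
            **{k: section.get(k, getattr(base_resp, k)) for k in _RESPONSE_KEYS}
        )
    return CircuitParams(**kwargs)


def load_config(path: str | Path | None = None, data: Optional[dict] = None) -> RunConfig:
    """Load a run configuration, filling omitted keys with defaults.

    Either a YAML file path or an already-parsed mapping may be given;
    with neither, the full default configuration is returned.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    _reject_unknown(data, _TOP_KEYS, "top level")
    return RunConfig(
        fiber_configs=_build_fibers(data.get("fibers", {})),
        circuit=_build_circuit(data.get("circuit", {})),
        diurnal=DiurnalParams(**_validated_diurnal(data.get("diurnal", {}))),
        seed=int(data.get("seed", 0)),
        output_dir=data.get("output_dir"),
    )


def _validated_diurnal(section: dict) -> dict:
    _reject_unknown(section, _DIURNAL_KEYS, "diurnal")
    return section


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------

def write_result(
    result,
    out_dir: str | Path,
    name: str,
    config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
    extra: Optional[dict] = None,
) -> dict[str, Path]:
    """Write an experiment result as a tidy CSV plus a JSON sidecar.

    Any result object exposing ``to_frame()`` is supported.  The sidecar
    records the full configuration, the seed, and the package version,
    so the table is regenerable from the sidecar alone.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_path = out_dir / f"{name}.csv"
    sidecar_path = out_dir / f"{name}.json"
    frame = result.to_frame()
    frame.to_csv(table_path, index=False, float_format="%.10g")
    sidecar = {
        "result": name,
        "seed": seed,
        "version": __version__,
        "config": (config or RunConfig()).to_dict(),
    }
    if extra:
        sidecar.update(extra)
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return {"table": table_path, "sidecar": sidecar_path}
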