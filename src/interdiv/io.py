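"""Config parsing, canonical serialization, and file writers/readers.

Conventions: YAML configs whose keys match the dataclass field names; TSV
(tab-delimited, UTF-8, '.' decimal) for event logs, snapshots and density
tables; JSON for summaries, reports and the run manifest.  Internally all
lengths are metres and all times hours; the config accepts the uptake
adaptation times in seconds through the explicit ``tau1_s`` / ``tau2_s``
keys.
"""
from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .kinetics import (DivisionLawParams, KernelParams, KineticParams,
                       MonodParams)
from .renewal import calibrate_uptake_rate
from .simulate import InitSpec, SimulationConfig
from .analytics import AgePDF

__all__ = [
    "load_config", "dump_config", "write_config",
    "write_events", "read_events", "write_snapshots", "read_snapshots",
    "write_density", "read_density", "write_json",
    "RunManifest",
]

_TOP_KEYS = {"mode", "D", "dt", "n_init", "t_end", "t_record_start", "seed",
             "snapshot_interval", "growth_factor", "n_cap", "nu_target", "S",
             "washout", "init", "kinetics", "division", "kernel"}
_KIN_KEYS = {"rho", "d", "Y_SX", "eta", "l_bar", "tau1_s", "tau2_s",
             "qS_mode", "qS", "monod"}
_DIV_KEYS = {"T", "l_inf", "l_c", "kappa"}
_KER_KEYS = {"alpha"}
_INIT_KEYS = {"mean_length", "sd_length", "min_length", "max_length",
              "mean_age", "sd_age", "qS1", "qS2"}
_MONOD_KEYS = {"qmax1", "K1", "qmax2", "K2", "K_I"}


def _check_keys(section: dict, allowed: set, where: str):
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


_STRING_KEYS = {"mode", "qS_mode", "washout"}


def _coerce_numbers(section: dict) -> dict:
    """YAML 1.1 reads '1.0e3' (no exponent sign) as a string; fix that."""
    out = {}
    for k, v in section.items():
        if isinstance(v, str) and k not in _STRING_KEYS and v != "auto":
            try:
                v = float(v)
            except ValueError:
                pass
        out[k] = v
    return out


def build_config(doc: dict, calibrate: bool = True) -> SimulationConfig:
    """Build a validated SimulationConfig from a parsed config mapping.

    ``qS: auto`` resolves the constant-saturating uptake rate through the
    renewal calibration: the Malthusian rate of the kinetic model is
    matched to D (chemostat — the condition for a steady state to exist)
    or to ``nu_target`` (batch).
    """
    _check_keys(doc, _TOP_KEYS, "config")
    doc = _coerce_numbers(doc)
    kin_doc = _coerce_numbers(dict(doc.get("kinetics", {})))
    _check_keys(kin_doc, _KIN_KEYS, "kinetics")
    monod_doc = _coerce_numbers(dict(kin_doc.pop("monod", {})))
    _check_keys(monod_doc, _MONOD_KEYS, "kinetics.monod")
    div_doc = _coerce_numbers(dict(doc.get("division", {})))
    _check_keys(div_doc, _DIV_KEYS, "division")
    ker_doc = _coerce_numbers(dict(doc.get("kernel", {})))
    _check_keys(ker_doc, _KER_KEYS, "kernel")
    init_doc = _coerce_numbers(dict(doc.get("init", {})))
    _check_keys(init_doc, _INIT_KEYS, "init")

    qS = kin_doc.pop("qS", "auto")
    if "tau1_s" in kin_doc:
        kin_doc["tau1"] = float(kin_doc.pop("tau1_s")) / 3600.0
    if "tau2_s" in kin_doc:
        kin_doc["tau2"] = float(kin_doc.pop("tau2_s")) / 3600.0
    kin = KineticParams(monod=MonodParams(**monod_doc),
                        qS_constant=None if qS == "auto" else float(qS),
                        **kin_doc)
    division = DivisionLawParams(**div_doc)
    kernel = KernelParams(**ker_doc)
    init = InitSpec(**init_doc)
    top = {k: v for k, v in doc.items()
           if k not in ("kinetics", "division", "kernel", "init")}
    cfg = SimulationConfig(init=init, kinetics=kin, division=division,
                           kernel=kernel, **top)
    if qS == "auto" and kin.qS_mode == "constant-saturating" and calibrate:
        target = cfg.D if cfg.mode == "chemostat" else cfg.nu_target
        q = calibrate_uptake_rate(kin, division, kernel, target)
        kin = KineticParams(rho=kin.rho, d=kin.d, Y_SX=kin.Y_SX, eta=kin.eta,
                            l_bar=kin.l_bar, tau1=kin.tau1, tau2=kin.tau2,
                            monod=kin.monod, qS_mode=kin.qS_mode,
                            qS_constant=q)
        cfg = SimulationConfig(init=init, kinetics=kin, division=division,
                               kernel=kernel, **top)
    return cfg


def load_config(path, calibrate: bool = True) -> SimulationConfig:
    """Load and validate a YAML simulation config (unknown keys rejected)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} does not parse to a mapping")
    return build_config(doc, calibrate=calibrate)


def dump_config(cfg: SimulationConfig) -> str:
    """Canonical YAML serialization (sorted keys, explicit units)."""
    kin = cfg.kinetics
    doc = {
        "mode": cfg.mode, "D": cfg.D, "dt": cfg.dt, "n_init": cfg.n_init,
        "t_end": cfg.t_end, "t_record_start": cfg.t_record_start,
        "seed": cfg.seed, "snapshot_interval": cfg.snapshot_interval,
        "growth_factor": cfg.growth_factor, "n_cap": cfg.n_cap,
        "nu_target": cfg.nu_target, "S": cfg.S, "washout": cfg.washout,
        "kinetics": {
            "rho": kin.rho, "d": kin.d, "Y_SX": kin.Y_SX, "eta": kin.eta,
            "l_bar": kin.l_bar, "tau1_s": kin.tau1 * 3600.0,
            "tau2_s": kin.tau2 * 3600.0, "qS_mode": kin.qS_mode,
            "qS": "auto" if kin.qS_constant is None else kin.qS_constant,
            "monod": asdict(kin.monod),
        },
        "division": asdict(cfg.division),
        "kernel": asdict(cfg.kernel),
        "init": asdict(cfg.init),
    }
    return yaml.safe_dump(doc, sort_keys=True, default_flow_style=False)


def write_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dump_config(cfg))


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_snapshots(snapshots: pd.DataFrame, path) -> None:
    snapshots.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_snapshots(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_density(pdf: AgePDF, path) -> None:
    """Two-column TSV (age, density) with a header naming kind and rate."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kind={pdf.kind} rate={pdf.rate}\n")
        fh.write("age\tdensity\n")
        for a, d in zip(pdf.grid, pdf.density):
            fh.write(f"{a:.10g}\t{d:.10g}\n")


def read_density(path) -> AgePDF:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
    meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
    df = pd.read_csv(path, sep="\t", comment="#")
    rate = None if meta.get("rate") in (None, "None") else float(meta["rate"])
    return AgePDF(df["age"].to_numpy(), df["density"].to_numpy(),
                  kind=meta.get("kind", "g"), rate=rate)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


@dataclass
class RunManifest:
    """Record of one run: config echo, seed, outputs and their row counts.

    Written atomically (tmp file + rename) at run end so a manifest on
    disk always names files that exist.
    """

    config_yaml: str
    seed: int
    version: str = "0.1.0"
    started: float = 0.0
    finished: float = 0.0
    outputs: dict = field(default_factory=dict)

    def add_output(self, name: str, path: str, rows: int):
        self.outputs[name] = {"path": str(path), "rows": int(rows)}

    def write(self, path) -> None:
        for entry in self.outputs.values():
            if not os.path.exists(entry["path"]):
                raise FileNotFoundError(
                    f"manifest names missing output {entry['path']}")
        doc = {"config": self.config_yaml, "seed": self.seed,
               "version": self.version, "started": self.started,
               "finished": self.finished or time.time(),
               "outputs": self.outputs}
        tmp = str(path) + ".tmp"
        write_json(doc, tmp)
        os.replace(tmp, path)
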