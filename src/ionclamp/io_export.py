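"""CSV export/import of simulation traces, YAML config parsing, plotting.

CSV schema (normative): ``time_ms, voltage_mV, net_current_nA`` followed, for
each channel key in roster order, by ``<key>_current_nA`` and
``<key>_conductance_uS`` — 3 + 2x11 = 25 columns for the default model.
RFC-4180 dialect, UTF-8, '.' decimal point, full-precision floats (values
survive a write/read round trip).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .channels import CHANNEL_KEYS
from .protocol import ClampProtocol, validate
from .simulator import SimulationConfig, TimeSeriesResult

__all__ = ["CsvSchemaError", "ConfigError", "write_csv", "read_csv",
           "csv_columns", "LoadedConfig", "load_config", "plot"]


class CsvSchemaError(ValueError):
    """CSV file does not match the trace schema."""


class ConfigError(ValueError):
    """Invalid configuration document."""


def csv_columns(channel_keys: list[str]) -> list[str]:
    cols = ["time_ms", "voltage_mV", "net_current_nA"]
    for key in channel_keys:
        cols.append(f"{key}_current_nA")
        cols.append(f"{key}_conductance_uS")
    return cols


def write_csv(result: TimeSeriesResult, destination) -> int:
    """Write a trace to CSV; returns the number of data rows written."""
    if len(result) == 0:
        raise ValueError("refusing to write an empty trace")
    data = {"time_ms": result.times, "voltage_mV": result.voltage,
            "net_current_nA": result.net_current}
    for key in result.channel_keys:
        data[f"{key}_current_nA"] = result.currents[key]
        data[f"{key}_conductance_uS"] = result.conductances[key]
    frame = pd.DataFrame(data, columns=csv_columns(result.channel_keys))
    frame.to_csv(destination, index=False, lineterminator="\n")
    return len(frame)


def read_csv(source) -> TimeSeriesResult:
    """Read a trace written by :func:`write_csv` back into memory.

    Columns must appear exactly in schema order; times must be strictly
    increasing and uniformly spaced (both checked).
    """
    frame = pd.read_csv(source)
    cols = list(frame.columns)
    if len(cols) < 3 or cols[:3] != ["time_ms", "voltage_mV",
                                     "net_current_nA"]:
        missing = [c for c in ("time_ms", "voltage_mV", "net_current_nA")
                   if c not in cols[:3]]
        raise CsvSchemaError(
            f"leading columns must be time_ms, voltage_mV, net_current_nA; "
            f"missing or misplaced: {missing or cols[:3]}")
    tail = cols[3:]
    if len(tail) % 2 != 0:
        raise CsvSchemaError("channel columns must come in "
                             "(current, conductance) pairs")
    channel_keys = []
    for i in range(0, len(tail), 2):
        cur_col, cond_col = tail[i], tail[i + 1]
        if not cur_col.endswith("_current_nA"):
            raise CsvSchemaError(f"expected a *_current_nA column, "
                                 f"got {cur_col!r}")
        key = cur_col[:-len("_current_nA")]
        if cond_col != f"{key}_conductance_uS":
            raise CsvSchemaError(
                f"expected column {key}_conductance_uS after {cur_col!r}, "
                f"got {cond_col!r}")
        channel_keys.append(key)
    try:
        return TimeSeriesResult(
            times=frame["time_ms"].to_numpy(float),
            voltage=frame["voltage_mV"].to_numpy(float),
            net_current=frame["net_current_nA"].to_numpy(float),
            currents={k: frame[f"{k}_current_nA"].to_numpy(float)
                      for k in channel_keys},
            conductances={k: frame[f"{k}_conductance_uS"].to_numpy(float)
                          for k in channel_keys},
        )
    except ValueError as exc:
        raise CsvSchemaError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Config file
# ---------------------------------------------------------------------------

_TOP_KEYS = {"mode", "amplitude", "baseline", "pre_ms", "clamp_ms", "post_ms",
             "dt_ms", "initial_voltage_mv", "temperature_k",
             "capacitance_nf", "auto_rest", "channels", "calcium"}
_CHANNEL_KEYS_ALLOWED = {"g_max", "p_max", "reversal_mv", "gates"}
_CALCIUM_KEYS = {"ca_rest_mm", "tau_ca_ms", "influx_scale"}
_GATE_FIELDS = {"v_half", "slope", "tau_min", "tau_amp", "tau_vpeak",
                "tau_sigma", "exponent", "ca_kd"}


@dataclass
class LoadedConfig:
    """Validated contents of a config document."""

    config: SimulationConfig
    protocol: ClampProtocol
    capacitance: float = 0.01
    magnitudes: dict[str, float] = field(default_factory=dict)
    reversals: dict[str, float] = field(default_factory=dict)
    gate_overrides: dict[str, dict[str, dict]] = field(default_factory=dict)
    calcium: dict[str, float] = field(default_factory=dict)

    def build_model(self):
        from .channels import CalciumPool
        from .membrane import build_default_model
        pool_kwargs = {}
        if "ca_rest_mm" in self.calcium:
            pool_kwargs["ca_rest"] = self.calcium["ca_rest_mm"]
            pool_kwargs["ca"] = self.calcium["ca_rest_mm"]
        if "tau_ca_ms" in self.calcium:
            pool_kwargs["tau_ca"] = self.calcium["tau_ca_ms"]
        if "influx_scale" in self.calcium:
            pool_kwargs["influx_scale"] = self.calcium["influx_scale"]
        return build_default_model(
            capacitance=self.capacitance,
            temperature=self.config.temperature,
            calcium_pool=CalciumPool(**pool_kwargs) if pool_kwargs else None,
            magnitudes=self.magnitudes,
            reversals=self.reversals,
            gate_overrides=self.gate_overrides,
        )


def _require_number(value, path: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)) \
            or not math.isfinite(float(value)):
        raise ConfigError(f"{path}: expected a finite number, got {value!r}")
    return float(value)


def load_config(source) -> LoadedConfig:
    """Parse and validate a YAML config document.

    An empty document yields all defaults (10/50/10 ms, C = 0.01 nF,
    dt = 0.01 ms).  Unknown keys are rejected with their key path; physical
    quantities are validated at load time (positivity, the 1,000 ms cap).
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    mode = doc.get("mode", "current")
    protocol = ClampProtocol(
        mode=mode,
        amplitude=_require_number(doc.get("amplitude", 0.0), "amplitude"),
        pre_ms=_require_number(doc.get("pre_ms", 10.0), "pre_ms"),
        clamp_ms=_require_number(doc.get("clamp_ms", 50.0), "clamp_ms"),
        post_ms=_require_number(doc.get("post_ms", 10.0), "post_ms"),
        baseline=None if doc.get("baseline") is None
        else _require_number(doc["baseline"], "baseline"),
    )
    try:
        validate(protocol)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    dt = _require_number(doc.get("dt_ms", 0.01), "dt_ms")
    temperature = _require_number(doc.get("temperature_k", 295.0),
                                  "temperature_k")
    if temperature <= 0:
        raise ConfigError("temperature_k must be positive")
    initial_v = _require_number(doc.get("initial_voltage_mv", -65.0),
                                "initial_voltage_mv")
    auto_rest = bool(doc.get("auto_rest", False))
    try:
        config = SimulationConfig(dt=dt, initial_voltage=initial_v,
                                  temperature=temperature,
                                  auto_rest=auto_rest)
    except ValueError as exc:
        raise ConfigError(f"dt_ms: {exc}") from exc

    capacitance = _require_number(doc.get("capacitance_nf", 0.01),
                                  "capacitance_nf")
    if capacitance <= 0:
        raise ConfigError("capacitance_nf must be positive")

    magnitudes: dict[str, float] = {}
    reversals: dict[str, float] = {}
    gate_overrides: dict[str, dict[str, dict]] = {}
    channels = doc.get("channels", {}) or {}
    if not isinstance(channels, dict):
        raise ConfigError("channels: expected a mapping")
    for ckey, cdoc in channels.items():
        if ckey not in CHANNEL_KEYS:
            raise ConfigError(f"channels.{ckey}: unknown channel key")
        if not isinstance(cdoc, dict):
            raise ConfigError(f"channels.{ckey}: expected a mapping")
        unknown = set(cdoc) - _CHANNEL_KEYS_ALLOWED
        if unknown:
            raise ConfigError(
                f"channels.{ckey}: unknown key(s) {sorted(unknown)}")
        for magkey in ("g_max", "p_max"):
            if magkey in cdoc:
                val = _require_number(cdoc[magkey],
                                      f"channels.{ckey}.{magkey}")
                if val < 0:
                    raise ConfigError(
                        f"channels.{ckey}.{magkey} must be >= 0, got {val}")
                magnitudes[ckey] = val
        if "reversal_mv" in cdoc:
            reversals[ckey] = _require_number(
                cdoc["reversal_mv"], f"channels.{ckey}.reversal_mv")
        gdoc = cdoc.get("gates", {}) or {}
        if not isinstance(gdoc, dict):
            raise ConfigError(f"channels.{ckey}.gates: expected a mapping")
        for gname, fields in gdoc.items():
            if not isinstance(fields, dict):
                raise ConfigError(
                    f"channels.{ckey}.gates.{gname}: expected a mapping")
            unknown = set(fields) - _GATE_FIELDS
            if unknown:
                raise ConfigError(f"channels.{ckey}.gates.{gname}: "
                                  f"unknown field(s) {sorted(unknown)}")
            clean = {}
            for fname, fval in fields.items():
                if fname == "exponent":
                    if not isinstance(fval, int) or fval < 1:
                        raise ConfigError(
                            f"channels.{ckey}.gates.{gname}.exponent "
                            f"must be a positive integer")
                    clean[fname] = fval
                else:
                    clean[fname] = _require_number(
                        fval, f"channels.{ckey}.gates.{gname}.{fname}")
            gate_overrides.setdefault(ckey, {})[gname] = clean

    calcium = doc.get("calcium", {}) or {}
    if not isinstance(calcium, dict):
        raise ConfigError("calcium: expected a mapping")
    unknown = set(calcium) - _CALCIUM_KEYS
    if unknown:
        raise ConfigError(f"calcium: unknown key(s) {sorted(unknown)}")
    calcium_clean = {}
    for key, val in calcium.items():
        num = _require_number(val, f"calcium.{key}")
        if key != "ca_rest_mm" and num <= 0:
            raise ConfigError(f"calcium.{key} must be positive")
        if key == "ca_rest_mm" and num < 0:
            raise ConfigError("calcium.ca_rest_mm must be >= 0")
        calcium_clean[key] = num

    return LoadedConfig(config=config, protocol=protocol,
                        capacitance=capacitance, magnitudes=magnitudes,
                        reversals=reversals, gate_overrides=gate_overrides,
                        calcium=calcium_clean)


def plot(result: TimeSeriesResult, destination) -> None:
    """Three stacked panels — voltage, per-channel currents, per-channel
    conductances — one colored line per channel, legend by channel key."""
    if len(result) == 0:
        raise ValueError("cannot plot an empty trace")
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=True)
    axes[0].plot(result.times, result.voltage, color="black")
    axes[0].set_ylabel("voltage (mV)")
    cmap = plt.get_cmap("tab20")
    for i, key in enumerate(result.channel_keys):
        color = cmap(i % 20)
        axes[1].plot(result.times, result.currents[key], color=color,
                     label=key, linewidth=1)
        axes[2].plot(result.times, result.conductances[key], color=color,
                     label=key, linewidth=1)
    axes[1].set_ylabel("current (nA)")
    axes[2].set_ylabel("conductance (uS)")
    axes[2].set_xlabel("time (ms)")
    if result.channel_keys:
        axes[1].legend(fontsize=7, ncol=3, loc="upper right")
    fig.tight_layout()
    fig.savefig(destination, dpi=100, metadata={"Software": None})
    plt.close(fig)
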