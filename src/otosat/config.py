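"""Run configuration: defaults, flat key-value config files, CLI merging.

Precedence is defaults <- config file <- CLI flags.  The defaults
reproduce the model baseline (37 degC, I = 0.20 M, Ksp = 4.47e-9,
sigma_C = 80 uM, C_T calibrated so C_crit(7.65) = 265 uM, activities
approximated by concentrations).
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, replace
from pathlib import Path

from .chemistry import ThermoParams
from .stability import RiskParams

__all__ = ["RunConfig", "ConfigError", "load_config", "DEFAULT_CONFIG"]

ACTIVITY_MODES = ("minimal", "davies")


class ConfigError(ValueError):
    """Malformed or unknown configuration input."""


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable effective configuration for a run."""

    thermo: ThermoParams = field(default_factory=ThermoParams)
    risk: RiskParams = field(default_factory=RiskParams)
    activity_mode: str = "minimal"
    seed: int | None = None
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.activity_mode not in ACTIVITY_MODES:
            raise ConfigError(
                f"activity_mode must be one of {ACTIVITY_MODES}, "
                f"got {self.activity_mode!r}"
            )

    def as_flat_dict(self) -> dict[str, object]:
        return {
            "pk1": self.thermo.pk1,
            "pk2": self.thermo.pk2,
            "ksp": self.thermo.ksp,
            "s_co2": self.thermo.s_co2,
            "temperature_c": self.thermo.temperature_c,
            "ionic_strength_m": self.thermo.ionic_strength_m,
            "davies_a": self.thermo.davies_a,
            "sigma_c": self.risk.sigma_c,
            "anchor_ph": self.risk.anchor_ph,
            "anchor_ccrit_umol": self.risk.anchor_ccrit_umol,
            "activity_mode": self.activity_mode,
            "seed": self.seed,
            "verbose": self.verbose,
        }


DEFAULT_CONFIG = RunConfig()

_THERMO_KEYS = (
    "pk1",
    "pk2",
    "ksp",
    "s_co2",
    "temperature_c",
    "ionic_strength_m",
    "davies_a",
)
_RISK_KEYS = ("sigma_c", "anchor_ph", "anchor_ccrit_umol")
_OTHER_KEYS = ("activity_mode", "seed", "verbose")
_ALL_KEYS = _THERMO_KEYS + _RISK_KEYS + _OTHER_KEYS


def _parse_flat_file(path: Path) -> dict[str, str]:
    """Parse a flat ``key = value`` text file ('#' starts a comment)."""
    entries: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key or not value:
            raise ConfigError(f"{path}:{lineno}: empty key or value in {raw!r}")
        entries[key.lower()] = value
    return entries


def _coerce(key: str, value: str) -> object:
    if key == "activity_mode":
        return value
    if key == "verbose":
        if value.lower() in ("true", "1", "yes"):
            return True
        if value.lower() in ("false", "0", "no"):
            return False
        raise ConfigError(f"cannot parse boolean {key} = {value!r}")
    if key == "seed":
        return int(value)
    try:
        return float(value)
    except ValueError as exc:
        raise ConfigError(f"cannot parse {key} = {value!r} as a number") from exc


def load_config(
    path: str | Path | None = None, **overrides: object
) -> RunConfig:
    """Build the effective configuration.

    Merges defaults <- file (if given) <- keyword overrides.  Unknown
    keys are rejected with a nearest-match suggestion; an absent path
    yields the model-baseline defaults.
    """
    entries: dict[str, object] = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        entries.update(
            {k: _coerce(k, v) for k, v in _parse_flat_file(p).items() if _known(k)}
        )
    for key, value in overrides.items():
        if value is None:
            continue
        _known(key)
        entries[key] = value

    thermo = replace(
        DEFAULT_CONFIG.thermo,
        **{k: entries[k] for k in _THERMO_KEYS if k in entries},
    )
    risk = replace(
        DEFAULT_CONFIG.risk, **{k: entries[k] for k in _RISK_KEYS if k in entries}
    )
    return RunConfig(
        thermo=thermo,
        risk=risk,
        activity_mode=str(entries.get("activity_mode", DEFAULT_CONFIG.activity_mode)),
        seed=entries.get("seed"),
        verbose=bool(entries.get("verbose", False)),
    )


def _known(key: str) -> bool:
    if key in _ALL_KEYS:
        return True
    hint = difflib.get_close_matches(key, _ALL_KEYS, n=1)
    suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
    raise ConfigError(f"unknown config key {key!r}{suggestion}")
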