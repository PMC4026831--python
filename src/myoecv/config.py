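"""Run configuration: YAML schema validation with defaults.

Every validation error names the offending key (dotted path); unknown
keys are reported rather than silently ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import CohortConfig, Distribution

__all__ = ["RunConfig", "ConfigError", "validate_config", "parse_config"]

STAGES = ("simulate", "fit_t1", "segment_lge", "ecv", "segments", "report")


class ConfigError(ValueError):
    """Carries the full list of validation errors."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass
class RunConfig:
    cohort: CohortConfig
    seed: int = 0
    output_dir: Path = Path("run")
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    register: bool = True
    raw: dict = field(default_factory=dict)


_DIST_KEYS = {"mean", "sd", "lo", "hi"}

# key -> (path in CohortConfig, lo, hi) for scalar overrides
_COHORT_SCALARS = {
    "n_hcm": (0, 10_000),
    "n_control": (0, 10_000),
    "n_lge_positive": (0, 10_000),
    "n_hypertensive_hcm": (0, 10_000),
    "snr": (1.0, float("inf")),
    "grid_size": (16, 512),
    "pixel_spacing": (0.1, 10.0),
    "endo_radius": (5.0, 60.0),
    "epi_radius": (6.0, 80.0),
    "rr_interval": (200.0, 3000.0),
    "hcm_thick_epi_radius": (6.0, 80.0),
    "thick_segment_ecv": (0.0, 1.0),
}

_DISTRIBUTIONS = {
    "ecv_remote": (0.0, 1.0),
    "ecv_border": (0.0, 1.0),
    "ecv_core": (0.0, 1.0),
    "hct_hcm": (0.0, 1.0),
    "hct_control": (0.0, 1.0),
    "age_hcm": (0.0, 120.0),
    "age_control": (0.0, 120.0),
    "bsa": (0.5, 3.5),
    "systolic_bp": (50.0, 260.0),
    "diastolic_bp": (20.0, 160.0),
}


def _parse_distribution(
    name: str, value, lo: float, hi: float, errors: list[str]
) -> Distribution | None:
    if isinstance(value, (int, float)):
        value = {"mean": float(value)}
    if not isinstance(value, dict):
        errors.append(f"{name}: expected number or mapping, got {type(value).__name__}")
        return None
    unknown = set(value) - _DIST_KEYS
    if unknown:
        errors.append(f"{name}: unknown keys {sorted(unknown)}")
        return None
    if "mean" not in value:
        errors.append(f"{name}.mean: required")
        return None
    mean = value["mean"]
    if not lo <= mean <= hi:
        errors.append(f"{name}.mean: {mean} outside [{lo}, {hi}]")
        return None
    sd = value.get("sd", 0.0)
    if sd < 0:
        errors.append(f"{name}.sd: must be non-negative")
        return None
    return Distribution(
        mean=float(mean),
        sd=float(sd),
        lo=float(value.get("lo", lo)),
        hi=float(value.get("hi", hi)),
    )


def parse_config(data: dict, source: str = "<config>") -> RunConfig:
    """Validate a configuration mapping; raises :class:`ConfigError`."""
    errors: list[str] = []
    if not isinstance(data, dict):
        raise ConfigError([f"{source}: top level must be a mapping"])
    known_top = {"seed", "output_dir", "stages", "register", "cohort", "scheme"}
    for key in set(data) - known_top:
        errors.append(f"{key}: unknown key")

    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")
        seed = 0
    register = data.get("register", True)
    if not isinstance(register, bool):
        errors.append("register: must be a boolean")
        register = True

    stages = {s: True for s in STAGES}
    raw_stages = data.get("stages", {})
    if isinstance(raw_stages, list):
        stages = {s: s in raw_stages for s in STAGES}
        for s in raw_stages:
            if s not in STAGES:
                errors.append(f"stages: unknown stage {s!r}")
    elif isinstance(raw_stages, dict):
        for s, flag in raw_stages.items():
            if s not in STAGES:
                errors.append(f"stages.{s}: unknown stage")
            elif not isinstance(flag, bool):
                errors.append(f"stages.{s}: must be a boolean")
            else:
                stages[s] = flag
    elif raw_stages:
        errors.append("stages: must be a list or mapping")

    kwargs = {}
    cohort_raw = data.get("cohort", {}) or {}
    if not isinstance(cohort_raw, dict):
        errors.append("cohort: must be a mapping")
        cohort_raw = {}
    known_cohort = (
        set(_COHORT_SCALARS) | set(_DISTRIBUTIONS) | {"segment_ecv", "hcm_thick_wedges"}
    )
    for key in set(cohort_raw) - known_cohort:
        errors.append(f"cohort.{key}: unknown key")
    for key, (lo, hi) in _COHORT_SCALARS.items():
        if key not in cohort_raw:
            continue
        val = cohort_raw[key]
        if not isinstance(val, (int, float)):
            errors.append(f"cohort.{key}: must be numeric")
        elif not lo <= val <= hi:
            errors.append(f"cohort.{key}: {val} outside [{lo}, {hi}]")
        else:
            kwargs[key] = val
    for key, (lo, hi) in _DISTRIBUTIONS.items():
        if key not in cohort_raw:
            continue
        dist = _parse_distribution(f"cohort.{key}", cohort_raw[key], lo, hi, errors)
        if dist is not None:
            kwargs[key] = dist
    if "segment_ecv" in cohort_raw:
        seg = cohort_raw["segment_ecv"]
        if not isinstance(seg, dict):
            errors.append("cohort.segment_ecv: must map wedge index to ECV")
        else:
            parsed = {}
            for k, v in seg.items():
                try:
                    wedge = int(k)
                except (TypeError, ValueError):
                    errors.append(f"cohort.segment_ecv.{k}: wedge index must be 0-5")
                    continue
                if not 0 <= wedge <= 5:
                    errors.append(f"cohort.segment_ecv.{k}: wedge index must be 0-5")
                elif not isinstance(v, (int, float)) or not 0 < v < 1:
                    errors.append(f"cohort.segment_ecv.{k}: ECV must lie in (0, 1)")
                else:
                    parsed[wedge] = float(v)
            kwargs["segment_ecv"] = parsed
    if "hcm_thick_wedges" in cohort_raw:
        kwargs["hcm_thick_wedges"] = cohort_raw["hcm_thick_wedges"]

    scheme_raw = data.get("scheme", {}) or {}
    if not isinstance(scheme_raw, dict):
        errors.append("scheme: must be a mapping")
        scheme_raw = {}
    for key in set(scheme_raw) - {"rr_interval", "base_tis"}:
        errors.append(f"scheme.{key}: unknown key")
    if "rr_interval" in scheme_raw:
        kwargs["rr_interval"] = scheme_raw["rr_interval"]
    if "base_tis" in scheme_raw:
        tis = scheme_raw["base_tis"]
        if not (isinstance(tis, list) and len(tis) == 3):
            errors.append("scheme.base_tis: must be a list of three values")
        else:
            kwargs["base_tis"] = tuple(float(t) for t in tis)

    cohort = None
    if not errors:
        try:
            cohort = CohortConfig(**kwargs)
        except (ValueError, TypeError) as exc:
            errors.append(f"cohort: {exc}")
    if errors:
        raise ConfigError(errors)
    return RunConfig(
        cohort=cohort,
        seed=seed,
        output_dir=Path(data.get("output_dir", "run")),
        stages=stages,
        register=register,
        raw=data,
    )


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"{path}: file not found"])
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError([f"{path}: invalid YAML ({exc})"]) from exc
    if data is None:
        raise ConfigError([f"{path}: config file is empty"])
    return parse_config(data, source=str(path))
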