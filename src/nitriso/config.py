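"""YAML run-configuration parsing and validation.

Column configurations are written as nested key-value sections::

    column:
      depths: [2.5, 7.5, 12.5, ...]
      no3_bw: 36.0
      break_depth: 50.0
    rates:
      denit_frac: [0.02, ...]      # scalar or one value per cell
      ntr_add: 2.0
      eps15_denit: 8.0
    nitrification:
      x_ao: 0.175
      eps_sum_ao: 25.445
    noise:
      noise_iso: 0.2
      seed: 1

Unknown keys are rejected by name; all physical parameters are validated
against their type invariants before any computation runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .column import ColumnConfig, ConfigError
from .nitrification import NitrificationParams

__all__ = ["ConfigError", "load_column_config", "dump_column_config", "load_nitrification_params"]

_SECTION_FIELDS: dict[str, tuple[str, ...]] = {
    "column": (
        "depths", "no3_bw", "d15n_bw", "d18o_bw", "o2_bw", "d18o_o2_bw",
        "eps_resp", "o2_efold", "break_depth", "no2_bw", "nh4_bw", "po4_bw",
        "alkalinity_bw", "iso_threshold",
    ),
    "rates": (
        "denit_frac", "ntr_add", "eps15_denit", "eps18_denit", "form",
        "remin_n_to_p", "alk_per_n", "no2_leak_frac",
    ),
    "nitrification": (
        "x_ao", "eps_sum_ao", "x_nob", "eps_k_h2o_nob", "eps_eq",
        "delta18o_h2o", "delta15n_om",
    ),
    "noise": ("noise_iso", "noise_conc", "seed"),
}


def _as_mapping(obj: Any, where: str) -> Mapping[str, Any]:
    if obj is None:
        return {}
    if not isinstance(obj, Mapping):
        raise ConfigError(f"section {where!r} must be a mapping")
    return obj


def _listify(value):
    return tuple(value) if isinstance(value, (list, tuple)) else value


def load_column_config(path: str | Path) -> ColumnConfig:
    """Parse and validate a column configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = _as_mapping(yaml.safe_load(path.read_text()), str(path))
    unknown = set(raw) - set(_SECTION_FIELDS)
    if unknown:
        raise ConfigError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    kwargs: dict[str, Any] = {}
    for section, allowed in _SECTION_FIELDS.items():
        content = _as_mapping(raw.get(section), section)
        bad = set(content) - set(allowed)
        if bad:
            raise ConfigError(
                f"unknown key(s) in section {section!r}: {', '.join(sorted(bad))}"
            )
        if section == "nitrification":
            if content:
                base = NitrificationParams.typical()
                merged = {f: content.get(f, getattr(base, f)) for f in allowed}
                kwargs["nitrification"] = NitrificationParams(**merged)
        else:
            for key, value in content.items():
                if key in ("depths", "denit_frac", "ntr_add"):
                    value = _listify(value)
                kwargs[key] = value
    return ColumnConfig(**kwargs)


def dump_column_config(config: ColumnConfig, path: str | Path | None = None) -> str:
    """Serialize a ColumnConfig to the nested-section YAML layout."""
    doc: dict[str, dict[str, Any]] = {}
    for section, allowed in _SECTION_FIELDS.items():
        body: dict[str, Any] = {}
        for key in allowed:
            if section == "nitrification":
                value = getattr(config.nitrification, key)
            else:
                value = getattr(config, key)
            if isinstance(value, tuple):
                value = [float(v) for v in value]
            body[key] = value
        doc[section] = body
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_nitrification_params(path: str | Path) -> tuple[NitrificationParams, dict]:
    """Parse an endmember config: nitrification params plus optional sections.

    Returns the parameter set and a dict with optional ``ranges`` (per
    parameter ``[low, high]`` for uncertainty propagation) and ``o2``
    (scenario keys ``d18o_o2_bw``, ``eps_resp``, ``f_o2_grid``,
    ``n_draws``, ``seed``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = _as_mapping(yaml.safe_load(path.read_text()), str(path))
    unknown = set(raw) - {"nitrification", "ranges", "o2"}
    if unknown:
        raise ConfigError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    nit = _as_mapping(raw.get("nitrification"), "nitrification")
    allowed = _SECTION_FIELDS["nitrification"]
    bad = set(nit) - set(allowed)
    if bad:
        raise ConfigError(f"unknown key(s) in section 'nitrification': {', '.join(sorted(bad))}")
    base = NitrificationParams.typical()
    params = NitrificationParams(**{f: nit.get(f, getattr(base, f)) for f in allowed})
    ranges = {
        str(k): (float(v[0]), float(v[1]))
        for k, v in _as_mapping(raw.get("ranges"), "ranges").items()
    }
    for name in ranges:
        if name not in allowed:
            raise ConfigError(f"unknown key(s) in section 'ranges': {name}")
    o2 = dict(_as_mapping(raw.get("o2"), "o2"))
    bad = set(o2) - {"d18o_o2_bw", "eps_resp", "f_o2_grid", "n_draws", "seed"}
    if bad:
        raise ConfigError(f"unknown key(s) in section 'o2': {', '.join(sorted(bad))}")
    return params, {"ranges": ranges, "o2": o2}
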