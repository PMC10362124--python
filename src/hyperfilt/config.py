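"""Filter parameter records as serializable configuration.

A config block is a mapping keyed by filter name, e.g.::

    exp:          {a: 1.0, q: 2.0, b: 0.5, n2: 8, c: 1.0}
    cosh-acosh:   {order: 4, n5: 1, n4: 2, eps: 1}

Unknown parameter keys are rejected, never silently ignored.
"""

from __future__ import annotations

import dataclasses

import yaml

from .frequency import CoshAcoshParams, SechAsechParams
from .spatial import ExpParams, SinhAsinhParams

__all__ = [
    "FILTER_NAMES",
    "SPATIAL_FILTERS",
    "FREQUENCY_FILTERS",
    "make_params",
    "params_to_dict",
    "load_config",
]

SPATIAL_FILTERS = ("exp", "sinh-asinh-r")
FREQUENCY_FILTERS = ("cosh-acosh", "sech-asech")
FILTER_NAMES = SPATIAL_FILTERS + FREQUENCY_FILTERS

_PARAM_TYPES = {
    "exp": ExpParams,
    "sinh-asinh-r": SinhAsinhParams,
    "cosh-acosh": CoshAcoshParams,
    "sech-asech": SechAsechParams,
}


def make_params(filter_name: str, overrides: dict | None = None):
    """Build the parameter record for *filter_name* from keyword overrides.

    Raises ``ValueError`` for unknown filter names or parameter keys.
    """
    try:
        cls = _PARAM_TYPES[filter_name]
    except KeyError:
        raise ValueError(
            f"unknown filter {filter_name!r}; choose from {list(FILTER_NAMES)}"
        ) from None
    overrides = dict(overrides or {})
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(
            f"unknown parameter(s) {sorted(unknown)} for filter {filter_name!r}; "
            f"valid keys: {sorted(known)}"
        )
    if "n2" in overrides:
        overrides["n2"] = int(overrides["n2"])
    return cls(**overrides)


def params_to_dict(params) -> dict:
    return dataclasses.asdict(params)


def load_config(path) -> dict:
    """Load a YAML config file into a plain dict (empty file -> {})."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return data
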