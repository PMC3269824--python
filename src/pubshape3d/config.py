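"""Key=value configuration files exposing the package defaults.

A config file holds ``section.key = value`` lines (``#`` comments allowed),
e.g.::

    sampling.max_conformers = 200
    shape.gaussian_height = 2.7
    neighbor.st_featured = 0.795
    eligibility.max_heavy_atoms = 50
    features.merge_radius = 1.0

:func:`load_config` parses such a file into constructor-ready keyword
dictionaries; :func:`build_configs` turns them into the dataclasses the
pipeline consumes.  Unknown sections or keys raise, so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields

from .eligibility import EligibilityConfig
from .features import FeatureRuleSet
from .neighboring import NeighborThresholds
from .sampling import SamplingConfig
from .shape import ShapeParams

__all__ = ["load_config", "build_configs"]

_SECTIONS = {
    "eligibility": EligibilityConfig,
    "sampling": SamplingConfig,
    "shape": ShapeParams,
    "features": FeatureRuleSet,
    "neighbor": NeighborThresholds,
}


def _coerce(cls, key: str, text: str):
    spec = {f.name: f for f in fields(cls)}
    if key not in spec:
        raise KeyError(f"unknown option {key!r} for section {cls.__name__}")
    text = text.strip()
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def load_config(path: str) -> dict[str, dict]:
    """Parse a key=value config file into per-section keyword dicts."""
    out: dict[str, dict] = {name: {} for name in _SECTIONS}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line or "." not in line.split("=", 1)[0]:
                raise ValueError(f"{path}:{lineno}: expected 'section.key = value'")
            dotted, value = (part.strip() for part in line.split("=", 1))
            section, key = dotted.split(".", 1)
            if section not in _SECTIONS:
                raise KeyError(f"{path}:{lineno}: unknown section {section!r}")
            out[section][key] = _coerce(_SECTIONS[section], key, value)
    return out


def build_configs(overrides: dict[str, dict] | None = None) -> dict[str, object]:
    """Instantiate every pipeline config, applying the given overrides."""
    overrides = overrides or {}
    return {
        name: cls(**overrides.get(name, {}))
        for name, cls in _SECTIONS.items()
    }
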