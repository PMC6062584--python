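"""Named light-field presets mirroring the experimental pattern geometry.

The experiments project patterns on a 23 cm plate with the source on the
+x side at a zenith angle of 40 deg.  The directionality patterns add an
artificial gradient about 5 times steeper than the natural fall-off with
distance to the projector:

* ``pos_like``    - artificial gradient reinforcing the natural one along
  -x (brightest toward the source); intensity and directionality push the
  larvae the same way.
* ``neg_like``    - the pattern rotated by 180 deg: the artificial gradient
  opposes the natural one, so intensity and directionality compete.
* ``tilted_like`` - artificial gradient turned onto the y axis
  (perpendicular to directionality), natural gradient along x at one
  fifth the magnitude; this decouples the two terms of the step weight.
* ``d90_like``    - overhead source (theta = 90 deg), gradient only.
* ``uniform``     - constant field (unbiased chain when beta = 0).

The coefficient scale is a simulation scale, not a radiometric one: it is
chosen so that at the published parameter point (beta = 0.014,
T ~ 9 W/m^2) both weight terms produce navigation indices of the measured
order while the plane stays positive over the whole plate.  See
docs/methods.md for the full rationale.
"""

from __future__ import annotations

import yaml

from .light_fields import LinearLightField

__all__ = ["PRESETS", "preset_names", "get_preset", "field_to_dict", "field_from_dict",
           "load_field", "save_field"]

#: slope of the natural fall-off toward the projector, W/m^2 per cm
NATURAL_SLOPE = 14.0
#: artificial projected gradient, about 5x the natural one
ARTIFICIAL_SLOPE = 70.0
#: centre irradiance shared by all presets, W/m^2
CENTRE_IRRADIANCE = 1000.0

PRESETS: dict[str, dict] = {
    "uniform": dict(a0=CENTRE_IRRADIANCE),
    "pos_like": dict(a0=CENTRE_IRRADIANCE, a1x=ARTIFICIAL_SLOPE + NATURAL_SLOPE),
    "neg_like": dict(a0=CENTRE_IRRADIANCE, a1x=-ARTIFICIAL_SLOPE + NATURAL_SLOPE),
    "tilted_like": dict(a0=CENTRE_IRRADIANCE, a1x=NATURAL_SLOPE, a1y=ARTIFICIAL_SLOPE),
    "d90_like": dict(a0=CENTRE_IRRADIANCE, a1x=-ARTIFICIAL_SLOPE, theta_deg=90.0),
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def get_preset(name: str) -> LinearLightField:
    """Return the named preset as a validated field."""
    try:
        kwargs = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown field preset {name!r}; choose from {preset_names()}"
        ) from None
    return LinearLightField(**kwargs)


def field_to_dict(field: LinearLightField) -> dict:
    return {
        "a0": float(field.a0),
        "a1x": float(field.a1x),
        "a1y": float(field.a1y),
        "plate_half_width": float(field.plate_half_width),
        "theta_deg": float(field.theta_deg),
        "source_direction": [float(v) for v in field.source_direction],
    }


def field_from_dict(data: dict) -> LinearLightField:
    known = {"a0", "a1x", "a1y", "plate_half_width", "theta_deg", "source_direction"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown field keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "source_direction" in kwargs:
        kwargs["source_direction"] = tuple(kwargs["source_direction"])
    return LinearLightField(**kwargs)


def load_field(path) -> LinearLightField:
    """Read a field from a YAML (or JSON; YAML is a superset) config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of field coefficients")
    return field_from_dict(data)


def save_field(field: LinearLightField, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(field_to_dict(field), fh, sort_keys=True)
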