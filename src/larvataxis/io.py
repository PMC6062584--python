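"""Track files, summaries, run configuration and synthetic fixtures.

The track CSV dialect is deliberately minimal and open: columns
``replicate, larva_id, step_index, x_cm, y_cm`` with a mandatory header,
0-based step index and row 0 at the origin.  Positions are serialized in
cm so the files read naturally against the 23 cm plate; floats are
written with 12 significant digits, which makes write -> read -> write
round-trips byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, MissingColumnError, UnknownFixtureError
from .light_fields import LinearLightField, SpectrumTable
from .presets import field_from_dict, field_to_dict, get_preset, PRESETS
from .simulator import EnsembleResult, ModelParams, Trajectory, simulate_ensemble

__all__ = [
    "TRACK_COLUMNS",
    "write_tracks",
    "read_tracks",
    "write_summary",
    "RunConfig",
    "load_run_config",
    "resolve_field",
    "generate_fixture",
    "FIXTURE_KINDS",
]

TRACK_COLUMNS = ["replicate", "larva_id", "step_index", "x_cm", "y_cm"]


def _iter_replicates(source):
    """Normalise an EnsembleResult / nested list / flat list of trajectories."""
    if isinstance(source, EnsembleResult):
        return source.trajectories
    if isinstance(source, Trajectory):
        return [[source]]
    source = list(source)
    if source and isinstance(source[0], Trajectory):
        return [source]
    return source


def write_tracks(path, source, sigma_cm: float = 0.01) -> None:
    """Write trajectories (sigma units internally) to a track CSV in cm."""
    rows = []
    for rep_idx, rep in enumerate(_iter_replicates(source)):
        for larva_idx, traj in enumerate(rep):
            pos_cm = traj.positions * sigma_cm
            n = len(pos_cm)
            rows.append(
                pd.DataFrame(
                    {
                        "replicate": np.full(n, rep_idx, dtype=int),
                        "larva_id": np.full(n, larva_idx, dtype=int),
                        "step_index": np.arange(n, dtype=int),
                        "x_cm": pos_cm[:, 0],
                        "y_cm": pos_cm[:, 1],
                    }
                )
            )
    if not rows:
        raise ValueError("no trajectories to write")
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def read_tracks(
    path, sigma_cm: float = 0.01, source_direction=(1.0, 0.0)
) -> list[list[Trajectory]]:
    """Read a track CSV back into trajectories grouped by (replicate, larva).

    Rows may appear in any order; steps are sorted by ``step_index``.
    Positions are converted from cm back to sigma units so the loaded
    trajectories feed directly into the metrics.

    Raises
    ------
    MissingColumnError
        If the header lacks one of the required columns.
    FormatError
        With the offending line number, on non-numeric or missing values.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing columns {missing}")
    for col in TRACK_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            # +2: 1-based line numbers and the header row
            line = int(bad.idxmax()) + 2
            raise FormatError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = coerced
    result: list[list[Trajectory]] = []
    for rep_id, rep_df in df.groupby("replicate", sort=True):
        larvae = []
        for _, larva_df in rep_df.groupby("larva_id", sort=True):
            larva_df = larva_df.sort_values("step_index")
            idx = larva_df["step_index"].to_numpy(int)
            if not np.array_equal(idx, np.arange(len(idx))):
                raise FormatError(
                    f"{path}: non-contiguous step_index for replicate {rep_id}"
                )
            pos = larva_df[["x_cm", "y_cm"]].to_numpy(float) / sigma_cm
            larvae.append(
                Trajectory(
                    positions=pos,
                    n_proposals=max(len(pos) - 1, 1),
                    termination="loaded",
                    source_direction=tuple(source_direction),
                )
            )
        result.append(larvae)
    return result


def _round12(obj):
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round12(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round12(float(obj))
    return obj


def write_summary(path, ensemble: EnsembleResult, field=None, params=None) -> None:
    """Write the ensemble summary JSON (indices, sd, acceptance, parameter echo)."""
    payload = {
        "ni_x": ensemble.ni_x,
        "ni_y": ensemble.ni_y,
        "sd_x": ensemble.sd_x,
        "sd_y": ensemble.sd_y,
        "n_larvae": len(ensemble.trajectories[0]),
        "n_replicates": ensemble.n_replicates,
        "acceptance_rate": ensemble.acceptance_rate,
        "termination_counts": ensemble.termination_counts(),
    }
    if field is not None:
        payload["field"] = field_to_dict(field)
    if params is not None:
        payload["params"] = asdict(params)
    with open(path, "w") as fh:
        json.dump(_round12(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


def summary_json(data) -> str:
    """Serialize any summary mapping with 12-significant-digit floats."""
    return json.dumps(_round12(data), indent=2, sort_keys=True) + "\n"


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved simulation run: field, parameters and ensemble sizes."""

    field: LinearLightField
    params: ModelParams
    n_larvae: int = 30
    n_replicates: int = 30

    def __post_init__(self) -> None:
        if self.params.seed is None:
            raise ValueError("run configs must carry an explicit seed")


def resolve_field(spec) -> LinearLightField:
    """Turn a preset name, config-file path, dict or field object into a field."""
    if isinstance(spec, LinearLightField):
        return spec
    if isinstance(spec, dict):
        return field_from_dict(spec)
    if isinstance(spec, str) and spec in PRESETS:
        return get_preset(spec)
    from .presets import load_field

    return load_field(spec)


def load_run_config(path) -> RunConfig:
    """Read a YAML run config: keys ``field`` (name/path/mapping), ``params``,
    ``n_larvae``, ``n_replicates``."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "field" not in data or "params" not in data:
        raise ValueError(f"{path}: run config needs 'field' and 'params' entries")
    params = ModelParams(**data["params"])
    return RunConfig(
        field=resolve_field(data["field"]),
        params=params,
        n_larvae=int(data.get("n_larvae", 30)),
        n_replicates=int(data.get("n_replicates", 30)),
    )


FIXTURE_KINDS = (
    "uniform_walk",
    "tilted_ensemble",
    "pos_ensemble",
    "ballistic",
    "loop",
    "flat_spectrum",
    "peaked_spectrum",
)


def _straight_trajectory(direction, n_steps=10, step_sigma=10.0):
    d = np.asarray(direction, float)
    d = d / np.hypot(*d) * step_sigma
    pos = np.vstack([np.zeros(2), np.cumsum(np.tile(d, (n_steps, 1)), axis=0)])
    return Trajectory(positions=pos, n_proposals=n_steps, termination="step_cap")


def _loop_trajectory(side_sigma=10.0):
    s = side_sigma
    pos = np.array([[0, 0], [s, 0], [s, s], [0, s], [0, 0]], dtype=float)
    return Trajectory(positions=pos, n_proposals=4, termination="step_cap")


def generate_fixture(kind: str, seed: int = 0):
    """Deterministic synthetic inputs for tests, docs and CLI smoke runs.

    Returns ``(field, trajectories)`` for the walk/ensemble/path kinds and
    ``(None, SpectrumTable)`` for the spectrum kinds.  Ensemble fixtures
    are small (5 larvae x 2 replicates, capped steps) on purpose.
    """
    if kind not in FIXTURE_KINDS:
        raise UnknownFixtureError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    if kind == "flat_spectrum":
        wl = np.arange(300.0, 701.0, 10.0)
        return None, SpectrumTable(wl, np.ones_like(wl))
    if kind == "peaked_spectrum":
        wl = np.arange(300.0, 701.0, 5.0)
        peak = np.clip(1.0 - np.abs(wl - 475.0) / 120.0, 0.0, None)
        return None, SpectrumTable(wl, peak)
    if kind == "ballistic":
        return get_preset("uniform"), [[_straight_trajectory((-1.0, 0.0))]]
    if kind == "loop":
        return get_preset("uniform"), [[_loop_trajectory()]]
    sim_spec = {
        "uniform_walk": ("uniform", dict(T=10.0, beta=0.0)),
        "tilted_ensemble": ("tilted_like", dict(T=4.0, beta=0.005)),
        "pos_ensemble": ("pos_like", dict(T=10.0, beta=0.014)),
    }[kind]
    field = get_preset(sim_spec[0])
    params = ModelParams(seed=seed, max_accepted_steps=500, **sim_spec[1])
    ens = simulate_ensemble(field, params, n_larvae=5, n_replicates=2)
    return field, ens
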