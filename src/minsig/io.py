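"""Configuration parsing and trajectory serialization.

Trajectories travel as plain TSV (tab-separated, header row, '.' decimal)
with a fixed column schema, one row per (cell, record time); run metadata
(parameters, seeds, engine) goes in a JSON sidecar next to the data file so
the table itself stays purely tabular.  Run configuration files are
TOML-dialect ``key = value`` text.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gillespie import COUNT_COLUMNS, Ensemble, Trajectory
from .network import NetworkParameters, preset, validate_parameters

__all__ = [
    "RunConfig",
    "ConfigError",
    "SchemaError",
    "TSV_COLUMNS",
    "read_config",
    "write_trajectories",
    "read_trajectories",
]

#: Fixed on-disk column order of the trajectory TSV.
TSV_COLUMNS = ("cell_id", "time", *COUNT_COLUMNS, "engine")

_PARAM_KEYS = (
    "x0", "x1_total", "x2_total", "x3_total", "k_a", "k_b1", "k_b2", "k_b3",
)


class ConfigError(ValueError):
    """Malformed, unknown-key, or ill-typed run configuration."""


class SchemaError(ValueError):
    """Trajectory file violates the TSV schema or a state invariant."""


@dataclass
class RunConfig:
    """Fully resolved settings for one simulation run.

    Parameter fields mirror :class:`~minsig.network.NetworkParameters`;
    ``engine`` selects the exact sampler (``ssa``) or the chemical-Langevin
    integrator (``cle``, which additionally needs ``dt``).  ``x0`` has no
    default: a run cannot start until the stimulus is chosen.
    """

    x0: float | None = None
    x1_total: int = 100
    x2_total: int = 100
    x3_total: int = 100
    k_a: float = 1e-5
    k_b1: float = 1.0
    k_b2: float = 1e-4
    k_b3: float = 1.0
    engine: str = "ssa"
    n_cells: int = 100
    t_max: float = 10.0
    n_records: int = 201
    dt: float | None = None
    master_seed: int = 0
    out: str | None = None

    def parameters(self) -> NetworkParameters:
        return NetworkParameters(
            **{k: getattr(self, k) for k in _PARAM_KEYS}
        )

    def record_times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_max, self.n_records)


_INT_KEYS = {"x1_total", "x2_total", "x3_total", "n_cells", "n_records",
             "master_seed"}
_FLOAT_KEYS = {"x0", "k_a", "k_b1", "k_b2", "k_b3", "t_max", "dt"}
_STR_KEYS = {"engine", "out"}
_ALL_KEYS = _INT_KEYS | _FLOAT_KEYS | _STR_KEYS


def read_config(path: str | Path) -> RunConfig:
    """Parse a TOML-dialect ``key = value`` run configuration.

    Unknown keys are an error (the message lists the valid keys); absent keys
    fall back to the defaults (the base preset parameter values; ``x0`` stays
    unset and must be supplied before simulating).  Parameter values are
    checked through :func:`~minsig.network.validate_parameters`; validation
    *errors* are fatal here, warnings are attached for the caller to log.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"malformed config {path}: {exc}") from exc
    unknown = sorted(set(raw) - _ALL_KEYS)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {', '.join(unknown)}; valid keys: "
            + ", ".join(sorted(_ALL_KEYS))
        )
    cfg = RunConfig()
    for key, value in raw.items():
        if key in _INT_KEYS:
            if isinstance(value, bool) or not isinstance(value, int):
                raise ConfigError(f"config key {key} must be an integer, got {value!r}")
            setattr(cfg, key, int(value))
        elif key in _FLOAT_KEYS:
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(f"config key {key} must be a number, got {value!r}")
            setattr(cfg, key, float(value))
        else:
            if not isinstance(value, str):
                raise ConfigError(f"config key {key} must be a string, got {value!r}")
            setattr(cfg, key, value)
    if cfg.engine not in ("ssa", "cle"):
        raise ConfigError(f"engine must be 'ssa' or 'cle', got {cfg.engine!r}")
    if cfg.n_records < 2:
        raise ConfigError("n_records must be >= 2")
    if cfg.x0 is not None:
        report = validate_parameters(cfg.parameters())
        if report.errors:
            raise ConfigError("invalid parameters: " + "; ".join(report.errors))
    return cfg


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_trajectories(ensemble: Ensemble, path: str | Path) -> Path:
    """Write an ensemble as TSV plus a JSON metadata sidecar.

    Rows are sorted by (cell_id, time); integer count fields serialize
    exactly, times at full repr precision.  The sidecar
    (``<path>.meta.json``) records the parameters, the master seed, and each
    cell's derived seed so any single cell can be re-simulated in isolation.
    Returns the data path.
    """
    path = Path(path)
    frames = []
    for tr in ensemble.trajectories:
        df = pd.DataFrame(tr.counts, columns=list(COUNT_COLUMNS))
        df.insert(0, "time", tr.record_times)
        df.insert(0, "cell_id", tr.cell_id)
        df["engine"] = tr.engine
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["cell_id", "time"], kind="stable")
    table.to_csv(path, sep="\t", index=False)
    meta = {
        "params": dataclasses.asdict(ensemble.params),
        "master_seed": ensemble.master_seed,
        "cell_seeds": {tr.cell_id: tr.seed for tr in ensemble.trajectories},
        "engine": ensemble.trajectories[0].engine if ensemble.trajectories else "ssa",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_trajectories(path: str | Path) -> Ensemble:
    """Read a trajectory TSV (and its sidecar, if present) back into an
    :class:`~minsig.gillespie.Ensemble`.

    Validates the schema and the state invariants on ingest: exact column
    set, nonnegative counts, and per-species conservation
    (inactive + active constant within each cell).  Violations raise
    :class:`SchemaError` naming the offending column or row.  Without a
    sidecar, totals are inferred from the data and ``x0`` is left unset.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in TSV_COLUMNS if c not in table.columns]
    extra = [c for c in table.columns if c not in TSV_COLUMNS]
    if missing or extra:
        raise SchemaError(
            f"bad trajectory schema in {path}: missing {missing or 'none'}, "
            f"unexpected {extra or 'none'}"
        )
    counts = table[list(COUNT_COLUMNS)]
    neg = counts.lt(0)
    if neg.any().any():
        col = neg.any()[neg.any()].index[0]
        row = int(neg[col].idxmax())
        raise SchemaError(f"negative count in column {col!r} at row {row}")
    engines = table["engine"].unique().tolist()
    is_ssa = all(e == "ssa" for e in engines)
    if is_ssa:
        frac = counts.to_numpy(dtype=float) % 1.0
        if np.any(frac != 0):
            bad = int(np.argwhere(frac != 0)[0, 0])
            raise SchemaError(f"non-integer count in an ssa trajectory at row {bad}")
    # Conservation per cell and species: inactive + active must be constant
    # (exactly for integer SSA states; to rounding for serialized CLE floats).
    for species in ("1", "2", "3"):
        total = table[f"x{species}"] + table[f"x{species}a"]
        per_cell_ref = total.groupby(table["cell_id"]).transform("first")
        if is_ssa:
            bad = total != per_cell_ref
        else:
            bad = ~np.isclose(total, per_cell_ref, rtol=1e-9, atol=1e-6)
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"conservation violated for species {species} at row {row}: "
                f"x{species} + x{species}a is not constant within the cell"
            )
    meta_path = _sidecar_path(path)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        params = NetworkParameters(**meta["params"])
        master_seed = int(meta["master_seed"])
        cell_seeds = {int(k): int(v) for k, v in meta["cell_seeds"].items()}
    else:
        first = table[table["cell_id"] == table["cell_id"].iloc[0]]
        params = NetworkParameters(
            x0=None,
            x1_total=int(first["x1"].iloc[0] + first["x1a"].iloc[0]),
            x2_total=int(first["x2"].iloc[0] + first["x2a"].iloc[0]),
            x3_total=int(first["x3"].iloc[0] + first["x3a"].iloc[0]),
        )
        master_seed = 0
        cell_seeds = {}
    trajectories = []
    dtype = np.int64 if is_ssa else float
    for cell_id, group in table.groupby("cell_id", sort=True):
        trajectories.append(
            Trajectory(
                cell_id=int(cell_id),
                seed=cell_seeds.get(int(cell_id), 0),
                record_times=group["time"].to_numpy(dtype=float),
                counts=group[list(COUNT_COLUMNS)].to_numpy(dtype=dtype),
                engine=str(group["engine"].iloc[0]),
            )
        )
    return Ensemble(params=params, master_seed=master_seed, trajectories=trajectories)
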