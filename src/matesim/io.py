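"""Readers and writers for configs, matrices, life tables and results.

All on-disk formats are plain text: run configurations are YAML key/value
files; mating matrices are tab-delimited square numeric tables (rows = male
age class, columns = female age class); life tables are tab-delimited with
columns ``age_class, male_survival, female_survival, male_fertility,
female_fertility``; results are written as a trajectory table and a curves
table.  Every writer's output round-trips through its reader.
"""

from __future__ import annotations

import os
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .engine import Population, SimConfig, SimResult, init_population
from .genetics import FEMALE, MALE, LocusSpec
from .life_tables import LifeTables, prolonged_tables, mortality_study_tables
from .mating import (
    ADULT_MIN_DEFAULT,
    YOUNG_MAX_DEFAULT,
    YOUNG_MIN_DEFAULT,
    MatingMatrix,
    build_matrix,
)

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "read_matrix",
    "write_matrix",
    "read_life_tables",
    "write_life_tables",
    "write_result",
    "read_result",
    "make_fixture",
]

TABLE_PRESETS = {
    "prolonged": prolonged_tables,
    "mortality_study": mortality_study_tables,
}


class ConfigError(ValueError):
    """A config file violated the schema; the message names the key path."""


def _check_keys(d: dict, allowed: set[str], required: set[str], path: str) -> None:
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected a mapping")
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    missing = required - set(d)
    if missing:
        raise ConfigError(f"{path}: missing required key(s) {sorted(missing)}")


# ---------------------------------------------------------------------------
# matrices and life tables

def read_matrix(path: str, label: str = "custom") -> MatingMatrix:
    """Read a square delimited numeric table of pair-formation probabilities."""
    M = np.atleast_2d(np.loadtxt(path))
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: matrix must be square, got shape {M.shape}")
    return MatingMatrix(M, label=label)


def write_matrix(matrix: MatingMatrix, path: str) -> None:
    np.savetxt(path, matrix.M, fmt="%.17g", delimiter="\t")


LIFE_TABLE_COLUMNS = [
    "age_class",
    "male_survival",
    "female_survival",
    "male_fertility",
    "female_fertility",
]


def read_life_tables(path: str) -> LifeTables:
    df = pd.read_csv(path, sep="\t")
    missing = set(LIFE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df = df.sort_values("age_class")
    n = len(df)
    if not (df["age_class"].to_numpy() == np.arange(1, n + 1)).all():
        raise ValueError(f"{path}: age_class must run 1..{n} without gaps")
    surv = np.vstack([df["male_survival"], df["female_survival"]])
    fert = np.vstack([df["male_fertility"], df["female_fertility"]])
    return LifeTables(surv, fert)


def write_life_tables(tables: LifeTables, path: str) -> None:
    n = tables.n_classes
    pd.DataFrame(
        {
            "age_class": np.arange(1, n + 1),
            "male_survival": tables.survival[MALE],
            "female_survival": tables.survival[FEMALE],
            "male_fertility": tables.fertility[MALE],
            "female_fertility": tables.fertility[FEMALE],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# config files

_TOP_KEYS = {
    "N", "loci", "tables", "matrix", "n_periods", "burn_in", "seed", "shift",
    "mutation_model", "max_attempts", "record_every",
}
_LOCUS_KEYS = {"id", "effect", "scope", "onset_class", "e", "mu", "h", "init_freq"}
_MATRIX_KEYS = {"label", "young_min", "young_max", "adult_min", "path", "rows"}
_TABLE_KEYS = {"preset", "path", "n_classes", "survival", "fertility"}


def _parse_matrix(spec, n_classes: int, path: str, base_dir: str) -> MatingMatrix:
    if isinstance(spec, str):
        spec = {"label": spec}
    _check_keys(spec, _MATRIX_KEYS, set(), path)
    if "rows" in spec:
        return MatingMatrix(np.asarray(spec["rows"], float), spec.get("label", "custom"))
    if "path" in spec:
        return read_matrix(
            os.path.join(base_dir, spec["path"]), spec.get("label", "custom")
        )
    if "label" not in spec:
        raise ConfigError(f"{path}: need one of label / rows / path")
    try:
        return build_matrix(
            spec["label"],
            young_min=spec.get("young_min", YOUNG_MIN_DEFAULT),
            young_max=spec.get("young_max", YOUNG_MAX_DEFAULT),
            adult_min=spec.get("adult_min", ADULT_MIN_DEFAULT),
            n_classes=n_classes,
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _parse_tables(spec, base_dir: str) -> LifeTables:
    if spec is None:
        return prolonged_tables()
    if isinstance(spec, str):
        spec = {"preset": spec}
    _check_keys(spec, _TABLE_KEYS, set(), "tables")
    if "path" in spec:
        return read_life_tables(os.path.join(base_dir, spec["path"]))
    if "survival" in spec or "fertility" in spec:
        _check_keys(spec, _TABLE_KEYS, {"survival", "fertility"}, "tables")
        return LifeTables(np.asarray(spec["survival"], float),
                          np.asarray(spec["fertility"], float))
    preset = spec.get("preset", "prolonged")
    if preset not in TABLE_PRESETS:
        raise ConfigError(
            f"tables.preset: unknown preset {preset!r}; "
            f"choose from {sorted(TABLE_PRESETS)}"
        )
    return TABLE_PRESETS[preset](spec.get("n_classes", 18))


def _parse_loci(spec) -> list[LocusSpec]:
    if not isinstance(spec, list) or not spec:
        raise ConfigError("loci: expected a non-empty list")
    loci = []
    for k, entry in enumerate(spec):
        _check_keys(entry, _LOCUS_KEYS, {"effect", "scope", "onset_class"}, f"loci[{k}]")
        entry = dict(entry)
        entry.setdefault("id", k + 1)
        try:
            loci.append(LocusSpec(**entry))
        except ValueError as exc:
            raise ConfigError(f"loci[{k}]: {exc}") from exc
    return loci


def load_config(path: str) -> SimConfig:
    """Parse and validate a YAML run configuration.

    Unknown keys are rejected; omitted optional keys take the documented
    defaults (prolonged life tables, 200 burn-in periods, seed 0).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base_dir = os.path.dirname(os.path.abspath(path))
    _check_keys(raw, _TOP_KEYS, {"N", "matrix", "loci"}, "config")
    tables = _parse_tables(raw.get("tables"), base_dir)
    matrix = _parse_matrix(raw["matrix"], tables.n_classes, "matrix", base_dir)
    shift = None
    if raw.get("shift") is not None:
        _check_keys(raw["shift"], {"period", "matrix"}, {"period", "matrix"}, "shift")
        shift = (
            int(raw["shift"]["period"]),
            _parse_matrix(raw["shift"]["matrix"], tables.n_classes, "shift.matrix", base_dir),
        )
    try:
        return SimConfig(
            N=int(raw["N"]),
            loci=_parse_loci(raw["loci"]),
            tables=tables,
            matrix=matrix,
            n_periods=int(raw.get("n_periods", 10000)),
            burn_in=int(raw.get("burn_in", 200)),
            seed=int(raw.get("seed", 0)),
            shift=shift,
            mutation_model=raw.get("mutation_model", "per_copy"),
            max_attempts=int(raw.get("max_attempts", 1_000_000)),
            record_every=int(raw.get("record_every", 1)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def _matrix_to_spec(matrix: MatingMatrix):
    return {"label": matrix.label, "rows": matrix.M.tolist()}


def save_config(config: SimConfig, path: str) -> None:
    """Serialise a config (matrices and tables inline) so that
    ``load_config(save_config(c))`` reproduces it exactly."""
    doc = {
        "N": config.N,
        "loci": [asdict(l) for l in config.loci],
        "tables": {
            "survival": config.tables.survival.tolist(),
            "fertility": config.tables.fertility.tolist(),
        },
        "matrix": _matrix_to_spec(config.matrix),
        "n_periods": config.n_periods,
        "burn_in": config.burn_in,
        "seed": config.seed,
        "mutation_model": config.mutation_model,
        "max_attempts": config.max_attempts,
        "record_every": config.record_every,
    }
    if config.shift is not None:
        doc["shift"] = {
            "period": config.shift[0],
            "matrix": _matrix_to_spec(config.shift[1]),
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# results

def write_result(result: SimResult, out_dir: str) -> dict[str, str]:
    """Write a run's trajectory and end-state curves as tab-delimited text.

    Returns the paths written: ``trajectory.tsv`` (period, locus, sex,
    frequency) and ``curves.tsv`` (sex, age_class, survival, fertility).
    """
    os.makedirs(out_dir, exist_ok=True)
    n_rec, n_loci, _ = result.freq.shape
    rows = []
    for ti in range(n_rec):
        for l in range(n_loci):
            for sex, name in ((MALE, "male"), (FEMALE, "female")):
                rows.append(
                    (int(result.periods[ti]), l + 1, name, result.freq[ti, l, sex])
                )
    traj_path = os.path.join(out_dir, "trajectory.tsv")
    pd.DataFrame(rows, columns=["period", "locus", "sex", "frequency"]).to_csv(
        traj_path, sep="\t", index=False, float_format="%.17g"
    )
    n = result.end_survivorship.shape[1]
    crows = []
    for sex, name in ((MALE, "male"), (FEMALE, "female")):
        for c in range(n):
            crows.append(
                (name, c + 1, result.end_survivorship[sex, c], result.end_fertility[sex, c])
            )
    curves_path = os.path.join(out_dir, "curves.tsv")
    pd.DataFrame(crows, columns=["sex", "age_class", "survival", "fertility"]).to_csv(
        curves_path, sep="\t", index=False, float_format="%.17g"
    )
    return {"trajectory": traj_path, "curves": curves_path}


def read_result(out_dir: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back the two tables written by :func:`write_result`."""
    traj = pd.read_csv(os.path.join(out_dir, "trajectory.tsv"), sep="\t")
    curves = pd.read_csv(os.path.join(out_dir, "curves.tsv"), sep="\t")
    return traj, curves


# ---------------------------------------------------------------------------
# fixtures

def make_fixture(kind: str, seed: int = 0):
    """Deterministic miniature inputs for tests and examples.

    ``toy_tables`` — 6-age-class tables (flat survival 0.8, fertility 0.9
    over classes 2-5); ``toy_matrix`` — 6-class age-indifferent matrix;
    ``tiny_pop`` — a 10-per-sex population plus its config, initialised on
    the toy tables with one late-onset mortality locus.
    """
    if kind == "toy_tables":
        surv = np.array([[0.8] * 5 + [0.0]] * 2)
        fert = np.array([[0.0, 0.9, 0.9, 0.9, 0.9, 0.0]] * 2)
        return LifeTables(surv, fert)
    if kind == "toy_matrix":
        return build_matrix("AP", young_min=2, young_max=4, adult_min=3, n_classes=6)
    if kind == "tiny_pop":
        tables = make_fixture("toy_tables")
        config = SimConfig(
            N=10,
            loci=[LocusSpec(1, "mortality", "both", 5, e=0.1, mu=0.01)],
            tables=tables,
            matrix=make_fixture("toy_matrix"),
            n_periods=10,
            burn_in=0,
            seed=seed,
        )
        pop = init_population(config, np.random.default_rng(seed))
        return pop, config
    raise ValueError(f"unknown fixture kind {kind!r}")
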