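"""Cohort file formats, validation and summary tables.

Two CSV files define a cohort on disk, both with mandatory headers and ages
in years (conversion to model time t = age - 40 is internal only):

* ``subjects.csv`` — id, entry_age, exit_age, event, bmi, mht, mp, fh
* ``longitudinal.csv`` — id, age, sqrt_md

Validation reports every violation with its row number (2-based, counting
the header as row 1).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import FH_LEVELS, MHT_LEVELS, MP_LEVELS

__all__ = [
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "cohort_summary",
    "format_count_pct",
]

AGE_ORIGIN = 40.0
MAX_AGE = 80.0

SUBJECT_COLUMNS = ["id", "entry_age", "exit_age", "event", "bmi", "mht", "mp", "fh"]
LONGITUDINAL_COLUMNS = ["id", "age", "sqrt_md"]
_CATEGORY_LEVELS = {"mht": MHT_LEVELS, "mp": MP_LEVELS, "fh": FH_LEVELS}


class CohortValidationError(ValueError):
    """Raised when cohort files violate the format contract.

    ``errors`` lists human-readable messages, each naming the file, the row
    number and the offending value.
    """

    def __init__(self, errors: list[str]) -> None:
        self.errors = errors
        super().__init__("cohort validation failed:\n  " + "\n  ".join(errors))


def _check_columns(df: pd.DataFrame, required: list[str], fname: str, errors: list[str]) -> bool:
    missing = [c for c in required if c not in df.columns]
    for c in missing:
        errors.append(f"{fname}: missing column {c!r}")
    return not missing


def read_cohort(subjects_path, longitudinal_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and validate a cohort, returning model-time tables.

    Returns ``(subjects, longitudinal)`` with columns (id, entry, exit,
    event, bmi, mht, mp, fh) and (id, t, y); entry/exit/t are years since
    age 40.  Raises :class:`CohortValidationError` listing every violation
    with its row number.
    """
    subj = pd.read_csv(subjects_path, float_precision="round_trip")
    long = pd.read_csv(longitudinal_path, float_precision="round_trip")
    errors: list[str] = []
    s_name = Path(subjects_path).name
    l_name = Path(longitudinal_path).name

    if not _check_columns(subj, SUBJECT_COLUMNS, s_name, errors):
        raise CohortValidationError(errors)
    if not _check_columns(long, LONGITUDINAL_COLUMNS, l_name, errors):
        raise CohortValidationError(errors)

    for pos, row in enumerate(subj.itertuples(index=False), start=2):
        if not (AGE_ORIGIN <= row.entry_age < row.exit_age <= MAX_AGE):
            errors.append(
                f"{s_name}, row {pos}: ages must satisfy 40 <= entry_age < "
                f"exit_age <= 80 (got {row.entry_age}, {row.exit_age})"
            )
        if row.event not in (0, 1):
            errors.append(f"{s_name}, row {pos}: event must be 0 or 1 (got {row.event})")
        for col in ("mht", "mp", "fh"):
            val = getattr(row, col)
            if val not in _CATEGORY_LEVELS[col]:
                errors.append(
                    f"{s_name}, row {pos}: unknown {col} category {val!r} "
                    f"(expected one of {_CATEGORY_LEVELS[col]})"
                )
        if not np.isfinite(row.bmi):
            errors.append(f"{s_name}, row {pos}: bmi must be finite")

    if subj["id"].duplicated().any():
        dup = subj.loc[subj["id"].duplicated(), "id"].tolist()
        errors.append(f"{s_name}: duplicated subject id(s) {dup}")

    known = set(subj["id"])
    exit_age = dict(zip(subj["id"], subj["exit_age"]))
    for pos, row in enumerate(long.itertuples(index=False), start=2):
        if row.id not in known:
            errors.append(f"{l_name}, row {pos}: unknown subject id {row.id!r}")
            continue
        if not (AGE_ORIGIN <= row.age <= exit_age[row.id] + 1e-9):
            errors.append(
                f"{l_name}, row {pos}: measurement age {row.age} outside "
                f"[40, exit_age={exit_age[row.id]}] for subject {row.id!r}"
            )

    if errors:
        raise CohortValidationError(errors)

    subjects = pd.DataFrame(
        {
            "id": subj["id"],
            "entry": subj["entry_age"] - AGE_ORIGIN,
            "exit": subj["exit_age"] - AGE_ORIGIN,
            "event": subj["event"].astype(int),
            "bmi": subj["bmi"].astype(float),
            "mht": subj["mht"],
            "mp": subj["mp"],
            "fh": subj["fh"],
        }
    )
    longitudinal = pd.DataFrame(
        {"id": long["id"], "t": long["age"] - AGE_ORIGIN, "y": long["sqrt_md"].astype(float)}
    )
    return subjects, longitudinal


def write_cohort(subjects: pd.DataFrame, longitudinal: pd.DataFrame, out_dir, truth: dict | None = None) -> dict:
    """Write model-time tables as age-scale CSV files (full precision).

    Returns the paths written; an optional truth record (generating
    parameters) is stored as JSON next to the data.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = pd.DataFrame(
        {
            "id": subjects["id"],
            "entry_age": subjects["entry"] + AGE_ORIGIN,
            "exit_age": subjects["exit"] + AGE_ORIGIN,
            "event": subjects["event"].astype(int),
            "bmi": subjects["bmi"],
            "mht": subjects["mht"],
            "mp": subjects["mp"],
            "fh": subjects["fh"],
        }
    )
    l = pd.DataFrame(
        {
            "id": longitudinal["id"],
            "age": longitudinal["t"] + AGE_ORIGIN,
            "sqrt_md": longitudinal["y"],
        }
    )
    paths = {
        "subjects": out / "subjects.csv",
        "longitudinal": out / "longitudinal.csv",
    }
    # repr-roundtrip float format keeps the round trip bit-exact
    s.to_csv(paths["subjects"], index=False, float_format=lambda x: repr(float(x)))
    l.to_csv(paths["longitudinal"], index=False, float_format=lambda x: repr(float(x)))
    if truth is not None:
        paths["truth"] = out / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1)
    return paths


def format_count_pct(count: int, total: int) -> str:
    """``"374 (72.2%)"`` — count with its within-stratum percentage, 1 decimal."""
    pct = 0.0 if total == 0 else 100.0 * count / total
    return f"{count} ({pct:.1f}%)"


def _mean_sd(x: pd.Series) -> str:
    if len(x) == 0:
        return "-"
    return f"{x.mean():.1f} ({x.std(ddof=1):.1f})"


def cohort_summary(subjects: pd.DataFrame, longitudinal: pd.DataFrame | None = None) -> pd.DataFrame:
    """Baseline-characteristics table split by diagnosis status.

    Counts with within-stratum percentages (one decimal) for the
    categorical covariates and the number of screens, mean (SD) for the
    continuous ones; columns for women with and without a diagnosis by end
    of follow-up, and for all women.
    """
    strata = {
        "yes": subjects[subjects["event"] == 1],
        "no": subjects[subjects["event"] == 0],
        "all": subjects,
    }
    rows: list[tuple[str, str, dict]] = []

    def add_categorical(var: str, levels) -> None:
        for level in levels:
            cells = {
                key: format_count_pct(int((sub[var] == level).sum()), len(sub))
                for key, sub in strata.items()
            }
            rows.append((var, str(level), cells))

    rows.append(("n", "", {k: str(len(v)) for k, v in strata.items()}))
    if longitudinal is not None:
        screens = longitudinal.groupby("id").size()
        counts = screens.reindex(subjects["id"]).fillna(0).astype(int)
        counts.index = subjects.index
        binned = counts.clip(upper=5).map(lambda k: f"{k}" if k < 5 else "5+")
        for level in sorted(binned.unique()):
            cells = {
                key: format_count_pct(int((binned[sub.index] == level).sum()), len(sub))
                for key, sub in strata.items()
            }
            rows.append(("screens", level, cells))
    add_categorical("mht", MHT_LEVELS)
    add_categorical("mp", MP_LEVELS)
    add_categorical("fh", FH_LEVELS)
    cells = {key: _mean_sd(sub["bmi"]) for key, sub in strata.items()}
    rows.append(("bmi", "mean (sd)", cells))
    if longitudinal is not None:
        first = longitudinal.sort_values("t").groupby("id")["y"].first()
        cells = {
            key: _mean_sd(first.reindex(sub["id"]).dropna()) for key, sub in strata.items()
        }
        rows.append(("sqrt_md at first screen", "mean (sd)", cells))

    return pd.DataFrame(
        {
            "characteristic": [r[0] for r in rows],
            "level": [r[1] for r in rows],
            "diagnosed": [r[2]["yes"] for r in rows],
            "not_diagnosed": [r[2]["no"] for r in rows],
            "all": [r[2]["all"] for r in rows],
        }
    )
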