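"""Long-format CSV schemas, readers/writers, run configuration and reports.

Every panel travels as a plain UTF-8 CSV with a header row; age groups are
serialized as ``"20-24"`` … ``"90-94"`` and periods as integer calendar
years.  Readers validate against the declared schema and reject offending
rows with their file line numbers (the header is line 1).  A column-mapping
option lets extracts with different headers be adapted without editing the
files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import frailty as fr
from .exceptions import ConfigurationError, SchemaError, ValidationError
from .panels import FEFit

log = logging.getLogger("macrofrailty")

STAR_THRESHOLDS = ((0.01, "***"), (0.05, "**"), (0.10, "*"))


def stars(pvalue: float) -> str:
    for cut, s in STAR_THRESHOLDS:
        if pvalue < cut:
            return s
    return ""


@dataclass(frozen=True)
class TableSchema:
    """Declarative description of one long-format table."""

    name: str
    columns: tuple[str, ...]
    key: tuple[str, ...]
    # column -> (predicate on a Series returning a boolean mask of VALID
    # rows, human description)
    constraints: Mapping[str, tuple[Callable[[pd.Series], pd.Series], str]] = field(
        default_factory=dict)
    dtypes: Mapping[str, str] = field(default_factory=dict)


def _in_unit(s: pd.Series) -> pd.Series:
    return (s >= 0) & (s <= 1)


def _positive(s: pd.Series) -> pd.Series:
    return s > 0


def _valid_age(s: pd.Series) -> pd.Series:
    return s.isin(fr.AGE_GROUPS)


def _valid_sex(s: pd.Series) -> pd.Series:
    return s.isin(fr.SEXES)


PREVALENCE_SCHEMA = TableSchema(
    name="prevalence",
    columns=("country", "period", "sex", "age_group", "condition", "prevalence"),
    key=("country", "period", "sex", "age_group", "condition"),
    constraints={
        "prevalence": (_in_unit, "prevalence must lie in [0, 1]"),
        "age_group": (_valid_age, "unknown age-group label"),
        "sex": (_valid_sex, "sex must be 'female' or 'male'"),
    },
    dtypes={"period": "int64", "prevalence": "float64"},
)

POPULATION_SCHEMA = TableSchema(
    name="population",
    columns=("country", "period", "sex", "age_group", "count"),
    key=("country", "period", "sex", "age_group"),
    constraints={
        "count": (_positive, "population count must be positive"),
        "age_group": (_valid_age, "unknown age-group label"),
        "sex": (_valid_sex, "sex must be 'female' or 'male'"),
    },
    dtypes={"period": "int64", "count": "float64"},
)

MORTALITY_SCHEMA = TableSchema(
    name="mortality",
    columns=("country", "period", "sex", "age_group", "mortality"),
    key=("country", "period", "sex", "age_group"),
    constraints={
        "mortality": (_positive, "mortality rate must be positive"),
        "age_group": (_valid_age, "unknown age-group label"),
        "sex": (_valid_sex, "sex must be 'female' or 'male'"),
    },
    dtypes={"period": "int64", "mortality": "float64"},
)

ECON_SCHEMA = TableSchema(
    name="econ",
    columns=("country", "period", "gdp_pw", "ln_gdp_initial",
             "share_20_24", "share_25_34", "share_35_44",
             "share_45_54", "share_55_64"),
    key=("country", "period"),
    constraints={
        "gdp_pw": (_positive, "GDP per working-age person must be positive"),
        "share_20_24": (_in_unit, "share must lie in [0, 1]"),
        "share_25_34": (_in_unit, "share must lie in [0, 1]"),
        "share_35_44": (_in_unit, "share must lie in [0, 1]"),
        "share_45_54": (_in_unit, "share must lie in [0, 1]"),
        "share_55_64": (_in_unit, "share must lie in [0, 1]"),
    },
    dtypes={"period": "int64"},
)

FRAILTY_SCHEMA = TableSchema(
    name="frailty",
    columns=("country", "period", "sex", "age_group", "frailty"),
    key=("country", "period", "sex", "age_group"),
    constraints={
        "frailty": (_in_unit, "frailty index must lie in [0, 1]"),
        "age_group": (_valid_age, "unknown age-group label"),
        "sex": (_valid_sex, "sex must be 'female' or 'male'"),
    },
    dtypes={"period": "int64", "frailty": "float64"},
)

GROUPING_SCHEMA = TableSchema(
    name="grouping",
    columns=("country", "group"),
    key=("country",),
    dtypes={},
)

SCHEMAS = {s.name: s for s in (
    PREVALENCE_SCHEMA, POPULATION_SCHEMA, MORTALITY_SCHEMA,
    ECON_SCHEMA, FRAILTY_SCHEMA, GROUPING_SCHEMA)}


def read_panel(
    path: str | Path,
    schema: TableSchema,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate one long-format CSV against its schema.

    ``column_map`` renames source headers to schema names (e.g. adapting a
    foreign extract); header matching is case-insensitive.  Constraint
    violations and duplicate keys raise with the offending file line number
    (header = line 1, first data row = line 2).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, encoding="utf-8")
    if column_map:
        df = df.rename(columns=dict(column_map))
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for want in schema.columns:
        if want in df.columns:
            continue
        if want.lower() in lower:
            rename[lower[want.lower()]] = want
        else:
            raise SchemaError(f"{schema.name}: missing required column {want!r}")
    df = df.rename(columns=rename)
    df = df[list(schema.columns)]
    for col, dtype in schema.dtypes.items():
        try:
            df[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{schema.name}: column {col!r} not coercible to {dtype}: {exc}")

    n_rejected = 0
    for col, (pred, desc) in schema.constraints.items():
        ok = pred(df[col])
        if not ok.all():
            first = int(np.flatnonzero(~ok.to_numpy())[0])
            n_rejected = int((~ok).sum())
            raise ValidationError(
                f"{schema.name}: {desc} — {n_rejected} offending row(s), "
                f"first at line {first + 2} (value {df[col].iloc[first]!r})")
    dup = df.duplicated(list(schema.key))
    if dup.any():
        first = int(np.flatnonzero(dup.to_numpy())[0])
        key = tuple(df.iloc[first][list(schema.key)])
        raise ValidationError(
            f"{schema.name}: duplicate key {key} at line {first + 2}")
    log.info("read %s: %d rows from %s (%d rejected)",
             schema.name, len(df), path, n_rejected)
    return df


def read_prevalence_csv(path, column_map=None) -> pd.DataFrame:
    return read_panel(path, PREVALENCE_SCHEMA, column_map)


def read_population_csv(path, column_map=None) -> pd.DataFrame:
    return read_panel(path, POPULATION_SCHEMA, column_map)


def read_mortality_csv(path, column_map=None) -> pd.DataFrame:
    return read_panel(path, MORTALITY_SCHEMA, column_map)


def read_econ_csv(path, column_map=None) -> pd.DataFrame:
    return read_panel(path, ECON_SCHEMA, column_map)


def read_frailty_csv(path, column_map=None) -> pd.DataFrame:
    return read_panel(path, FRAILTY_SCHEMA, column_map)


def read_grouping_csv(path, column_map=None) -> dict[str, str]:
    df = read_panel(path, GROUPING_SCHEMA, column_map)
    return dict(zip(df["country"], df["group"]))


def write_panel(df: pd.DataFrame, path: str | Path, schema: TableSchema | None = None) -> Path:
    """Write a panel as CSV in canonical column order (deterministic bytes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df
    if schema is not None:
        out = df[list(schema.columns)]
    out.to_csv(path, index=False, lineterminator="\n")
    log.info("wrote %d rows to %s", len(out), path)
    return path


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and analysis options for a pipeline run."""

    prevalence_path: str | None = None
    population_path: str | None = None
    mortality_path: str | None = None
    econ_path: str | None = None
    grouping_path: str | None = None
    out_dir: str = "out"
    sexes: tuple[str, ...] = fr.SEXES
    age_ranges: tuple[tuple[str, str], ...] = (
        ("20-24", "90-94"), ("20-24", "60-64"),
        ("50-54", "50-54"), ("60-64", "60-64"),
    )
    growth_spec: str = "benchmark"
    horizon_years: int = 29
    seed: int = 0

    def validate(self, require: Sequence[str] = ()) -> None:
        for attr in require:
            p = getattr(self, f"{attr}_path")
            if p is None:
                raise ConfigurationError(f"config is missing {attr}_path")
            if not Path(p).exists():
                raise ConfigurationError(f"{attr}_path does not exist: {p}")
        for lo, hi in self.age_ranges:
            fr.age_range(lo, hi)
        for s in self.sexes:
            if s not in fr.SEXES:
                raise ConfigurationError(f"unknown sex {s!r}")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a flat YAML key-value document into a :class:`RunConfig`."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must be a flat key-value document")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "age_ranges" in raw:
        raw["age_ranges"] = tuple(tuple(r) for r in raw["age_ranges"])
    if "sexes" in raw:
        raw["sexes"] = tuple(raw["sexes"])
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# result reports
# ---------------------------------------------------------------------------

def _fit_table(fit: FEFit) -> pd.DataFrame:
    """Coefficient table in journal layout: estimate, (clustered SE), stars."""
    rows = []
    pv = fit.pvalues
    for name in fit.params.index:
        rows.append({
            "term": name,
            "estimate": fit.params[name],
            "se": fit.se[name],
            "stars": stars(pv[name]),
        })
    rows.append({"term": "Observations", "estimate": fit.nobs, "se": "", "stars": ""})
    rows.append({"term": "R2 (overall)", "estimate": round(fit.r2_overall, 3),
                 "se": "", "stars": ""})
    rows.append({"term": "R2 (within)", "estimate": round(fit.r2_within, 3),
                 "se": "", "stars": ""})
    rows.append({"term": "Country FE",
                 "estimate": "Yes" if "country" in fit.absorbed else "No",
                 "se": "", "stars": ""})
    rows.append({"term": "Period FE",
                 "estimate": "Yes" if "period" in fit.absorbed else "No",
                 "se": "", "stars": ""})
    if "age_group" in fit.absorbed:
        rows.append({"term": "Age FE", "estimate": "Yes", "se": "", "stars": ""})
    has_conv = any(str(t).startswith("lny0_x_") for t in fit.params.index)
    rows.append({"term": "Initial GDP/worker x Period FE",
                 "estimate": "Yes" if has_conv else "No", "se": "", "stars": ""})
    return pd.DataFrame(rows)


def write_results(
    fits: Mapping[str, FEFit],
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write coefficient tables, trend tables and run metadata.

    Each fit becomes ``fit_<name>.csv`` (estimate, clustered SE, significance
    stars at the 10/5/1 percent levels, N, R² and fixed-effect indicator
    rows); each table becomes ``table_<name>.csv``.  Metadata (config echo,
    seed, library versions) goes to ``run_metadata.json``.  With no fits and
    no tables only the metadata file is written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        for name, fit in fits.items():
            p = out_dir / f"fit_{name}.csv"
            _fit_table(fit).to_csv(p, index=False, lineterminator="\n")
            written[f"fit_{name}"] = p
        for name, tab in tables.items():
            p = out_dir / f"table_{name}.csv"
            tab.to_csv(p, index=False, lineterminator="\n")
            written[f"table_{name}"] = p
        meta = {
            "seed": seed,
            "config": dataclasses.asdict(config) if config is not None else None,
            "versions": {
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "outputs": sorted(str(p.name) for p in written.values()),
        }
        mp = out_dir / "run_metadata.json"
        with open(mp, "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        written["metadata"] = mp
        return written
    except OSError as exc:
        raise OSError(f"cannot write results under {out_dir}: {exc}") from exc
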