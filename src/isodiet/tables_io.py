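"""Tabular I/O: validated isotope tables, run configuration, provenance.

The interchange format is plain UTF-8 CSV with "." decimals; per-mil values
are stored as floats.  An :class:`IsotopeTable` is a thin, validated wrapper
around a :class:`pandas.DataFrame` in long format, one row per
(sample, analyte, element) measurement.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .defaults import AA_ALIASES, AA_VOCAB, BULK, ELEMENTS, SEXES
from .errors import ConfigError, SchemaError, VocabularyError

COLUMNS = ["sample_id", "sex", "tissue", "analyte", "element",
           "delta", "sd", "n_replicates"]

_NUMERIC = {"delta": float, "sd": float, "n_replicates": int}

VALID_MODELS = ("model0p", "model0wd", "model1", "model2")


def _normalize_analyte(name: str) -> str:
    name = str(name).strip()
    return AA_ALIASES.get(name, name)


@dataclass(frozen=True)
class AAIsotopeValue:
    """One amino acid's delta value: element, ‰ value and 1σ uncertainty."""

    analyte: str
    element: str
    delta: float
    sd: float

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise SchemaError(f"unknown element {self.element!r}; expected C or N")
        if not (self.sd >= 0):
            raise SchemaError(f"sd must be >= 0, got {self.sd}")


class IsotopeTable:
    """Long-format table of bulk and per-AA delta measurements.

    Invariants enforced at construction: ``sd >= 0``, ``n_replicates >= 1``,
    element in {C, N} (C is reported vs VPDB, N vs AIR), analyte either
    ``"bulk"`` or a member of the controlled AA vocabulary.  Asp/Asn and
    Glu/Gln are collapsed to Asx/Glx at ingest.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = self._validate(df)

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        df = df[COLUMNS].copy()
        for col, typ in _NUMERIC.items():
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[converted.isna() & df[col].notna()]
            if len(bad):
                line = int(bad[0]) + 2  # header is line 1
                raise SchemaError(
                    f"non-numeric value {df.loc[bad[0], col]!r} in column "
                    f"{col!r} at line {line}")
            if converted.isna().any():
                line = int(df.index[converted.isna()][0]) + 2
                raise SchemaError(f"missing value in column {col!r} at line {line}")
            df[col] = converted.astype(typ)
        df["analyte"] = df["analyte"].map(_normalize_analyte)
        bad_aa = sorted(set(df["analyte"]) - set(AA_VOCAB) - {BULK})
        if bad_aa:
            raise VocabularyError(
                f"unknown analyte name(s): {', '.join(bad_aa)}; expected 'bulk' "
                f"or one of {', '.join(AA_VOCAB)}")
        bad_el = sorted(set(df["element"]) - set(ELEMENTS))
        if bad_el:
            raise SchemaError(f"unknown element(s): {', '.join(bad_el)}")
        bad_sex = sorted(set(df["sex"]) - set(SEXES))
        if bad_sex:
            raise SchemaError(f"unknown sex value(s): {', '.join(bad_sex)}")
        if (df["sd"] < 0).any():
            raise SchemaError("sd must be >= 0 for every row")
        if df["sd"].isna().any():
            raise SchemaError("sd may not be missing; the mixing model needs it")
        if (df["n_replicates"] < 1).any():
            raise SchemaError("n_replicates must be >= 1")
        return df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IsotopeTable):
            return NotImplemented
        if len(self) != len(other):
            return False
        a, b = self.df, other.df
        obj = ["sample_id", "sex", "tissue", "analyte", "element"]
        return (a[obj].equals(b[obj])
                and np.allclose(a["delta"], b["delta"], rtol=0, atol=5e-7)
                and np.allclose(a["sd"], b["sd"], rtol=0, atol=5e-7)
                and (a["n_replicates"] == b["n_replicates"]).all())

    def rows_for(self, sample_id: str) -> pd.DataFrame:
        return self.df[self.df["sample_id"] == sample_id]

    def values(self, sample_id: str) -> list[AAIsotopeValue]:
        return [AAIsotopeValue(r.analyte, r.element, r.delta, r.sd)
                for r in self.rows_for(sample_id).itertuples()]


def read_isotope_table(path: str | Path) -> IsotopeTable:
    """Read and validate a long-format isotope CSV."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"sample_id": str, "sex": str,
                                  "tissue": str, "analyte": str,
                                  "element": str})
    return IsotopeTable(df)


def write_isotope_table(table: IsotopeTable, path: str | Path) -> None:
    """Write a table so it reads back equal (floats kept to 9 sig. digits)."""
    df = table.df.copy()
    for col in ("delta", "sd"):
        df[col] = df[col].map(lambda v: format(float(v), ".9g"))
    df.to_csv(path, index=False, lineterminator="\n")


@dataclass
class MCMCSettings:
    burn_in: int = 5000
    iterations: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ConfigError(f"burn_in must be >= 0, got {self.burn_in}")
        if self.iterations < 1:
            raise ConfigError(f"iterations must be >= 1, got {self.iterations}")


@dataclass
class RunConfig:
    """A fit run: model choice, input tables, and sampler settings."""

    model_name: str
    source_table: Path | None = None
    consumer_table: Path | None = None
    offsets_table: Path | None = None
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    olive_oil_enabled: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_name not in VALID_MODELS:
            raise ConfigError(
                f"unknown model_name {self.model_name!r}; valid names: "
                f"{', '.join(VALID_MODELS)}")
        for attr in ("source_table", "consumer_table", "offsets_table"):
            p = getattr(self, attr)
            if p is not None:
                p = Path(p)
                setattr(self, attr, p)
                if not p.exists():
                    raise ConfigError(f"{attr} path does not exist: {p}")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON — a YAML subset) run configuration.

    Omitted MCMC settings default to a 5000-iteration burn-in followed by
    10000 retained iterations; the seed defaults to 0.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "model_name" not in raw:
        raise ConfigError("config must define model_name")
    known = {"model_name", "source_table", "consumer_table", "offsets_table",
             "mcmc", "olive_oil_enabled"}
    mcmc = MCMCSettings(**(raw.get("mcmc") or {}))
    base = path.parent

    def _resolve(key: str) -> Path | None:
        v = raw.get(key)
        return None if v is None else (base / v if not Path(v).is_absolute() else Path(v))

    return RunConfig(
        model_name=raw["model_name"],
        source_table=_resolve("source_table"),
        consumer_table=_resolve("consumer_table"),
        offsets_table=_resolve("offsets_table"),
        mcmc=mcmc,
        olive_oil_enabled=bool(raw.get("olive_oil_enabled", False)),
        extra={k: v for k, v in raw.items() if k not in known},
    )


def provenance_record(config: Mapping | None, seed: int,
                      inputs: Iterable[str | Path] = ()) -> dict:
    """Provenance written alongside every CLI output: config hash, seed,
    package/python versions.  Deliberately timestamp-free so that repeat runs
    are byte-identical."""
    from . import __version__

    cfg_json = json.dumps(config, sort_keys=True, default=str) if config else ""
    return {
        "isodiet_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "seed": int(seed),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        # basenames only: records must be byte-identical across working dirs
        "inputs": [Path(p).name for p in inputs],
    }


def write_provenance(out_dir: str | Path, record: dict) -> Path:
    out = Path(out_dir) / "provenance.json"
    out.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return out
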