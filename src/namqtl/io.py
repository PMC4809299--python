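"""Readers and writers for the pipeline's plain-text formats.

Formats (all TSV/CSV, '#' lines are header metadata and are skipped):

* genotypes.tsv — line_id, family, then one 0/1/2/NA column per marker
* map.tsv       — marker, chromosome, cM
* phenotypes.csv — line_id, year, rep, trait, value (long format)
* weather.csv   — day, mean_temp (consecutive 1-based days)
* blues.csv     — line_id, then one column per trait

Every writer accepts a ``meta`` mapping emitted as ``# key: value`` header
lines so outputs carry version, config hash and seed.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from namqtl import __version__
from namqtl.types import (
    ConfigurationError,
    GeneticMap,
    GenotypeMatrix,
    validate_phenotypes,
)

logger = logging.getLogger("namqtl")

_MISSING_TOKENS = {"NA", "."}
_FLOAT_FORMAT = "%.10g"


class ParseError(ValueError):
    """Raised when an input file violates the documented format."""


def _header_lines(meta: dict | None) -> str:
    meta = dict(meta or {})
    meta.setdefault("namqtl_version", __version__)
    return "".join(f"# {key}: {value}\n" for key, value in meta.items())


def _write_table(df: pd.DataFrame, path, sep: str, meta: dict | None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    df.to_csv(buf, sep=sep, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")
    path.write_text(_header_lines(meta) + buf.getvalue())


def _read_table(path, sep: str, dtype=None, keep_default_na: bool = True) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep=sep, comment="#", dtype=dtype,
            keep_default_na=keep_default_na,
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise ParseError(f"{path}: {exc}") from exc


# -- genotypes ---------------------------------------------------------------

def write_genotypes(genotypes: GenotypeMatrix, path, meta: dict | None = None):
    df = genotypes.to_frame()
    marker_cols = list(genotypes.marker_ids)
    formatted = df[marker_cols].map(
        lambda v: "NA" if np.isnan(v) else str(int(v))
    )
    out = pd.concat([df[["line_id", "family"]], formatted], axis=1)
    _write_table(out, path, "\t", meta)


def read_genotypes(path) -> GenotypeMatrix:
    df = _read_table(path, "\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["line_id", "family"]:
        raise ParseError(
            f"{path}: first two columns must be line_id, family "
            f"(got {list(df.columns[:2])})"
        )
    marker_ids = tuple(df.columns[2:])
    if not marker_ids:
        raise ParseError(f"{path}: no marker columns")
    if df["line_id"].duplicated().any():
        dup = df.loc[df["line_id"].duplicated(), "line_id"].iloc[0]
        raise ParseError(f"{path}: duplicate line_id {dup!r}")

    dosage = np.empty((len(df), len(marker_ids)), dtype=float)
    for col_idx, marker in enumerate(marker_ids):
        tokens = df[marker].astype(str).str.strip()
        for row_idx, token in enumerate(tokens):
            if token in _MISSING_TOKENS:
                dosage[row_idx, col_idx] = np.nan
            elif token in ("0", "1", "2"):
                dosage[row_idx, col_idx] = float(token)
            else:
                raise ParseError(
                    f"{path}: invalid dosage {token!r} at line "
                    f"{df['line_id'].iloc[row_idx]!r}, marker {marker!r}"
                )
    genotypes = GenotypeMatrix(
        line_ids=df["line_id"].to_numpy(dtype=object),
        families=df["family"].to_numpy(dtype=object),
        marker_ids=marker_ids,
        dosage=dosage,
    )
    logger.info("read %d lines x %d markers from %s",
                genotypes.n_lines, genotypes.n_markers, path)
    return genotypes


# -- genetic map -------------------------------------------------------------

def write_map(gmap: GeneticMap, path, meta: dict | None = None):
    _write_table(gmap.to_frame(), path, "\t", meta)


def read_map(path) -> GeneticMap:
    df = _read_table(path, "\t")
    expected = ["marker", "chromosome", "cM"]
    if list(df.columns[:3]) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    df["chromosome"] = df["chromosome"].astype(str)
    ordered = df.sort_values(
        ["chromosome", "cM"], kind="stable", ignore_index=True
    )
    if not ordered["marker"].equals(df["marker"]):
        warnings.warn(f"{path}: map rows were not sorted; sorting by (chromosome, cM)")
        df = ordered
    return GeneticMap(
        marker_ids=tuple(df["marker"].astype(str)),
        chromosomes=tuple(df["chromosome"]),
        positions_cm=df["cM"].to_numpy(dtype=float),
    )


# -- phenotypes --------------------------------------------------------------

def write_phenotypes(records: pd.DataFrame, path, meta: dict | None = None):
    _write_table(validate_phenotypes(records), path, ",", meta)


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_table(path, ",")
    required = ["line_id", "year", "rep", "trait", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    n_before = len(df)
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    dropped = n_before - len(df)
    if dropped:
        logger.info("dropped %d phenotype rows with missing values", dropped)
    key = ["line_id", "year", "rep", "trait"]
    if df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key)].iloc[0]
        raise ParseError(
            f"{path}: duplicate record for (line={dup['line_id']!r}, "
            f"year={dup['year']!r}, rep={dup['rep']!r}, trait={dup['trait']!r})"
        )
    return validate_phenotypes(df)


# -- weather -----------------------------------------------------------------

def write_weather(daily_mean_temps, path, meta: dict | None = None):
    temps = np.asarray(daily_mean_temps, dtype=float)
    df = pd.DataFrame({"day": np.arange(1, temps.size + 1), "mean_temp": temps})
    _write_table(df, path, ",", meta)


def read_weather(path) -> np.ndarray:
    df = _read_table(path, ",")
    for col in ("day", "mean_temp"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    days = df["day"].to_numpy(dtype=int)
    expected = np.arange(1, len(days) + 1)
    if not np.array_equal(days, expected):
        gap = int(expected[days != expected][0]) if len(days) else 1
        raise ParseError(f"{path}: day series has a gap at day {gap}")
    return df["mean_temp"].to_numpy(dtype=float)


# -- BLUEs and generic tables ------------------------------------------------

def write_blues(blues_table: pd.DataFrame, path, meta: dict | None = None):
    out = blues_table.reset_index()
    if out.columns[0] != "line_id":
        out = out.rename(columns={out.columns[0]: "line_id"})
    _write_table(out, path, ",", meta)


def read_blues(path) -> pd.DataFrame:
    df = _read_table(path, ",")
    if "line_id" not in df.columns:
        raise ParseError(f"{path}: missing line_id column")
    return df.set_index("line_id")


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None):
    _write_table(df, path, "\t", meta)


def read_tsv(path) -> pd.DataFrame:
    return _read_table(path, "\t")


# -- truth file for recovery tests ------------------------------------------

def write_qtl_truth(qtl_model, gmap: GeneticMap, path, meta: dict | None = None):
    rows = []
    for idx, beta, mask in zip(
        qtl_model.marker_indices, qtl_model.effects, qtl_model.family_masks
    ):
        rows.append(
            {
                "marker": gmap.marker_ids[idx],
                "chromosome": gmap.chromosomes[idx],
                "cM": gmap.positions_cm[idx],
                "beta": beta,
                "effect_2beta": 2.0 * beta,
                "families": ";".join(sorted(mask)) if mask is not None else "all",
            }
        )
    _write_table(pd.DataFrame.from_records(
        rows, columns=["marker", "chromosome", "cM", "beta", "effect_2beta", "families"]
    ), path, "\t", meta)
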