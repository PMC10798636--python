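"""Tabular I/O, configuration parsing, and the media-recipe calculator.

The canonical on-disk dialect is headered TSV (tab-separated, UTF-8, "."
decimal); CSV is accepted on read via ``csv=True``. Every reader enforces
the schema and value invariants of the table it loads and raises
:class:`~nutriq.errors.FormatError` naming the file, line and column of
the first violation; every writer produces files its reader accepts and
round-trips values losslessly (shortest-repr floats).

Growth-law parameters load from a flat YAML file::

    kappa_t: 4.0
    phi_0: 0.1
    phi_R_max: 0.6
    substrates:
      - {name: glucose, kappa_n_star: 10.0, f: 0.8}

The media-recipe helper converts a salt-stock table row (grams dissolved,
formula weight, final volume) to millimolar, with a half-away-from-zero
rounding companion matching 1-decimal printed recipes.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DomainError, FormatError
from .growth_law import GrowthContext, SubstrateParams
from .phenotype import CFUObservation, ODSeries
from .titration import TitrationCurve

__all__ = [
    "media_molarity",
    "round_half_away",
    "read_growth_config",
    "read_od_series",
    "write_od_series",
    "read_titration",
    "write_titration",
    "read_cfu",
    "write_cfu",
    "read_areas",
    "write_areas",
    "read_abundance",
    "read_foldchange",
    "read_substrates",
    "write_table",
]


# ---------------------------------------------------------------------------
# Media recipe calculator
# ---------------------------------------------------------------------------

def media_molarity(mass_g: float, formula_weight_da: float, volume_L: float) -> float:
    """Molarity in mM of ``mass_g`` grams dissolved to ``volume_L`` liters.

    molarity_mM = 1000 · mass / (formula weight · volume).
    """
    if not (mass_g > 0 and formula_weight_da > 0 and volume_L > 0):
        raise DomainError("mass, formula weight and volume must all be > 0")
    return 1000.0 * mass_g / (formula_weight_da * volume_L)


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero, as printed recipe tables do.

    Python's built-in ``round`` is banker's rounding; recipe tables round
    22.95 → 23.0, so exact halves move away from zero here.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Growth-law configuration
# ---------------------------------------------------------------------------

def read_growth_config(path) -> tuple[GrowthContext, list[SubstrateParams]]:
    """Load a GrowthContext and substrate list from a YAML config file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a key-value mapping")
    for key in ("kappa_t", "phi_0", "phi_R_max"):
        if key not in raw:
            raise ConfigError(f"{path}: missing required key {key!r}")
    try:
        ctx = GrowthContext(
            kappa_t=float(raw["kappa_t"]),
            phi_0=float(raw["phi_0"]),
            phi_R_max=float(raw["phi_R_max"]),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: invalid growth-law parameters: {exc}") from exc
    substrates: list[SubstrateParams] = []
    for i, entry in enumerate(raw.get("substrates") or []):
        if not isinstance(entry, dict):
            raise ConfigError(f"{path}: substrates[{i}] must be a mapping")
        try:
            substrates.append(
                SubstrateParams(
                    name=str(entry["name"]),
                    kappa_n_star=float(entry["kappa_n_star"]),
                    f=float(entry["f"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: substrates[{i}] invalid: {exc}") from exc
    return ctx, substrates


# ---------------------------------------------------------------------------
# Generic schema-checked table reading
# ---------------------------------------------------------------------------

def _read_table(path, columns: dict, csv: bool = False) -> pd.DataFrame:
    """Read a headered TSV/CSV and validate ``columns``.

    ``columns`` maps column name → (dtype, validator, message); validator
    may be None. Reports the first offending data line (1-based, header
    is line 1).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    sep = "," if csv else "\t"
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable as {'CSV' if csv else 'TSV'}: {exc}") from exc
    for name, (dtype, validator, message) in columns.items():
        if name not in df.columns:
            raise FormatError(f"{path}: missing required column {name!r} in header")
        if dtype is not None:
            try:
                if dtype is int:
                    as_float = df[name].astype(float)
                    frac = as_float != np.floor(as_float)
                    if frac.any():
                        line = int(np.flatnonzero(frac.to_numpy())[0]) + 2
                        raise FormatError(
                            f"{path}:{line}: column {name!r}: expected an "
                            f"integer, got {df[name].iloc[line - 2]!r}"
                        )
                    df[name] = as_float.astype(int)
                else:
                    df[name] = df[name].astype(dtype)
            except FormatError:
                raise
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"{path}: column {name!r} is not {dtype}: {exc}"
                ) from exc
        if validator is not None:
            bad = ~df[name].map(validator)
            if bad.any():
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
                raise FormatError(
                    f"{path}:{line}: column {name!r}: {message} "
                    f"(value {df[name].iloc[line - 2]!r})"
                )
    return df


def write_table(df: pd.DataFrame, path, csv: bool = False) -> None:
    """Write a DataFrame as headered TSV (or CSV).

    Floats use 17 significant digits so values round-trip losslessly.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="," if csv else "\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# OD series
# ---------------------------------------------------------------------------

_OD_SCHEMA = {
    "time_h": (float, None, ""),
    "od600": (float, lambda v: v > 0, "OD600 must be > 0"),
}


def read_od_series(path, label: str | None = None, csv: bool = False):
    """Read OD series from TSV with columns time_h, od600 [, label].

    A file holding a single series returns one :class:`ODSeries`; with a
    ``label`` column holding several labels, pass ``label=`` to select
    one, or receive a list of all series.
    """
    df = _read_table(path, _OD_SCHEMA, csv=csv)
    if "label" in df.columns:
        if label is not None:
            df = df[df["label"] == label]
            if df.empty:
                raise FormatError(f"{path}: no rows with label {label!r}")
            return _od_from_frame(df, str(label), path)
        groups = [
            _od_from_frame(g, str(lab), path) for lab, g in df.groupby("label", sort=False)
        ]
        return groups[0] if len(groups) == 1 else groups
    return _od_from_frame(df, label or "", path)


def _od_from_frame(df: pd.DataFrame, label: str, path) -> ODSeries:
    try:
        return ODSeries(
            times=df["time_h"].to_numpy(float),
            od600=df["od600"].to_numpy(float),
            label=label,
        )
    except DomainError as exc:  # pragma: no cover - defensive
        raise FormatError(f"{path}: {exc}") from exc
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_od_series(series, path, csv: bool = False) -> None:
    """Write one ODSeries or a list of them (multi-series get a label column)."""
    if isinstance(series, ODSeries):
        df = pd.DataFrame({"time_h": series.times, "od600": series.od600})
        if series.label:
            df["label"] = series.label
    else:
        frames = [
            pd.DataFrame(
                {"time_h": s.times, "od600": s.od600, "label": s.label or f"series_{i}"}
            )
            for i, s in enumerate(series)
        ]
        df = pd.concat(frames, ignore_index=True)
    write_table(df, path, csv=csv)


# ---------------------------------------------------------------------------
# Titration curves
# ---------------------------------------------------------------------------

_TITRATION_SCHEMA = {
    "x": (float, lambda v: v >= 0, "induction fraction must be >= 0"),
    "lambda": (float, lambda v: v >= 0, "growth rate must be >= 0"),
}


def read_titration(path, mode: str = "hard_min", csv: bool = False) -> TitrationCurve:
    """Read a 2-column (x, lambda) titration TSV."""
    df = _read_table(path, _TITRATION_SCHEMA, csv=csv)
    try:
        return TitrationCurve(
            x=df["x"].to_numpy(float),
            growth_rate=df["lambda"].to_numpy(float),
            mode=mode,
        )
    except DomainError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_titration(curve: TitrationCurve, path, csv: bool = False) -> None:
    write_table(
        pd.DataFrame({"x": curve.x, "lambda": curve.growth_rate}), path, csv=csv
    )


# ---------------------------------------------------------------------------
# CFU observations
# ---------------------------------------------------------------------------

_CFU_SCHEMA = {
    "stage": (str, lambda v: v in ("initial", "final"), "stage must be initial|final"),
    "colonies": (int, lambda v: v >= 0, "colonies must be >= 0"),
    "dilution_factor": (float, lambda v: v >= 1, "dilution_factor must be >= 1"),
    "plated_volume_mL": (float, lambda v: v > 0, "plated_volume_mL must be > 0"),
}


def read_cfu(path, csv: bool = False) -> dict[str, list[CFUObservation]]:
    """Read CFU platings; returns {'initial': [...], 'final': [...]}."""
    df = _read_table(path, _CFU_SCHEMA, csv=csv)
    out: dict[str, list[CFUObservation]] = {"initial": [], "final": []}
    for _, row in df.iterrows():
        out[row["stage"]].append(
            CFUObservation(
                colonies=int(row["colonies"]),
                dilution_factor=float(row["dilution_factor"]),
                plated_volume_mL=float(row["plated_volume_mL"]),
            )
        )
    return out


def write_cfu(observations: dict, path, csv: bool = False) -> None:
    """Write {'initial': [...], 'final': [...]} CFU observations."""
    rows = []
    for stage, obs_list in observations.items():
        for i, obs in enumerate(obs_list, start=1):
            rows.append(
                {
                    "stage": stage,
                    "colonies": obs.colonies,
                    "dilution_factor": obs.dilution_factor,
                    "plated_volume_mL": obs.plated_volume_mL,
                    "replicate": i,
                }
            )
    write_table(pd.DataFrame(rows), path, csv=csv)


# ---------------------------------------------------------------------------
# Colony areas and proteomics tables
# ---------------------------------------------------------------------------

_AREA_SCHEMA = {
    "colony_id": (str, None, ""),
    "day": (int, None, ""),
    "area": (float, lambda v: v > 0, "colony area must be > 0"),
}

_ABUNDANCE_SCHEMA = {
    "gene_id": (str, lambda v: len(v) > 0, "gene_id must be non-empty"),
    "copies_per_cell": (float, lambda v: v >= 0, "copies_per_cell must be >= 0"),
    "length_aa": (int, lambda v: v >= 1, "length_aa must be >= 1"),
}

_FOLDCHANGE_SCHEMA = {
    "gene_id": (str, lambda v: len(v) > 0, "gene_id must be non-empty"),
    "fold_change": (float, lambda v: v > 0, "fold_change must be > 0"),
}

_SUBSTRATE_SCHEMA = {
    "substrate": (str, lambda v: len(v) > 0, "substrate must be non-empty"),
    "gene_id": (str, lambda v: len(v) > 0, "gene_id must be non-empty"),
    "growth_rate": (float, lambda v: v > 0, "growth_rate must be > 0"),
}


def read_areas(path, csv: bool = False) -> pd.DataFrame:
    return _read_table(path, _AREA_SCHEMA, csv=csv)


def write_areas(df: pd.DataFrame, path, csv: bool = False) -> None:
    write_table(df, path, csv=csv)


def read_abundance(path, csv: bool = False) -> pd.DataFrame:
    df = _read_table(path, _ABUNDANCE_SCHEMA, csv=csv)
    _unique_genes(df, path)
    return df


def read_foldchange(path, csv: bool = False) -> pd.DataFrame:
    df = _read_table(path, _FOLDCHANGE_SCHEMA, csv=csv)
    _unique_genes(df, path)
    return df


def read_substrates(path, csv: bool = False) -> pd.DataFrame:
    df = _read_table(path, _SUBSTRATE_SCHEMA, csv=csv)
    _unique_genes(df, path)
    return df


def _unique_genes(df: pd.DataFrame, path) -> None:
    dup = df["gene_id"].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise FormatError(
            f"{path}:{line}: column 'gene_id': duplicate gene id "
            f"{df['gene_id'].iloc[line - 2]!r}"
        )
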