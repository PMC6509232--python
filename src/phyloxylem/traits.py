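"""Species trait/climate table ingestion, transforms and summaries.

The table holds, per species: five xylem tissue fractions in percent of
cross-sectional area (vessel VF, fiber FF, ray RF, axial parenchyma AF and
total parenchyma RAF = RF + AF), mean vessel lumen area A (mm^2), vessel
density N (mm^-2), midpoint latitude/longitude, and thirteen climate
indices grouped as thermal (MAT, ABT, PET, WI, CI, MTWM, MTCM),
moisture (MAP, PWQ, PCQ) and integrative (AET, Im, NPP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FRACTION_COLUMNS = ["VF", "FF", "RF", "AF", "RAF"]
THERMAL_INDICES = ["MAT", "ABT", "PET", "WI", "CI", "MTWM", "MTCM"]
MOISTURE_INDICES = ["MAP", "PWQ", "PCQ"]
INTEGRATIVE_INDICES = ["AET", "Im", "NPP"]
CLIMATE_INDICES = THERMAL_INDICES + MOISTURE_INDICES + INTEGRATIVE_INDICES
CLIMATE_GROUPS = {
    "thermal": THERMAL_INDICES,
    "moisture": MOISTURE_INDICES,
    "integrative": INTEGRATIVE_INDICES,
}

#: tolerance (percentage points) on RAF == RF + AF, absorbing table rounding
RAF_SUM_TOL = 0.5


class TraitTableError(ValueError):
    """Raised for unusable trait-table input."""


@dataclass(frozen=True)
class VesselMetrics:
    """Vessel composition metrics of Zanne et al.-style F/S form.

    ``F = A * N`` is the (unitless) vessel lumen fraction; ``S = A / N``
    (mm^4) separates few-large from many-small vessel strategies.
    Algebraically F * S = A^2 and F / S = N^2, so
    log10 F + log10 S = 2 log10 A.
    """

    F: np.ndarray
    S: np.ndarray
    logF: np.ndarray
    logS: np.ndarray


def vessel_metrics(A, N) -> VesselMetrics:
    """Compute F = A*N, S = A/N and their log10 transforms.

    Parameters
    ----------
    A : array-like
        Mean vessel lumen area, mm^2, strictly positive.
    N : array-like
        Vessel density, mm^-2, strictly positive.
    """
    A = np.asarray(A, dtype=float)
    N = np.asarray(N, dtype=float)
    valid = ~(np.isnan(A) | np.isnan(N))
    if np.any((A[valid] <= 0) | (N[valid] <= 0)):
        raise ValueError("A and N must be strictly positive")
    F = A * N
    S = A / N
    return VesselMetrics(F=F, S=S, logF=np.log10(F), logS=np.log10(S))


def sqrt_fractions(table: pd.DataFrame, columns=FRACTION_COLUMNS) -> pd.DataFrame:
    """Square-root transform percent tissue fractions (variance stabilizing;
    fractions are bounded percentages).  Idempotence is guarded by a frame
    attribute so a pipeline re-run cannot transform twice."""
    if table.attrs.get("sqrt_transformed"):
        return table
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            continue
        vals = out[col].astype(float)
        if (vals.dropna() < 0).any():
            raise ValueError(f"negative values in fraction column {col!r}")
        out[col] = np.sqrt(vals)
    out.attrs["sqrt_transformed"] = True
    return out


def _validate_row(row: pd.Series) -> list[str]:
    reasons = []
    for col in FRACTION_COLUMNS:
        v = row.get(col)
        if v is not None and not pd.isna(v) and not (0 <= v <= 100):
            reasons.append(f"{col} fraction out of range [0, 100]: {v}")
    for col, desc in (("A", "vessel area"), ("N", "vessel density")):
        v = row.get(col)
        if v is not None and not pd.isna(v) and v <= 0:
            reasons.append(f"nonpositive {desc} ({col}={v})")
    lat = row.get("lat_mid")
    if lat is not None and not pd.isna(lat) and not (-90 <= lat <= 90):
        reasons.append(f"latitude out of range: {lat}")
    rf, af, raf = (row.get(c) for c in ("RF", "AF", "RAF"))
    if all(v is not None and not pd.isna(v) for v in (rf, af, raf)):
        if abs(raf - (rf + af)) > RAF_SUM_TOL:
            reasons.append(f"RAF != RF + AF beyond {RAF_SUM_TOL} points")
    return reasons


def load_traits(
    path: str | Path | pd.DataFrame,
    column_map: dict[str, str] | None = None,
    species_column: str = "species",
) -> pd.DataFrame:
    """Load and validate the species x trait CSV.

    ``column_map`` maps canonical names (VF, FF, ..., MAT, ..., lat_mid) to
    the file's column headers.  Rows violating a range invariant are dropped
    with a logged per-row reason; missing cells are preserved as NaN.  When
    RAF is absent but RF and AF are present it is recomputed as their sum.
    """
    if isinstance(path, pd.DataFrame):
        raw = path.copy()
    else:
        raw = pd.read_csv(path)
    if column_map:
        missing = [src for src in column_map.values() if src not in raw.columns]
        if missing:
            raise TraitTableError(f"mapped columns absent from file: {missing}")
        raw = raw.rename(columns={src: dst for dst, src in column_map.items()})
    if species_column not in raw.columns:
        raise TraitTableError(f"no species column {species_column!r}")
    raw[species_column] = raw[species_column].astype(str).str.strip()
    raw = raw.set_index(species_column)

    if "RAF" not in raw.columns and {"RF", "AF"} <= set(raw.columns):
        raw["RAF"] = raw["RF"] + raw["AF"]

    keep, dropped = [], []
    for species, row in raw.iterrows():
        reasons = _validate_row(row)
        if reasons:
            dropped.append((species, reasons))
        else:
            keep.append(species)
    if dropped:
        for species, reasons in dropped:
            logger.warning("dropping %s: %s", species, "; ".join(reasons))
    table = raw.loc[keep]
    if table.empty:
        raise TraitTableError("no valid rows in trait table")
    table.attrs["n_dropped"] = len(dropped)
    table.attrs["dropped"] = dropped
    return table


def summarize(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Per-column min, max, mean, sd and adjusted Fisher-Pearson skewness
    (g1 with the small-sample bias correction)."""
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for col in columns:
        vals = table[col].dropna().astype(float)
        if len(vals) < 2:
            logger.warning("column %s has < 2 values; excluded from summary", col)
            continue
        rows.append(
            {
                "trait": col,
                "n": len(vals),
                "min": vals.min(),
                "max": vals.max(),
                "mean": vals.mean(),
                "sd": vals.std(ddof=1),
                "skewness": stats.skew(vals, bias=False) if vals.nunique() > 1 else 0.0,
            }
        )
    if not rows:
        raise TraitTableError("no summarizable columns")
    return pd.DataFrame(rows).set_index("trait")


def match_tree_and_table(tree, table: pd.DataFrame):
    """Intersect tree tips with table species; both sides pruned, mismatches
    logged and counted.  Returns (pruned_tree, aligned_table)."""
    tips = set(tree.tip_labels)
    species = set(table.index)
    only_tree = sorted(tips - species)
    only_table = sorted(species - tips)
    common = sorted(tips & species)
    if not common:
        raise TraitTableError("tree and trait table share no species")
    if only_tree:
        logger.warning("%d tree tips absent from table (dropped)", len(only_tree))
    if only_table:
        logger.warning("%d table species absent from tree (dropped)", len(only_table))
    pruned = tree.prune(common) if only_tree else tree
    aligned = table.loc[common]
    aligned.attrs["n_dropped_tree"] = len(only_tree)
    aligned.attrs["n_dropped_table"] = len(only_table)
    return pruned, aligned
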