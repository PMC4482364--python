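"""Trait-table ingestion and predictor preparation.

The analysis table has one row per *analysis taxon* — a species-by-region
population. Species whose geographic range straddles the Tropic of Capricorn
appear twice, once per region, each with its own trait values. The response
is proportional range decline in [0, 1]; predictors follow the study's
codings: region (north/south factor), pre-decline geographic range,
mean annual rainfall, mean female body mass and mean litter size (all
natural-log transformed and standardised), and habitat openness as a raw
ordinal rank from 0 (grassland/shrubland) to 4 (rainforest).

Because the beta likelihood lives on the open interval, exact 0/1 declines
are compressed with the Smithson–Verkuilen transform
``y' = (y (n - 1) + 0.5) / n`` before fitting (an epsilon clamp is available
as an alternative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TROPIC_OF_CAPRICORN",
    "DECLINE_CATEGORIES",
    "REQUIRED_COLUMNS",
    "SchemaError",
    "TraitValidationError",
    "TraitTable",
    "PreparedData",
    "read_trait_table",
    "assign_region",
    "categorize_decline",
    "squeeze_response",
    "unsqueeze_response",
    "prepare_predictors",
]

#: Latitude of the Tropic of Capricorn (degrees; negative = southern
#: hemisphere). Range centroids north of this line are 'north'.
TROPIC_OF_CAPRICORN = -23.43665

#: Decline categories partitioning [0, 1]: None iff y == 0, then half-open
#: bins (0, 0.25], (0.25, 0.50], (0.50, 1].
DECLINE_CATEGORIES = ("None", "Low", "Moderate", "High")

#: Canonical column names; a column_map can translate other headers to these.
REQUIRED_COLUMNS = (
    "taxon_id",
    "species",
    "genus",
    "decline",
    "range_km2",
    "rainfall_mm",
    "female_mass_g",
    "habitat_openness",
    "litter_size",
)

#: Columns entered on the natural-log scale and standardised.
LOG_COLUMNS = ("range_km2", "female_mass_g", "rainfall_mm", "litter_size")

#: Pretty names matching the regression-table row labels.
PREDICTOR_LABELS = {
    "ns": "NS",
    "range_km2": "log Range",
    "female_mass_g": "log Female mass",
    "rainfall_mm": "log Rainfall",
    "habitat_openness": "Habitat openness",
    "litter_size": "log Litter",
}


class SchemaError(ValueError):
    """Input file lacks a required column."""


class TraitValidationError(ValueError):
    """A row violates the trait-table contract (names the offending taxa)."""


@dataclass
class TraitTable:
    """Validated analysis table (one row per species-by-region taxon)."""

    data: pd.DataFrame
    provenance: str = "<memory>"

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        if df["taxon_id"].duplicated().any():
            dupes = df.loc[df["taxon_id"].duplicated(), "taxon_id"].tolist()
            raise TraitValidationError(f"duplicate taxon_id values: {dupes}")
        bad = df[(df["decline"] < 0) | (df["decline"] > 1)]
        if len(bad):
            raise TraitValidationError(
                f"decline outside [0, 1] for taxa: {bad['taxon_id'].tolist()}"
            )
        if "region" in df.columns:
            counts = df.groupby("species")["region"].nunique()
            sizes = df.groupby("species").size()
            clashes = sizes[(sizes > 1) & (sizes != counts)].index.tolist()
            if clashes:
                raise TraitValidationError(
                    f"species repeated within one region: {clashes}"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def taxa(self) -> list[str]:
        return self.data["taxon_id"].tolist()

    def tip_mapping(self) -> dict[str, str]:
        """Analysis taxon -> tree tip (species) mapping for covariance expansion."""
        return dict(zip(self.data["taxon_id"], self.data["species"]))


def read_trait_table(path, fmt: str | None = None,
                     column_map: Mapping[str, str] | None = None) -> TraitTable:
    """Read a trait table from CSV or XLSX.

    Parameters
    ----------
    path:
        Input file; format inferred from the suffix unless ``fmt`` is given
        (``"csv"`` or ``"xlsx"``).
    column_map:
        Optional mapping from the file's column headers to the canonical
        names in :data:`REQUIRED_COLUMNS`.

    Rows missing any required predictor are dropped and logged by taxon id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "xlsx":
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns: {missing}")
    check_cols = [c for c in REQUIRED_COLUMNS if c != "taxon_id"]
    incomplete = df[check_cols].isna().any(axis=1)
    if incomplete.any():
        dropped = df.loc[incomplete, "taxon_id"].tolist()
        logger.warning(
            "%s: dropped %d rows with missing required predictors: %s",
            path.name, len(dropped), dropped,
        )
        df = df.loc[~incomplete].reset_index(drop=True)
    return TraitTable(data=df, provenance=path.name)


def assign_region(latitude_or_record,
                  tropic_latitude: float = TROPIC_OF_CAPRICORN) -> str:
    """Assign 'north' or 'south' from a range-centroid latitude.

    Accepts a latitude (degrees) or a mapping/row with ``region`` and/or
    ``centroid_latitude`` fields; an explicit region overrides the latitude.
    A centroid exactly on the tropic is 'south' ("north of the Tropic" read
    strictly).
    """
    rec = latitude_or_record
    if isinstance(rec, (int, float, np.floating)):
        lat = float(rec)
    else:
        region = rec.get("region") if hasattr(rec, "get") else rec["region"]
        if region is not None and not (isinstance(region, float) and np.isnan(region)):
            region = str(region).lower()
            if region not in ("north", "south"):
                raise ValueError(f"unknown region {region!r}")
            return region
        lat = rec.get("centroid_latitude") if hasattr(rec, "get") else None
        if lat is None or (isinstance(lat, float) and np.isnan(lat)):
            raise ValueError("neither region nor centroid_latitude available")
        lat = float(lat)
    return "north" if lat > tropic_latitude else "south"


def assign_regions(table: TraitTable,
                   tropic_latitude: float = TROPIC_OF_CAPRICORN) -> TraitTable:
    """Fill the ``region`` column of a table from centroid latitudes."""
    df = table.data.copy()
    if "region" not in df.columns:
        df["region"] = None
    df["region"] = [
        assign_region(row, tropic_latitude) for _, row in df.iterrows()
    ]
    return TraitTable(data=df, provenance=table.provenance)


def categorize_decline(y):
    """Map proportional decline(s) to {None, Low, Moderate, High}.

    ``None`` iff y == 0, Low on (0, 0.25], Moderate on (0.25, 0.50], High on
    (0.50, 1]. Scalar in -> string out; array in -> object array out.
    """
    arr = np.asarray(y, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("decline values must lie in [0, 1]")
    cats = np.where(
        arr == 0, "None",
        np.where(arr <= 0.25, "Low", np.where(arr <= 0.50, "Moderate", "High")),
    )
    if np.isscalar(y) or np.ndim(y) == 0:
        return str(cats[()])
    return cats


def squeeze_response(y, n: int) -> np.ndarray:
    """Smithson–Verkuilen compression of [0, 1] responses into (0, 1).

    ``y' = (y (n - 1) + 0.5) / n`` with ``n`` the number of analysis taxa.
    Strictly order-preserving; 0.5 is a fixed point.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    arr = np.asarray(y, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("responses must lie in [0, 1]")
    return (arr * (n - 1) + 0.5) / n


def unsqueeze_response(y_prime, n: int) -> np.ndarray:
    """Invert :func:`squeeze_response`."""
    return (np.asarray(y_prime, dtype=float) * n - 0.5) / (n - 1)


@dataclass
class PreparedData:
    """Model-ready response and predictor columns.

    ``response`` is the squeezed decline in (0, 1). ``predictors`` holds one
    column per model term (region indicator ``NS`` with north = 1, the four
    standardised natural-log predictors, and the raw habitat-openness rank),
    ordered as in the regression tables. ``scaling`` stores per-column
    (mean, sd) of the log-scale values so standardisation can be inverted.
    """

    taxa: list[str]
    response: np.ndarray
    raw_response: np.ndarray
    predictors: pd.DataFrame
    scaling: dict[str, tuple[float, float]]
    squeeze_rule: str = "smithson-verkuilen"

    def unstandardize(self, column: str) -> np.ndarray:
        """Recover the log-scale values of a standardised column."""
        label = PREDICTOR_LABELS.get(column, column)
        mean, sd = self.scaling[label]
        return self.predictors[label].to_numpy() * sd + mean


def prepare_predictors(table: TraitTable,
                       squeeze_rule: str = "smithson-verkuilen",
                       clamp_eps: float = 1e-4) -> PreparedData:
    """Transform and standardise the predictor columns; squeeze the response.

    Natural logs of range, female mass, rainfall and litter size, each
    centred and scaled by its own sample mean and sd (n - 1 denominator);
    habitat openness passes through as its raw rank; region is coded
    north = 1, south = 0.
    """
    df = table.data
    if len(df) < 2:
        raise ValueError("need at least 2 taxa to prepare predictors")
    if "region" not in df.columns or df["region"].isna().any():
        raise ValueError("regions must be assigned before preparation")

    cols: dict[str, np.ndarray] = {}
    scaling: dict[str, tuple[float, float]] = {}
    region = df["region"].astype(str).str.lower()
    if not region.isin(("north", "south")).all():
        raise ValueError("region column must contain only 'north'/'south'")
    cols["NS"] = (region == "north").to_numpy(dtype=float)

    for raw_col in LOG_COLUMNS:
        vals = df[raw_col].to_numpy(dtype=float)
        if np.any(vals <= 0):
            bad = df.loc[vals <= 0, "taxon_id"].tolist()
            raise TraitValidationError(
                f"non-positive values in {raw_col} for taxa: {bad}"
            )
        logs = np.log(vals)
        mean = float(np.mean(logs))
        sd = float(np.std(logs, ddof=1))
        if sd == 0:
            raise TraitValidationError(
                f"column {raw_col} has zero variance; cannot standardise"
            )
        label = PREDICTOR_LABELS[raw_col]
        cols[label] = (logs - mean) / sd
        scaling[label] = (mean, sd)

    ranks = df["habitat_openness"].to_numpy(dtype=float)
    if not np.all(np.isin(ranks, [0, 1, 2, 3, 4])):
        raise TraitValidationError("habitat_openness must be a rank in {0..4}")
    cols["Habitat openness"] = ranks

    order = ["NS", "log Range", "log Female mass", "log Rainfall",
             "Habitat openness", "log Litter"]
    predictors = pd.DataFrame({k: cols[k] for k in order},
                              index=df["taxon_id"].tolist())

    raw_y = df["decline"].to_numpy(dtype=float)
    n = len(df)
    if squeeze_rule == "smithson-verkuilen":
        y = squeeze_response(raw_y, n)
    elif squeeze_rule == "clamp":
        y = np.clip(raw_y, clamp_eps, 1.0 - clamp_eps)
    elif squeeze_rule == "none":
        # For responses already strictly inside (0, 1), e.g. beta-simulated
        # data; compressing such data onto common boundary values would
        # discard the tail information that identifies the dispersion.
        if np.any((raw_y <= 0) | (raw_y >= 1)):
            raise TraitValidationError(
                "squeeze_rule='none' requires responses strictly in (0, 1)"
            )
        y = raw_y.copy()
    else:
        raise ValueError(f"unknown squeeze rule {squeeze_rule!r}")

    return PreparedData(
        taxa=df["taxon_id"].tolist(),
        response=y,
        raw_response=raw_y,
        predictors=predictors,
        scaling=scaling,
        squeeze_rule=squeeze_rule,
    )
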