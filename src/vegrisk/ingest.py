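"""Input parsing, non-detect substitution, and per-combination summaries.

Monitoring data for trace contaminants are heavily left-censored: a large
fraction of samples fall below the analytical limit of detection (LOD).
Following GEMS/FOOD practice for low-level contaminants, non-detects are
substituted with LOD/2 when the non-detect proportion is below 60% and with
the full LOD when it is 60% or higher; summaries (mean, P50, P95, max) are
then computed on the completed data.

Tables are plain :class:`pandas.DataFrame` objects with fixed column schemas:

========================  ===============================================================
sampling table            region, category, concentration_mg_per_kg (NaN for
                          non-detects), detected (0/1), lod_mg_per_kg
consumption table         region, category, fc_kg_per_day
limits table              category, limit_mg_per_kg
========================  ===============================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, SchemaError

logger = logging.getLogger(__name__)

SAMPLING_COLUMNS = [
    "region",
    "category",
    "concentration_mg_per_kg",
    "detected",
    "lod_mg_per_kg",
]
CONSUMPTION_COLUMNS = ["region", "category", "fc_kg_per_day"]
LIMIT_COLUMNS = ["category", "limit_mg_per_kg"]
TOX_KEYS = ["rfd_ug_per_kg_day", "bmdl01_ug_per_kg_day", "body_weight_kg"]


@dataclass(frozen=True)
class ToxRefs:
    """Toxicological reference values for the contaminant under assessment.

    Parameters
    ----------
    rfd : float
        Oral reference dose, ug/(kg body weight * day).
    bmdl01 : float
        Lower 95% confidence bound on the benchmark dose for a 1% response,
        ug/(kg body weight * day).
    body_weight : float
        Reference adult body weight, kg.
    """

    rfd: float
    bmdl01: float
    body_weight: float

    def __post_init__(self) -> None:
        for name in ("rfd", "bmdl01", "body_weight"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise SchemaError(f"ToxRefs.{name} must be strictly positive, got {v!r}")


def _check_columns(df: pd.DataFrame, required: list[str], path: object) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
    return df[required].copy()


def _require_numeric(df: pd.DataFrame, column: str, path: object, *, allow_nan: bool = False) -> None:
    coerced = pd.to_numeric(df[column], errors="coerce")
    bad = coerced.isna() & df[column].notna()
    if bad.any():
        row = int(bad.idxmax())
        raise SchemaError(f"{path}: non-numeric value in column '{column}' at row {row}")
    if not allow_nan and coerced.isna().any():
        row = int(coerced.isna().idxmax())
        raise SchemaError(f"{path}: missing value in column '{column}' at row {row}")
    df[column] = coerced


def read_sampling_csv(path: str | Path) -> pd.DataFrame:
    """Read raw per-sample concentration records with censoring metadata.

    Non-detect rows (``detected == 0``) leave ``concentration_mg_per_kg``
    empty; every row must carry a positive LOD.
    """
    df = _check_columns(pd.read_csv(path), SAMPLING_COLUMNS, path)
    _require_numeric(df, "concentration_mg_per_kg", path, allow_nan=True)
    _require_numeric(df, "detected", path)
    _require_numeric(df, "lod_mg_per_kg", path)
    if not df["detected"].isin([0, 1]).all():
        row = int((~df["detected"].isin([0, 1])).idxmax())
        raise SchemaError(f"{path}: column 'detected' must be 0/1, bad value at row {row}")
    df["detected"] = df["detected"].astype(bool)
    if (df["lod_mg_per_kg"] <= 0).any():
        row = int((df["lod_mg_per_kg"] <= 0).idxmax())
        raise SchemaError(f"{path}: non-positive LOD in column 'lod_mg_per_kg' at row {row}")
    det = df["detected"]
    if df.loc[det, "concentration_mg_per_kg"].isna().any():
        row = int((det & df["concentration_mg_per_kg"].isna()).idxmax())
        raise SchemaError(f"{path}: detected record missing concentration at row {row}")
    if (df.loc[det, "concentration_mg_per_kg"] < 0).any():
        row = int((det & (df["concentration_mg_per_kg"] < 0)).idxmax())
        raise SchemaError(f"{path}: negative concentration at row {row}")
    return df


def read_consumption_csv(path: str | Path) -> pd.DataFrame:
    """Read the region x category mean daily consumption table (kg/day)."""
    df = _check_columns(pd.read_csv(path), CONSUMPTION_COLUMNS, path)
    _require_numeric(df, "fc_kg_per_day", path)
    if (df["fc_kg_per_day"] <= 0).any():
        row = int((df["fc_kg_per_day"] <= 0).idxmax())
        raise SchemaError(f"{path}: non-positive value in column 'fc_kg_per_day' at row {row}")
    return df


def read_limits_csv(path: str | Path) -> pd.DataFrame:
    """Read the category -> regulatory limit table (mg/kg)."""
    df = _check_columns(pd.read_csv(path), LIMIT_COLUMNS, path)
    _require_numeric(df, "limit_mg_per_kg", path)
    if (df["limit_mg_per_kg"] <= 0).any():
        row = int((df["limit_mg_per_kg"] <= 0).idxmax())
        raise SchemaError(f"{path}: non-positive value in column 'limit_mg_per_kg' at row {row}")
    return df


def read_tox_config(path: str | Path) -> ToxRefs:
    """Read toxicological reference values from YAML (mapping) or two-column CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if not {"key", "value"}.issubset(df.columns):
            raise SchemaError(f"{path}: tox CSV needs columns 'key' and 'value'")
        raw = dict(zip(df["key"], df["value"]))
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: tox config must be a mapping")
    missing = [k for k in TOX_KEYS if k not in raw]
    if missing:
        raise SchemaError(f"{path}: missing tox key(s) {missing}")
    try:
        vals = {k: float(raw[k]) for k in TOX_KEYS}
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: non-numeric tox value ({exc})") from exc
    return ToxRefs(
        rfd=vals["rfd_ug_per_kg_day"],
        bmdl01=vals["bmdl01_ug_per_kg_day"],
        body_weight=vals["body_weight_kg"],
    )


def substitute_nondetects(table: pd.DataFrame, scope: str = "global") -> pd.DataFrame:
    """Replace censored concentrations by the GEMS/FOOD rule.

    If the non-detect proportion (over ``scope``: ``"global"`` or
    ``"per_combination"``) is below 60%, non-detects become LOD/2; at 60% or
    above they become the full LOD. Detected records are untouched, and the
    returned table carries a concentration for every record (idempotent:
    a table without non-detects passes through unchanged).
    """
    if scope not in ("global", "per_combination"):
        raise ValueError(f"scope must be 'global' or 'per_combination', got {scope!r}")
    out = table.copy()
    nd = ~out["detected"].astype(bool)
    if not nd.any():
        return out
    if out.loc[nd, "lod_mg_per_kg"].isna().any():
        row = int((nd & out["lod_mg_per_kg"].isna()).idxmax())
        raise DataError(f"nondetect record at row {row} lacks an LOD")

    def _fill(mask: pd.Series, frac: float) -> None:
        factor = 1.0 if frac >= 0.6 else 0.5
        out.loc[mask, "concentration_mg_per_kg"] = out.loc[mask, "lod_mg_per_kg"] * factor

    if scope == "global":
        _fill(nd, nd.mean())
    else:
        for _, idx in out.groupby(["region", "category"], sort=False).groups.items():
            sub_nd = nd.loc[idx]
            if sub_nd.any():
                _fill(sub_nd[sub_nd].index.to_series(), sub_nd.mean())
    return out


def summarize_combinations(
    table: pd.DataFrame, quantile_method: str = "linear"
) -> pd.DataFrame:
    """Summarise each (region, category) group after censoring substitution.

    Returns one row per combination with ``n``, ``mean``, ``p50``, ``p95``,
    ``max`` (mg/kg) and ``nd_fraction``. Quantiles use ``quantile_method``
    (any :func:`numpy.quantile` method; default linear interpolation between
    order statistics at rank p*(n-1)).
    """
    if table["concentration_mg_per_kg"].isna().any():
        raise DataError("summarize_combinations requires substituted concentrations (no NaN)")
    rows = []
    for (region, category), grp in table.groupby(["region", "category"], sort=True):
        x = grp["concentration_mg_per_kg"].to_numpy(float)
        if x.size == 0:  # pragma: no cover - groupby never yields empty groups
            logger.warning("empty group (%s, %s) excluded", region, category)
            continue
        rows.append(
            {
                "region": region,
                "category": category,
                "n": int(x.size),
                "mean": float(x.mean()),
                "p50": float(np.quantile(x, 0.5, method=quantile_method)),
                "p95": float(np.quantile(x, 0.95, method=quantile_method)),
                "max": float(x.max()),
                "nd_fraction": float(1.0 - grp["detected"].mean()),
            }
        )
    return pd.DataFrame(rows)
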