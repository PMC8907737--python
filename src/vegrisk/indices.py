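"""Exposure and pollution indexes: NIPI, hazard index, margin of exposure.

Three complementary per-combination indexes quantify dietary lead risk:

* **NIPI** (Nemerow integrated pollution index)
  ``Pc = sqrt((Pmax^2 + Pave^2) / 2)`` with single-factor pollution indexes
  ``P = X / S`` (concentration over regulatory limit). Combines worst-case
  and average contamination; dimensionless.
* **HI** (hazard index) ``HI = EDI95 / RfD``: estimated daily intake at high
  (95th-percentile) contamination relative to the oral reference dose.
  HI < 1 is conventionally acceptable.
* **MOE** (margin of exposure) ``MOE = BMDL01 / EDI50``: benchmark-dose
  lower bound over median-contamination intake. Larger is safer.

Estimated daily intake is ``EDI = FC * X / W`` with consumption FC in
kg/day, concentration X in mg/kg and body weight W in kg; the mg -> ug
conversion (x1000) is applied so EDI shares the ug/(kg*day) scale of RfD
and BMDL01.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd

from .errors import DataError, DomainError
from .ingest import ToxRefs

logger = logging.getLogger(__name__)

#: Sentinel cap for MOE when median exposure is (numerically) zero.
MOE_CAP = 1e6

FEATURE_COLUMNS = ["pc", "hi", "moe"]


def pollution_index(x: float, s: float) -> float:
    """Single-factor pollution index P = X/S (concentration over limit)."""
    if s <= 0:
        raise DomainError(f"limit must be positive, got {s}")
    if x < 0:
        raise DomainError(f"concentration must be non-negative, got {x}")
    return x / s


def nemerow_index(p_max: float, p_ave: float) -> float:
    """Nemerow integrated pollution index sqrt((Pmax^2 + Pave^2)/2).

    Always lies in [Pmax/sqrt(2), Pmax].
    """
    if p_ave < 0 or p_max < 0:
        raise DomainError("pollution indexes must be non-negative")
    if p_ave > p_max:
        # a mean of identical values can exceed the max by rounding error
        if p_ave <= p_max * (1 + 1e-9) + 1e-12:
            p_ave = p_max
        else:
            raise DomainError(f"inconsistent summary: p_ave {p_ave} > p_max {p_max}")
    return math.sqrt((p_max**2 + p_ave**2) / 2.0)


def estimated_daily_intake(fc: float, x: float, w: float) -> float:
    """EDI = FC*X/W in ug/(kg*day) from FC [kg/day], X [mg/kg], W [kg]."""
    if w <= 0:
        raise DomainError(f"body weight must be positive, got {w}")
    if fc <= 0:
        raise DomainError(f"consumption must be positive, got {fc}")
    if x < 0:
        raise DomainError(f"concentration must be non-negative, got {x}")
    return fc * x / w * 1000.0


def hazard_index(edi95: float, rfd: float) -> float:
    """Noncarcinogenic hazard index HI = EDI95/RfD (both ug/(kg*day))."""
    if rfd <= 0:
        raise DomainError(f"RfD must be positive, got {rfd}")
    if edi95 < 0:
        raise DomainError(f"EDI must be non-negative, got {edi95}")
    return edi95 / rfd


def margin_of_exposure(bmdl01: float, edi50: float) -> float:
    """Margin of exposure MOE = BMDL01/EDI50 (both ug/(kg*day)).

    Undefined at zero exposure; callers aggregating whole tables should cap
    rather than fail (see :func:`build_feature_matrix`).
    """
    if bmdl01 <= 0:
        raise DomainError(f"BMDL01 must be positive, got {bmdl01}")
    if edi50 <= 0:
        raise DomainError(f"EDI50 must be positive, got {edi50}")
    return bmdl01 / edi50


def build_feature_matrix(
    stats: pd.DataFrame,
    consumption: pd.DataFrame,
    limits: pd.DataFrame,
    tox: ToxRefs,
    *,
    moe_cap: float = MOE_CAP,
) -> pd.DataFrame:
    """Assemble the (pc, hi, moe) clustering features per combination.

    ``pc`` uses the group's max and mean over the category limit (the mean of
    per-sample pollution indexes equals mean concentration over the limit, so
    summary means are exact inputs); ``hi`` uses intake at the 95th
    percentile; ``moe`` uses intake at the median, capped at ``moe_cap``
    (with a warning) if median exposure is zero or the ratio overflows it.

    Rows are ordered region-major lexicographically. Combinations lacking a
    consumption entry or a category limit raise :class:`DataError` listing
    all offenders.
    """
    fc_map = {
        (r, c): fc
        for r, c, fc in consumption[["region", "category", "fc_kg_per_day"]].itertuples(index=False)
    }
    s_map = dict(limits[["category", "limit_mg_per_kg"]].itertuples(index=False))

    missing_fc = []
    missing_s = []
    rows = []
    for row in stats.sort_values(["region", "category"]).itertuples(index=False):
        key = (row.region, row.category)
        if key not in fc_map:
            missing_fc.append(key)
            continue
        if row.category not in s_map:
            missing_s.append(key)
            continue
        s = s_map[row.category]
        fc = fc_map[key]
        pc = nemerow_index(pollution_index(row.max, s), pollution_index(row.mean, s))
        hi = hazard_index(estimated_daily_intake(fc, row.p95, tox.body_weight), tox.rfd)
        edi50 = fc * row.p50 / tox.body_weight * 1000.0
        if edi50 <= 0:
            logger.warning(
                "zero median exposure for %s; MOE capped at %g", key, moe_cap
            )
            moe = moe_cap
        else:
            moe = min(margin_of_exposure(tox.bmdl01, edi50), moe_cap)
        rows.append({"region": row.region, "category": row.category, "pc": pc, "hi": hi, "moe": moe})
    problems = []
    if missing_fc:
        problems.append(f"no consumption entry for {sorted(missing_fc)}")
    if missing_s:
        problems.append(f"no category limit for {sorted(missing_s)}")
    if problems:
        raise DataError("; ".join(problems))
    return pd.DataFrame(rows, columns=["region", "category", *FEATURE_COLUMNS])


def write_indices_csv(features: pd.DataFrame, path: str | Path) -> None:
    """Write the feature matrix with full precision plus 3-decimal display columns."""
    out = features.copy()
    for col in FEATURE_COLUMNS:
        out[f"{col}_rounded"] = out[col].round(3)
    out.to_csv(path, index=False)
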