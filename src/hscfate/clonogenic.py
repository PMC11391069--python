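"""Statistics for single-cell in-vitro assays.

Covers three clonal readouts: Poisson-corrected plating frequencies for
manually seeded wells (limiting-dilution single-hit model), division
kinetics of single plated cells over 3 days, and day-11 megakaryocyte and
day-28 cobblestone-area-forming cell (CAFC) frequencies.

Under Poisson seeding at mean ``lambda`` cells/well with an independent
per-cell readout probability p, a well is positive with probability
``1 - exp(-lambda * p)``; inverting the observed positive-well fraction f
gives ``p = -ln(1 - f) / lambda``. When f approaches or exceeds the single-
hit maximum ``1 - exp(-lambda)`` the estimate saturates (p would exceed 1)
and is clipped with a warning.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

SEEDING_SORTED = "sorted_single"
SEEDING_POISSON = "manual_poisson"


class SaturationError(ValueError):
    """All wells positive: the single-hit model cannot be inverted."""


def poisson_corrected_frequency(
    n_positive_wells: int, n_wells: int, lam: float
) -> float:
    """Per-cell readout probability from Poisson-seeded well outcomes.

    Parameters
    ----------
    n_positive_wells, n_wells
        Positive and total evaluable well counts.
    lam
        Mean cells seeded per well (Poisson mean).
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not 0 <= n_positive_wells <= n_wells:
        raise ValueError("need 0 <= n_positive <= n_wells")
    f = n_positive_wells / n_wells
    if f >= 1.0:
        raise SaturationError("all wells positive: frequency unidentifiable")
    p = -math.log1p(-f) / lam
    if f >= 1.0 - math.exp(-lam):
        warnings.warn(
            f"observed fraction {f:.3f} at or beyond single-hit saturation "
            f"{1 - math.exp(-lam):.3f}; estimate clipped to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return min(p, 1.0)


def division_kinetics(wells: pd.DataFrame, days=(1, 2, 3)) -> pd.DataFrame:
    """Cumulative fraction of wells whose cell has divided, per day.

    `wells` is long format with columns well_id, day, readout ('divided' or
    'none'). A well must be observed on every requested day; wells with a
    missing observation are excluded and reported in the `n_excluded` attr.
    Once divided, a well stays divided (cumulative).
    """
    days = sorted(days)
    obs = wells.pivot_table(
        index="well_id", columns="day", values="readout", aggfunc="first"
    )
    missing = [d for d in days if d not in obs.columns]
    if missing:
        obs[missing] = np.nan
    complete = obs[days].notna().all(axis=1)
    evaluable = obs.loc[complete, days]
    if evaluable.empty:
        raise ValueError("no evaluable wells (all have missing days)")
    divided = (evaluable == "divided").to_numpy()
    cumulative = np.maximum.accumulate(divided, axis=1)
    out = pd.DataFrame(
        {"day": days, "n_wells": len(evaluable),
         "n_divided": cumulative.sum(axis=0),
         "cumulative_fraction": cumulative.mean(axis=0)}
    )
    out.attrs["n_excluded"] = int((~complete).sum())
    return out


def megakaryocyte_frequency(
    n_positive_wells: int,
    n_wells: int,
    seeding_mode: str = SEEDING_SORTED,
    lam: float = 1.0,
) -> float:
    """Fraction of clones producing megakaryocytes (scored at day 11).

    Single-sorted wells report the raw positive fraction; manually seeded
    plates are corrected for Poisson co-seeding via the single-hit model.
    """
    if n_wells <= 0:
        raise ValueError("no wells scored")
    if seeding_mode == SEEDING_SORTED:
        return n_positive_wells / n_wells
    if seeding_mode == SEEDING_POISSON:
        return poisson_corrected_frequency(n_positive_wells, n_wells, lam)
    raise ValueError(f"unknown seeding mode: {seeding_mode!r}")


def cafc_frequency(
    n_cafc: int,
    n_input_cells: int,
    non_migrated_24h: int | None = None,
    non_migrated_48h: int | None = None,
) -> dict:
    """CAFC frequency per input cell and migrated fractions at 24 h / 48 h.

    A CAFC is a cluster of more than three cobblestone-like cells under the
    stromal layer, counted 28 days post co-culture; migration is inferred
    from the cells remaining on top of the stroma at 24 h and 48 h.
    """
    if n_input_cells < 1:
        raise ValueError("need at least one input cell")
    if n_cafc < 0:
        raise ValueError("negative CAFC count")
    out = {"cafc_per_input": n_cafc / n_input_cells}
    for label, n_nm in (("24h", non_migrated_24h), ("48h", non_migrated_48h)):
        if n_nm is None:
            continue
        if n_nm > n_input_cells:
            raise ValueError(
                f"non-migrated cells ({n_nm}) exceed input ({n_input_cells})"
            )
        out[f"migrated_fraction_{label}"] = max(0.0, 1.0 - n_nm / n_input_cells)
    return out


def well_table_frequencies(wells: pd.DataFrame, lam: float = 1.0) -> pd.DataFrame:
    """Per-plate summary of a long well-outcome table.

    Expects columns plate_id, well_id, seeding_mode, day, readout. For each
    plate and scored readout, reports the raw positive fraction and, for
    manually seeded plates, the Poisson-corrected per-cell frequency.
    """
    records = []
    for (plate, mode), sub in wells.groupby(["plate_id", "seeding_mode"], sort=True):
        n = sub["well_id"].nunique()
        for readout in ("divided", "megakaryocyte_present", "cafc_present"):
            pos = sub.loc[sub["readout"] == readout, "well_id"].nunique()
            if pos == 0 and readout not in set(sub["readout"]):
                continue
            rec = {"plate_id": plate, "seeding_mode": mode, "readout": readout,
                   "n_wells": n, "n_positive": pos, "fraction": pos / n}
            if mode == SEEDING_POISSON:
                try:
                    rec["per_cell_frequency"] = poisson_corrected_frequency(pos, n, lam)
                except SaturationError:
                    rec["per_cell_frequency"] = np.nan
            else:
                rec["per_cell_frequency"] = pos / n
            records.append(rec)
    return pd.DataFrame(records)
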