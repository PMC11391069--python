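"""Transplantation chimerism scoring and lymphoid/myeloid lineage-bias calls.

Competitive-transplantation readouts arrive as per-mouse flow-cytometry event
counts: donor (CD45.2, or Gata-1 eGFP for platelets/erythrocytes) and total
events per blood compartment and lineage. This module turns those counts into

* donor chimerism (percent of a compartment that is donor-derived),
* a month-2 reconstitution call (was the graft detectable at all),
* per-lineage positivity calls,
* relative B/T/NK/myeloid contributions within donor leukocytes,
* the lymphoid-to-myeloid (L/M) ratio, and
* a lineage-bias category (L-bi / Bal / M-bi) against a reference interval
  derived from unmanipulated age-matched mice.

Thresholds follow the published gating rules: a mouse is reconstituted when
donor leukocytes and/or platelets reach >= 0.1% of the compartment backed by
>= 10 donor-gate events; a single lineage is positive at >= 0.01% and >= 10
events. Classification is scale-free in the event counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, gmean

LYMPHOID_LINEAGES = ("B", "T", "NK")
MYELOID_LINEAGE = "myeloid"
LEUKOCYTE_LINEAGES = LYMPHOID_LINEAGES + (MYELOID_LINEAGE,)

#: default printed thresholds
RECONSTITUTION_MIN_PERCENT = 0.1
LINEAGE_MIN_PERCENT = 0.01
MIN_DONOR_EVENTS = 10

CATEGORY_M_BI = "M-bi"
CATEGORY_BAL = "Bal"
CATEGORY_L_BI = "L-bi"


class DataError(ValueError):
    """Raised when event counts are internally inconsistent."""


@dataclass(frozen=True)
class ReconstitutionCall:
    mouse_id: str
    positive: bool
    evidence: tuple[str, ...] = ()

    def __post_init__(self):
        if self.positive and not self.evidence:
            raise ValueError("positive call requires non-empty evidence")


@dataclass(frozen=True)
class ReferenceInterval:
    """L/M bounds delimiting the balanced (Bal) category."""

    reference_mode: str
    lower: float
    upper: float
    derivation_rule: str
    cohort_size: int

    def __post_init__(self):
        if not (0 < self.lower < self.upper):
            raise ValueError(
                f"degenerate reference interval: ({self.lower}, {self.upper})"
            )


@dataclass(frozen=True)
class LineageBiasCall:
    mouse_id: str
    rel_contributions: dict = field(default_factory=dict)
    l_fraction: float = float("nan")
    m_fraction: float = float("nan")
    lm_ratio: float = float("nan")
    reference_mode: str = ""
    category: str = ""


def donor_chimerism(donor_events: int, total_events: int) -> float:
    """Donor contribution as percent of a compartment; NaN when no events.

    A NaN marks an unmeasurable compartment and is excluded from calls.
    """
    if donor_events < 0 or total_events < 0:
        raise DataError("event counts must be non-negative")
    if donor_events > total_events:
        raise DataError(
            f"donor events ({donor_events}) exceed total ({total_events})"
        )
    if total_events == 0:
        return float("nan")
    return 100.0 * donor_events / total_events


def call_reconstitution(
    measurements: pd.DataFrame,
    mouse_id: str | None = None,
    min_percent: float = RECONSTITUTION_MIN_PERCENT,
    min_events: int = MIN_DONOR_EVENTS,
) -> ReconstitutionCall:
    """Month-2 reconstitution call from leukocyte and/or platelet chimerism.

    Positive iff at least one of the two compartments reaches `min_percent`
    donor frequency *and* `min_events` donor events in that same compartment.
    Expects rows with columns lineage, donor_events, total_events (already
    restricted to the month-2 timepoint of one mouse).
    """
    if mouse_id is None:
        ids = measurements["mouse_id"].unique()
        if len(ids) != 1:
            raise ValueError("measurements must belong to a single mouse")
        mouse_id = str(ids[0])
    rows = measurements[measurements["lineage"].isin(["leukocyte_total", "platelet"])]
    if rows.empty:
        raise ValueError(f"no month-2 leukocyte/platelet record for {mouse_id}")
    evidence = []
    for _, r in rows.iterrows():
        freq = donor_chimerism(int(r["donor_events"]), int(r["total_events"]))
        if not math.isnan(freq) and freq >= min_percent and r["donor_events"] >= min_events:
            evidence.append(str(r["lineage"]))
    return ReconstitutionCall(mouse_id, bool(evidence), tuple(evidence))


def call_lineage_positive(
    donor_frequency: float,
    donor_events: int,
    min_percent: float = LINEAGE_MIN_PERCENT,
    min_events: int = MIN_DONOR_EVENTS,
) -> bool:
    """Single-lineage positivity: >= 0.01% donor frequency and >= 10 events.

    Applied identically to peripheral-blood lineages and bone-marrow
    progenitor/HSC compartments.
    """
    if math.isnan(donor_frequency):
        return False
    return donor_frequency >= min_percent and donor_events >= min_events


def relative_contributions(lineage_events: dict) -> dict:
    """Fractions of donor leukocytes per lineage (B, T, NK, myeloid).

    Raises if every lineage is zero (mouse not evaluable) or a required
    lineage is missing (no imputation for absent T/NK panels).
    """
    missing = [ln for ln in LEUKOCYTE_LINEAGES if ln not in lineage_events]
    if missing:
        raise ValueError(f"missing lineage counts: {missing}; refusing to impute")
    events = np.array([float(lineage_events[ln]) for ln in LEUKOCYTE_LINEAGES])
    if np.any(events < 0):
        raise DataError("negative lineage events")
    total = events.sum()
    if total == 0:
        raise DataError("all-zero donor lineage events: mouse not evaluable")
    return dict(zip(LEUKOCYTE_LINEAGES, events / total))


def lm_ratio(rel_contributions: dict) -> float:
    """Lymphoid (B+T+NK) over myeloid fraction; +inf when myeloid is zero."""
    lymphoid = sum(rel_contributions[ln] for ln in LYMPHOID_LINEAGES)
    myeloid = rel_contributions[MYELOID_LINEAGE]
    if myeloid == 0:
        return math.inf
    return lymphoid / myeloid


def derive_reference_interval(
    cohort_lm: np.ndarray | list,
    rule: str = "central80",
    reference_mode: str = "adult",
) -> ReferenceInterval:
    """Bal bounds from the L/M ratios of an unmanipulated reference cohort.

    Rules: ``central80`` (10th-90th percentile, linear interpolation;
    default), ``minmax``, ``geometric`` (geometric mean x/÷ gSD^2).
    """
    values = np.asarray(cohort_lm, dtype=float)
    if values.size < 2:
        raise ValueError("reference cohort needs at least 2 mice")
    if rule == "central80":
        lower, upper = np.percentile(values, [10, 90], method="linear")
    elif rule == "minmax":
        lower, upper = values.min(), values.max()
    elif rule == "geometric":
        if np.any(values <= 0):
            raise ValueError("geometric rule requires strictly positive L/M values")
        logs = np.log(values)
        gsd = math.exp(logs.std(ddof=1))
        center = gmean(values)
        lower, upper = center / gsd**2, center * gsd**2
    else:
        raise ValueError(f"unknown derivation rule: {rule!r}")
    return ReferenceInterval(reference_mode, float(lower), float(upper), rule, values.size)


def classify_lineage_bias(lm: float, interval: ReferenceInterval) -> str:
    """L-bi / Bal / M-bi category; Bal is closed on both boundaries."""
    if math.isnan(lm):
        raise ValueError("cannot classify NaN L/M ratio")
    if math.isinf(lm):
        return CATEGORY_L_BI
    if lm < interval.lower:
        return CATEGORY_M_BI
    if lm <= interval.upper:
        return CATEGORY_BAL
    return CATEGORY_L_BI


def bm_lm_balance(lymphoid_events: float, myeloid_events: float) -> tuple[float, float]:
    """Two-bin lymphoid/myeloid balance of donor cells in the bone marrow."""
    if lymphoid_events < 0 or myeloid_events < 0:
        raise DataError("negative event counts")
    total = lymphoid_events + myeloid_events
    if total == 0:
        raise DataError("all-zero donor events in BM")
    return lymphoid_events / total, myeloid_events / total


def classify_mouse(
    measurements: pd.DataFrame,
    interval: ReferenceInterval,
    reconstitution_timepoint: float = 2,
    bias_timepoint: float | None = None,
    reconstitution_min_percent: float = RECONSTITUTION_MIN_PERCENT,
    min_events: int = MIN_DONOR_EVENTS,
) -> LineageBiasCall | None:
    """Full per-mouse pipeline: reconstitution gate then bias classification.

    Returns None for mice failing month-2 reconstitution (excluded, as only
    reconstituted mice are categorized). `bias_timepoint` defaults to the
    latest timepoint present (the 5-6 month analysis point).
    """
    ids = measurements["mouse_id"].unique()
    if len(ids) != 1:
        raise ValueError("one mouse at a time")
    mouse_id = str(ids[0])
    m2 = measurements[measurements["timepoint_months"] == reconstitution_timepoint]
    pb2 = m2[m2.get("compartment", "PB") == "PB"] if "compartment" in m2 else m2
    recon = call_reconstitution(pb2, mouse_id,
                                min_percent=reconstitution_min_percent,
                                min_events=min_events)
    if not recon.positive:
        return None
    if bias_timepoint is None:
        bias_timepoint = measurements["timepoint_months"].max()
    late = measurements[measurements["timepoint_months"] == bias_timepoint]
    if "compartment" in late:
        late = late[late["compartment"] == "PB"]
    events = {
        str(r["lineage"]): float(r["donor_events"])
        for _, r in late.iterrows()
        if r["lineage"] in LEUKOCYTE_LINEAGES
    }
    rel = relative_contributions(events)
    lm = lm_ratio(rel)
    l_frac = sum(rel[ln] for ln in LYMPHOID_LINEAGES)
    m_frac = rel[MYELOID_LINEAGE]
    return LineageBiasCall(
        mouse_id=mouse_id,
        rel_contributions=rel,
        l_fraction=l_frac,
        m_fraction=m_frac,
        lm_ratio=lm,
        reference_mode=interval.reference_mode,
        category=classify_lineage_bias(lm, interval),
    )


def classify_cohort(
    measurements: pd.DataFrame, interval: ReferenceInterval, **kwargs
) -> pd.DataFrame:
    """Classify every mouse in a long-format PB table; one row per mouse.

    Non-reconstituted mice appear with category "not-reconstituted" so cohort
    accounting stays auditable.
    """
    rows = []
    for mouse_id, sub in measurements.groupby("mouse_id", sort=True):
        call = classify_mouse(sub, interval, **kwargs)
        if call is None:
            rows.append({"mouse_id": mouse_id, "category": "not-reconstituted"})
            continue
        row = {
            "mouse_id": mouse_id,
            "l_fraction": call.l_fraction,
            "m_fraction": call.m_fraction,
            "lm_ratio": call.lm_ratio,
            "reference_mode": call.reference_mode,
            "category": call.category,
        }
        for ln in LEUKOCYTE_LINEAGES:
            row[f"frac_{ln}"] = call.rel_contributions[ln]
        rows.append(row)
    return pd.DataFrame(rows)


def durability_summary(calls: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Per-group proportions of positive mice, with Fisher-exact contrasts.

    `calls` holds one row per mouse with boolean columns (e.g.
    myeloid_positive, hsc_positive) indicating long-term repopulation. Output
    has one row per (group, outcome) with n, n_positive, proportion; pairs of
    groups can be compared with :func:`fisher_between_groups`.
    """
    if calls.empty:
        raise ValueError("empty cohort")
    bool_cols = [c for c in calls.columns if calls[c].dtype == bool]
    if not bool_cols:
        raise ValueError("no boolean outcome columns found")
    records = []
    for group, sub in calls.groupby(group_col, sort=True):
        if sub.empty:
            raise ValueError(f"empty group {group}")
        for col in bool_cols:
            n = len(sub)
            k = int(sub[col].sum())
            records.append(
                {group_col: group, "outcome": col, "n": n, "n_positive": k,
                 "proportion": k / n}
            )
    return pd.DataFrame(records)


def fisher_between_groups(summary: pd.DataFrame, outcome: str, group_a, group_b,
                          group_col: str = "group") -> float:
    """Two-sided Fisher exact p for one outcome between two groups."""
    sub = summary[summary["outcome"] == outcome].set_index(group_col)
    table = [
        [sub.loc[g, "n_positive"], sub.loc[g, "n"] - sub.loc[g, "n_positive"]]
        for g in (group_a, group_b)
    ]
    return float(fisher_exact(table, alternative="two-sided")[1])
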