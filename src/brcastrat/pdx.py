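"""PDX platinum/taxane response metrics.

Two complementary read-outs per PDX model:

* growth-rate metric — each animal's tumor growth rate is the ordinary
  least-squares slope of natural-log volume versus day. Each treated animal's
  rate is compared to the control-arm mean; the model-level value is the mean
  reduction over treated animals, expressed in percentage points (Δslope x
  100, ln-units/day). Models with a mean reduction > 5 points are responders.
  That threshold corresponds to a treated:control volume ratio of
  exp(-0.05 x 14) ≈ 0.50 over 14 days from equal baselines — i.e. a 50%
  relative volume decrease.
* modified RECIST — percent volume change at the end of treatment (day 28 for
  4-week, day 21 for 3-week regimens) versus day 0, categorised CR/PR/SD/PD;
  the modal category over replicate animals is the model call and CR/PR
  designate responders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import exp

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECIST_ORDER = ("CR", "PR", "SD", "PD")  # most to least responsive


@dataclass
class GrowthFit:
    animal_id: str
    slope: float  # ln(mm^3)/day
    intercept: float
    n_points: int


@dataclass
class ResponseConfig:
    """Response thresholds.

    reduction_threshold is in percentage points of growth-rate reduction,
    i.e. (control mean slope - treated slope) x 100 with slopes in natural-log
    units per day. recist_cuts are percent volume changes: CR < -80,
    PR [-80, -30), SD [-30, 20], PD > 20.
    """

    reduction_threshold: float = 5.0
    recist_end_day: float = 28.0
    end_day_tolerance: float = 3.0
    cr_cut: float = -80.0
    pr_cut: float = -30.0
    pd_cut: float = 20.0
    relative_reduction: bool = False  # alternative reading: % of control slope

    def __post_init__(self) -> None:
        if not self.cr_cut < self.pr_cut < self.pd_cut:
            raise ValueError("RECIST cuts must be ordered")

    def implied_volume_ratio(self, days: float = 14.0) -> float:
        """Treated:control volume ratio at `days` implied by the threshold."""
        return exp(-self.reduction_threshold / 100.0 * days)


@dataclass
class ResponseCall:
    model_id: str
    mean_reduction: float
    responder_growth: bool
    recist_mode: str
    responder_recist: bool
    n_treated: int = 0
    n_control: int = 0


def fit_growth_rate(days, volumes, animal_id: str = "animal") -> GrowthFit:
    """OLS slope of ln(volume) vs day for one animal.

    Requires at least three strictly positive volume measurements.
    """
    days = np.asarray(days, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if days.shape != volumes.shape:
        raise ValueError("days and volumes must align")
    if len(days) < 3:
        raise ValueError(f"animal {animal_id}: need >= 3 timepoints, got {len(days)}")
    if (volumes <= 0).any():
        raise ValueError(f"animal {animal_id}: volumes must be strictly positive")
    if len(np.unique(days)) != len(days):
        raise ValueError(f"animal {animal_id}: duplicate measurement days")
    slope, intercept = np.polyfit(days, np.log(volumes), 1)
    return GrowthFit(animal_id=animal_id, slope=float(slope), intercept=float(intercept), n_points=len(days))


def growth_rate_reduction(
    treated_fits: list[GrowthFit],
    control_fits: list[GrowthFit],
    config: ResponseConfig | None = None,
) -> tuple[list[float], float]:
    """Per-treated-animal and mean growth-rate reductions (percentage points).

    Each treated animal is compared against the control-arm *mean* slope.
    """
    config = config or ResponseConfig()
    if not treated_fits or not control_fits:
        raise ValueError("both arms need at least one valid growth fit")
    control_mean = float(np.mean([f.slope for f in control_fits]))
    per_animal = []
    for f in treated_fits:
        if config.relative_reduction:
            if control_mean == 0:
                raise ZeroDivisionError("relative reduction undefined for zero control slope")
            per_animal.append(100.0 * (control_mean - f.slope) / control_mean)
        else:
            per_animal.append(100.0 * (control_mean - f.slope))
    return per_animal, float(np.mean(per_animal))


def delta_volume(days, volumes, config: ResponseConfig | None = None) -> float:
    """Percent volume change at end of treatment versus baseline (day 0).

    The end-of-treatment volume is the measurement nearest the configured end
    day within ± end_day_tolerance days.
    """
    config = config or ResponseConfig()
    days = np.asarray(days, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if 0.0 not in days:
        raise ValueError("baseline (day 0) measurement missing")
    v0 = float(volumes[days == 0.0][0])
    gap = np.abs(days - config.recist_end_day)
    i = int(np.argmin(gap))
    if gap[i] > config.end_day_tolerance:
        raise ValueError(
            f"no measurement within ±{config.end_day_tolerance} days of day {config.recist_end_day}"
        )
    return 100.0 * (float(volumes[i]) - v0) / v0


def mrecist_category(dvol: float, config: ResponseConfig | None = None) -> str:
    """Modified-RECIST category for one animal's percent volume change."""
    config = config or ResponseConfig()
    if not np.isfinite(dvol):
        raise ValueError("Δvol must be finite")
    if dvol < config.cr_cut:
        return "CR"
    if dvol < config.pr_cut:  # boundary -80 falls here (less responsive side)
        return "PR"
    if dvol <= config.pd_cut:  # boundary -30 and +20 fall in SD
        return "SD"
    return "PD"


def modal_category(categories: list[str]) -> str:
    """Modal RECIST category over replicate animals; ties break conservatively
    toward the less-responsive category."""
    if not categories:
        raise ValueError("need at least one category")
    counts = {c: categories.count(c) for c in set(categories)}
    best = max(counts.values())
    # among tied modes pick the one latest in the responsiveness order
    return max((c for c, n in counts.items() if n == best), key=RECIST_ORDER.index)


def model_response(
    model_id: str,
    treated: pd.DataFrame,
    control: pd.DataFrame,
    config: ResponseConfig | None = None,
) -> ResponseCall:
    """Full response call for one PDX model.

    ``treated``/``control``: long tables with columns animal_id, day,
    volume_mm3 for each arm. Animals with fewer than three valid timepoints
    are excluded with a log entry.
    """
    config = config or ResponseConfig()

    def _fits(arm: pd.DataFrame) -> list[GrowthFit]:
        fits = []
        for aid, grp in arm.groupby("animal_id"):
            grp = grp.sort_values("day")
            try:
                fits.append(fit_growth_rate(grp["day"], grp["volume_mm3"], animal_id=str(aid)))
            except ValueError as e:
                logger.warning("model %s: excluding animal %s (%s)", model_id, aid, e)
        return fits

    treated_fits, control_fits = _fits(treated), _fits(control)
    _, mean_reduction = growth_rate_reduction(treated_fits, control_fits, config)

    categories = []
    for aid, grp in treated.groupby("animal_id"):
        grp = grp.sort_values("day")
        try:
            categories.append(mrecist_category(delta_volume(grp["day"], grp["volume_mm3"], config), config))
        except ValueError as e:
            logger.warning("model %s: RECIST excludes animal %s (%s)", model_id, aid, e)
    recist_mode = modal_category(categories) if categories else "SD"

    return ResponseCall(
        model_id=model_id,
        mean_reduction=mean_reduction,
        responder_growth=mean_reduction > config.reduction_threshold,
        recist_mode=recist_mode,
        responder_recist=recist_mode in ("CR", "PR"),
        n_treated=len(treated_fits),
        n_control=len(control_fits),
    )


def cohort_response(
    volumes: pd.DataFrame,
    treated_arm: str = "treated",
    control_arm: str = "control",
    config: ResponseConfig | None = None,
) -> pd.DataFrame:
    """Response calls for every model in a long volume table.

    Columns required: model_id, arm, animal_id, day, volume_mm3.
    """
    rows = []
    for mid, grp in volumes.groupby("model_id", sort=True):
        call = model_response(
            str(mid),
            grp[grp["arm"] == treated_arm],
            grp[grp["arm"] == control_arm],
            config,
        )
        rows.append(
            {
                "model_id": call.model_id,
                "mean_reduction": call.mean_reduction,
                "responder_growth": call.responder_growth,
                "recist_mode": call.recist_mode,
                "responder_recist": call.responder_recist,
            }
        )
    return pd.DataFrame(rows)
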