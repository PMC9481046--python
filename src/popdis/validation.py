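"""Multi-level validation of disaggregated population estimates.

An estimate is scored against validation zones (VZ) by aggregating the
estimated TZ populations into each VZ unit (proportional-area overlay) and
comparing with the known census counts.  Seven relative accuracy statistics
are computed, all in percent:

====== =====================================================================
R²     explained share of the population variance (can be negative)
NRMSE  RMSE of residuals normalized by the mean VZ population
RTAE   sum of absolute unit errors over the total population
MAPE   mean absolute percentage error over units with nonzero population
UE     share of true population in units that received a zero estimate
OE     share of estimate mass not landing inside any VZ unit
APE    per-unit absolute percentage error (basis of the group analyses)
====== =====================================================================

Two-fold validation scores the same estimate at the contiguous section
level (L1) and the non-contiguous block level (L0); only the latter can
expose mass allocated to streets and unpopulated areas (OE/UE), which is
why single-level validation on contiguous units can flatter a method.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geo_core import InvalidInputError, ZoneSet, aggregate_estimate

logger = logging.getLogger(__name__)

#: absolute tolerance under which an estimate counts as exactly zero (UE)
ZERO_TOL = 1e-9

GROUP_KEYS = ("LAND_USE", "AREA", "DENSITY")


@dataclass
class ValidationSeries:
    """Aligned known/estimated populations over one VZ level."""

    unit_ids: np.ndarray
    known: np.ndarray
    estimated: np.ndarray
    areas: np.ndarray
    outside_pop: float = 0.0
    landuse_shares: pd.DataFrame | None = None   # share_R/share_C/share_O
    level: str = ""

    def __post_init__(self) -> None:
        n = len(self.known)
        if not (len(self.estimated) == len(self.areas) == len(self.unit_ids) == n):
            raise InvalidInputError("validation series vectors must align")

    @property
    def n(self) -> int:
        return len(self.known)

    @property
    def total(self) -> float:
        return float(np.sum(self.known))

    @property
    def mean(self) -> float:
        return float(np.mean(self.known))

    def ape(self) -> tuple[np.ndarray, np.ndarray]:
        """APE (%) for units with positive known population + their mask."""
        pos = self.known > 0
        ape = np.abs(self.known[pos] - self.estimated[pos]) / self.known[pos] * 100.0
        return ape, pos


@dataclass
class MetricReport:
    r2: float
    nrmse: float
    rtae: float
    mape: float
    mape_excluded: int
    ue: float
    oe: float
    level: str = ""
    tag: str = ""

    def as_dict(self) -> dict:
        return {
            "r2": self.r2, "nrmse": self.nrmse, "rtae": self.rtae,
            "mape": self.mape, "mape_excluded": self.mape_excluded,
            "ue": self.ue, "oe": self.oe, "level": self.level, "tag": self.tag,
        }


def build_series(
    vz: ZoneSet,
    estimate=None,
    per_unit: pd.Series | None = None,
    landuse_shares: pd.DataFrame | None = None,
) -> ValidationSeries:
    """Aggregate a TZ estimate onto VZ units and align it with the census.

    ``estimate`` is any object with a ``df`` of (tz_id, geometry, pop) rows,
    or such a DataFrame.  Alternatively a precomputed ``per_unit`` series
    (indexed by unit_id; missing units imply zero, residual mass counts as
    outside) may be supplied.
    """
    if len(vz) == 0:
        raise InvalidInputError("empty validation zone set")
    if per_unit is not None:
        est = per_unit.reindex(vz.unit_ids, fill_value=0.0).to_numpy(dtype=float)
        outside = float(per_unit.sum() - est.sum())
    else:
        df = getattr(estimate, "df", estimate)
        est_series, outside = aggregate_estimate(df, vz)
        est = est_series.to_numpy(dtype=float)
    if landuse_shares is None:
        cols = [c for c in ("share_R", "share_C", "share_O") if c in vz.df.columns]
        if cols:
            landuse_shares = vz.df[["unit_id", *cols]]
    return ValidationSeries(
        unit_ids=vz.unit_ids,
        known=vz.populations,
        estimated=est,
        areas=vz.areas,
        outside_pop=max(outside, 0.0),
        landuse_shares=landuse_shares,
        level=vz.level,
    )


def compute_metrics(s: ValidationSeries, tag: str = "") -> MetricReport:
    """The seven accuracy statistics for one series (values in percent)."""
    if s.n < 2:
        raise InvalidInputError("at least two validation units required")
    if s.total <= 0:
        raise InvalidInputError("total known population must be positive")
    resid = s.known - s.estimated
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((s.known - s.mean) ** 2))
    r2 = (1.0 - ss_res / ss_tot) * 100.0 if ss_tot > 0 else float("nan")
    if ss_tot == 0:
        logger.warning("all known populations equal; R^2 undefined")
    nrmse = np.sqrt(ss_res / s.n) / s.mean * 100.0
    rtae = float(np.sum(np.abs(resid))) / s.total * 100.0
    pos = s.known > 0
    excluded = int(np.sum(~pos))
    mape = (
        float(np.mean(np.abs(resid[pos]) / s.known[pos])) * 100.0
        if pos.any()
        else float("nan")
    )
    zero_est = np.abs(s.estimated) < ZERO_TOL
    ue = float(np.sum(s.known[zero_est])) / s.total * 100.0
    oe = (s.total - float(np.sum(s.estimated))) / s.total * 100.0
    if abs(oe) < ZERO_TOL:        # absorb float dust from exact conservation
        oe = 0.0
    return MetricReport(
        r2=r2, nrmse=float(nrmse), rtae=rtae, mape=mape,
        mape_excluded=excluded, ue=ue, oe=oe, level=s.level, tag=tag,
    )


def two_fold_validate(
    estimate,
    vz_l1: ZoneSet,
    vz_l0: ZoneSet,
    tag: str = "",
) -> tuple[MetricReport, MetricReport]:
    """Score the same estimate at both validation levels.

    OE/UE are meaningful at the non-contiguous L0 level; at the contiguous
    L1 level OE is near zero by construction but still reported.
    """
    rep1 = compute_metrics(build_series(vz_l1, estimate), tag=tag)
    rep0 = compute_metrics(build_series(vz_l0, estimate), tag=tag)
    return rep1, rep0


# ---------------------------------------------------------------------------
# error structure
# ---------------------------------------------------------------------------

@dataclass
class ErrorGroupResult:
    key: str
    groups: dict[str, np.ndarray]          # group label -> APE vector
    summary: pd.DataFrame                  # label, n, median, mean
    tests: pd.DataFrame | None = None      # pairwise rank-sum results


def group_errors(
    s: ValidationSeries,
    key: str,
    dominance_threshold: float = 0.8,
) -> ErrorGroupResult:
    """Group per-unit APEs by land-use dominance or by area/density quartile.

    LAND_USE groups: mostly-residential / mostly-commercial / mostly-other
    (strictly more than the threshold share) and no-dominant.  AREA and
    DENSITY use quartiles Q1..Q4 (linear-interpolation quantiles; boundary
    units fall to the lower quartile).  APE is only defined for units with
    positive census population.
    """
    if key not in GROUP_KEYS:
        raise InvalidInputError(f"unknown grouping key {key!r}")
    ape, pos = s.ape()
    if key == "LAND_USE":
        if s.landuse_shares is None:
            raise InvalidInputError("land-use shares required for LAND_USE grouping")
        sh = (
            s.landuse_shares.set_index("unit_id")
            .reindex(s.unit_ids)[["share_R", "share_C", "share_O"]]
            .to_numpy(dtype=float)[pos]
        )
        labels = np.full(len(ape), "no-dominant", dtype=object)
        for j, name in ((0, "mostly-residential"), (1, "mostly-commercial"),
                        (2, "mostly-other")):
            labels[sh[:, j] > dominance_threshold] = name
        order = ["mostly-residential", "mostly-commercial", "mostly-other",
                 "no-dominant"]
    else:
        base = s.areas[pos] if key == "AREA" else (s.known[pos] / s.areas[pos])
        qs = np.quantile(base, [0.25, 0.5, 0.75])
        labels = np.array(
            ["Q1" if v <= qs[0] else "Q2" if v <= qs[1] else "Q3" if v <= qs[2]
             else "Q4" for v in base],
            dtype=object,
        )
        order = ["Q1", "Q2", "Q3", "Q4"]
    groups = {name: ape[labels == name] for name in order}
    summary = pd.DataFrame(
        [
            {"group": name, "n": len(v),
             "median_ape": float(np.median(v)) if len(v) else float("nan"),
             "mean_ape": float(np.mean(v)) if len(v) else float("nan")}
            for name, v in groups.items()
        ]
    )
    return ErrorGroupResult(key=key, groups=groups, summary=summary)


def rank_sum_compare(result: ErrorGroupResult) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test for every pair of non-empty groups.

    Exact enumeration for small tie-free groups (both sizes <= 20), normal
    approximation with tie correction otherwise.  Pairs with a group of
    size < 2 are skipped and noted.
    """
    nonempty = {k: v for k, v in result.groups.items() if len(v) > 0}
    if len(nonempty) < 2:
        raise InvalidInputError("need at least two non-empty groups")
    rows = []
    for (ka, va), (kb, vb) in itertools.combinations(nonempty.items(), 2):
        if len(va) < 2 or len(vb) < 2:
            rows.append({"group_a": ka, "group_b": kb, "statistic": float("nan"),
                         "p_value": float("nan"), "method": "skipped (n < 2)"})
            continue
        small = len(va) <= 20 and len(vb) <= 20
        ties = len(np.unique(np.concatenate([va, vb]))) < len(va) + len(vb)
        method = "exact" if small and not ties else "asymptotic"
        res = stats.mannwhitneyu(va, vb, alternative="two-sided", method=method)
        rows.append({"group_a": ka, "group_b": kb,
                     "statistic": float(res.statistic),
                     "p_value": float(res.pvalue), "method": method})
    table = pd.DataFrame(rows)
    result.tests = table
    return table
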