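"""From fraction-unfolded measurements to catalytic unfolding efficacy.

The analysis chain mirrors the pulse-labeling study design: replicate
deconvolved fractions are aggregated into per-condition time courses,
the spontaneous (inhibitor-free) course is subtracted pointwise, initial
unfolding rates are estimated by through-origin least squares on the early
points (points with substantial substrate depletion — corrected fraction
above a cutoff — are excluded), and the catalytic unfolding efficacy is
the slope of the molar unfolding rate against inhibitor concentration.

Units discipline: a fraction-per-minute rate times the substrate
concentration (uM) gives a molar rate in uM/min; its regression slope on
inhibitor concentration (uM) is therefore a dimensionless count per
minute — substrate molecules unfolded per inhibitor molecule per minute.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .simulate import KineticPreset, two_state_fraction

logger = logging.getLogger("hdxpulse.kinetics")

#: Corrected unfolded fraction above which a point is treated as suffering
#: substantial substrate depletion and excluded from initial-rate fits.
DEPLETION_CUTOFF = 0.30
#: Maximum time (minutes) of the linear-phase window used for inhibitors
#: whose activity decays during the incubation.
LINEAR_PHASE_CAP = 10.0


@dataclasses.dataclass(frozen=True)
class TimeCourse:
    """Mean fraction unfolded vs time for one condition."""

    condition: dict
    times: np.ndarray
    fractions: np.ndarray
    sds: np.ndarray
    ns: np.ndarray
    flags: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        fractions = np.asarray(self.fractions, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        ns = np.asarray(self.ns, dtype=int)
        for name, arr in (("fractions", fractions), ("sds", sds), ("ns", ns)):
            if arr.shape != times.shape:
                raise ValueError(f"{name} must match times in length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        finite = fractions[np.isfinite(fractions)]
        if np.any((finite < 0) | (finite > 1)):
            raise ValueError("fractions must be in [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fractions", fractions)
        object.__setattr__(self, "sds", sds)
        object.__setattr__(self, "ns", ns)
        if not self.flags:
            object.__setattr__(self, "flags", tuple(() for _ in times))

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclasses.dataclass(frozen=True)
class RateEstimate:
    """Initial unfolding rate with its inclusion/exclusion provenance."""

    rate: float
    molar_rate: float
    stderr: float
    included_times: tuple[float, ...]
    excluded: tuple[tuple[float, str], ...]
    n: int
    withheld_reason: str | None = None

    @property
    def withheld(self) -> bool:
        return self.withheld_reason is not None


@dataclasses.dataclass(frozen=True)
class EfficacyEstimate:
    """Catalytic unfolding efficacy from the rate-vs-concentration regression."""

    efficacy: float
    stderr: float
    intercept: float
    r_squared: float
    through_origin_efficacy: float
    rates: dict
    n_concentrations: int


@dataclasses.dataclass(frozen=True)
class KineticFit:
    """Global two-state model fit across conditions."""

    k_spont: float
    efficacy: float
    k_decay: float
    stderr: dict
    rss: float
    n: int
    aic: float
    fixed_k_decay: bool


def assemble_time_course(
    records: pd.DataFrame,
    condition_cols: Sequence[str] = (),
    time_col: str = "time_min",
    fraction_col: str = "fraction_unfolded",
) -> TimeCourse:
    """Aggregate replicate fractions to mean +/- SD per time point.

    ``condition_cols`` must be constant across rows (mixed conditions are
    rejected).  Non-finite fractions (non-converged or ambiguous fits) are
    dropped from the aggregation but counted in the point flags.  A single
    replicate yields an SD of NaN, not 0.
    """
    if records.empty:
        raise ValueError("no records to assemble")
    condition: dict = {}
    for col in condition_cols:
        values = records[col].dropna().unique()
        if len(values) > 1:
            raise ValueError(f"mixed conditions in column {col!r}: {values!r}")
        condition[col] = values[0] if len(values) else None
    times, means, sds, ns, flags = [], [], [], [], []
    for t, group in records.groupby(time_col, sort=True):
        values = pd.to_numeric(group[fraction_col], errors="coerce")
        usable = values[np.isfinite(values)]
        point_flags: list[str] = []
        if len(usable) < len(values):
            point_flags.append(f"dropped_{len(values) - len(usable)}_unusable")
        if len(usable) == 0:
            means.append(float("nan"))
            sds.append(float("nan"))
            point_flags.append("no_usable_replicates")
        else:
            means.append(float(usable.mean()))
            sds.append(float(usable.std(ddof=1)) if len(usable) > 1 else float("nan"))
        times.append(float(t))
        ns.append(len(usable))
        flags.append(tuple(point_flags))
    if len(times) < 2:
        raise ValueError("a time course needs at least 2 time points")
    return TimeCourse(
        condition=condition,
        times=np.array(times),
        fractions=np.array(means),
        sds=np.array(sds),
        ns=np.array(ns),
        flags=tuple(flags),
    )


def subtract_spontaneous(
    catalyzed: TimeCourse, spontaneous: TimeCourse, interpolate: bool = False
) -> TimeCourse:
    """Pointwise difference of catalyzed minus spontaneous unfolding.

    Negative differences are clipped to 0 and flagged; SDs combine in
    quadrature.  Time grids must match unless ``interpolate`` is set, in
    which case the spontaneous course is linearly interpolated onto the
    catalyzed grid.
    """
    if catalyzed.times.shape == spontaneous.times.shape and np.allclose(
        catalyzed.times, spontaneous.times, atol=1e-9
    ):
        spont_f, spont_sd = spontaneous.fractions, spontaneous.sds
    elif interpolate:
        spont_f = np.interp(catalyzed.times, spontaneous.times, spontaneous.fractions)
        spont_sd = np.interp(catalyzed.times, spontaneous.times, spontaneous.sds)
    else:
        raise ValueError(
            "time grids differ; pass interpolate=True to interpolate the "
            "spontaneous course"
        )
    diff = catalyzed.fractions - spont_f
    clipped = diff < 0
    diff = np.clip(diff, 0.0, None)
    sds = np.sqrt(catalyzed.sds**2 + spont_sd**2)
    flags = tuple(
        point + (("clipped_negative",) if was_clipped else ())
        for point, was_clipped in zip(catalyzed.flags, clipped)
    )
    condition = dict(catalyzed.condition)
    condition["spontaneous_subtracted"] = True
    return TimeCourse(
        condition=condition,
        times=catalyzed.times,
        fractions=diff,
        sds=sds,
        ns=catalyzed.ns,
        flags=flags,
    )


def initial_rate(
    course: TimeCourse,
    depletion_cutoff: float = DEPLETION_CUTOFF,
    max_time: float | None = None,
    substrate_conc_um: float | None = None,
) -> RateEstimate:
    """Initial unfolding rate by OLS through the origin on early points.

    Points whose corrected fraction exceeds ``depletion_cutoff`` are
    excluded (substrate depletion), as are points beyond ``max_time`` when a
    linear-phase cap applies; the estimate is withheld (NaN, with a reason)
    if fewer than 2 usable points remain.
    """
    if substrate_conc_um is None:
        substrate_conc_um = float(course.condition.get("substrate_conc_um", np.nan))
    excluded: list[tuple[float, str]] = []
    mask = np.ones(course.n_points, dtype=bool)
    for i, (t, fraction) in enumerate(zip(course.times, course.fractions)):
        if not np.isfinite(fraction):
            mask[i] = False
            excluded.append((float(t), "no_usable_replicates"))
        elif fraction > depletion_cutoff:
            mask[i] = False
            excluded.append((float(t), "substrate_depletion"))
        elif max_time is not None and t > max_time:
            mask[i] = False
            excluded.append((float(t), "beyond_linear_phase"))
    t = course.times[mask]
    y = course.fractions[mask]
    if t.size < 2:
        logger.warning("initial rate withheld: %d usable point(s)", t.size)
        return RateEstimate(
            rate=float("nan"),
            molar_rate=float("nan"),
            stderr=float("nan"),
            included_times=tuple(t),
            excluded=tuple(excluded),
            n=int(t.size),
            withheld_reason="fewer than 2 usable points",
        )
    slope = float(np.dot(t, y) / np.dot(t, t))
    residuals = y - slope * t
    stderr = float(np.sqrt(np.sum(residuals**2) / (t.size - 1) / np.dot(t, t)))
    return RateEstimate(
        rate=slope,
        molar_rate=slope * substrate_conc_um,
        stderr=stderr,
        included_times=tuple(float(v) for v in t),
        excluded=tuple(excluded),
        n=int(t.size),
    )


def efficacy_regression(
    rates: Mapping[float, RateEstimate], substrate_conc_um: float
) -> EfficacyEstimate:
    """Catalytic unfolding efficacy: slope of molar rate vs inhibitor conc.

    Both the free-intercept and through-origin slopes are computed; the
    free-intercept slope is reported as primary.  Withheld rates are
    skipped (and logged); at least two distinct concentrations must remain.
    """
    concs, molar = [], []
    kept: dict[float, RateEstimate] = {}
    for conc, estimate in sorted(rates.items()):
        if estimate.withheld or not np.isfinite(estimate.rate):
            logger.info(
                "dropping concentration %.3g uM from efficacy regression: %s",
                conc, estimate.withheld_reason or "non-finite rate",
            )
            continue
        molar_rate = estimate.molar_rate
        if not np.isfinite(molar_rate):
            molar_rate = estimate.rate * substrate_conc_um
        concs.append(float(conc))
        molar.append(float(molar_rate))
        kept[float(conc)] = estimate
    if len(set(concs)) < 2:
        raise ValueError(
            "efficacy regression needs rates at >= 2 distinct inhibitor concentrations"
        )
    x = np.asarray(concs)
    y = np.asarray(molar)
    free = sm.OLS(y, sm.add_constant(x)).fit()
    origin = sm.OLS(y, x[:, None]).fit()
    return EfficacyEstimate(
        efficacy=float(free.params[1]),
        stderr=float(free.bse[1]),
        intercept=float(free.params[0]),
        r_squared=float(free.rsquared),
        through_origin_efficacy=float(origin.params[0]),
        rates=kept,
        n_concentrations=len(set(concs)),
    )


def fit_kinetic_model(
    courses: Mapping[float, TimeCourse],
    template: KineticPreset,
    fix_k_decay: float | None = None,
) -> KineticFit:
    """Weighted nonlinear least squares of the two-state model.

    ``courses`` maps inhibitor concentration (uM; 0 denotes the spontaneous
    control) to a time course.  At least two conditions including the
    spontaneous control are required, and the pooled data must span more
    than one time point.  ``fix_k_decay`` pins the inhibitor-decay rate
    (use 0 for a stable, wild-type-like inhibitor).
    """
    if len(courses) < 2 or 0.0 not in courses:
        raise ValueError(
            "kinetic fit needs >= 2 conditions including a spontaneous control (0 uM)"
        )
    n_times = {t for course in courses.values() for t in course.times}
    if len(n_times) < 2:
        raise ValueError("kinetic model is not identifiable from a single time point")

    fit_decay = fix_k_decay is None

    def unpack(theta: np.ndarray) -> tuple[float, float, float]:
        k_spont, efficacy = theta[0], theta[1]
        k_decay = theta[2] if fit_decay else fix_k_decay
        return float(k_spont), float(efficacy), float(k_decay)

    def residuals(theta: np.ndarray) -> np.ndarray:
        k_spont, efficacy, k_decay = unpack(theta)
        out = []
        for conc, course in sorted(courses.items()):
            preset = dataclasses.replace(
                template,
                k_spont=k_spont,
                efficacy=efficacy if conc > 0 else 0.0,
                inhibitor_conc_um=conc if conc > 0 else 1.0,
                k_decay=k_decay,
            )
            predicted = two_state_fraction(course.times, preset)
            sd = np.where(
                np.isfinite(course.sds) & (course.sds > 0), course.sds, 1.0
            )
            mask = np.isfinite(course.fractions)
            out.append(((predicted - course.fractions) / sd)[mask])
        return np.concatenate(out)

    x0 = [max(template.k_spont, 1e-3), max(template.efficacy, 0.1)]
    if fit_decay:
        x0.append(max(template.k_decay, 1e-3))
    x0 = np.asarray(x0)
    lower = np.zeros_like(x0)
    result = least_squares(residuals, x0, bounds=(lower, np.inf), method="trf")
    if result.status <= 0:
        raise RuntimeError("kinetic model fit did not converge")
    k_spont, efficacy, k_decay = unpack(result.x)
    n = result.fun.size
    n_params = result.x.size
    rss = float(np.sum(result.fun**2))
    # Parameter covariance from the Gauss-Newton approximation.
    jac = result.jac
    try:
        cov = np.linalg.inv(jac.T @ jac) * rss / max(n - n_params, 1)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(n_params, np.nan)
    stderr = {"k_spont": float(se[0]), "efficacy": float(se[1])}
    if fit_decay:
        stderr["k_decay"] = float(se[2])
    aic = n * np.log(max(rss, 1e-12) / n) + 2 * n_params
    return KineticFit(
        k_spont=k_spont,
        efficacy=efficacy,
        k_decay=k_decay,
        stderr=stderr,
        rss=rss,
        n=n,
        aic=float(aic),
        fixed_k_decay=not fit_decay,
    )
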