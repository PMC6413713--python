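"""Cerebrovascular reactivity from steady-state contrast-enhanced series.

A blood-pool iron-oxide agent darkens the T2-weighted signal in
proportion to blood volume, so the log signal drop from the pre-contrast
baseline Spre to the post-contrast steady state S0 measures baseline
blood volume:

    CBV0 = -ln(S0 / Spre)

and the percent CBV change after a vasodilator stimulus is the ratio of
log signal ratios (unit-invariant; any overall intensity scaling
cancels):

    dCBV%(t) = 100 * ln(S(t) / S0) / ln(S0 / Spre)

Reactivity is summarized by an ordinary least-squares fit of
sqrt(dCBV%) against time (minutes after the stimulus) and by the mean
"late" dCBV% over repetitions 90-100 (40-46.7 min).  ROI-mean signals
are formed before the logs ("ROI-mean-then-log").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CVR_REGIONS, WHOLE_BRAIN, CvrAcquisition, CvrResult, LabelAtlas
from .roi import region_signal_series

#: Post-contrast steady-state window (1-based repetitions, inclusive):
#: 5 min after the contrast agent through the vasodilator injection.
STEADY_WINDOW = (15, 30)

#: Late-response window (1-based repetitions, inclusive): 40-46.7 min
#: after the stimulus.
LATE_WINDOW = (90, 100)


def _window_slice(window: tuple[int, int], n_rep: int, what: str) -> slice:
    lo, hi = window
    if not (1 <= lo <= hi <= n_rep):
        raise ValueError(f"{what} window {window} outside series of {n_rep} repetitions")
    return slice(lo - 1, hi)


def _mean_signals(
    acq: CvrAcquisition, atlas: LabelAtlas, regions: tuple[str, ...]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    pre = region_signal_series(acq.pre_contrast, atlas, regions)
    main = region_signal_series(acq.main_series, atlas, regions)
    return pre, main


def compute_cbv0(
    acq: CvrAcquisition,
    atlas: LabelAtlas,
    steady_window: tuple[int, int] = STEADY_WINDOW,
    regions: tuple[str, ...] = CVR_REGIONS,
) -> pd.DataFrame:
    """Baseline blood volume per region: -ln(steady mean / pre-contrast mean).

    A negative value (steady signal above baseline, i.e. contrast
    failure) is kept but flagged.
    """
    if steady_window[1] > acq.acz_rep:
        raise ValueError("steady window must end at or before the stimulus repetition")
    sl = _window_slice(steady_window, acq.n_rep, "steady")
    pre, main = _mean_signals(acq, atlas, regions)
    rows = []
    for region in list(regions) + [WHOLE_BRAIN]:
        spre = float(pre[region].mean())
        s0 = float(main[region].iloc[sl].mean())
        if spre <= 0 or s0 <= 0:
            raise ValueError(f"region {region!r}: non-positive mean signal")
        cbv0 = -np.log(s0 / spre)
        rows.append(
            {"region": region, "cbv0": cbv0, "negative": cbv0 < 0,
             "spre": spre, "s0": s0}
        )
    return pd.DataFrame(rows)


def compute_dcbv_series(
    acq: CvrAcquisition,
    atlas: LabelAtlas,
    steady_window: tuple[int, int] = STEADY_WINDOW,
    regions: tuple[str, ...] = CVR_REGIONS,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Percent CBV change over the whole main series, per region.

    Returns (times_min, table) where times_min is the axis in minutes
    relative to the stimulus (negative before it) and the table has one
    column per region plus ``whole_brain``.
    """
    cbv0 = compute_cbv0(acq, atlas, steady_window, regions).set_index("region")
    _, main = _mean_signals(acq, atlas, regions)
    times = acq.times_min()
    out = {}
    for region in list(regions) + [WHOLE_BRAIN]:
        spre = cbv0.loc[region, "spre"]
        s0 = cbv0.loc[region, "s0"]
        log_drop = np.log(s0 / spre)
        if log_drop == 0:
            raise ValueError(f"region {region!r}: zero baseline CBV (no contrast effect)")
        out[region] = 100.0 * np.log(main[region].to_numpy() / s0) / log_drop
    return times, pd.DataFrame(out)


@dataclass
class SlopeFit:
    slope_a: float
    intercept_b: float
    corr_r: float
    n_clipped: int
    n_points: int


def fit_cvr_slope(times_min: np.ndarray, dcbv_pct: np.ndarray) -> SlopeFit:
    """OLS of sqrt(dCBV%) on time over the post-stimulus window (t >= 0).

    Negative dCBV% points are clipped to 0 before the square root (their
    count is reported); ``corr_r`` is the Pearson correlation between the
    fitted line and the data, NaN when the data have zero variance.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(dcbv_pct, dtype=float)
    post = t >= 0
    t, y = t[post], y[post]
    n_clipped = int(np.sum(y < 0))
    y = np.sqrt(np.clip(y, 0.0, None))
    keep = np.isfinite(y)
    t, y = t[keep], y[keep]
    if t.size < 3:
        raise ValueError("need >= 3 post-stimulus points to fit the response slope")
    if np.all(y == 0):
        raise ValueError("all post-stimulus points clipped; response fit undefined")
    tb, yb = t.mean(), y.mean()
    sxx = float(np.sum((t - tb) ** 2))
    sxy = float(np.sum((t - tb) * (y - yb)))
    slope = sxy / sxx
    intercept = yb - slope * tb
    syy = float(np.sum((y - yb) ** 2))
    if syy == 0:
        corr = np.nan
    else:
        # correlation of the fitted line with the data = |corr(t, y)|
        corr = abs(sxy) / np.sqrt(sxx * syy)
    return SlopeFit(slope, intercept, float(corr), n_clipped, int(t.size))


def late_dcbv(
    dcbv_pct: np.ndarray,
    window: tuple[int, int] = LATE_WINDOW,
) -> float:
    """Mean dCBV% over a 1-based inclusive repetition window (default 90-100)."""
    y = np.asarray(dcbv_pct, dtype=float)
    sl = _window_slice(window, y.size, "late")
    return float(np.mean(y[sl]))


def cvr_pipeline(
    acq: CvrAcquisition,
    atlas: LabelAtlas,
    steady_window: tuple[int, int] = STEADY_WINDOW,
    late_window: tuple[int, int] = LATE_WINDOW,
    regions: tuple[str, ...] = CVR_REGIONS,
) -> list[CvrResult]:
    """Full per-subject reactivity analysis: one CvrResult per region
    (plus ``whole_brain``, used by the cohort-level exclusion rule)."""
    cbv0 = compute_cbv0(acq, atlas, steady_window, regions).set_index("region")
    times, dcbv = compute_dcbv_series(acq, atlas, steady_window, regions)
    results = []
    # strictly post-stimulus repetitions: the repetition at t = 0 is the
    # one the vasodilator follows, so it still carries the flat steady state
    post = times > 0
    for region in list(regions) + [WHOLE_BRAIN]:
        series = dcbv[region].to_numpy()
        try:
            fit = fit_cvr_slope(times[post], series[post])
        except ValueError:
            # whole response clipped away (e.g. contrast failure): keep the
            # subject row so the exclusion rule can judge it, fit undefined
            n_clip = int(np.sum(series[post] < 0))
            fit = SlopeFit(np.nan, np.nan, np.nan, n_clip, int(np.sum(post)))
        results.append(
            CvrResult(
                subject_id=acq.subject_id,
                region=region,
                cbv0=float(cbv0.loc[region, "cbv0"]),
                cbv0_negative=bool(cbv0.loc[region, "negative"]),
                times_min=times,
                dcbv_pct=series,
                slope_a=fit.slope_a,
                intercept_b=fit.intercept_b,
                corr_r=fit.corr_r,
                late_dcbv_pct=late_dcbv(series, late_window),
                n_clipped=fit.n_clipped,
            )
        )
    return results


def apply_exclusion(
    per_subject: dict[str, list[CvrResult]],
) -> tuple[dict[str, list[CvrResult]], pd.DataFrame]:
    """Drop subjects whose whole-brain mean post-stimulus dCBV% is negative.

    Mirrors the study's outlier rule (animals with negative response to
    the vasodilator are contrast/physiology failures).  Returns the
    retained subjects and an exclusion log.
    """
    retained: dict[str, list[CvrResult]] = {}
    log_rows = []
    for sid, results in per_subject.items():
        wb = next((r for r in results if r.region == WHOLE_BRAIN), None)
        if wb is None:
            raise ValueError(f"subject {sid!r}: whole-brain region missing")
        post = wb.times_min >= 0
        mean_post = float(np.mean(wb.dcbv_pct[post]))
        if mean_post < 0:
            log_rows.append({"subject_id": sid, "whole_brain_mean_dcbv_pct": mean_post})
            for r in results:
                r.excluded = True
        else:
            retained[sid] = results
    if not retained:
        warnings.warn("all subjects excluded by the negative-response rule")
    log = pd.DataFrame(log_rows, columns=["subject_id", "whole_brain_mean_dcbv_pct"])
    return retained, log
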