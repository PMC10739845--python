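"""Terminal-restriction-fragment (TRF) lane quantification.

Turns southern-blot densitometry traces into the three telomere phenotypes
used downstream:

* **aTL** — average TRF length of a lane, either the classic
  probe-bias-corrected weighted mean ``sum(OD) / sum(OD / L)`` or the mean of
  a Gaussian fitted to the corrected abundance profile;
* **RTL** — the lane's aTL divided by the reference (HeLa) lane's aTL on the
  same gel, which cancels gel-to-gel migration differences;
* **STP** — short-telomere proportion, the fraction of lane signal mapping
  below a 5 kb cutoff.

Lanes whose Gaussian fit explains less than a configurable fraction of the
corrected abundance variance (default 60%) are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .containers import LaneProfile

__all__ = [
    "Calibration",
    "TrfEstimate",
    "calibrate_ladder",
    "quantify_lane",
    "compute_rtl",
    "compute_stp",
]


class CalibrationError(ValueError):
    pass


class QuantificationError(ValueError):
    pass


@dataclass
class Calibration:
    """Monotone map from migration distance to log10 fragment length.

    ``coefficients`` are ``(a, b)`` of ``log10(size) = a + b * distance``
    with ``b < 0``; ``valid_range`` is the bp interval bracketed by the
    ladder, outside which the map is extrapolation and signal is clipped.
    """

    coefficients: tuple[float, float]
    valid_range: tuple[float, float]
    rmse_pixels: float = float("nan")

    def length_at(self, distance):
        a, b = self.coefficients
        return np.power(10.0, a + b * np.asarray(distance, dtype=float))


@dataclass
class TrfEstimate:
    lane_id: str
    aTL_weighted: float
    aTL_gauss: float
    fit_r2: float
    accepted: bool
    clipped_fraction: float = 0.0
    RTL: float = float("nan")
    STP: float = float("nan")

    @property
    def aTL(self) -> float:
        """Default aTL: Gaussian-fit mean when accepted, else weighted mean."""
        return self.aTL_gauss if self.accepted else self.aTL_weighted


def _rolling_min_baseline(intensity: np.ndarray, frac: float = 0.10) -> np.ndarray:
    """Rolling-minimum background over a window of `frac` of the lane."""
    w = max(int(round(frac * intensity.size)), 1)
    pad = w // 2
    padded = np.pad(intensity, pad, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, w)
    base = windows.min(axis=1)
    return base[: intensity.size]


def calibrate_ladder(ladder: LaneProfile, known_sizes: list[float]) -> Calibration:
    """Fit the migration map from a ladder lane.

    Peaks are local maxima above the lane's background; the ``k`` largest
    sizes are matched to the ``k`` smallest migration distances in order
    (sizes must be sorted descending). Requires at least 3 matched peaks.
    """
    if sorted(known_sizes, reverse=True) != list(known_sizes):
        raise CalibrationError("known_sizes must be sorted descending")
    intensity = ladder.intensity - _rolling_min_baseline(ladder.intensity)
    height = max(intensity.max() * 0.2, 1e-12)
    peaks, _ = signal.find_peaks(intensity, height=height, distance=5)
    if len(peaks) < 3 or len(peaks) < len(known_sizes):
        raise CalibrationError(
            f"found {len(peaks)} ladder peaks for {len(known_sizes)} known sizes "
            f"(need >= 3 and >= number of sizes); matched at pixels {list(peaks)}"
        )
    distances = np.sort(ladder.pixels[peaks])[: len(known_sizes)]
    logsize = np.log10(np.asarray(known_sizes, dtype=float))
    b, a = np.polyfit(distances, logsize, 1)
    # report residuals on the pixel axis: invert the fit per ladder rung
    pred_d = (logsize - a) / b
    rmse = float(np.sqrt(np.mean((pred_d - distances) ** 2)))
    return Calibration((float(a), float(b)), (min(known_sizes), max(known_sizes)), rmse)


def _corrected_profile(lane: LaneProfile, cal: Calibration, background: str = "rolling_min"):
    """Background-subtract, map pixels to lengths, and bias-correct.

    Returns ``(lengths, od, abundance, clipped_fraction)`` restricted to the
    calibration's valid range; ``abundance = od / length`` undoes the probe's
    proportional-to-length binding. ``background`` is ``rolling_min``
    (default; tracks a drifting baseline but erodes plateaus wider than the
    window) or ``none`` for pre-subtracted traces.
    """
    if background == "rolling_min":
        od = lane.intensity - _rolling_min_baseline(lane.intensity)
    elif background == "none":
        od = lane.intensity.copy()
    else:
        raise ValueError(f"unknown background mode {background!r}")
    od = np.clip(od, 0.0, None)
    total = od.sum()
    if total <= 0:
        raise QuantificationError(f"lane {lane.lane_id}: no signal above background")
    lengths = cal.length_at(lane.pixels)
    lo, hi = cal.valid_range
    keep = (lengths >= lo) & (lengths <= hi)
    clipped = float(od[~keep].sum() / total)
    lengths, od = lengths[keep], od[keep]
    if od.sum() <= 0:
        raise QuantificationError(
            f"lane {lane.lane_id}: all signal outside calibratable range"
        )
    return lengths, od, od / lengths, clipped


def _gaussian(x, amp, mu, sd):
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def quantify_lane(
    lane: LaneProfile, cal: Calibration, fit_threshold: float = 0.60
) -> TrfEstimate:
    """Estimate aTL for one lane with a fit-quality acceptance gate.

    The weighted aTL is ``sum(OD) / sum(OD / L)`` (the mean of the
    bias-corrected abundance distribution); the Gaussian aTL is the mean of a
    nonlinear least-squares Gaussian fitted to corrected abundance vs length.
    ``accepted`` requires the Gaussian to explain at least ``fit_threshold``
    of the abundance variance.
    """
    lengths, od, abundance, clipped = _corrected_profile(lane, cal)
    atl_weighted = float(od.sum() / (od / lengths).sum())

    centroid = float(np.sum(lengths * abundance) / abundance.sum())
    sd0 = float(
        np.sqrt(np.sum(abundance * (lengths - centroid) ** 2) / abundance.sum())
    )
    sd0 = max(sd0, np.abs(np.diff(lengths)).min() if lengths.size > 1 else 1.0)
    try:
        popt, _ = optimize.curve_fit(
            _gaussian,
            lengths,
            abundance,
            p0=(abundance.max(), centroid, sd0),
            maxfev=200 * 4,
            xtol=1e-8,
            ftol=1e-8,
        )
        fitted = _gaussian(lengths, *popt)
        ss_res = float(np.sum((abundance - fitted) ** 2))
        ss_tot = float(np.sum((abundance - abundance.mean()) ** 2))
        fit_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        atl_gauss = float(popt[1])
    except RuntimeError:
        fit_r2, atl_gauss = 0.0, float("nan")

    accepted = bool(fit_r2 >= fit_threshold and np.isfinite(atl_gauss))
    return TrfEstimate(
        lane_id=lane.lane_id,
        aTL_weighted=atl_weighted,
        aTL_gauss=atl_gauss,
        fit_r2=float(fit_r2),
        accepted=accepted,
        clipped_fraction=clipped,
    )


def compute_rtl(
    batch: list[TrfEstimate], reference: TrfEstimate, use: str = "auto"
) -> list[TrfEstimate]:
    """Attach RTL = sample aTL / reference aTL to each estimate.

    ``use`` picks the aTL variant for *both* numerator and denominator:
    ``"weighted"``, ``"gauss"`` or ``"auto"`` (the reference's accepted
    default). Rejected samples get ``NaN`` RTL, never zero.
    """
    if not reference.accepted:
        raise ValueError("reference lane was rejected by the fit-quality gate")

    def pick(est: TrfEstimate) -> float:
        if use == "weighted":
            return est.aTL_weighted
        if use == "gauss":
            return est.aTL_gauss
        return est.aTL

    ref_atl = pick(reference)
    out = []
    for est in batch:
        rtl = pick(est) / ref_atl if est.accepted else float("nan")
        out.append(
            TrfEstimate(
                est.lane_id,
                est.aTL_weighted,
                est.aTL_gauss,
                est.fit_r2,
                est.accepted,
                est.clipped_fraction,
                RTL=float(rtl),
                STP=est.STP,
            )
        )
    return out


def compute_stp(
    lane: LaneProfile,
    cal: Calibration,
    cutoff: float = 5_000.0,
    corrected: bool = False,
    background: str = "rolling_min",
) -> float:
    """Short-telomere proportion: fraction of lane signal below ``cutoff`` bp.

    By default the ratio is taken on raw band intensity; ``corrected=True``
    uses probe-bias-corrected abundance instead, which weights short
    fragments more heavily.
    """
    lengths, od, abundance, _ = _corrected_profile(lane, cal, background)
    weights = abundance if corrected else od
    return float(weights[lengths < cutoff].sum() / weights.sum())
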