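"""ADIFAB free-fatty-acid quantification and DSC transition extraction.

The ADIFAB probe reports unbound free fatty acid (FFA) through the ratio of
its emission at 550 and 457 nm:

    R    = (I550 - I550_blank) / (I457 - I457_blank)
    R0   = the same ratio for the zero-FFA control
    [FFA] = Kd * Q * (R - R0) / (Rmax - R)
    Rmax  = (R0_measured / R0_calibration) * Rmax_calibration
    [FFA]_net = [FFA]_PLA - [FFA]_background

with the kit calibration constants Kd = 32, Q = 5, Rmax_calibration =
0.762.  Kd's units are the kit's concentration units, so reported FFA
values inherit them ("Kd units" by default).

DSC thermograms are reduced to the main transition temperature Tm (peak of
the baseline-subtracted endotherm, parabolic-refined) and the width of the
transition at half height (dT1/2), plus an optional pre-transition peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ADIFAB2_CONSTANTS = dict(Kd=32.0, Q=5.0, Rmax_calibration=0.762)


class SaturationError(ValueError):
    """R at or beyond Rmax: the probe is saturated and Eq. inversion diverges."""


@dataclass(frozen=True)
class FluorescenceReading:
    sample_id: str
    I550: float
    I457: float
    I550_blank: float = 0.0
    I457_blank: float = 0.0


@dataclass
class AssayConstants:
    Kd: float = 32.0
    Q: float = 5.0
    Rmax_calibration: float = 0.762
    R0_calibration: float = 0.3
    unit: str = "Kd units"

    def __post_init__(self) -> None:
        if self.Kd <= 0 or self.Q <= 0 or self.Rmax_calibration <= 0:
            raise ValueError("Kd, Q and Rmax_calibration must be positive")


@dataclass
class Thermogram:
    temperature: np.ndarray  # deg C, strictly increasing
    heat_flow: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.heat_flow = np.asarray(self.heat_flow, dtype=float)
        if self.temperature.size != self.heat_flow.size:
            raise ValueError("temperature and heat flow must have equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly increasing")


@dataclass
class TransitionResult:
    tm: float | None               # deg C; None when no transition found
    delta_t_half: float | None     # deg C, full width at half height
    pre_transition_tm: float | None = None
    peak_height: float = 0.0
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# ADIFAB equations
# ---------------------------------------------------------------------------

def adifab_ratio(reading: FluorescenceReading) -> float:
    """Blank-corrected 550/457 intensity ratio R (Eqs for R and R0 alike)."""
    denom = reading.I457 - reading.I457_blank
    if denom == 0:
        raise ValueError(f"sample {reading.sample_id!r}: zero 457 nm denominator")
    return (reading.I550 - reading.I550_blank) / denom


def calibration_rescale(r0_measured: float, constants: AssayConstants) -> float:
    """Working Rmax: (R0_measured / R0_calibration) * Rmax_calibration."""
    if r0_measured < 0 or constants.R0_calibration <= 0:
        raise ValueError("R0 values must be positive")
    rmax = (r0_measured / constants.R0_calibration) * constants.Rmax_calibration
    if rmax == 0:
        import logging
        logging.getLogger("memprobe").warning(
            "R0_measured = 0 gives working Rmax = 0; implausible calibration")
    return rmax


def ffa_concentration(r: float, r0: float, constants: AssayConstants,
                      rmax: float | None = None) -> float:
    """Unbound FFA in Kd units: Kd * Q * (R - R0) / (Rmax - R).

    Values below baseline (R < R0) are returned as-is (negative); callers
    should flag them rather than clip.
    """
    if rmax is None:
        rmax = constants.Rmax_calibration
    if r >= rmax:
        raise SaturationError(f"R = {r} >= Rmax = {rmax}: probe saturated")
    return constants.Kd * constants.Q * (r - r0) / (rmax - r)


def net_ffa(ffa_pla: float, ffa_background: float) -> float:
    """Enzyme-generated FFA: total minus the no-enzyme background."""
    return ffa_pla - ffa_background


def quantify_readings(readings: list[FluorescenceReading], r0: float,
                      constants: AssayConstants,
                      rmax: float | None = None) -> list[dict]:
    """Tidy per-sample records: sample_id, R, FFA, below-baseline flag."""
    rows = []
    for rd in readings:
        r = adifab_ratio(rd)
        ffa = ffa_concentration(r, r0, constants, rmax=rmax)
        rows.append({"sample_id": rd.sample_id, "R": r, "ffa": ffa,
                     "unit": constants.unit, "below_baseline": ffa < 0})
    return rows


# ---------------------------------------------------------------------------
# DSC transition extraction
# ---------------------------------------------------------------------------

def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    if i == 0 or i == y.size - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y[i])
    d = 0.5 * (y0 - y2) / denom
    d = float(np.clip(d, -1.0, 1.0))
    xr = x[i] + d * (x[i] - x[i - 1])
    yr = y1 - 0.25 * (y0 - y2) * d
    return float(xr), float(yr)


def _half_height_width(t: np.ndarray, y: np.ndarray, ipk: int, half: float) -> float | None:
    """Full width where y crosses `half`, linearly interpolated."""
    left = None
    for i in range(ipk, 0, -1):
        if y[i - 1] < half <= y[i]:
            frac = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    right = None
    for i in range(ipk, y.size - 1):
        if y[i + 1] < half <= y[i]:
            frac = (y[i] - half) / (y[i] - y[i + 1])
            right = t[i] + frac * (t[i + 1] - t[i])
            break
    if left is None or right is None:
        return None
    return float(right - left)


def extract_transition(thermogram: Thermogram, flank_fraction: float = 0.15,
                       noise_floor_sigmas: float = 5.0,
                       pre_prominence: float = 0.05) -> TransitionResult:
    """Tm and dT1/2 of the main endotherm after linear baseline subtraction.

    The baseline is fit to the outer `flank_fraction` of the temperature
    range on each side.  A peak must rise `noise_floor_sigmas` flank
    standard deviations above the baseline to count; otherwise the result
    is "no transition" (not an exception).  The largest secondary maximum
    below Tm with relative prominence >= `pre_prominence` of the main peak
    is reported as the pre-transition.
    """
    t = thermogram.temperature
    y = thermogram.heat_flow
    if t.size < 10:
        raise ValueError("thermogram needs at least 10 grid points")
    k = max(2, int(flank_fraction * t.size))
    flank_t = np.concatenate([t[:k], t[-k:]])
    flank_y = np.concatenate([y[:k], y[-k:]])
    slope, intercept = np.polyfit(flank_t, flank_y, 1)
    excess = y - (slope * t + intercept)
    noise = float(np.std(flank_y - (slope * flank_t + intercept)))

    ipk = int(np.argmax(excess))
    height = float(excess[ipk])
    if height <= max(noise_floor_sigmas * noise, 1e-12):
        return TransitionResult(tm=None, delta_t_half=None,
                                flags=["no transition"])
    tm, h_ref = _parabolic_refine(t, excess, ipk)
    width = _half_height_width(t, excess, ipk, height / 2.0)
    flags = []
    if width is None:
        flags.append("half-height width not bracketed")

    # pre-transition: secondary local maximum below the main peak
    pre_tm = None
    from scipy.signal import find_peaks
    floor = max(pre_prominence * height, noise_floor_sigmas * noise)
    peaks, props = find_peaks(excess[:ipk], prominence=floor)
    if peaks.size:
        best = peaks[np.argmax(props["prominences"])]
        # require separation from the main peak's own shoulder
        if excess[best] < 0.9 * height:
            pre_tm, _ = _parabolic_refine(t, excess, int(best))
    return TransitionResult(tm=tm, delta_t_half=width, pre_transition_tm=pre_tm,
                            peak_height=height, flags=flags)
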