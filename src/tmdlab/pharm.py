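"""Pharmacological summary statistics.

Hill dose-response fitting (EC50, Hill coefficient, maximal response),
model-light 10-90% rise/decay times, percent inverse agonism, and
reference-response normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np

from .photobleach import IntensityTrace

__all__ = [
    "HillFit",
    "KineticsResult",
    "InverseAgonismResult",
    "fit_hill",
    "time_10_90",
    "inverse_agonism_percent",
    "normalize_response",
]


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill equation r(c) = baseline + emax c^n / (c^n + EC50^n)."""

    ec50_uM: float
    hill_n: float
    emax: float
    baseline: float
    residual_ss: float
    stderr: dict[str, float | None]
    extrapolated: bool
    unidentifiable: bool = False

    def predict(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        out = np.full(c.shape, self.baseline)
        pos = c > 0
        cn = np.power(c[pos], self.hill_n)
        out[pos] = self.baseline + self.emax * cn / (cn + self.ec50_uM ** self.hill_n)
        return out


def fit_hill(
    concentrations_uM,
    responses,
    free_baseline: bool = False,
) -> HillFit:
    """Least-squares Hill fit with baseline fixed at 0 by default.

    EC50 is initialized at the tested concentration whose mean response is
    nearest half-maximum and the Hill coefficient at 1; parameter standard
    errors come from the curvature (covariance) at the optimum.  An EC50
    outside the tested concentration range is flagged extrapolated, and a
    flat response surface is flagged unidentifiable.
    """
    c = np.asarray(concentrations_uM, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.size != r.size:
        raise ValueError("concentration/response length mismatch")
    if np.unique(c).size < 4:
        raise ValueError("need >= 4 distinct concentrations")

    span = float(r.max() - r.min())
    flat = span < 1e-12 or span < 0.02 * max(abs(r).max(), 1e-12)

    pos = c > 0
    target = r.min() + 0.5 * span
    ec50_init = float(c[pos][np.argmin(np.abs(r[pos] - target))])

    params = lmfit.Parameters()
    params.add("ec50", value=ec50_init, min=1e-12)
    params.add("n", value=1.0, min=1e-3, max=20.0)
    params.add("emax", value=float(r.max()) if r.max() > 0 else 1.0)
    params.add("baseline", value=0.0, vary=free_baseline)

    def resid(p):
        model = np.full(c.shape, p["baseline"].value)
        cn = np.power(c[pos], p["n"].value)
        model[pos] += p["emax"].value * cn / (cn + p["ec50"].value ** p["n"].value)
        return model - r

    out = lmfit.minimize(resid, params, method="leastsq",
                         xtol=1e-14, ftol=1e-14)
    p = out.params
    stderr = {k: (p[k].stderr if p[k].vary else None)
              for k in ("ec50", "n", "emax", "baseline")}
    tested = c[pos]
    extrapolated = not (tested.min() <= p["ec50"].value <= tested.max())
    return HillFit(
        ec50_uM=float(p["ec50"].value),
        hill_n=float(p["n"].value),
        emax=float(p["emax"].value),
        baseline=float(p["baseline"].value),
        residual_ss=float(np.sum(np.asarray(out.residual) ** 2)),
        stderr=stderr,
        extrapolated=extrapolated,
        unidentifiable=flat,
    )


@dataclass(frozen=True)
class KineticsResult:
    """10-90% transition time for a drug response."""

    t_10_90_s: float
    direction: str  # "on" or "off"
    t10_s: float
    t90_s: float

    def __post_init__(self) -> None:
        if self.t_10_90_s <= 0:
            raise ValueError("t_10_90 must be positive")


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float,
                    rising: bool) -> float:
    """First time y crosses ``level``, linearly interpolated."""
    above = y >= level if rising else y <= level
    idx = np.flatnonzero(above)
    if idx.size == 0:
        raise ValueError("trace never crosses the threshold")
    i = idx[0]
    if i == 0:
        return float(t[0])
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    frac = (level - y0) / (y1 - y0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def time_10_90(
    trace: IntensityTrace,
    epoch_start_s: float,
    direction: str = "on",
    epoch_end_s: float | None = None,
    smooth_window: int = 0,
) -> KineticsResult:
    """Time between the 10% and 90% crossings of a response transition.

    The pre-epoch baseline is the mean before ``epoch_start_s`` and the
    plateau is the mean of the final 10% of the epoch; the 10% and 90%
    thresholds of the amplitude are located by linear interpolation between
    adjacent samples.  Raises if the amplitude is indistinguishable from
    baseline noise (< 3 baseline s.d.).
    """
    if direction not in ("on", "off"):
        raise ValueError("direction must be 'on' or 'off'")
    t = trace.time_s
    y = trace.intensity.astype(float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        y = np.convolve(y, kernel, mode="same")
    if epoch_end_s is None:
        epoch_end_s = float(t[-1])
    pre = t < epoch_start_s
    if pre.sum() < 2:
        raise ValueError("no pre-epoch baseline samples")
    baseline = float(np.mean(y[pre]))
    base_sd = float(np.std(y[pre], ddof=1))
    in_epoch = (t >= epoch_start_s) & (t <= epoch_end_s)
    tail_start = epoch_end_s - 0.1 * (epoch_end_s - epoch_start_s)
    tail = in_epoch & (t >= tail_start)
    plateau = float(np.mean(y[tail]))
    amplitude = plateau - baseline
    if abs(amplitude) < 3.0 * base_sd:
        raise ValueError("no response: amplitude within baseline noise")

    rising = amplitude > 0
    lv10 = baseline + 0.1 * amplitude
    lv90 = baseline + 0.9 * amplitude
    seg = in_epoch
    t10 = _first_crossing(t[seg], y[seg], lv10, rising)
    t90 = _first_crossing(t[seg], y[seg], lv90, rising)
    if t90 <= t10:
        raise ValueError("90% crossing precedes 10% crossing")
    return KineticsResult(t_10_90_s=t90 - t10, direction=direction,
                          t10_s=t10, t90_s=t90)


@dataclass(frozen=True)
class InverseAgonismResult:
    I_NAM: float
    I_Glu: float
    percent: float


def inverse_agonism_percent(I_NAM: float, I_Glu: float) -> InverseAgonismResult:
    """Percent inverse agonism = 100 I_NAM / (I_NAM + I_Glu).

    Inputs are the raw (non-negative) amplitudes of the outward current under
    the negative modulator and the agonist-evoked current in the same cell.
    """
    if I_NAM < 0 or I_Glu < 0:
        raise ValueError("amplitudes must be non-negative magnitudes")
    if I_NAM == 0 and I_Glu == 0:
        raise ValueError("both amplitudes zero: percent undefined")
    return InverseAgonismResult(I_NAM, I_Glu, 100.0 * I_NAM / (I_NAM + I_Glu))


def normalize_response(amplitude: float, reference_amplitude: float) -> float:
    """Response as a fraction of a saturating reference response."""
    if reference_amplitude <= 0:
        raise ValueError("reference amplitude must be positive")
    return amplitude / reference_amplitude
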