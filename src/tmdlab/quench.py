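"""Stretched-exponential analysis of stopped-flow Tl+ quench traces.

Gramicidin-permeabilized vesicles loaded with an ANTS fluorophore are mixed
with the channel-permeant quencher Tl+; the ensemble fluorescence decay is
well represented by a stretched exponential,

    F(t) = F(inf) + (F(0) - F(inf)) * exp{-(t / tau0)^beta},

a compact surrogate for a sum of exponentials arising from the vesicle size
distribution (beta = 1 is a homogeneous sample).  The quench rate — the
initial Tl+ influx rate, reporting gramicidin activity and hence bilayer
properties — is the decay rate of the normalized stretched exponential
evaluated at 2 ms:

    Rate = (beta / tau0) * (t / tau0)^(beta - 1) | t = 2 ms.

Rates are averaged over quencher trials and normalized to matched
no-modulator control experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd

from .simulate import stretched_exp

__all__ = [
    "StretchedExpFit",
    "QuenchRateResult",
    "correct_compound_fluorescence",
    "fit_stretched_exp",
    "rate_at",
    "experiment_rate",
]

DEFAULT_WINDOW_MS = (2.0, 100.0)  # instrument dead time excludes t < 2 ms


@dataclass(frozen=True)
class StretchedExpFit:
    """Stretched-exponential parameters fitted over a time window."""

    F0: float
    Finf: float
    tau0_ms: float
    beta: float
    fit_window_ms: tuple[float, float]
    residual_ss: float
    flagged: bool = False  # non-decaying trace / parameter at bound

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"beta={self.beta} outside (0, 1]")
        if self.tau0_ms <= 0:
            raise ValueError("tau0 must be positive")
        if not self.flagged and self.F0 <= self.Finf:
            raise ValueError("need F0 > Finf for a decaying trace")


def correct_compound_fluorescence(
    trace: pd.DataFrame,
    compound_only_reference: pd.DataFrame | float | None,
) -> pd.DataFrame:
    """Remove the modulator's own (constant) fluorescence from a trace.

    The correction is additive-offset removal: the mean level of a
    compound-only reference (or a scalar offset) is subtracted, so that
    control traces line up across compounds.  A reference of 0 leaves the
    trace unchanged.
    """
    if compound_only_reference is None:
        raise ValueError(
            "a compound-only reference is required to correct for compound "
            "fluorescence"
        )
    if isinstance(compound_only_reference, pd.DataFrame):
        offset = float(compound_only_reference["fluorescence"].mean())
    else:
        offset = float(compound_only_reference)
    out = trace.copy()
    out["fluorescence"] = out["fluorescence"] - offset
    return out


def fit_stretched_exp(
    trace: pd.DataFrame,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
) -> StretchedExpFit:
    """Least-squares stretched-exponential fit over the given window.

    F0 and Finf are initialized from the first and last window samples,
    beta at 0.8, and tau0 at the time the trace reaches the 1/e level of
    its window span; beta is constrained to (0, 1].  A non-decaying trace
    yields a flagged fit rather than an exception.
    """
    lo, hi = window_ms
    t = trace["time_ms"].to_numpy(dtype=float)
    y = trace["fluorescence"].to_numpy(dtype=float)
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 20:
        raise ValueError(f"only {int(sel.sum())} samples in window; need >= 20")
    tw, yw = t[sel], y[sel]

    f0_init, finf_init = float(yw[0]), float(yw[-1])
    span = f0_init - finf_init
    flagged = span <= 0
    if flagged:
        # non-decaying: report a pinned fit rather than diverging
        return StretchedExpFit(
            F0=f0_init, Finf=finf_init, tau0_ms=float("inf") if span == 0 else hi,
            beta=1.0, fit_window_ms=(lo, hi),
            residual_ss=float(np.sum((yw - yw.mean()) ** 2)), flagged=True,
        )
    level_1e = finf_init + span / math.e
    below = np.flatnonzero(yw <= level_1e)
    tau_init = float(tw[below[0]]) if below.size else float(tw[-1])

    params = lmfit.Parameters()
    params.add("F0", value=f0_init)
    params.add("Finf", value=finf_init)
    params.add("tau0", value=max(tau_init, 1e-6), min=1e-9)
    params.add("beta", value=0.8, min=1e-6, max=1.0)

    def resid(p):
        return stretched_exp(tw, p["F0"].value, p["Finf"].value,
                             p["tau0"].value, p["beta"].value) - yw

    out = lmfit.minimize(resid, params, method="leastsq",
                         xtol=1e-14, ftol=1e-14)
    p = out.params
    at_bound = p["beta"].value >= 1.0 - 1e-9 and p["beta"].init_value < 1.0
    return StretchedExpFit(
        F0=float(p["F0"].value),
        Finf=float(p["Finf"].value),
        tau0_ms=float(p["tau0"].value),
        beta=float(min(p["beta"].value, 1.0)),
        fit_window_ms=(lo, hi),
        residual_ss=float(np.sum(np.asarray(out.residual) ** 2)),
        flagged=at_bound,
    )


def rate_at(fit: StretchedExpFit, t_ms: float = 2.0) -> float:
    """Quench rate (ms^-1): (beta/tau0) (t/tau0)^(beta-1) at t = t_ms.

    This is the decay rate of the normalized stretched exponential; for
    beta = 1 it collapses to 1/tau0 at every t.
    """
    if not math.isfinite(fit.tau0_ms) or fit.tau0_ms <= 0:
        raise ValueError("tau0 must be finite and positive")
    return (fit.beta / fit.tau0_ms) * (t_ms / fit.tau0_ms) ** (fit.beta - 1.0)


@dataclass(frozen=True)
class QuenchRateResult:
    """Per-experiment quench rate and its control-normalized value."""

    rate_per_ms: float
    rate_sem: float
    normalized_rate: float
    n_trials: int


def experiment_rate(
    trial_fits: list[StretchedExpFit],
    control_rate_per_ms: float,
    t_ms: float = 2.0,
) -> QuenchRateResult:
    """Average quench rate over an experiment's quencher trials.

    The experiment Rate is the mean of the per-trial rates at ``t_ms``;
    normalized_rate = Rate / Rate_cntrl, where Rate_cntrl comes from matched
    experiments without the modulator.
    """
    if not trial_fits:
        raise ValueError("need at least one quencher-trial fit")
    if control_rate_per_ms <= 0:
        raise ValueError("control rate must be positive")
    rates = np.array([rate_at(f, t_ms) for f in trial_fits])
    sem = float(rates.std(ddof=1) / math.sqrt(rates.size)) if rates.size > 1 else 0.0
    mean = float(rates.mean())
    return QuenchRateResult(
        rate_per_ms=mean,
        rate_sem=sem,
        normalized_rate=mean / control_rate_per_ms,
        n_trials=rates.size,
    )


def rates_summary(results: list[QuenchRateResult]) -> dict[str, float]:
    """Cross-experiment mean +/- s.e.m. of normalized rates (>= 3 experiments
    is the usual reporting convention)."""
    vals = np.array([r.normalized_rate for r in results])
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
    return {"mean_normalized_rate": float(vals.mean()),
            "sem": sem, "n_experiments": int(vals.size)}
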