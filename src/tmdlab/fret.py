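"""Ratiometric FRET from two-channel recordings.

FRET is computed as I_Acceptor / (I_Donor + I_Acceptor), normalized to the
basal value before drug application, and drug responses are quantified as
plateau changes, optionally re-expressed as a fraction of a saturating
reference response recorded in the same cell.  No bleed-through or
direct-excitation corrections are applied: the quantities of interest are
relative FRET changes, not absolute efficiencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Epoch

__all__ = [
    "FretSeries",
    "FretResponse",
    "compute_fret",
    "normalize_baseline",
    "response_amplitude",
    "donor_recovery",
]

_MIN_PLATEAU_SAMPLES = 5
_MIN_EPOCH_SAMPLES = 20


@dataclass(frozen=True)
class FretSeries:
    """Paired donor/acceptor intensities with drug-application epochs."""

    time_s: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    epochs: tuple[Epoch, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        d = np.asarray(self.donor, dtype=float)
        a = np.asarray(self.acceptor, dtype=float)
        for name, arr in (("time_s", t), ("donor", d), ("acceptor", a)):
            if arr.size != t.size:
                raise ValueError(f"{name}: length mismatch")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name}: non-finite values")
        if np.any(d < 0) or np.any(a < 0):
            raise ValueError("negative intensities")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time not strictly increasing")
        eps = sorted(self.epochs, key=lambda e: e.start_s)
        for x, y in zip(eps, eps[1:]):
            if y.start_s < x.end_s:
                raise ValueError(f"epochs {x.label} and {y.label} overlap")
        for e in eps:
            if e.start_s < t[0] or e.end_s > t[-1]:
                raise ValueError(f"epoch {e.label} outside the series span")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "donor", d)
        object.__setattr__(self, "acceptor", a)
        object.__setattr__(self, "epochs", tuple(eps))


@dataclass(frozen=True)
class FretResponse:
    """Baseline-normalized plateau change for one drug epoch."""

    label: str
    delta_fret_norm: float
    ref_normalized: float | None = None


def compute_fret(series: FretSeries) -> np.ndarray:
    """Pointwise FRET ratio I_A / (I_D + I_A).

    Samples with zero total intensity are undefined and returned as NaN,
    never as 0; they propagate as gaps downstream.
    """
    total = series.donor + series.acceptor
    out = np.full(total.size, np.nan)
    ok = total > 0
    out[ok] = series.acceptor[ok] / total[ok]
    return out


def normalize_baseline(
    fret: np.ndarray,
    time_s: np.ndarray,
    baseline_window_s: tuple[float, float],
    epochs: tuple[Epoch, ...] = (),
) -> np.ndarray:
    """Divide a FRET trace by its mean over the pre-drug baseline window.

    The window must precede the first epoch, not overlap any epoch, and
    contain at least five defined samples; the baseline mean maps to 1.
    """
    lo, hi = baseline_window_s
    for e in epochs:
        if lo < e.end_s and e.start_s < hi:
            raise ValueError(f"baseline window overlaps epoch {e.label}")
        if hi > e.start_s:
            raise ValueError(
                f"baseline window must precede epoch {e.label}"
            )
    mask = (time_s >= lo) & (time_s <= hi) & np.isfinite(fret)
    if mask.sum() < _MIN_PLATEAU_SAMPLES:
        raise ValueError(
            f"baseline window contains {int(mask.sum())} samples; need >= "
            f"{_MIN_PLATEAU_SAMPLES}"
        )
    base = float(np.mean(fret[mask]))
    if base == 0.0:
        raise ValueError("baseline FRET is zero; cannot normalize")
    return fret / base


def _plateau(normalized: np.ndarray, time_s: np.ndarray, epoch: Epoch) -> float:
    """Mean of the last 25% of an epoch (the steady-state window)."""
    in_epoch = (time_s >= epoch.start_s) & (time_s <= epoch.end_s)
    if in_epoch.sum() < _MIN_EPOCH_SAMPLES:
        raise ValueError(
            f"epoch {epoch.label} has {int(in_epoch.sum())} samples; need >= "
            f"{_MIN_EPOCH_SAMPLES}"
        )
    win_start = epoch.end_s - 0.25 * (epoch.end_s - epoch.start_s)
    window = in_epoch & (time_s >= win_start) & np.isfinite(normalized)
    if window.sum() < _MIN_PLATEAU_SAMPLES:
        raise ValueError(f"epoch {epoch.label}: plateau window too short")
    return float(np.mean(normalized[window]))


def response_amplitude(
    normalized: np.ndarray,
    time_s: np.ndarray,
    epoch: Epoch,
    reference_epoch: Epoch | None = None,
) -> FretResponse:
    """Plateau change of a baseline-normalized trace for one epoch.

    delta = mean(last 25% of the epoch) - 1.  When a reference epoch (the
    saturating-drug application in the same recording) is given, the response
    is also expressed as delta / delta_reference.
    """
    delta = _plateau(normalized, time_s, epoch) - 1.0
    ref_norm = None
    if reference_epoch is not None:
        delta_ref = _plateau(normalized, time_s, reference_epoch) - 1.0
        if delta_ref == 0.0:
            raise ValueError("reference epoch shows no response")
        ref_norm = delta / delta_ref
    return FretResponse(epoch.label, delta, ref_norm)


@dataclass(frozen=True)
class DonorRecovery:
    recovery: float
    acceptor_loss: float
    acceptor_bleached: bool


def donor_recovery(
    I_D_before: float,
    I_D_after: float,
    I_A_before: float,
    I_A_after: float,
) -> DonorRecovery:
    """Fractional donor-fluorescence recovery after acceptor photobleaching.

    recovery = (I_D_after - I_D_before) / I_D_before.  A positive recovery
    indicates energy transfer was occurring.  If the acceptor lost less than
    80% of its intensity the bleach is flagged incomplete, but the value is
    still returned.  For an idealized two-fluorophore pair with conserved
    total intensity and FRET ratio E, full acceptor bleaching returns the
    transferred fraction to the donor: recovery = E / (1 - E).
    """
    if I_D_before <= 0:
        raise ValueError("donor intensity before bleach must be positive")
    loss = 1.0 - I_A_after / I_A_before if I_A_before > 0 else 1.0
    return DonorRecovery(
        recovery=(I_D_after - I_D_before) / I_D_before,
        acceptor_loss=loss,
        acceptor_bleached=loss >= 0.80,
    )


def responses_table(responses: list[FretResponse]) -> pd.DataFrame:
    """Tidy per-epoch response table."""
    return pd.DataFrame(
        [{"label": r.label, "delta_fret_norm": r.delta_fret_norm,
          "ref_normalized": r.ref_normalized} for r in responses]
    )
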