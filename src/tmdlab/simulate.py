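"""Synthetic data with known ground truth for every pipeline stage.

Emulates the raw material of a single-molecule receptor-dimerization study:

* single-molecule pulldown photobleaching movies — monomer/dimer mixtures with
  independent per-subunit labeling, chance colocalization background,
  exponential bleaching and Gaussian camera read noise;
* live-cell two-channel (donor/acceptor) FRET recordings with drug-application
  epochs and first-order on/off kinetics;
* Hill-type dose-response tables, with a preset bank of literature parameter
  sets for regression tests;
* whole-cell current traces with single-exponential activation/deactivation;
* stopped-flow fluorescence quench trials following a stretched-exponential
  decay, with compound-fluorescence offsets and matched no-quencher controls.

All generators take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .photobleach import IntensityTrace
from .stoichiometry import StoichiometryModel

__all__ = [
    "SpotTruth",
    "SimPullConfig",
    "Epoch",
    "DrugKinetics",
    "FretProtocol",
    "QuenchSimConfig",
    "QuenchExperiment",
    "DOSE_RESPONSE_PRESETS",
    "gen_photobleach_cohort",
    "gen_fret_series",
    "gen_dose_response",
    "gen_current_trace",
    "gen_quench_trials",
]


# ---------------------------------------------------------------------------
# single-molecule pulldown photobleaching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpotTruth:
    """Ground truth for one emitted (visible) spot."""

    spot_id: str
    complex_type: str  # monomer | dimer | colocalized_pair
    n_labeled: int
    bleach_times: tuple[float, ...]
    unit_intensity: float

    def __post_init__(self) -> None:
        if self.n_labeled < 1:
            raise ValueError("unlabeled complexes are invisible and never emitted")
        if len(self.bleach_times) != self.n_labeled:
            raise ValueError("one bleach time per fluorophore required")
        if any(t <= 0 for t in self.bleach_times):
            raise ValueError("bleach times must be positive")


@dataclass(frozen=True)
class SimPullConfig:
    """Photobleaching-movie simulation parameters.

    20 Hz is the typical sCMOS frame rate for this kind of recording; the
    bleaching time constant and SNR are fixture choices with no single
    literature value.
    """

    n_spots: int
    model: StoichiometryModel
    bleach_tau_s: float = 10.0
    frame_rate_hz: float = 20.0
    movie_length_s: float = 60.0
    snr: float = 5.0
    unit_intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots <= 0:
            raise ValueError("n_spots must be positive")
        for name in ("bleach_tau_s", "frame_rate_hz", "movie_length_s", "snr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def gen_photobleach_cohort(
    config: SimPullConfig,
) -> tuple[list[IntensityTrace], list[SpotTruth]]:
    """Simulate a cohort of per-spot bleaching traces with ground truth.

    Complexes are monomers or dimers per the model fractions; each subunit is
    labeled independently with probability p; unlabeled complexes are
    discarded (invisible).  With probability b a visible spot additionally
    contains one extra labeled monomer (chance colocalization).  Intensity at
    time t is unit_intensity x (unbleached fluorophores) plus Gaussian read
    noise of s.d. unit_intensity / snr; bleach times are i.i.d. exponential.
    """
    m = config.model
    rng = np.random.default_rng(config.seed)
    t = np.arange(
        0.0, config.movie_length_s, 1.0 / config.frame_rate_hz
    )
    noise_sd = config.unit_intensity / config.snr

    traces: list[IntensityTrace] = []
    truths: list[SpotTruth] = []
    emitted = 0
    while emitted < config.n_spots:
        is_dimer = rng.random() < m.f_dimer
        n_subunits = 2 if is_dimer else 1
        n_labeled = int(rng.binomial(n_subunits, m.p))
        if n_labeled == 0:
            continue  # invisible, never emitted
        complex_type = "dimer" if is_dimer else "monomer"
        if rng.random() < m.b:
            # extra labeled monomer sharing the diffraction-limited spot
            n_labeled += 1
            complex_type = "colocalized_pair"
        bleach = tuple(
            float(x) for x in rng.exponential(config.bleach_tau_s, n_labeled)
        )
        spot_id = f"spot{emitted:06d}"
        truths.append(
            SpotTruth(spot_id, complex_type, n_labeled, bleach,
                      config.unit_intensity)
        )
        n_alive = (np.asarray(bleach)[:, None] > t[None, :]).sum(axis=0)
        y = config.unit_intensity * n_alive + rng.normal(0.0, noise_sd, t.size)
        traces.append(IntensityTrace(spot_id, t, y))
        emitted += 1
    return traces, truths


# ---------------------------------------------------------------------------
# live-cell two-channel FRET
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Epoch:
    label: str
    start_s: float
    end_s: float
    drug: str
    concentration_uM: float = 0.0

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"epoch {self.label}: end before start")


@dataclass(frozen=True)
class DrugKinetics:
    tau_on_s: float
    tau_off_s: float
    max_delta_fret: float


@dataclass(frozen=True)
class FretProtocol:
    """Drug-application protocol for a simulated two-channel recording."""

    epochs: tuple[Epoch, ...]
    kinetics: dict[str, DrugKinetics]
    baseline_fret: float = 0.30
    total_intensity: float = 1000.0
    noise_sd: float = 0.0
    sample_rate_hz: float = 1.0
    duration_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        eps = sorted(self.epochs, key=lambda e: e.start_s)
        for a, b in zip(eps, eps[1:]):
            if b.start_s < a.end_s:
                raise ValueError(f"epochs {a.label} and {b.label} overlap")
        object.__setattr__(self, "epochs", tuple(eps))
        if not 0.0 <= self.baseline_fret <= 1.0:
            raise ValueError("baseline_fret outside [0, 1]")
        for drug, k in self.kinetics.items():
            total = self.baseline_fret + k.max_delta_fret
            if not 0.0 <= total <= 1.0:
                raise ValueError(
                    f"{drug}: baseline + max_delta_fret = {total} outside [0, 1]"
                )


def _true_fret(protocol: FretProtocol, t: np.ndarray) -> np.ndarray:
    """Piecewise-exponential true FRET trajectory, computed sequentially."""
    events: list[tuple[float, float, float]] = []  # (time, new target, tau)
    for ep in protocol.epochs:
        kin = protocol.kinetics[ep.drug]
        events.append((ep.start_s, protocol.baseline_fret + kin.max_delta_fret,
                       kin.tau_on_s))
        events.append((ep.end_s, protocol.baseline_fret, kin.tau_off_s))
    events.sort(key=lambda e: e[0])
    fret = np.empty(t.size)
    idx = 0
    target, tau = protocol.baseline_fret, None
    value = protocol.baseline_fret
    last_t = t[0]
    for i, ti in enumerate(t):
        while idx < len(events) and events[idx][0] <= ti:
            # relax to the moment of the event, then switch target
            ev_t, ev_target, ev_tau = events[idx]
            if tau is not None:
                value = target + (value - target) * math.exp(-(ev_t - last_t) / tau)
            last_t = ev_t
            target, tau = ev_target, ev_tau
            idx += 1
        if tau is None:
            fret[i] = value
        else:
            fret[i] = target + (value - target) * math.exp(-(ti - last_t) / tau)
    return fret


def gen_fret_series(protocol: FretProtocol) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a donor/acceptor recording and its ground-truth responses.

    True FRET relaxes exponentially toward baseline + max_delta_fret during a
    drug epoch (tau_on) and back to baseline afterwards (tau_off).  Acceptor
    intensity is total x FRET and donor is total x (1 - FRET), each plus
    independent Gaussian noise, so donor + acceptor is conserved in
    expectation.  The truth table records, per epoch, the asymptotic plateau
    delta-FRET, the achieved end-of-epoch delta, and the closed-form 10-90%
    on/off times tau ln 9.
    """
    dur = protocol.duration_s
    if dur is None:
        dur = max(e.end_s for e in protocol.epochs) + 30.0
    for ep in protocol.epochs:
        if ep.end_s > dur:
            raise ValueError(f"epoch {ep.label} extends beyond the series end")
    rng = np.random.default_rng(protocol.seed)
    t = np.arange(0.0, dur, 1.0 / protocol.sample_rate_hz)
    fret = _true_fret(protocol, t)
    acceptor = protocol.total_intensity * fret
    donor = protocol.total_intensity * (1.0 - fret)
    if protocol.noise_sd > 0:
        donor = donor + rng.normal(0.0, protocol.noise_sd, t.size)
        acceptor = acceptor + rng.normal(0.0, protocol.noise_sd, t.size)

    series = pd.DataFrame({"time_s": t, "donor": donor, "acceptor": acceptor})
    rows = []
    for ep in protocol.epochs:
        kin = protocol.kinetics[ep.drug]
        dur_ep = ep.end_s - ep.start_s
        achieved = kin.max_delta_fret * (1.0 - math.exp(-dur_ep / kin.tau_on_s))
        rows.append({
            "label": ep.label,
            "drug": ep.drug,
            "concentration_uM": ep.concentration_uM,
            "true_delta_fret": kin.max_delta_fret,
            "achieved_delta_fret": achieved,
            "t_10_90_on_s": kin.tau_on_s * math.log(9.0),
            "t_10_90_off_s": kin.tau_off_s * math.log(9.0),
        })
    return series, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dose-response tables
# ---------------------------------------------------------------------------

# Literature parameter sets (EC50 in uM; emax relative to saturating LY48
# where applicable) for regression-test use.
DOSE_RESPONSE_PRESETS: dict[str, dict[str, float]] = {
    "LY48-GIRK": {"ec50_uM": 0.23, "hill_n": 1.0, "emax": 1.0},
    "LY48-TMD": {"ec50_uM": 1.2, "hill_n": 1.0, "emax": 1.0},
    "TASP-TMD": {"ec50_uM": 0.9, "hill_n": 1.0, "emax": 1.3},
    "CBiPES-TMD": {"ec50_uM": 3.5, "hill_n": 1.0, "emax": 1.0},
    "BINA-TMD": {"ec50_uM": 3.1, "hill_n": 1.0, "emax": 0.8},
    "Ro64-TMD": {"ec50_uM": 2.1, "hill_n": 1.0, "emax": 1.0},
}


def hill_response(c: np.ndarray, ec50_uM: float, hill_n: float,
                  emax: float) -> np.ndarray:
    """Hill equation r(c) = emax c^n / (c^n + EC50^n), r(0) = 0."""
    c = np.asarray(c, dtype=float)
    out = np.zeros_like(c)
    pos = c > 0
    cn = np.power(c[pos], hill_n)
    out[pos] = emax * cn / (cn + ec50_uM ** hill_n)
    return out


def gen_dose_response(
    ec50_uM: float | None = None,
    hill_n: float = 1.0,
    emax: float = 1.0,
    concentrations_uM: list[float] | np.ndarray | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    preset: str | None = None,
) -> pd.DataFrame:
    """Hill-model dose-response table with per-replicate Gaussian noise."""
    if preset is not None:
        params = DOSE_RESPONSE_PRESETS[preset]
        ec50_uM, hill_n, emax = (params["ec50_uM"], params["hill_n"],
                                 params["emax"])
    if ec50_uM is None or ec50_uM <= 0:
        raise ValueError("ec50_uM must be positive")
    if concentrations_uM is None or len(concentrations_uM) == 0:
        raise ValueError("empty concentration list")
    c = np.asarray(concentrations_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    mean = hill_response(c, ec50_uM, hill_n, emax)
    rows = []
    for rep in range(n_replicates):
        r = mean + (rng.normal(0.0, noise_sd, c.size) if noise_sd > 0 else 0.0)
        rows.append(pd.DataFrame({
            "concentration_uM": c, "response": r, "replicate": rep,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# whole-cell current traces
# ---------------------------------------------------------------------------

def gen_current_trace(
    tau_on_s: float,
    tau_off_s: float,
    plateau: float,
    epochs: list[tuple[float, float]],
    sample_rate_hz: float = 100.0,
    duration_s: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    trace_id: str = "current",
) -> IntensityTrace:
    """Single-exponential drug-response current: rise toward ``plateau``
    during each (start_s, end_s) epoch, decay back to zero afterwards."""
    if tau_on_s <= 0 or tau_off_s <= 0:
        raise ValueError("time constants must be positive")
    if duration_s is None:
        duration_s = max(e for _, e in epochs) + 8.0 * tau_off_s
    t = np.arange(0.0, duration_s, 1.0 / sample_rate_hz)
    y = np.zeros(t.size)
    value = 0.0
    events: list[tuple[float, float, float]] = []
    for start, end in epochs:
        events.append((start, plateau, tau_on_s))
        events.append((end, 0.0, tau_off_s))
    events.sort(key=lambda e: e[0])
    idx, target, tau, last_t = 0, 0.0, None, t[0]
    for i, ti in enumerate(t):
        while idx < len(events) and events[idx][0] <= ti:
            ev_t, ev_target, ev_tau = events[idx]
            if tau is not None:
                value = target + (value - target) * math.exp(-(ev_t - last_t) / tau)
            last_t, target, tau = ev_t, ev_target, ev_tau
            idx += 1
        y[i] = value if tau is None else (
            target + (value - target) * math.exp(-(ti - last_t) / tau)
        )
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return IntensityTrace(trace_id, t, y)


# ---------------------------------------------------------------------------
# stopped-flow quench trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuenchSimConfig:
    """Stretched-exponential quench simulation parameters.

    Defaults of nine quencher and four control trials per experiment follow
    standard stopped-flow practice for this assay.
    """

    tau0_ms: float
    beta: float
    F0: float = 10.0
    Finf: float = 2.0
    compound_offset: float = 0.0
    n_quench_trials: int = 9
    n_control_trials: int = 4
    dt_ms: float = 0.1
    t_max_ms: float = 150.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"beta={self.beta} outside (0, 1]")
        if self.tau0_ms <= 0:
            raise ValueError("tau0_ms must be positive")
        if not self.F0 > self.Finf >= 0:
            raise ValueError("need F0 > Finf >= 0")


@dataclass(frozen=True)
class QuenchExperiment:
    """Simulated stopped-flow experiment: trial table plus ground truth."""

    trials: pd.DataFrame  # time_ms, fluorescence, trial_id, quencher
    compound_reference: pd.DataFrame  # time_ms, fluorescence (compound only)
    config: QuenchSimConfig


def stretched_exp(t_ms: np.ndarray, F0: float, Finf: float, tau0_ms: float,
                  beta: float) -> np.ndarray:
    """F(t) = Finf + (F0 - Finf) exp{-(t/tau0)^beta}."""
    t_ms = np.asarray(t_ms, dtype=float)
    return Finf + (F0 - Finf) * np.exp(-np.power(t_ms / tau0_ms, beta))


def gen_quench_trials(config: QuenchSimConfig) -> QuenchExperiment:
    """Simulate quencher and control stopped-flow trials.

    Quencher trials follow the stretched exponential plus the compound's own
    (constant) fluorescence and noise; control trials are flat at
    F0 + compound_offset plus noise.  A noiseless compound-only reference
    trace is included for the additive-offset correction.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.dt_ms, config.t_max_ms + config.dt_ms / 2, config.dt_ms)
    frames = []
    decay = stretched_exp(t, config.F0, config.Finf, config.tau0_ms, config.beta)
    for i in range(config.n_quench_trials):
        y = decay + config.compound_offset
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, t.size)
        frames.append(pd.DataFrame({
            "time_ms": t, "fluorescence": y,
            "trial_id": f"q{i:02d}", "quencher": True,
        }))
    for i in range(config.n_control_trials):
        y = np.full(t.size, config.F0 + config.compound_offset)
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, t.size)
        frames.append(pd.DataFrame({
            "time_ms": t, "fluorescence": y,
            "trial_id": f"c{i:02d}", "quencher": False,
        }))
    reference = pd.DataFrame({
        "time_ms": t,
        "fluorescence": np.full(t.size, config.compound_offset),
    })
    return QuenchExperiment(pd.concat(frames, ignore_index=True), reference,
                            config)
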