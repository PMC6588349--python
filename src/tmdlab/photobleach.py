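"""Photobleaching step detection and per-movie step-count summaries.

Single fluorophores bleach in discrete, irreversible intensity drops, so the
number of downward steps in a spot's intensity trace counts the fluorophores
(and hence labeled subunits) it contains.  Traces are segmented into
piecewise-constant levels by greedy binary change-point splitting; the number
of steps is chosen with a BIC-like penalty and, in photobleaching mode, levels
are constrained to decrease toward zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntensityTrace",
    "StepFit",
    "MovieSummary",
    "estimate_noise",
    "detect_steps",
    "classify_spot",
    "summarize_movie",
    "aggregate_condition",
]

_MIN_SAMPLES = 10


@dataclass(frozen=True)
class IntensityTrace:
    """A uniformly sampled single-channel fluorescence time series."""

    trace_id: str
    time_s: np.ndarray
    intensity: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "intensity", y)
        if t.size < _MIN_SAMPLES:
            raise ValueError(
                f"trace {self.trace_id}: {t.size} samples < {_MIN_SAMPLES}"
            )
        if t.size != y.size:
            raise ValueError(f"trace {self.trace_id}: time/intensity length mismatch")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"trace {self.trace_id}: time not strictly increasing")
        if np.ptp(dt) > 1e-3 * np.median(dt):
            raise ValueError(f"trace {self.trace_id}: sampling not uniform")
        if not np.all(np.isfinite(y)):
            raise ValueError(f"trace {self.trace_id}: non-finite intensity")

    @property
    def dt_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])


@dataclass(frozen=True)
class StepFit:
    """Piecewise-constant fit of a bleaching trace."""

    trace_id: str
    n_steps: int
    step_times_s: list[float]
    levels: list[float]
    sse: float
    noise_sd_hat: float

    def __post_init__(self) -> None:
        if len(self.levels) != self.n_steps + 1:
            raise ValueError("need n_steps + 1 levels")
        if any(b <= a for a, b in zip(self.step_times_s, self.step_times_s[1:])):
            raise ValueError("step times must be strictly increasing")


def estimate_noise(trace: IntensityTrace) -> float:
    """Robust noise s.d. from the median absolute deviation of first
    differences, scaled by 1/(sqrt(2) * 0.6745).

    Bleaching steps are sparse outliers among the differences and are ignored
    by the MAD; a constant trace returns 0.
    """
    d = np.diff(trace.intensity)
    mad = float(np.median(np.abs(d - np.median(d))))
    return mad / (math.sqrt(2.0) * 0.6745)


def _segment_cost(pre_y: np.ndarray, pre_y2: np.ndarray, i: int, j: int) -> float:
    """SSE of fitting samples [i, j) with their mean, from prefix sums."""
    n = j - i
    s = pre_y[j] - pre_y[i]
    s2 = pre_y2[j] - pre_y2[i]
    return s2 - s * s / n


def _best_split(
    pre_y: np.ndarray,
    pre_y2: np.ndarray,
    i: int,
    j: int,
    max_up: float | None,
) -> tuple[int, float] | None:
    """Best single change point in [i, j): (index, SSE gain), or None.

    ``max_up`` rejects candidate splits whose right mean exceeds the left
    mean by more than the threshold (photobleaching is monotone decreasing).
    """
    n = j - i
    if n < 2:
        return None
    k = np.arange(i + 1, j)
    nl = k - i
    nr = j - k
    sl = pre_y[k] - pre_y[i]
    sr = pre_y[j] - pre_y[k]
    cost = (pre_y2[k] - pre_y2[i] - sl * sl / nl) + (
        pre_y2[j] - pre_y2[k] - sr * sr / nr
    )
    if max_up is not None:
        up = sr / nr - sl / nl
        cost = np.where(up > max_up, np.inf, cost)
    best = int(np.argmin(cost))
    if not np.isfinite(cost[best]):
        return None
    gain = _segment_cost(pre_y, pre_y2, i, j) - cost[best]
    return k[best], gain


def detect_steps(
    trace: IntensityTrace,
    max_steps: int = 6,
    penalty_scale: float = 2.0,
    monotone: bool = True,
) -> StepFit:
    """Detect bleaching steps by penalized greedy binary splitting.

    The trace is split recursively at the change point giving the largest SSE
    reduction; the number of change points k is then chosen to minimize

        SSE(k) + penalty_scale * k * noise_sd_hat**2 * ln N.

    In photobleaching mode (``monotone``) candidate splits that create an
    up-step larger than 2 * noise_sd_hat are rejected.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    y = trace.intensity
    n = y.size
    noise = estimate_noise(trace)
    pre_y = np.concatenate(([0.0], np.cumsum(y)))
    pre_y2 = np.concatenate(([0.0], np.cumsum(y * y)))
    max_up = 2.0 * noise if monotone else None

    def total_sse(cps: list[int]) -> float:
        bounds = [0] + cps + [n]
        return sum(_segment_cost(pre_y, pre_y2, i, j)
                   for i, j in zip(bounds, bounds[1:]))

    def refine(cps: list[int]) -> list[int]:
        # re-optimize each change point between its neighbors; greedy splits
        # can land a frame off a true transition, which would otherwise force
        # a spurious extra step later
        cps = sorted(cps)
        for _ in range(5):
            moved = False
            for i in range(len(cps)):
                lo = cps[i - 1] if i > 0 else 0
                hi = cps[i + 1] if i + 1 < len(cps) else n
                found = _best_split(pre_y, pre_y2, lo, hi, max_up)
                if found is not None and found[0] != cps[i]:
                    cps[i] = found[0]
                    moved = True
            if not moved:
                break
        return cps

    # greedy split sequence with per-stage refinement; one candidate model
    # (change-point set, SSE) per model order k
    models: list[tuple[list[int], float]] = [([], total_sse([]))]
    cps: list[int] = []
    for _ in range(max_steps):
        bounds = [0] + cps + [n]
        candidates = []
        for i, j in zip(bounds, bounds[1:]):
            found = _best_split(pre_y, pre_y2, i, j, max_up)
            if found is not None:
                candidates.append(found)
        if not candidates:
            break
        k_idx, _gain = max(candidates, key=lambda c: c[1])
        cps = refine(cps + [k_idx])
        models.append((list(cps), total_sse(cps)))

    penalty = penalty_scale * noise * noise * math.log(n)
    scores = [sse + penalty * k for k, (_, sse) in enumerate(models)]
    # prefer the smallest model order within float tolerance of the optimum
    tol = 1e-9 * max(models[0][1], 1.0)
    best = min(scores)
    best_k = next(k for k, s in enumerate(scores) if s <= best + tol)

    cps = models[best_k][0]
    bounds = [0] + cps + [n]
    levels = [float(np.mean(y[i:j])) for i, j in zip(bounds, bounds[1:])]
    sse = float(sum(_segment_cost(pre_y, pre_y2, i, j)
                    for i, j in zip(bounds, bounds[1:])))
    # change point k marks the first sample of the new level
    step_times = [float(trace.time_s[k]) for k in cps]
    return StepFit(
        trace_id=trace.trace_id,
        n_steps=best_k,
        step_times_s=step_times,
        levels=levels,
        sse=sse,
        noise_sd_hat=noise,
    )


def classify_spot(fit: StepFit) -> str:
    """Assign a spot to {1, 2, 3plus, rejected} from its step fit.

    Rejected when no step was found, when the molecule did not bleach to
    baseline (final level beyond 3 noise s.d. of zero), or when any fitted
    step is smaller than 3 noise s.d. (not a credible fluorophore loss).
    """
    if fit.n_steps == 0:
        return "rejected"
    tol = 3.0 * fit.noise_sd_hat
    if abs(fit.levels[-1]) > tol:
        return "rejected"
    heights = [a - b for a, b in zip(fit.levels, fit.levels[1:])]
    if any(h < tol for h in heights):
        return "rejected"
    if fit.n_steps == 1:
        return "1"
    if fit.n_steps == 2:
        return "2"
    return "3plus"


@dataclass(frozen=True)
class MovieSummary:
    """Step-category counts and two-step percentage for one movie."""

    movie_id: str
    counts: dict[str, int]
    pct_two_step: float = field(init=False)
    n_accepted: int = field(init=False)

    def __post_init__(self) -> None:
        accepted = sum(self.counts.get(k, 0) for k in ("1", "2", "3plus"))
        if accepted < 1:
            raise ValueError(f"movie {self.movie_id}: zero accepted spots")
        object.__setattr__(self, "n_accepted", accepted)
        object.__setattr__(
            self, "pct_two_step", 100.0 * self.counts.get("2", 0) / accepted
        )


def summarize_movie(categories: list[str], movie_id: str) -> MovieSummary:
    """Tally spot categories for one movie.

    Percentages are computed among accepted spots (1, 2, 3plus); rejected
    spots are counted but excluded from the denominator.
    """
    counts = {k: 0 for k in ("1", "2", "3plus", "rejected")}
    for c in categories:
        if c not in counts:
            raise ValueError(f"unknown category {c!r}")
        counts[c] += 1
    return MovieSummary(movie_id=movie_id, counts=counts)


def aggregate_condition(
    movies: list[MovieSummary],
) -> tuple[float, float, int, dict[str, int]]:
    """Mean and s.e.m. of pct_two_step across movies, with pooled counts.

    The movie is the statistical unit.  Returns (mean, sem, n_movies,
    pooled_counts); with a single movie the s.e.m. is NaN (undefined).
    """
    if not movies:
        raise ValueError("no movies to aggregate")
    pct = np.array([m.pct_two_step for m in movies])
    pooled = {k: 0 for k in ("1", "2", "3plus", "rejected")}
    for m in movies:
        for k in pooled:
            pooled[k] += m.counts.get(k, 0)
    mean = float(pct.mean())
    sem = float(pct.std(ddof=1) / math.sqrt(pct.size)) if pct.size > 1 else float("nan")
    return mean, sem, len(movies), pooled
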