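"""Step detection: noise estimation, change points, classification, summaries."""

import itertools
import math

import numpy as np
import pytest

from tmdlab.photobleach import (IntensityTrace, MovieSummary, StepFit,
                                aggregate_condition, classify_spot,
                                detect_steps, estimate_noise, summarize_movie)
from tmdlab.stoichiometry import StoichiometryModel
from tmdlab.simulate import SimPullConfig, gen_photobleach_cohort

from conftest import make_staircase


class TestEstimateNoise:
    def test_constant_trace_gives_zero(self):
        tr = make_staircase([5.0], [100])
        assert estimate_noise(tr) == 0.0

    def test_gaussian_noise_recovered_within_two_percent(self):
        rng = np.random.default_rng(42)
        tr = IntensityTrace("g", np.arange(100_000) * 0.05,
                            rng.normal(0.0, 1.0, 100_000))
        assert estimate_noise(tr) == pytest.approx(1.0, rel=0.02)

    def test_steps_are_ignored_as_sparse_outliers(self):
        tr = make_staircase([2.0, 1.0, 0.0], [1000, 1000, 1000])
        assert estimate_noise(tr) == pytest.approx(0.0, abs=1e-12)


def _exhaustive_oracle(y, max_k=3):
    """Minimal-SSE segmentation by enumerating all change-point sets.

    Returns (k, change_points) for the smallest k achieving the global
    minimum SSE (noiseless identifiability: SSE 0 at the true k).
    """
    n = y.size
    pre = np.concatenate(([0.0], np.cumsum(y)))
    pre2 = np.concatenate(([0.0], np.cumsum(y * y)))

    def sse(bounds):
        return sum((pre2[j] - pre2[i]) - (pre[j] - pre[i]) ** 2 / (j - i)
                   for i, j in zip(bounds, bounds[1:]))

    best = (0, (), sse([0, n]))
    for k in range(1, max_k + 1):
        for cps in itertools.combinations(range(1, n), k):
            s = sse([0, *cps, n])
            if s < best[2] - 1e-9:
                best = (k, cps, s)
    return best[0], list(best[1])


class TestDetectSteps:
    def test_noiseless_staircase_exact(self):
        tr = make_staircase([2.0, 1.0, 0.0], [60, 80, 60], dt=0.05)
        fit = detect_steps(tr)
        assert fit.n_steps == 2
        assert fit.step_times_s == pytest.approx([60 * 0.05, 140 * 0.05])
        assert fit.levels == pytest.approx([2.0, 1.0, 0.0])

    def test_constant_zero_trace_has_no_steps(self):
        fit = detect_steps(make_staircase([0.0], [200]))
        assert fit.n_steps == 0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            IntensityTrace("short", np.arange(5) * 0.1, np.zeros(5))

    def test_matches_exhaustive_oracle_on_noiseless_traces(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            k_true = rng.integers(0, 4)
            n_seg = k_true + 1
            # decreasing integer levels ending at 0, segments >= 5 samples
            levels = np.sort(rng.choice(np.arange(0, 8), n_seg,
                                        replace=False))[::-1]
            levels = levels - levels[-1]
            lengths = rng.integers(10, 20, n_seg)
            tr = make_staircase(levels.astype(float), lengths)
            k_o, cps_o = _exhaustive_oracle(tr.intensity, max_k=3)
            fit = detect_steps(tr, max_steps=3)
            assert fit.n_steps == k_o
            assert [int(round(t / tr.dt_s)) for t in fit.step_times_s] == cps_o

    def test_affine_rescaling_leaves_step_count_unchanged(self):
        rng = np.random.default_rng(8)
        tr = make_staircase([2.0, 1.0, 0.0], [100, 100, 100], noise_sd=0.2,
                            rng=rng)
        base = detect_steps(tr).n_steps
        for gain, offset in [(3.7, 10.0), (0.25, -4.0)]:
            scaled = IntensityTrace("s", tr.time_s,
                                    gain * tr.intensity + offset)
            assert detect_steps(scaled).n_steps == base

    def test_true_step_count_recovered_on_separated_cohort(self):
        # snr 5, steps separated by >= 20 frames: >= 95% exact recovery
        rng = np.random.default_rng(11)
        n_correct = 0
        n_spots = 1000
        dt, n = 0.05, 600
        for i in range(n_spots):
            k = rng.integers(1, 3)
            cuts = np.sort(rng.choice(np.arange(40, n - 40, 20), k,
                                      replace=False))
            lengths = np.diff([0, *cuts, n])
            levels = np.arange(k, -1, -1, dtype=float)
            tr = make_staircase(levels, lengths, dt=dt, noise_sd=0.2, rng=rng,
                                trace_id=f"s{i}")
            if detect_steps(tr).n_steps == k:
                n_correct += 1
        assert n_correct / n_spots >= 0.95


class TestClassify:
    def _fit(self, n_steps, levels, noise=0.1):
        times = [float(i + 1) for i in range(n_steps)]
        return StepFit("x", n_steps, times, levels, 0.0, noise)

    def test_categories_by_step_count(self):
        assert classify_spot(self._fit(1, [1.0, 0.0])) == "1"
        assert classify_spot(self._fit(2, [2.0, 1.0, 0.0])) == "2"
        assert classify_spot(self._fit(5, [5.0, 4.0, 3.0, 2.0, 1.0, 0.0])) == "3plus"

    def test_zero_steps_rejected(self):
        assert classify_spot(self._fit(0, [1.0])) == "rejected"

    def test_incomplete_bleach_rejected(self):
        # final level far from zero: molecule still fluorescing
        assert classify_spot(self._fit(1, [2.0, 1.0])) == "rejected"

    def test_sub_noise_step_rejected(self):
        assert classify_spot(self._fit(2, [1.0, 0.85, 0.0], noise=0.1)) == "rejected"


class TestSummaries:
    def test_two_step_percentage(self):
        cats = ["1"] * 40 + ["2"] * 60
        assert summarize_movie(cats, "m").pct_two_step == 60.0
        cats = ["1"] * 55 + ["2"] * 45
        assert summarize_movie(cats, "m").pct_two_step == 45.0

    def test_rejected_excluded_from_denominator(self):
        cats = ["1"] * 50 + ["2"] * 50 + ["rejected"] * 100
        s = summarize_movie(cats, "m")
        assert s.pct_two_step == 50.0
        assert s.n_accepted == 100

    def test_all_one_step_gives_zero_percent(self):
        assert summarize_movie(["1"] * 100, "m").pct_two_step == 0.0

    def test_no_accepted_spots_names_movie(self):
        with pytest.raises(ValueError, match="badmovie"):
            summarize_movie(["rejected"] * 5, "badmovie")

    def test_percentage_invariant_to_spot_order(self):
        rng = np.random.default_rng(0)
        cats = ["1"] * 30 + ["2"] * 50 + ["3plus"] * 10 + ["rejected"] * 10
        shuffled = list(cats)
        rng.shuffle(shuffled)
        assert (summarize_movie(cats, "m").pct_two_step
                == summarize_movie(shuffled, "m").pct_two_step)


class TestAggregate:
    def _movie(self, n2, n1, mid):
        return summarize_movie(["2"] * n2 + ["1"] * n1, mid)

    def test_identical_movies_sem_zero(self):
        movies = [self._movie(45, 55, f"m{i}") for i in range(4)]
        mean, sem, n, _pooled = aggregate_condition(movies)
        assert mean == 45.0 and sem == 0.0 and n == 4

    def test_two_movie_sem_hand_computed(self):
        movies = [self._movie(40, 60, "a"), self._movie(50, 50, "b")]
        mean, sem, _, pooled = aggregate_condition(movies)
        assert mean == pytest.approx(45.0)
        assert sem == pytest.approx(5.0)
        assert pooled["2"] == 90

    def test_single_movie_sem_undefined(self):
        mean, sem, n, _ = aggregate_condition([self._movie(45, 55, "a")])
        assert mean == 45.0 and math.isnan(sem) and n == 1

    def test_simulated_movies_recover_forward_two_step_percent(self):
        # 20 movies at f = 0.6, p = 0.8: mean within 2 pp of the ~45%
        # two-step level the binomial model predicts for this mixture
        from tmdlab.pipeline import count_steps_table
        model = StoichiometryModel(p=0.8, b=0.0, f_dimer=0.634)
        movies = []
        for i in range(20):
            traces, _ = gen_photobleach_cohort(
                SimPullConfig(n_spots=120, model=model, seed=100 + i))
            table = count_steps_table(traces)
            movies.append(summarize_movie(list(table["category"]), f"m{i}"))
        mean, _, _, _ = aggregate_condition(movies)
        assert mean == pytest.approx(45.0, abs=2.0)
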