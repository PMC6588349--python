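"""Generator ground-truth and reproducibility properties."""

import numpy as np
import pytest
from scipy import stats

from tmdlab.photobleach import IntensityTrace
from tmdlab.simulate import (DrugKinetics, Epoch, FretProtocol, QuenchSimConfig,
                             SimPullConfig, gen_current_trace, gen_dose_response,
                             gen_fret_series, gen_photobleach_cohort,
                             gen_quench_trials, hill_response, stretched_exp)
from tmdlab.stoichiometry import CATEGORIES, StoichiometryModel, forward_distribution

# short movies: category statistics do not depend on the bleaching dynamics
FAST = dict(movie_length_s=0.5, frame_rate_hz=20.0)


def _truth_category(t):
    return {1: "1", 2: "2"}.get(t.n_labeled, "3plus")


class TestPhotobleachCohort:
    def test_fully_labeled_pure_dimer_has_two_fluorophores(self):
        model = StoichiometryModel(p=1.0, b=0.0, f_dimer=1.0)
        _, truth = gen_photobleach_cohort(
            SimPullConfig(n_spots=200, model=model, seed=0, **FAST))
        assert all(t.n_labeled == 2 for t in truth)

    def test_binomial_two_label_fraction_conditional_on_visibility(self):
        # P(2 labels | visible) = p^2 / (2p - p^2) = 2/3 at p = 0.8
        model = StoichiometryModel(p=0.8, b=0.0, f_dimer=1.0)
        _, truth = gen_photobleach_cohort(
            SimPullConfig(n_spots=50_000, model=model, seed=7, **FAST))
        frac2 = np.mean([t.n_labeled == 2 for t in truth])
        assert frac2 == pytest.approx(2.0 / 3.0, abs=0.01)

    def test_category_frequencies_match_forward_model(self):
        # chi-square goodness of fit against the analytic distribution
        model = StoichiometryModel(p=0.8, b=0.075, f_dimer=0.6)
        _, truth = gen_photobleach_cohort(
            SimPullConfig(n_spots=50_000, model=model, seed=5, **FAST))
        cats = [_truth_category(t) for t in truth]
        observed = np.array([cats.count(c) for c in CATEGORIES])
        expected = len(cats) * np.array(
            [forward_distribution(model)[c] for c in CATEGORIES])
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01

    def test_same_seed_bit_identical_different_seed_not(self):
        model = StoichiometryModel(p=0.8, b=0.05, f_dimer=0.6)
        cfg = SimPullConfig(n_spots=50, model=model, seed=3)
        a, _ = gen_photobleach_cohort(cfg)
        b, _ = gen_photobleach_cohort(cfg)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.intensity, tb.intensity)
        c, _ = gen_photobleach_cohort(
            SimPullConfig(n_spots=50, model=model, seed=4))
        assert not np.array_equal(a[0].intensity, c[0].intensity)

    def test_unlabeled_complexes_never_emitted(self):
        model = StoichiometryModel(p=0.3, b=0.0, f_dimer=0.5)
        _, truth = gen_photobleach_cohort(
            SimPullConfig(n_spots=500, model=model, seed=1, **FAST))
        assert all(t.n_labeled >= 1 for t in truth)
        assert all(len(t.bleach_times) == t.n_labeled for t in truth)

    def test_invalid_model_rejected_with_named_invariant(self):
        with pytest.raises(ValueError, match="f_dimer"):
            StoichiometryModel(p=0.8, b=0.0, f_dimer=1.5)
        with pytest.raises(ValueError, match="n_spots"):
            SimPullConfig(n_spots=0,
                          model=StoichiometryModel(p=0.8, b=0, f_dimer=1))


class TestFretSeries:
    PROTO = dict(
        kinetics={"LY48": DrugKinetics(tau_on_s=5.0, tau_off_s=5.0,
                                       max_delta_fret=0.10)},
        baseline_fret=0.30, sample_rate_hz=2.0,
    )

    def test_noiseless_plateau_exact(self):
        # long epoch relative to tau: plateau = baseline + delta
        prot = FretProtocol(epochs=(Epoch("a", 50.0, 200.0, "LY48", 10.0),),
                            noise_sd=0.0, duration_s=240.0, **self.PROTO)
        series, truth = gen_fret_series(prot)
        fret = series.acceptor / (series.donor + series.acceptor)
        late = series.time_s.between(190, 200)
        assert fret[late].to_numpy() == pytest.approx(0.40, abs=1e-9)
        assert truth.loc[0, "true_delta_fret"] == 0.10

    def test_noiseless_conserves_total_intensity(self):
        prot = FretProtocol(epochs=(Epoch("a", 20.0, 80.0, "LY48", 1.0),),
                            noise_sd=0.0, duration_s=120.0, **self.PROTO)
        series, _ = gen_fret_series(prot)
        total = (series.donor + series.acceptor).to_numpy()
        np.testing.assert_allclose(total, 1000.0, rtol=1e-12)

    def test_ground_truth_rise_time_closed_form(self):
        kin = {"LY48": DrugKinetics(6.51, 6.51, 0.10)}
        prot = FretProtocol(epochs=(Epoch("a", 50.0, 200.0, "LY48", 10.0),),
                            kinetics=kin, baseline_fret=0.3, noise_sd=0.0,
                            sample_rate_hz=2.0, duration_s=240.0)
        _, truth = gen_fret_series(prot)
        assert truth.loc[0, "t_10_90_on_s"] == pytest.approx(14.3, abs=0.005)

    def test_epoch_beyond_series_end_rejected(self):
        prot = FretProtocol(epochs=(Epoch("a", 50.0, 300.0, "LY48", 1.0),),
                            noise_sd=0.0, duration_s=100.0, **self.PROTO)
        with pytest.raises(ValueError, match="beyond"):
            gen_fret_series(prot)


class TestDoseResponse:
    def test_half_max_at_ec50_and_zero_at_zero(self):
        table = gen_dose_response(ec50_uM=2.0, hill_n=1.0, emax=0.8,
                                  concentrations_uM=[0.0, 2.0], noise_sd=0.0,
                                  n_replicates=1)
        assert table.response.iloc[0] == 0.0
        assert table.response.iloc[1] == pytest.approx(0.4)

    def test_preset_half_max_at_literature_ec50(self):
        table = gen_dose_response(preset="LY48-TMD",
                                  concentrations_uM=[1.2], noise_sd=0.0,
                                  n_replicates=1)
        assert table.response.iloc[0] == pytest.approx(0.5)

    def test_empty_concentrations_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gen_dose_response(ec50_uM=1.0, concentrations_uM=[])


class TestCurrentTrace:
    @pytest.mark.parametrize("tau,expected", [(6.51, 14.3), (0.865, 1.90)])
    def test_rise_time_is_tau_ln9(self, tau, expected):
        from tmdlab.pharm import time_10_90
        trace = gen_current_trace(tau, tau, 1.0, [(10.0, 10.0 + 20 * tau)],
                                  sample_rate_hz=max(100.0, 50 / tau),
                                  noise_sd=0.0)
        res = time_10_90(trace, 10.0, "on", epoch_end_s=10.0 + 20 * tau)
        assert res.t_10_90_s == pytest.approx(expected, abs=0.01)

    def test_zero_plateau_gives_flat_trace(self):
        trace = gen_current_trace(1.0, 1.0, 0.0, [(1.0, 5.0)], noise_sd=0.0)
        assert np.all(trace.intensity == 0.0)


class TestQuenchTrials:
    def test_beta_one_is_single_exponential(self):
        cfg = QuenchSimConfig(tau0_ms=5.0, beta=1.0, noise_sd=0.0)
        exp = gen_quench_trials(cfg)
        trial = exp.trials[exp.trials.trial_id == "q00"]
        t = trial.time_ms.to_numpy()
        expected = 2.0 + 8.0 * np.exp(-t / 5.0)
        np.testing.assert_allclose(trial.fluorescence.to_numpy(), expected,
                                   rtol=1e-12)

    def test_long_time_limit_is_finf_plus_offset(self):
        cfg = QuenchSimConfig(tau0_ms=2.0, beta=0.9, compound_offset=3.0,
                              noise_sd=0.0, t_max_ms=200.0)
        exp = gen_quench_trials(cfg)
        last = exp.trials[exp.trials.quencher].groupby("trial_id").last()
        assert last.fluorescence.to_numpy() == pytest.approx(2.0 + 3.0,
                                                             abs=1e-6)

    def test_trial_counts_default_nine_and_four(self):
        exp = gen_quench_trials(QuenchSimConfig(tau0_ms=5.0, beta=0.8))
        assert exp.trials[exp.trials.quencher].trial_id.nunique() == 9
        assert exp.trials[~exp.trials.quencher].trial_id.nunique() == 4

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            QuenchSimConfig(tau0_ms=5.0, beta=1.5)
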