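"""Chi-square fitting: per-residue, global multi-field, and cluster."""

import numpy as np
import pytest

from relaxdisp import (
    ClusterSpec,
    DispersionProfile,
    FieldContext,
    ModelParams,
    SimulationSpec,
    chi2,
    fit_cluster,
    fit_global,
    fit_residue,
    simulate_cluster,
    simulate_multifield,
    simulate_profile,
)
from relaxdisp.fitting import _residuals, _starts


def _noiseless(params, seed=0, **kw):
    return simulate_profile(SimulationSpec(params=params, seed=seed, **kw))


class TestChi2:
    def test_perfect_fit_is_zero(self, slow_params):
        prof = _noiseless(slow_params)
        assert chi2(prof, slow_params) == pytest.approx(0.0, abs=1e-18)

    def test_single_point_residual_equals_sigma(self):
        prof = DispersionProfile(
            residue=1,
            field=FieldContext(600.0),
            nu_cpmg=np.array([100.0]),
            r2eff=np.array([10.0 + 0.5]),
            sigma=0.5,
        )
        assert chi2(prof, ModelParams(1, r20=10.0)) == pytest.approx(1.0)

    def test_sum_of_squared_normalized_residuals(self):
        sigma = 0.25
        prof = DispersionProfile(
            residue=1,
            field=FieldContext(600.0),
            nu_cpmg=np.array([50.0, 100.0, 200.0]),
            r2eff=10.0 + sigma * np.array([1.0, 2.0, 2.0]),
            sigma=sigma,
        )
        assert chi2(prof, ModelParams(1, r20=10.0)) == pytest.approx(9.0)


class TestFitResidue:
    def test_noiseless_fast_recovery(self, fast_params):
        fit = fit_residue(_noiseless(fast_params), 2)
        assert fit.converged
        assert fit.chi2 < 1e-8
        assert float(fit.params.r20) == pytest.approx(15.23, rel=1e-4)
        assert fit.params.kex == pytest.approx(3750.3, rel=1e-4)
        assert fit.params.phi == pytest.approx(47457.4, rel=1e-4)

    def test_noiseless_slow_recovery(self, slow_params):
        fit = fit_residue(_noiseless(slow_params), 3)
        assert fit.chi2 < 1e-8
        assert float(fit.params.r20) == pytest.approx(15.23, rel=1e-4)
        assert fit.params.kex == pytest.approx(306.2, rel=1e-4)
        assert fit.params.pb == pytest.approx(0.072, rel=1e-4)
        assert fit.params.dw == pytest.approx(1875.5, rel=1e-4)

    def test_flat_data_model1(self):
        prof = DispersionProfile(
            residue=1,
            field=FieldContext(600.0),
            nu_cpmg=np.linspace(25, 2000, 10),
            r2eff=np.full(10, 10.0),
            sigma=0.1,
        )
        fit = fit_residue(prof, 1)
        assert float(fit.params.r20) == pytest.approx(10.0, abs=1e-8)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-12)
        assert fit.k_params == 1

    def test_parameter_counts(self, fast_params, slow_params):
        prof = _noiseless(slow_params)
        assert fit_residue(prof, 1).k_params == 1
        assert fit_residue(prof, 2).k_params == 3
        assert fit_residue(prof, 3).k_params == 4

    def test_too_few_points_rejected(self, slow_params):
        prof = DispersionProfile(
            residue=1,
            field=FieldContext(600.0),
            nu_cpmg=np.array([50.0, 100.0, 500.0, 1000.0]),
            r2eff=np.array([20.0, 18.0, 16.0, 15.5]),
            sigma=0.1,
        )
        with pytest.raises(ValueError):
            fit_residue(prof, 3)

    def test_chi2_non_increasing_with_model_complexity(self, fast_params, slow_params):
        """More parameters never fit worse (within optimizer tolerance)."""
        for params, seed in ((fast_params, 11), (slow_params, 12)):
            prof = simulate_profile(
                SimulationSpec(params=params, seed=seed, noise_percent=5)
            )
            c = {m: fit_residue(prof, m).chi2 for m in (1, 2, 3)}
            assert c[2] <= c[1] + 1e-6
            assert c[3] <= c[2] + 1e-6

    def test_multistart_dominance(self, slow_params):
        """The returned optimum beats every grid start point."""
        prof = simulate_profile(
            SimulationSpec(params=slow_params, seed=5, noise_percent=5)
        )
        fit = fit_residue(prof, 3)
        for x0 in _starts(fit._series, 3):
            start_chi2 = float(np.sum(_residuals(x0, fit._series, 3) ** 2))
            assert fit.chi2 <= start_chi2 + 1e-9

    @pytest.mark.parametrize("trial", range(8))
    def test_random_parameter_recovery(self, trial):
        """Noiseless round trip over random valid parameter draws."""
        rng = np.random.default_rng(1000 + trial)
        kex = 10 ** rng.uniform(2.2, 3.6)
        pb = rng.uniform(0.02, 0.3)
        dw = 10 ** rng.uniform(2.8, 3.4)
        truth = ModelParams(3, r20=rng.uniform(8, 30), kex=kex, pb=pb, dw=dw)
        fit = fit_residue(_noiseless(truth, seed=trial), 3)
        assert fit.chi2 < 1e-6
        assert fit.params.kex == pytest.approx(truth.kex, rel=1e-3)
        assert fit.params.pb == pytest.approx(truth.pb, rel=1e-3)
        assert fit.params.dw == pytest.approx(truth.dw, rel=1e-3)
        assert float(fit.params.r20) == pytest.approx(float(truth.r20), rel=1e-3)


class TestFitGlobal:
    def test_two_field_slow_recovery(self, slow_params, two_fields):
        profs = simulate_multifield(
            SimulationSpec(params=slow_params, seed=1, fields=two_fields)
        )
        fit = fit_global(profs, 3)
        assert fit.chi2 < 1e-8
        assert fit.params.kex == pytest.approx(306.2, rel=1e-4)
        assert fit.params.pb == pytest.approx(0.072, rel=1e-4)
        assert fit.params.dw == pytest.approx(1875.5, rel=1e-4)  # at 800 MHz
        assert np.asarray(fit.params.r20) == pytest.approx([15.23, 15.23], rel=1e-4)
        assert fit.k_params == 5  # one extra r20 for the second field

    def test_two_field_fast_recovery(self, fast_params, two_fields):
        profs = simulate_multifield(
            SimulationSpec(params=fast_params, seed=1, fields=two_fields)
        )
        fit = fit_global(profs, 2)
        assert fit.params.kex == pytest.approx(3750.3, rel=1e-4)
        assert fit.params.phi == pytest.approx(47457.4, rel=1e-4)
        assert np.asarray(fit.params.r20) == pytest.approx([15.23, 15.23], rel=1e-4)

    def test_duplicated_field_matches_single_fit(self, slow_params):
        prof = _noiseless(slow_params)
        single = fit_residue(prof, 3)
        twin = DispersionProfile(
            residue=prof.residue,
            field=prof.field,
            nu_cpmg=prof.nu_cpmg.copy(),
            r2eff=prof.r2eff.copy(),
            sigma=prof.sigma,
        )
        joint = fit_global([prof, twin], 3)
        assert joint.params.kex == pytest.approx(single.params.kex, rel=1e-6)
        assert joint.chi2 == pytest.approx(0.0, abs=1e-8)

    def test_single_field_degenerates_to_fit_residue(self, slow_params):
        prof = _noiseless(slow_params)
        single = fit_residue(prof, 3)
        joint = fit_global([prof], 3)
        assert joint.k_params == single.k_params
        assert joint.params.kex == pytest.approx(single.params.kex, rel=1e-8)

    def test_temperature_mismatch_warns(self, slow_params):
        fields = (
            FieldContext(800.0, temperature_k=298.0),
            FieldContext(600.0, temperature_k=310.0),
        )
        profs = simulate_multifield(
            SimulationSpec(params=slow_params, seed=1, fields=fields)
        )
        with pytest.warns(UserWarning):
            fit_global(profs, 1)


class TestFitCluster:
    def test_noiseless_shared_recovery(self, cluster_params):
        profs = simulate_cluster(SimulationSpec(params=cluster_params, seed=2))
        results = fit_cluster(profs, ClusterSpec([1, 2, 3, 4]), 3)
        assert len(results) == 4
        kexs = {r.params.kex for r in results}
        pbs = {r.params.pb for r in results}
        assert len(kexs) == 1 and len(pbs) == 1  # shared across members
        assert results[0].params.kex == pytest.approx(306.15, rel=1e-4)
        assert results[0].params.pb == pytest.approx(0.072, rel=1e-4)
        for res, truth in zip(results, cluster_params):
            assert res.params.dw == pytest.approx(truth.dw, rel=1e-4)
            assert float(res.params.r20) == pytest.approx(float(truth.r20), rel=1e-4)
        assert sum(r.partial_chi2 for r in results) == pytest.approx(
            results[0].chi2, abs=1e-10
        )

    def test_cluster_of_one_matches_fit_residue(self, slow_params):
        prof = _noiseless(slow_params)
        (joint,) = fit_cluster([prof], ClusterSpec([1]), 3)
        single = fit_residue(prof, 3)
        assert joint.params.kex == pytest.approx(single.params.kex, rel=1e-8)
        assert joint.params.dw == pytest.approx(single.params.dw, rel=1e-8)

    def test_insufficient_residue_dropped(self, cluster_params):
        profs = simulate_cluster(SimulationSpec(params=cluster_params, seed=2))
        short = DispersionProfile(
            residue=9,
            field=FieldContext(800.0),
            nu_cpmg=np.array([50.0, 500.0, 1000.0]),
            r2eff=np.array([20.0, 16.0, 15.5]),
            sigma=0.1,
        )
        with pytest.warns(UserWarning):
            results = fit_cluster(
                profs + [short], ClusterSpec([1, 2, 3, 4, 9]), 3
            )
        assert [r.residue for r in results] == [1, 2, 3, 4]
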