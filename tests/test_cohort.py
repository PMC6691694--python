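import numpy as np
import pandas as pd
import pytest

from radnomics.cohort import (
    CohortParams,
    PhantomParams,
    SurvivalParams,
    generate_clinical,
    generate_cohort,
    generate_survival,
    generate_tumor_phantom,
)
from radnomics.survival import concordance_index


class TestPhantom:
    def test_same_seed_same_index_identical(self, small_params):
        p1, m1 = generate_tumor_phantom(small_params, 3, 0.4)
        p2, m2 = generate_tumor_phantom(small_params, 3, 0.4)
        np.testing.assert_array_equal(p1.cet1w, p2.cet1w)
        np.testing.assert_array_equal(p1.t2w, p2.t2w)
        np.testing.assert_array_equal(m1.voxels, m2.voxels)

    def test_different_seed_differs(self, small_params):
        import dataclasses

        p1, _ = generate_tumor_phantom(small_params, 3, 0.4)
        other = dataclasses.replace(small_params, rng_seed=small_params.rng_seed + 1)
        p2, _ = generate_tumor_phantom(other, 3, 0.4)
        assert not np.array_equal(p1.cet1w, p2.cet1w)

    def test_degenerate_field_constant_in_mask(self, small_params):
        import dataclasses

        params = dataclasses.replace(small_params, noise_sd=0.0)
        pair, mask = generate_tumor_phantom(params, 0, heterogeneity=0.0)
        for vol in (pair.cet1w, pair.t2w):
            assert np.ptp(vol[mask.voxels]) == 0.0
            assert vol[mask.voxels].var() == 0.0

    def test_heterogeneity_raises_in_mask_variance(self, small_params):
        import dataclasses

        params = dataclasses.replace(small_params, rng_seed=11)
        var = {}
        for h in (0.1, 0.9):
            vs = []
            for i in range(20):
                pair, mask = generate_tumor_phantom(params, i, h)
                vs.append(pair.cet1w[mask.voxels].var())
            var[h] = np.mean(vs)
        assert var[0.9] > var[0.1]

    def test_tumor_too_large_raises(self):
        params = PhantomParams(grid_shape=(16, 16, 16), voxel_spacing=(1, 1, 1),
                               tumor_radius_range=(20.0, 25.0))
        with pytest.raises(ValueError, match="does not fit"):
            generate_tumor_phantom(params, 0, 0.5)

    def test_mask_inside_grid(self, small_patient):
        _, mask = small_patient
        v = mask.voxels
        assert not v[0].any() and not v[-1].any()
        assert not v[:, 0].any() and not v[:, -1].any()
        assert not v[:, :, 0].any() and not v[:, :, -1].any()


class TestClinical:
    def test_contract_and_invariants(self):
        rng = np.random.default_rng(0)
        df = generate_clinical(140, rng)
        assert len(df) == 140
        assert df["age"].between(10, 90).all()
        assert set(df["gender"]) <= {0, 1}
        assert df["t_stage"].isin([1, 2, 3, 4]).all()
        assert df["n_stage"].isin([1, 2, 3, 4]).all()
        assert (df["hgb"] > 0).all() and (df["platelets"] > 0).all()

    def test_large_sample_marginals(self):
        rng = np.random.default_rng(1)
        df = generate_clinical(10_000, rng)
        assert abs(df["age"].mean() - 46) < 0.5
        assert (df["histology"] == 3).mean() >= 0.95
        assert abs(df["gender"].mean() - 103 / 140) < 0.02


class TestSurvival:
    @staticmethod
    def _clin(n, seed=0):
        return generate_clinical(n, np.random.default_rng(seed))

    def test_null_betas_give_chance_concordance(self):
        n = 3000
        clin = self._clin(n)
        het = np.random.default_rng(2).uniform(size=n)
        params = SurvivalParams(true_betas={"heterogeneity": 0.0})
        out, gt = generate_survival(clin, het, params, np.random.default_rng(3))
        # the *generating* heterogeneity should carry no signal
        c, _ = concordance_index(het, out["time"], out["event"])
        assert abs(c - 0.5) < 0.03

    def test_censored_times_respect_minimum_followup(self):
        clin = self._clin(140)
        het = np.random.default_rng(4).uniform(size=140)
        params = SurvivalParams()
        out, _ = generate_survival(clin, het, params, np.random.default_rng(5))
        censored = out[out["event"] == 0]
        assert (censored["time"] >= params.min_followup).all()
        assert (out["time"] > 0).all()

    def test_event_fraction_near_target(self):
        clin = self._clin(4000, seed=6)
        het = np.random.default_rng(6).uniform(size=4000)
        params = SurvivalParams()
        out, _ = generate_survival(clin, het, params, np.random.default_rng(7))
        assert abs(out["event"].mean() - params.target_event_fraction) < 0.04

    def test_unknown_beta_covariate_rejected(self):
        clin = self._clin(10)
        with pytest.raises(KeyError):
            generate_survival(clin, np.zeros(10),
                              SurvivalParams(true_betas={"nope": 1.0}),
                              np.random.default_rng(0))

    def test_concordance_monotone_in_effect_size(self):
        cs = []
        for beta in (0.5, 2.0, 4.0):
            clin = self._clin(2000, seed=8)
            het = np.random.default_rng(8).uniform(size=2000)
            params = SurvivalParams(true_betas={"heterogeneity": beta})
            out, gt = generate_survival(clin, het, params, np.random.default_rng(9))
            c, _ = concordance_index(np.array(gt["linear_predictor"]),
                                     out["time"], out["event"])
            cs.append(c)
        assert cs[0] < cs[1] < cs[2]


class TestCohort:
    def test_identical_seed_bit_identical(self, small_params):
        import dataclasses

        params = CohortParams(phantom=dataclasses.replace(small_params, n_patients=6))
        c1 = generate_cohort(params, seed=21)
        c2 = generate_cohort(params, seed=21)
        pd.testing.assert_frame_equal(c1.clinical, c2.clinical)
        pd.testing.assert_frame_equal(c1.outcomes, c2.outcomes)
        np.testing.assert_array_equal(c1.patients[2][0].cet1w, c2.patients[2][0].cet1w)

    def test_pipeline_outputs_hide_ground_truth(self, small_params, tmp_path):
        import dataclasses
        import json

        from radnomics.cohort import write_cohort

        params = CohortParams(phantom=dataclasses.replace(small_params, n_patients=4))
        cohort = generate_cohort(params, seed=3)
        for tab in (cohort.clinical, cohort.outcomes):
            assert "heterogeneity" not in tab.columns
            assert not any("beta" in c for c in tab.columns)
        manifest = write_cohort(cohort, tmp_path)
        assert "true_betas" not in json.dumps(manifest)
        # ground truth is stored alongside, in its own file only
        assert (tmp_path / "ground_truth.json").exists()
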