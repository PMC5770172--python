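"""Range calibration, POM comparison, median model, drug-block bookkeeping."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pomcal import analysis, synthetic
from pomcal.analysis import (RangeBox, compare_parameter_distributions,
                             drug_block_experiment, lhs_candidates,
                             lhs_range_calibrate, median_model)
from pomcal.ap_model import (BIOMARKER_NAMES, BiomarkerVector,
                             ParameterVector, Rejection)
from pomcal.refine import PopulationOfModels


def make_pom(theta, rng=None):
    theta = np.atleast_2d(theta)
    Y = np.tile([10.0, 150.0, 280.0, 105.0, -74.0, -5.0, 200.0],
                (theta.shape[0], 1))
    return PopulationOfModels(theta=theta, biomarkers=Y)


class TestLhs:
    def test_study_shape(self, rng):
        cand = lhs_candidates(np.tile([0.0, 2.0], (11, 1)), 10, 1000, rng)
        assert cand.shape == (10_000, 11)

    def test_exact_stratification_per_replicate(self, rng):
        bounds = np.tile([0.0, 1.0], (4, 1))
        reps, divs = 3, 50
        cand = lhs_candidates(bounds, reps, divs, rng)
        for r in range(reps):
            block = cand[r * divs:(r + 1) * divs]
            for k in range(4):
                strata = np.floor(block[:, k] * divs).astype(int)
                assert np.array_equal(np.sort(strata), np.arange(divs))

    def test_known_acceptance_region_volume(self, rng):
        """Filter box occupying 25% of the search volume: the accepted
        fraction of 10,000 LHS candidates is 0.25 +- 0.02."""
        cols = list(BIOMARKER_NAMES)
        data = pd.DataFrame([[0.0] * 7, [0.5, 0.5, 1, 1, 1, 1, 1]],
                            columns=cols)

        def forward(theta):
            return theta.copy(), np.ones(theta.shape[0], dtype=bool)

        pom = lhs_range_calibrate(data, forward, np.tile([0.0, 1.0], (7, 1)),
                                  replicates=10, divisions=1000, seed=4)
        assert pom.size / 10_000 == pytest.approx(0.25, abs=0.02)

    def test_vacuous_filter_accepts_all_valid(self, rng):
        cols = list(BIOMARKER_NAMES)
        data = pd.DataFrame([[-1e12] * 7, [1e12] * 7], columns=cols)

        def forward(theta):
            return theta.copy(), np.ones(theta.shape[0], dtype=bool)

        pom = lhs_range_calibrate(data, forward, np.tile([0.0, 1.0], (7, 1)),
                                  replicates=2, divisions=100, seed=1)
        assert pom.size == 200


class TestRangeBox:
    def test_every_row_inside_own_box(self, sr_table):
        box = RangeBox.from_table(sr_table)
        assert box.contains(sr_table.to_numpy()).all()

    def test_outside_point_excluded(self, sr_table):
        box = RangeBox.from_table(sr_table)
        y = sr_table.iloc[0].to_numpy().copy()
        y[2] = box.hi[2] + 1.0
        assert not box.contains(y)[0]


class TestCompareParameterDistributions:
    def test_identical_poms(self, rng):
        theta = rng.normal(1, 0.1, size=(80, 11))
        rep = compare_parameter_distributions(make_pom(theta),
                                              make_pom(theta.copy()))
        assert np.allclose(rep["median_shift_pct"], 0)
        assert rep["no_change"].all()
        assert not rep["significant"].any()

    def test_doubled_parameter_detected(self, rng):
        theta = rng.normal(1, 0.1, size=(60, 11))
        theta_b = theta.copy()
        theta_b[:, 5] *= 2.0
        rep = compare_parameter_distributions(make_pom(theta),
                                              make_pom(theta_b))
        assert rep.loc[5, "median_shift_pct"] == pytest.approx(100.0)
        assert rep.loc[5, "significant"]
        assert not rep.loc[0, "significant"]

    def test_known_forty_percent_shift_recovered(self):
        """A constructed -40% shift in one parameter (n=300 each) is
        reported within +-5% and flagged as the most significant."""
        r = np.random.default_rng(123)
        theta_a = r.normal(1.0, 0.15, size=(300, 11))
        theta_b = r.normal(1.0, 0.15, size=(300, 11))
        theta_b[:, 2] *= 0.6
        rep = compare_parameter_distributions(make_pom(theta_a),
                                              make_pom(theta_b))
        assert rep.loc[2, "median_shift_pct"] == pytest.approx(-40.0, abs=5.0)
        assert rep.loc[2, "p_value"] == rep["p_value"].min()

    def test_mann_whitney_matches_exact_enumeration(self):
        """For n=m=4 without ties, the reported two-sided p-value equals the
        exact null distribution of U obtained by enumerating all C(8,4)
        group assignments."""
        x = np.array([1.1, 2.3, 3.1, 4.0])
        y = np.array([1.9, 2.8, 4.5, 5.2])
        pooled = np.concatenate([x, y])

        def u_stat(a, b):
            return sum((ai > bj) for ai in a for bj in b)

        u_obs = u_stat(x, y)
        n = len(x)
        us = []
        for comb in itertools.combinations(range(8), n):
            a = pooled[list(comb)]
            b = pooled[[i for i in range(8) if i not in comb]]
            us.append(u_stat(a, b))
        us = np.asarray(us)
        # two-sided exact p: distance of U from its mean under the null
        mu = n * n / 2
        p_exact = np.mean(np.abs(us - mu) >= abs(u_obs - mu))

        rep = compare_parameter_distributions(
            make_pom(np.tile(x[:, None], (1, 11))),
            make_pom(np.tile(y[:, None], (1, 11))))
        assert rep.loc[0, "p_value"] == pytest.approx(p_exact, abs=1e-12)

    def test_empty_pom_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_parameter_distributions(
                make_pom(np.empty((0, 11))), make_pom(rng.normal(size=(5, 11))))


class TestMedianModel:
    def test_identical_members(self):
        theta = np.tile(ParameterVector(gK1=1.3).to_array(), (7, 1))
        assert median_model(make_pom(theta)) == ParameterVector(gK1=1.3)

    def test_odd_count_median(self):
        rows = [ParameterVector(gK1=v).to_array() for v in (0.5, 1.0, 1.5)]
        assert median_model(make_pom(np.array(rows))).gK1 == 1.0

    def test_permutation_invariance(self, rng):
        theta = rng.normal(1, 0.2, size=(50, 11))
        perm = rng.permutation(50)
        a = median_model(make_pom(theta))
        b = median_model(make_pom(theta[perm]))
        assert a == b

    def test_center_recovery(self):
        """Median of a POM sampled around a known center recovers the center
        within 2 standard errors per component (SE of a Gaussian median)."""
        r = np.random.default_rng(77)
        center = r.uniform(0.6, 1.4, size=11)
        n = 501
        theta = r.normal(center, 0.2, size=(n, 11))
        med = median_model(make_pom(theta)).to_array()
        se = 1.2533 * 0.2 / np.sqrt(n)
        assert np.all(np.abs(med - center) < 2 * se + 0.005)


class TestDrugBlockExperiment:
    @staticmethod
    def surrogate_forward(theta: ParameterVector):
        sur = synthetic.toy_models()["surrogate"]
        Y, _ = sur(theta.to_array()[None, :])
        return BiomarkerVector.from_array(Y[0])

    def test_zero_block_is_exact_noop(self, rng):
        theta = rng.uniform(0.5, 1.5, size=(5, 11))
        pom = make_pom(theta)
        rep = drug_block_experiment(pom, "gKr", 0.0,
                                    forward_fn=self.surrogate_forward)
        for n in BIOMARKER_NAMES:
            assert np.array_equal(rep[f"pre_{n}"], rep[f"post_{n}"])
        assert not rep["apd90_decreased"].any()

    def test_repolarizing_block_prolongs_surrogate_apd(self, rng):
        theta = np.tile(np.ones(11), (4, 1))
        rep = drug_block_experiment(make_pom(theta), "gKr", 0.5,
                                    forward_fn=self.surrogate_forward)
        assert (rep["post_APD90"] > rep["pre_APD90"]).all()

    def test_elevated_rmp_flag(self):
        """A member repolarizing to -55 mV post-block is flagged (threshold
        -60 mV); failures are recorded per member, not raised."""
        calls = {"n": 0}

        def fake_forward(theta):
            calls["n"] += 1
            if calls["n"] % 2 == 0:   # post-block call
                return BiomarkerVector(APD20=10, APD50=100, APD90=200,
                                       APA=80, RMP=-55.0, V20=-5,
                                       dVdtmax=150)
            return BiomarkerVector(APD20=10, APD50=100, APD90=180,
                                   APA=105, RMP=-80.0, V20=-5, dVdtmax=200)

        rep = drug_block_experiment(make_pom(np.ones((3, 11))), "gKr", 0.5,
                                    forward_fn=fake_forward)
        assert rep["elevated_rmp"].all()
        assert not rep["apd90_decreased"].any()

    def test_post_block_failure_recorded(self):
        calls = {"n": 0}

        def flaky_forward(theta):
            calls["n"] += 1
            if calls["n"] % 2 == 0:
                return Rejection("no-excitation")
            return BiomarkerVector(APD20=10, APD50=100, APD90=180, APA=105,
                                   RMP=-80.0, V20=-5, dVdtmax=200)

        rep = drug_block_experiment(make_pom(np.ones((2, 11))), "gKr", 0.9,
                                    forward_fn=flaky_forward)
        assert (rep["post_failed"] == "no-excitation").all()
        assert rep["post_APD90"].isna().all()
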