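import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eradiff import differential
from eradiff.feature_table import ClrMatrix, InputError


def clr_from(values, taxa=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    taxa = taxa or [f"g__{j}" for j in range(p)]
    return ClrMatrix(values=pd.DataFrame(values, index=idx, columns=taxa), pseudocount=1.0)


def balanced_design(n, rng, day_range=28):
    era = np.array(["pre"] * (n // 2) + ["covid"] * (n - n // 2))
    day = rng.integers(0, day_range, size=n)
    pc1 = rng.normal(size=n)
    pc2 = rng.normal(size=n)
    return era, day, pc1, pc2


class TestFitTaxonModels:
    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        n = 20
        era, day, pc1, pc2 = balanced_design(n, rng)
        y = rng.normal(size=(n, 3))
        clr = clr_from(y)
        results = differential.fit_taxon_models(clr, clr.taxa, era, day, pc1, pc2)
        x = sm.add_constant(
            np.column_stack([(era == "covid").astype(float), day, pc1, pc2])
        )
        for j, taxon in enumerate(clr.taxa):
            fit = sm.OLS(y[:, j], x).fit()
            assert results.loc[taxon, "beta_era"] == pytest.approx(fit.params[1], abs=1e-8)
            assert results.loc[taxon, "se"] == pytest.approx(fit.bse[1], abs=1e-8)
            assert results.loc[taxon, "p"] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_normal_equations_oracle(self, rng):
        n = 15
        era, day, pc1, pc2 = balanced_design(n, rng)
        y = rng.normal(size=(n, 2))
        clr = clr_from(y)
        results = differential.fit_taxon_models(clr, clr.taxa, era, day, pc1, pc2)
        x = np.column_stack(
            [np.ones(n), (era == "covid").astype(float), day, pc1, pc2]
        )
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(results["beta_era"].values, beta[1], atol=1e-8)

    def test_generate_and_recover(self, rng):
        n = 40
        era = np.array(["pre"] * 20 + ["covid"] * 20)
        day = np.zeros(n)
        pc1 = np.zeros(n)
        pc2 = rng.normal(size=n) * 0  # null covariates
        y = 3.0 * (era == "covid") + rng.normal(scale=0.1, size=n)
        clr = clr_from(np.column_stack([y, rng.normal(size=n)]))
        # constant covariate columns are collinear with the intercept; jitter
        pc1 = rng.normal(scale=1e-3, size=n)
        pc2 = rng.normal(scale=1e-3, size=n)
        day = rng.integers(0, 28, size=n)
        results = differential.fit_taxon_models(clr, clr.taxa, era, day, pc1, pc2)
        assert results.loc["g__0", "beta_era"] == pytest.approx(3.0, abs=0.15)
        assert results.loc["g__0", "q"] < 1e-10

    def test_mediated_effect_shrinks_when_adjusted(self, rng):
        n = 100
        era_ind = np.array([0.0] * 50 + [1.0] * 50)
        era = np.where(era_ind == 1, "covid", "pre")
        pc1 = era_ind * 2.0 + rng.normal(scale=0.5, size=n)  # correlated with era
        y = 2.0 * pc1 + rng.normal(scale=0.2, size=n)  # effect runs through pc1
        day = rng.integers(0, 28, size=n)
        pc2 = rng.normal(size=n)
        clr = clr_from(y[:, None])
        adjusted = differential.fit_taxon_models(clr, clr.taxa, era, day, pc1, pc2)
        # unadjusted: regress on era alone via near-null covariates
        unadjusted = differential.fit_taxon_models(
            clr, clr.taxa, era, day,
            rng.normal(scale=1e-6, size=n), rng.normal(scale=1e-6, size=n))
        assert abs(adjusted.loc["g__0", "beta_era"]) < abs(unadjusted.loc["g__0", "beta_era"])

    def test_single_era_errors(self, rng):
        clr = clr_from(rng.normal(size=(10, 2)))
        with pytest.raises(InputError):
            differential.fit_taxon_models(
                clr, clr.taxa, ["pre"] * 10, np.arange(10),
                rng.normal(size=10), rng.normal(size=10))

    def test_too_few_samples_errors(self, rng):
        clr = clr_from(rng.normal(size=(6, 2)))
        era = ["pre"] * 3 + ["covid"] * 3
        with pytest.raises(InputError):
            differential.fit_taxon_models(
                clr, clr.taxa, era, np.arange(6), rng.normal(size=6), rng.normal(size=6))

    def test_rank_deficient_errors(self, rng):
        n = 12
        era = np.array(["pre"] * 6 + ["covid"] * 6)
        pc1 = (era == "covid").astype(float)  # duplicates the era column
        clr = clr_from(rng.normal(size=(n, 2)))
        with pytest.raises(InputError, match="rank"):
            differential.fit_taxon_models(
                clr, clr.taxa, era, np.arange(n), pc1, rng.normal(size=n))

    def test_q_at_least_p(self, rng):
        n = 30
        era, day, pc1, pc2 = balanced_design(n, rng)
        clr = clr_from(rng.normal(size=(n, 8)))
        results = differential.fit_taxon_models(clr, clr.taxa, era, day, pc1, pc2)
        assert (results["q"] >= results["p"] - 1e-12).all()
        assert ((results["q"] >= 0) & (results["q"] <= 1)).all()


def bh_oracle(p):
    """Literal step-up: q_i = min over j>=rank(i) of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, m * p[i] / rank)
        q[i] = min(prev, 1.0)
    return q


class TestBhAdjust:
    def test_single_p(self):
        assert differential.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_example(self):
        np.testing.assert_allclose(
            differential.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-12
        )

    def test_all_ones(self):
        np.testing.assert_allclose(differential.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert len(differential.bh_adjust([])) == 0

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            differential.bh_adjust([0.5, 1.5])

    @settings(max_examples=150, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
    def test_matches_step_up_oracle(self, pvals):
        np.testing.assert_allclose(
            differential.bh_adjust(pvals), bh_oracle(pvals), atol=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(differential.bh_adjust(pvals), expected, atol=1e-12)


class TestVolcanoSelect:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["taxon", "beta_era", "q"]).set_index("taxon")

    def test_boundary_beta_excluded(self):
        res = self._results([("g__a", 2.0, 0.001)])
        assert differential.volcano_select(res) == ([], [])

    def test_negative_effect_is_pre(self):
        res = self._results([("g__a", -2.5, 0.01)])
        assert differential.volcano_select(res) == ([], ["g__a"])

    def test_q_above_threshold_excluded(self):
        res = self._results([("g__a", 3.0, 0.06)])
        assert differential.volcano_select(res) == ([], [])

    def test_split_by_sign(self):
        res = self._results(
            [("g__a", 3.0, 0.01), ("g__b", -4.0, 0.001), ("g__c", 0.5, 0.0001)]
        )
        assert differential.volcano_select(res) == (["g__a"], ["g__b"])


def make_lopo_inputs(rng, n_patients=6, per_patient=5, effect=None, single_patient=None):
    rows = []
    patients = [f"p{i}" for i in range(n_patients)]
    eras = ["pre" if i < n_patients // 2 else "covid" for i in range(n_patients)]
    values = []
    for pid, era in zip(patients, eras):
        for k in range(per_patient):
            y = rng.normal(scale=0.3)
            if effect is not None and era == "covid":
                y += effect
            if single_patient is not None and pid == single_patient:
                y += 10.0
            rows.append(
                {
                    "sample_id": f"{pid}_{k}",
                    "patient_id": pid,
                    "era": era,
                    "admission_day": 0,
                    "collection_day": k * 3,
                }
            )
            values.append([y, rng.normal()])
    meta = pd.DataFrame(rows).set_index("sample_id")
    clr = ClrMatrix(
        values=pd.DataFrame(values, index=meta.index, columns=["g__sig", "g__noise"]),
        pseudocount=1.0,
    )
    n = len(meta)
    return clr, meta, rng.normal(scale=0.1, size=n), rng.normal(scale=0.1, size=n)


class TestLeaveOnePatientOut:
    def test_homogeneous_effect_fraction_one(self, rng):
        clr, meta, pc1, pc2 = make_lopo_inputs(rng, effect=4.0)
        report = differential.leave_one_patient_out(clr, meta, clr.taxa, pc1, pc2)
        assert report.fractions["g__sig"] == 1.0
        assert report.stable_taxa == ["g__sig"]
        assert report.n_runs == 6

    def test_single_patient_driven_signal_fails_its_run(self, rng):
        # signal carried by one covid patient: dropping that patient kills it
        clr, meta, pc1, pc2 = make_lopo_inputs(rng, effect=None, single_patient="p5")
        report = differential.leave_one_patient_out(clr, meta, clr.taxa, pc1, pc2)
        assert not report.per_run.loc["p5", "g__sig"]
        assert report.fractions["g__sig"] <= (report.n_runs - 1) / report.n_runs

    def test_run_count_equals_patient_count(self, rng):
        clr, meta, pc1, pc2 = make_lopo_inputs(rng, n_patients=8, effect=4.0)
        report = differential.leave_one_patient_out(clr, meta, clr.taxa, pc1, pc2)
        assert report.n_runs == 8
        assert report.per_run.shape[0] == 8

    def test_dropping_sole_era_patient_errors(self, rng):
        clr, meta, pc1, pc2 = make_lopo_inputs(rng, n_patients=4, effect=2.5)
        # relabel so only one patient is covid
        meta = meta.copy()
        meta.loc[meta["patient_id"] == "p2", "era"] = "pre"
        with pytest.raises(InputError, match="p3"):
            differential.leave_one_patient_out(clr, meta, clr.taxa, pc1, pc2)

    def test_too_few_patients_errors(self, rng):
        clr, meta, pc1, pc2 = make_lopo_inputs(rng, n_patients=2, effect=3.0)
        with pytest.raises(InputError):
            differential.leave_one_patient_out(clr, meta, clr.taxa, pc1, pc2)
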