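"""Quadrants, hot-spot search, propensity projection and KS enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from crystalgp import gpr, mechanisms as mech
from crystalgp.scales import AMINO_ACIDS
from oracles import ks_statistic_brute


class TestQuadrants:
    def _frame(self, points):
        return pd.DataFrame(points, columns=["sGRAVY", "sSCE"])

    def test_four_centroids_get_four_labels(self):
        df = self._frame([(-1, 1), (1, 1), (1, -1), (-1, -1)])
        out = mech.assign_quadrants(df, reference_means=(0.0, 0.0))
        assert out["quadrant"].tolist() == ["Q1", "Q2", "Q3", "Q4"]

    def test_boundary_point_takes_lower_index(self):
        df = self._frame([(0.0, 0.0)])
        out = mech.assign_quadrants(df, reference_means=(0.0, 0.0))
        assert out["quadrant"].item() == "Q1"

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        df = self._frame(rng.normal(size=(30, 2)))
        a = mech.assign_quadrants(df, reference_means=(0.0, 0.0))
        perm = rng.permutation(30)
        b = mech.assign_quadrants(df.iloc[perm], reference_means=(0.0, 0.0))
        assert (b["quadrant"].sort_index() == a["quadrant"].sort_index()).all()

    def test_default_reference_is_dataset_mean(self):
        df = self._frame([(-1, 5), (1, 5), (-1, 7), (1, 7)])
        out = mech.assign_quadrants(df)
        assert out.attrs["reference_means"] == {"sGRAVY": 0.0, "sSCE": 6.0}

    def test_nonfinite_reference_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            mech.assign_quadrants(self._frame([(0, 0)]), reference_means=(np.nan, 0.0))


class TestKsTwoSample:
    def test_identical_samples(self):
        d, p = mech.ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_disjoint_samples(self):
        d, _ = mech.ks_two_sample([0, 0], [1, 1])
        assert d == 1.0

    def test_known_small_case(self):
        d, _ = mech.ks_two_sample([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1 / 3)

    def test_undersized_rejected(self):
        with pytest.raises(ValueError):
            mech.ks_two_sample([1.0], [1, 2, 3])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(min_value=0, max_value=6), min_size=2, max_size=8),
        b=st.lists(st.integers(min_value=0, max_value=6), min_size=2, max_size=8),
    )
    def test_statistic_equals_brute_force(self, a, b):
        d, _ = mech.ks_two_sample(a, b)
        assert d == pytest.approx(ks_statistic_brute(a, b), abs=1e-12)

    def test_p_value_close_to_scipy_asymptotic(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=40)
        b = rng.normal(0.7, 1.0, size=35)
        d, p = mech.ks_two_sample(a, b)
        ref = ks_2samp(a, b, method="asymp")
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=0.2)  # correction differs slightly


class TestProjection:
    def test_single_point(self):
        df = pd.DataFrame({"sGRAVY": [0.1], "sSCE": [0.9], "predicted_propensity": [0.25]})
        out = mech.project_propensity(df, bins=5)
        assert len(out) == 1
        assert out["mean_propensity"].item() == 0.25

    def test_uniform_propensity_flat_map(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"sGRAVY": rng.normal(size=100), "sSCE": rng.normal(size=100),
             "predicted_propensity": np.full(100, 0.17)}
        )
        out = mech.project_propensity(df, bins=4)
        assert np.allclose(out["mean_propensity"], 0.17)

    def test_mass_conservation(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"sGRAVY": rng.normal(size=200), "sSCE": rng.normal(size=200),
             "predicted_propensity": rng.uniform(0, 0.4, 200)}
        )
        out = mech.project_propensity(df, bins=6)
        weighted = (out["mean_propensity"] * out["count"]).sum() / out["count"].sum()
        assert weighted == pytest.approx(df["predicted_propensity"].mean(), abs=1e-12)
        assert out["count"].sum() == 200


class TestEnrichment:
    def _setup(self, seed, shift=0.0):
        rng = np.random.default_rng(seed)
        n = 80
        feats = pd.DataFrame(
            {"f_shift": rng.normal(size=n), "f_null": rng.normal(size=n)},
            index=[f"P{i}" for i in range(n)],
        )
        predicted = pd.Series(rng.uniform(0, 0.4, n), index=feats.index)
        easy = predicted >= predicted.quantile(0.75)
        feats.loc[easy, "f_shift"] += shift
        quads = pd.DataFrame({"quadrant": ["Q1"] * n}, index=feats.index)
        return quads, predicted, feats

    def test_identical_groups_empty_table(self):
        quads, predicted, feats = self._setup(0, shift=0.0)
        # make the compared feature literally identical between groups
        feats["f_shift"] = 1.0 + 0 * feats["f_shift"]
        feats["f_null"] = 2.0
        out = mech.enrichment_tables(quads, predicted, feats)
        assert out.empty

    def test_planted_shift_detected_with_direction(self):
        detected = 0
        for seed in range(10):
            quads, predicted, feats = self._setup(seed, shift=2.5)
            out = mech.enrichment_tables(quads, predicted, feats, alpha=0.05)
            hit = out[(out["feature"] == "f_shift") & (out["direction"] == "enriched")]
            detected += int(len(hit) == 1)
        assert detected >= 9

    def test_small_quadrant_skipped(self, caplog):
        quads, predicted, feats = self._setup(1, shift=2.0)
        quads.iloc[5:] = "Q3"  # Q1 keeps only 5 members → below min size
        with caplog.at_level("INFO"):
            out = mech.enrichment_tables(quads, predicted, feats, min_group_size=10)
        assert not (out["group_a"] == "Q1-easy").any()


@pytest.fixture(scope="module")
def planted_model():
    """GPR trained on data with a single bump in two composition dims."""
    rng = np.random.default_rng(6)
    n = 120
    cols = [f"frac_{aa}" for aa in AMINO_ACIDS]
    comp = rng.dirichlet(np.full(20, 5.0), size=n)
    X = pd.DataFrame(comp, columns=cols, index=[f"P{i}" for i in range(n)])
    centre_g, centre_a = 0.10, 0.09
    f = np.exp(
        -0.5 * ((X["frac_G"] - centre_g) / 0.02) ** 2
        - 0.5 * ((X["frac_A"] - centre_a) / 0.02) ** 2
    ) * 0.5 + rng.normal(0, 0.01, n)
    f = np.clip(f, 0.0, 1.0)
    Xs, scaler = gpr.zscore_fit_apply(X)
    model = gpr.train_restarts(Xs, np.asarray(f), n_restarts=15, seed=6)
    model.scaler = scaler
    pi = pd.Series(np.asarray(f) ** 2, index=X.index)
    return model, X, pi, (centre_g, centre_a)


class TestHotspotSearch:
    def test_top_hit_near_planted_maximum(self, planted_model):
        model, X, pi, (cg, ca) = planted_model
        hits = mech.hotspot_search(model, X, pi, percentile=95.0)
        top = hits.iloc[0]
        # one grid cell = range/3 for a 4-point grid
        step_g = (X["frac_G"].max() - X["frac_G"].min()) / 3
        step_a = (X["frac_A"].max() - X["frac_A"].min()) / 3
        assert abs(top["frac_G"] - cg) <= step_g
        assert abs(top["frac_A"] - ca) <= step_a

    def test_outputs_on_simplex_and_not_worse_than_seed(self, planted_model):
        model, X, pi, _ = planted_model
        hits = mech.hotspot_search(model, X, pi, percentile=95.0)
        comp_cols = [f"frac_{aa}" for aa in AMINO_ACIDS]
        sums = hits[comp_cols].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        for seed_id, group in hits.groupby("seed"):
            seed_pred = group.loc[
                (group[comp_cols] - X.loc[seed_id, comp_cols]).abs().sum(axis=1) < 1e-12,
                "predicted_propensity",
            ]
            assert group["predicted_propensity"].max() >= seed_pred.min() - 1e-12

    def test_percentile_validation(self, planted_model):
        model, X, pi, _ = planted_model
        with pytest.raises(ValueError):
            mech.hotspot_search(model, X, pi, percentile=0.0)
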