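import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import xlogy

from methphen.dmr import ComparisonSpec, call_dmrs, estimate_pi0_slim, slim_qvalues
from methphen.dmr import test_bin as single_bin_test
from methphen.dmr import test_bins as batch_bin_test


# ---------------------------------------------------------------------------
# independent oracle: iteratively refined grid search of the binomial
# likelihood for a 2-group comparison without covariate
# ---------------------------------------------------------------------------

def _binom_ll(k, n, p):
    return float(np.sum(xlogy(k, p) + xlogy(n - k, 1 - p)))


def _grid_max(fun, lo=0.0, hi=1.0, levels=8, points=101):
    best_x, best = None, -np.inf
    for _ in range(levels):
        xs = np.linspace(lo, hi, points)
        vals = np.array([fun(x) for x in xs])
        i = int(np.argmax(vals))
        if vals[i] > best:
            best, best_x = vals[i], xs[i]
        span = (hi - lo) / (points - 1)
        lo, hi = max(best_x - span, 0.0), min(best_x + span, 1.0)
    return best


def grid_lrt_oracle(meth_a, total_a, meth_b, total_b):
    """LRT statistic by nested grid maximization of the binomial likelihood."""
    ka, na = np.asarray(meth_a), np.asarray(total_a)
    kb, nb = np.asarray(meth_b), np.asarray(total_b)
    ll_a = _grid_max(lambda p: _binom_ll(ka, na, p))
    ll_b = _grid_max(lambda p: _binom_ll(kb, nb, p))
    ll_0 = _grid_max(
        lambda p: _binom_ll(ka, na, p) + _binom_ll(kb, nb, p)
    )
    return 2.0 * (ll_a + ll_b - ll_0)


class TestTestBin:
    def test_identical_counts_null(self):
        p, d = single_bin_test([5, 5, 5, 5], [10, 10, 10, 10], [True, True, False, False])
        assert d == 0.0
        assert p == 1.0

    def test_pooled_diff_arithmetic(self):
        p, d = single_bin_test(
            [5, 6, 15, 14], [20, 20, 20, 20], [True, True, False, False]
        )
        assert d == pytest.approx(11 / 40 - 29 / 40, abs=1e-12)

    @pytest.mark.parametrize(
        "ka,kb",
        [((3, 7), (12, 15)), ((0, 1), (10, 9)), ((5, 5), (5, 6)), ((18, 19), (2, 1))],
    )
    def test_lrt_matches_grid_oracle(self, ka, kb):
        n = (20, 20)
        res = batch_bin_test(
            np.array([[*ka, *kb]], dtype=float),
            np.array([[*n, *n]], dtype=float),
            np.array([True, True, False, False]),
        )
        expected = grid_lrt_oracle(ka, n, kb, n)
        assert res["lrt"].iloc[0] == pytest.approx(expected, abs=1e-6)

    def test_group_swap_negates_diff(self, rng):
        n_bins = 50
        total = rng.integers(5, 40, size=(n_bins, 8)).astype(float)
        meth = rng.binomial(total.astype(int), 0.4).astype(float)
        group = np.array([True] * 4 + [False] * 4)
        donor = np.array(["D1", "D2", "D3", "D4"] * 2)
        a = batch_bin_test(meth, total, group, donor)
        b = batch_bin_test(meth, total, ~group, donor)
        np.testing.assert_allclose(a["meth_diff"], -b["meth_diff"], atol=1e-12)
        np.testing.assert_allclose(a["p_value"], b["p_value"], atol=1e-9)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="groups"):
            single_bin_test([1, 2], [0, 5], [True, False])

    def test_wald_close_to_lrt_at_large_counts(self):
        meth = np.array([[30.0, 32.0, 60.0, 61.0]]) * 10
        total = np.array([[100.0] * 4]) * 10
        group = np.array([True, True, False, False])
        lrt = batch_bin_test(meth, total, group, method="lrt")["p_value"].iloc[0]
        wald = batch_bin_test(meth, total, group, method="wald")["p_value"].iloc[0]
        assert np.log(wald) == pytest.approx(np.log(lrt), rel=0.2)

    def test_donor_covariate_reduces_false_positives(self):
        """When donor composition differs between the groups (as with a
        donor lacking one population), strong donor effects inflate the
        unadjusted test; the covariate-adjusted test on the same null data
        calls far fewer false positives."""
        rng = np.random.default_rng(11)
        n_bins = 800
        # D1/D2 appear in both groups; D3 only in A, D4 only in B
        donor = np.array(["D1", "D2", "D3", "D3", "D1", "D2", "D4", "D4"])
        group = np.array([True] * 4 + [False] * 4)
        donor_idx = np.array([0, 1, 2, 2, 0, 1, 3, 3])
        eff = rng.normal(0, 1.5, size=(n_bins, 4))
        mu = 1 / (1 + np.exp(-eff[:, donor_idx]))
        total = np.full((n_bins, 8), 30.0)
        meth = rng.binomial(30, mu).astype(float)
        p_adj = batch_bin_test(meth, total, group, donor)["p_value"]
        p_raw = batch_bin_test(meth, total, group, None)["p_value"]
        assert (p_adj < 0.05).sum() < (p_raw < 0.05).sum()
        assert (p_raw < 0.05).mean() > 0.10  # donor noise really does inflate

    def test_type_i_control_null(self):
        """On correct-model null data the p<alpha fraction is within 3 MC SE
        of alpha (coverage high enough for the chi-square approximation)."""
        rng = np.random.default_rng(21)
        n_bins = 4000
        group = np.array([True] * 4 + [False] * 4)
        donor = np.array(["D1", "D2", "D3", "D4"] * 2)
        total = np.full((n_bins, 8), 60.0)
        mu = rng.uniform(0.2, 0.8, size=n_bins)
        meth = rng.binomial(60, mu[:, None], size=(n_bins, 8)).astype(float)
        p = batch_bin_test(meth, total, group, donor)["p_value"].to_numpy()
        for alpha in (0.01, 0.05):
            se = np.sqrt(alpha * (1 - alpha) / n_bins)
            assert abs((p < alpha).mean() - alpha) < 3 * se


class TestSlim:
    def test_identical_ps_identical_qs(self):
        q = slim_qvalues(np.full(100, 0.3))
        assert len(set(np.round(q, 15))) == 1

    def test_uniform_pi0_and_bh_bound(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=1000)
        pi0 = estimate_pi0_slim(p)
        assert pi0 >= 0.8
        q = slim_qvalues(p)
        # independent textbook BH
        order = np.argsort(p)
        bh_sorted = np.minimum.accumulate((p[order] * len(p) / np.arange(1, len(p) + 1))[::-1])[::-1]
        bh = np.empty_like(p)
        bh[order] = np.minimum(bh_sorted, 1.0)
        assert np.all(q >= bh * pi0 - 1e-12)

    def test_three_value_bh_oracle(self):
        q = slim_qvalues(np.array([1e-12, 0.5, 0.9]), pi0=1.0)
        # by hand: q3 = 0.9, q2 = min(0.5*3/2, 0.9) = 0.75, q1 = min(3e-12, ...)
        np.testing.assert_allclose(q, [3e-12, 0.75, 0.9])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500) ** 2
        q = slim_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_q_le_one(self):
        q = slim_qvalues(np.linspace(0.001, 1.0, 200))
        assert np.all(q <= 1.0)

    def test_out_of_range_p(self):
        with pytest.raises(ValueError):
            slim_qvalues(np.array([0.5, 1.5]))

    def test_few_pvalues_fallback(self, caplog):
        with caplog.at_level("WARNING"):
            pi0 = estimate_pi0_slim(np.array([0.1, 0.5, 0.9]))
        assert pi0 == 1.0

    def test_pi0_drops_with_signal(self):
        rng = np.random.default_rng(9)
        p = np.concatenate([rng.uniform(size=500), rng.uniform(size=500) * 1e-4])
        assert estimate_pi0_slim(p) < 0.8


def _null_matrix(rng, n_bins=500, cov=25):
    from methphen.io_binning import BinnedMethylationMatrix

    sheet = pd.DataFrame(
        {
            "sample_id": [f"D{d}_{p}" for d in range(1, 5) for p in ("NL", "NB")],
            "donor": [f"D{d}" for d in range(1, 5) for _ in range(2)],
            "phenotype": ["luminal", "basal"] * 4,
            "disease": ["normal"] * 8,
        }
    )
    total = np.full((n_bins, 8), cov, dtype=np.int64)
    mu = rng.uniform(0.2, 0.8, size=n_bins)
    meth = rng.binomial(cov, mu[:, None], size=(n_bins, 8))
    bins = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_bins) * 100,
            "end": np.arange(n_bins) * 100 + 100,
            "n_cpgs": 2,
        }
    )
    return BinnedMethylationMatrix(bins, meth, total, sheet)


class TestCallDmrs:
    SPEC = ComparisonSpec(group_a=("luminal", "normal"), group_b=("basal", "normal"))

    def test_null_matrix_few_calls(self, rng):
        mat = _null_matrix(rng, n_bins=1000)
        ds = call_dmrs(mat, self.SPEC)
        assert ds.n_dmrs <= 1  # <= 0.1% of bins

    def test_degenerate_thresholds_pass_through(self, rng):
        mat = _null_matrix(rng, n_bins=200)
        spec = ComparisonSpec(
            group_a=("luminal", "normal"), group_b=("basal", "normal"),
            q_threshold=1.1, diff_threshold=0.0,
        )
        ds = call_dmrs(mat, spec)
        nonzero_diff = (ds.table["meth_diff"].abs() > 0).sum()
        assert ds.n_dmrs == nonzero_diff  # every bin with any difference
        assert ds.universe_size == 200

    def test_planted_region_recovered(self, small_study):
        mat = small_study["matrix"]
        truth = small_study["truth"]
        ds = call_dmrs(mat, self.SPEC)
        planted = truth.regions.query("effect_class == 'phenotype_shared'")
        planted_ids = set(planted["chrom"].astype(str) + ":" + planted["start"].astype(str))
        universe = set(mat.bins["chrom"].astype(str) + ":" + mat.bins["start"].astype(str))
        recovered = ds.dmr_bin_ids() & planted_ids
        assert len(recovered) / max(len(planted_ids & universe), 1) >= 0.8
        # direction matches the planted sign
        d = ds.dmrs.copy()
        d["bid"] = d["chrom"].astype(str) + ":" + d["start"].astype(str)
        tmap = planted.set_index(
            planted["chrom"].astype(str) + ":" + planted["start"].astype(str)
        )["direction"]
        hits = d[d["bid"].isin(tmap.index)]
        assert (hits.set_index("bid")["direction"] == tmap.loc[hits["bid"]]).all()

    def test_missing_group_raises(self, rng):
        mat = _null_matrix(rng, n_bins=50)
        spec = ComparisonSpec(group_a=("luminal", "cancer"), group_b=("basal", "normal"))
        with pytest.raises(ValueError, match="empty group"):
            call_dmrs(mat, spec)

    def test_same_groups_invalid(self):
        spec = ComparisonSpec(group_a=("basal", "normal"), group_b=("basal", "normal"))
        with pytest.raises(ValueError, match="disjoint"):
            spec.validate()

    def test_dmr_definition_invariant(self, small_study):
        ds = call_dmrs(small_study["matrix"], self.SPEC)
        d = ds.dmrs
        assert (d["q_value"] < ds.q_threshold).all()
        assert (d["meth_diff"].abs() > ds.diff_threshold).all()
        assert (
            np.where(d["meth_diff"] >= 0, "hyper", "hypo") == d["direction"]
        ).all()

    def test_bed_export(self, small_study, tmp_path):
        ds = call_dmrs(small_study["matrix"], self.SPEC)
        path = tmp_path / "dmrs.bed"
        ds.to_bed(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == ds.n_dmrs
        fields = lines[0].split("\t")
        assert fields[3] == "NL-NB" and fields[5] == "."
        assert 0 <= float(fields[4]) <= 300


@pytest.fixture
def rng():
    return np.random.default_rng(42)
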