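"""Normalization, NB Wald DE, BH, shrinkage and qPCR concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import oracles
from piratrue import expression as ex


def nb_counts(rng, mu, disp, size):
    r = 1.0 / disp
    return rng.negative_binomial(r, r / (r + mu), size=size)


class TestSizeFactors:
    def test_identical_samples(self):
        m = pd.DataFrame({"a": [10, 5, 7], "b": [10, 5, 7]}, index=list("xyz"))
        assert np.allclose(ex.size_factors(m), [1.0, 1.0])

    def test_doubled_sample(self):
        m = pd.DataFrame({"a": [10, 4, 8], "b": [20, 8, 16]}, index=list("xyz"))
        sf = ex.size_factors(m)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        assert np.prod(sf) == pytest.approx(1.0)

    def test_hand_computed_median_of_ratios(self):
        m = pd.DataFrame(
            {"a": [4, 9, 16, 3], "b": [1, 3, 4, 6], "c": [16, 27, 4, 12]},
            index=list("wxyz"),
        )
        # geometric means per entry: 4, 9, ~6.35, ~6.0; ratios per sample,
        # size factor = median ratio, then geometric-mean centered
        geo = sps.gmean(m, axis=1)
        raw = m.div(geo, axis=0).median(axis=0)
        expected = raw / sps.gmean(raw)
        assert np.allclose(ex.size_factors(m), expected)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(41)
        m = pd.DataFrame(
            rng.poisson(20, size=(15, 6)) + 1,
            index=[f"e{i}" for i in range(15)],
            columns=[f"s{i}" for i in range(6)],
        )
        sf = ex.size_factors(m)
        perm_rows = m.sample(frac=1, random_state=1)
        perm_cols = m[[f"s{i}" for i in (3, 1, 5, 0, 2, 4)]]
        assert np.allclose(ex.size_factors(perm_rows), sf)
        assert np.allclose(ex.size_factors(perm_cols)[sf.index], sf)

    def test_all_zero_sample_errors(self):
        m = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="b"):
            ex.size_factors(m)


class TestNormalize:
    def test_log2_values(self):
        m = pd.DataFrame({"a": [0, 7]}, index=["x", "y"])
        sf = pd.Series({"a": 1.0})
        norm = ex.normalize(m, sf)
        assert norm.loc["x", "a"] == 0.0
        assert norm.loc["y", "a"] == pytest.approx(3.0)  # log2(8)

    def test_monotone_in_counts_per_sample(self):
        rng = np.random.default_rng(42)
        m = pd.DataFrame(
            rng.poisson(15, size=(30, 4)) + 1, columns=list("abcd")
        )
        norm = ex.normalize(m, ex.size_factors(m))
        for c in m.columns:
            order = m[c].argsort(kind="mergesort")
            assert (np.diff(norm[c].to_numpy()[order]) >= 0).all()

    def test_nonpositive_pseudocount_errors(self):
        m = pd.DataFrame({"a": [1]})
        with pytest.raises(ValueError, match="pseudocount"):
            ex.normalize(m, pd.Series({"a": 1.0}), pseudocount=0)


class TestBhAdjust:
    def test_single_and_degenerate(self):
        assert ex.bh_adjust([0.03]) == pytest.approx([0.03])
        assert ex.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_hand_case(self):
        got = ex.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_nan_propagation_and_family_size(self):
        got = ex.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(got[1])
        # family excludes the missing value: m = 2
        assert got[0] == pytest.approx(0.02)
        assert got[2] == pytest.approx(0.04)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            ex.bh_adjust([0.5, 1.5])

    def test_matches_reference_implementations_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(43)
        for n in (1, 5, 50, 500):
            p = rng.uniform(size=n)
            ours = ex.bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref)
            assert np.allclose(ours, oracles.bh_by_hand(list(p)))
            assert (ours >= p - 1e-12).all()


class TestShrinkage:
    def test_closed_forms(self):
        lfc = pd.Series([2.0, 2.0, 2.0])
        se = pd.Series([1e-9, 100.0, 1.0])
        shrunk = ex.shrink_series(lfc, se, prior_sd=1.0)
        assert shrunk[0] == pytest.approx(2.0)  # se -> 0: shrunk -> raw
        assert shrunk[1] == pytest.approx(0.0, abs=1e-3)  # se >> prior: -> 0
        assert shrunk[2] == pytest.approx(1.0)  # se == prior: raw / 2

    def test_never_flips_sign_or_grows(self):
        rng = np.random.default_rng(44)
        lfc = pd.Series(rng.normal(0, 2, size=200))
        se = pd.Series(rng.uniform(0.01, 3, size=200))
        shrunk = ex.shrink_series(lfc, se, prior_sd=0.8)
        assert (np.sign(shrunk) == np.sign(lfc)).all()
        assert (shrunk.abs() <= lfc.abs() + 1e-12).all()

    def test_nonpositive_prior_errors(self):
        with pytest.raises(ValueError, match="prior_sd"):
            ex.shrink_series(pd.Series([1.0]), pd.Series([1.0]), prior_sd=0.0)


class TestNbWaldDe:
    def _contrast(self, n_case, n_ref, adjust=None):
        case = [f"c{i}" for i in range(n_case)]
        ref = [f"r{i}" for i in range(n_ref)]
        return ex.Contrast("test", case, ref, adjust)

    def test_identical_group_means_give_zero(self):
        contrast = self._contrast(4, 4)
        m = pd.DataFrame(
            {s: [50, 20] for s in contrast.samples}, index=["e1", "e2"]
        )
        res = ex.nb_wald_de(m, contrast)
        assert np.allclose(res["log2fc"], 0.0, atol=1e-8)
        assert np.allclose(res["stat"], 0.0, atol=1e-8)

    def test_recovers_planted_fold_change(self):
        rng = np.random.default_rng(45)
        contrast = self._contrast(30, 30)
        rows = {}
        for i in range(40):
            case = nb_counts(rng, 200.0, 0.05, 30)  # 4-fold up
            ref = nb_counts(rng, 50.0, 0.05, 30)
            rows[f"e{i}"] = np.concatenate([case, ref])
        m = pd.DataFrame.from_dict(rows, orient="index", columns=contrast.samples)
        unit = pd.Series(1.0, index=contrast.samples)  # no library-size differences
        res = ex.nb_wald_de(m, contrast, factors=unit)
        assert res["log2fc"].mean() == pytest.approx(2.0, abs=0.15)
        assert (res["padj"] < 0.05).mean() > 0.9

    def test_adjustment_covariate_absorbs_confounder(self):
        # group effect zero; covariate drives counts; adjusted model must not call DE
        rng = np.random.default_rng(46)
        contrast_plain = self._contrast(20, 20)
        samples = contrast_plain.samples
        # covariate correlated with group: 15 of 20 cases are level B
        level = {s: ("B" if (i < 15 or 20 <= i < 25) else "A") for i, s in enumerate(samples)}
        rows = {}
        for i in range(30):
            mu = np.array([120.0 if level[s] == "B" else 30.0 for s in samples])
            r = 1 / 0.05
            rows[f"e{i}"] = rng.negative_binomial(r, r / (r + mu))
        m = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
        unit = pd.Series(1.0, index=samples)
        plain = ex.nb_wald_de(m, contrast_plain, factors=unit)
        adjusted = ex.nb_wald_de(
            m, ex.Contrast("adj", contrast_plain.case, contrast_plain.ref, level),
            factors=unit,
        )
        assert (plain["padj"] < 0.05).sum() > (adjusted["padj"] < 0.05).sum()
        assert abs(adjusted["log2fc"].mean()) < abs(plain["log2fc"].mean())

    def test_all_zero_entry_excluded_from_family(self):
        contrast = self._contrast(3, 3)
        m = pd.DataFrame(
            {s: [50, 0] for s in contrast.samples}, index=["e1", "zero"]
        )
        res = ex.nb_wald_de(m, contrast)
        assert np.isnan(res.loc["zero", "p"])
        assert res.loc["e1", "padj"] == pytest.approx(res.loc["e1", "p"])

    def test_confounded_adjustment_errors(self):
        contrast = self._contrast(3, 3)
        confounded = {s: ("x" if s.startswith("c") else "y") for s in contrast.samples}
        m = pd.DataFrame({s: [5] for s in contrast.samples}, index=["e1"])
        with pytest.raises(ValueError, match="singular"):
            ex.nb_wald_de(m, ex.Contrast("bad", contrast.case, contrast.ref, confounded))

    def test_too_small_groups_error(self):
        m = pd.DataFrame({"c0": [5], "r0": [5], "r1": [5]}, index=["e1"])
        with pytest.raises(ValueError, match=">=2"):
            ex.nb_wald_de(m, ex.Contrast("t", ["c0"], ["r0", "r1"]))

    def test_permuted_labels_give_uniform_pvalues(self):
        rng = np.random.default_rng(47)
        contrast = self._contrast(25, 25)
        m = pd.DataFrame(
            nb_counts(rng, 50.0, 0.1, (300, 50)),
            index=[f"e{i}" for i in range(300)],
            columns=contrast.samples,
        )
        res = ex.nb_wald_de(m, contrast)
        ks = sps.kstest(res["p"].dropna(), "uniform").statistic
        assert ks < 0.08


class TestDdcqConcordance:
    def _cq(self, ddcq_by_sample, ref="s0"):
        rows = [
            {"sample": s, "cq_target": 20.0 + d, "cq_control": 20.0}
            for s, d in ddcq_by_sample.items()
        ]
        return pd.DataFrame(rows)

    def test_reference_sample_is_unity(self):
        cq = self._cq({"s0": 0.0, "s1": 2.0, "s2": -1.0})
        norm = pd.Series({"s0": 1.0, "s1": 2.0, "s2": 3.0})
        rel, r, p = ex.ddcq_concordance(cq, "s0", norm)
        assert rel["s0"] == pytest.approx(1.0)
        assert rel["s1"] == pytest.approx(0.25)  # ddCq = 2 -> 2^-2
        assert rel["s2"] == pytest.approx(2.0)

    def test_perfect_linear_relation_gives_r_one(self):
        rng = np.random.default_rng(48)
        norm = pd.Series({f"s{i}": float(v) for i, v in enumerate(rng.uniform(2, 10, 12))})
        # Cq = a - b * normalized  ->  log2 relative expression linear in normalized
        cq = pd.DataFrame(
            {
                "sample": norm.index,
                "cq_target": 30.0 - 1.7 * norm.to_numpy(),
                "cq_control": 18.0,
            }
        )
        _, r, p = ex.ddcq_concordance(cq, "s0", norm)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_too_few_shared_samples_errors(self):
        cq = self._cq({"s0": 0.0, "s1": 1.0})
        norm = pd.Series({"s0": 1.0, "s1": 2.0})
        with pytest.raises(ValueError, match="shared samples"):
            ex.ddcq_concordance(cq, "s0", norm)
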