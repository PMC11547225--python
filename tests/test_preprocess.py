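"""Filtering, beta/M conversion, assumption screen, batch adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sermeth import preprocess, synthdata
from sermeth.preprocess import beta_to_m, m_to_beta


class TestBetaM:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)],
    )
    def test_closed_form_values(self, beta, expected):
        df = pd.DataFrame({"s": [beta]})
        assert beta_to_m(df).iloc[0, 0] == pytest.approx(expected)

    def test_clipping_keeps_extremes_finite(self):
        df = pd.DataFrame({"s": [1.0, 0.0]})
        m = beta_to_m(df, clip_eps=1e-6)
        assert m.iloc[0, 0] == pytest.approx(np.log2((1 - 1e-6) / 1e-6))
        assert m.iloc[0, 0] == pytest.approx(19.93, abs=0.01)
        assert np.isfinite(m.to_numpy()).all()

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_round_trip_identity_on_clipped_values(self, betas):
        df = pd.DataFrame({"s": betas})
        clipped = df.clip(1e-6, 1 - 1e-6)
        back = m_to_beta(beta_to_m(df))
        assert np.allclose(back, clipped, atol=1e-12)

    def test_invalid_eps_rejected(self):
        with pytest.raises(ValueError):
            beta_to_m(pd.DataFrame({"s": [0.5]}), clip_eps=0.7)


class TestFilterProbes:
    def _toy(self, toy_annotation):
        idx = toy_annotation.index
        beta = pd.DataFrame(np.full((6, 2), 0.5), index=idx, columns=["p1", "p2"])
        detp = pd.DataFrame(0.001, index=idx, columns=beta.columns)
        beads = pd.DataFrame(20, index=idx, columns=beta.columns)
        detp.loc["cg0", "p2"] = 0.02   # detection failure in one sample
        beads.loc["cg1", "p1"] = 2     # low bead count
        # cg2 cross-reactive, cg5 on chrX; cg3 and cg4 clean
        return beta, synthdata.DetectionStats(detp, beads)

    def test_toy_matrix_keeps_only_clean_probes(self, toy_annotation):
        beta, det = self._toy(toy_annotation)
        out, report = preprocess.filter_probes(beta, det, toy_annotation)
        assert sorted(out.index) == ["cg3", "cg4"]
        assert report.removed == {"detection_p": 1, "bead_count": 1,
                                  "cross_reactive": 1, "snp": 0,
                                  "sex_chrom": 1, "assumptions": 0}

    def test_counts_sum_to_removed_total(self, toy_annotation):
        beta, det = self._toy(toy_annotation)
        out, report = preprocess.filter_probes(beta, det, toy_annotation)
        assert report.n_input - report.n_output == sum(report.removed.values())

    def test_all_pass_input_unchanged(self, toy_annotation):
        idx = toy_annotation.index[3:5]  # clean autosomal probes
        beta = pd.DataFrame(np.full((2, 2), 0.4), index=idx, columns=["p1", "p2"])
        det = synthdata.DetectionStats(
            pd.DataFrame(0.001, index=idx, columns=beta.columns),
            pd.DataFrame(10, index=idx, columns=beta.columns))
        out, _ = preprocess.filter_probes(beta, det, toy_annotation)
        pd.testing.assert_frame_equal(out, beta)

    def test_mean_detection_p_reported_per_sample(self, toy_annotation):
        beta, det = self._toy(toy_annotation)
        _, report = preprocess.filter_probes(beta, det, toy_annotation)
        assert set(report.mean_detection_p_per_sample) == {"p1", "p2"}
        assert report.mean_detection_p_per_sample["p2"] == pytest.approx(
            det.detection_p["p2"].mean())

    def test_unannotated_probe_raises(self, toy_annotation):
        beta = pd.DataFrame({"p1": [0.5]}, index=["cg_missing"])
        det = synthdata.DetectionStats(
            pd.DataFrame({"p1": [0.001]}, index=["cg_missing"]),
            pd.DataFrame({"p1": [10]}, index=["cg_missing"]))
        with pytest.raises(KeyError, match="cg_missing"):
            preprocess.filter_probes(beta, det, toy_annotation)


class TestAssumptionFilter:
    def _groups(self, n_per=15):
        cols = [f"s{i}" for i in range(2 * n_per)]
        return cols, pd.Series(["A"] * n_per + ["B"] * n_per, index=cols)

    def test_null_rejection_rate_bounded_by_union(self):
        # i.i.d. Normal residuals: rejections stay near the union bound 4*alpha
        cols, groups = self._groups()
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(0, 1, size=(800, 30)), columns=cols)
        rep = preprocess.assumption_filter(m, groups, alpha=0.01)
        frac = 1 - rep["keep"].mean()
        assert frac <= 4 * 0.01 + 0.02
        assert frac > 0  # the screen does something

    def test_heteroscedastic_probe_flagged(self):
        cols, groups = self._groups()
        rng = np.random.default_rng(1)
        y = np.concatenate([rng.normal(0, 1, 15), rng.normal(0, 10, 15)])
        m = pd.DataFrame([y], columns=cols)
        rep = preprocess.assumption_filter(m, groups, alpha=0.05)
        assert not rep["keep"].iloc[0]
        assert "homoscedasticity" in rep["reason"].iloc[0] or "normality" in rep["reason"].iloc[0]

    def test_constant_probe_marked_degenerate(self):
        cols, groups = self._groups(3)
        m = pd.DataFrame([[1.0] * 6], columns=cols)
        rep = preprocess.assumption_filter(m, groups, alpha=0.05)
        assert not rep["keep"].iloc[0]
        assert rep["reason"].iloc[0] == "degenerate"

    def test_too_few_samples_per_group_raises(self):
        cols = ["a", "b", "c", "d"]
        groups = pd.Series(["A", "A", "B", "B"], index=cols)
        m = pd.DataFrame(np.zeros((1, 4)), columns=cols)
        with pytest.raises(ValueError):
            preprocess.assumption_filter(m, groups)


class TestCombat:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(50, 6)), columns=list("abcdef"))
        batch = pd.Series(["x"] * 6, index=m.columns)
        out = preprocess.combat_adjust(m, batch)
        pd.testing.assert_frame_equal(out, m)

    def _batched(self, gamma=1.5, group_delta=0.0, n=200, seed=2):
        # slide effect shared per batch with per-probe scatter, the
        # structure the empirical-Bayes adjustment models
        rng = np.random.default_rng(seed)
        cols = [f"s{i}" for i in range(20)]
        batch = pd.Series(["b1"] * 10 + ["b2"] * 10, index=cols)
        group = pd.Series((["g1"] * 5 + ["g2"] * 5) * 2, index=cols)
        m = rng.normal(0, 1, size=(n, 20))
        m[:, 10:] += rng.normal(gamma, 0.5, size=n)[:, None]
        m[:, (group == "g2").to_numpy()] += group_delta
        return pd.DataFrame(m, columns=cols), batch, group

    def test_known_additive_shift_removed(self):
        # the systematic batch shift is removed; what remains is the
        # shrinkage residual of per-probe noise, centred on zero
        m, batch, group = self._batched(gamma=1.5)
        out = preprocess.combat_adjust(m, batch, group)
        pre = (m.loc[:, batch == "b1"].mean(axis=1)
               - m.loc[:, batch == "b2"].mean(axis=1))
        post = (out.loc[:, batch == "b1"].mean(axis=1)
                - out.loc[:, batch == "b2"].mean(axis=1))
        assert abs(post.mean()) < 0.05
        assert post.abs().mean() < 0.2 * pre.abs().mean()

    def test_matches_reference_adjustment_output(self):
        # frozen oracle: the same fixture adjusted by the Bioconductor
        # reference implementation (sva::ComBat, parametric priors)
        from pathlib import Path

        data = Path(__file__).parent / "data"
        dat = pd.read_csv(data / "combat_input.csv")
        ref = pd.read_csv(data / "combat_reference_output.csv")
        ref.columns = dat.columns
        batch = pd.Series(["b1"] * 10 + ["b2"] * 10, index=dat.columns)
        group = pd.Series((["g1"] * 5 + ["g2"] * 5) * 2, index=dat.columns)
        out = preprocess.combat_adjust(dat, batch, group)
        assert np.abs(out.to_numpy() - ref.to_numpy()).max() < 1e-4

    def test_protected_group_effect_preserved(self):
        m, batch, group = self._batched(gamma=1.5, group_delta=2.0)
        out = preprocess.combat_adjust(m, batch, group)
        eff = (out.loc[:, group == "g2"].mean(axis=1)
               - out.loc[:, group == "g1"].mean(axis=1))
        assert abs(eff.mean() - 2.0) / 2.0 < 0.10

    def test_balanced_batches_keep_global_probe_means(self):
        m, batch, group = self._batched(gamma=1.0)
        out = preprocess.combat_adjust(m, batch, group)
        assert np.allclose(out.mean(axis=1), m.mean(axis=1), atol=0.15)

    def test_single_sample_batch_raises(self):
        m, batch, _ = self._batched()
        batch.iloc[0] = "solo"
        with pytest.raises(ValueError, match="solo"):
            preprocess.combat_adjust(m, batch)

    def test_confounded_design_raises(self):
        m, batch, _ = self._batched()
        group = batch.copy()  # batch == group exactly
        with pytest.raises(ValueError, match="confounded"):
            preprocess.combat_adjust(m, batch, group)


class TestMostVariable:
    def test_matches_brute_force_order(self):
        rng = np.random.default_rng(3)
        beta = pd.DataFrame(rng.uniform(size=(10, 5)),
                            index=[f"cg{i}" for i in range(10)])
        top = preprocess.select_most_variable(beta, 4)
        var = beta.var(axis=1, ddof=1)
        brute = sorted(beta.index, key=lambda p: (-var[p], p))[:4]
        assert top == brute

    def test_single_varying_probe_ranks_first(self):
        beta = pd.DataFrame(np.full((5, 4), 0.5), index=[f"cg{i}" for i in range(5)])
        beta.loc["cg3"] = [0.1, 0.9, 0.1, 0.9]
        assert preprocess.select_most_variable(beta, 1) == ["cg3"]

    def test_k_equal_n_is_permutation(self):
        rng = np.random.default_rng(4)
        beta = pd.DataFrame(rng.uniform(size=(6, 3)),
                            index=[f"cg{i}" for i in range(6)])
        assert sorted(preprocess.select_most_variable(beta, 6)) == sorted(beta.index)

    @pytest.mark.parametrize("k", [0, -1, 99])
    def test_bad_k_rejected(self, k):
        beta = pd.DataFrame(np.zeros((3, 2)), index=list("abc"))
        with pytest.raises(ValueError):
            preprocess.select_most_variable(beta, k)
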