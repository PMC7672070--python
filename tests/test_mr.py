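"""Two-sample MR: harmonisation, clumping and estimator oracles."""

import numpy as np
import pandas as pd
import pytest

from brainage import MRSimConfig, generate_mr_summary
from brainage.mr import (
    harmonise,
    ivw,
    ld_clump,
    mr_egger,
    mr_suite,
    weighted_median,
)


def _sumstats(ids, ea, oa, beta, se, eaf=None, pval=None):
    n = len(ids)
    return pd.DataFrame({
        "variant_id": ids, "effect_allele": ea, "other_allele": oa,
        "beta": beta, "se": se,
        "pval": pval if pval is not None else [0.01] * n,
        "eaf": eaf if eaf is not None else [0.3] * n,
    })


def _random_harmonised(n, seed, theta=0.3):
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
    sy = rng.uniform(0.005, 0.05, n)
    by = theta * bx + rng.normal(0, sy)
    return pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(n)],
        "beta_x": bx, "se_x": rng.uniform(0.005, 0.02, n),
        "beta_y": by, "se_y": sy, "p_x": rng.uniform(size=n),
    })


class TestHarmonise:
    def test_aligned_tables_pass_through(self):
        exp = _sumstats(["v1", "v2"], ["A", "G"], ["G", "T"], [0.1, -0.2], [0.01, 0.02])
        out = _sumstats(["v1", "v2"], ["A", "G"], ["G", "T"], [0.05, 0.07], [0.01, 0.02])
        h, audit = harmonise(exp, out)
        assert np.allclose(h["beta_y"], [0.05, 0.07])
        assert all(a["action"] == "keep" for a in audit)

    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = _sumstats(["v1"], ["A"], ["G"], [0.1], [0.01], eaf=[0.3])
        out = _sumstats(["v1"], ["G"], ["A"], [0.05], [0.01], eaf=[0.7])
        h, audit = harmonise(exp, out)
        assert h["beta_y"].iloc[0] == pytest.approx(-0.05)
        assert h["eaf_outcome"].iloc[0] == pytest.approx(0.3)
        assert audit[0]["action"] == "flip"

    def test_palindromic_dropped_with_audit(self):
        ids = [f"v{i}" for i in range(10)]
        ea = ["A"] * 8 + ["A", "C"]
        oa = ["G"] * 8 + ["T", "G"]       # last two are palindromic
        exp = _sumstats(ids, ea, oa, [0.1] * 10, [0.01] * 10)
        out = _sumstats(ids, ea, oa, [0.05] * 10, [0.01] * 10)
        h, audit = harmonise(exp, out)
        assert len(h) == 8
        dropped = [a for a in audit if a["action"] == "drop"]
        assert {a["variant_id"] for a in dropped} == {"v8", "v9"}
        assert all(a["reason"] == "palindromic" for a in dropped)

    def test_palindromic_inferred_from_allele_frequency(self):
        exp = _sumstats(["v1"], ["A"], ["T"], [0.1], [0.01], eaf=[0.2])
        out = _sumstats(["v1"], ["A"], ["T"], [0.05], [0.01], eaf=[0.8])
        h, audit = harmonise(exp, out, palindromic="infer")
        assert len(h) == 1
        assert h["beta_y"].iloc[0] == pytest.approx(-0.05)

    def test_incompatible_alleles_dropped_with_reason(self):
        exp = _sumstats(["v1"], ["A"], ["G"], [0.1], [0.01])
        out = _sumstats(["v1"], ["A"], ["C"], [0.05], [0.01])
        h, audit = harmonise(exp, out)
        assert len(h) == 0
        assert "incompatible" in audit[0]["reason"]

    def test_strand_complement_resolved(self):
        # exposure A/G reported as T/C on the other strand in the outcome
        exp = _sumstats(["v1"], ["A"], ["G"], [0.1], [0.01])
        out = _sumstats(["v1"], ["T"], ["C"], [0.05], [0.01])
        h, audit = harmonise(exp, out)
        assert len(h) == 1
        assert h["beta_y"].iloc[0] == pytest.approx(0.05)

    def test_orientation_invariance_of_estimates(self):
        """Flipping any variant's reported orientation leaves every estimate
        unchanged to 1e-10."""
        cfg = MRSimConfig(n_variants=15, theta=0.1, se_x=0.01, se_y=0.01, seed=1)
        exposure, outcome, _ = generate_mr_summary(cfg)
        h1, _ = harmonise(exposure, outcome)
        flipped = outcome.copy()
        for idx in (0, 5, 9):
            flipped.loc[idx, ["effect_allele", "other_allele"]] = \
                outcome.loc[idx, ["other_allele", "effect_allele"]].to_numpy()
            flipped.loc[idx, "beta"] = -outcome.loc[idx, "beta"]
            flipped.loc[idx, "eaf"] = 1.0 - outcome.loc[idx, "eaf"]
        h2, _ = harmonise(exposure, flipped)
        for fn in (ivw, mr_egger, lambda v: weighted_median(v, 200, seed=0)):
            assert fn(h1).estimate == pytest.approx(fn(h2).estimate, abs=1e-10)


class TestLDClump:
    @staticmethod
    def _variants(pvals):
        n = len(pvals)
        df = _random_harmonised(n, seed=0)
        df["p_x"] = pvals
        return df

    def test_identity_matrix_keeps_all(self):
        v = self._variants([0.1, 0.2, 0.3])
        out = ld_clump(v, np.eye(3), 0.1)
        assert len(out) == 3

    def test_perfect_ld_keeps_single_most_significant(self):
        v = self._variants([0.5, 0.01, 0.3])
        out = ld_clump(v, np.ones((3, 3)), 0.1)
        assert len(out) == 1
        assert out["p_x"].iloc[0] == 0.01

    def test_matches_independent_greedy_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            n = int(rng.integers(3, 12))
            v = self._variants(rng.uniform(size=n))
            a = rng.uniform(size=(n, n))
            r2 = (a + a.T) / 2
            np.fill_diagonal(r2, 1.0)
            got = set(ld_clump(v, r2, 0.4)["variant_id"])
            # brute-force re-simulation of the greedy rule
            remaining = sorted(range(n), key=lambda i: (v["p_x"].iloc[i],
                                                        v["variant_id"].iloc[i]))
            kept, removed = [], set()
            for i in remaining:
                if i in removed:
                    continue
                kept.append(i)
                for j in range(n):
                    if j != i and r2[i, j] >= 0.4:
                        removed.add(j)
            assert got == {v["variant_id"].iloc[i] for i in kept}

    def test_misaligned_matrix_rejected(self):
        v = self._variants([0.1, 0.2])
        with pytest.raises(ValueError):
            ld_clump(v, np.eye(3), 0.1)


class TestIVW:
    def test_single_instrument_is_wald_ratio(self):
        v = pd.DataFrame({"beta_x": [0.5], "se_x": [0.01],
                          "beta_y": [0.1], "se_y": [0.01]})
        res = ivw(v)
        assert res.estimate == pytest.approx(0.2)
        assert res.n_variants == 1

    def test_duplicating_a_variant_shrinks_se_by_sqrt2(self):
        one = pd.DataFrame({"beta_x": [0.4], "se_x": [0.01],
                            "beta_y": [0.12], "se_y": [0.02]})
        two = pd.concat([one, one], ignore_index=True)
        r1, r2 = ivw(one), ivw(two)
        assert r1.estimate == pytest.approx(r2.estimate)
        assert r2.se == pytest.approx(r1.se / np.sqrt(2))

    def test_matches_weighted_regression_through_origin_oracle(self):
        v = _random_harmonised(20, seed=4)
        res = ivw(v)
        bx, by, sy = (v[c].to_numpy() for c in ("beta_x", "beta_y", "se_y"))
        w = 1.0 / sy ** 2
        # normal equation for weighted no-intercept regression
        est = (w * bx * by).sum() / (w * bx ** 2).sum()
        se = 1.0 / np.sqrt((w * bx ** 2).sum())
        assert res.estimate == pytest.approx(est, abs=1e-8)
        assert res.se == pytest.approx(se, abs=1e-8)
        q = ((bx ** 2 / sy ** 2) * (by / bx - est) ** 2).sum()
        assert res.q_statistic == pytest.approx(q, abs=1e-8)
        assert res.q_df == 19


class TestMREgger:
    def test_noiseless_affine_recovered_exactly(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.3])
        v = pd.DataFrame({"beta_x": bx, "se_x": 0.01,
                          "beta_y": 0.03 + 0.5 * bx, "se_y": 0.01})
        res = mr_egger(v)
        assert res.intercept == pytest.approx(0.03, abs=1e-10)
        assert res.estimate == pytest.approx(0.5, abs=1e-10)

    def test_ray_through_origin_matches_ivw(self):
        bx = np.array([0.05, 0.1, 0.15, 0.25])
        v = pd.DataFrame({"beta_x": bx, "se_x": 0.01,
                          "beta_y": 0.4 * bx, "se_y": 0.01})
        res = mr_egger(v)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.estimate == pytest.approx(ivw(v).estimate, abs=1e-10)

    def test_matches_weighted_ols_oracle(self):
        v = _random_harmonised(20, seed=5)
        res = mr_egger(v)
        bx = np.abs(v["beta_x"].to_numpy())
        by = np.where(v["beta_x"] < 0, -v["beta_y"], v["beta_y"])
        w = 1.0 / v["se_y"].to_numpy() ** 2
        X = np.column_stack([np.ones_like(bx), bx])
        XtWX = X.T @ (w[:, None] * X)
        coef = np.linalg.solve(XtWX, X.T @ (w * by))
        resid = by - X @ coef
        scale = (w * resid ** 2).sum() / (len(bx) - 2)
        cov = scale * np.linalg.inv(XtWX)
        assert res.intercept == pytest.approx(coef[0], abs=1e-8)
        assert res.estimate == pytest.approx(coef[1], abs=1e-8)
        assert res.intercept_se == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-8)
        assert res.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-8)
        assert res.q_df == 18

    def test_requires_three_variants(self):
        v = _random_harmonised(2, seed=6)
        with pytest.raises(ValueError):
            mr_egger(v)

    def test_degenerate_design_rejected(self):
        v = pd.DataFrame({"beta_x": [0.1, 0.1, 0.1], "se_x": 0.01,
                          "beta_y": [0.0, 0.1, 0.2], "se_y": 0.01})
        with pytest.raises(ValueError, match="degenerate"):
            mr_egger(v)


class TestWeightedMedian:
    def test_single_variant_is_the_ratio(self):
        v = pd.DataFrame({"beta_x": [0.4], "se_x": [0.01],
                          "beta_y": [0.1], "se_y": [0.01]})
        res = weighted_median(v, n_bootstrap=10, seed=0)
        assert res.estimate == pytest.approx(0.25)

    def test_equal_weights_pick_middle_element(self):
        v = pd.DataFrame({"beta_x": [1.0, 1.0, 1.0], "se_x": [0.01] * 3,
                          "beta_y": [0.1, 0.2, 0.9], "se_y": [0.01] * 3})
        res = weighted_median(v, n_bootstrap=10, seed=0)
        assert res.estimate == pytest.approx(0.2)

    def test_matches_cumulative_weight_scan_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(2, 15))
            v = _random_harmonised(n, seed=100 + trial)
            res = weighted_median(v, n_bootstrap=2, seed=0)
            ratios = (v["beta_y"] / v["beta_x"]).to_numpy()
            weights = (v["beta_x"] ** 2 / v["se_y"] ** 2).to_numpy()
            order = np.argsort(ratios)
            r, w = ratios[order], weights[order]
            cum = (np.cumsum(w) - 0.5 * w) / w.sum()
            # scan the piecewise-linear cumulative weight function for 0.5
            if cum[0] >= 0.5:
                expected = r[0]
            elif cum[-1] <= 0.5:
                expected = r[-1]
            else:
                expected = float(np.interp(0.5, cum, r))
            assert res.estimate == pytest.approx(expected, abs=1e-10)

    def test_bootstrap_se_is_seeded(self):
        v = _random_harmonised(10, seed=8)
        a = weighted_median(v, n_bootstrap=100, seed=42)
        b = weighted_median(v, n_bootstrap=100, seed=42)
        assert a.se == b.se

    def test_zero_exposure_effect_rejected(self):
        v = pd.DataFrame({"beta_x": [0.0], "se_x": [0.01],
                          "beta_y": [0.1], "se_y": [0.01]})
        with pytest.raises(ZeroDivisionError):
            weighted_median(v, n_bootstrap=10, seed=0)


class TestMRSuite:
    def test_homogeneous_noise_free_input_has_zero_q(self):
        cfg = MRSimConfig(n_variants=10, theta=0.5, se_x=0.0, se_y=0.0, seed=9)
        exposure, outcome, _ = generate_mr_summary(cfg)
        out = mr_suite(exposure, outcome, n_bootstrap=10, seed=0)
        res = out["results"]
        assert res["ivw"].estimate == pytest.approx(0.5, abs=1e-12)
        assert res["ivw"].q_statistic == 0.0
        # Egger's Q goes through a least-squares solve whose round-off is
        # amplified by the 1/se^2 weights; zero only up to that noise
        assert res["egger"].q_statistic == pytest.approx(0.0, abs=1e-6)
        assert not out["heterogeneity_flag"]

    def test_fewer_than_three_variants_downgrades_with_warning(self):
        cfg = MRSimConfig(n_variants=2, theta=0.1, seed=10)
        exposure, outcome, _ = generate_mr_summary(cfg)
        out = mr_suite(exposure, outcome, n_bootstrap=10, seed=0)
        assert "egger" not in out["results"]
        assert any("Egger skipped" in w for w in out["warnings"])

    def test_clumping_inside_suite(self):
        cfg = MRSimConfig(n_variants=6, theta=0.2, seed=11)
        exposure, outcome, _ = generate_mr_summary(cfg)
        r2 = np.eye(6)
        r2[0, 1] = r2[1, 0] = 0.9       # variants 0 and 1 in strong LD
        out = mr_suite(exposure, outcome, ld_r2_matrix=r2, r2_threshold=0.1,
                       n_bootstrap=10, seed=0)
        assert out["results"]["ivw"].n_variants == 5
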