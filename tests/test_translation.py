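import numpy as np
import pandas as pd
import pytest

from clipmaps.translation import (SENSE_CODONS, TranslationError,
                                  codon_enrichment, codon_fraction_matrix,
                                  codon_fractions, feature_significance,
                                  fit_halflife_model,
                                  occupancy_vs_feature_curve,
                                  transcript_optimality)


class TestOptimality:
    table = {c: 0.5 for c in SENSE_CODONS} | {"AAA": 0.2, "GGT": 0.8}

    def test_mean_over_reading_frame(self):
        assert transcript_optimality("AAAGGT", self.table) == \
            pytest.approx(0.5)

    def test_homopolymeric_cds(self):
        assert transcript_optimality("AAAAAAAAA", self.table) == \
            pytest.approx(0.2)

    def test_length_not_divisible_by_three_rejected(self):
        with pytest.raises(TranslationError, match="divisible"):
            transcript_optimality("AAAA", self.table)

    def test_stop_codon_outside_table_named_in_error(self):
        with pytest.raises(TranslationError, match="TAA"):
            transcript_optimality("AAATAAGGT", self.table)


class TestCodonEnrichment:
    def _fractions(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        seqs = {}
        codons = np.array(SENSE_CODONS)
        for i in range(n):
            seqs[f"t{i}"] = "".join(rng.choice(codons, size=200))
        return codon_fraction_matrix(seqs)

    def test_uniform_occupancy_scores_exactly_one(self):
        F = self._fractions()
        occ = pd.Series(1.0, index=F.index)
        res = codon_enrichment(occ, F, n_boot=0)
        assert np.abs(res.scores["score"] - 1.0).max() < 1e-12

    def test_degenerate_weight_on_single_transcript(self):
        F = self._fractions(n=10)
        occ = pd.Series(0.0, index=F.index)
        occ["t3"] = 5.0
        res = codon_enrichment(occ, F, n_boot=0)
        expected = F.loc["t3"] / F.mean(axis=0)
        np.testing.assert_allclose(res.scores["score"].to_numpy(),
                                   expected.to_numpy())

    def test_weighted_conservation_identity(self):
        # averaging scores weighted by mean codon fractions gives exactly 1
        F = self._fractions(seed=4)
        rng = np.random.default_rng(5)
        occ = pd.Series(rng.random(len(F)) + 0.1, index=F.index)
        res = codon_enrichment(occ, F, n_boot=0)
        weights = F.mean(axis=0)
        total = (res.scores["score"] * weights).sum() / weights.sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_occupancy_rejected(self):
        F = self._fractions(n=5)
        with pytest.raises(TranslationError):
            codon_enrichment(pd.Series(0.0, index=F.index), F)

    def test_planted_composition_bias_detected(self):
        rng = np.random.default_rng(6)
        codons = np.array(SENSE_CODONS)
        p = np.full(len(codons), 1.0 / len(codons))
        p_rich = p.copy()
        p_rich[list(codons).index("AAA")] *= 3
        p_rich /= p_rich.sum()
        seqs = {}
        for i in range(300):
            probs = p_rich if i < 150 else p
            seqs[f"t{i}"] = "".join(rng.choice(codons, size=150, p=probs))
        F = codon_fraction_matrix(seqs)
        occ = pd.Series([3.0] * 150 + [1.0] * 150, index=F.index)
        res = codon_enrichment(occ, F, n_boot=300,
                               rng=np.random.default_rng(7))
        row = res.scores.loc["AAA"]
        assert row["score"] > 1.0 and row["ci_low"] > 1.0


class TestFeatureCurve:
    def _features(self, occ, n=200):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, size=n)
        return pd.DataFrame({"optimality": x, "occupancy": occ(x)})

    def test_constant_occupancy_gives_flat_curve(self):
        df = self._features(lambda x: np.full_like(x, 3.0))
        curve = occupancy_vs_feature_curve(df, "optimality", n_boot=0)
        np.testing.assert_allclose(curve["occupancy"], 3.0)

    def test_noise_free_monotone_relation_preserved(self):
        df = self._features(lambda x: 2.0 * x + 1.0)
        curve = occupancy_vs_feature_curve(df, "optimality", n_boot=0)
        assert (np.diff(curve["occupancy"]) >= -1e-9).all()

    def test_planted_negative_relation_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 1000)
        occ = -1.5 * x + 20 + rng.standard_normal(1000)
        df = pd.DataFrame({"optimality": x, "occupancy": occ})
        curve = occupancy_vs_feature_curve(df, "optimality", n_boot=0)
        from scipy.stats import spearmanr
        rho, _ = spearmanr(curve["optimality"], curve["occupancy"])
        assert rho <= -0.9

    def test_too_few_transcripts_rejected(self):
        df = pd.DataFrame({"optimality": range(10),
                           "occupancy": range(10)})
        with pytest.raises(TranslationError):
            occupancy_vs_feature_curve(df, "optimality")


class TestHalfLifeFit:
    def test_noise_free_exact_recovery(self):
        t = np.linspace(5, 60, 100)
        df = pd.DataFrame({"halflife": t, "occupancy": 2.0 * t + 3.0})
        fit = fit_halflife_model(df, n_boot=0)
        assert fit.a == pytest.approx(2.0)
        assert fit.b == pytest.approx(3.0)
        assert fit.ratio == pytest.approx(2.0 / 3.0)

    def test_null_slope_ci_contains_zero(self):
        rng = np.random.default_rng(3)
        t = np.exp(np.log(15) + 0.6 * rng.standard_normal(800))
        df = pd.DataFrame({"halflife": t,
                           "occupancy": 5.0 + rng.standard_normal(800)})
        fit = fit_halflife_model(df, n_boot=400, rng=rng)
        assert fit.a_ci[0] <= 0.0 <= fit.a_ci[1]

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(4)
        t = np.exp(np.log(15) + 0.6 * rng.standard_normal(300))
        occ = 0.4 * t + 2.0 + 0.1 * rng.standard_normal(300)
        df = pd.DataFrame({"halflife": t, "occupancy": occ})
        f1 = fit_halflife_model(df, n_boot=0)
        df2 = df.assign(occupancy=df["occupancy"] * 3.0)
        f2 = fit_halflife_model(df2, n_boot=0)
        assert f2.a == pytest.approx(3.0 * f1.a)
        assert f2.b == pytest.approx(3.0 * f1.b)
        assert f2.ratio == pytest.approx(f1.ratio)

    def test_parameter_recovery_with_noise(self):
        rng = np.random.default_rng(5)
        t = np.exp(np.log(15) + 0.6 * rng.standard_normal(2000))
        occ = 0.5 * t + 0.1 + 0.1 * rng.standard_normal(2000)
        df = pd.DataFrame({"halflife": t, "occupancy": occ})
        fit = fit_halflife_model(df, n_boot=300, rng=rng)
        assert abs(fit.a - 0.5) / 0.5 <= 0.1
        assert abs(fit.b - 0.1) / 0.1 <= 0.1


def _feature_frame(rng, n, beta_opt=0.0):
    X = pd.DataFrame({
        "length": np.exp(7 + 0.3 * rng.standard_normal(n)),
        "optimality": rng.uniform(0.2, 0.9, n),
        "expression": np.exp(2 + rng.standard_normal(n)),
        "halflife": np.exp(np.log(15) + 0.6 * rng.standard_normal(n)),
    })
    y = (0.002 * X["length"] + beta_opt * X["optimality"]
         + 0.2 * np.log(X["expression"]) + rng.standard_normal(n))
    X["occupancy_per_nt"] = y
    return X


class TestFeatureSignificance:
    def test_null_feature_pvalues_roughly_uniform(self):
        from scipy.stats import kstest
        rng = np.random.default_rng(6)
        ps = [feature_significance(_feature_frame(rng, 300))
              .loc["optimality", "p_value"] for _ in range(120)]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_planted_optimality_effect_dominates(self):
        rng = np.random.default_rng(7)
        sig = feature_significance(_feature_frame(rng, 2000, beta_opt=-3.0))
        assert sig.loc["optimality", "p_value"] < 1e-3
        assert sig["p_value"].idxmin() == "optimality"
        assert sig.loc["optimality", "sign"] == -1

    def test_duplicated_feature_raises_collinearity_error(self):
        rng = np.random.default_rng(8)
        X = _feature_frame(rng, 200)
        X["opt2"] = X["optimality"]
        with pytest.raises(TranslationError, match="collinear"):
            feature_significance(
                X, feature_cols=("length", "optimality", "opt2"))

    def test_lrt_matches_squared_t_statistic_asymptotics(self):
        import statsmodels.api as sm
        from scipy import stats
        rng = np.random.default_rng(9)
        X = _feature_frame(rng, 5000, beta_opt=-0.4)
        sig = feature_significance(X)
        # compare against Wald p from the full model on the same rows
        df = X.copy()
        keep = pd.Series(True, index=df.index)
        for col in ("length", "optimality", "expression", "halflife"):
            qlo, qhi = df[col].quantile([0.05, 0.95])
            keep &= (df[col] >= qlo) & (df[col] <= qhi)
        df = df[keep]
        design = sm.add_constant(df[["length", "optimality", "expression",
                                     "halflife"]])
        wald = sm.OLS(df["occupancy_per_nt"], design).fit()
        p_wald = wald.pvalues["optimality"]
        lp1 = -np.log10(sig.loc["optimality", "p_value"])
        lp2 = -np.log10(p_wald)
        assert abs(lp1 - lp2) / lp2 < 0.1
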