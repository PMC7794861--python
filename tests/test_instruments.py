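"""Instrument construction: IO, harmonization, GRS, strength, confounders."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ivmr import (build_grs, confounder_screen, harmonize,
                  impute_missing_genotypes, instrument_strength,
                  read_summary_stats, write_summary_stats)
from conftest import summary_table


class TestReadWrite:
    def test_well_formed_table_roundtrip(self, tmp_path):
        table = summary_table([
            ("rs1", "A", "G", 0.2, 0.10, 0.01, 1e-8, 1000),
            ("rs2", "C", "T", 0.4, -0.05, 0.02, 1e-4, 1000),
            ("rs3", "G", "A", 0.1, 0.02, 0.01, 0.5, 1000),
        ])
        path = tmp_path / "stats.tsv"
        write_summary_stats(table, path)
        out, exclusions = read_summary_stats(path)
        assert len(out) == 3 and exclusions.empty
        pd.testing.assert_frame_equal(out, table, check_dtype=False)

    def test_nonpositive_se_excluded_with_reason(self):
        from ivmr.instruments import validate_summary_stats
        table = summary_table([
            ("rs1", "A", "G", 0.2, 0.1, 0.0, 0.1, 10),
            ("rs2", "C", "T", 0.4, 0.1, 0.02, 0.1, 10),
        ])
        valid, excl = validate_summary_stats(table)
        assert list(valid["variant_id"]) == ["rs2"]
        assert excl.iloc[0]["reason"] == "nonpositive SE"

    def test_missing_required_column_is_hard_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("variant_id\teffect_allele\tbeta\nrs1\tA\t0.1\n")
        with pytest.raises(ValueError, match="other_allele"):
            read_summary_stats(path)

    def test_column_aliases_mapped(self):
        buf = io.StringIO("SNP\tA1\tA2\tEffect\tStdErr\nrs1\ta\tg\t0.1\t0.02\n")
        out, _ = read_summary_stats(buf)
        assert out.loc[0, "variant_id"] == "rs1"
        assert out.loc[0, "effect_allele"] == "A"   # upper-cased
        assert out.loc[0, "beta"] == pytest.approx(0.1)

    def test_unparsable_row_logged_and_skipped(self, tmp_path):
        path = tmp_path / "stats.tsv"
        path.write_text("variant_id\teffect_allele\tother_allele\tbeta\tse\n"
                        "rs1\tA\tG\tnot_a_number\t0.02\n"
                        "rs2\tC\tT\t0.1\t0.02\n")
        out, excl = read_summary_stats(path)
        assert list(out["variant_id"]) == ["rs2"]
        assert "beta" in excl.iloc[0]["reason"]


class TestHarmonize:
    def _tables(self):
        expo = summary_table([
            ("rs1", "A", "G", 0.30, 0.10, 0.01, 1e-8, 5000),
            ("rs2", "C", "T", 0.20, 0.08, 0.01, 1e-6, 5000),
            ("rs3", "A", "T", 0.50, 0.05, 0.01, 1e-4, 5000),
        ])
        outc = summary_table([
            ("rs1", "A", "G", 0.30, 0.02, 0.005, 0.01, 8000),
            ("rs2", "T", "C", 0.80, 0.10, 0.02, 0.02, 8000),
            ("rs3", "A", "T", 0.50, 0.01, 0.01, 0.5, 8000),
        ])
        return expo, outc

    def test_identical_alleles_unchanged(self):
        expo, outc = self._tables()
        h = harmonize(expo, outc)
        row = h.table.set_index("variant_id").loc["rs1"]
        assert row["gamma"] == pytest.approx(0.10)
        assert row["Gamma"] == pytest.approx(0.02)

    def test_swapped_alleles_flip_beta_and_eaf(self):
        expo, outc = self._tables()
        h = harmonize(expo, outc)
        row = h.table.set_index("variant_id").loc["rs2"]
        assert row["Gamma"] == pytest.approx(-0.10)
        assert row["eaf_outcome"] == pytest.approx(0.20)

    def test_palindromic_excluded_under_strict_policy(self):
        expo, outc = self._tables()
        h = harmonize(expo, outc)
        assert "rs3" not in set(h.table["variant_id"])
        reasons = dict(zip(h.exclusions["variant_id"], h.exclusions["reason"]))
        assert reasons["rs3"] == "palindromic"

    def test_palindromic_kept_when_eaf_unambiguous(self):
        expo = summary_table([("rs9", "A", "T", 0.20, 0.1, 0.01, 0.1, 100)])
        outc = summary_table([("rs9", "A", "T", 0.25, 0.2, 0.02, 0.1, 100)])
        h = harmonize(expo, outc, palindrome_policy="eaf-infer")
        assert list(h.table["variant_id"]) == ["rs9"]
        # ambiguous frequency near 0.5 still excluded
        outc.loc[0, "eaf"] = 0.5
        h2 = harmonize(expo, outc, palindrome_policy="eaf-infer")
        assert h2.table.empty

    def test_allele_mismatch_excluded(self):
        expo = summary_table([("rs5", "A", "C", 0.2, 0.1, 0.01, 0.1, 100)])
        outc = summary_table([("rs5", "A", "G", 0.2, 0.1, 0.01, 0.1, 100)])
        h = harmonize(expo, outc)
        assert h.table.empty
        assert h.exclusions.iloc[0]["reason"] == "allele mismatch"

    def test_conservation_every_snp_retained_or_logged(self):
        expo, outc = self._tables()
        expo = pd.concat([expo, summary_table(
            [("rs_only_e", "A", "G", 0.1, 0.1, 0.01, 0.1, 100)])],
            ignore_index=True)
        h = harmonize(expo, outc)
        seen = set(h.table["variant_id"]) | set(h.exclusions["variant_id"])
        assert seen == set(expo["variant_id"]) | set(outc["variant_id"])
        assert not (set(h.table["variant_id"])
                    & set(h.exclusions["variant_id"]))

    def test_harmonization_is_involution_safe(self):
        expo, outc = self._tables()
        h1 = harmonize(expo, outc)
        # rebuild the outcome table from the harmonized set and re-harmonize
        outc2 = summary_table([
            (r["variant_id"], r["effect_allele"], r["other_allele"],
             r["eaf_outcome"], r["Gamma"], r["se_Gamma"], 0.5, 8000)
            for _, r in h1.table.iterrows()])
        h2 = harmonize(expo, outc2)
        np.testing.assert_allclose(h2.table["Gamma"], h1.table["Gamma"])
        np.testing.assert_allclose(h2.table["gamma"], h1.table["gamma"])


class TestGRS:
    def test_zero_weights_zero_score(self):
        G = np.random.default_rng(0).binomial(2, 0.3, (10, 4))
        assert np.all(build_grs(G, np.zeros(4)) == 0)

    def test_single_snp_identity(self):
        G = np.random.default_rng(0).binomial(2, 0.3, (10, 1))
        np.testing.assert_array_equal(build_grs(G, np.array([1.0])), G[:, 0])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        G = rng.binomial(2, 0.3, (5, 4)).astype(float)
        w = rng.normal(size=4)
        expected = [sum(w[j] * G[i, j] for j in range(4)) for i in range(5)]
        np.testing.assert_allclose(build_grs(G, w), expected)

    def test_length_mismatch_and_missing_rejected(self):
        G = np.ones((5, 3))
        with pytest.raises(ValueError):
            build_grs(G, np.ones(2))
        G[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_grs(G, np.ones(3))

    def test_explicit_imputation_by_expected_dosage(self):
        G = np.array([[np.nan, 1.0], [2.0, np.nan]])
        out = impute_missing_genotypes(G, np.array([0.25, 0.4]))
        np.testing.assert_allclose(out, [[0.5, 1.0], [2.0, 0.8]])


class TestStrength:
    def test_formula_arithmetic(self):
        # n = 102, k = 1, R^2 = 0.5 -> F = 100
        rng = np.random.default_rng(1)
        # construct data with exact R^2 = 0.5 via orthogonal residual
        n = 102
        s = rng.normal(size=n)
        s = (s - s.mean()) / s.std()
        e = rng.normal(size=n)
        e -= e.mean()
        e -= s * ((e @ s) / (s @ s))   # orthogonalise against the score
        e /= e.std()
        x = s + e                                   # halves the variance
        d = instrument_strength(s, x, k=1)
        assert d.r_squared == pytest.approx(0.5, abs=1e-12)
        assert d.f_statistic == pytest.approx(100.0, abs=1e-9)

    def test_perfect_instrument_reports_infinite_f(self):
        s = np.arange(10.0)
        d = instrument_strength(s, s)
        assert d.r_squared == 1.0 and np.isinf(d.f_statistic)

    def test_degenerate_score_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            instrument_strength(np.ones(10), np.arange(10.0))

    @given(r2=st.floats(0.01, 0.95))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_f_increases_with_r_squared(self, r2):
        n, k = 200, 1
        f = (n - k - 1) / k * r2 / (1 - r2)
        f_hi = (n - k - 1) / k * (r2 + 0.01) / (1 - r2 - 0.01)
        assert f_hi > f

    def test_simulated_variance_share_recovered(self):
        # gamma tuned so the GRS explains ~0.7% of exposure variance
        from ivmr import SimulationConfig, simulate_cohort
        maf = np.full(10, 0.3)
        target = 0.007
        total_var = 4.0
        gvar = target * total_var / 10
        gamma = np.sqrt(gvar / (2 * 0.3 * 0.7)) * np.ones(10)
        cfg = SimulationConfig(
            n_individuals=100_000, n_snps=10, maf=maf, gamma=gamma,
            exposure_sd=np.sqrt(total_var * (1 - target)),
            confounder_effect_x=0.0, confounder_effect_y=0.0,
            causal_beta=0.0, baseline_logodds=-2.0, seed=23)
        data = simulate_cohort(cfg)
        grs = build_grs(data.genotypes, gamma)
        d = instrument_strength(grs, data.exposure)
        assert d.r_squared == pytest.approx(target, abs=0.002)


class TestConfounderScreen:
    def test_self_regression_unit_slope(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=500)
        cov = pd.DataFrame({"itself": (s - s.mean()) / s.std()})
        out = confounder_screen(s, cov)
        assert out.loc[0, "beta"] == pytest.approx(1.0, abs=1e-9)
        assert out.loc[0, "pvalue"] < 1e-100

    def test_known_association_recovered(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=2000)
        z = (s - s.mean()) / s.std()
        cov = pd.DataFrame({"c": 0.1 * z + rng.normal(0, 1, 2000)})
        out = confounder_screen(s, cov)
        assert abs(out.loc[0, "beta"] - 0.1) < 3 * out.loc[0, "se"]

    def test_nominal_false_positive_rate(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=300)
        flags = []
        for _ in range(200):
            cov = pd.DataFrame({"indep": rng.normal(size=300)})
            flags.append(bool(confounder_screen(s, cov)["flagged"].iloc[0]))
        rate = np.mean(flags)
        assert 0.01 <= rate <= 0.10   # ~5% nominal

    def test_constant_covariate_skipped(self):
        s = np.random.default_rng(5).normal(size=50)
        out = confounder_screen(s, pd.DataFrame({"const": np.ones(50)}))
        assert out.loc[0, "note"] == "constant covariate skipped"
        assert np.isnan(out.loc[0, "beta"])
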