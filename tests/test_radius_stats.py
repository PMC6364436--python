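import math

import numpy as np
import pandas as pd
import pytest

from conftest import label_series, locus_series
from locusgeo import radius_stats as rs
from locusgeo.encoding import apply_minmax, binary_encode, fit_minmax
from locusgeo.geometry import ALL_SPECS, all_radii
from locusgeo.io import CSNP, RSNP, ColumnSpec, ValidationError


class TestSplitByClass:
    def test_partition_sizes(self):
        radii = pd.Series(
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
            index=[f"s{i}" for i in range(8)],
        )
        labels = pd.Series(
            [RSNP] * 3 + [CSNP] * 5, index=[f"s{i}" for i in range(8)]
        )
        sets = rs.split_by_class(radii, labels)
        assert sets.rsnp.size == 3 and sets.csnp.size == 5

    def test_singletons_dropped_and_counts_conserved(self, small_dataset):
        table, records, _ = small_dataset
        enc = binary_encode(table)
        scaled = apply_minmax(enc, fit_minmax(enc))
        radii = all_radii(enc, scaled, locus_series(records))
        labels = label_series(records)
        col = radii["pearson_unscaled"]
        sets = rs.split_by_class(col, labels)
        # brute-force counting oracle
        n_nonsingleton = int(col.notna().sum())
        assert sets.rsnp.size + sets.csnp.size == n_nonsingleton
        expected_r = sum(
            1 for r in records if r.is_rsnp and not math.isnan(col[r.snp_id])
        )
        assert sets.rsnp.size == expected_r


class TestMoments:
    def test_symmetric_samples_zero_skew(self):
        skew, _ = rs.radius_moments(np.array([1.0, 2.0, 3.0]))
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_skewness(self):
        # {0,0,0,1}: m2=3/16, m3=3/32 -> g1 = (3/32)/(3/16)^1.5
        x = np.array([0.0, 0.0, 0.0, 1.0])
        skew, kurt = rs.radius_moments(x)
        m2, m3, m4 = 3 / 16, 3 / 32, 0.25 * (3 * (0.25**4) + 0.75**4)
        assert skew == pytest.approx(m3 / m2**1.5)
        assert kurt == pytest.approx(m4 / m2**2)

    def test_gaussian_monte_carlo(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(100_000)
        skew, kurt = rs.radius_moments(x)
        assert abs(skew) < 0.03
        assert kurt == pytest.approx(3.0, abs=0.1)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValidationError):
            rs.radius_moments(np.array([2.0, 2.0, 2.0]))


class TestDensity:
    def test_nonnegative_and_integrates_to_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(3.0, 1.0, size=500)
        kde = rs.radius_density(x)
        grid = np.linspace(-3, 9, 2001)
        vals = kde(grid)
        assert (vals >= 0).all()
        integral = np.trapezoid(vals, grid)
        assert 0.99 <= integral <= 1.01

    def test_mode_near_sample_mode(self):
        rng = np.random.default_rng(9)
        x = rng.normal(5.0, 0.5, size=4000)
        kde = rs.radius_density(x)
        grid = np.linspace(2, 8, 1200)
        assert grid[np.argmax(kde(grid))] == pytest.approx(5.0, abs=0.2)


class TestEmpiricalLlr:
    def test_identical_class_samples_give_zero(self):
        x = np.array([0.1, 0.4, 0.5, 0.9, 1.3, 2.0, 2.2, 3.0, 3.3, 4.0, 4.4])
        sets = rs.RadiusClassSets(rsnp=x.copy(), csnp=x.copy())
        emp = rs.empirical_llr(sets)
        occupied = (emp.counts_rsnp + emp.counts_csnp) > 0
        assert np.allclose(emp.llr[occupied], 0.0)

    def test_direct_formula_on_constructed_bins(self):
        # both classes n=4 on [0,11] with 11 unit bins; first bin holds 2 r, 1 c:
        # normalized LLR = ln((2/4)/(1/4)) = ln 2; raw-mode LR = 2
        sets = rs.RadiusClassSets(
            rsnp=np.array([0.1, 0.2, 3.5, 11.0]),
            csnp=np.array([0.5, 5.5, 7.5, 9.2]),
        )
        emp = rs.empirical_llr(sets)
        assert emp.counts_rsnp[0] == 2 and emp.counts_csnp[0] == 1
        assert emp.llr[0] == pytest.approx(math.log(2.0))
        raw = rs.empirical_llr(sets, mode="raw")
        assert raw.llr[0] == pytest.approx(math.log(2.0))  # equal class totals

    def test_normalized_vs_raw_offset_is_class_total_ratio(self):
        rng = np.random.default_rng(3)
        sets = rs.RadiusClassSets(
            rsnp=rng.normal(5, 1, size=40), csnp=rng.normal(5, 1, size=400)
        )
        norm = rs.empirical_llr(sets)
        raw = rs.empirical_llr(sets, mode="raw")
        both = ~norm.pseudocount_bins
        r_tot = norm.counts_rsnp.sum() + 0.5 * norm.pseudocount_bins.sum()
        c_tot = norm.counts_csnp.sum() + 0.5 * norm.pseudocount_bins.sum()
        np.testing.assert_allclose(
            norm.llr[both] - raw.llr[both], math.log(c_tot / r_tot), atol=1e-9
        )

    def test_separated_classes_force_llr_signs(self):
        sets = rs.RadiusClassSets(
            rsnp=np.linspace(10, 12, 30), csnp=np.linspace(0, 2, 30)
        )
        emp = rs.empirical_llr(sets)
        assert emp.llr[-1] > 0
        assert emp.llr[0] < 0

    def test_counts_conserve_totals_and_pseudocount_flags(self):
        rng = np.random.default_rng(4)
        sets = rs.RadiusClassSets(
            rsnp=rng.normal(2, 0.3, 25), csnp=rng.normal(4, 0.3, 50)
        )
        emp = rs.empirical_llr(sets)
        assert emp.counts_rsnp.sum() == 25
        assert emp.counts_csnp.sum() == 50
        assert np.isfinite(emp.llr).all()
        zero_bins = (emp.counts_rsnp == 0) | (emp.counts_csnp == 0)
        np.testing.assert_array_equal(emp.pseudocount_bins, zero_bins)

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            rs.empirical_llr(rs.RadiusClassSets(np.array([]), np.array([1.0])))


class TestParametricFits:
    def test_normal_mle_divisor_n(self):
        fit = rs.fit_radius_distribution(
            np.array([-1.0, 1.0] * 5), "normal"
        )
        assert fit.mu == pytest.approx(0.0)
        assert fit.sigma == pytest.approx(1.0)  # divisor n, not n-1

    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(123)
        samples = rng.lognormal(mean=0.0, sigma=0.5, size=5000)
        fit = rs.fit_radius_distribution(samples, "lognormal")
        assert fit.mu == pytest.approx(0.0, abs=0.05)
        assert fit.sigma == pytest.approx(0.5, abs=0.05)
        normal_fit = rs.fit_radius_distribution(samples, "normal")
        assert fit.aic < normal_fit.aic

    def test_normal_parameter_recovery_and_aic(self):
        rng = np.random.default_rng(124)
        samples = rng.normal(5.0, 0.5, size=5000)
        fit = rs.fit_radius_distribution(samples, "normal")
        assert fit.mu == pytest.approx(5.0, abs=0.05)
        assert fit.sigma == pytest.approx(0.5, abs=0.05)
        assert fit.aic < rs.fit_radius_distribution(samples, "lognormal").aic
        assert rs.select_family_by_aic(samples) == "normal"

    def test_nonpositive_samples_replaced_by_epsilon(self):
        samples = np.array([0.0, 0.0] + list(np.linspace(0.5, 2.0, 20)))
        fit = rs.fit_radius_distribution(samples, "lognormal")
        assert np.isfinite(fit.mu) and np.isfinite(fit.aic)

    def test_too_few_or_constant_samples_rejected(self):
        with pytest.raises(ValidationError):
            rs.fit_radius_distribution(np.ones(5), "normal")
        with pytest.raises(ValidationError):
            rs.fit_radius_distribution(np.full(20, 3.0), "lognormal")


class TestDefaultFamilies:
    def test_family_assignment(self):
        fam = rs.default_families()
        assert len(fam) == 10
        assert fam["pearson_unscaled"] == "normal"
        assert fam["cosine_scaled"] == "normal"
        assert fam["canberra_scaled"] == "lognormal"
        assert fam["euclidean_unscaled"] == "lognormal"
        assert fam["manhattan_unscaled"] == "lognormal"

    def test_auto_mode_selects_generating_family(self):
        rng = np.random.default_rng(6)
        assert rs.select_family_by_aic(rng.lognormal(0, 0.8, 3000)) == "lognormal"


def _fit(key, label, family, mu, sigma):
    return rs.RadiusDistFit(
        spec_key=key, label=label, family=family, mu=mu, sigma=sigma, aic=0.0, n=100
    )


class TestLlrFeatures:
    def _radii(self, values):
        return pd.DataFrame(
            {"pearson_unscaled": values},
            index=pd.Index([f"s{i}" for i in range(len(values))]),
        )

    def test_singleton_snps_get_zero_in_all_columns(self):
        radii = pd.DataFrame(
            {spec.key: [np.nan, 1.0] for spec in ALL_SPECS},
            index=pd.Index(["lone", "paired"]),
        )
        fits = {
            spec.key: (
                _fit(spec.key, "rSNP", "normal", 1.5, 0.4),
                _fit(spec.key, "cSNP", "normal", 0.8, 0.4),
            )
            for spec in ALL_SPECS
        }
        block = rs.llr_features(radii, fits)
        assert block.shape == (2, 10)
        assert (block.loc["lone"] == 0.0).all()
        assert (block.loc["paired"] != 0.0).all()

    def test_identical_fits_give_zero_everywhere(self):
        radii = self._radii([0.5, 1.0, 1.5])
        f = _fit("pearson_unscaled", "rSNP", "normal", 1.0, 0.3)
        block = rs.llr_features(radii, {"pearson_unscaled": (f, f)})
        assert (block.to_numpy() == 0.0).all()

    def test_closed_form_normal_llr_hits_clamp_boundary(self):
        # ln φ(1; 1, 0.1) − ln φ(1; 0, 0.1) = (1)^2 / (2·0.01) = 50 exactly
        radii = self._radii([1.0])
        fits = {
            "pearson_unscaled": (
                _fit("pearson_unscaled", "rSNP", "normal", 1.0, 0.1),
                _fit("pearson_unscaled", "cSNP", "normal", 0.0, 0.1),
            )
        }
        block = rs.llr_features(radii, fits)
        assert block.iloc[0, 0] == pytest.approx(50.0)

    def test_far_tail_values_clamped(self):
        radii = self._radii([10.0])
        fits = {
            "pearson_unscaled": (
                _fit("pearson_unscaled", "rSNP", "normal", 10.0, 0.01),
                _fit("pearson_unscaled", "cSNP", "normal", 0.0, 0.01),
            )
        }
        block = rs.llr_features(radii, fits)
        assert block.iloc[0, 0] == 50.0

    def test_monotone_in_radius_for_shifted_equal_scale_fits(self):
        grid = np.linspace(0.1, 5.0, 200)
        for family, mus in (("normal", (2.0, 1.0)), ("lognormal", (0.5, 0.0))):
            fits = {
                "pearson_unscaled": (
                    _fit("pearson_unscaled", "rSNP", family, mus[0], 0.4),
                    _fit("pearson_unscaled", "cSNP", family, mus[1], 0.4),
                )
            }
            block = rs.llr_features(self._radii(grid), fits)
            vals = block.iloc[:, 0].to_numpy()
            assert (np.diff(vals) >= -1e-12).all(), family

    def test_missing_fit_rejected(self):
        with pytest.raises(ValidationError):
            rs.llr_features(self._radii([1.0]), {})


class TestAppendLlr:
    def test_column_count_and_provenance(self, small_dataset):
        table, records, _ = small_dataset
        enc = binary_encode(table)
        scaled = apply_minmax(enc, fit_minmax(enc))
        radii = all_radii(enc, scaled, locus_series(records))
        fits = rs.fit_class_conditionals(radii, label_series(records))
        block = rs.llr_features(radii, fits)
        out = rs.append_llr(table, block)
        assert out.n_features == table.n_features + 10
        llr_cols = [c for c in out.schema if c.startswith(rs.LLR_PREFIX)]
        assert len(llr_cols) == 10
        assert all(out.schema[c].kind == "continuous" for c in llr_cols)
        # base columns unchanged
        pd.testing.assert_frame_equal(out.data[table.data.columns], table.data)

    def test_misalignment_rejected(self, tiny_table):
        table, _ = tiny_table
        block = pd.DataFrame({"LLR_x": [0.0]}, index=pd.Index(["nope"]))
        with pytest.raises(ValidationError):
            rs.append_llr(table, block)


class TestLeakageDiscipline:
    def test_validation_labels_cannot_touch_training_fits(self, small_dataset):
        """Permuting validation labels leaves fits and validation LLRs bit-identical."""
        table, records, _ = small_dataset
        enc = binary_encode(table)
        scaled = apply_minmax(enc, fit_minmax(enc))
        loci = locus_series(records)
        radii = all_radii(enc, scaled, loci)
        labels = label_series(records)
        locus_ids = sorted({r.locus_id for r in records})
        train_loci = set(locus_ids[: len(locus_ids) // 2])
        train_ids = pd.Index([r.snp_id for r in records if r.locus_id in train_loci])
        val_ids = pd.Index([r.snp_id for r in records if r.locus_id not in train_loci])

        permuted = labels.copy()
        rng = np.random.default_rng(0)
        permuted.loc[val_ids] = rng.permutation(permuted.loc[val_ids].to_numpy())

        fits_a = rs.fit_class_conditionals(radii, labels, fit_subset=train_ids)
        fits_b = rs.fit_class_conditionals(radii, permuted, fit_subset=train_ids)
        for key in fits_a:
            for fa, fb in zip(fits_a[key], fits_b[key]):
                assert (fa.mu, fa.sigma, fa.aic, fa.n) == (fb.mu, fb.sigma, fb.aic, fb.n)
        llr_a = rs.llr_features(radii.loc[val_ids], fits_a)
        llr_b = rs.llr_features(radii.loc[val_ids], fits_b)
        assert (llr_a.to_numpy() == llr_b.to_numpy()).all()
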