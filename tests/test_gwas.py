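import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from conftest import make_genotypes, make_map

from namqtl import gwas, simulate as sim


def brute_force_holm(pvalues):
    """Independent step-down oracle: sort, scale by (m - i), cumulative max."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, p[idx] * (m - rank))
        adjusted[idx] = min(running, 1.0)
    return adjusted


class TestSchwarzCriterion:
    def test_unit_rss_ratio(self):
        assert gwas.schwarz_criterion(100.0, 100, 2) == pytest.approx(
            2 * math.log(100)
        )

    def test_useless_predictor_costs_log_n(self):
        base = gwas.schwarz_criterion(40.0, 200, 3)
        assert gwas.schwarz_criterion(40.0, 200, 4) == pytest.approx(
            base + math.log(200)
        )

    def test_direct_evaluation(self):
        assert gwas.schwarz_criterion(25.0, 50, 3) == pytest.approx(
            50 * math.log(0.5) + 3 * math.log(50)
        )

    def test_perfect_fit_short_circuits(self):
        assert gwas.schwarz_criterion(0.0, 50, 3) == -math.inf

    def test_preconditions(self):
        with pytest.raises(ValueError):
            gwas.schwarz_criterion(1.0, 5, 5)
        with pytest.raises(ValueError):
            gwas.schwarz_criterion(1.0, 5, 0)


class TestHolmAdjust:
    def test_worked_example(self):
        adjusted, sig = gwas.holm_adjust([0.01, 0.03, 0.04])
        assert np.allclose(adjusted, [0.03, 0.06, 0.06])
        assert sig.tolist() == [True, False, False]

    def test_single_pvalue(self):
        adjusted, _ = gwas.holm_adjust([0.04])
        assert adjusted[0] == pytest.approx(0.04)

    def test_all_ones(self):
        adjusted, sig = gwas.holm_adjust([1.0, 1.0, 1.0])
        assert np.allclose(adjusted, 1.0)
        assert not sig.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gwas.holm_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            gwas.holm_adjust([-0.1])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        adjusted, _ = gwas.holm_adjust(p)
        assert (adjusted >= p - 1e-15).all()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            adjusted, _ = gwas.holm_adjust(p)
            assert np.array_equal(adjusted, brute_force_holm(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = rng.uniform(size=100)
        adjusted, sig = gwas.holm_adjust(p)
        reject, corrected, _, _ = multipletests(p, alpha=0.05, method="holm")
        assert np.allclose(adjusted, corrected)
        assert np.array_equal(sig, reject)


class TestImputation:
    def test_family_mean_fill(self):
        geno = make_genotypes(
            [[0, 2], [2, np.nan], [np.nan, 0], [1, 1]],
            families=["A", "A", "B", "B"],
        )
        filled = gwas.impute_family_mean(geno)
        assert filled[1, 1] == pytest.approx(2.0)  # family A mean at m1
        assert filled[2, 0] == pytest.approx(1.0)  # family B mean at m0
        assert not np.isnan(filled).any()

    def test_no_missing_passthrough(self):
        geno = make_genotypes([[0, 1], [2, 1]])
        assert np.array_equal(gwas.impute_family_mean(geno), geno.dosage)


class TestSelectCofactors:
    def test_large_effect_marker_selected_first(self, qtl_trait, small_map):
        pop, model, blues = qtl_trait
        cof = gwas.select_cofactors(pop, blues, gmap=small_map)
        truth = {small_map.marker_ids[i] for i in model.marker_indices}
        assert cof.markers[0] in truth

    def test_sbc_trajectory_strictly_decreasing(self, qtl_trait, small_map):
        pop, _, blues = qtl_trait
        cof = gwas.select_cofactors(pop, blues, gmap=small_map)
        diffs = np.diff(cof.sbc_trajectory)
        assert (diffs < 0).all()

    def test_duplicate_column_never_selected(self):
        rng = np.random.default_rng(15)
        n = 200
        causal = rng.integers(0, 3, n).astype(float)
        noise = rng.integers(0, 3, (n, 3)).astype(float)
        dosage = np.column_stack([causal, causal, noise])
        geno = make_genotypes(dosage, marker_ids=["dup1", "dup2", "a", "b", "c"])
        y = pd.Series(3.0 * causal + rng.normal(0, 1, n), index=geno.line_ids)
        cof = gwas.select_cofactors(geno, y)
        assert len(set(cof.markers) & {"dup1", "dup2"}) == 1

    def test_null_trait_near_empty_set(self):
        # Forward SBC selection admits the occasional noise marker (the
        # best of m chi-square gains can beat the ln(n) penalty), but null
        # cofactor sets stay near-empty relative to the candidate pool.
        selected = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            dosage = rng.integers(0, 3, (300, 100)).astype(float)
            geno = make_genotypes(dosage)
            y = pd.Series(rng.normal(size=300), index=geno.line_ids)
            selected.append(len(gwas.select_cofactors(geno, y)))
        assert np.mean(selected) < 3
        assert max(selected) <= 6

    def test_deterministic(self, qtl_trait, small_map):
        pop, _, blues = qtl_trait
        a = gwas.select_cofactors(pop, blues, gmap=small_map)
        b = gwas.select_cofactors(pop, blues, gmap=small_map)
        assert a.markers == b.markers


class TestScanGenome:
    def test_noise_free_linear_trait(self):
        rng = np.random.default_rng(21)
        dosage = rng.integers(0, 3, (100, 4)).astype(float)
        geno = make_genotypes(dosage)
        gmap = make_map(geno.marker_ids, ["chr1"] * 4, [0.0, 10.0, 20.0, 30.0])
        y = pd.Series(5.0 * dosage[:, 2], index=geno.line_ids)
        scan = gwas.scan_genome(geno, y, gmap=gmap)
        row = scan[scan["marker"] == "m2"].iloc[0]
        assert row["beta"] == pytest.approx(5.0, abs=1e-8)
        assert row["effect_2beta"] == pytest.approx(10.0, abs=1e-8)
        assert row["p_raw"] < 1e-30

    def test_self_exclusion_of_cofactor(self, qtl_trait, small_map):
        pop, model, blues = qtl_trait
        cof = gwas.select_cofactors(pop, blues, gmap=small_map)
        scan = gwas.scan_genome(pop, blues, cofactors=cof, gmap=small_map)
        for marker in cof.markers:
            row = scan[scan["marker"] == marker].iloc[0]
            assert marker in row["excluded_cofactors"].split(",")
            assert np.isfinite(row["beta"])

    def test_exclusion_window_boundary(self):
        # Cofactor at 0.5 cM is excluded, at exactly 1.0 cM retained.
        rng = np.random.default_rng(22)
        dosage = rng.integers(0, 3, (150, 3)).astype(float)
        geno = make_genotypes(dosage, marker_ids=["t", "near", "far"])
        gmap = make_map(["t", "near", "far"], ["chr1"] * 3, [10.0, 10.5, 11.0])
        y = pd.Series(rng.normal(size=150), index=geno.line_ids)
        cof = gwas.CofactorSet(markers=("near", "far"), sbc_trajectory=(0.0,))
        scan = gwas.scan_genome(geno, y, cofactors=cof, gmap=gmap)
        excluded = scan[scan["marker"] == "t"]["excluded_cofactors"].iloc[0]
        assert excluded == "near"

    def test_cross_chromosome_cofactors_always_retained(self):
        rng = np.random.default_rng(23)
        dosage = rng.integers(0, 3, (150, 2)).astype(float)
        geno = make_genotypes(dosage, marker_ids=["t", "other"])
        gmap = make_map(["t", "other"], ["chr1", "chr2"], [10.0, 10.0])
        y = pd.Series(rng.normal(size=150), index=geno.line_ids)
        cof = gwas.CofactorSet(markers=("other",), sbc_trajectory=(0.0,))
        scan = gwas.scan_genome(geno, y, cofactors=cof, gmap=gmap)
        assert scan[scan["marker"] == "t"]["excluded_cofactors"].iloc[0] == ""

    def test_monomorphic_marker_untested(self):
        rng = np.random.default_rng(24)
        dosage = np.column_stack(
            [np.zeros(80), rng.integers(0, 3, 80).astype(float)]
        )
        geno = make_genotypes(dosage)
        gmap = make_map(geno.marker_ids, ["chr1", "chr1"], [0.0, 5.0])
        y = pd.Series(rng.normal(size=80), index=geno.line_ids)
        scan = gwas.scan_genome(geno, y, gmap=gmap)
        assert not scan.loc[scan["marker"] == "m0", "tested"].iloc[0]
        assert np.isnan(scan.loc[scan["marker"] == "m0", "p_holm"].iloc[0])

    def test_adjusted_at_least_raw(self, qtl_trait, small_map):
        pop, _, blues = qtl_trait
        scan = gwas.scan_genome(pop, blues, gmap=small_map)
        tested = scan[scan["tested"]]
        assert (tested["p_holm"] >= tested["p_raw"] - 1e-15).all()
        assert tested["r2"].between(0, 1).all()

    def test_null_pvalues_uniform(self):
        # Global null with independent markers: raw p-values ~ U(0, 1).
        rng = np.random.default_rng(25)
        n, m = 500, 120
        dosage = rng.integers(0, 3, (n, m)).astype(float)
        geno = make_genotypes(dosage, families=["A"] * (n // 2) + ["B"] * (n // 2))
        gmap = make_map(
            geno.marker_ids, ["chr1"] * m, np.arange(m, dtype=float)
        )
        y = pd.Series(rng.normal(size=n), index=geno.line_ids)
        scan = gwas.scan_genome(geno, y, gmap=gmap)
        stat = scipy.stats.kstest(scan["p_raw"], "uniform")
        assert stat.pvalue > 0.01

    def test_beta_unbiased_over_replicates(self):
        # Mean estimate over replicates within 2 SE of the true coefficient.
        true_beta = 1.5
        estimates = []
        rng = np.random.default_rng(26)
        for _ in range(100):
            dosage = rng.integers(0, 3, (120, 5)).astype(float)
            geno = make_genotypes(dosage)
            gmap = make_map(
                geno.marker_ids, ["chr1"] * 5, np.arange(5, dtype=float) * 30
            )
            y = pd.Series(
                true_beta * dosage[:, 2] + rng.normal(0, 1, 120),
                index=geno.line_ids,
            )
            scan = gwas.scan_genome(geno, y, gmap=gmap)
            estimates.append(scan.loc[scan["marker"] == "m2", "beta"].iloc[0])
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - true_beta) < 2 * se

    def test_monomorphic_families_do_not_shift_beta(self):
        # With family effects in the model, lines of families where the
        # marker is monomorphic carry no information about its slope.
        rng = np.random.default_rng(27)
        n_per = 60
        seg = rng.integers(0, 3, n_per).astype(float)
        dosage_a = np.column_stack([seg, rng.integers(0, 3, n_per).astype(float)])
        dosage_b = np.column_stack(
            [np.zeros(n_per), rng.integers(0, 3, n_per).astype(float)]
        )
        geno = make_genotypes(
            np.vstack([dosage_a, dosage_b]),
            families=["A"] * n_per + ["B"] * n_per,
        )
        gmap = make_map(geno.marker_ids, ["chr1", "chr1"], [0.0, 50.0])
        y_values = np.concatenate(
            [2.0 * seg + rng.normal(0, 1, n_per), 5.0 + rng.normal(0, 1, n_per)]
        )
        y = pd.Series(y_values, index=geno.line_ids)
        full = gwas.scan_genome(geno, y, gmap=gmap)
        sub_idx = np.arange(n_per)
        sub = geno.subset_lines(sub_idx)
        reduced = gwas.scan_genome(sub, y.iloc[sub_idx], gmap=gmap)
        beta_full = full.loc[full["marker"] == "m0", "beta"].iloc[0]
        beta_reduced = reduced.loc[reduced["marker"] == "m0", "beta"].iloc[0]
        assert beta_full == pytest.approx(beta_reduced, abs=1e-10)


class TestSingleMarkerR2:
    def test_exact_linear_function(self):
        rng = np.random.default_rng(31)
        dosage = rng.integers(0, 3, (60, 2)).astype(float)
        geno = make_genotypes(dosage)
        y = pd.Series(4.0 - 2.0 * dosage[:, 0], index=geno.line_ids)
        assert gwas.single_marker_r2(geno, y, "m0") == pytest.approx(1.0)

    def test_independent_trait_near_zero(self):
        rng = np.random.default_rng(32)
        n = 2000
        dosage = rng.integers(0, 3, (n, 1)).astype(float)
        geno = make_genotypes(dosage)
        y = pd.Series(rng.normal(size=n), index=geno.line_ids)
        assert gwas.single_marker_r2(geno, y, "m0") < 10 / n * 3

    def test_bounds(self, qtl_trait):
        pop, _, blues = qtl_trait
        for marker in pop.marker_ids[:10]:
            if np.std(pop.dosage[:, pop.marker_ids.index(marker)]) == 0:
                continue
            r2 = gwas.single_marker_r2(pop, blues, marker)
            assert 0.0 <= r2 <= 1.0

    def test_monomorphic_rejected(self):
        geno = make_genotypes([[0.0], [0.0], [0.0]])
        y = pd.Series([1.0, 2.0, 3.0], index=geno.line_ids)
        with pytest.raises(ValueError):
            gwas.single_marker_r2(geno, y, "m0")


class TestFamilyNestedEffects:
    def test_single_segregating_family(self):
        rng = np.random.default_rng(41)
        n_fam, n_per = 5, 30
        blocks, families = [], []
        for f in range(n_fam):
            col = (
                rng.integers(0, 3, n_per).astype(float)
                if f == 0
                else np.zeros(n_per)
            )
            blocks.append(col)
            families += [f"F{f}"] * n_per
        geno = make_genotypes(np.concatenate(blocks)[:, None], families=families)
        y = pd.Series(rng.normal(size=n_fam * n_per), index=geno.line_ids)
        effects = gwas.family_nested_effects(geno, y, marker="m0")
        assert effects["estimable"].sum() == 1
        assert (~effects["estimable"]).sum() == n_fam - 1

    def test_family_specific_effect_recovered(self):
        rng = np.random.default_rng(42)
        n_per = 50
        d_a = rng.integers(0, 3, n_per).astype(float)
        d_b = rng.integers(0, 3, n_per).astype(float)
        geno = make_genotypes(
            np.concatenate([d_a, d_b])[:, None],
            families=["A"] * n_per + ["B"] * n_per,
        )
        y = pd.Series(
            np.concatenate([8.0 * d_a, np.zeros(n_per)]), index=geno.line_ids
        )
        effects = gwas.family_nested_effects(geno, y, marker="m0").set_index("family")
        assert effects.loc["A", "beta"] == pytest.approx(8.0)
        assert effects.loc["B", "beta"] == pytest.approx(0.0, abs=1e-10)

    def test_pooled_beta_is_sxx_weighted_combination(self):
        # With family intercepts, the common-slope OLS estimate equals
        # sum_f Sxy_f / sum_f Sxx_f: the Sxx-weighted mean of family slopes.
        rng = np.random.default_rng(43)
        n_per = 40
        d = [rng.integers(0, 3, n_per).astype(float) for _ in range(3)]
        geno = make_genotypes(
            np.concatenate(d)[:, None],
            families=["A"] * n_per + ["B"] * n_per + ["C"] * n_per,
        )
        y_vals = np.concatenate(
            [2.0 * d[0], -1.0 * d[1] + 5.0, 0.5 * d[2]]
        ) + rng.normal(0, 0.3, 3 * n_per)
        y = pd.Series(y_vals, index=geno.line_ids)
        nested = gwas.family_nested_effects(geno, y, marker="m0").set_index("family")
        sxx = {}
        sxy = {}
        for fam, dosage_block in zip("ABC", d):
            sel = np.asarray(geno.families) == fam
            v = y_vals[sel]
            sxx[fam] = ((dosage_block - dosage_block.mean()) ** 2).sum()
            sxy[fam] = ((dosage_block - dosage_block.mean()) * (v - v.mean())).sum()
        pooled_oracle = sum(sxy.values()) / sum(sxx.values())
        weighted = sum(
            nested.loc[f, "beta"] * sxx[f] for f in "ABC"
        ) / sum(sxx.values())
        assert weighted == pytest.approx(pooled_oracle)
        # and the oracle matches an explicit pooled OLS fit
        base, _ = gwas.family_design(geno.families)
        x = np.column_stack([base, geno.dosage[:, 0]])
        coef, *_ = np.linalg.lstsq(x, y_vals, rcond=None)
        assert coef[-1] == pytest.approx(pooled_oracle)

    def test_everywhere_monomorphic_rejected(self):
        geno = make_genotypes(np.zeros((10, 1)), families=["A"] * 5 + ["B"] * 5)
        y = pd.Series(np.arange(10.0), index=geno.line_ids)
        with pytest.raises(ValueError):
            gwas.family_nested_effects(geno, y, marker="m0")
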