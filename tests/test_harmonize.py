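"""Panel filtering, allele harmonisation, dosages, scores, and
instrument-strength arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from edumr.harmonize import (
    EDUCATION_VARIANTS_NOT_IN_HRC,
    MYOPIA_VARIANTS_NOT_IN_HRC,
    AlleleScore,
    Orientation,
    VariantPanel,
    build_allele_score,
    demo_education_panel,
    demo_myopia_panel,
    f_from_partial_r2,
    filter_to_reference,
    harmonize_effect_allele,
    hrc_reference_ids,
    probabilities_to_dosage,
    score_strength,
    synthetic_panel,
)
from edumr.simulate import GenotypeMatrix, simulate_genotypes


def _hard_call_matrix(dosages, effect="A", other="G", rsids=None):
    """GenotypeMatrix from integer hard calls, one row per participant."""
    d = np.atleast_2d(np.asarray(dosages))
    n, m = d.shape
    probs = np.zeros((n, m, 3))
    for g in range(3):
        probs[:, :, g] = d == g
    rsids = rsids or [f"rs{i}" for i in range(m)]
    return GenotypeMatrix(
        np.array([f"P{i}" for i in range(n)]),
        np.array(rsids),
        probs,
        np.array([effect] * m),
        np.array([other] * m),
    )


class TestFilterToReference:
    def test_myopia_panel_drops_six_non_hrc_variants(self, rng):
        panel = demo_myopia_panel(rng)
        assert len(panel) == 50
        kept, excluded = filter_to_reference(panel, hrc_reference_ids(panel))
        assert len(kept) == 44
        assert sorted(excluded) == sorted(MYOPIA_VARIANTS_NOT_IN_HRC)

    def test_education_panel_drops_five_non_hrc_variants(self, rng):
        panel = demo_education_panel(rng)
        assert len(panel) == 74
        kept, excluded = filter_to_reference(panel, hrc_reference_ids(panel))
        assert len(kept) == 69
        assert sorted(excluded) == sorted(EDUCATION_VARIANTS_NOT_IN_HRC)

    def test_full_reference_is_identity(self, rng):
        panel = synthetic_panel(10, "test", rng)
        kept, excluded = filter_to_reference(panel, set(panel.rsids))
        assert kept.rsids == panel.rsids
        assert excluded == []

    def test_kept_plus_excluded_conserves_entries(self, rng):
        panel = synthetic_panel(20, "test", rng)
        ref = set(panel.rsids[::2])
        kept, excluded = filter_to_reference(panel, ref)
        assert len(kept) + len(excluded) == len(panel)

    def test_empty_result_raises(self, rng):
        panel = synthetic_panel(5, "test", rng)
        with pytest.raises(ValueError, match="no instruments"):
            filter_to_reference(panel, {"rs0"})


class TestDosage:
    @pytest.mark.parametrize(
        "triple,expected",
        [((1, 0, 0), 0.0), ((0, 0, 1), 2.0), ((0.1, 0.5, 0.4), 1.3), ((0, 1, 0), 1.0)],
    )
    def test_values(self, triple, expected):
        assert probabilities_to_dosage(triple) == pytest.approx(expected)

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            probabilities_to_dosage((-0.1, 0.6, 0.5))

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            probabilities_to_dosage((0.5, 0.5, 0.5))


class TestHarmonizeEffectAllele:
    def test_matching_alleles_same(self):
        assert harmonize_effect_allele("A", "G", "A", "G")[0] is Orientation.SAME

    def test_swapped_alleles_flip(self):
        assert harmonize_effect_allele("A", "G", "G", "A")[0] is Orientation.FLIP

    def test_strand_flip_resolved_by_complement(self):
        # panel A/G on the other strand reads T/C
        assert harmonize_effect_allele("A", "G", "T", "C")[0] is Orientation.SAME
        assert harmonize_effect_allele("A", "G", "C", "T")[0] is Orientation.FLIP

    def test_palindromic_near_half_frequency_dropped(self):
        # Both strand readings of an A/T variant are A/T, so at ~50%
        # frequency neither the alleles nor the frequency identify the
        # orientation: SAME and FLIP are indistinguishable.
        orient, reason = harmonize_effect_allele("A", "T", "A", "T", cohort_eaf=0.49)
        assert orient is Orientation.DROP
        assert "palindromic" in reason

    def test_palindromic_far_from_half_kept(self):
        assert (
            harmonize_effect_allele("A", "T", "A", "T", cohort_eaf=0.2)[0]
            is Orientation.SAME
        )

    def test_inconsistent_allele_sets_dropped(self):
        orient, reason = harmonize_effect_allele("A", "G", "A", "T")
        assert orient is Orientation.DROP
        assert "inconsistent" in reason


class TestAlleleScore:
    def test_single_variant_score(self):
        gm = _hard_call_matrix([[0], [1], [2]])
        panel = VariantPanel(
            pd.DataFrame(
                {"rsid": ["rs0"], "effect_allele": ["A"], "other_allele": ["G"],
                 "weight": [0.5]}
            )
        )
        score = build_allele_score(gm, panel)
        np.testing.assert_allclose(score.values, [0.0, 0.5, 1.0])

    def test_zero_weights_zero_score(self, rng):
        panel = synthetic_panel(4, "t", rng)
        panel = panel.with_weights(np.zeros(4))
        gm = simulate_genotypes(30, panel, (0.1, 0.5), rng)
        np.testing.assert_allclose(build_allele_score(gm, panel).values, 0.0)

    def test_matches_brute_force_sum(self, rng):
        dosages = rng.integers(0, 3, size=(8, 3))
        weights = np.array([0.2, -0.4, 1.1])
        gm = _hard_call_matrix(dosages)
        panel = VariantPanel(
            pd.DataFrame(
                {"rsid": ["rs0", "rs1", "rs2"], "effect_allele": "A",
                 "other_allele": "G", "weight": weights}
            )
        )
        expected = [sum(w * d for w, d in zip(weights, row)) for row in dosages]
        np.testing.assert_allclose(build_allele_score(gm, panel).values, expected)

    def test_missing_variant_raises_with_rsids(self, rng):
        panel = synthetic_panel(3, "t", rng)
        gm = simulate_genotypes(10, panel, (0.2, 0.4), rng)
        bigger = VariantPanel(
            pd.concat(
                [panel.df,
                 pd.DataFrame({"rsid": ["rsMISSING"], "effect_allele": ["A"],
                               "other_allele": ["G"], "weight": [1.0]})],
                ignore_index=True,
            )
        )
        with pytest.raises(ValueError, match="rsMISSING"):
            build_allele_score(gm, bigger)

    def test_missing_dosage_imputed_with_twice_eaf(self):
        gm = _hard_call_matrix([[2], [2], [0], [0]])
        gm.probabilities[0, 0, :] = np.nan
        panel = VariantPanel(
            pd.DataFrame({"rsid": ["rs0"], "effect_allele": ["A"],
                          "other_allele": ["G"], "weight": [1.0]})
        )
        score = build_allele_score(gm, panel)
        # eaf from the three observed dosages {2, 0, 0} -> 1/3
        assert score.values[0] == pytest.approx(2 * (1 / 3))

    def test_score_linear_over_disjoint_panels(self, rng):
        p1 = synthetic_panel(3, "a", rng, rsid_start=100)
        p2 = synthetic_panel(4, "b", rng, rsid_start=200)
        union = VariantPanel(pd.concat([p1.df, p2.df], ignore_index=True), "u")
        gm = simulate_genotypes(50, union, (0.1, 0.5), rng)
        s_union = build_allele_score(gm, union).values
        s_sum = build_allele_score(gm, p1).values + build_allele_score(gm, p2).values
        np.testing.assert_allclose(s_union, s_sum, atol=1e-12)

    def test_flip_every_allele_preserves_correlation_magnitude(self, rng):
        panel = synthetic_panel(6, "t", rng)
        gm = simulate_genotypes(400, panel, (0.1, 0.5), rng)
        s = build_allele_score(gm, panel).values
        flipped_df = panel.df.rename(
            columns={"effect_allele": "other_allele", "other_allele": "effect_allele"}
        )
        s_flip = build_allele_score(gm, VariantPanel(flipped_df)).values
        # flipped score is the affine image 2*sum(w) - S
        np.testing.assert_allclose(s_flip, 2 * panel.weights.sum() - s, atol=1e-10)
        pheno = s + rng.normal(0, 1, len(s))
        assert abs(np.corrcoef(s, pheno)[0, 1]) == pytest.approx(
            abs(np.corrcoef(s_flip, pheno)[0, 1]), abs=1e-12
        )


class TestScoreStrength:
    def test_perfect_fit_gives_unit_r2_and_inf_f(self, rng):
        s = rng.normal(0, 1, 100)
        r2, f = score_strength(s, s.copy())
        assert r2 == pytest.approx(1.0)
        assert np.isinf(f)

    def test_f_from_printed_r2_and_n(self):
        # partial R2 of 4.32% at n=69798 with age+sex covariates
        f = f_from_partial_r2(0.0432, 69_798, n_covariates=2)
        assert f == pytest.approx(3155, rel=0.005)

    def test_null_score_f_calibrated(self, rng):
        n, reps = 2000, 300
        crit = stats.f.ppf(0.95, 1, n - 2)
        exceed = 0
        for _ in range(reps):
            s = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n)
            _, f = score_strength(s, y)
            exceed += f > crit
        # expect ~5% exceedances; binomial 99% bounds for 300 reps
        assert 0.02 < exceed / reps < 0.09

    def test_constant_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            score_strength(np.ones(50), rng.normal(0, 1, 50))


class TestPanelIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        panel = synthetic_panel(7, "myopia_23andme", rng)
        path = tmp_path / "panel.tsv"
        panel.to_tsv(path)
        back = VariantPanel.from_tsv(path, "myopia_23andme")
        pd.testing.assert_frame_equal(panel.df, back.df)

    def test_duplicate_rsids_rejected(self):
        df = pd.DataFrame(
            {"rsid": ["rs1", "rs1"], "effect_allele": "A", "other_allele": "G",
             "weight": [0.1, 0.2]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            VariantPanel(df)

    def test_nonfinite_weight_rejected(self):
        df = pd.DataFrame(
            {"rsid": ["rs1"], "effect_allele": "A", "other_allele": "G",
             "weight": [np.inf]}
        )
        with pytest.raises(ValueError, match="finite"):
            VariantPanel(df)
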