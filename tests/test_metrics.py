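"""Tests for the per-variant accuracy metrics and coverage summaries."""

import numpy as np
import pandas as pd
import pytest

import covpower as cp
from covpower.metrics import MIN_MINOR_ALLELE_COPIES

from oracles import (
    concordance_by_loop,
    ma_concordance_by_pairs,
    pearson_r2_by_sums,
)


def _tiny_panel(haps: np.ndarray, group: str = "G") -> cp.HaplotypePanel:
    n = haps.shape[0] // 2
    L = haps.shape[1]
    samples = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n)], "population": "P", "ancestry_group": group}
    )
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, L + 1) * 10,
            "variant_id": [f"v{j}" for j in range(L)],
            "ref": "A",
            "alt": "C",
        }
    )
    return cp.HaplotypePanel(samples=samples, variants=variants, haplotypes=haps.astype(np.uint8))


class TestGroupAlleleStats:
    def test_singleton_fails_downstream_filter(self):
        haps = np.zeros((10, 1), dtype=np.uint8)
        haps[3, 0] = 1  # alt count 1 of 10
        stats = cp.group_allele_stats(_tiny_panel(haps), "G")
        assert stats.maf.iloc[0] == pytest.approx(0.1)
        assert stats.mac.iloc[0] == 1 < MIN_MINOR_ALLELE_COPIES

    def test_major_alt_resolves_minor_to_ref(self):
        haps = np.zeros((10, 1), dtype=np.uint8)
        haps[:7, 0] = 1  # alt frequency 0.7
        stats = cp.group_allele_stats(_tiny_panel(haps), "G")
        assert not stats.minor_is_alt.iloc[0]
        assert stats.maf.iloc[0] == pytest.approx(0.3)

    def test_tie_resolves_minor_to_alt(self):
        haps = np.zeros((10, 1), dtype=np.uint8)
        haps[:5, 0] = 1
        stats = cp.group_allele_stats(_tiny_panel(haps), "G")
        assert stats.minor_is_alt.iloc[0]
        assert stats.maf.iloc[0] == pytest.approx(0.5)

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            cp.group_allele_stats(_tiny_panel(np.zeros((4, 2), dtype=np.uint8)), "nope")


class TestImputationR2:
    def test_perfect_linear_relation(self):
        assert cp.imputation_r2([0, 1, 2, 1], [0.0, 0.5, 1.0, 0.5]) == pytest.approx(1.0)

    def test_constant_imputed_returns_zero(self):
        assert cp.imputation_r2([0, 1, 2, 1], [1, 1, 1, 1]) == 0.0

    def test_derived_value_matches_definitional_sums(self):
        obs, imp = [0, 1, 2], [0.1, 0.9, 1.8]
        expected = pearson_r2_by_sums(obs, imp)
        got = cp.imputation_r2(obs, imp)
        assert got == pytest.approx(expected, abs=1e-12)
        assert round(got, 4) == 0.9988

    def test_orientation_invariance(self, rng):
        obs = rng.integers(0, 3, 30)
        imp = rng.random(30) * 2
        assert cp.imputation_r2(obs, imp) == pytest.approx(
            cp.imputation_r2(2 - obs, 2 - imp), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cp.imputation_r2([0, 1], [0.5])


class TestBestGuess:
    @pytest.mark.parametrize(
        "probs,expected",
        [((0.2, 0.5, 0.3), 1), ((0.5, 0.5, 0.0), 0), ((1 / 3, 1 / 3, 1 / 3), 0)],
    )
    def test_argmax_with_low_dosage_ties(self, probs, expected):
        assert cp.best_guess_genotype(*probs) == expected

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            cp.best_guess_genotype(-0.1, 0.6, 0.5)


class TestConcordances:
    def test_genotype_concordance_examples(self):
        assert cp.genotype_concordance([0, 1, 2], [0, 1, 2]) == 1.0
        assert cp.genotype_concordance([0, 0, 0, 0], [0, 0, 0, 2]) == 0.75
        assert cp.genotype_concordance([0, 1, 2], [1, 2, 0]) == 0.0

    def test_ma_concordance_derived_example(self):
        # minor = alt; kept pairs: (1,1) match, (2,0) mismatch
        assert cp.ma_concordance([0, 1, 2, 0], [0, 1, 0, 0], True) == pytest.approx(0.5)

    def test_ma_concordance_empty_denominator_convention(self):
        assert cp.ma_concordance([0, 0, 0], [0, 0, 0], True) == 1.0

    def test_ma_concordance_identical_vectors(self):
        assert cp.ma_concordance([0, 1, 2, 0], [0, 1, 2, 0], True) == 1.0

    def test_ma_matches_pair_oracle_and_bounds_gc(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 20))
            obs = rng.integers(0, 3, n)
            bg = rng.integers(0, 3, n)
            minor_is_alt = bool(rng.integers(0, 2))
            ma = cp.ma_concordance(obs, bg, minor_is_alt)
            gc = cp.genotype_concordance(obs, bg)
            assert ma == pytest.approx(ma_concordance_by_pairs(obs, bg, minor_is_alt))
            assert gc == pytest.approx(concordance_by_loop(obs, bg))
            assert ma <= gc + 1e-12


class TestComputeVariantMetrics:
    def test_full_array_all_typed_all_one(self, toy_cohort):
        array = cp.design_array(toy_cohort, toy_cohort.n_variants, seed=0)
        batch = list(toy_cohort.samples["sample_id"][:10])
        out = cp.impute_batch(toy_cohort, array, batch, cp.HmmParams())
        # extend to all samples by imputing the complement as a second batch
        rest = [s for s in toy_cohort.samples["sample_id"] if s not in batch]
        out2 = cp.impute_batch(toy_cohort, array, rest, cp.HmmParams())
        combined = cp.ImputedDosages.concatenate([out, out2]).reorder(
            list(toy_cohort.samples["sample_id"])
        )
        m = cp.compute_variant_metrics(toy_cohort, combined, "EUR", array)
        assert m.typed.all()
        assert (m.r2 == 1).all() and (m.geno_conc == 1).all() and (m.ma_conc == 1).all()

    def test_mac_filter_row_count_matches_direct_scan(self, toy_cohort, toy_imputed):
        array, imputed = toy_imputed
        for g in ("EUR", "AFR"):
            m = cp.compute_variant_metrics(toy_cohort, imputed, g, array)
            ids = toy_cohort.group_sample_ids(g)
            G = toy_cohort.genotypes()[toy_cohort.sample_index(ids)]
            two_n = 2 * len(ids)
            alt = G.sum(axis=0)
            mac = np.minimum(alt, two_n - alt)
            assert len(m) == int((mac >= MIN_MINOR_ALLELE_COPIES).sum())

    def test_ma_never_exceeds_genotype_concordance(self, toy_cohort, toy_imputed):
        array, imputed = toy_imputed
        m = cp.compute_variant_metrics(toy_cohort, imputed, "AFR", array)
        assert (m.ma_conc <= m.geno_conc + 1e-12).all()
        assert m[["r2", "geno_conc", "ma_conc"]].ge(0).all().all()
        assert m[["r2", "geno_conc", "ma_conc"]].le(1).all().all()

    def test_metrics_match_definitional_oracles(self, toy_cohort, toy_imputed, rng):
        array, imputed = toy_imputed
        g = "EUR"
        m = cp.compute_variant_metrics(toy_cohort, imputed, g, array)
        ids = toy_cohort.group_sample_ids(g)
        obs_all = toy_cohort.genotypes()[toy_cohort.sample_index(ids)]
        imp = imputed.reorder(ids)
        vid_to_col = {v: j for j, v in enumerate(toy_cohort.variants["variant_id"])}
        stats = cp.group_allele_stats(toy_cohort, g)
        rows = m[~m.typed].sample(n=min(60, (~m.typed).sum()), random_state=1)
        for _, row in rows.iterrows():
            j = vid_to_col[row.variant_id]
            obs = obs_all[:, j]
            dos = imp.probs[:, j, 1] + 2 * imp.probs[:, j, 2]
            bg = np.argmax(imp.probs[:, j, :], axis=1)
            assert row.r2 == pytest.approx(pearson_r2_by_sums(obs, dos), abs=1e-10)
            assert row.geno_conc == pytest.approx(concordance_by_loop(obs, bg))
            minor_is_alt = bool(stats.minor_is_alt.iloc[j])
            assert row.ma_conc == pytest.approx(
                ma_concordance_by_pairs(obs, bg, minor_is_alt)
            )

    def test_group_restriction(self, toy_cohort, toy_imputed):
        # permuting the other group's imputed rows does not change EUR metrics
        array, imputed = toy_imputed
        base = cp.compute_variant_metrics(toy_cohort, imputed, "EUR", array)
        afr = toy_cohort.group_sample_ids("AFR")
        eur = toy_cohort.group_sample_ids("EUR")
        shuffled = cp.ImputedDosages(
            sample_ids=eur + afr[::-1],
            variants=imputed.variants,
            probs=np.concatenate(
                [imputed.reorder(eur).probs, imputed.reorder(afr[::-1]).probs]
            ),
            typed=imputed.typed,
        )
        again = cp.compute_variant_metrics(toy_cohort, shuffled, "EUR", array)
        pd.testing.assert_frame_equal(base, again)

    def test_missing_group_sample_rejected(self, toy_cohort, toy_imputed):
        array, imputed = toy_imputed
        partial = imputed.reorder(list(imputed.sample_ids)[:-1])
        with pytest.raises(ValueError, match="missing"):
            cp.compute_variant_metrics(toy_cohort, partial, "AFR", array)


class TestCoverageSummary:
    def _metrics(self, maf, r2):
        n = len(maf)
        return pd.DataFrame(
            {
                "maf": maf,
                "r2": r2,
                "geno_conc": np.ones(n),
                "ma_conc": np.ones(n),
                "ma_conc_defined": [True] * n,
            }
        )

    def test_all_perfect(self):
        s = cp.coverage_summary(self._metrics([0.2, 0.3], [1.0, 1.0]), ((0.0, 0.5),))
        assert s.frac_r2_ge_threshold.iloc[0] == 1.0
        assert s.mean_r2.iloc[0] == 1.0

    def test_threshold_arithmetic(self):
        s = cp.coverage_summary(self._metrics([0.2, 0.3], [0.7, 0.9]), ((0.0, 0.5),), 0.8)
        assert s.frac_r2_ge_threshold.iloc[0] == pytest.approx(0.5)
        assert s.mean_r2.iloc[0] == pytest.approx(0.8)

    def test_binning_bookkeeping(self):
        s = cp.coverage_summary(
            self._metrics([0.02, 0.2, 0.3], [1, 1, 1]), ((0.01, 0.05), (0.05, 0.5))
        )
        assert list(s.n_variants) == [1, 2]

    def test_malformed_edges_rejected(self):
        with pytest.raises(ValueError):
            cp.coverage_summary(self._metrics([0.2], [1.0]), ((0.3, 0.2),))


class TestArrayOverlap:
    def test_full_overlap(self, toy_cohort):
        arr = cp.design_array(toy_cohort, 50, seed=1)
        rep = cp.array_overlap_summary(toy_cohort, arr)
        assert rep["pct_in_panel"] == 100.0

    def test_half_absent(self, toy_cohort):
        pairs = sorted(toy_cohort.positions())[:20]
        off = [("1", 10_000_000 + i) for i in range(20)]
        arr = cp.ArrayDefinition.from_pairs("half", list(pairs) + off)
        rep = cp.array_overlap_summary(toy_cohort, arr)
        assert rep["pct_in_panel"] == pytest.approx(50.0)

    def test_singleton_positions_reduce_filtered_overlap(self):
        # 8 variants; 2 are singletons in the (single) group -> filtered 75% of raw
        haps = np.zeros((10, 8), dtype=np.uint8)
        haps[:4, :6] = 1  # variants 0-5: mac 4
        haps[0, 6] = 1  # singleton
        haps[1, 7] = 1  # singleton
        panel = _tiny_panel(haps)
        arr = cp.ArrayDefinition.from_pairs("toy", panel.positions())
        rep = cp.array_overlap_summary(panel, arr)
        assert rep["pct_in_panel"] == 100.0
        assert rep["pct_in_panel_maf_filtered"] == pytest.approx(75.0)
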