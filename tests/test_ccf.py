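import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, binomtest

from ccfrisk.ccf import (CCF_GRID, build_gene_ccf_matrix, ccf_posterior,
                         clonality_preference_test, count_subclones,
                         estimate_ccfs, estimate_multiplicity,
                         locus_copy_number)
from ccfrisk.exceptions import ValidationError
from ccfrisk.io import (ClinicalRecord, Cohort, CopyNumberSegment,
                        SampleInfo, SegmentIndex, VariantCall)


class TestMultiplicity:
    @pytest.mark.parametrize("vaf,purity,cn,expected", [
        (0.5, 1.0, 2, 1),      # diploid heterozygous clonal
        (0.8, 1.0, 2, 2),      # round(1.6) = 2 mutant copies
        (0.05, 0.5, 2, 1),     # clamped at 1 from below
        (0.9, 1.0, 4, 4),      # round(3.6) = 4, within CN
        (0.99, 1.0, 2, 2),     # clamped at total CN from above
    ])
    def test_point_estimate(self, vaf, purity, cn, expected):
        assert estimate_multiplicity(vaf, purity, cn) == expected

    def test_nonpositive_purity_rejected(self):
        with pytest.raises(ValidationError):
            estimate_multiplicity(0.5, 0.0, 2)


class TestLocusCopyNumber:
    def _index(self):
        return SegmentIndex([CopyNumberSegment("S1", "3", 1, 1000, 4.0)])

    def test_covering_segment(self):
        v = VariantCall("S1", "G", "3", 500, "C", "T", 10, 100)
        assert locus_copy_number(v, self._index()) == (4.0, False)

    def test_inclusive_end_boundary(self):
        v = VariantCall("S1", "G", "3", 1000, "C", "T", 10, 100)
        assert locus_copy_number(v, self._index()) == (4.0, False)

    def test_diploid_fallback_flagged(self):
        v = VariantCall("S1", "G", "7", 500, "C", "T", 10, 100)
        assert locus_copy_number(v, self._index()) == (2.0, True)


class TestPosterior:
    def test_pure_diploid_het_is_clonal(self):
        est = ccf_posterior(500, 1000, purity=1.0, total_cn=2, m=1)
        assert est.ccf_point == 1.00
        assert est.is_clonal

    def test_zero_alt_reads_is_subclonal(self):
        est = ccf_posterior(0, 1000, purity=1.0, total_cn=2, m=1)
        assert est.ccf_point == CCF_GRID[0]
        assert not est.is_clonal

    def test_matches_brute_force_grid_normalization(self):
        # independent route: explicit binomial pmf over the 100-point grid
        alt, depth, purity, cn, m = 150, 1000, 0.6, 2.0, 1
        est = ccf_posterior(alt, depth, purity, cn, m)
        v = np.clip(CCF_GRID * m * purity / (purity * cn + (1 - purity) * 2),
                    1e-6, 1 - 1e-6)
        pmf = binom.pmf(alt, depth, v)
        post = pmf / pmf.sum()
        assert np.allclose(est.posterior, post, atol=1e-12)
        assert est.p_clonal == pytest.approx(post[CCF_GRID > 0.9].sum(),
                                             abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 1000), st.floats(0.1, 1.0),
           st.sampled_from([1.0, 2.0, 3.0, 4.0]), st.integers(1, 2))
    def test_posterior_normalized(self, alt, purity, cn, m):
        est = ccf_posterior(alt, 1000, purity, cn, m)
        assert est.posterior.sum() == pytest.approx(1.0, abs=1e-9)
        assert est.is_clonal == (est.p_clonal > 0.5)

    def test_point_estimate_monotone_in_alt(self):
        points = [ccf_posterior(a, 500, 0.7, 2, 1).ccf_point
                  for a in range(0, 200, 10)]
        assert all(b >= a for a, b in zip(points, points[1:]))

    def test_identity_limit(self):
        # purity 1, CN 2, m 1: CCF = 2*VAF up to one grid step
        for alt in (50, 120, 250, 400):
            est = ccf_posterior(alt, 1000, 1.0, 2, 1)
            assert abs(est.ccf_point - min(1.0, 2 * alt / 1000)) <= 0.011

    def test_inconsistent_multiplicity_reduced(self):
        # m=4 at CN 2 implies VAF > 1 at CCF 1; largest consistent m is used
        est = ccf_posterior(400, 1000, purity=1.0, total_cn=2, m=4)
        assert est.multiplicity == 2

    def test_clonality_calibration_at_depth_1000(self):
        rng = np.random.default_rng(5)
        purity, cn, m = 0.8, 2.0, 1
        v_clonal = 1.0 * m * purity / (purity * cn + (1 - purity) * 2)
        alts = rng.binomial(1000, v_clonal, size=400)
        calls = [ccf_posterior(a, 1000, purity, cn, m).is_clonal for a in alts]
        assert np.mean(calls) >= 0.99
        alts = rng.binomial(1000, 0.2 * v_clonal, size=400)
        calls = [ccf_posterior(a, 1000, purity, cn, m).is_clonal for a in alts]
        assert np.mean(calls) <= 0.01


class TestSubclones:
    def test_all_clonal_single_cluster(self):
        model = count_subclones(np.full(60, 1.0))
        assert len(model.cluster_centers) == 1
        assert model.n_subclones == 0

    def test_two_planted_clusters_recovered(self):
        rng = np.random.default_rng(3)
        ccf = np.r_[np.clip(rng.normal(1.0, 0.01, 50), 0, 1),
                    np.clip(rng.normal(0.4, 0.02, 50), 0, 1)]
        model = count_subclones(ccf, seed=0)
        assert len(model.cluster_centers) == 2
        assert model.n_subclones == 1
        assert abs(model.cluster_centers[0] - 1.0) < 0.05
        assert abs(model.cluster_centers[1] - 0.4) < 0.05

    def test_too_few_mutations_flagged(self):
        model = count_subclones(np.array([0.5, 0.6, 0.7]))
        assert model.flagged
        assert len(model.cluster_centers) == 1

    def test_well_separated_recovery_rate(self):
        # planted K recovered in >= 90% of seeds for separated mixtures
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            ccf = np.r_[np.clip(rng.normal(0.95, 0.03, 40), 0.01, 1),
                        np.clip(rng.normal(0.55, 0.03, 40), 0.01, 1),
                        np.clip(rng.normal(0.20, 0.03, 40), 0.01, 1)]
            model = count_subclones(ccf, seed=seed)
            hits += len(model.cluster_centers) == 3
        assert hits >= 9


class TestClonalityPreference:
    @staticmethod
    def _table(gene_counts, global_fraction=0.716, total=3000):
        """Build a CCF table with given per-gene (subclonal, total) counts
        plus filler genes holding the cohort fraction at ``global_fraction``."""
        rows = []
        for gene, (k, n) in gene_counts.items():
            for i in range(n):
                rows.append((f"S{i % 50}", gene, i < k))
        n_named = sum(n for _, n in gene_counts.values())
        k_named = sum(k for k, _ in gene_counts.values())
        n_fill = total - n_named
        k_fill = int(round(global_fraction * total)) - k_named
        for i in range(n_fill):
            rows.append((f"S{i % 50}", f"FILL{i % 40}", i < k_fill))
        frame = pd.DataFrame(rows, columns=["sample_id", "gene", "subclonal"])
        frame["is_clonal"] = ~frame["subclonal"]
        frame["ccf_point"] = np.where(frame["subclonal"], 0.3, 1.0)
        return frame.drop(columns="subclonal")

    def test_exhaustive_enumeration_8_of_8(self):
        table = self._table({"ADAM29": (8, 8)})
        res = clonality_preference_test(table)
        row = res.set_index("gene").loc["ADAM29"]
        f = (~table["is_clonal"]).mean()
        # independent route: exhaustive two-sided tail sum over 9 outcomes
        pmf = binom.pmf(np.arange(9), 8, f)
        expected = pmf[pmf <= pmf[8] * (1 + 1e-7)].sum()
        assert row["p_value"] == pytest.approx(expected, rel=1e-9)
        assert row["p_value"] == pytest.approx(
            binomtest(8, 8, f, alternative="two-sided").pvalue, rel=1e-12)

    def test_gene_at_global_fraction_not_significant(self):
        # 72% subclonal against a global fraction engineered to ~0.716
        table = self._table({"NEUTRAL": (18, 25)})
        res = clonality_preference_test(table).set_index("gene")
        assert res.loc["NEUTRAL", "p_value"] > 0.5

    def test_strong_subclonal_bias_small_fdr(self):
        # 35/36 subclonal against ~0.716: direction + FDR below 0.05
        table = self._table({"FRY": (35, 36)})
        res = clonality_preference_test(table).set_index("gene")
        assert res.loc["FRY", "subclonal_fraction"] > 0.716
        assert res.loc["FRY", "fdr"] < 0.05


class TestGeneMatrix:
    def _cohort(self):
        samples = [SampleInfo("S1", 0.8), SampleInfo("S2", 0.8)]
        clinical = [ClinicalRecord(s.sample_id, 10.0, 1) for s in samples]
        variants = [
            VariantCall("S1", "MUC17", "7", 100, "C", "T", 120, 1000),
            VariantCall("S1", "MUC17", "7", 200, "C", "T", 320, 1000),
            VariantCall("S1", "TP53", "17", 100, "C", "T", 400, 1000),
        ]
        return Cohort.assemble(variants, [], samples, clinical)

    def test_max_ccf_per_gene_and_wildtype_zero(self):
        cohort = self._cohort()
        table = estimate_ccfs(cohort)
        matrix = build_gene_ccf_matrix(table, cohort,
                                       genes=["MUC17", "TP53", "EP300"])
        per_gene = table[table.gene == "MUC17"]["ccf_point"]
        assert matrix.frame.loc["S1", "MUC17"] == per_gene.max()
        assert matrix.frame.loc["S2", "MUC17"] == 0.0
        assert matrix.frame.loc["S2", "EP300"] == 0.0
        assert matrix.shape == (2, 3)

    def test_batch_and_scalar_paths_agree(self):
        cohort = self._cohort()
        table = estimate_ccfs(cohort)
        for _, row in table.iterrows():
            est = ccf_posterior(row.alt_reads, row.total_depth, row.purity,
                                row.total_cn, row.multiplicity)
            assert est.ccf_point == pytest.approx(row.ccf_point)
            assert est.p_clonal == pytest.approx(row.p_clonal, abs=1e-12)
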