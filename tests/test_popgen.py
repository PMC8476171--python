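"""Depth ratios, Weir–Cockerham F_ST (vs an independent oracle), consensus."""

import numpy as np
import pytest

from strataphase import popgen
from strataphase.containers import MISSING, make_windows

from conftest import make_quartets


def wc_theta_oracle(hap_a, hap_b):
    """Independently coded two-group haploid Weir–Cockerham estimator.

    Direct ANOVA on the allele indicator: among-group and within-group sums
    of squares computed by explicit per-sequence loops, combined into the
    theta ratio.  Returns per-site (numerator, denominator) pairs.
    """
    out = []
    for row_a, row_b in zip(np.asarray(hap_a), np.asarray(hap_b)):
        groups = [
            [x for x in row_a if x != MISSING],
            [x for x in row_b if x != MISSING],
        ]
        sizes = [len(g) for g in groups]
        if min(sizes) < 2:
            out.append((np.nan, np.nan))
            continue
        n_tot = sum(sizes)
        grand = sum(sum(g) for g in groups) / n_tot
        ss_between = 0.0
        ss_within = 0.0
        for g in groups:
            mean_g = sum(g) / len(g)
            ss_between += len(g) * (mean_g - grand) ** 2
            ss_within += sum((x - mean_g) ** 2 for x in g)
        msp = ss_between / (2 - 1)
        msg = ss_within / (n_tot - 2)
        nc = n_tot - sum(s * s for s in sizes) / n_tot
        out.append((msp - msg, msp + (nc - 1) * msg))
    return out


class TestWcFst:
    def test_matches_oracle_on_random_instances(self):
        """100 random small instances with missing data agree with the
        independently coded ANOVA oracle to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_sites = int(rng.integers(1, 30))
            na, nb = int(rng.integers(2, 12)), int(rng.integers(2, 12))
            a = rng.integers(0, 2, size=(n_sites, na)).astype(np.int8)
            b = rng.integers(0, 2, size=(n_sites, nb)).astype(np.int8)
            a[rng.random(a.shape) < 0.1] = MISSING
            b[rng.random(b.shape) < 0.1] = MISSING
            num, den = popgen.wc_fst_components(a, b)
            for i, (onum, oden) in enumerate(wc_theta_oracle(a, b)):
                if np.isnan(onum):
                    assert np.isnan(num[i])
                else:
                    assert num[i] == pytest.approx(onum, abs=1e-12)
                    assert den[i] == pytest.approx(oden, abs=1e-12)

    def test_fixed_difference_gives_one(self):
        for n in (2, 5, 15):
            a = np.zeros((3, n), dtype=np.int8)
            b = np.ones((3, n), dtype=np.int8)
            fst = popgen.wc_fst_sites(a, b)
            assert np.allclose(fst, 1.0)

    def test_panmictic_pool_near_zero(self):
        """Two groups drawn from one pool: windowed F_ST fluctuates around
        zero; mean within +/-0.02 over 10^4 SNPs."""
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, size=10_000)
        a = (rng.random((10_000, 8)) < p[:, None]).astype(np.int8)
        b = (rng.random((10_000, 8)) < p[:, None]).astype(np.int8)
        pos = np.arange(1, 10_001)
        win = make_windows(10_000, 100)
        df = popgen.wc_fst_windows(a, b, pos, win)
        assert abs(df.fst.mean()) < 0.02

    def test_monomorphic_window_missing(self):
        a = np.zeros((5, 4), dtype=np.int8)
        b = np.zeros((5, 4), dtype=np.int8)
        df = popgen.wc_fst_windows(a, b, np.arange(1, 6), make_windows(5, 5))
        assert np.isnan(df.fst.iloc[0])

    def test_estimator_not_clipped_below_zero(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, size=(200, 4)).astype(np.int8)
        b = rng.integers(0, 2, size=(200, 4)).astype(np.int8)
        fst = popgen.wc_fst_sites(a, b)
        assert np.nanmin(fst) < 0  # negative estimates reported as-is

    def test_bounded_by_one(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, size=(500, 6)).astype(np.int8)
        b = rng.integers(0, 2, size=(500, 6)).astype(np.int8)
        fst = popgen.wc_fst_sites(a, b)
        assert np.nanmax(fst) <= 1.0 + 1e-12


class TestDepthRatio:
    def test_identical_depths_give_unity(self):
        q = make_quartets([[1, 0, 1, 0]] * 10, dp=np.full((10, 4), 30))
        df = popgen.depth_ratio_windows(q, make_windows(2000, 2000))
        assert df.depth_ratio.iloc[0] == pytest.approx(1.0)

    def test_invariant_to_uniform_rescaling(self):
        rng = np.random.default_rng(0)
        dp = rng.poisson(30, size=(50, 4))
        q1 = make_quartets([[1, 0, 1, 0]] * 50, dp=dp)
        q2 = make_quartets([[1, 0, 1, 0]] * 50, dp=dp * 3)
        w = make_windows(6000, 1000)
        r1 = popgen.depth_ratio_windows(q1, w).depth_ratio
        r2 = popgen.depth_ratio_windows(q2, w).depth_ratio
        assert np.allclose(r1.dropna(), r2.dropna())

    def test_zero_daughter_depth_missing_with_warning(self):
        dp = np.array([[30, 30, 30, 0]] * 5)
        q = make_quartets([[1, 0, 1, 0]] * 5, dp=dp)
        with pytest.warns(UserWarning):
            df = popgen.depth_ratio_windows(q, make_windows(1000, 1000))
        assert np.isnan(df.depth_ratio.iloc[0])

    def test_empty_window_flagged_missing(self):
        q = make_quartets([[1, 0, 1, 0]], pos=[150])
        df = popgen.depth_ratio_windows(q, make_windows(2000, 1000))
        assert df.n_snps.tolist() == [1, 0]
        assert np.isnan(df.depth_ratio.iloc[1])

    def test_hemizygous_simulation_near_half(self, errorfree_sim):
        panel, truth, q = errorfree_sim
        deleted = truth.y_deleted_sites
        if deleted.sum() == 0:
            pytest.skip("no deleted genes drawn in fixture")
        idx = q.pedigree.indices(q.samples)
        ratio = q.dp[deleted][:, idx["son"]].mean() / q.dp[deleted][:, idx["daughter"]].mean()
        assert ratio == pytest.approx(0.5, abs=0.05)


class TestHemizygosity:
    def _ratios(self, vals):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(vals))],
                "start": np.arange(len(vals)) * 1000,
                "end": np.arange(1, len(vals) + 1) * 1000,
                "depth_ratio": vals,
                "n_snps": [5] * len(vals),
            }
        )

    def test_threshold_is_strict(self):
        calls = popgen.call_hemizygous(self._ratios([0.58, 1.0, 0.75, 0.7499]))
        assert calls.hemizygous.tolist() == [True, False, False, True]

    def test_uncallable_gene_flagged(self):
        calls = popgen.call_hemizygous(self._ratios([np.nan]))
        assert not calls.callable.iloc[0]
        assert calls.hemizygous.isna().iloc[0]

    def test_recall_precision_on_simulation(self):
        """Genes simulated with deletion probability 0 or 1 at 35x depth are
        recovered with recall and precision at least 0.95."""
        import pandas as pd

        from strataphase import simcross

        rng = np.random.default_rng(8)
        n_genes = 60
        starts = np.arange(n_genes) * 10_000
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i:03d}" for i in range(n_genes)],
                "chrom": "chrXIX",
                "start": starts,
                "end": starts + 6_000,
            }
        )
        # two strata with deletion probability 0 and 1; genes assigned by interval
        half = n_genes // 2 * 10_000
        cfg = simcross.SimConfig(
            chrom_length_bp=n_genes * 10_000,
            par=(),
            strata=(
                simcross.StratumSpec(0, half, 3.0, 1.0, "del"),
                simcross.StratumSpec(half, n_genes * 10_000, 3.0, 0.0, "keep"),
            ),
            genes=genes,
            seed=8,
        )
        panel, truth = simcross.simulate_sex_chromosome(cfg)
        q = simcross.simulate_quartets(panel, truth, cfg)
        calls = popgen.call_hemizygous(popgen.gene_depth_ratio(q, genes))
        called = calls[calls.callable]
        truth_del = called.gene_id.isin(truth.deleted_gene_ids)
        pred = called.hemizygous.astype(bool)
        tp = int((pred & truth_del).sum())
        recall = tp / int(truth_del.sum())
        precision = tp / int(pred.sum())
        assert recall >= 0.95 and precision >= 0.95


class TestConsensus:
    def _haps(self, n_alt, n_total):
        h = np.zeros((1, n_total), dtype=np.int8)
        h[0, :n_alt] = 1
        return h

    def test_exact_half_counts_as_major(self):
        assert popgen.consensus_alleles(self._haps(4, 8))[0] == 1

    def test_strict_majority_convention(self):
        assert popgen.consensus_alleles(self._haps(4, 8), strict_majority=True)[0] == 0
        assert popgen.consensus_alleles(self._haps(5, 8), strict_majority=True)[0] == 1

    def test_zero_and_all_carriers(self):
        assert popgen.consensus_alleles(self._haps(0, 8))[0] == 0
        assert popgen.consensus_alleles(self._haps(8, 8))[0] == 1

    def test_missing_sequences_excluded_from_denominator(self):
        h = np.array([[1, 1, MISSING, MISSING]], dtype=np.int8)
        assert popgen.consensus_alleles(h)[0] == 1

    def test_substitution_into_reference(self):
        ref_cds = "ATGAAACCC"
        haps = np.array([[1, 1, 1, 0], [0, 0, 0, 1]], dtype=np.int8)
        seq = popgen.consensus_sequence(
            haps,
            positions=np.array([1004, 1007]),
            alt_bases=np.array(["G", "T"]),
            ref_cds=ref_cds,
            cds_start=1000,
        )
        assert seq == "ATGGAACCC"  # first SNP major ALT, second minor kept REF

    def test_minus_strand_reverse_complemented(self):
        seq = popgen.consensus_sequence(
            np.zeros((0, 4), dtype=np.int8),
            positions=np.array([], dtype=int),
            alt_bases=np.array([]),
            ref_cds="ATGAAA",
            cds_start=0,
            strand="-",
        )
        assert seq == "TTTCAT"

    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            popgen.consensus_sequence(
                np.zeros((0, 4), dtype=np.int8),
                positions=np.array([], dtype=int),
                alt_bases=np.array([]),
                ref_cds="ATGA",
                cds_start=0,
            )


class TestPrematureStops:
    def test_internal_stop_found(self):
        assert popgen.find_premature_stop("ATGTAAAAATGA") == 1

    def test_terminal_stop_is_not_premature(self):
        assert popgen.find_premature_stop("ATGAAATGA") is None

    def test_injected_nonsense_counted_on_y_only(self):
        from strataphase import simcross

        rng = np.random.default_rng(5)
        x = simcross.random_cds(100, rng)
        y = simcross.inject_nonsense(x, rng)
        df = popgen.scan_premature_stops({"gene_X": x, "gene_Y": y})
        by_gene = df.set_index("gene_id").has_premature_stop
        assert not by_gene["gene_X"] and by_gene["gene_Y"]


class TestEstimateNe:
    def test_study_scale_worked_example(self):
        est = popgen.estimate_ne(pi=0.001, mu=5e-8)
        assert est.ne == pytest.approx(5000.0)
        assert est.theta == est.pi

    def test_degenerate_inputs(self):
        assert popgen.estimate_ne(0.0, 1e-8).ne == 0.0
        assert popgen.estimate_ne(4e-8, 1e-8).ne == pytest.approx(1.0)
        with pytest.raises(ValueError):
            popgen.estimate_ne(0.001, 0.0)
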