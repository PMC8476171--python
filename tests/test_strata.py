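"""Changepoint segmentation, NG86 divergence and stratum dating."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from strataphase import simcross, strata
from strataphase.strata import (
    detect_changepoints,
    estimate_stratum_age,
    jukes_cantor,
    ng86_divergence,
    segments_from_changepoints,
    summarize_strata,
)


# ---------------------------------------------------------------------------
# independent changepoint oracle: DP over number of segments

def changepoint_oracle(y, penalty, min_len):
    """Exact segmentation by a k-segment dynamic program, independent of the
    optimal-partitioning implementation: for each segment count k find the
    best layout, then minimize total cost + penalty*(k-1) over k."""
    y = np.asarray(y, float)
    n = len(y)

    def sse(i, j):
        seg = y[i:j]
        return float(np.sum((seg - seg.mean()) ** 2))

    kmax = n // min_len
    best = {}
    prev = {}
    for j in range(min_len, n + 1):
        best[(1, j)] = sse(0, j)
    for k in range(2, kmax + 1):
        for j in range(k * min_len, n + 1):
            cands = [
                (best[(k - 1, s)] + sse(s, j), s)
                for s in range((k - 1) * min_len, j - min_len + 1)
                if (k - 1, s) in best
            ]
            if cands:
                val, s = min(cands)
                best[(k, j)] = val
                prev[(k, j)] = s
    options = [
        (best[(k, n)] + penalty * (k - 1), k) for k in range(1, kmax + 1) if (k, n) in best
    ]
    _, k_opt = min(options)
    bounds = []
    j, k = n, k_opt
    while k > 1:
        s = prev[(k, j)]
        bounds.append(s)
        j, k = s, k - 1
    return sorted(bounds)


class TestChangepoints:
    def test_constant_series_no_changepoints(self):
        assert detect_changepoints(np.ones(100)) == []

    def test_step_series_boundary_within_two_windows(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([np.full(120, 0.6), np.full(80, 1.0)])
        y += rng.normal(0, 0.05, size=200)
        cps = detect_changepoints(y)
        assert len(cps) == 1
        assert abs(cps[0] - 120) <= 2

    def test_staircase_matches_oracle_exactly(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([np.full(60, 0.5), np.full(70, 0.8), np.full(70, 1.1)])
        y += rng.normal(0, 0.05, size=200)
        pen = strata.bic_penalty(y)
        cps = detect_changepoints(y, penalty=pen)
        assert cps == changepoint_oracle(y, pen, 5)
        assert len(cps) == 2

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_random_series_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 120))
        y = rng.normal(0, 1, size=n)
        # add a couple of genuine level shifts
        for cut in rng.integers(10, n - 10, size=2):
            y[cut:] += rng.normal(0, 2)
        for pen in (1.0, 5.0, 20.0):
            assert detect_changepoints(y, penalty=pen) == changepoint_oracle(y, pen, 5)

    def test_min_segment_length_enforced(self):
        y = np.concatenate([np.zeros(3), np.ones(97)])
        cps = detect_changepoints(y, penalty=0.5, min_segment_length=5)
        assert all(c >= 5 for c in cps)

    def test_short_series_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert detect_changepoints(np.arange(6), min_segment_length=5) == []

    def test_missing_values_indices_map_to_original(self):
        y = np.concatenate([np.full(50, 0.5), np.full(50, 1.5)]).astype(float)
        y[::7] = np.nan
        cps = detect_changepoints(y, penalty=1.0)
        assert len(cps) == 1
        assert abs(cps[0] - 50) <= 2

    def test_segments_tile_series(self):
        segs = segments_from_changepoints(100, [20, 60])
        assert segs == [(0, 20), (20, 60), (60, 100)]


# ---------------------------------------------------------------------------
# independent NG86 oracle

def ng86_oracle(a, b):
    """Fresh transliteration of the Nei–Gojobori counting method.

    Stop-codon conventions match the implementation's documented choices:
    changes to stops are nonsynonymous for site counting; pathways through
    stop intermediates are excluded unless all are blocked.
    """

    def translate(codon):
        return str(Seq(codon).translate())

    def sites(codon):
        syn = 0.0
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mut = codon[:pos] + base + codon[pos + 1 :]
                if translate(mut) == translate(codon):
                    syn += 1 / 3
        return syn, 3 - syn

    def diffs(c1, c2):
        positions = [i for i in range(3) if c1[i] != c2[i]]
        if not positions:
            return 0.0, 0.0
        results = []
        for order in itertools.permutations(positions):
            current, sd, nd, through_stop = c1, 0, 0, False
            for pos in order:
                nxt = current[:pos] + c2[pos] + current[pos + 1 :]
                if translate(nxt) == "*" and nxt != c2:
                    through_stop = True
                if translate(nxt) == translate(current):
                    sd += 1
                else:
                    nd += 1
                current = nxt
            results.append((sd, nd, through_stop))
        usable = [(s, n) for s, n, blocked in results if not blocked] or [
            (s, n) for s, n, _ in results
        ]
        return (
            sum(s for s, _ in usable) / len(usable),
            sum(n for _, n in usable) / len(usable),
        )

    S = N = Sd = Nd = 0.0
    for k in range(len(a) // 3):
        c1, c2 = a[3 * k : 3 * k + 3], b[3 * k : 3 * k + 3]
        if translate(c1) == "*" or translate(c2) == "*":
            continue
        s1, n1 = sites(c1)
        s2, n2 = sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = diffs(c1, c2)
        Sd += sd
        Nd += nd
    return Sd / S, Nd / N


class TestNg86:
    def test_identical_sequences_zero(self):
        d = ng86_divergence("ATGAAATGC", "ATGAAATGC")
        assert d.ds == 0.0 and d.dn == 0.0

    def test_third_position_synonymy(self):
        d = ng86_divergence("TTT", "TTC")  # Phe -> Phe
        assert d.syn_diffs == 1.0 and d.nonsyn_diffs == 0.0
        assert d.dn == 0.0 and d.ds > 0

    def test_matches_oracle_on_random_pairs(self):
        """pS and pN agree with an independently coded NG86 oracle to 1e-9
        on random diverged 100-codon pairs."""
        rng = np.random.default_rng(17)
        for _ in range(30):
            x = simcross.random_cds(100, rng)
            y = simcross.evolve_cds(x, 5.0, 2e-3, 0.4, rng)
            d = ng86_divergence(x, y)
            ps, pn = ng86_oracle(x, y)
            assert d.ps == pytest.approx(ps, abs=1e-9)
            assert d.pn == pytest.approx(pn, abs=1e-9)

    def test_symmetric_in_argument_order(self):
        rng = np.random.default_rng(18)
        x = simcross.random_cds(80, rng)
        y = simcross.evolve_cds(x, 8.0, 2e-3, 0.3, rng)
        d1, d2 = ng86_divergence(x, y), ng86_divergence(y, x)
        assert d1.ds == pytest.approx(d2.ds, abs=1e-12)
        assert d1.dn == pytest.approx(d2.dn, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            ng86_divergence("ATGAAA", "ATG")

    def test_shared_internal_stop_flags_gene(self):
        d = ng86_divergence("ATGTAAAAA", "ATGTAAAAA")
        assert d.flagged

    def test_jukes_cantor_limits(self):
        assert jukes_cantor(0.0) == 0.0
        assert np.isinf(jukes_cantor(0.8))
        assert jukes_cantor(0.1) == pytest.approx(-0.75 * np.log(1 - 4 / 3 * 0.1))


class TestStratumAge:
    def test_table_worked_examples(self):
        assert estimate_stratum_age(0.012, 0.099, 14.3) == pytest.approx(1.73, abs=0.01)
        assert estimate_stratum_age(0.030, 0.060, 14.3) == pytest.approx(7.15, abs=0.01)

    def test_par_limit_zero(self):
        assert estimate_stratum_age(0.0, 0.05, 14.3) == 0.0

    def test_zero_outgroup_divergence_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(estimate_stratum_age(0.01, 0.0, 14.3))


class TestSummarize:
    def _segments(self):
        return pd.DataFrame(
            [
                {"label": "A", "start": 0, "end": 1000},
                {"label": "B", "start": 1000, "end": 2000},
            ]
        )

    def test_all_hemizygous_is_100_percent(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "start": [100, 500],
                "end": [200, 600],
                "callable": [True, True],
                "hemizygous": [True, True],
            }
        )
        table, _ = summarize_strata(self._segments(), gene_stats=genes)
        assert table.set_index("label").pct_hemizygous["A"] == 100.0

    def test_age_from_ds_ratio_columns(self):
        div = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "start": [100, 1500],
                "end": [200, 1600],
                "ds": [0.03, 0.004],
                "dn": [0.007, 0.001],
                "omega": [0.24, 0.38],
                "ds_out": [0.060, 0.065],
            }
        )
        table, _ = summarize_strata(self._segments(), gene_divergence=div, split_time_my=14.3)
        ages = table.set_index("label").age_my
        assert ages["A"] == pytest.approx(14.3 * 0.03 / 0.06, abs=0.01)
        assert ages["B"] == pytest.approx(14.3 * 0.004 / 0.065, abs=0.01)

    def test_mannwhitney_p_uniform_under_null(self):
        """Identical strata give uniform Mann–Whitney p-values over
        replicates (type-I error calibration)."""
        rng = np.random.default_rng(23)
        pvals = []
        segs = self._segments()
        for _ in range(200):
            div = pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(40)],
                    "start": np.r_[rng.integers(0, 900, 20), rng.integers(1000, 1900, 20)],
                    "end": 0,
                    "ds": rng.exponential(0.05, 40),
                }
            )
            div["end"] = div["start"] + 50
            _, pw = summarize_strata(segs, gene_divergence=div)
            pvals.append(pw[pw.statistic == "ds"].p_raw.iloc[0])
        from scipy import stats as sps

        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001

    def test_two_strata_age_recovery(self):
        """Ages {3, 12} My simulated under the generator clock are recovered
        within 20% through the consensus dS ratio pipeline."""
        rng = np.random.default_rng(29)
        rows = []
        for label, (lo, hi), t in (("young", (0, 1000), 3.0), ("old", (1000, 2000), 12.0)):
            for g in range(60):
                x, y, out = simcross.simulate_gene_triplet(300, t, 14.3, 2.5e-3, 0.25, rng)
                dxy = ng86_divergence(x, y)
                dout = ng86_divergence(y, out)
                rows.append(
                    {
                        "gene_id": f"{label}{g}",
                        "start": lo + g,
                        "end": lo + g + 1,
                        "ds": dxy.ds,
                        "ds_out": dout.ds,
                    }
                )
        table, _ = summarize_strata(
            pd.DataFrame(
                [
                    {"label": "young", "start": 0, "end": 1000},
                    {"label": "old", "start": 1000, "end": 2000},
                ]
            ),
            gene_divergence=pd.DataFrame(rows),
        )
        ages = table.set_index("label").age_my
        assert abs(ages["young"] - 3.0) / 3.0 < 0.2
        assert abs(ages["old"] - 12.0) / 12.0 < 0.2
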