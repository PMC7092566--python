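from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from caniuc.io import TranscriptRecord
from caniuc.positional import (
    assign_positions,
    hypergeometric_enrichment,
    make_windows,
    merge_regions,
    scan,
)


def hypergeom_tail_oracle(k, n, K, N):
    """Exact rational upper tail P(X >= k)."""
    total = comb(N, n)
    num = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(n, K) + 1))
    return Fraction(num, total)


class TestAssignPositions:
    def test_mean_of_transcript_midpoints(self):
        records = [
            TranscriptRecord("g1", "chr1", 100, 200),
            TranscriptRecord("g1", "chr1", 300, 500),
        ]
        pos = assign_positions(records)
        assert pos.loc[0, "position"] == 275.0

    def test_single_transcript(self):
        pos = assign_positions([TranscriptRecord("g1", "chr1", 0, 1000)])
        assert pos.loc[0, "position"] == 500.0

    def test_multi_chromosome_gene_rejected(self):
        records = [
            TranscriptRecord("g1", "chr1", 0, 10),
            TranscriptRecord("g1", "chr2", 0, 10),
        ]
        with pytest.raises(ValueError, match="g1"):
            assign_positions(records)

    def test_fifty_gene_fixture_matches_independent_arithmetic(self):
        rng = np.random.default_rng(0)
        records, expected = [], {}
        for i in range(50):
            k = int(rng.integers(1, 4))
            mids = []
            for _ in range(k):
                start = int(rng.integers(0, 10_000))
                end = start + int(rng.integers(1, 5_000))
                records.append(TranscriptRecord(f"g{i}", "chr1", start, end))
                mids.append((start + end) / 2)
            expected[f"g{i}"] = sum(mids) / len(mids)
        pos = assign_positions(records).set_index("gene_id")
        for gene, want in expected.items():
            assert pos.loc[gene, "position"] == pytest.approx(want, rel=1e-12)


class TestMakeWindows:
    def test_forced_tiling_of_one_mb(self):
        w = make_windows({"chr1": 1_000_000})
        assert w[["start", "end"]].to_numpy().tolist() == [
            [0, 1_000_000],
            [250_000, 1_000_000],
            [500_000, 1_000_000],
            [750_000, 1_000_000],
        ]

    def test_interior_base_in_exactly_four_windows(self):
        w = make_windows({"chr1": 2_000_000})
        pos = 900_000
        containing = ((w["start"] <= pos) & (pos < w["end"])).sum()
        assert containing == 4

    def test_matches_enumeration_oracle_random_lengths(self):
        rng = np.random.default_rng(1)
        lengths = {f"chr{i}": int(rng.integers(1, 5_000_000)) for i in range(5)}
        w = make_windows(lengths)
        expected = []
        for chrom, L in lengths.items():
            s = 0
            while s < L:
                expected.append((chrom, s, min(s + 1_000_000, L)))
                s += 250_000
        assert list(map(tuple, w.to_numpy())) == expected

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="width > step"):
            make_windows({"chr1": 100}, width=10, step=10)
        with pytest.raises(ValueError, match="non-positive"):
            make_windows({"chr1": 0})


class TestHypergeometricEnrichment:
    def test_zero_draws_full_tail(self):
        assert hypergeometric_enrichment(0, 10, 50, 1000) == 1.0

    def test_all_marked_population(self):
        assert hypergeometric_enrichment(7, 7, 20, 20) == pytest.approx(1.0)

    def test_matches_rational_oracle(self):
        assert hypergeometric_enrichment(5, 10, 50, 1000) == pytest.approx(
            float(hypergeom_tail_oracle(5, 10, 50, 1000)), rel=1e-10
        )

    def test_monotone_non_increasing_in_k(self):
        vals = [hypergeometric_enrichment(k, 15, 40, 200) for k in range(16)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("args", [(5, 4, 10, 20), (3, 5, 2, 20), (1, 5, 30, 20)])
    def test_invalid_parameters_rejected(self, args):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(*args)


def _toy_universe(rng, n=400, chrom_length=5_000_000, frac_up=0.1):
    positions = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "chrom": "chr1",
            "position": np.sort(rng.uniform(0, chrom_length, n)),
        }
    )
    call = np.where(rng.random(n) < frac_up, "up", "ns")
    de = pd.DataFrame({"gene_id": positions["gene_id"], "call": call})
    return positions, de


class TestScan:
    def test_no_calls_no_significant_windows(self):
        rng = np.random.default_rng(2)
        positions, de = _toy_universe(rng, frac_up=0.0)
        w = scan(positions, de, {"chr1": 5_000_000}, "up")
        assert not w["significant"].any()
        assert (w["p_hyper"] == 1.0).all()

    def test_window_counts_match_brute_force(self):
        rng = np.random.default_rng(3)
        positions, de = _toy_universe(rng)
        w = scan(positions, de, {"chr1": 5_000_000}, "up")
        merged = positions.merge(de, on="gene_id")
        for row in w.itertuples(index=False):
            inside = (merged["position"] >= row.start) & (merged["position"] < row.end)
            assert row.n_genes == inside.sum()
            assert row.n_direction == (inside & (merged["call"] == "up")).sum()
            assert row.p_hyper == pytest.approx(
                float(
                    hypergeom_tail_oracle(
                        row.n_direction,
                        row.n_genes,
                        (merged["call"] == "up").sum(),
                        len(merged),
                    )
                ),
                rel=1e-9,
            )

    def test_interior_gene_counted_four_times(self):
        rng = np.random.default_rng(4)
        positions, de = _toy_universe(rng)
        w = scan(positions, de, {"chr1": 5_000_000}, "up")
        interior = (positions["position"] >= 750_000) & (
            positions["position"] < 4_250_000
        )
        # each interior gene lies in exactly 4 windows; edge genes in fewer
        count_interior = 0
        for row in w.itertuples(index=False):
            inside = (positions["position"] >= row.start) & (positions["position"] < row.end)
            count_interior += (inside & interior).sum()
        assert count_interior == 4 * interior.sum()

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(5)
        positions, de = _toy_universe(rng)
        w1 = scan(positions, de, {"chr1": 5_000_000}, "up")
        shuffled = positions.sample(frac=1, random_state=1).reset_index(drop=True)
        w2 = scan(shuffled, de, {"chr1": 5_000_000}, "up")
        pd.testing.assert_frame_equal(w1, w2)

    def test_planted_hotspot_significant(self):
        rng = np.random.default_rng(6)
        n = 2000
        chrom_length = 20_000_000
        positions = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "chrom": "chr1",
                "position": rng.uniform(0, chrom_length, n),
            }
        )
        call = np.where(rng.random(n) < 0.05, "up", "ns")
        # pack 30 extra up genes into [3.0, 3.5) Mb
        hot = rng.choice(np.flatnonzero(call == "ns"), 30, replace=False)
        call[hot] = "up"
        positions.loc[hot, "position"] = rng.uniform(3_000_000, 3_500_000, 30)
        de = pd.DataFrame({"gene_id": positions["gene_id"], "call": call})
        w = scan(positions, de, {"chr1": chrom_length}, "up")
        sig = w[w["significant"]]
        assert len(sig) > 0
        assert ((sig["start"] <= 3_000_000) & (sig["end"] >= 3_500_000)).any()


class TestMergeRegions:
    def _windows(self, rows, direction="up"):
        w = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "n_genes", "n_direction",
                           "p_hyper", "significant"]
        )
        w.attrs["direction"] = direction
        return w

    def test_overlapping_windows_union(self):
        rng = np.random.default_rng(7)
        positions, de = _toy_universe(rng, n=100, chrom_length=3_000_000)
        w = self._windows(
            [
                ("chr1", 0, 1_000_000, 10, 5, 1e-9, True),
                ("chr1", 250_000, 1_250_000, 10, 5, 1e-9, True),
            ]
        )
        regions = merge_regions(w, positions, de)
        assert len(regions) == 1
        assert (regions.loc[0, "start"], regions.loc[0, "end"]) == (0, 1_250_000)

    def test_distant_windows_stay_separate(self):
        rng = np.random.default_rng(8)
        positions, de = _toy_universe(rng, n=100, chrom_length=10_000_000)
        w = self._windows(
            [
                ("chr1", 0, 1_000_000, 10, 5, 1e-9, True),
                ("chr1", 6_000_000, 7_000_000, 10, 5, 1e-9, True),
            ]
        )
        regions = merge_regions(w, positions, de)
        assert len(regions) == 2

    def test_region_p_matches_rational_oracle(self):
        rng = np.random.default_rng(9)
        positions, de = _toy_universe(rng, n=300, chrom_length=4_000_000)
        w = self._windows([("chr1", 1_000_000, 2_000_000, 0, 0, 1e-9, True)])
        regions = merge_regions(w, positions, de)
        merged = positions.merge(de, on="gene_id")
        inside = (merged["position"] >= 1_000_000) & (merged["position"] < 2_000_000)
        k = int((inside & (merged["call"] == "up")).sum())
        n = int(inside.sum())
        K = int((merged["call"] == "up").sum())
        assert regions.loc[0, "n_genes"] == n
        assert regions.loc[0, "n_direction"] == k
        assert regions.loc[0, "p_region"] == pytest.approx(
            float(hypergeom_tail_oracle(k, n, K, len(merged))), rel=1e-9
        )
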