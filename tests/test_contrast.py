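from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from caniuc.contrast import (
    classify_genes,
    fisher_exact,
    per_cluster_de,
    replication_cluster_test,
)
from caniuc.de import vst
from caniuc.simulate import SimulationDesign, simulate_counts


def fisher_oracle(a, b, c, d):
    """Independent enumeration: hypergeometric probabilities as exact
    rationals via factorials; two-sided p by the point-probability rule."""
    from math import factorial

    def hyper(x, r1, r2, c1):
        n = r1 + r2
        return Fraction(
            factorial(r1) * factorial(r2) * factorial(c1) * factorial(n - c1),
            factorial(x)
            * factorial(r1 - x)
            * factorial(c1 - x)
            * factorial(r2 - c1 + x)
            * factorial(n),
        )

    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = hyper(a, r1, r2, c1)
    return sum(hyper(x, r1, r2, c1) for x in range(lo, hi + 1) if hyper(x, r1, r2, c1) <= obs)


class TestFisherExact:
    def test_replication_split_worked_example(self):
        """8/8 mutant tumors in one cluster, 3/4 wild-type in the other."""
        assert round(fisher_exact([[8, 1], [0, 3]]), 4) == 0.0182

    def test_balanced_table_p_one(self):
        assert fisher_exact([[1, 1], [1, 1]]) == 1.0

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 21, 4)
            if a + b + c + d == 0:
                continue
            p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(float(fisher_oracle(a, b, c, d)), rel=1e-12)

    def test_cross_check_against_scipy(self):
        """Independent library cross-check on tables away from ties."""
        from scipy import stats

        rng = np.random.default_rng(5)
        for _ in range(100):
            t = rng.integers(0, 30, (2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact(t) == pytest.approx(
                stats.fisher_exact(t).pvalue, rel=1e-6
            )

    def test_transpose_and_swap_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            t = rng.integers(0, 15, (2, 2))
            if t.sum() == 0:
                continue
            p = fisher_exact(t)
            assert p == pytest.approx(fisher_exact(t.T), rel=1e-12)
            assert p == pytest.approx(fisher_exact(t[::-1, ::-1]), rel=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fisher_exact([[0, 0], [0, 0]])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fisher_exact([[1, -1], [0, 2]])


def brute_force_category(lfc_m, call_m, lfc_w, call_w, band=0.5):
    """Literal scalar re-application of the written classification rule."""
    sig_m, sig_w = call_m != "ns", call_w != "ns"
    if sig_m and sig_w:
        return "shared" if (lfc_m > 0) == (lfc_w > 0) else "opposite"
    if sig_m or sig_w:
        other = lfc_w if sig_m else lfc_m
        mine = lfc_m if sig_m else lfc_w
        if (mine > 0) != (other > 0) and other != 0:
            return "discriminating"
        if -band < other < band:
            return "discriminating"
    return "other"


def _random_de_pair(rng, n):
    lfc = rng.normal(0, 1.5, n)
    q = rng.random(n) ** 2
    call = np.where((lfc >= 1) & (q < 0.01), "up",
                    np.where((lfc <= -1) & (q < 0.01), "down", "ns"))
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "log2fc": lfc, "q": q, "call": call,
    })


class TestClassifyGenes:
    def _pair(self, lfc_m, q_m, lfc_w, q_w):
        def row(lfc, q):
            call = "ns"
            if q < 0.01 and lfc >= 1:
                call = "up"
            elif q < 0.01 and lfc <= -1:
                call = "down"
            return pd.DataFrame(
                {"gene_id": ["g"], "log2fc": [lfc], "q": [q], "call": [call]}
            )
        return row(lfc_m, q_m), row(lfc_w, q_w)

    @pytest.mark.parametrize(
        "lfc_m,q_m,lfc_w,q_w,expected",
        [
            (2.0, 1e-5, 0.1, 0.8, "discriminating"),   # unchanged partner
            (2.0, 1e-5, 1.4, 1e-4, "shared"),           # both up
            (-1.5, 1e-4, -2.2, 1e-6, "shared"),         # both down
            (2.0, 1e-5, -1.3, 1e-4, "opposite"),        # significant, reversed
            (2.0, 1e-5, 0.7, 0.5, "other"),             # outside band, not reversed
            (2.0, 1e-5, -0.2, 0.9, "discriminating"),   # reverse-signed partner
            (0.3, 0.9, 0.2, 0.8, "other"),              # neither significant
            (2.0, 1e-5, 0.5, 0.5, "other"),             # band is open at 0.5
        ],
    )
    def test_rule_branches(self, lfc_m, q_m, lfc_w, q_w, expected):
        de_mut, de_wt = self._pair(lfc_m, q_m, lfc_w, q_w)
        assert classify_genes(de_mut, de_wt)["category"].iloc[0] == expected

    def test_partitions_universe_and_matches_brute_force(self):
        rng = np.random.default_rng(2)
        de_mut = _random_de_pair(rng, 2000)
        de_wt = _random_de_pair(rng, 2000)
        out = classify_genes(de_mut, de_wt)
        assert len(out) == 2000
        assert set(out["category"]) <= {"shared", "opposite", "discriminating", "other"}
        expected = [
            brute_force_category(m_l, m_c, w_l, w_c)
            for m_l, m_c, w_l, w_c in zip(
                de_mut["log2fc"], de_mut["call"], de_wt["log2fc"], de_wt["call"]
            )
        ]
        assert out["category"].tolist() == expected

    def test_mismatched_universe_rejected(self):
        rng = np.random.default_rng(3)
        de_mut = _random_de_pair(rng, 10)
        de_wt = _random_de_pair(rng, 10)
        with pytest.raises(ValueError, match="universe"):
            classify_genes(de_mut, de_wt.iloc[:5])


@pytest.fixture(scope="module")
def two_program():
    """Planted mut-only, wt-only and shared programs."""
    design = SimulationDesign(
        n_genes=4000, n_tumors_mut=8, n_tumors_wt=7, n_normals=5,
        frac_de_shared=0.05, frac_de_mut_only=0.05, frac_de_wt_only=0.05,
        frac_opposite=0.0, effect_log2fc=2.0, dispersion=0.1, seed=10,
        hotspots=[],
    )
    counts, samples, truth = simulate_counts(design)
    de_mut, de_wt = per_cluster_de(counts, samples)
    return counts, samples, truth, de_mut, de_wt


class TestPerClusterDE:
    def test_mut_only_genes_recovered(self, two_program):
        _, _, truth, de_mut, de_wt = two_program
        de_mut = de_mut.set_index("gene_id")
        de_wt = de_wt.set_index("gene_id")
        planted = truth.genes[truth.genes.status == "de_mut"]
        genes = [g for g in planted.gene_id if g in de_mut.index]
        expected_call = np.where(
            planted.set_index("gene_id").loc[genes, "sign"] > 0, "up", "down"
        )
        hit = (de_mut.loc[genes, "call"].to_numpy() == expected_call)
        unchanged = (de_wt.loc[genes, "call"] == "ns") & (
            de_wt.loc[genes, "log2fc"].abs() < 0.5
        )
        assert (hit & unchanged.to_numpy()).mean() >= 0.8

    def test_shared_genes_called_same_sign_in_both(self, two_program):
        _, _, truth, de_mut, de_wt = two_program
        de_mut = de_mut.set_index("gene_id")
        de_wt = de_wt.set_index("gene_id")
        planted = truth.genes[truth.genes.status == "de_shared"]
        genes = [g for g in planted.gene_id if g in de_mut.index]
        both = (de_mut.loc[genes, "call"] != "ns") & (
            de_mut.loc[genes, "call"] == de_wt.loc[genes, "call"]
        )
        assert both.mean() >= 0.8

    def test_same_universe(self, two_program):
        _, _, _, de_mut, de_wt = two_program
        assert de_mut["gene_id"].tolist() == de_wt["gene_id"].tolist()

    def test_classification_recovers_planted_structure(self, two_program):
        _, _, truth, de_mut, de_wt = two_program
        out = classify_genes(de_mut, de_wt).set_index("gene_id")
        status = truth.genes.set_index("gene_id").loc[out.index, "status"]
        disc = out.loc[status.isin(["de_mut", "de_wt"]), "category"]
        assert (disc == "discriminating").mean() >= 0.7
        shared = out.loc[status == "de_shared", "category"]
        assert (shared == "shared").mean() >= 0.7


class TestReplicationClusterTest:
    def test_planted_signature_split(self, two_program):
        counts, samples, truth, _, _ = two_program
        expr = vst(counts)
        tumors = samples[samples.tissue == "tumor"]
        genotypes = dict(zip(tumors.sample_id, tumors.group))
        # keep 8 mut + 4 wt, as in a replication cohort
        keep = tumors.sample_id[:8].tolist() + tumors.sample_id[8:12].tolist()
        signature = truth.genes.loc[
            truth.genes.status.isin(["de_mut", "de_wt"]), "gene_id"
        ].head(131)
        assignments, table, p = replication_cluster_test(
            expr[keep], {s: genotypes[s] for s in keep}, signature
        )
        acc = max(
            (assignments[tumors.sample_id[:8]] == 1).mean(),
            (assignments[tumors.sample_id[:8]] == 2).mean(),
        )
        assert acc == 1.0
        assert p < 0.05

    def test_perfect_separation_minimal_p(self):
        # duplicated, perfectly separated profiles: 5 mut at 0, 4 wt at 10
        expr = pd.DataFrame(
            np.hstack([np.zeros((30, 5)), np.full((30, 4), 10.0)]),
            index=[f"g{i}" for i in range(30)],
            columns=[f"m{i}" for i in range(5)] + [f"w{i}" for i in range(4)],
        )
        genotypes = {f"m{i}": "mut" for i in range(5)} | {f"w{i}": "wt" for i in range(4)}
        assignments, table, p = replication_cluster_test(expr, genotypes, expr.index)
        assert sorted(table.ravel().tolist()) == [0, 0, 4, 5]
        # minimal achievable two-sided p for these margins: the observed
        # table is the unique most extreme one, so p = its point probability
        assert p == pytest.approx(float(fisher_oracle(5, 0, 0, 4)), rel=1e-12)
        assert p == pytest.approx(1 / comb(9, 5), rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        expr = pd.DataFrame(np.zeros((5, 3)), columns=["a", "b", "c"],
                            index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match=">=4"):
            replication_cluster_test(expr, {"a": "mut", "b": "wt", "c": "wt"}, expr.index)
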