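"""Per-cluster differential expression versus normals, gene classification
into shared / opposite / discriminating categories, and the replication
hierarchical-clustering + Fisher exact genotype-association test.

Classification rule (applied to the two per-cluster DE tables on the same
gene universe):

* ``shared``          — significant in both clusters, same direction;
* ``opposite``        — significant in both clusters, opposite directions;
* ``discriminating``  — significant in exactly one cluster while the
  other cluster shows the reverse-signed fold change or an "unchanged"
  fold change strictly inside (-0.5, 0.5);
* ``other``           — everything else.

Significance means the DE call is 'up' or 'down' (|log2FC| >= 1 and
q < 0.01 at the defaults). The unchanged band is open at +/-0.5, so a
non-significant partner sitting exactly at |log2FC| = 0.5 with the same
sign leaves the gene in ``other``.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .de import nb_wald_test
from .io import CountMatrix

UNCHANGED_BAND = 0.5

CATEGORY_SHARED = "shared"
CATEGORY_OPPOSITE = "opposite"
CATEGORY_DISCRIMINATING = "discriminating"
CATEGORY_OTHER = "other"


def per_cluster_de(
    counts: CountMatrix,
    samples: pd.DataFrame,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the NB Wald test once per tumor cluster against normals, on a
    shared gene universe (genes expressed in any of the involved samples)."""
    involved = samples.loc[
        samples["group"].isin(["mut", "wt"]) | (samples["tissue"] == "normal"),
        "sample_id",
    ].tolist()
    sub = counts.subset_samples(involved)
    expressed = sub.values.sum(axis=1) > 0
    universe = [g for g, keep in zip(sub.gene_ids, expressed) if keep]
    common = counts.subset_genes(universe)
    de_mut = nb_wald_test(
        common, samples, "mut", "normal", lfc_threshold, q_threshold, filter_zero=False
    )
    de_wt = nb_wald_test(
        common, samples, "wt", "normal", lfc_threshold, q_threshold, filter_zero=False
    )
    return de_mut, de_wt


def _classify_one(
    lfc_a: float, sig_a: bool, lfc_b: float, sig_b: bool, band: float
) -> str:
    if sig_a and sig_b:
        return CATEGORY_SHARED if lfc_a * lfc_b > 0 else CATEGORY_OPPOSITE
    if sig_a ^ sig_b:
        lfc_sig, lfc_other = (lfc_a, lfc_b) if sig_a else (lfc_b, lfc_a)
        reverse = lfc_sig * lfc_other < 0
        unchanged = -band < lfc_other < band
        if reverse or unchanged:
            return CATEGORY_DISCRIMINATING
    return CATEGORY_OTHER


def classify_genes(
    de_mut: pd.DataFrame, de_wt: pd.DataFrame, band: float = UNCHANGED_BAND
) -> pd.DataFrame:
    """Assign every gene of the shared universe to exactly one category.

    Both inputs must cover the same genes (any order); output keeps the
    mut-table gene order.
    """
    if set(de_mut["gene_id"]) != set(de_wt["gene_id"]):
        raise ValueError("per-cluster DE tables cover different gene universes")
    wt = de_wt.set_index("gene_id").loc[de_mut["gene_id"]]
    lfc_m = de_mut["log2fc"].to_numpy()
    lfc_w = wt["log2fc"].to_numpy()
    sig_m = de_mut["call"].to_numpy() != "ns"
    sig_w = wt["call"].to_numpy() != "ns"

    both = sig_m & sig_w
    one = sig_m ^ sig_w
    same_sign = lfc_m * lfc_w > 0
    lfc_other = np.where(sig_m, lfc_w, lfc_m)
    reverse = lfc_m * lfc_w < 0
    unchanged = (lfc_other > -band) & (lfc_other < band)

    category = np.full(len(lfc_m), CATEGORY_OTHER, dtype=object)
    category[both & same_sign] = CATEGORY_SHARED
    category[both & ~same_sign] = CATEGORY_OPPOSITE
    category[one & (reverse | unchanged)] = CATEGORY_DISCRIMINATING

    return pd.DataFrame(
        {
            "gene_id": de_mut["gene_id"].to_numpy(),
            "log2fc_mut": lfc_m,
            "q_mut": de_mut["q"].to_numpy(),
            "call_mut": de_mut["call"].to_numpy(),
            "log2fc_wt": lfc_w,
            "q_wt": wt["q"].to_numpy(),
            "call_wt": wt["call"].to_numpy(),
            "category": category,
        }
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Uses the point-probability rule: with margins fixed, sum the
    hypergeometric probabilities of every table no more probable than the
    observed one. Computed in exact integer arithmetic, so ties are handled
    without floating-point guards.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    a, b, c, d = (int(x) for x in t.ravel())
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    n_total = a + b + c + d
    if n_total == 0:
        raise ValueError("all-zero table")
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    obs = comb(r1, a) * comb(r2, c1 - a)
    num = sum(
        w
        for x in range(lo, hi + 1)
        if (w := comb(r1, x) * comb(r2, c1 - x)) <= obs
    )
    return float(Fraction(num, comb(n_total, c1)))


def replication_cluster_test(
    expr_vst: pd.DataFrame,
    genotypes: dict[str, str] | pd.Series,
    gene_subset,
) -> tuple[pd.Series, np.ndarray, float]:
    """Cluster samples on a gene signature and test the genotype split.

    Average-linkage agglomerative clustering (Euclidean distance) on the
    ``gene_subset`` rows, cut at k=2; the resulting 2x2 genotype x cluster
    table is tested with the two-sided Fisher exact test. Returns
    (cluster assignments, contingency table [mut,wt] x [cluster1,2], p).
    """
    genotypes = dict(genotypes)
    sample_ids = [s for s in expr_vst.columns if s in genotypes]
    if len(sample_ids) < 4:
        raise ValueError(f"need >=4 genotyped samples, got {len(sample_ids)}")
    labels = [genotypes[s] for s in sample_ids]
    if set(labels) != {"mut", "wt"}:
        raise ValueError("both genotypes ('mut' and 'wt') must be present")
    subset = [g for g in gene_subset if g in expr_vst.index]
    if not subset:
        raise ValueError("gene subset shares no genes with the expression matrix")

    X = expr_vst.loc[subset, sample_ids].to_numpy(dtype=float).T
    Z = linkage(pdist(X, metric="euclidean"), method="average")
    clusters = fcluster(Z, t=2, criterion="maxclust")
    if len(np.unique(clusters)) < 2:
        raise ValueError("degenerate clustering: single cluster at k=2")

    table = np.zeros((2, 2), dtype=int)
    for lab, cl in zip(labels, clusters):
        table[0 if lab == "mut" else 1, cl - 1] += 1
    p = fisher_exact(table)
    return pd.Series(clusters, index=sample_ids, name="cluster"), table, p
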