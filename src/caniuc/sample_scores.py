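"""Per-tumor z-score significance against the normal baseline, and the
Jaccard coherence comparison between mutation-defined tumor groups.

Each tumor's expression (on the variance-stabilized scale) is standardized
gene-by-gene against the mean and standard deviation of the normal
samples; |z| >= 2.5 flags a gene as significantly changed in that tumor.
Tumors from the same mutation group are expected to share more flagged
genes with each other than with the other group, which is quantified by
pairwise Jaccard similarity of the flagged-gene sets and tested by a
group-label permutation test (Mann-Whitney U available as a legacy option,
but pairwise scores are not independent, so permutation is the default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

Z_THRESHOLD = 2.5


@dataclass
class SampleGeneSignificance:
    """Per-tumor z-scores (genes x tumors) plus derived significant sets."""

    z: pd.DataFrame
    z_threshold: float
    up_sets: dict[str, frozenset[str]]
    down_sets: dict[str, frozenset[str]]

    def all_sets(self) -> dict[str, frozenset[str]]:
        return {s: self.up_sets[s] | self.down_sets[s] for s in self.z.columns}

    def sets(self, kind: str) -> dict[str, frozenset[str]]:
        if kind == "up":
            return self.up_sets
        if kind == "down":
            return self.down_sets
        if kind == "all":
            return self.all_sets()
        raise ValueError(f"unknown set kind {kind!r}")


@dataclass
class JaccardComparison:
    """Pairwise Jaccard scores partitioned into within-mut / within-wt /
    between, with one-sided p-values that within-group similarity exceeds
    between-group similarity."""

    scores: pd.DataFrame  # columns: sample_a, sample_b, partition, jaccard
    p_within_mut_vs_between: float
    p_within_wt_vs_between: float
    method: str
    set_kind: str


def per_sample_zscores(
    expr_vst: pd.DataFrame,
    samples: pd.DataFrame,
    z_threshold: float = Z_THRESHOLD,
) -> SampleGeneSignificance:
    """Standardize each tumor against the normal baseline, gene by gene.

    The per-gene normal standard deviation (sample sd, n-1 denominator) is
    floored at the 5th percentile of the positive per-gene sds; with only a
    handful of normals, raw sds of near-constant genes are otherwise
    unstably small and produce runaway z-scores. The |z| >= threshold
    boundary is inclusive.
    """
    normal_ids = samples.loc[samples["tissue"] == "normal", "sample_id"].tolist()
    tumor_ids = samples.loc[samples["tissue"] == "tumor", "sample_id"].tolist()
    if len(normal_ids) < 3:
        raise ValueError(f"need >=3 normal samples, got {len(normal_ids)}")
    normals = expr_vst[normal_ids].to_numpy(dtype=float)
    mean = normals.mean(axis=1)
    sd = normals.std(axis=1, ddof=1)
    positive = sd[sd > 0]
    if positive.size == 0:
        raise ValueError("normal baseline has zero variance for every gene")
    floor = np.percentile(positive, 5)
    sd = np.maximum(sd, floor)

    tumors = expr_vst[tumor_ids].to_numpy(dtype=float)
    z = (tumors - mean[:, None]) / sd[:, None]
    z_frame = pd.DataFrame(z, index=expr_vst.index, columns=tumor_ids)

    genes = expr_vst.index.to_numpy()
    up_sets, down_sets = {}, {}
    for j, sample in enumerate(tumor_ids):
        up_sets[sample] = frozenset(genes[z[:, j] >= z_threshold])
        down_sets[sample] = frozenset(genes[z[:, j] <= -z_threshold])
    return SampleGeneSignificance(z_frame, z_threshold, up_sets, down_sets)


def jaccard(a: set | frozenset, b: set | frozenset) -> float:
    """|a n b| / |a u b|; 0 when both sets are empty."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def _pair_partition(ga: str, gb: str) -> str:
    if ga == gb == "mut":
        return "within_mut"
    if ga == gb == "wt":
        return "within_wt"
    return "between"


def compare_group_similarity(
    sig: SampleGeneSignificance,
    samples: pd.DataFrame,
    method: str = "permutation",
    n_perm: int = 10_000,
    seed: int = 0,
    set_kind: str = "all",
) -> JaccardComparison:
    """Test whether tumors share more flagged genes within their mutation
    group than across groups.

    The statistic per group is mean(within-group Jaccard) - mean(between
    Jaccard). The permutation null shuffles group labels over tumors
    (preserving group sizes); p = (1 + #{perm >= observed}) / (1 + n_perm).
    The Mann-Whitney option compares within vs between pair scores directly.
    """
    if method not in ("permutation", "mwu"):
        raise ValueError(f"unknown method {method!r}")
    tumors = samples.loc[samples["tissue"] == "tumor"]
    groups = dict(zip(tumors["sample_id"], tumors["group"]))
    ids = [s for s in sig.z.columns if s in groups]
    labels = np.array([groups[s] for s in ids])
    if (labels == "mut").sum() < 2 or (labels == "wt").sum() < 2:
        raise ValueError("need >=2 tumors in each group")

    sets = sig.sets(set_kind)
    n = len(ids)
    J = np.zeros((n, n))
    rows = []
    for i, j in combinations(range(n), 2):
        score = jaccard(sets[ids[i]], sets[ids[j]])
        J[i, j] = J[j, i] = score
        rows.append(
            {
                "sample_a": ids[i],
                "sample_b": ids[j],
                "partition": _pair_partition(labels[i], labels[j]),
                "jaccard": score,
            }
        )
    scores = pd.DataFrame(rows)

    iu = np.triu_indices(n, k=1)

    def _stats(lab: np.ndarray) -> tuple[float, float]:
        same = lab[:, None] == lab[None, :]
        mut_pair = (lab[:, None] == "mut") & (lab[None, :] == "mut")
        wt_pair = (lab[:, None] == "wt") & (lab[None, :] == "wt")
        between = ~same
        jm = J[iu][mut_pair[iu]]
        jw = J[iu][wt_pair[iu]]
        jb = J[iu][between[iu]]
        return jm.mean() - jb.mean(), jw.mean() - jb.mean()

    obs_mut, obs_wt = _stats(labels)

    if method == "permutation":
        rng = np.random.default_rng(seed)
        ge_mut = ge_wt = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            sm, sw = _stats(perm)
            ge_mut += sm >= obs_mut
            ge_wt += sw >= obs_wt
        p_mut = (1 + ge_mut) / (1 + n_perm)
        p_wt = (1 + ge_wt) / (1 + n_perm)
    else:
        within_mut = scores.loc[scores["partition"] == "within_mut", "jaccard"]
        within_wt = scores.loc[scores["partition"] == "within_wt", "jaccard"]
        between = scores.loc[scores["partition"] == "between", "jaccard"]
        p_mut = stats.mannwhitneyu(within_mut, between, alternative="greater").pvalue
        p_wt = stats.mannwhitneyu(within_wt, between, alternative="greater").pvalue

    return JaccardComparison(
        scores=scores,
        p_within_mut_vs_between=float(p_mut),
        p_within_wt_vs_between=float(p_wt),
        method=method,
        set_kind=set_kind,
    )
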