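"""Normalization and negative-binomial differential expression.

The test is a deliberately compact NB Wald test: median-of-ratios size
factors, per-gene method-of-moments dispersion shrunk halfway toward a
fitted mean-dispersion trend alpha(mu) = a0 + a1/mu, a delta-method
standard error for the log2 fold change, and Benjamini-Hochberg FDR
control. A gene is called up (down) when log2FC >= 1 (<= -1) and q < 0.01
— the calling thresholds the downstream analysis is built around. There is
no outlier replacement, independent filtering, or fold-change shrinkage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

LFC_THRESHOLD = 1.0
Q_THRESHOLD = 0.01
PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For genes with non-zero counts in every sample, each sample's factor is
    the median over genes of count / geometric-mean-across-samples.
    """
    values = counts.values.astype(float)
    all_pos = np.all(values > 0, axis=1)
    if not np.any(all_pos):
        raise ValueError(
            "no gene has non-zero counts in all samples; filter the matrix "
            "or provide size factors directly"
        )
    ref = values[all_pos]
    gm = np.exp(np.mean(np.log(ref), axis=1))
    factors = np.median(ref / gm[:, None], axis=0)
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def tpm(counts: CountMatrix, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: per sample, (count/length) normalized to 1e6.

    A sample whose counts are all zero gets TPM 0 everywhere.
    """
    lengths = lengths.reindex(counts.gene_ids)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()[:5]
        raise ValueError(f"non-positive gene lengths, e.g. {bad}")
    rate = counts.values / lengths.to_numpy()[:, None]
    total = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, rate / total * 1e6, 0.0)
    return pd.DataFrame(out, index=counts.gene_ids, columns=counts.sample_ids)


def vst(counts: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Variance-stabilizing transform: log2(count / size_factor + 1)."""
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.sample_ids)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    norm = counts.values / factors.to_numpy()[None, :]
    return pd.DataFrame(
        np.log2(norm + 1.0), index=counts.gene_ids, columns=counts.sample_ids
    )


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    log2fc: float | np.ndarray,
    q: float | np.ndarray,
    lfc_threshold: float = LFC_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
):
    """Significance call: 'up' if log2FC >= threshold and q below cutoff,
    'down' for the mirrored condition, otherwise 'ns'. Boundary |log2FC|
    exactly at the threshold counts as called."""
    log2fc = np.asarray(log2fc, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("q must lie in [0, 1]")
    sig = q < q_threshold
    call = np.where(
        sig & (log2fc >= lfc_threshold),
        "up",
        np.where(sig & (log2fc <= -lfc_threshold), "down", "ns"),
    )
    if call.ndim == 0:
        return call.item()
    return call


def _select_samples(samples: pd.DataFrame, label: str) -> list[str]:
    """A group label addresses either a tissue ('tumor'/'normal') or a
    mutation group ('mut'/'wt')."""
    if label in ("tumor", "normal"):
        chosen = samples.loc[samples["tissue"] == label, "sample_id"]
    else:
        chosen = samples.loc[samples["group"] == label, "sample_id"]
    return chosen.tolist()


def _dispersion_estimates(
    norm: np.ndarray, groups: list[np.ndarray], inv_sf: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene method-of-moments dispersion pooled across groups, and its
    50/50 shrinkage toward the fitted trend alpha(mu) = a0 + a1/mu."""
    n_genes = norm.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    for idx in groups:
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        # normalized counts have Var ~= mu * mean(1/s) + alpha * mu^2
        shot = m * np.mean(inv_sf[idx])
        with np.errstate(invalid="ignore", divide="ignore"):
            alpha_g = np.where(m > 0, (v - shot) / np.maximum(m, 1e-300) ** 2, 0.0)
        w = len(idx) - 1
        num += w * np.nan_to_num(alpha_g)
        den += w
    raw = np.maximum(num / np.maximum(den, 1), 0.0)

    mu = norm.mean(axis=1)
    use = (mu > 0) & np.isfinite(raw)
    if use.sum() >= 10:
        X = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
        coef, *_ = np.linalg.lstsq(X, raw[use], rcond=None)
        with np.errstate(divide="ignore"):
            trend = coef[0] + coef[1] / np.maximum(mu, 1e-300)
        trend = np.maximum(trend, DISPERSION_FLOOR)
    else:  # too few genes to fit a trend; fall back to the global mean
        trend = np.full(n_genes, max(raw[use].mean() if use.any() else 0.0, DISPERSION_FLOOR))
    shrunk = np.maximum(0.5 * raw + 0.5 * trend, DISPERSION_FLOOR)
    return raw, shrunk


def nb_wald_test(
    counts: CountMatrix,
    samples: pd.DataFrame,
    case_group: str,
    control_group: str,
    lfc_threshold: float = LFC_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
    filter_zero: bool = True,
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test on normalized counts.

    Returns a table with one row per tested gene: ``gene_id``,
    ``base_mean`` (mean normalized count over the tested samples),
    ``log2fc`` (case vs control, pseudocount 0.5), ``p``, ``q`` and
    ``call``. Genes with zero counts across all tested samples are removed
    before testing when ``filter_zero`` is set; rows keep the input gene
    order.
    """
    case_ids = _select_samples(samples, case_group)
    control_ids = _select_samples(samples, control_group)
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(case_ids)} {case_group!r} "
            f"vs {len(control_ids)} {control_group!r}"
        )
    sub = counts.subset_samples(case_ids + control_ids)
    gene_ids = np.array(sub.gene_ids)
    values = sub.values.astype(float)
    if filter_zero:
        expressed = values.sum(axis=1) > 0
        values = values[expressed]
        gene_ids = gene_ids[expressed]
    if len(gene_ids) == 0:
        raise ValueError("no expressed genes to test")

    sf = size_factors(CountMatrix(pd.DataFrame(
        np.maximum(values, 0).astype(np.int64), index=gene_ids, columns=sub.sample_ids
    ))).to_numpy()
    norm = values / sf[None, :]
    inv_sf = 1.0 / sf

    n_case = len(case_ids)
    case_idx = np.arange(n_case)
    control_idx = np.arange(n_case, n_case + len(control_ids))
    _, alpha = _dispersion_estimates(norm, [case_idx, control_idx], inv_sf)

    m_case = norm[:, case_idx].mean(axis=1)
    m_ctrl = norm[:, control_idx].mean(axis=1)
    log2fc = np.log2((m_case + PSEUDOCOUNT) / (m_ctrl + PSEUDOCOUNT))

    ln2sq = np.log(2.0) ** 2

    def _logscale_var(m: np.ndarray, idx: np.ndarray) -> np.ndarray:
        # Var(mean of normalized counts) under NB, then delta method
        var_mean = (m * np.sum(inv_sf[idx]) + alpha * m**2 * len(idx)) / len(idx) ** 2
        return var_mean / ((m + PSEUDOCOUNT) ** 2 * ln2sq)

    se = np.sqrt(_logscale_var(m_case, case_idx) + _logscale_var(m_ctrl, control_idx))
    se = np.maximum(se, 1e-12)
    wald = log2fc / se
    # t reference with the two-group residual df guards the plug-in SE at small n
    df = len(case_ids) + len(control_ids) - 2
    p = 2.0 * stats.t.sf(np.abs(wald), df)
    p = np.clip(p, 0.0, 1.0)
    both_zero = (m_case == 0) & (m_ctrl == 0)
    p[both_zero] = 1.0
    q = bh_adjust(p)
    call = call_de(log2fc, q, lfc_threshold, q_threshold)

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "call": call,
        }
    )
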