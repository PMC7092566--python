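"""Sliding-window positional scan for chromosomal hotspots of dysregulation.

Each gene gets a single genomic position: the mean over its transcripts of
the midpoint between first and last base. Chromosomes are tiled with 1 Mb
windows advancing in 250 kb steps (i.e. consecutive windows overlap by
750 kb), so every interior base is covered by exactly four windows. Each
window is tested for over-representation of up- (or down-) regulated genes
with the hypergeometric upper tail; windows beating the Bonferroni-
corrected threshold are merged (union of overlapping or adjacent
significant windows) into regions whose p-value is recomputed from the
region-level gene counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import TranscriptRecord

logger = logging.getLogger("caniuc")

WINDOW_WIDTH = 1_000_000
WINDOW_STEP = 250_000


def assign_positions(transcripts: list[TranscriptRecord]) -> pd.DataFrame:
    """One position per gene: mean over its transcripts of (start + end)/2.

    A gene with transcripts on more than one chromosome is an error.
    """
    if not transcripts:
        raise ValueError("no transcripts provided")
    frame = pd.DataFrame(transcripts, columns=["gene_id", "chrom", "start", "end"])
    chrom_counts = frame.groupby("gene_id")["chrom"].nunique()
    multi = chrom_counts.index[chrom_counts > 1].tolist()
    if multi:
        raise ValueError(f"genes with transcripts on multiple chromosomes: {multi}")
    frame["midpoint"] = (frame["start"] + frame["end"]) / 2.0
    grouped = frame.groupby("gene_id", sort=False).agg(
        chrom=("chrom", "first"), position=("midpoint", "mean")
    )
    return grouped.reset_index()[["gene_id", "chrom", "position"]]


def make_windows(
    chrom_lengths: dict[str, int],
    width: int = WINDOW_WIDTH,
    step: int = WINDOW_STEP,
) -> pd.DataFrame:
    """Tile each chromosome with overlapping windows anchored at 0.

    Starts advance by ``step`` while start < length; ends are truncated at
    the chromosome end rather than dropped.
    """
    if not (width > step > 0):
        raise ValueError(f"need width > step > 0, got width={width}, step={step}")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom!r}")
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + width, length)))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def hypergeometric_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked,
    n drawn). P(X >= 0) = 1 by convention."""
    if not (0 <= k <= n <= N):
        raise ValueError(f"need 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not (k <= K <= N):
        raise ValueError(f"need k <= K <= N, got k={k}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _scan_universe(
    positions: pd.DataFrame, de: pd.DataFrame, direction: str
) -> pd.DataFrame:
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    merged = positions.merge(de[["gene_id", "call"]], on="gene_id", how="inner")
    dropped = len(positions) - len(merged)
    if dropped or len(merged) < len(de):
        logger.warning(
            "positional scan universe: %d positioned genes lack DE records, "
            "%d tested genes lack positions; using %d genes",
            dropped,
            len(de) - len(merged),
            len(merged),
        )
    if merged.empty:
        raise ValueError("no genes have both a position and a DE record")
    merged["marked"] = merged["call"] == direction
    return merged


def scan(
    positions: pd.DataFrame,
    de: pd.DataFrame,
    chrom_lengths: dict[str, int],
    direction: str,
    alpha: float = 0.05,
    width: int = WINDOW_WIDTH,
    step: int = WINDOW_STEP,
) -> pd.DataFrame:
    """Hypergeometric over-representation of one call direction per window.

    Population N = genes with both a position and a DE record; K = those
    called in ``direction``. Window membership is half-open [start, end).
    ``significant`` applies Bonferroni over every window tested in this
    scan. Output is sorted by (chrom, start) and carries the scan
    parameters in ``DataFrame.attrs``.
    """
    universe = _scan_universe(positions, de, direction)
    N = len(universe)
    K = int(universe["marked"].sum())
    windows = make_windows(chrom_lengths, width, step)
    n_windows = len(windows)

    n_genes = np.zeros(n_windows, dtype=int)
    n_dir = np.zeros(n_windows, dtype=int)
    for chrom, idx in windows.groupby("chrom").groups.items():
        sub = universe[universe["chrom"] == chrom]
        pos = np.sort(sub["position"].to_numpy())
        marked_pos = np.sort(sub.loc[sub["marked"], "position"].to_numpy())
        w = windows.loc[idx]
        starts = w["start"].to_numpy()
        ends = w["end"].to_numpy()
        n_genes[idx] = np.searchsorted(pos, ends, side="left") - np.searchsorted(
            pos, starts, side="left"
        )
        n_dir[idx] = np.searchsorted(marked_pos, ends, side="left") - np.searchsorted(
            marked_pos, starts, side="left"
        )

    # vectorized upper tail; the k=0 convention (p=1) matches sf(-1)
    p = stats.hypergeom.sf(n_dir - 1, N, K, n_genes)
    out = windows.copy()
    out["n_genes"] = n_genes
    out["n_direction"] = n_dir
    out["p_hyper"] = p
    out["significant"] = p < alpha / n_windows
    out = out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    out.attrs.update(
        {
            "direction": direction,
            "alpha": alpha,
            "n_windows": n_windows,
            "population": N,
            "marked": K,
            "width": width,
            "step": step,
        }
    )
    return out


def merge_regions(
    windows: pd.DataFrame, positions: pd.DataFrame, de: pd.DataFrame
) -> pd.DataFrame:
    """Merge overlapping-or-adjacent significant windows into regions.

    Region gene counts are re-tallied over the union interval and the
    region p-value is the hypergeometric upper tail on those counts with
    the same population and marked totals as the originating scan.
    """
    direction = windows.attrs.get("direction")
    if direction is None:
        raise ValueError("windows must come from scan() (missing attrs)")
    universe = _scan_universe(positions, de, direction)
    N = len(universe)
    K = int(universe["marked"].sum())

    sig = windows[windows["significant"]].sort_values(["chrom", "start"])
    regions = []
    for chrom, group in sig.groupby("chrom", sort=True):
        current = None
        for row in group.itertuples(index=False):
            if current is not None and row.start <= current[1]:
                current[1] = max(current[1], row.end)
            else:
                if current is not None:
                    regions.append((chrom, *current))
                current = [row.start, row.end]
        if current is not None:
            regions.append((chrom, *current))

    rows = []
    for chrom, start, end in regions:
        sub = universe[universe["chrom"] == chrom]
        inside = (sub["position"] >= start) & (sub["position"] < end)
        n = int(inside.sum())
        k = int((inside & sub["marked"]).sum())
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_genes": n,
                "n_direction": k,
                "p_region": hypergeometric_enrichment(k, n, K, N),
                "direction": direction,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_genes", "n_direction", "p_region", "direction"],
    )
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
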