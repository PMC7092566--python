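"""Synthetic bulk RNA-seq data with planted, recoverable structure.

The generator emulates the study design the pipeline targets: ~15 tumors
split into two mutation-defined groups plus ~5 normal tissues, negative-
binomial counts over a realistic dynamic range, planted differentially
expressed genes (shared between groups, group-specific, and a small
opposite-direction fraction), and chromosomal windows over-populated with
dysregulated genes. Every planted feature is recorded in a
:class:`SimulationTruth` so downstream stages can be scored for recovery.

Counts are drawn NB(mean = baseline x size_factor x 2^(signed log2FC when
the sample's group carries the effect), dispersion alpha) with
var = mu + alpha * mu^2. Baseline means are log-normal on the log2 scale
(mean 6, sd 2), spanning low-count through saturated genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSet, GeneSetCollection, TranscriptRecord

STATUS_NULL = "null"
STATUS_SHARED = "de_shared"
STATUS_MUT = "de_mut"
STATUS_WT = "de_wt"
STATUS_OPPOSITE = "de_opposite"


@dataclass(frozen=True)
class Hotspot:
    """A chromosomal interval deliberately over-populated with genes
    dysregulated in one direction in one tumor group."""

    chrom: str
    start: int
    end: int
    n_genes: int
    direction: str  # "up" | "down"
    group: str  # "mut" | "wt" | "shared"


@dataclass
class SimulationDesign:
    """Parameters of one synthetic dataset.

    Defaults reproduce the target study's scale: 8 + 7 tumors in two
    mutation groups, 5 normals, 20,000 genes on 10 pseudo-chromosomes of
    60 Mb (one chromosome per 2000 genes, ~33 genes/Mb), ~6% shared and
    ~5% per-group planted DE genes at |log2FC| = 2, and a default hotspot
    mirroring the strongest reported locus: 45 up-regulated genes of the
    wt group packed into a 2.5 Mb interval.
    """

    n_genes: int = 20_000
    n_tumors_mut: int = 8
    n_tumors_wt: int = 7
    n_normals: int = 5
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.1
    frac_de_shared: float = 0.06
    frac_de_mut_only: float = 0.05
    frac_de_wt_only: float = 0.05
    frac_opposite: float = 0.0004
    effect_log2fc: float = 2.0
    n_chroms: int = 10
    chrom_length: int = 60_000_000
    hotspots: list[Hotspot] = field(
        default_factory=lambda: [Hotspot("chr1", 36_250_000, 38_750_000, 45, "up", "wt")]
    )
    library_size_sd: float = 0.2
    library_size_factors: Sequence[float] | None = None
    seed: int = 0

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}

    def n_samples(self) -> int:
        return self.n_tumors_mut + self.n_tumors_wt + self.n_normals

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if min(self.n_tumors_mut, self.n_tumors_wt) < 2 or self.n_normals < 2:
            raise ValueError("need >=2 samples per tumor group and >=2 normals")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        fracs = (
            self.frac_de_shared
            + self.frac_de_mut_only
            + self.frac_de_wt_only
            + self.frac_opposite
        )
        if not 0 <= fracs <= 1:
            raise ValueError("DE fractions must be non-negative and sum to <= 1")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be non-negative")
        if self.n_chroms < 1 or self.chrom_length <= 0:
            raise ValueError("need >=1 chromosome of positive length")
        names = set(self.chrom_names())
        for h in self.hotspots:
            if h.chrom not in names:
                raise ValueError(f"hotspot chromosome {h.chrom!r} not in design")
            if not (0 <= h.start < h.end <= self.chrom_length):
                raise ValueError(f"hotspot interval out of chromosome bounds: {h}")
            if h.direction not in ("up", "down"):
                raise ValueError(f"hotspot direction must be up/down: {h}")
            if h.group not in ("mut", "wt", "shared"):
                raise ValueError(f"hotspot group must be mut/wt/shared: {h}")
        if self.library_size_factors is not None:
            lsf = np.asarray(self.library_size_factors, dtype=float)
            if lsf.shape != (self.n_samples(),) or np.any(lsf <= 0):
                raise ValueError("library_size_factors must be positive, one per sample")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset.

    ``genes`` holds one row per gene: planted status, sign, and log2FC.
    ``sample_clusters`` maps tumor sample -> planted cluster label.
    ``hotspots`` are the planted intervals; ``hotspot_genes`` maps each
    hotspot index to the gene ids placed inside it (filled in by
    :func:`simulate_annotation`).
    """

    genes: pd.DataFrame
    sample_clusters: dict[str, str]
    hotspots: list[Hotspot]
    hotspot_genes: dict[int, list[str]] = field(default_factory=dict)

    def planted_de(self) -> set[str]:
        mask = self.genes["status"] != STATUS_NULL
        return set(self.genes.loc[mask, "gene_id"])


def _assign_status(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    n = design.n_genes
    n_shared = int(round(design.frac_de_shared * n))
    n_mut = int(round(design.frac_de_mut_only * n))
    n_wt = int(round(design.frac_de_wt_only * n))
    n_opp = int(round(design.frac_opposite * n))
    if n_shared + n_mut + n_wt + n_opp > n:
        raise ValueError("DE fractions leave no null genes")
    perm = rng.permutation(n)
    status = np.full(n, STATUS_NULL, dtype=object)
    cursor = 0
    for label, count in [
        (STATUS_SHARED, n_shared),
        (STATUS_MUT, n_mut),
        (STATUS_WT, n_wt),
        (STATUS_OPPOSITE, n_opp),
    ]:
        status[perm[cursor : cursor + count]] = label
        cursor += count
    sign = np.where(rng.random(n) < 0.5, 1, -1)
    sign[status == STATUS_NULL] = 0
    log2fc = np.where(status == STATUS_NULL, 0.0, design.effect_log2fc)
    gene_ids = [f"g{i:05d}" for i in range(n)]
    return pd.DataFrame(
        {"gene_id": gene_ids, "status": status, "sign": sign, "log2fc": log2fc}
    )


def simulate_counts(
    design: SimulationDesign,
) -> tuple[CountMatrix, pd.DataFrame, SimulationTruth]:
    """Draw a count matrix, sample table, and ground truth from a design."""
    design.validate()
    rng = np.random.default_rng(design.seed)

    genes = _assign_status(design, rng)
    n = design.n_genes

    sample_ids = (
        [f"mut{i + 1:02d}" for i in range(design.n_tumors_mut)]
        + [f"wt{i + 1:02d}" for i in range(design.n_tumors_wt)]
        + [f"norm{i + 1:02d}" for i in range(design.n_normals)]
    )
    tissue = ["tumor"] * (design.n_tumors_mut + design.n_tumors_wt) + [
        "normal"
    ] * design.n_normals
    group = (
        ["mut"] * design.n_tumors_mut
        + ["wt"] * design.n_tumors_wt
        + ["none"] * design.n_normals
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "tissue": tissue, "group": group})

    baseline = 2.0 ** rng.normal(design.baseline_log2_mean, design.baseline_log2_sd, n)

    if design.library_size_factors is not None:
        sf = np.asarray(design.library_size_factors, dtype=float)
    else:
        sf = 2.0 ** rng.normal(0.0, design.library_size_sd, design.n_samples())
        sf /= np.exp(np.mean(np.log(sf)))  # geometric mean 1

    status = genes["status"].to_numpy()
    sign = genes["sign"].to_numpy().astype(float)
    lfc = genes["log2fc"].to_numpy()

    # per-gene signed shift applied to each tumor group (normals never shift)
    shift_mut = np.zeros(n)
    shift_wt = np.zeros(n)
    shared = status == STATUS_SHARED
    shift_mut[shared] = sign[shared] * lfc[shared]
    shift_wt[shared] = sign[shared] * lfc[shared]
    mut_only = status == STATUS_MUT
    shift_mut[mut_only] = sign[mut_only] * lfc[mut_only]
    wt_only = status == STATUS_WT
    shift_wt[wt_only] = sign[wt_only] * lfc[wt_only]
    opp = status == STATUS_OPPOSITE
    shift_mut[opp] = sign[opp] * lfc[opp]
    shift_wt[opp] = -sign[opp] * lfc[opp]

    group_shift = {"mut": shift_mut, "wt": shift_wt, "none": np.zeros(n)}
    mean = np.empty((n, design.n_samples()))
    for j, g in enumerate(group):
        mean[:, j] = baseline * sf[j] * 2.0 ** group_shift[g]

    r = 1.0 / design.dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)

    frame = pd.DataFrame(counts, index=genes["gene_id"].tolist(), columns=sample_ids)
    truth = SimulationTruth(
        genes=genes,
        sample_clusters={
            s: g for s, g, t in zip(sample_ids, group, tissue) if t == "tumor"
        },
        hotspots=list(design.hotspots),
    )
    return CountMatrix(frame), samples, truth


_HOTSPOT_STATUS = {"mut": STATUS_MUT, "wt": STATUS_WT, "shared": STATUS_SHARED}


def simulate_annotation(
    design: SimulationDesign, truth: SimulationTruth
) -> list[TranscriptRecord]:
    """Place genes on the synthetic genome, 1-3 transcripts each.

    Non-hotspot genes are uniform on a random chromosome; each hotspot is
    packed with the demanded number of genes carrying the matching planted
    status and direction, positioned uniformly inside its interval. The
    mean of a gene's transcript midpoints equals its drawn position
    exactly, so positional assignment downstream recovers the planted
    geometry. Records the chosen hotspot gene ids in ``truth.hotspot_genes``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed + 1)
    genes = truth.genes
    n = len(genes)
    margin = 50_000
    if design.chrom_length <= 2 * margin:
        raise ValueError("chromosome too short for transcript placement margin")

    chrom_names = design.chrom_names()
    chrom_idx = rng.integers(0, design.n_chroms, n)
    position = rng.uniform(margin, design.chrom_length - margin, n)

    status = genes["status"].to_numpy()
    sign = genes["sign"].to_numpy()
    claimed = np.zeros(n, dtype=bool)
    truth.hotspot_genes = {}
    for h_i, h in enumerate(truth.hotspots):
        want_status = _HOTSPOT_STATUS[h.group]
        want_sign = 1 if h.direction == "up" else -1
        eligible = np.flatnonzero((status == want_status) & (sign == want_sign) & ~claimed)
        if len(eligible) < h.n_genes:
            raise ValueError(
                f"hotspot {h} demands {h.n_genes} genes with status {want_status} "
                f"sign {want_sign:+d} but only {len(eligible)} are available"
            )
        chosen = rng.choice(eligible, size=h.n_genes, replace=False)
        claimed[chosen] = True
        chrom_idx[chosen] = chrom_names.index(h.chrom)
        lo = max(h.start, margin)
        hi = min(h.end, design.chrom_length - margin)
        position[chosen] = rng.uniform(lo, hi, h.n_genes)
        truth.hotspot_genes[h_i] = genes["gene_id"].iloc[chosen].tolist()

    records: list[TranscriptRecord] = []
    gene_ids = genes["gene_id"].tolist()
    n_tx = rng.integers(1, 4, n)
    for i in range(n):
        chrom = chrom_names[chrom_idx[i]]
        k = int(n_tx[i])
        jitter = rng.uniform(-5_000, 5_000, k)
        midpoints = position[i] + jitter - jitter.mean()
        half = rng.uniform(500, 25_000, k)
        for m, hl in zip(midpoints, half):
            start = int(round(m - hl))
            end = int(round(m + hl))
            # integer rounding moves each midpoint by <0.5 bp; keep intervals valid
            records.append(TranscriptRecord(gene_ids[i], chrom, start, max(end, start + 1)))
    return records


def simulate_gene_sets(
    truth: SimulationTruth,
    n_sets: int = 10,
    seed: int = 0,
    enriched_size: int = 100,
    enriched_frac: float = 0.6,
) -> GeneSetCollection:
    """One set enriched in planted DE genes plus random background sets.

    The enriched set (named ``PLANTED_DE``) draws ``enriched_frac`` of its
    members from the planted DE genes and the rest from null genes; the
    remaining ``n_sets - 1`` sets are uniform draws from the whole universe.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    universe = truth.genes["gene_id"].to_numpy()
    planted = truth.genes.loc[truth.genes["status"] != STATUS_NULL, "gene_id"].to_numpy()
    nulls = truth.genes.loc[truth.genes["status"] == STATUS_NULL, "gene_id"].to_numpy()

    n_planted = min(int(round(enriched_frac * enriched_size)), len(planted))
    n_null = min(enriched_size - n_planted, len(nulls))
    members = np.concatenate(
        [
            rng.choice(planted, size=n_planted, replace=False),
            rng.choice(nulls, size=n_null, replace=False),
        ]
    )
    sets = {"PLANTED_DE": GeneSet("planted dysregulated genes", frozenset(members))}
    for i in range(n_sets - 1):
        size = int(rng.integers(20, 201))
        size = min(size, len(universe))
        draw = rng.choice(universe, size=size, replace=False)
        sets[f"RANDOM_{i + 1:02d}"] = GeneSet("random background set", frozenset(draw))
    return GeneSetCollection(sets)


def null_design(**overrides) -> SimulationDesign:
    """A design with no planted structure (all DE fractions zero)."""
    base = SimulationDesign(
        frac_de_shared=0.0, frac_de_mut_only=0.0, frac_de_wt_only=0.0,
        frac_opposite=0.0, hotspots=[],
    )
    return replace(base, **overrides)
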