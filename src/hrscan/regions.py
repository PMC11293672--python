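"""Genomic regions of differentiation: clustering, strict culling, and the
divergence-over-time statistic.

Significant loci are grouped by single-linkage clustering along each
chromosome: loci within ``gap_bp`` (default 1 Mbp) of another belong to one
region; groups whose closest SNPs are further apart are split.  "Strict"
culling then keeps only regions unlikely to be sampling artifacts.

The divergence-over-time statistic asks, locus by locus, whether the HR lines'
allele-frequency trajectory between two sampled generations differs from the
control lines': a paired T statistic over the 4 lines of each linetype is
computed on the per-line AF change, and ``D = |T_HR - T_C|``.  The null is
built by pooling D over all loci under each of the 35 line permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .afdata import AFTable, intersect_shared_loci
from .difftest import PermutationSet, ScanResult, arcsine_transform

__all__ = [
    "Region",
    "cluster_regions",
    "strict_cull",
    "DivergenceResult",
    "divergence_scan",
    "divergence_regions",
    "region_af_profile",
]

DEFAULT_GAP_BP = 1_000_000


@dataclass
class Region:
    """A clustered interval of significant loci (1-based, inclusive ends)."""

    chrom: str
    start: int
    end: int
    n_significant: int
    min_p: float
    loci_pos: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    strict: bool | None = None

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")
        if self.n_significant < 1:
            raise ValueError("region must contain at least one significant locus")


def cluster_regions(
    chrom: np.ndarray,
    pos: np.ndarray,
    p: np.ndarray | None = None,
    gap_bp: int = DEFAULT_GAP_BP,
) -> list[Region]:
    """Single-linkage clustering of loci along chromosomes with a gap rule.

    Consecutive loci on the same chromosome separated by more than ``gap_bp``
    start a new region.  ``p`` (optional per-locus p-values) populates
    ``min_p``.  Loci on different chromosomes never merge.  Idempotent and
    order-independent (input is sorted internally).
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    if p is None:
        p = np.full(len(pos), np.nan)
    p = np.asarray(p, dtype=np.float64)
    order = np.lexsort((pos, chrom))
    chrom, pos, p = chrom[order], pos[order], p[order]

    regions: list[Region] = []
    start = 0
    for i in range(1, len(pos) + 1):
        boundary = (
            i == len(pos)
            or chrom[i] != chrom[i - 1]
            or pos[i] - pos[i - 1] > gap_bp
        )
        if boundary:
            block = slice(start, i)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mp = float(np.nanmin(p[block])) if np.any(~np.isnan(p[block])) else np.nan
            regions.append(
                Region(
                    chrom=str(chrom[start]),
                    start=int(pos[start]),
                    end=int(pos[i - 1]),
                    n_significant=i - start,
                    min_p=mp,
                    loci_pos=pos[block].copy(),
                )
            )
            start = i
    return regions


def strict_cull(
    regions: list[Region],
    test_kind: str = "wrt",
    min_loci: int = 20,
    p_cut: float | None = None,
) -> list[Region]:
    """Apply "strict" culling to clustered regions.

    Regions with a single significant locus are dropped first.  A region is
    then kept iff it has at least ``min_loci`` significant loci OR its lowest
    p-value is below ``p_cut``.  The default cutoff is 1e-4 for the regularized
    tests and 1e-6 for the plain Welch test (whose p-values run naturally
    lower).  Output is a subset of the input; kept regions get ``strict=True``.
    """
    if p_cut is None:
        p_cut = 1e-6 if test_kind == "welch" else 1e-4
    kept = []
    for r in regions:
        if r.n_significant == 1:
            continue
        if r.n_significant >= min_loci or (not np.isnan(r.min_p) and r.min_p < p_cut):
            r.strict = True
            kept.append(r)
    return kept


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": np.arange(1, len(regions) + 1),
            "chrom": [r.chrom for r in regions],
            "minPOS": [r.start for r in regions],
            "maxPOS": [r.end for r in regions],
            "size": [r.size for r in regions],
            "n_loci": [r.n_significant for r in regions],
            "min_p": [r.min_p for r in regions],
            "strict": [bool(r.strict) for r in regions],
        }
    )


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Paired T over the last axis: mean(d) / (sd(d)/sqrt(n)); nan if sd == 0."""
    n = diff.shape[-1]
    m = diff.mean(axis=-1)
    sd = diff.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(sd > 0, t, np.nan)


@dataclass
class DivergenceResult:
    """Per-locus divergence-over-time statistic and its permutation threshold."""

    chrom: np.ndarray
    pos: np.ndarray
    d: np.ndarray  # |T_HR - T_C| per shared locus; nan where either T failed
    threshold: float  # upper-5% point of the pooled permutation null
    exceedance: float  # fraction of observed finite D above threshold
    n_null: int

    @property
    def n_loci(self) -> int:
        return len(self.pos)


def divergence_scan(
    g22: AFTable,
    g61: AFTable,
    perms: PermutationSet,
    tail: float = 0.05,
    transform: bool = False,
) -> DivergenceResult:
    """Divergence-over-time scan between two sampled generations.

    For each locus shared by the two tables, a paired T statistic across the 4
    lines of each linetype is computed on the per-line AF change
    (later - earlier); ``D = |T_HR - T_C|``.  Loci where either paired T fails
    (zero variance of the changes) are excluded.  The null pools D over all
    loci under each of the 35 unordered line partitions; the threshold is the
    value exceeded by ``tail`` of the null mass, and the exceedance is the
    share of observed D above it.  ``transform`` applies the angular transform
    to AF before differencing (off by default: the statistic is defined on raw
    per-line mean allele frequencies).
    """
    a, b = intersect_shared_loci(g22, g61)
    fa, fb = (arcsine_transform(a.af), arcsine_transform(b.af)) if transform else (a.af, b.af)
    diff = fb - fa  # (n_loci, 8): later minus earlier

    def d_for(ga, gb):
        return np.abs(_paired_t(diff[:, ga]) - _paired_t(diff[:, gb]))

    obs_pa, obs_pb = perms.partitions[perms.observed_index]
    # orient the observed partition so group A is the HR set
    hr = frozenset(int(i) for i in a.design.hr_indices)
    if frozenset(obs_pa) != hr:
        obs_pa, obs_pb = obs_pb, obs_pa
    d_obs = d_for(np.array(obs_pa), np.array(obs_pb))

    null = []
    for pa, pb in perms.partitions:
        null.append(d_for(np.array(pa), np.array(pb)))
    pool = np.concatenate(null)
    pool = pool[~np.isnan(pool)]
    threshold = float(np.quantile(pool, 1.0 - tail)) if pool.size else np.nan
    finite = d_obs[~np.isnan(d_obs)]
    exceedance = float(np.mean(finite > threshold)) if finite.size else np.nan
    return DivergenceResult(a.chrom, a.pos, d_obs, threshold, exceedance, pool.size)


def divergence_regions(
    result: DivergenceResult,
    top_n: int = 1400,
    min_loci: int = 20,
    gap_bp: int = DEFAULT_GAP_BP,
) -> list[Region]:
    """Cluster the ``top_n`` most divergent loci and keep dense clusters.

    Takes the ``top_n`` loci by D (all, with a warning, if fewer are defined),
    clusters them with the 1 Mbp gap rule, and keeps clusters containing at
    least ``min_loci`` of them.
    """
    finite = ~np.isnan(result.d)
    idx = np.flatnonzero(finite)
    if idx.size < top_n:
        warnings.warn(
            f"only {idx.size} loci with defined D < top_n={top_n}; using all",
            stacklevel=2,
        )
        top = idx
    else:
        order = np.argsort(result.d[idx])[::-1]
        top = idx[order[:top_n]]
    regions = cluster_regions(result.chrom[top], result.pos[top], gap_bp=gap_bp)
    return [r for r in regions if r.n_significant >= min_loci]


def region_af_profile(
    regions: list[Region],
    g22: AFTable,
    g61: AFTable,
    p_source: ScanResult,
    anchor: str = "g22",
    p_nominal: float = 0.05,
) -> pd.DataFrame:
    """Per-region, per-line mean AF at both generations.

    For each region, its loci with nominal ``p < p_nominal`` in the anchor
    generation's scan are selected, matched by (chrom, pos) into the other
    generation, and the AF averaged per line and generation.  Regions whose
    anchor loci are absent from the other generation report missing (NaN)
    means there, not zeros.
    """
    anchor_table = g22 if anchor == "g22" else g61
    other_table = g61 if anchor == "g22" else g22
    if p_source.n_loci != anchor_table.n_loci or not np.array_equal(
        p_source.pos, anchor_table.pos
    ):
        raise ValueError("p_source loci must match the anchor table")

    other_key = pd.MultiIndex.from_arrays([other_table.chrom, other_table.pos])
    rows = []
    for ri, r in enumerate(regions, start=1):
        with np.errstate(invalid="ignore"):
            sel = (
                (anchor_table.chrom == r.chrom)
                & (anchor_table.pos >= r.start)
                & (anchor_table.pos <= r.end)
                & (p_source.p < p_nominal)
            )
        anchor_af = anchor_table.af[sel]
        key = pd.MultiIndex.from_arrays([anchor_table.chrom[sel], anchor_table.pos[sel]])
        loc = other_key.get_indexer(key)
        matched = loc[loc >= 0]
        other_af = other_table.af[matched] if matched.size else None
        for j, line in enumerate(anchor_table.design.lines):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                af_anchor = float(np.nanmean(anchor_af[:, j])) if anchor_af.size else np.nan
                af_other = float(np.nanmean(other_af[:, j])) if other_af is not None else np.nan
            rows.append(
                {
                    "region": ri,
                    "chrom": r.chrom,
                    "line": line,
                    "linetype": anchor_table.design.linetypes[j],
                    "af_g22": af_anchor if anchor == "g22" else af_other,
                    "af_g61": af_other if anchor == "g22" else af_anchor,
                    "n_anchor_loci": int(sel.sum()),
                    "n_matched_loci": int(matched.size),
                }
            )
    return pd.DataFrame(rows)
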