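"""Monte-Carlo models of allele-frequency estimation error.

Two measurement models mirror how the two sampled generations of the
experiment were sequenced:

* **Pooled sequencing** (generation-22 style): DNA from ~20 mice is pooled and
  read at a modest depth, so the 40 underlying allele copies are themselves
  resampled with replacement by the reads.  Estimated AF = alt reads / depth.
* **Individual genotyping** (generation-61 style): 10 mice are genotyped
  individually; rare genotyping errors collapse heterozygotes to homozygotes.
  Estimated AF = alt alleles / 20.

Both models are unbiased but the pooled model carries an extra read-resampling
layer and therefore a larger sampling variance.  Grids of the estimated-AF
distribution on a 0.05-spaced lattice of true frequencies support both power
analyses and noise injection into forward-simulation output.

The empirical depth and genotype-quality distributions of the original data
are not published; the defaults reproduce their stated means (24X pooled
depth with a DP >= 10 floor; genotype error ~1% from Phred-scaled qualities)
and are pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .afdata import AFTable
from .difftest import arcsine_transform, welch_t_arrays

__all__ = [
    "PooledSeqModel",
    "IndividualSeqModel",
    "AFDistributionGrid",
    "sample_pooled_af",
    "sample_individual_af",
    "build_grid",
    "power_af_test",
    "inject_sampling_noise",
]


def _default_depth(rng: np.random.Generator, size: int) -> np.ndarray:
    """Poisson(24) read depth truncated at >= 10 (rejection resampling)."""
    d = rng.poisson(24.0, size=size)
    for _ in range(100):
        low = d < 10
        if not low.any():
            break
        d[low] = rng.poisson(24.0, size=int(low.sum()))
    return np.maximum(d, 10)


def _default_error_prob(rng: np.random.Generator, size) -> np.ndarray:
    """Per-call genotyping error 10^(-GQ/10), GQ ~ Normal(25, 8) clipped >= 6."""
    gq = np.clip(rng.normal(25.0, 8.0, size=size), 6.0, None)
    return 10.0 ** (-gq / 10.0)


@dataclass(frozen=True)
class PooledSeqModel:
    """Pooled-sequencing measurement model (default: 20 mice, ~24X depth)."""

    n_mice: int = 20
    depth_distribution: Callable[[np.random.Generator, int], np.ndarray] = _default_depth


@dataclass(frozen=True)
class IndividualSeqModel:
    """Individual-genotyping measurement model (default: 10 mice, ~1% error)."""

    n_mice: int = 10
    genotype_error_distribution: Callable = _default_error_prob


def sample_pooled_af(
    p: float, model: PooledSeqModel, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Estimated AF under pooled sequencing at true population AF ``p``.

    Draws ``2 * n_mice`` allele copies ~ Bernoulli(p), a read depth ``d`` from
    the model's depth distribution, then ``d`` reads with replacement from the
    allele pool; returns alt reads / d.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("true AF must be in [0, 1]")
    n_alleles = 2 * model.n_mice
    alt = rng.binomial(n_alleles, p, size=size)
    depth = model.depth_distribution(rng, size)
    reads = rng.binomial(depth, alt / n_alleles)
    return reads / depth


def sample_individual_af(
    p: float, model: IndividualSeqModel, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Estimated AF under individual genotyping at true population AF ``p``.

    Each of ``n_mice`` genotypes ~ Binomial(2, p).  Each heterozygote is, with
    its sampled error probability, collapsed to a homozygote of its first
    allele (direction-symmetric on average).  Returns alt alleles / 2 n_mice.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("true AF must be in [0, 1]")
    geno = rng.binomial(2, p, size=(size, model.n_mice))
    err = model.genotype_error_distribution(rng, (size, model.n_mice))
    het = geno == 1
    flips = het & (rng.random((size, model.n_mice)) < err)
    # first allele of a heterozygote is alt or ref with equal probability
    to_alt = rng.random((size, model.n_mice)) < 0.5
    geno = np.where(flips, np.where(to_alt, 2, 0), geno)
    return geno.sum(axis=1) / (2 * model.n_mice)


GRID_POINTS = np.round(np.arange(1, 20) * 0.05, 2)  # 0.05, 0.10, ..., 0.95


@dataclass
class AFDistributionGrid:
    """Empirical estimated-AF distributions on the 0.05-spaced true-AF grid."""

    points: np.ndarray  # (19,)
    samples: np.ndarray  # (19, n_rep)

    @property
    def n_rep(self) -> int:
        return self.samples.shape[1]

    def save_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.samples.T, columns=[f"{p:.2f}" for p in self.points]).to_csv(
            path, sep="\t", index=False
        )


def build_grid(
    model, rng: np.random.Generator, n_rep: int = 100_000
) -> AFDistributionGrid:
    """Sample ``n_rep`` estimated AFs at each of the 19 true-AF grid points."""
    sampler = (
        sample_pooled_af if isinstance(model, PooledSeqModel) else sample_individual_af
    )
    samples = np.empty((len(GRID_POINTS), n_rep))
    for i, p in enumerate(GRID_POINTS):
        samples[i] = sampler(float(p), model, rng, size=n_rep)
    return AFDistributionGrid(points=GRID_POINTS.copy(), samples=samples)


def power_af_test(
    model,
    rng: np.random.Generator,
    p_a: float = 0.4,
    p_b: float = 0.6,
    n_rep: int = 10_000,
    n_lines: int = 4,
    alpha: float = 0.05,
) -> float:
    """Power of the 4-vs-4 Welch test under a measurement model.

    Per replicate, ``n_lines`` estimated AFs are drawn at true AF ``p_a`` and
    ``n_lines`` at ``p_b``, angular-transformed, and compared with the
    unequal-variance T-test; power is the fraction of replicates with
    ``p <= alpha``.  Degenerate replicates (test undefined) count as
    non-significant.
    """
    sampler = (
        sample_pooled_af if isinstance(model, PooledSeqModel) else sample_individual_af
    )
    a = sampler(p_a, model, rng, size=n_rep * n_lines).reshape(n_rep, n_lines)
    b = sampler(p_b, model, rng, size=n_rep * n_lines).reshape(n_rep, n_lines)
    _, p, _ = welch_t_arrays(arcsine_transform(a), arcsine_transform(b))
    return float(np.mean(p[~np.isnan(p)] <= alpha) * (1 - np.isnan(p).mean()))


def inject_sampling_noise(
    table: AFTable, grid: AFDistributionGrid, rng: np.random.Generator,
    preserve_fixed: bool = False,
) -> AFTable:
    """Replace each AF with a draw from the matching grid distribution.

    Each (finite) allele frequency is rounded to the nearest grid point (values
    outside [0.05, 0.95], including fixed loci, clamp to the nearest endpoint
    unless ``preserve_fixed``) and replaced by a random draw from that point's
    empirical estimated-AF distribution.  Missing values stay missing.
    """
    af = table.af
    out = af.copy()
    finite = ~np.isnan(af)
    idx = np.clip(np.rint(af[finite] / 0.05).astype(int), 1, 19) - 1
    cols = rng.integers(0, grid.n_rep, size=idx.size)
    out[finite] = grid.samples[idx, cols]
    if preserve_fixed:
        fixed = finite & ((af == 0.0) | (af == 1.0))
        out[fixed] = af[fixed]
    from dataclasses import replace

    return replace(table, af=out)
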