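"""Synthetic per-line allele-frequency tables with the structure the scans
assume: 8 exchangeable replicate lines, drift-driven among-line variance that
grows with generation, and (optionally) planted HR-vs-C differentiated regions
of linked SNPs — so every pipeline stage can be exercised without sequencing
data.

Drift is simulated per line per generation as binomial resampling of 2*Ne
allele copies (default Ne = 20, matching 10 breeding pairs), so the among-line
variance after g generations follows the Wright-Fisher expectation
``p(1-p) * (1 - (1 - 1/(2Ne))^g)``.

Planted regions shift the selected (HR) lines' mean AF by ``delta``; linked
SNPs within a region share one latent haplotype frequency per line plus small
per-SNP jitter, mimicking a differentiated haplotype block without a
recombination map.  Two-generation mode activates regions per generation to
create "churn" (signals present early that dissipate, new ones arising late).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .afdata import AFTable, LineDesign

__all__ = ["PlantedRegion", "SynthConfig", "generate_null", "generate_selected"]


@dataclass(frozen=True)
class PlantedRegion:
    """A differentiated haplotype block to plant into the HR lines."""

    chrom: str
    start: int
    span_bp: int
    n_linked_snps: int
    delta: float  # HR-vs-C mean AF shift, in [-1, 1]
    active: tuple[str, ...] = ("g22", "g61")  # generation tags where present

    @property
    def end(self) -> int:
        return self.start + self.span_bp - 1

    def __post_init__(self) -> None:
        if not -1.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [-1, 1]")
        if self.n_linked_snps < 1 or self.span_bp < 1:
            raise ValueError("region must contain at least one SNP and one bp")


@dataclass
class SynthConfig:
    """Generator configuration.

    ``chromosomes`` maps names to sizes in bp; ``n_loci`` background SNPs are
    scattered over them proportionally to size.  ``ne`` is the per-line
    Wright-Fisher effective size driving drift (default 20, i.e. 10 breeding
    pairs).  Founder AFs are uniform on ``founder_af_range`` (emulating the
    post-MAF-filter spectrum of segregating loci).
    """

    n_loci: int = 2000
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 100_000_000, "chr2": 80_000_000}
    )
    generations: int = 22
    ne: int = 20
    founder_af_range: tuple[float, float] = (0.1, 0.9)
    planted: tuple[PlantedRegion, ...] = ()
    jitter_sd: float = 0.02
    design: LineDesign = field(default_factory=LineDesign.default)

    def validate_planted(self) -> None:
        by_chrom: dict[str, list[PlantedRegion]] = {}
        for r in self.planted:
            by_chrom.setdefault(r.chrom, []).append(r)
        for regs in by_chrom.values():
            regs = sorted(regs, key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"planted regions overlap on {a.chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )


def _positions(cfg: SynthConfig, rng: np.random.Generator):
    sizes = np.array(list(cfg.chromosomes.values()), dtype=np.float64)
    names = list(cfg.chromosomes)
    n_per = np.maximum(np.round(cfg.n_loci * sizes / sizes.sum()).astype(int), 1)
    chroms, poss = [], []
    for name, size, n in zip(names, sizes, n_per):
        pos = np.sort(rng.choice(np.arange(1, int(size) + 1), size=n, replace=False))
        chroms.append(np.full(n, name, dtype=object))
        poss.append(pos)
    return np.concatenate(chroms), np.concatenate(poss).astype(np.int64)


def _drift(founder: np.ndarray, n_lines: int, generations: int, ne: int,
           rng: np.random.Generator) -> np.ndarray:
    """Independent per-line binomial(2*Ne) resampling for ``generations``."""
    two_ne = 2 * ne
    af = np.tile(founder[:, None], (1, n_lines))
    for _ in range(generations):
        af = rng.binomial(two_ne, af) / two_ne
    return af


def generate_null(cfg: SynthConfig, rng: np.random.Generator) -> AFTable:
    """Drift-only table: all 8 lines exchangeable around shared founder AFs."""
    chrom, pos = _positions(cfg, rng)
    founder = rng.uniform(*cfg.founder_af_range, size=len(pos))
    af = _drift(founder, cfg.design.n_lines, cfg.generations, cfg.ne, rng)
    t = AFTable(chrom=chrom, pos=pos, af=af, design=cfg.design,
                generation=cfg.generations)
    return t.sort().validate()


def _mask_planted(chrom: np.ndarray, pos: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Background loci falling inside a planted span (to be excluded)."""
    inside = np.zeros(len(pos), dtype=bool)
    for r in cfg.planted:
        inside |= (chrom == r.chrom) & (pos >= r.start) & (pos <= r.end)
    return inside


def _plan_blocks(cfg: SynthConfig, rng: np.random.Generator):
    """Draw each planted block's SNP positions and base haplotype frequency once,
    so both generations of a churn pair share loci."""
    blocks = []
    for r in cfg.planted:
        snp_pos = np.sort(
            rng.choice(np.arange(r.start, r.end + 1), size=r.n_linked_snps, replace=False)
        )
        base = rng.uniform(0.3, 0.7)
        blocks.append((r, snp_pos, base))
    return blocks


def _plant(table: AFTable, cfg: SynthConfig, blocks, tag: str,
           rng: np.random.Generator) -> AFTable:
    """Append planted blocks to a drifted table; HR lines shifted when active."""
    hr = table.design.hr_indices
    n_lines = table.design.n_lines
    add_chrom, add_pos, add_af = [], [], []
    for r, snp_pos, base in blocks:
        block = np.full((r.n_linked_snps, n_lines), base)
        block += rng.normal(0.0, cfg.jitter_sd, size=block.shape)
        if tag in r.active:
            # per-line latent shift shared by all linked SNPs in the block
            shift = r.delta + rng.normal(0.0, cfg.jitter_sd, size=len(hr))
            block[:, hr] += shift[None, :]
        add_chrom.append(np.full(r.n_linked_snps, r.chrom, dtype=object))
        add_pos.append(snp_pos)
        add_af.append(np.clip(block, 0.0, 1.0))
    if not add_pos:
        return table
    out = AFTable(
        chrom=np.concatenate([table.chrom, *add_chrom]),
        pos=np.concatenate([table.pos, *add_pos]).astype(np.int64),
        af=np.concatenate([table.af, *add_af]),
        design=table.design,
        generation=table.generation,
    )
    return out.sort().validate()


def generate_selected(
    cfg: SynthConfig,
    rng: np.random.Generator,
    two_generations: bool = False,
    generations_late: int = 61,
) -> AFTable | tuple[AFTable, AFTable]:
    """Drifted table(s) with planted differentiated regions.

    Single-generation mode returns one table with every region whose ``active``
    tags include ``"g22"``.  Two-generation mode returns ``(early, late)``
    tables sharing background loci: the late table drifts
    ``generations_late - cfg.generations`` further, and each planted region is
    present only in the generations its ``active`` tags name — churn.
    ``delta = 0`` regions reduce to the null background.
    """
    cfg.validate_planted()
    chrom, pos = _positions(cfg, rng)
    keep = ~_mask_planted(chrom, pos, cfg)
    chrom, pos = chrom[keep], pos[keep]
    founder = rng.uniform(*cfg.founder_af_range, size=len(pos))
    af_early = _drift(founder, cfg.design.n_lines, cfg.generations, cfg.ne, rng)
    blocks = _plan_blocks(cfg, rng)
    early = AFTable(chrom=chrom, pos=pos, af=af_early, design=cfg.design,
                    generation=cfg.generations)
    early = _plant(early.sort().validate(), cfg, blocks, "g22", rng)
    if not two_generations:
        return early
    extra = generations_late - cfg.generations
    if extra < 0:
        raise ValueError("generations_late must be >= cfg.generations")
    af_late = _drift(af_early.ravel(), 1, extra, cfg.ne, rng).reshape(af_early.shape)
    late = AFTable(chrom=chrom, pos=pos, af=af_late, design=cfg.design,
                   generation=generations_late)
    late = _plant(late.sort().validate(), cfg, blocks, "g61", rng)
    return early, late


def truth_frame(cfg: SynthConfig) -> pd.DataFrame:
    """Planted-region truth table for scoring recovered regions."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in cfg.planted],
            "start": [r.start for r in cfg.planted],
            "end": [r.end for r in cfg.planted],
            "n_linked_snps": [r.n_linked_snps for r in cfg.planted],
            "delta": [r.delta for r in cfg.planted],
            "active": [",".join(r.active) for r in cfg.planted],
        }
    )
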