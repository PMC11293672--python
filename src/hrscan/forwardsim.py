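"""Forward-in-time simulation of a replicated within-family selection
experiment on wheel running, with an optional evolvable physiological
constraint.

Model
-----
Each line is a closed population of 10 breeding pairs.  An individual's
phenotype (revolutions/day) is

    y = S * (mu + beta1 * X1 + beta2 * X2),     clamped to [floor, cap]

where ``X1`` is the summed signed effect of its alleles at 2,096 unlinked
biallelic trait loci with a leptokurtic effect-size distribution (many loci of
tiny effect, few of large effect), ``X2 ~ N(0, 1)`` is the environmental draw,
and ``S`` is a seasonal multiplier cycling with the ~3-month generations.

Under the constrained model each mouse also carries 100 constraint loci giving
an evolvable ceiling

    C = S * (muC + betaC1 * XC1 + betaC2 * XC2)

and its realized running is ``min(y, C)``; because alleles that raise the
ceiling are themselves favoured in selected lines, the ceiling evolves upward
until the selected trait plateaus.

Breeding: selected (HR) lines produce 5 males + 5 females per family and the
highest-running mouse of each sex within each family breeds; control lines
produce 2 + 2 and a random (first) mouse of each sex breeds.  Pairing among
the 20 chosen breeders is random with sibling pairs disallowed.  Loci are
unlinked, with free recombination, no mutation and no dominance.

Breeder allele counts (out of 40 copies) are snapshotted at generation 0,
every 5 generations, and at generations 22 and 61, from which downstream
differentiation scans run exactly as on sequencing-derived AF tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .difftest import arcsine_transform, welch_t_arrays

__all__ = [
    "Architecture",
    "seasonal_multiplier",
    "LineState",
    "found_line",
    "advance_generation",
    "run_line",
    "run_experiment",
    "ExperimentResult",
    "snapshot_af",
    "power_scan_sim",
    "power_by_generation",
    "power_by_class",
    "heritability_estimate",
    "selection_differential_summary",
    "cross_generation_consistency",
    "consistency_by_simulation",
    "noisy_reanalysis",
]

DEFAULT_SAVE_GENS = tuple(sorted(set(range(0, 61, 5)) | {22, 61}))


@dataclass(frozen=True)
class Architecture:
    """Genetic model constants for the trait and its constraint.

    Trait-class counts follow the printed endpoints (720 loci at +/-0.4, 480 at
    +/-0.8, 8 at +/-204.8) as the monotone sequence summing to 2,096; they are
    overridable.  The implied founder-generation genetic variance gives
    narrow-sense heritability ~0.32 and a phenotypic CV ~0.56.
    """

    trait_effects: tuple[float, ...] = tuple(0.4 * 2.0**k for k in range(10))
    trait_counts: tuple[int, ...] = (720, 480, 360, 240, 120, 80, 48, 24, 16, 8)
    beta1: float = 1.3
    beta2: float = 2100.0
    mu: float = 4570.0
    floor: float = 100.0
    cap: float = 50000.0
    season_cycle: tuple[float, ...] = (0.769, 1.0, 1.3, 1.0)
    season_phase: int = 0
    constraint_effects: tuple[float, ...] = (1.0, 4.0, 11.0, 36.0, 101.0, 306.0)
    constraint_counts: tuple[int, ...] = (48, 24, 12, 8, 5, 3)
    betaC1: float = 1.0
    betaC2: float = 1750.0
    muC: float = 10000.0

    def __post_init__(self) -> None:
        if len(self.trait_effects) != len(self.trait_counts):
            raise ValueError("trait effect/count length mismatch")
        if any(e <= 0 for e in self.trait_effects) or any(
            c < 1 for c in self.trait_counts
        ):
            raise ValueError("effects must be > 0 and counts >= 1")

    @property
    def n_trait_loci(self) -> int:
        return int(sum(self.trait_counts))

    @property
    def n_constraint_loci(self) -> int:
        return int(sum(self.constraint_counts))

    def trait_effect_vector(self) -> np.ndarray:
        return np.repeat(self.trait_effects, self.trait_counts).astype(np.float64)

    def constraint_effect_vector(self) -> np.ndarray:
        return np.repeat(self.constraint_effects, self.constraint_counts).astype(
            np.float64
        )

    def trait_class_index(self) -> np.ndarray:
        """Per-locus index into ``trait_effects``."""
        return np.repeat(np.arange(len(self.trait_effects)), self.trait_counts)

    # founder-generation analytics -------------------------------------------------
    def founder_genetic_variance(self) -> float:
        """Var(X1) at the founder generation: 2 * sum(n_i * e_i^2)."""
        e = self.trait_effect_vector()
        return float(2.0 * np.sum(e**2))

    def founder_heritability(self) -> float:
        vg = self.beta1**2 * self.founder_genetic_variance()
        return vg / (vg + self.beta2**2)

    def founder_cv(self) -> float:
        vg = self.beta1**2 * self.founder_genetic_variance()
        return float(np.sqrt(vg + self.beta2**2) / self.mu)


def seasonal_multiplier(generation: int, arch: Architecture | None = None) -> float:
    """Seasonal multiplier S for a generation (period-4 cycle by default)."""
    arch = arch or Architecture()
    cycle = arch.season_cycle
    return cycle[(generation + arch.season_phase) % len(cycle)]


def phenotype(x1: np.ndarray, x2: np.ndarray, s: float, arch: Architecture) -> np.ndarray:
    """Realized running: ``clamp(S*(mu + beta1*X1 + beta2*X2), floor, cap)``."""
    y = s * (arch.mu + arch.beta1 * np.asarray(x1) + arch.beta2 * np.asarray(x2))
    return np.clip(y, arch.floor, arch.cap)


def constraint_value(xc1: np.ndarray, xc2: np.ndarray, s: float, arch: Architecture) -> np.ndarray:
    """Evolvable ceiling: ``S*(muC + betaC1*XC1 + betaC2*XC2)`` (not floored)."""
    return s * (arch.muC + arch.betaC1 * np.asarray(xc1) + arch.betaC2 * np.asarray(xc2))


def apply_constraint(y: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Running truncated at the individual's ceiling: ``min(y, C)``."""
    return np.minimum(y, c)


@dataclass
class LineState:
    """Breeders of one line at one generation.

    ``genos`` holds 0/1 indicators of the "plus" allele, shape
    (20 breeders, 2 copies, n_loci); breeders 0-9 are male, 10-19 female.
    ``family`` is each breeder's natal family id (used to bar sib pairing).
    ``y`` is each breeder's own realized running (measured in its cohort).
    """

    genos: np.ndarray  # uint8 (20, 2, Lt)
    cgenos: np.ndarray | None  # uint8 (20, 2, Lc) or None (unconstrained)
    family: np.ndarray  # int (20,)
    y: np.ndarray  # float (20,)
    generation: int

    def allele_counts(self) -> np.ndarray:
        """Plus-allele count per trait locus among the 40 breeder copies."""
        return self.genos.sum(axis=(0, 1)).astype(np.int64)


def _signed_sum(counts: np.ndarray, e: np.ndarray) -> np.ndarray:
    # counts in {0,1,2} plus alleles -> signed allelic sum 2*counts - 2 per locus
    return 2.0 * (counts @ e) - 2.0 * e.sum()


def found_line(
    rng: np.random.Generator, arch: Architecture, constrained: bool
) -> LineState:
    """Found a line: 10 males + 10 females, every allele +/- with p = 0.5."""
    lt = arch.n_trait_loci
    genos = rng.integers(0, 2, size=(20, 2, lt), dtype=np.uint8)
    cgenos = None
    s0 = seasonal_multiplier(0, arch)
    x1 = _signed_sum(genos.sum(axis=1), arch.trait_effect_vector())
    y = phenotype(x1, rng.standard_normal(20), s0, arch)
    if constrained:
        cgenos = rng.integers(0, 2, size=(20, 2, arch.n_constraint_loci), dtype=np.uint8)
        xc1 = _signed_sum(cgenos.sum(axis=1), arch.constraint_effect_vector())
        c = constraint_value(xc1, rng.standard_normal(20), s0, arch)
        y = apply_constraint(y, c)
    # founders come from distinct families, so sib-barring never binds at first pairing
    family = np.arange(20)
    return LineState(genos=genos, cgenos=cgenos, family=family, y=y, generation=0)


def _pair(rng: np.random.Generator, family: np.ndarray, max_retries: int = 1000):
    """Random male-female pairing with sibling pairs disallowed."""
    mfam, ffam = family[:10], family[10:]
    for _ in range(max_retries):
        perm = rng.permutation(10)
        if not np.any(mfam == ffam[perm]):
            return perm
    raise RuntimeError("could not form a sibling-free pairing")


def _gametes(parents: np.ndarray, n_off: int, rng: np.random.Generator) -> np.ndarray:
    """One gamete per offspring per parent: free recombination across loci.

    ``parents``: (10, 2, L) -> returns (10, n_off, L).
    """
    bits = rng.integers(0, 2, size=(parents.shape[0], n_off, parents.shape[2]), dtype=np.uint8)
    return np.where(bits, parents[:, None, 1, :], parents[:, None, 0, :])


@dataclass
class GenRecord:
    """Per-generation bookkeeping from one line advance."""

    generation: int
    mean_running: float
    seldiff_male: np.ndarray  # per family; nan where within-family SD == 0
    seldiff_female: np.ndarray
    midparent_y: np.ndarray  # (10,) parents' mean measured running per pair
    offspring_mean_y: np.ndarray  # (10,) family mean offspring running


def advance_generation(
    state: LineState,
    linetype: str,
    constrained: bool,
    arch: Architecture,
    rng: np.random.Generator,
) -> tuple[LineState, GenRecord]:
    """Breed one generation and select the next breeders.

    HR lines: 10 offspring per family (5 of each sex), the top runner per sex
    per family breeds.  Control lines: 4 offspring per family (2 + 2), the
    first of each sex breeds (random with respect to running).
    """
    gen = state.generation + 1
    s = seasonal_multiplier(gen, arch)
    n_off = 10 if linetype == "HR" else 4
    n_half = n_off // 2  # males first, then females

    perm = _pair(rng, state.family)
    sires = state.genos[:10]
    dams = state.genos[10:][perm]
    gam_s = _gametes(sires, n_off, rng)
    gam_d = _gametes(dams, n_off, rng)
    counts = (gam_s + gam_d).astype(np.float64)  # (10, n_off, L)
    x1 = _signed_sum(counts, arch.trait_effect_vector())
    y = phenotype(x1, rng.standard_normal((10, n_off)), s, arch)

    cg_s = cg_d = None
    if constrained:
        csires = state.cgenos[:10]
        cdams = state.cgenos[10:][perm]
        cg_s = _gametes(csires, n_off, rng)
        cg_d = _gametes(cdams, n_off, rng)
        ccounts = (cg_s + cg_d).astype(np.float64)
        xc1 = _signed_sum(ccounts, arch.constraint_effect_vector())
        c = constraint_value(xc1, rng.standard_normal((10, n_off)), s, arch)
        y = apply_constraint(y, c)

    fam_idx = np.arange(10)
    if linetype == "HR":
        sel_m = np.argmax(y[:, :n_half], axis=1)
        sel_f = n_half + np.argmax(y[:, n_half:], axis=1)
    else:
        sel_m = np.zeros(10, dtype=np.int64)
        sel_f = np.full(10, n_half, dtype=np.int64)

    def _differential(block: np.ndarray, chosen: np.ndarray) -> np.ndarray:
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        picked = block[fam_idx, chosen]
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (picked - mean) / sd
        return np.where(sd > 0, d, np.nan)

    sd_m = _differential(y[:, :n_half], sel_m)
    sd_f = _differential(y[:, n_half:], sel_f - n_half)

    new_genos = np.concatenate(
        [
            np.stack([gam_s[fam_idx, sel_m], gam_d[fam_idx, sel_m]], axis=1),
            np.stack([gam_s[fam_idx, sel_f], gam_d[fam_idx, sel_f]], axis=1),
        ]
    ).astype(np.uint8)
    new_cgenos = None
    if constrained:
        new_cgenos = np.concatenate(
            [
                np.stack([cg_s[fam_idx, sel_m], cg_d[fam_idx, sel_m]], axis=1),
                np.stack([cg_s[fam_idx, sel_f], cg_d[fam_idx, sel_f]], axis=1),
            ]
        ).astype(np.uint8)

    new_y = np.concatenate([y[fam_idx, sel_m], y[fam_idx, sel_f]])
    new_family = np.concatenate([fam_idx, fam_idx])
    record = GenRecord(
        generation=gen,
        mean_running=float(y.mean()),
        seldiff_male=sd_m,
        seldiff_female=sd_f,
        midparent_y=0.5 * (state.y[:10] + state.y[10:][perm]),
        offspring_mean_y=y.mean(axis=1),
    )
    new_state = LineState(
        genos=new_genos, cgenos=new_cgenos, family=new_family, y=new_y, generation=gen
    )
    return new_state, record


@dataclass
class LineResult:
    """Trajectory and snapshots of one simulated line."""

    linetype: str
    snapshots: dict[int, np.ndarray]  # generation -> trait allele counts (Lt,)
    mean_running: np.ndarray  # (generations + 1,), index = generation
    seldiff_mean: np.ndarray  # per-generation mean standardized differential
    midparent_y: np.ndarray  # (generations, 10)
    offspring_mean_y: np.ndarray  # (generations, 10)


def run_line(
    linetype: str,
    constrained: bool,
    rng: np.random.Generator,
    arch: Architecture | None = None,
    generations: int = 61,
    save_gens: Iterable[int] = DEFAULT_SAVE_GENS,
) -> LineResult:
    arch = arch or Architecture()
    save = set(save_gens)
    state = found_line(rng, arch, constrained)
    snapshots = {}
    if 0 in save:
        snapshots[0] = state.allele_counts()
    mean_running = np.empty(generations + 1)
    mean_running[0] = float(state.y.mean())
    seldiff = np.full(generations + 1, np.nan)
    midp = np.empty((generations, 10))
    offm = np.empty((generations, 10))
    for g in range(1, generations + 1):
        state, rec = advance_generation(state, linetype, constrained, arch, rng)
        mean_running[g] = rec.mean_running
        both = np.concatenate([rec.seldiff_male, rec.seldiff_female])
        seldiff[g] = np.nanmean(both) if np.any(~np.isnan(both)) else np.nan
        midp[g - 1] = rec.midparent_y
        offm[g - 1] = rec.offspring_mean_y
        if g in save:
            snapshots[g] = state.allele_counts()
    return LineResult(
        linetype=linetype,
        snapshots=snapshots,
        mean_running=mean_running,
        seldiff_mean=seldiff,
        midparent_y=midp,
        offspring_mean_y=offm,
    )


@dataclass
class SimResult:
    """One replicate: 4 HR and 4 C lines run in parallel."""

    hr_lines: list[LineResult]
    c_lines: list[LineResult]

    def lines(self) -> list[LineResult]:
        return self.hr_lines + self.c_lines


@dataclass
class ExperimentResult:
    """A set of replicate simulations under one model."""

    model: str  # "constrained" | "unconstrained"
    sims: list[SimResult]
    arch: Architecture
    save_gens: tuple[int, ...]


def run_experiment(
    n_sims: int,
    model: str,
    seed: int | np.random.SeedSequence,
    arch: Architecture | None = None,
    generations: int = 61,
    n_hr: int = 4,
    n_c: int = 4,
    save_gens: Iterable[int] = DEFAULT_SAVE_GENS,
) -> ExperimentResult:
    """Run ``n_sims`` replicates of the full 8-line experiment.

    Each replicate runs ``n_hr`` selected and ``n_c`` control lines for
    ``generations`` generations, snapshotting breeder allele counts at
    ``save_gens``.  Identical seeds replay identical trajectories.
    """
    if model not in ("constrained", "unconstrained"):
        raise ValueError("model must be 'constrained' or 'unconstrained'")
    constrained = model == "constrained"
    arch = arch or Architecture()
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    sims = []
    for child in ss.spawn(n_sims):
        line_seeds = child.spawn(n_hr + n_c)
        hr = [
            run_line("HR", constrained, np.random.default_rng(s), arch, generations, save_gens)
            for s in line_seeds[:n_hr]
        ]
        c = [
            run_line("C", constrained, np.random.default_rng(s), arch, generations, save_gens)
            for s in line_seeds[n_hr:]
        ]
        sims.append(SimResult(hr_lines=hr, c_lines=c))
    return ExperimentResult(
        model=model, sims=sims, arch=arch, save_gens=tuple(sorted(set(save_gens)))
    )


# --------------------------------------------------------------------------------
# analytics


def snapshot_af(sim: SimResult, generation: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-line breeder AF at a saved generation: (HR (4, L), C (4, L))."""
    hr = np.stack([l.snapshots[generation] for l in sim.hr_lines]) / 40.0
    c = np.stack([l.snapshots[generation] for l in sim.c_lines]) / 40.0
    return hr, c


def _locus_p(hr_af: np.ndarray, c_af: np.ndarray) -> np.ndarray:
    """Per-locus Welch p on angular-transformed per-line AF (nan = failed)."""
    _, p, _ = welch_t_arrays(arcsine_transform(hr_af.T), arcsine_transform(c_af.T))
    return p


def power_scan_sim(
    sim: SimResult, generation: int, alpha: float = 0.05, loci: np.ndarray | None = None
) -> float:
    """Fraction of computable loci with Welch p <= alpha at one generation."""
    hr, c = snapshot_af(sim, generation)
    p = _locus_p(hr, c)
    if loci is not None:
        p = p[loci]
    ok = ~np.isnan(p)
    return float(np.mean(p[ok] <= alpha)) if ok.any() else np.nan


def power_by_generation(exp: ExperimentResult, alpha: float = 0.05):
    """Mean per-simulation power at each saved generation (plus per-sim values)."""
    import pandas as pd

    rows = []
    for g in exp.save_gens:
        vals = [power_scan_sim(s, g, alpha) for s in exp.sims]
        rows.append(
            {
                "generation": g,
                "power": float(np.nanmean(vals)),
                "sd": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else np.nan,
                "n_sims": len(vals),
            }
        )
    return pd.DataFrame(rows)


def power_by_class(
    exp: ExperimentResult, generation: int, alpha: float = 0.05
):
    """Mean power per trait effect-size class at one generation."""
    import pandas as pd

    cls = exp.arch.trait_class_index()
    rows = []
    for k, e in enumerate(exp.arch.trait_effects):
        mask = cls == k
        vals = [power_scan_sim(s, generation, alpha, loci=mask) for s in exp.sims]
        rows.append(
            {
                "effect_size": e,
                "n_loci": int(mask.sum()),
                "power": float(np.nanmean(vals)),
            }
        )
    return pd.DataFrame(rows)


def heritability_estimate(
    line_results: Iterable[LineResult], generation: int = 1
) -> float:
    """Narrow-sense heritability from the offspring-midparent regression.

    Pools (midparent running, family-mean offspring running) pairs for the
    transition into ``generation`` across the given (control) lines and
    returns the standardized regression coefficient: both variables are
    z-scored before the least-squares fit.  Standardizing removes the seasonal
    scale difference between the parents' and offspring's measurement
    occasions, which would otherwise multiply a raw-scale slope by
    ``S(gen)/S(gen-1)``.  Returns nan when degenerate.
    """
    mids, offs = [], []
    for lr in line_results:
        mids.append(lr.midparent_y[generation - 1])
        offs.append(lr.offspring_mean_y[generation - 1])
    m = np.concatenate(mids)
    o = np.concatenate(offs)
    if len(m) < 3 or np.std(m) == 0 or np.std(o) == 0:
        return float("nan")
    return float(np.corrcoef(m, o)[0, 1])


def selection_differential_summary(exp: ExperimentResult):
    """Mean standardized within-family selection differential per linetype."""
    import pandas as pd

    rows = []
    for linetype, getter in (("HR", "hr_lines"), ("C", "c_lines")):
        vals = np.concatenate(
            [lr.seldiff_mean[1:] for s in exp.sims for lr in getattr(s, getter)]
        )
        rows.append(
            {
                "linetype": linetype,
                "mean_differential": float(np.nanmean(vals)),
                "sd": float(np.nanstd(vals, ddof=1)),
            }
        )
    return pd.DataFrame(rows)


def cross_generation_consistency(
    p22: np.ndarray, p61: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """Pearson r of p-values and the persistence fraction of significant loci.

    Returns ``(r, fraction)`` where ``fraction`` is the share of loci with
    ``p22 <= alpha`` that also have ``p61 <= alpha``; nan when no locus is
    significant at the earlier generation.
    """
    both = ~np.isnan(p22) & ~np.isnan(p61)
    if both.sum() >= 3 and np.std(p22[both]) > 0 and np.std(p61[both]) > 0:
        r = float(np.corrcoef(p22[both], p61[both])[0, 1])
    else:
        r = float("nan")
    early = both & (p22 <= alpha)
    frac = float(np.mean(p61[early] <= alpha)) if early.any() else float("nan")
    return r, frac


def consistency_by_simulation(
    exp: ExperimentResult, gen_a: int = 22, gen_b: int = 61, alpha: float = 0.05
):
    """Per-simulation p-value correlation and persistence between generations."""
    import pandas as pd

    rows = []
    for i, sim in enumerate(exp.sims):
        p_a = _locus_p(*snapshot_af(sim, gen_a))
        p_b = _locus_p(*snapshot_af(sim, gen_b))
        r, frac = cross_generation_consistency(p_a, p_b, alpha)
        rows.append({"sim": i, "r": r, "consistency": frac})
    return pd.DataFrame(rows)


def noisy_reanalysis(
    exp: ExperimentResult,
    grid22,
    grid61,
    rng: np.random.Generator,
    gen_a: int = 22,
    gen_b: int = 61,
    alpha: float = 0.05,
):
    """Consistency analytics after injecting measurement error into the AFs.

    Each line's true breeder AF at ``gen_a`` is replaced by a draw from the
    pooled-sequencing error grid and at ``gen_b`` from the individual-
    genotyping grid (true AF rounded to the nearest 0.05 grid point), then the
    per-locus Welch tests, p-value correlation and persistence fraction are
    recomputed per simulation.
    """
    import pandas as pd

    def _noisy(af: np.ndarray, grid) -> np.ndarray:
        idx = np.clip(np.rint(af / 0.05).astype(int), 1, 19) - 1
        cols = rng.integers(0, grid.n_rep, size=af.shape)
        return grid.samples[idx, cols]

    rows = []
    for i, sim in enumerate(exp.sims):
        hr_a, c_a = snapshot_af(sim, gen_a)
        hr_b, c_b = snapshot_af(sim, gen_b)
        p_a = _locus_p(_noisy(hr_a, grid22), _noisy(c_a, grid22))
        p_b = _locus_p(_noisy(hr_b, grid61), _noisy(c_b, grid61))
        r, frac = cross_generation_consistency(p_a, p_b, alpha)
        rows.append({"sim": i, "r": r, "consistency": frac})
    return pd.DataFrame(rows)
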