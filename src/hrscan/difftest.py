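"""Per-locus differentiation tests and the exhaustive line-permutation FDR.

Three tests compare the 4 selected (HR) with the 4 control (C) lines at each
locus, all on angular-transformed allele frequencies ``arcsin(sqrt(af))``:

* **Welch** — the ordinary unequal-variance T-test on 4 vs 4 line values.
* **RegT** — a regularized (moderated) T-test: each group's variance is shrunk
  toward a background variance ``v_bar`` estimated genome-wide, with
  ``nu0`` pseudo-observations, to stabilise the tiny-sample variance
  estimates; group degrees of freedom grow accordingly.
* **WRT** — identical to RegT except ``v_bar`` is estimated over a sliding
  window of neighbouring loci on the same chromosome, so the shrinkage target
  tracks local variance structure.

With 8 lines split 4 vs 4 there are exactly C(8,4)/2 = 35 distinct unordered
partitions, so the permutation null can be enumerated exhaustively.  The
false-discovery rate at a p cutoff is computed directly as
``(mean permuted discoveries per permutation) / (observed discoveries)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .afdata import AFTable, LineDesign

__all__ = [
    "arcsine_transform",
    "welch_t",
    "welch_t_arrays",
    "RegularizationContext",
    "ScanResult",
    "PermutationSet",
    "enumerate_permutations",
    "regularized_t",
    "windowed_regularized_t",
    "welch_scan",
    "direct_fdr",
    "scan_with_fdr",
]


def arcsine_transform(af):
    """Angular transform ``arcsin(sqrt(af))``, mapping [0, 1] -> [0, pi/2].

    The classical variance-stabilising transform for proportions; monotone, so
    it preserves allele-frequency ordering.  Values outside [0, 1] raise.
    """
    af = np.asarray(af, dtype=np.float64)
    with np.errstate(invalid="ignore"):
        out_of_range = (af < 0) | (af > 1)
    if np.any(out_of_range):
        raise ValueError("allele frequency outside [0, 1]")
    return np.arcsin(np.sqrt(af))


def _group_moments(x: np.ndarray):
    """Per-row count, mean and sample variance ignoring NaN."""
    n = np.sum(~np.isnan(x), axis=-1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(x, axis=-1)
        v = np.nanvar(x, axis=-1, ddof=1)
    return n, m, v


def welch_t_arrays(
    a: np.ndarray,
    b: np.ndarray,
    var_a: np.ndarray | None = None,
    var_b: np.ndarray | None = None,
    df_a: np.ndarray | None = None,
    df_b: np.ndarray | None = None,
):
    """Vectorised Welch T over the last axis, with explicit failure handling.

    ``var_*``/``df_*`` override the per-group variances and degrees of freedom
    (used by the regularized variants).  Returns ``(t, p, df)``; a locus where
    the statistic is undefined (zero variance in both groups with equal means,
    or fewer than 2 values in a group) carries ``nan`` in all three outputs and
    is treated as "failed" downstream.  Zero variance with unequal means gives
    ``t = +/-inf`` and ``p = 0``.
    """
    na, ma, va = _group_moments(a)
    nb, mb, vb = _group_moments(b)
    if var_a is not None:
        va = var_a
    if var_b is not None:
        vb = var_b
    dfa = (na - 1) if df_a is None else df_a
    dfb = (nb - 1) if df_b is None else df_b

    with np.errstate(divide="ignore", invalid="ignore"):
        sa = va / na
        sb = vb / nb
        se2 = sa + sb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (sa**2 / dfa + sb**2 / dfb)
        # one-sided variance degeneracy: df -> own group's df
        only_a = (sb == 0) & (sa > 0)
        only_b = (sa == 0) & (sb > 0)
        df = np.where(only_a, dfa, df)
        df = np.where(only_b, dfb, df)
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1e-12))

    with np.errstate(invalid="ignore"):
        failed = (na < 2) | (nb < 2) | ((se2 == 0) & (ma == mb)) | np.isnan(se2)
        infinite = (se2 == 0) & (ma != mb) & ~failed
        t = np.where(failed, np.nan, t)
        t = np.where(infinite, np.sign(np.where(np.isnan(ma - mb), 0, ma - mb)) * np.inf, t)
    p = np.where(failed, np.nan, p)
    p = np.where(infinite, 0.0, p)
    df = np.where(failed | infinite, np.nan, df)
    return t, p, df


def welch_t(group_a, group_b):
    """Scalar Welch T-test for two small groups; returns ``(T, p)``."""
    a = np.asarray(group_a, dtype=np.float64)[None, :]
    b = np.asarray(group_b, dtype=np.float64)[None, :]
    t, p, _ = welch_t_arrays(a, b)
    return float(t[0]), float(p[0])


@dataclass(frozen=True)
class RegularizationContext:
    """Shrinkage configuration for the regularized tests.

    ``nu0`` is the number of pseudo-observations granted to the background
    variance ``v_bar``; ``window_size`` (odd, >= 3) is the sliding-window width
    in loci for WRT.  The background is the mean of the pooled per-locus
    variances, genome-wide (RegT) or over the centered window (WRT).
    """

    nu0: float = 4.0
    window_size: int = 1001

    def __post_init__(self) -> None:
        if self.nu0 <= 0:
            raise ValueError("nu0 must be positive")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")


@dataclass
class ScanResult:
    """Per-locus statistics for one differentiation test."""

    chrom: np.ndarray
    pos: np.ndarray
    test: str
    t: np.ndarray
    p: np.ndarray
    df: np.ndarray
    perm_p: np.ndarray | None = None  # (n_loci, n_permutations)
    fdr_threshold_p: float | None = None
    fdr: np.ndarray | None = None
    significant: np.ndarray | None = None

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    def to_frame(self):
        import pandas as pd

        with np.errstate(divide="ignore"):
            neglog = -np.log10(self.p)
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "test": self.test,
                "T": self.t,
                "p": self.p,
                "neglog10p": neglog,
            }
        )
        if self.fdr is not None:
            df["fdr"] = self.fdr
        if self.significant is not None:
            df["significant"] = self.significant.astype(int)
        return df


@dataclass(frozen=True)
class PermutationSet:
    """All distinct unordered 4-vs-4 partitions of the 8 line labels."""

    partitions: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    observed_index: int

    def __len__(self) -> int:
        return len(self.partitions)


def enumerate_permutations(design: LineDesign) -> PermutationSet:
    """Enumerate all C(8,4)/2 = 35 unordered 4-vs-4 partitions.

    Each partition is normalised to contain line index 0 in its first group,
    which removes the group-label symmetry ({A,B} == {B,A}).  The observed
    design partition is included.
    """
    if design.n_lines != 8 or not design.is_balanced_4v4():
        raise ValueError("exhaustive enumeration requires 8 lines split 4 vs 4")
    all_idx = frozenset(range(8))
    parts = []
    for combo in combinations(range(8), 4):
        if 0 not in combo:
            continue
        other = tuple(sorted(all_idx - set(combo)))
        parts.append((combo, other))
    hr = frozenset(int(i) for i in design.hr_indices)
    observed = None
    for k, (ga, gb) in enumerate(parts):
        if frozenset(ga) == hr or frozenset(gb) == hr:
            observed = k
    assert observed is not None and len(parts) == 35
    return PermutationSet(partitions=tuple(parts), observed_index=observed)


def _pooled_variance(x: np.ndarray, ga, gb):
    """Per-locus pooled (within-group) variance across the two groups."""
    na, _, va = _group_moments(x[:, ga])
    nb, _, vb = _group_moments(x[:, gb])
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return pooled


def _window_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated windows at the edges (NaN-aware)."""
    n = len(values)
    half = window // 2
    good = ~np.isnan(values)
    v = np.where(good, values, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(v)])
    cn = np.concatenate([[0], np.cumsum(good.astype(np.int64))])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    tot = cs[hi] - cs[lo]
    cnt = cn[hi] - cn[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt > 0, tot / cnt, np.nan)


def _regularized_welch(x, ga, gb, v_bar, nu0):
    na, _, va = _group_moments(x[:, ga])
    nb, _, vb = _group_moments(x[:, gb])
    with np.errstate(invalid="ignore"):
        sa = (nu0 * v_bar + (na - 1) * va) / (nu0 + na - 1)
        sb = (nu0 * v_bar + (nb - 1) * vb) / (nu0 + nb - 1)
    return welch_t_arrays(
        x[:, ga], x[:, gb], var_a=sa, var_b=sb, df_a=na + nu0 - 1, df_b=nb + nu0 - 1
    )


def _scan(table: AFTable, kind: str, ctx: RegularizationContext | None, ga, gb):
    x = arcsine_transform(table.af)
    if kind == "welch":
        t, p, df = welch_t_arrays(x[:, ga], x[:, gb])
        return t, p, df
    assert ctx is not None
    pooled = _pooled_variance(x, ga, gb)
    if kind == "regt":
        v_bar = np.full(table.n_loci, np.nanmean(pooled))
    elif kind == "wrt":
        v_bar = np.empty(table.n_loci)
        for ch in np.unique(table.chrom):
            m = table.chrom == ch
            n_ch = int(m.sum())
            if n_ch < ctx.window_size:
                warnings.warn(
                    f"chromosome {ch} has {n_ch} loci < window "
                    f"{ctx.window_size}; using chromosome-wide v_bar",
                    stacklevel=3,
                )
            v_bar[m] = _window_mean(pooled[m], min(ctx.window_size, 2 * n_ch + 1))
    else:  # pragma: no cover
        raise ValueError(f"unknown test kind {kind!r}")
    return _regularized_welch(x, ga, gb, v_bar, ctx.nu0)


def _check_design(table: AFTable):
    d = table.design
    if len(d.hr_indices) < 2 or len(d.c_indices) < 2:
        raise ValueError("need at least 2 lines per linetype")
    return d.hr_indices, d.c_indices


def welch_scan(table: AFTable) -> ScanResult:
    """Plain Welch T-test at every locus (HR vs C), on transformed AF."""
    ga, gb = _check_design(table)
    t, p, df = _scan(table, "welch", None, ga, gb)
    return ScanResult(table.chrom, table.pos, "welch", t, p, df)


def regularized_t(table: AFTable, ctx: RegularizationContext | None = None) -> ScanResult:
    """Regularized T-test with a genome-wide background variance.

    Group variances are shrunk toward ``v_bar`` (the genome-wide mean of the
    pooled per-locus variances) with ``ctx.nu0`` pseudo-observations; the
    effective group degrees of freedom are ``n_g + nu0 - 1``.  As ``nu0 -> 0``
    this reduces to the plain Welch test.
    """
    ctx = ctx or RegularizationContext()
    ga, gb = _check_design(table)
    t, p, df = _scan(table, "regt", ctx, ga, gb)
    return ScanResult(table.chrom, table.pos, "regt", t, p, df)


def windowed_regularized_t(
    table: AFTable, ctx: RegularizationContext | None = None
) -> ScanResult:
    """Regularized T-test with a sliding-window background variance (WRT).

    Identical to :func:`regularized_t` except ``v_bar`` at each locus is the
    mean pooled variance over a centered window of ``ctx.window_size`` loci on
    the same chromosome (truncated at chromosome ends).  A window spanning the
    whole genome reproduces the genome-wide test.
    """
    ctx = ctx or RegularizationContext()
    ga, gb = _check_design(table)
    t, p, df = _scan(table, "wrt", ctx, ga, gb)
    return ScanResult(table.chrom, table.pos, "wrt", t, p, df)


_SCANNERS = {
    "welch": lambda t, ctx, ga, gb: _scan(t, "welch", None, ga, gb),
    "regt": lambda t, ctx, ga, gb: _scan(t, "regt", ctx, ga, gb),
    "wrt": lambda t, ctx, ga, gb: _scan(t, "wrt", ctx, ga, gb),
}


@dataclass
class FdrResult:
    """Direct permutation FDR at a target rate."""

    threshold_p: float | None
    fdr: np.ndarray  # per locus; nan outside the candidate set
    significant: np.ndarray

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def direct_fdr(
    observed_p: np.ndarray,
    permuted_p: np.ndarray,
    target_fdr: float = 0.01,
    candidate_p: float = 0.05,
) -> FdrResult:
    """Direct FDR from exhaustively permuted p-values.

    For each candidate locus (observed ``p < candidate_p``), the FDR at its
    p-value ``p0`` is ``(#{permuted p <= p0} / n_perm) / #{observed p <= p0}``.
    The significance threshold is the largest candidate p whose FDR is at or
    below ``target_fdr``; all loci with ``p <= threshold`` are significant
    (inclusive ties).  Loci whose test failed (``nan``) are excluded from both
    numerator and denominator counts.
    """
    observed_p = np.asarray(observed_p, dtype=np.float64)
    n_perm = permuted_p.shape[1]
    obs_sorted = np.sort(observed_p[~np.isnan(observed_p)])
    perm_sorted = np.sort(permuted_p[~np.isnan(permuted_p)].ravel())

    candidates = ~np.isnan(observed_p) & (observed_p < candidate_p)
    fdr = np.full_like(observed_p, np.nan)
    if candidates.any():
        p0 = observed_p[candidates]
        n_false = np.searchsorted(perm_sorted, p0, side="right") / n_perm
        n_disc = np.searchsorted(obs_sorted, p0, side="right")
        fdr[candidates] = n_false / n_disc

    ok = candidates & (fdr <= target_fdr)
    if not ok.any():
        return FdrResult(None, fdr, np.zeros_like(candidates))
    threshold = float(observed_p[ok].max())
    with np.errstate(invalid="ignore"):
        significant = ~np.isnan(observed_p) & (observed_p <= threshold)
    return FdrResult(threshold, fdr, significant)


def scan_with_fdr(
    table: AFTable,
    test: str = "wrt",
    ctx: RegularizationContext | None = None,
    target_fdr: float = 0.01,
    candidate_p: float = 0.05,
    perms: PermutationSet | None = None,
) -> ScanResult:
    """Run one test plus its exhaustive 35-permutation FDR.

    The permutation null recomputes the full test (including the background
    variance for the regularized variants) under every 4-vs-4 relabelling of
    the lines; the observed partition is one of the 35.
    """
    if test not in _SCANNERS:
        raise ValueError(f"unknown test {test!r}; expected welch|regt|wrt")
    ctx = ctx or RegularizationContext()
    ga, gb = _check_design(table)
    perms = perms or enumerate_permutations(table.design)
    scanner = _SCANNERS[test]

    t, p, df = scanner(table, ctx, ga, gb)
    perm_p = np.empty((table.n_loci, len(perms)))
    for k, (pa, pb) in enumerate(perms.partitions):
        if k == perms.observed_index:
            perm_p[:, k] = p
            continue
        _, pk, _ = scanner(table, ctx, np.array(pa), np.array(pb))
        perm_p[:, k] = pk

    res = ScanResult(table.chrom, table.pos, test, t, p, df, perm_p=perm_p)
    # The observed partition is one of the 35, but its column cannot enter the
    # FDR numerator: counting the observed discoveries among the "permuted"
    # ones would bound the FDR below by 1/35 ~ 0.029 and make a 0.01 target
    # unattainable for any data.  The null ensemble is the 34 true relabelings.
    null_cols = np.ones(len(perms), dtype=bool)
    null_cols[perms.observed_index] = False
    f = direct_fdr(
        p, perm_p[:, null_cols], target_fdr=target_fdr, candidate_p=candidate_p
    )
    res.fdr_threshold_p = f.threshold_p
    res.fdr = f.fdr
    res.significant = f.significant
    return res
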