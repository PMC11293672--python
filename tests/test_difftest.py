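"""Differentiation statistics: transform, Welch, regularized variants,
exhaustive permutations and the direct FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hrscan.difftest import (
    PermutationSet,
    RegularizationContext,
    arcsine_transform,
    direct_fdr,
    enumerate_permutations,
    regularized_t,
    scan_with_fdr,
    welch_scan,
    welch_t,
    welch_t_arrays,
    windowed_regularized_t,
)
from hrscan.afdata import LineDesign
from hrscan.synthdata import SynthConfig, generate_null

from conftest import make_table


class TestArcsine:
    @pytest.mark.parametrize(
        "af,expected",
        [(0.0, 0.0), (1.0, np.pi / 2), (0.25, np.pi / 6), (0.5, np.pi / 4)],
    )
    def test_closed_forms(self, af, expected):
        assert arcsine_transform(af) == pytest.approx(expected)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            arcsine_transform(1.0001)
        with pytest.raises(ValueError):
            arcsine_transform(-0.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_and_bounded(self, a, b):
        ta, tb = arcsine_transform(a), arcsine_transform(b)
        assert 0 <= ta <= np.pi / 2
        if a < b:
            assert ta < tb


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_scipy_oracle(self):
        a = [0.1, 0.2, 0.15, 0.12]
        b = [0.5, 0.55, 0.6, 0.52]
        t, p = welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_hand_computed_formula(self):
        # textbook Welch evaluated independently
        a = np.array([0.1, 0.2, 0.15, 0.12])
        b = np.array([0.5, 0.55, 0.6, 0.52])
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 4 + vb / 4
        t_ref = (a.mean() - b.mean()) / np.sqrt(se2)
        df_ref = se2**2 / ((va / 4) ** 2 / 3 + (vb / 4) ** 2 / 3)
        t, p = welch_t(a, b)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_ref), df_ref))

    def test_one_group_constant(self):
        # zero variance in one group: df collapses to the varying group's
        t, p, df = welch_t_arrays(
            np.array([[0.3, 0.3, 0.3, 0.3]]), np.array([[0.5, 0.6, 0.7, 0.9]])
        )
        assert np.isfinite(t[0]) and df[0] == pytest.approx(3.0)

    def test_zero_variance_both_equal_means_fails(self):
        t, p, df = welch_t_arrays(
            np.array([[0.2, 0.2, 0.2, 0.2]]), np.array([[0.2, 0.2, 0.2, 0.2]])
        )
        assert np.isnan(t[0]) and np.isnan(p[0])

    def test_zero_variance_unequal_means_is_infinite(self):
        t, p, _ = welch_t_arrays(
            np.array([[1.0, 1.0, 1.0, 1.0]]), np.array([[0.0, 0.0, 0.0, 0.0]])
        )
        assert np.isposinf(t[0]) and p[0] == 0.0


class TestRegularized:
    def test_homogeneous_variance_is_fixed_point(self, rng):
        # every locus shares the same group variance -> shrinkage changes nothing
        base = rng.uniform(0.3, 0.5, size=200)
        offsets = np.array([0.0, 0.02, 0.04, 0.06] * 2)
        af = base[:, None] + offsets[None, :]
        t = make_table(af)
        reg = regularized_t(t, RegularizationContext(nu0=4.0))
        plain = welch_scan(t)
        # identical variances genome-wide: v_bar equals every per-locus variance
        assert np.allclose(reg.t, plain.t, rtol=1e-10)

    def test_nu0_to_zero_recovers_welch(self, rng):
        af = rng.uniform(0.1, 0.9, size=(100, 8))
        t = make_table(af)
        reg = regularized_t(t, RegularizationContext(nu0=1e-9))
        plain = welch_scan(t)
        assert np.allclose(reg.t, plain.t, rtol=1e-5)
        assert np.allclose(reg.p, plain.p, rtol=1e-4)

    def test_outlier_variance_locus_shrinks_toward_background(self, rng):
        af = np.tile(rng.uniform(0.4, 0.6, size=(200, 1)), (1, 8))
        af += rng.normal(0, 0.01, size=af.shape)
        # one locus with a huge within-group spread and a mean shift
        af[0] = [0.05, 0.95, 0.10, 0.90, 0.45, 0.55, 0.48, 0.52]
        t = make_table(np.clip(af, 0, 1))
        reg = regularized_t(t, RegularizationContext(nu0=4.0))
        plain = welch_scan(t)
        x = arcsine_transform(t.af[0])
        hr, c = x[:4], x[4:]
        v_bar = np.nanmean(
            (np.var(arcsine_transform(t.af)[:, :4], axis=1, ddof=1) * 3
             + np.var(arcsine_transform(t.af)[:, 4:], axis=1, ddof=1) * 3) / 6
        )
        t_with_vbar = (hr.mean() - c.mean()) / np.sqrt(v_bar / 4 + v_bar / 4)
        # |T| strictly between plain Welch (own variance) and full-v_bar Welch
        lo, hi = sorted([abs(plain.t[0]), abs(t_with_vbar)])
        assert lo < abs(reg.t[0]) < hi


class TestWindowed:
    def test_window_spanning_genome_equals_regt(self, rng):
        af = rng.uniform(0.1, 0.9, size=(50, 8))
        t = make_table(af)
        ctx = RegularizationContext(nu0=4.0, window_size=101)  # > n_loci
        with pytest.warns(UserWarning, match="using chromosome-wide"):
            wrt = windowed_regularized_t(t, ctx)
        reg = regularized_t(t, RegularizationContext(nu0=4.0))
        assert np.allclose(wrt.t, reg.t)

    def test_local_variance_direction(self, rng):
        # chr2 loci have much larger within-group spread; WRT should judge
        # chr2 loci against the local (higher) background, RegT against the
        # global mixture
        af1 = 0.5 + rng.normal(0, 0.005, size=(300, 8))
        af2 = 0.5 + rng.normal(0, 0.15, size=(300, 8))
        af = np.clip(np.concatenate([af1, af2]), 0, 1)
        chrom = ["chr1"] * 300 + ["chr2"] * 300
        pos = list(range(1, 301)) * 2
        t = make_table(af, chrom=chrom, pos=np.array(pos) * 100)
        ctx = RegularizationContext(nu0=4.0, window_size=151)
        wrt = windowed_regularized_t(t, ctx)
        reg = regularized_t(t, RegularizationContext(nu0=4.0))
        chr2 = t.chrom == "chr2"
        # local background on chr2 is larger than the global mean background,
        # so WRT statistics there are (in absolute value) no larger than RegT's
        assert np.nanmean(np.abs(wrt.t[chr2])) < np.nanmean(np.abs(reg.t[chr2]))

    def test_homogeneous_wrt_equals_regt(self, rng):
        base = rng.uniform(0.3, 0.5, size=600)
        offsets = np.array([0.0, 0.02, 0.04, 0.06] * 2)
        t = make_table(base[:, None] + offsets[None, :])
        wrt = windowed_regularized_t(t, RegularizationContext(nu0=4.0, window_size=51))
        reg = regularized_t(t, RegularizationContext(nu0=4.0))
        assert np.allclose(wrt.t, reg.t, rtol=1e-8)

    def test_regt_wrt_p_values_nearly_identical_on_drifted_null(self, rng):
        # mirrors the observed near-unity correlation between the two tests
        table = generate_null(SynthConfig(n_loci=800, generations=22), rng)
        reg = regularized_t(table)
        wrt = windowed_regularized_t(table, RegularizationContext(window_size=201))
        ok = ~np.isnan(reg.p) & ~np.isnan(wrt.p)
        r = np.corrcoef(reg.p[ok], wrt.p[ok])[0, 1]
        assert r > 0.99


class TestPermutations:
    def test_count_is_35(self, design):
        assert len(enumerate_permutations(design)) == 35

    def test_observed_partition_included_once(self, design):
        perms = enumerate_permutations(design)
        hr = frozenset(int(i) for i in design.hr_indices)
        hits = [
            k
            for k, (a, b) in enumerate(perms.partitions)
            if frozenset(a) == hr or frozenset(b) == hr
        ]
        assert hits == [perms.observed_index]

    def test_no_duplicate_partitions(self, design):
        perms = enumerate_permutations(design)
        seen = {frozenset([frozenset(a), frozenset(b)]) for a, b in perms.partitions}
        assert len(seen) == 35

    def test_each_line_appears_equally_often(self, design):
        # combinatorial oracle: every non-anchor line is in the anchor's group
        # in C(6,3)=20 partitions and opposite in 15
        perms = enumerate_permutations(design)
        counts = np.zeros(8, dtype=int)
        for a, _ in perms.partitions:
            counts[list(a)] += 1
        assert counts[0] == 35
        assert all(c == 15 for c in counts[1:])

    def test_non_4v4_design_rejected(self):
        d = LineDesign(lines=("a", "b", "c", "d"), linetypes=("HR", "HR", "C", "C"))
        with pytest.raises(ValueError):
            enumerate_permutations(d)

    def test_group_swap_invariance(self, toy_table):
        # partition {A,B} and {B,A} give identical two-sided p-values
        from hrscan.difftest import _scan

        perms = enumerate_permutations(toy_table.design)
        a, b = perms.partitions[3]
        _, p1, _ = _scan(toy_table, "welch", None, np.array(a), np.array(b))
        _, p2, _ = _scan(toy_table, "welch", None, np.array(b), np.array(a))
        assert np.allclose(p1, p2, equal_nan=True)


class TestDirectFdr:
    def test_clean_separation(self, rng):
        observed = np.full(10, 0.001)
        permuted = rng.uniform(0.5, 1.0, size=(10, 35))
        res = direct_fdr(observed, permuted, target_fdr=0.01)
        assert res.n_significant == 10
        assert np.allclose(res.fdr[~np.isnan(res.fdr)], 0.0)

    def test_null_self_consistency(self, rng):
        # observed identical to every permutation: FDR ~ 1, nothing significant
        p = rng.uniform(0, 1, size=500)
        permuted = np.tile(p[:, None], (1, 35))
        res = direct_fdr(p, permuted, target_fdr=0.01)
        assert res.n_significant == 0
        cand = ~np.isnan(res.fdr)
        assert np.all(res.fdr[cand] >= 1.0)

    def test_planted_counting_oracle(self, rng):
        observed = np.concatenate([rng.uniform(0.05, 1.0, size=100), np.full(5, 1e-6)])
        permuted = rng.uniform(0, 1, size=(105, 35))
        res = direct_fdr(observed, permuted, target_fdr=0.01)
        assert res.n_significant == 5
        assert set(np.flatnonzero(res.significant)) == {100, 101, 102, 103, 104}

    def test_monotone_in_target(self, rng):
        observed = np.concatenate(
            [rng.uniform(0, 1, size=300), rng.uniform(0, 1e-4, size=10)]
        )
        permuted = rng.uniform(0, 1, size=(310, 35))
        sets = []
        for target in (0.01, 0.05, 0.2, 0.5):
            res = direct_fdr(observed, permuted, target_fdr=target)
            sets.append(set(np.flatnonzero(res.significant)))
        for small, big in zip(sets, sets[1:]):
            assert small <= big

    def test_failed_loci_excluded(self, rng):
        observed = np.array([0.001, np.nan, 0.001])
        permuted = np.full((3, 35), 0.9)
        permuted[1] = np.nan
        res = direct_fdr(observed, permuted)
        assert res.n_significant == 2
        assert not res.significant[1]

    def test_no_threshold_is_valid_result(self, rng):
        res = direct_fdr(rng.uniform(0.2, 1, 50), rng.uniform(0, 1, (50, 35)))
        assert res.threshold_p is None and res.n_significant == 0


class TestScanWithFdr:
    def test_null_calibration(self):
        # exchangeable lines: flagged fraction stays at or below the target
        flagged = 0
        total = 0
        for seed in range(4):
            rng = np.random.default_rng(1000 + seed)
            table = generate_null(SynthConfig(n_loci=500, generations=22), rng)
            res = scan_with_fdr(table, test="regt")
            flagged += int(res.significant.sum())
            total += res.n_loci
        assert flagged / total <= 0.011

    def test_permutation_matrix_shape_and_observed_column(self, rng):
        table = generate_null(SynthConfig(n_loci=120, generations=10), rng)
        res = scan_with_fdr(table, test="welch")
        assert res.perm_p.shape == (120, 35)
        perms = enumerate_permutations(table.design)
        assert np.allclose(
            res.perm_p[:, perms.observed_index], res.p, equal_nan=True
        )

    def test_planted_signal_is_detected(self, rng):
        af = rng.uniform(0.4, 0.6, size=(400, 8))
        af[:30, :4] = rng.uniform(0.93, 1.0, size=(30, 4))  # HR lines shifted
        af[:30, 4:] = rng.uniform(0.0, 0.07, size=(30, 4))
        t = make_table(np.clip(af, 0, 1))
        res = scan_with_fdr(t, test="welch")
        assert res.significant[:30].all()
        assert res.significant[30:].sum() <= 2
        # the regularized scan detects the same planted block
        reg = scan_with_fdr(t, test="regt")
        assert reg.significant[:30].all()
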