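"""Kruskal-Wallis and Dunn's test against independent from-definition oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from toothmap import (
    DomainMeasurement,
    GroupSample,
    compare_domains,
    dunns_test,
    kruskal_wallis,
)


def midranks(values):
    """Independent mid-rank computation via sorted runs (no scipy)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def direct_kw_h(groups):
    """Tie-corrected H via the equivalent variance-ratio identity
    H = (N-1) * sum_i n_i (rbar_i - rbar)^2 / sum_ij (r_ij - rbar)^2."""
    pooled = np.concatenate(groups)
    ranks = midranks(pooled)
    rbar = ranks.mean()
    denom = ((ranks - rbar) ** 2).sum()
    if denom == 0:
        return 0.0
    num, start = 0.0, 0
    for g in groups:
        r = ranks[start : start + len(g)]
        num += len(g) * (r.mean() - rbar) ** 2
        start += len(g)
    return (len(pooled) - 1) * num / denom


def direct_dunn_z(groups, i, j):
    """Dunn's z from the definition, with ranks and ties found by scanning."""
    pooled = np.concatenate(groups)
    ranks = midranks(pooled)
    n = len(pooled)
    tie_sum = 0.0
    for v in set(pooled.tolist()):
        t = float(np.sum(pooled == v))
        tie_sum += t**3 - t
    var = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    bounds = np.cumsum([0] + [len(g) for g in groups])
    ri = ranks[bounds[i] : bounds[i + 1]].mean()
    rj = ranks[bounds[j] : bounds[j + 1]].mean()
    return (ri - rj) / np.sqrt(var * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))


def as_groups(arrays):
    return [GroupSample(str(k), tuple(a)) for k, a in enumerate(arrays)]


class TestKruskalWallis:
    def test_identical_distributions_give_zero_h(self):
        res = kruskal_wallis(as_groups([(1, 2, 3), (1, 2, 3)]))
        assert res.H == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_groups_match_rank_arithmetic(self):
        groups = [(1.0, 2.0, 3.0), (10.0, 20.0, 30.0)]
        res = kruskal_wallis(as_groups(groups))
        # ranks 1,2,3 vs 4,5,6: H = 12/(6*7) * (3*2^2 + 3*5^2) - 3*7
        expected = 12.0 / 42.0 * (3 * 2.0**2 + 3 * 5.0**2) - 21.0
        assert res.H == pytest.approx(expected, abs=1e-12)
        assert res.H == pytest.approx(direct_kw_h(groups), abs=1e-12)

    def test_all_values_identical_is_not_an_error(self):
        res = kruskal_wallis(as_groups([(5.0, 5.0), (5.0, 5.0)]))
        assert res.H == 0.0 and res.p_value == 1.0

    def test_matches_direct_recomputation_on_many_small_datasets(self):
        """H agrees with the independent variance-ratio identity and with
        scipy's implementation on 100 seeded small datasets with ties."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [
                rng.integers(0, 8, size=int(rng.integers(2, 9))).astype(float)
                for _ in range(k)
            ]
            if len(np.unique(np.concatenate(groups))) == 1:
                continue
            res = kruskal_wallis(as_groups(groups))
            assert res.H == pytest.approx(direct_kw_h(groups), abs=1e-10)
            h_scipy, p_scipy = sps.kruskal(*groups)
            assert res.H == pytest.approx(h_scipy, abs=1e-10)
            assert res.p_value == pytest.approx(p_scipy, abs=1e-10)

    def test_no_ties_correction_is_identity(self):
        rng = np.random.default_rng(1)
        groups = [rng.random(6), rng.random(7)]
        res = kruskal_wallis(as_groups(groups))
        assert res.tie_correction == 1.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        groups = [rng.integers(0, 50, 8).astype(float) for _ in range(3)]
        base = kruskal_wallis(as_groups(groups)).H
        for transform in (np.exp, lambda x: x**3, lambda x: x / (1 + np.abs(x))):
            transformed = [transform(np.asarray(g) / 10.0) for g in groups]
            assert kruskal_wallis(as_groups(transformed)).H == pytest.approx(base, abs=1e-10)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            kruskal_wallis(as_groups([(1, 2, 3)]))


class TestDunn:
    def test_identical_groups_give_zero_z(self):
        res = dunns_test(as_groups([(1, 2, 3), (1, 2, 3)]))
        (pair,) = res.comparisons
        assert pair.z == pytest.approx(0.0, abs=1e-12)
        assert pair.p_adjusted == pytest.approx(1.0)

    def test_swapping_groups_flips_sign_only(self):
        a, b = (1.0, 2.0, 3.0, 4.0), (10.0, 12.0, 14.0, 16.0)
        z1 = dunns_test(as_groups([a, b])).comparisons[0]
        z2 = dunns_test(as_groups([b, a])).comparisons[0]
        assert z1.z == pytest.approx(-z2.z)
        assert z1.p_raw == pytest.approx(z2.p_raw)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [
                rng.integers(0, 8, size=int(rng.integers(2, 9))).astype(float)
                for _ in range(k)
            ]
            res = dunns_test(as_groups(groups), adjustment="none")
            idx = 0
            for i in range(k):
                for j in range(i + 1, k):
                    expected = direct_dunn_z(groups, i, j)
                    if np.isfinite(expected):
                        assert res.comparisons[idx].z == pytest.approx(expected, abs=1e-10)
                    idx += 1

    def test_bonferroni_adjustment(self):
        groups = as_groups([(1, 2), (3, 4), (50, 60)])
        res = dunns_test(groups, adjustment="bonferroni")
        for c in res.comparisons:
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 3))

    def test_only_shifted_group_pairs_significant(self):
        """Three groups, one shifted far beyond the pooled spread: exactly
        the two pairs involving the shifted group reach significance."""
        rng = np.random.default_rng(3)
        a = tuple(rng.normal(10, 1, 20))
        b = tuple(rng.normal(10, 1, 20))
        c = tuple(rng.normal(40, 1, 20))  # >= 5 pooled SDs away
        res = dunns_test(as_groups([a, b, c]))
        flags = {(p.group_a, p.group_b): p.significant for p in res.comparisons}
        assert flags[("0", "1")] is False
        assert flags[("0", "2")] is True and flags[("1", "2")] is True

    def test_unknown_adjustment_rejected(self):
        with pytest.raises(ValueError, match="adjustment"):
            dunns_test(as_groups([(1, 2), (3, 4)]), adjustment="fdr")

    def test_holm_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(5)
        groups = [tuple(rng.normal(loc, 1, 10)) for loc in (0, 1, 3)]
        bonf = dunns_test(as_groups(groups), adjustment="bonferroni")
        holm = dunns_test(as_groups(groups), adjustment="holm")
        for cb, ch in zip(bonf.comparisons, holm.comparisons):
            assert ch.p_adjusted <= cb.p_adjusted + 1e-12


def _measurement(factor, stage, roi, fraction):
    area = 1000
    dom = int(round(fraction * 10))
    return DomainMeasurement(
        factor=factor, stage=stage, roi_id=roi, roi_area=area, domain_area=dom,
        fraction=100.0 * dom / area, band_histogram={"all": dom},
    )


class TestCompareDomains:
    @staticmethod
    def _study(rng, shift_factor=None, n=16):
        ms = []
        for factor in ("sdc1", "sdc4"):
            for stage in ("late_bud", "early_bell_cl"):
                loc = 30.0
                if factor == shift_factor and stage == "early_bell_cl":
                    loc = 60.0
                for frac in rng.normal(loc, 4.0, n):
                    ms.append(_measurement(factor, stage, "cervical_loop",
                                           float(np.clip(frac, 0, 100))))
        return ms

    def test_only_truly_shifted_factor_flagged(self):
        """Synthetic positive/negative control over 20 seeds: the factor
        whose generating fraction differs between stages is flagged, the
        unchanged factor is not, in at least 18/20 runs."""
        correct = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            report = compare_domains(self._study(rng, shift_factor="sdc4"))
            flagged = set(report.loc[report.significant, "factor"])
            correct += flagged == {"sdc4"}
        assert correct >= 18

    def test_null_study_controls_familywise_error(self):
        """With no true differences across four stage groups, the omnibus-
        gated, Bonferroni-adjusted report flags anything in only about 5%
        of runs; over 60 seeded runs that is at most 7 flagged runs."""
        stages = ("late_bud", "cap", "early_bell_cl", "early_bell_iee")
        flagged_runs = 0
        for seed in range(60):
            rng = np.random.default_rng(200 + seed)
            ms = [
                _measurement("sdc1", stage, "cervical_loop", float(np.clip(v, 0, 100)))
                for stage in stages
                for v in rng.normal(30.0, 4.0, 16)
            ]
            flagged_runs += bool(compare_domains(ms).significant.any())
        assert flagged_runs <= 7

    def test_single_group_rejected(self):
        ms = [_measurement("sdc1", "cap", "iee", 30.0) for _ in range(5)]
        with pytest.raises(ValueError, match="single"):
            compare_domains(ms)

    def test_report_is_tidy(self):
        rng = np.random.default_rng(0)
        report = compare_domains(self._study(rng))
        assert set(report.columns) >= {
            "factor", "group_a", "group_b", "z", "p_adjusted", "significant",
        }
        assert len(report) == 2  # one pair per factor
        assert "pseudo-replicates" in report.attrs["note"]
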