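"""Analysis of deviance and level pooling against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from karyometry import (
    DomainError,
    anodev_oneway,
    karyotype_length_test,
    per_chromosome_tests,
    pool_levels,
    simulate_measurements,
    simulate_study,
)


def brute_force_anova(values, groups):
    """Hand sums-of-squares one-way ANOVA (independent of the GLM path)."""
    values = list(map(float, values))
    levels = list(dict.fromkeys(groups))
    grand = sum(values) / len(values)
    between = 0.0
    within = 0.0
    for lev in levels:
        ys = [v for v, g in zip(values, groups) if g == lev]
        m = sum(ys) / len(ys)
        between += len(ys) * (m - grand) ** 2
        within += sum((y - m) ** 2 for y in ys)
    df1, df2 = len(levels) - 1, len(values) - len(levels)
    f = (between / df1) / (within / df2) if within > 0 else float("inf")
    p = float(stats.f.sf(f, df1, df2)) if within > 0 else 0.0
    return between, within, df1, df2, f, p


class TestAnodevOneway:
    def test_hand_oracle_two_groups(self):
        res = anodev_oneway([1, 2, 3, 11, 12, 13], list("aaabbb"))
        assert res.deviance_explained == pytest.approx(150.0, rel=1e-12)
        assert (res.df_factor, res.df_residual) == (1, 4)
        assert res.test_statistic == pytest.approx(150.0, rel=1e-12)

    def test_identical_groups_no_effect(self):
        res = anodev_oneway([5.0] * 6, list("aaabbb"))
        assert res.deviance_explained == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0
        assert res.degenerate

    def test_zero_residual_deviance_degenerate(self):
        res = anodev_oneway([1.0, 1.0, 2.0, 2.0], list("aabb"))
        assert res.degenerate
        assert res.p_value == 0.0
        assert res.deviance_explained == pytest.approx(1.0)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            k = int(rng.integers(2, 6))
            sizes = rng.integers(2, 8, size=k)
            groups = [f"g{i}" for i in range(k) for _ in range(sizes[i])]
            values = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), len(groups))
            res = anodev_oneway(values, groups)
            between, within, df1, df2, f, p = brute_force_anova(values, groups)
            assert res.deviance_explained == pytest.approx(between, rel=1e-10)
            assert (res.df_factor, res.df_residual) == (df1, df2)
            assert res.test_statistic == pytest.approx(f, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-10, abs=1e-300)

    def test_single_level_rejected(self):
        with pytest.raises(DomainError):
            anodev_oneway([1.0, 2.0], ["a", "a"])


class TestDfStructure:
    def test_karyotype_length_df(self, synthetic_study):
        """5 populations x 10 metaphases -> factor/residual df (4, 45)."""
        anodev, _ = karyotype_length_test(synthetic_study)
        assert (anodev.df_factor, anodev.df_residual) == (4, 45)

    def test_per_chromosome_df(self, synthetic_study):
        """Both homologues used: 5 x 10 x 2 observations -> df (4, 95)."""
        tests = per_chromosome_tests(synthetic_study)
        assert len(tests) == 10
        for t in tests:
            assert (t.anodev.df_factor, t.anodev.df_residual) == (4, 95)

    def test_identical_populations_p_one(self, study_params):
        ds = simulate_measurements(study_params[0], seed=5)
        doubled = type(ds)(
            metaphases=ds.metaphases
            + tuple(
                type(m)(
                    specimen_id=m.specimen_id + "x",
                    colony_id=m.colony_id,
                    population_id="COPY",
                    chromosomes=m.chromosomes,
                )
                for m in ds.metaphases
            ),
            ploidy_2n=ds.ploidy_2n,
        )
        for t in per_chromosome_tests(doubled):
            assert t.anodev.p_value == pytest.approx(1.0)

    def test_holm_adjustment_monotone(self, synthetic_study):
        raw = per_chromosome_tests(synthetic_study, correction="none")
        adj = per_chromosome_tests(synthetic_study, correction="holm")
        for r, a in zip(raw, adj):
            assert a.p_adjusted >= r.anodev.p_value - 1e-15


# ---------------------------------------------------------------------------
# pooling oracle: independent enumeration of set partitions + statsmodels fits


def _partitions(levels):
    """All set partitions via itertools (independent of the package's recursion)."""
    if len(levels) == 1:
        yield [levels]
        return
    head, rest = levels[0], levels[1:]
    for sub in _partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[head] + sub[i]] + sub[i + 1:]
        yield [[head]] + sub


def oracle_pool(values, groups, alpha):
    """Coarsest partition not significantly worse than the full model.

    Deviances come from explicit residual sums of squares around block
    means computed with numpy (no shared code with the implementation).
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups, dtype=object)
    levels = list(dict.fromkeys(groups))

    def resid_dev(partition):
        dev = 0.0
        for block in partition:
            y = values[np.isin(groups, block)]
            dev += float(((y - y.mean()) ** 2).sum())
        return dev

    dev_full = resid_dev([[lev] for lev in levels])
    df_full = len(values) - len(levels)
    admissible = []
    for part in _partitions(levels):
        ddf = len(levels) - len(part)
        dev = resid_dev(part)
        if ddf == 0:
            admissible.append((len(part), dev, part))
            continue
        f = ((dev - dev_full) / ddf) / (dev_full / df_full)
        if float(stats.f.sf(f, ddf, df_full)) >= alpha:
            admissible.append((len(part), dev, part))
    nblocks, dev, _ = min(admissible, key=lambda t: (t[0], t[1]))
    best = [
        p for n, d, p in admissible
        if n == nblocks and abs(d - dev) <= 1e-9 * max(dev, 1.0)
    ]
    return {frozenset(map(frozenset, p)) for p in best}, nblocks


class TestPoolLevels:
    def test_separated_group_isolated(self, rng):
        values = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(100, 1, 10)]
        )
        groups = ["g1"] * 10 + ["g2"] * 10 + ["g3"] * 10
        res = pool_levels(values, groups, alpha=0.05)
        blocks = {frozenset(b) for b in res.partition}
        assert blocks == {frozenset({"g1", "g2"}), frozenset({"g3"})}
        assert res.letters["g3"] == "a"  # largest mean gets "a"
        assert res.letters["g1"] == res.letters["g2"] == "b"

    def test_alpha_zero_pools_everything(self, rng):
        values = rng.normal(0, 1, 30) + np.repeat([0, 5, 50], 10)
        groups = np.repeat(["a", "b", "c"], 10)
        res = pool_levels(values, groups, alpha=0.0)
        assert len(res.partition) == 1

    def test_alpha_one_keeps_all_levels_separate(self, rng):
        values = rng.normal(0, 1, 30) + np.repeat([0, 1, 2], 10)
        groups = np.repeat(["a", "b", "c"], 10)
        res = pool_levels(values, groups, alpha=1.0)
        assert len(res.partition) == 3

    def test_degenerate_constant_data_single_block(self):
        res = pool_levels([3.0] * 12, np.repeat(["a", "b", "c"], 4))
        assert res.degenerate
        assert len(res.partition) == 1

    def test_letters_consistent_with_partition(self, synthetic_study):
        _, grouping = karyotype_length_test(synthetic_study)
        for block in grouping.partition:
            letters = {grouping.letters[lev] for lev in block}
            assert len(letters) == 1
        all_letters = [grouping.letters[lev] for b in grouping.partition for lev in b]
        assert len(set(all_letters)) == len(grouping.partition)

    @pytest.mark.parametrize("n_levels", [3, 4, 5])
    def test_agrees_with_exhaustive_oracle(self, n_levels, rng):
        """Randomized suite: implementation vs brute-force partition search."""
        for trial in range(12):
            means = rng.uniform(0, 6, n_levels)
            sd = rng.uniform(0.5, 2.0)
            n = int(rng.integers(4, 9))
            values = np.concatenate(
                [rng.normal(m, sd, n) for m in means]
            )
            groups = [f"g{i}" for i in range(n_levels) for _ in range(n)]
            alpha = float(rng.choice([0.01, 0.05, 0.1]))
            res = pool_levels(values, groups, alpha=alpha)
            oracle_best, oracle_nblocks = oracle_pool(values, groups, alpha)
            got = frozenset(frozenset(b) for b in res.partition)
            assert len(res.partition) == oracle_nblocks
            assert got in oracle_best


class TestSyntheticStudyGrouping:
    def test_population_effect_detected(self, synthetic_study):
        anodev, grouping = karyotype_length_test(synthetic_study)
        assert anodev.p_value < 0.05
        # CI and TO differ by 0.34 μm (noise scale): never separated; both
        # are far (>9 μm) from MC and CC
        assert grouping.letters["CI"] == grouping.letters["TO"]
        assert grouping.letters["CI"] != grouping.letters["MC"]
        assert grouping.letters["CI"] != grouping.letters["CC"]

    def test_grouping_stable_across_seeds(self, study_params):
        """Distant populations never pool; close CI/TO pool at most seeds.

        CI and TO differ by 0.34 μm (far below the per-metaphase KL noise),
        so they share a letter except for the ~alpha fraction of seeds where
        the contrast is spuriously significant.  CI and TO are both ≥ 9 μm
        from MC and CC and must never share their letters.
        """
        n_seeds = 40
        ci_to_together = 0
        for seed in range(n_seeds):
            ds = simulate_study(study_params, seed=seed)
            _, g = karyotype_length_test(ds)
            for near in ("CI", "TO"):
                for far in ("MC", "CC"):
                    assert g.letters[near] != g.letters[far]
            if g.letters["CI"] == g.letters["TO"]:
                ci_to_together += 1
        assert ci_to_together >= 0.8 * n_seeds
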