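"""Population comparisons: Gaussian analysis of deviance and level pooling.

Karyotype length (and individual chromosome lengths) are compared across
populations with a one-way Gaussian/identity GLM.  For a Gaussian model the
deviance is the residual sum of squares, so the analysis of deviance is the
classical one-way ANOVA: the factor's explained deviance is the
between-group sum of squares and the F test compares it with the residual
mean square.

When the population effect is significant, statistically indistinguishable
levels are pooled: a coarser grouping of the populations is acceptable when
collapsing levels does not significantly increase the model deviance (F test
against the full, all-levels-separate model).  Among acceptable groupings
the coarsest one (fewest blocks) is returned, and blocks receive
compact-letter-display labels ("a" for the block with the largest mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .karyodata import MeasurementDataset
from .morphometry import DomainError, karyotype_length

#: residual deviance below this (relative to total SS) is treated as an
#: exact fit, which makes the F statistic degenerate
_DEGENERATE_RTOL = 1e-12

#: exact partition search is used up to this many factor levels
#: (Bell(10) = 115 975 partitions is still enumerable; beyond that a
#: greedy agglomeration over block pairs is used)
_EXACT_LEVEL_LIMIT = 10


@dataclass(frozen=True)
class AnodevResult:
    """One-way analysis of deviance for a Gaussian/identity GLM."""

    deviance_explained: float
    df_factor: int
    df_residual: int
    test_statistic: float
    p_value: float
    degenerate: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Deviance({self.df_factor},{self.df_residual}) = "
            f"{self.deviance_explained:.4g}; p = {self.p_value:.4g}"
        )


@dataclass(frozen=True)
class GroupingResult:
    """A partition of factor levels into statistically indistinct blocks."""

    partition: tuple[tuple[str, ...], ...]
    letters: dict[str, str]
    alpha: float
    degenerate: bool = False
    residual_deviance: float = 0.0


def _check_inputs(values: Sequence[float], groups: Sequence) -> tuple[np.ndarray, list]:
    y = np.asarray(values, dtype=float)
    g = list(groups)
    if y.ndim != 1 or len(g) != y.size:
        raise DomainError("values and groups must be parallel 1-D sequences")
    if not np.all(np.isfinite(y)):
        raise DomainError("values must be finite")
    levels = list(dict.fromkeys(g))
    if len(levels) < 2:
        raise DomainError("at least 2 factor levels required")
    return y, levels


def anodev_oneway(values: Sequence[float], groups: Sequence) -> AnodevResult:
    """One-way Gaussian GLM analysis of deviance (≡ one-way ANOVA).

    Fits the null (intercept-only) and the factor model with a Gaussian
    family and identity link; the explained deviance is the drop in deviance
    from null to factor model (the between-group sum of squares) and is
    tested with F = (ΔD/df_factor) / (D_resid/df_residual).

    Zero residual deviance with a real group effect is degenerate (the
    factor model fits exactly); it is reported with p = 0 and a flag.
    """
    y, levels = _check_inputs(values, groups)
    g = list(groups)
    df_factor = len(levels) - 1
    df_residual = y.size - len(levels)
    if df_residual <= 0:
        raise DomainError("no residual degrees of freedom")
    if np.ptp(y) == 0.0:
        # constant response: zero deviance everywhere, no effect to test
        return AnodevResult(0.0, df_factor, df_residual, 0.0, 1.0, True)
    design = np.column_stack(
        [np.ones(y.size)]
        + [np.asarray([1.0 if gi == lev else 0.0 for gi in g]) for lev in levels[1:]]
    )
    null_fit = sm.GLM(y, np.ones((y.size, 1)), family=sm.families.Gaussian()).fit()
    full_fit = sm.GLM(y, design, family=sm.families.Gaussian()).fit()
    dev_null = float(null_fit.deviance)
    dev_resid = float(full_fit.deviance)
    dev_explained = max(dev_null - dev_resid, 0.0)
    scale = max(dev_null, 1.0)
    if dev_resid <= _DEGENERATE_RTOL * scale:
        if dev_explained <= _DEGENERATE_RTOL * scale:
            # all observations identical everywhere: no effect at all
            return AnodevResult(0.0, df_factor, df_residual, 0.0, 1.0, True)
        return AnodevResult(
            dev_explained, df_factor, df_residual, float("inf"), 0.0, True
        )
    f_stat = (dev_explained / df_factor) / (dev_resid / df_residual)
    p = float(stats.f.sf(f_stat, df_factor, df_residual))
    return AnodevResult(dev_explained, df_factor, df_residual, f_stat, p)


# ---------------------------------------------------------------------------
# level pooling


def _level_stats(y: np.ndarray, g: list, levels: list) -> dict:
    """Per-level sufficient statistics (n, Σy, Σy²) for partition deviances."""
    out = {}
    garr = np.asarray(g, dtype=object)
    for lev in levels:
        yi = y[garr == lev]
        out[lev] = (yi.size, float(yi.sum()), float((yi**2).sum()))
    return out


def _partition_deviance(partition, level_stats) -> float:
    """Residual deviance (within-block SS) of a partition model."""
    dev = 0.0
    for block in partition:
        n = sum(level_stats[lev][0] for lev in block)
        s = sum(level_stats[lev][1] for lev in block)
        ss = sum(level_stats[lev][2] for lev in block)
        dev += ss - s * s / n
    return max(dev, 0.0)


def _iter_partitions(items: list) -> Iterator[list[list]]:
    """All set partitions of ``items`` (restricted-growth recursion)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in _iter_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1:]
        yield [[first]] + sub


def _is_admissible(
    partition, level_stats, dev_full: float, df_full: int, n_levels: int,
    alpha: float, scale: float,
) -> tuple[bool, float]:
    """F test of a pooled partition against the full (singleton) model."""
    dev_p = _partition_deviance(partition, level_stats)
    delta_df = n_levels - len(partition)
    if delta_df == 0:
        return True, dev_p
    delta_dev = max(dev_p - dev_full, 0.0)
    if dev_full <= _DEGENERATE_RTOL * scale:
        return delta_dev <= _DEGENERATE_RTOL * scale, dev_p
    f_stat = (delta_dev / delta_df) / (dev_full / df_full)
    p = float(stats.f.sf(f_stat, delta_df, df_full))
    # significant iff p < alpha, so a pooled model is acceptable when p >= alpha
    return p >= alpha, dev_p


def _assign_letters(partition, level_stats) -> dict[str, str]:
    def block_mean(block):
        n = sum(level_stats[lev][0] for lev in block)
        s = sum(level_stats[lev][1] for lev in block)
        return s / n

    ordered = sorted(partition, key=block_mean, reverse=True)
    letters = {}
    for i, block in enumerate(ordered):
        label = chr(ord("a") + i) if i < 26 else f"a{i}"
        for lev in block:
            letters[lev] = label
    return letters


def pool_levels(
    values: Sequence[float], groups: Sequence, alpha: float = 0.05
) -> GroupingResult:
    """Pool factor levels that do not differ significantly.

    A candidate grouping (set partition of the levels) is acceptable when
    the F test of its deviance increase over the full model — with the
    numerator df equal to the number of levels collapsed — is
    non-significant at ``alpha``.  The coarsest acceptable grouping is
    returned; ties are broken by smaller residual deviance, then by a
    canonical ordering of the partition, so the result is deterministic.

    Up to 10 levels the partition lattice is searched exhaustively; beyond
    that a greedy agglomeration merges the pair of blocks with the closest
    means whose merge remains acceptable, repeating until no merge passes.

    Data with zero variance everywhere yield a single block with the
    ``degenerate`` flag set.
    """
    if not 0.0 <= alpha <= 1.0:
        raise DomainError("alpha must be in [0, 1]")
    y, levels = _check_inputs(values, groups)
    g = list(groups)
    level_stats = _level_stats(y, g, levels)
    n_levels = len(levels)
    full = [[lev] for lev in levels]
    dev_full = _partition_deviance(full, level_stats)
    df_full = y.size - n_levels
    if df_full <= 0:
        raise DomainError("no residual degrees of freedom")
    total_dev = _partition_deviance([levels], level_stats)
    scale = max(total_dev, 1.0)
    if total_dev <= _DEGENERATE_RTOL * scale and total_dev <= 1e-12:
        partition = (tuple(levels),)
        return GroupingResult(
            partition, {lev: "a" for lev in levels}, alpha, True, 0.0
        )

    def canon(partition):
        blocks = [tuple(sorted(b, key=levels.index)) for b in partition]
        return tuple(sorted(blocks, key=lambda b: levels.index(b[0])))

    if n_levels <= _EXACT_LEVEL_LIMIT:
        best = None
        for part in _iter_partitions(levels):
            ok, dev_p = _is_admissible(
                part, level_stats, dev_full, df_full, n_levels, alpha, scale
            )
            if not ok:
                continue
            key = (len(part), dev_p, canon(part))
            if best is None or key < best[0]:
                best = (key, canon(part), dev_p)
        assert best is not None  # the full partition is always admissible
        partition, dev_p = best[1], best[2]
    else:  # greedy fallback for wide factors
        blocks = [list(b) for b in full]
        dev_p = dev_full
        while len(blocks) > 1:
            def bmean(b):
                n = sum(level_stats[lev][0] for lev in b)
                return sum(level_stats[lev][1] for lev in b) / n

            pairs = sorted(
                (
                    (abs(bmean(blocks[i]) - bmean(blocks[j])), i, j)
                    for i in range(len(blocks))
                    for j in range(i + 1, len(blocks))
                )
            )
            merged = None
            for _, i, j in pairs:
                cand = (
                    [b for k, b in enumerate(blocks) if k not in (i, j)]
                    + [blocks[i] + blocks[j]]
                )
                ok, dev_c = _is_admissible(
                    cand, level_stats, dev_full, df_full, n_levels, alpha, scale
                )
                if ok:
                    merged = (cand, dev_c)
                    break
            if merged is None:
                break
            blocks, dev_p = merged
        partition = canon(blocks)

    return GroupingResult(
        partition=partition,
        letters=_assign_letters(partition, level_stats),
        alpha=alpha,
        degenerate=False,
        residual_deviance=dev_p,
    )


# ---------------------------------------------------------------------------
# dataset-level drivers


@dataclass(frozen=True)
class ChromosomeTest:
    """Per-homologue-pair population comparison."""

    pair_rank: int
    anodev: AnodevResult
    grouping: GroupingResult
    p_adjusted: float = field(default=float("nan"))


def karyotype_length_test(
    dataset: MeasurementDataset, alpha: float = 0.05
) -> tuple[AnodevResult, GroupingResult]:
    """Population effect on per-metaphase karyotype length."""
    values = [karyotype_length(m) for m in dataset.metaphases]
    groups = [m.population_id for m in dataset.metaphases]
    return anodev_oneway(values, groups), pool_levels(values, groups, alpha)


def per_chromosome_tests(
    dataset: MeasurementDataset,
    alpha: float = 0.05,
    correction: str = "none",
) -> list[ChromosomeTest]:
    """One test per homologue pair, both homologues used as observations.

    With 5 populations × 10 metaphases × 2 homologues this reproduces the
    (4, 95) degrees-of-freedom structure.  Raw p-values are reported by
    default; ``correction="holm"`` applies a Holm step-down adjustment
    across the pairs.
    """
    if correction not in {"none", "holm"}:
        raise DomainError(f"unknown correction {correction!r}")
    n_pairs = dataset.ploidy_2n // 2
    results = []
    for pair in range(n_pairs):
        values: list[float] = []
        groups: list[str] = []
        for m in dataset.metaphases:
            for idx in (2 * pair, 2 * pair + 1):
                values.append(m.chromosomes[idx].total_length_um)
                groups.append(m.population_id)
        results.append(
            (anodev_oneway(values, groups), pool_levels(values, groups, alpha))
        )
    raw_p = [a.p_value for a, _ in results]
    if correction == "holm":
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(raw_p, alpha=alpha, method="holm")[1]
    else:
        adj = raw_p
    return [
        ChromosomeTest(pair + 1, a, gr, float(adj[pair]))
        for pair, (a, gr) in enumerate(results)
    ]
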