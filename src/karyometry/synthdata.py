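"""Seeded generators emulating the study's raw inputs.

Two kinds of raw data feed the pipeline and neither ships with the package:
per-metaphase chromosome measurement tables and flow-cytometry fluorescence
histograms.  The generators here produce both with the statistical structure
the analysis assumes, parameterized by the published per-population homologue
means ± SD (packaged verbatim as the bundled summary table) and by nominal
cytometer settings.  All generators are pure functions of (params, seed).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flowcyto import DROSOPHILA_1C_PG, FluorescenceHistogram
from .karyodata import (
    ChromosomeMeasurement,
    MeasurementDataset,
    MetaphaseKaryotype,
)
from .morphometry import DomainError

#: lengths are truncated below this (μm) to avoid non-physical draws;
#: negligible at the packaged parameter values (means ≥ 2.6, SD ≤ 0.9)
MIN_LENGTH_UM = 0.1


@dataclass(frozen=True)
class PopulationParams:
    """Simulation parameters for one population's measurement table.

    ``homologue_mean_tl_um``/``homologue_sd_tl_um`` hold one value per
    chromosome of the diploid set (2n entries, descending mean).  Arm ratios
    are drawn uniformly from ``arm_ratio_range``; the default [1.0, 1.3]
    keeps every simulated chromosome metacentric.
    """

    population_id: str
    homologue_mean_tl_um: tuple[float, ...]
    homologue_sd_tl_um: tuple[float, ...]
    arm_ratio_range: tuple[float, float] = (1.0, 1.3)
    n_metaphases: int = 10
    within_pair_correlation: float = 0.0

    def __post_init__(self) -> None:
        means = self.homologue_mean_tl_um
        sds = self.homologue_sd_tl_um
        if len(means) != len(sds) or not means or len(means) % 2:
            raise DomainError("need matching, even-length mean/SD tuples")
        if any(m <= 0 for m in means) or any(s < 0 for s in sds):
            raise DomainError("means must be positive, SDs non-negative")
        if any(b > a + 1e-9 for a, b in zip(means, means[1:])):
            raise DomainError("means must be non-increasing across ranks")
        lo, hi = self.arm_ratio_range
        if not 1.0 <= lo <= hi:
            raise DomainError("arm ratio range must satisfy 1 <= lo <= hi")
        if self.n_metaphases < 1:
            raise DomainError("need at least one metaphase")
        if not -1.0 <= self.within_pair_correlation <= 1.0:
            raise DomainError("correlation must be in [-1, 1]")

    @property
    def ploidy_2n(self) -> int:
        return len(self.homologue_mean_tl_um)


@dataclass(frozen=True)
class FlowSimParams:
    """Simulation parameters for a two-peak fluorescence histogram."""

    true_1c_pg: float
    standard_1c_pg: float = DROSOPHILA_1C_PG
    standard_channel: float = 200.0
    peak_cv: float = 0.02
    n_events: int = 10_000
    background_fraction: float = 0.0
    n_channels: int = 1024
    channel_max: float = 1024.0
    sample_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(self.true_1c_pg, self.standard_1c_pg, self.standard_channel) <= 0:
            raise DomainError("masses and channels must be positive")
        if not 0 < self.peak_cv < 0.2:
            raise DomainError("peak CV must be in (0, 0.2)")
        if self.n_events < 1:
            raise DomainError("need at least one event")
        if not 0.0 <= self.background_fraction < 1.0:
            raise DomainError("background fraction must be in [0, 1)")
        if not 0.0 < self.sample_fraction < 1.0:
            raise DomainError("sample fraction must be in (0, 1)")

    @property
    def sample_channel(self) -> float:
        # fluorescence scales linearly with DNA content; ploidy factors cancel
        return self.standard_channel * self.true_1c_pg / self.standard_1c_pg


def table1_params(
    level: str = "homologue", n_metaphases: int = 10
) -> list[PopulationParams]:
    """Per-population parameters from the packaged karyomorphometric table.

    ``level="homologue"`` keeps the two printed rows of each homologue pair
    as distinct per-chromosome means; ``level="pair"`` replaces both by the
    pair average.  Populations are returned in fixture order
    (CI, TO, BG, MC, CC).
    """
    if level not in {"homologue", "pair"}:
        raise DomainError(f"unknown level {level!r}")
    df = load_table1()
    params = []
    for pop in df["population_id"].unique():
        sub = df[df["population_id"] == pop].sort_values(
            ["pair_rank", "homologue"]
        )
        means = sub["mean_tl_um"].to_numpy(dtype=float)
        sds = sub["sd_tl_um"].to_numpy(dtype=float)
        if level == "pair":
            means = np.repeat((means[0::2] + means[1::2]) / 2.0, 2)
            sds = np.repeat((sds[0::2] + sds[1::2]) / 2.0, 2)
        # printed rows are sorted within pairs; enforce global descending order
        order = np.argsort(-means, kind="stable")
        params.append(
            PopulationParams(
                population_id=str(pop),
                homologue_mean_tl_um=tuple(means[order]),
                homologue_sd_tl_um=tuple(sds[order]),
                n_metaphases=n_metaphases,
            )
        )
    return params


def load_table1() -> pd.DataFrame:
    """The packaged per-population homologue means ± SD (long format)."""
    ref = importlib.resources.files("karyometry").joinpath("data/table1.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def table1_dataset() -> MeasurementDataset:
    """Expand the packaged summary table to one metaphase per population.

    Each population's 20 printed mean TLs become the chromosomes of a
    single synthetic metaphase with equal arms (L = S = TL/2, metacentric).
    Useful as a deterministic fixture: each population's karyotype length
    equals the printed column sum.
    """
    df = load_table1()
    metaphases = []
    for pop in df["population_id"].unique():
        sub = df[df["population_id"] == pop].sort_values(
            ["pair_rank", "homologue"]
        )
        tls = sorted(sub["mean_tl_um"].to_numpy(dtype=float), reverse=True)
        chroms = tuple(
            ChromosomeMeasurement(
                long_arm_um=tl / 2.0,
                short_arm_um=tl / 2.0,
                total_length_um=tl,
                chromosome_index=i + 1,
            )
            for i, tl in enumerate(tls)
        )
        metaphases.append(
            MetaphaseKaryotype(
                specimen_id=f"{pop}-summary",
                colony_id=f"{pop}-summary",
                population_id=str(pop),
                chromosomes=chroms,
            )
        )
    return MeasurementDataset(metaphases=tuple(metaphases), ploidy_2n=len(chroms))


def simulate_measurements(
    params: PopulationParams, seed: int
) -> MeasurementDataset:
    """Simulate one population's per-metaphase measurement table.

    Each chromosome's TL is drawn from Normal(mean, SD) truncated below at
    0.1 μm (independently per metaphase; an optional within-pair correlation
    draws homologue pairs from a bivariate normal instead).  The arm ratio r
    is uniform on ``arm_ratio_range`` and the arms follow from
    L = TL·r/(1+r), S = TL/(1+r).  Chromosomes are re-ranked by descending
    TL within each metaphase, as an observer measuring a spread would.
    """
    rng = np.random.default_rng(seed)
    n2 = params.ploidy_2n
    means = np.asarray(params.homologue_mean_tl_um)
    sds = np.asarray(params.homologue_sd_tl_um)
    rho = params.within_pair_correlation
    metaphases = []
    for k in range(params.n_metaphases):
        if rho == 0.0:
            tl = rng.normal(means, sds)
        else:
            tl = np.empty(n2)
            for p in range(n2 // 2):
                i, j = 2 * p, 2 * p + 1
                cov = rho * sds[i] * sds[j]
                tl[i], tl[j] = rng.multivariate_normal(
                    [means[i], means[j]],
                    [[sds[i] ** 2, cov], [cov, sds[j] ** 2]],
                )
        tl = np.maximum(tl, MIN_LENGTH_UM)
        r = rng.uniform(*params.arm_ratio_range, size=n2)
        long_arm = tl * r / (1.0 + r)
        short_arm = tl / (1.0 + r)
        order = np.argsort(-tl, kind="stable")
        chroms = tuple(
            ChromosomeMeasurement(
                long_arm_um=float(long_arm[i]),
                short_arm_um=float(short_arm[i]),
                total_length_um=float(tl[i]),
                chromosome_index=rank + 1,
            )
            for rank, i in enumerate(order)
        )
        metaphases.append(
            MetaphaseKaryotype(
                specimen_id=f"{params.population_id}-{k + 1:02d}",
                colony_id=f"{params.population_id}-c1",
                population_id=params.population_id,
                chromosomes=chroms,
            )
        )
    return MeasurementDataset(metaphases=tuple(metaphases), ploidy_2n=n2)


def simulate_study(
    params_list: list[PopulationParams], seed: int
) -> MeasurementDataset:
    """Simulate a multi-population dataset (one sub-seed per population)."""
    if not params_list:
        raise DomainError("need at least one population")
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, len(params_list))
    metaphases: list[MetaphaseKaryotype] = []
    ploidy = params_list[0].ploidy_2n
    for p, s in zip(params_list, seeds):
        metaphases.extend(simulate_measurements(p, int(s)).metaphases)
    return MeasurementDataset(metaphases=tuple(metaphases), ploidy_2n=ploidy)


def simulate_histogram(params: FlowSimParams, seed: int) -> FluorescenceHistogram:
    """Simulate a two-peak (sample + internal standard) histogram.

    Events are split between a Gaussian standard peak at
    ``standard_channel`` and a Gaussian sample peak at the channel implied
    by the fluorescence ratio; an optional uniform background is added.
    Events are binned onto a fixed grid of ``n_channels`` bins over
    (0, channel_max].  A warning flag is set when the two peaks are closer
    than three combined SDs (unresolvable by peak finding).
    """
    rng = np.random.default_rng(seed)
    n_bg = int(round(params.background_fraction * params.n_events))
    n_signal = params.n_events - n_bg
    n_sample = int(round(params.sample_fraction * n_signal))
    n_std = n_signal - n_sample
    mu_std = params.standard_channel
    mu_sam = params.sample_channel
    sd_std = params.peak_cv * mu_std
    sd_sam = params.peak_cv * mu_sam
    events = np.concatenate(
        [
            rng.normal(mu_std, sd_std, n_std),
            rng.normal(mu_sam, sd_sam, n_sample),
            rng.uniform(0.0, params.channel_max, n_bg),
        ]
    )
    edges = np.linspace(0.0, params.channel_max, params.n_channels + 1)
    counts, _ = np.histogram(np.clip(events, 0.0, params.channel_max - 1e-9), edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    warning = ""
    if abs(mu_sam - mu_std) < 3.0 * (sd_std + sd_sam):
        warning = (
            "sample and standard peaks closer than 3 combined SDs; "
            "they may be unresolvable"
        )
    return FluorescenceHistogram(
        channel_values=centers, counts=counts.astype(float), warning=warning
    )
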