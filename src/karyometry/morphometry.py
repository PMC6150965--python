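"""Karyomorphometric statistics and chromosome morphology classification.

Implements the standard descriptive toolkit of metaphase karyomorphometry:

* arm ratio ``r = L/S`` and centromere-position morphology classes after
  Levan's nomenclature (metacentric, submetacentric, subtelocentric,
  acrocentric);
* relative chromosome length ``RL = TL × 100 / ΣTL``;
* karyotype asymmetry index ``AI = Σ long arms / Σ total length × 100``;
* karyotype length ``KL = ΣTL`` and its coefficient of variation across
  specimens;
* the diploid karyotype formula (e.g. ``2K = 20M``) and arm number ``2AN``.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field

from .karyodata import (
    MeasurementDataset,
    MetaphaseKaryotype,
    PopulationSummary,
)

#: Levan-style class bounds on r = L/S: label -> (lower incl., upper excl.)
#: and number of arms counted for the fundamental number 2AN.
DEFAULT_SCHEME: dict[str, tuple[float, float, int]] = {
    "M": (1.0, 1.7, 2),
    "SM": (1.7, 3.0, 2),
    "ST": (3.0, 7.0, 1),
    "A": (7.0, math.inf, 1),
}

CLASS_ORDER = ("M", "SM", "ST", "A")


class DomainError(ValueError):
    pass


def arm_ratio(long_arm: float, short_arm: float) -> float:
    """Arm ratio r = L/S, defined for L >= S > 0 (so always >= 1)."""
    if short_arm <= 0:
        raise DomainError(f"short arm must be positive, got {short_arm}")
    if long_arm < short_arm:
        raise DomainError(
            f"long arm ({long_arm}) < short arm ({short_arm}); "
            "repair arm order before computing r"
        )
    return long_arm / short_arm


def classify_morphology(
    r: float, scheme: dict[str, tuple[float, float, int]] | None = None
) -> str:
    """Morphology class label for arm ratio ``r``; bounds are lower-inclusive."""
    if r < 1.0:
        raise DomainError(f"arm ratio must be >= 1, got {r}")
    scheme = scheme or DEFAULT_SCHEME
    for label, (lo, hi, _) in scheme.items():
        if lo <= r < hi:
            return label
    raise DomainError(f"no morphology class covers r={r}")  # pragma: no cover


def relative_length(tl: float, sum_tl: float) -> float:
    """Relative length RL = TL × 100 / ΣTL, in percent."""
    if sum_tl <= 0:
        raise DomainError("sum of total lengths must be positive")
    if not 0 < tl <= sum_tl:
        raise DomainError(f"TL {tl} outside (0, ΣTL={sum_tl}]")
    return tl * 100.0 / sum_tl


def relative_lengths(karyotype: MetaphaseKaryotype) -> list[float]:
    """Per-chromosome RL for one metaphase (sums to 100)."""
    total = sum(karyotype.total_lengths())
    return [relative_length(tl, total) for tl in karyotype.total_lengths()]


def asymmetry_index(karyotype: MetaphaseKaryotype) -> float:
    """Karyotype asymmetry index AI = Σ long arms / Σ total length × 100.

    50 for a perfectly metacentric karyotype (all L = S), approaching 100
    in the telocentric limit.
    """
    if not karyotype.chromosomes:
        raise DomainError("empty karyotype")
    long_sum = sum(c.long_arm_um for c in karyotype.chromosomes)
    total = sum(c.long_arm_um + c.short_arm_um for c in karyotype.chromosomes)
    return long_sum / total * 100.0


def karyotype_length(obj: MetaphaseKaryotype | PopulationSummary) -> float:
    """Karyotype length KL: ΣTL of a metaphase, or Σ mean TL of a summary."""
    if isinstance(obj, PopulationSummary):
        if not obj.per_chromosome:
            raise DomainError("empty summary")
        return sum(row[1] for row in obj.per_chromosome)
    if not obj.chromosomes:
        raise DomainError("empty karyotype")
    return sum(obj.total_lengths())


@dataclass(frozen=True)
class KaryotypeFormula:
    """Diploid karyotype formula with arm number (fundamental number)."""

    counts: dict[str, int]
    formula_string: str
    arm_number_2AN: int
    ploidy_2n: int
    haploid_n: int


def karyotype_formula(
    class_labels: list[str] | tuple[str, ...],
    scheme: dict[str, tuple[float, float, int]] | None = None,
) -> KaryotypeFormula:
    """Render the diploid karyotype formula from per-chromosome class labels.

    Counts are concatenated in the fixed order M, SM, ST, A (zero counts
    omitted), e.g. 20 metacentrics give ``2K = 20M`` with 2AN = 40.
    Metacentric and submetacentric chromosomes contribute two arms to 2AN;
    subtelocentric and acrocentric contribute one.
    """
    scheme = scheme or DEFAULT_SCHEME
    n2 = len(class_labels)
    if n2 == 0 or n2 % 2 != 0:
        raise DomainError(f"diploid class count must be positive even, got {n2}")
    unknown = set(class_labels) - set(scheme)
    if unknown:
        raise DomainError(f"unknown morphology label(s): {sorted(unknown)}")
    counts = {lab: 0 for lab in scheme}
    for lab in class_labels:
        counts[lab] += 1
    order = [lab for lab in CLASS_ORDER if lab in scheme]
    order += [lab for lab in scheme if lab not in order]
    terms = [f"{counts[lab]}{lab}" for lab in order if counts[lab]]
    arm_number = sum(counts[lab] * scheme[lab][2] for lab in scheme)
    return KaryotypeFormula(
        counts={lab: counts[lab] for lab in order},
        formula_string="2K = " + " + ".join(terms),
        arm_number_2AN=arm_number,
        ploidy_2n=n2,
        haploid_n=n2 // 2,
    )


def summarize_population(
    dataset: MeasurementDataset,
    population_id: str,
    grouping: str = "specimen",
    scheme: dict[str, tuple[float, float, int]] | None = None,
) -> PopulationSummary:
    """Per-rank mean ± SD of TL across a population's metaphases.

    The averaging unit defaults to one metaphase per specimen
    (``grouping="specimen"``); ``grouping="colony"`` first averages the
    metaphases of each colony so colonies become the replicates.  The
    morphology class of each ranked chromosome is classified from its mean
    arm ratio.  SD uses the sample (n−1) denominator; with a single
    replicate SD is reported as 0 and flagged.
    """
    metas = dataset.metaphases_for(population_id)
    if not metas:
        raise DomainError(f"no metaphases for population {population_id!r}")
    if grouping not in {"specimen", "colony"}:
        raise DomainError(f"unknown grouping {grouping!r}")

    # replicate x rank matrices of TL and r
    if grouping == "specimen":
        units = [[m] for m in metas]
    else:
        by_colony: dict[str, list[MetaphaseKaryotype]] = {}
        for m in metas:
            by_colony.setdefault(m.colony_id, []).append(m)
        units = [by_colony[c] for c in sorted(by_colony)]

    n2 = dataset.ploidy_2n
    tl_rows: list[list[float]] = []
    r_rows: list[list[float]] = []
    for unit in units:
        tls = [0.0] * n2
        rs = [0.0] * n2
        for m in unit:
            for i, c in enumerate(m.chromosomes):
                tls[i] += c.total_length_um
                rs[i] += arm_ratio(c.long_arm_um, c.short_arm_um)
        k = len(unit)
        tl_rows.append([v / k for v in tls])
        r_rows.append([v / k for v in rs])

    n = len(tl_rows)
    sd_flag = "single-replicate: SD undefined, reported as 0" if n < 2 else ""
    per_chromosome = []
    for rank in range(n2):
        col = [row[rank] for row in tl_rows]
        rcol = [row[rank] for row in r_rows]
        mean_tl = statistics.fmean(col)
        sd_tl = statistics.stdev(col) if n >= 2 else 0.0
        mean_r = statistics.fmean(rcol)
        per_chromosome.append(
            (rank + 1, mean_tl, sd_tl, mean_r, classify_morphology(mean_r, scheme))
        )
    # ranking by per-metaphase TL does not guarantee monotone means; re-sort
    per_chromosome.sort(key=lambda row: -row[1])
    per_chromosome = [
        (i + 1, *row[1:]) for i, row in enumerate(per_chromosome)
    ]
    return PopulationSummary(
        population_id=population_id,
        n_metaphases=len(metas),
        per_chromosome=tuple(per_chromosome),
        karyotype_length_um=sum(row[1] for row in per_chromosome),
        sd_flag=sd_flag,
    )


def karyotype_cv(per_specimen_kls: list[float] | tuple[float, ...]) -> float:
    """Coefficient of variation SD/mean of per-specimen karyotype lengths."""
    if len(per_specimen_kls) < 2:
        raise DomainError("CV requires at least 2 values")
    mean = statistics.fmean(per_specimen_kls)
    if mean == 0:
        raise DomainError("CV undefined for zero mean")
    return statistics.stdev(per_specimen_kls) / mean


@dataclass(frozen=True)
class CvValidationReport:
    """Outlier screen: flags CVs further than one SD from the mean CV."""

    passed: bool
    flagged: tuple[int, ...] = field(default=())
    mean_cv: float = 0.0
    sd_cv: float = 0.0


def cv_validation(per_specimen_cvs: list[float] | tuple[float, ...]) -> CvValidationReport:
    """Flag every CV with |CV − mean| > SD; passes iff nothing is flagged."""
    if len(per_specimen_cvs) < 2:
        raise DomainError("validation requires at least 2 CV values")
    mean = statistics.fmean(per_specimen_cvs)
    sd = statistics.stdev(per_specimen_cvs)
    flagged = tuple(
        i for i, v in enumerate(per_specimen_cvs) if abs(v - mean) > sd + 1e-15
    )
    return CvValidationReport(
        passed=not flagged, flagged=flagged, mean_cv=mean, sd_cv=sd
    )
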