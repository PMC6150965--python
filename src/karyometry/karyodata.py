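"""Domain types, tabular I/O and validation for chromosome measurement data.

A *measurement dataset* is a collection of metaphase karyotypes, each one
being the 2n chromosomes measured on a single metaphase spread of one
specimen.  Every chromosome carries a long-arm length L, a short-arm length
S and a total length TL (all in μm); within a metaphase, chromosomes are
ranked by descending TL and consecutive ranks are paired into homologues.

The on-disk dialect is a plain CSV/TSV with header columns
``population_id, colony_id, specimen_id, chromosome_index, long_arm_um,
short_arm_um, total_length_um`` (decimal point, μm).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: default tolerance (μm) for |TL - (L+S)| when TL is measured independently
DEFAULT_TL_TOLERANCE_UM = 0.05

MEASUREMENT_COLUMNS = [
    "population_id",
    "colony_id",
    "specimen_id",
    "chromosome_index",
    "long_arm_um",
    "short_arm_um",
    "total_length_um",
]

REQUIRED_COLUMNS = [
    "population_id",
    "specimen_id",
    "chromosome_index",
    "long_arm_um",
    "short_arm_um",
]


class FormatError(ValueError):
    """Raised when an input table does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass(frozen=True)
class ChromosomeMeasurement:
    """One chromosome's arm and total lengths from one metaphase.

    Invariants: ``L >= S > 0`` and ``|TL - (L + S)| <= tolerance``.
    """

    long_arm_um: float
    short_arm_um: float
    total_length_um: float
    chromosome_index: int

    def __post_init__(self) -> None:
        if self.short_arm_um <= 0:
            raise ValidationError(
                f"short arm must be positive, got {self.short_arm_um}"
            )
        if self.long_arm_um < self.short_arm_um:
            raise ValidationError(
                f"long arm ({self.long_arm_um}) shorter than short arm "
                f"({self.short_arm_um}); repair or reject upstream"
            )
        if self.total_length_um <= 0:
            raise ValidationError("total length must be positive")
        if self.chromosome_index < 1:
            raise ValidationError("chromosome_index must be >= 1")


@dataclass(frozen=True)
class MetaphaseKaryotype:
    """All 2n chromosomes of one metaphase, ranked by descending TL.

    Homologue pairs follow the size-rank rule: ranks (1, 2) form pair 1,
    ranks (3, 4) pair 2, and so on.  With a uniform all-metacentric
    karyotype this is the only pairing information available.
    """

    specimen_id: str
    colony_id: str
    population_id: str
    chromosomes: tuple[ChromosomeMeasurement, ...]
    homologue_pairs: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.chromosomes)
        if n == 0 or n % 2 != 0:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: chromosome count {n} is not "
                "a positive even number"
            )
        if not self.homologue_pairs:
            object.__setattr__(
                self,
                "homologue_pairs",
                tuple((2 * i, 2 * i + 1) for i in range(n // 2)),
            )
        covered = sorted(i for pair in self.homologue_pairs for i in pair)
        if covered != list(range(n)):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: homologue pairs do not "
                "partition the chromosomes"
            )

    @property
    def ploidy_2n(self) -> int:
        return len(self.chromosomes)

    def total_lengths(self) -> list[float]:
        return [c.total_length_um for c in self.chromosomes]


@dataclass(frozen=True)
class PopulationSummary:
    """Ranked homologue means ± SD for one population (summary-table shape).

    ``per_chromosome`` holds one entry per rank in the diploid set:
    ``(rank, mean_TL, sd_TL, mean_r, morphology_label)``.
    """

    population_id: str
    n_metaphases: int
    per_chromosome: tuple[tuple[int, float, float, float, str], ...]
    karyotype_length_um: float
    sd_flag: str = ""

    def __post_init__(self) -> None:
        ranks = [row[0] for row in self.per_chromosome]
        if ranks != sorted(ranks) or len(set(ranks)) != len(ranks):
            raise ValidationError("summary ranks must be strictly increasing")
        means = [row[1] for row in self.per_chromosome]
        for a, b in zip(means, means[1:]):
            if b > a + 1e-9:
                raise ValidationError("mean TL must be non-increasing with rank")
        kl = sum(means)
        if not math.isclose(kl, self.karyotype_length_um, abs_tol=1e-6):
            raise ValidationError(
                f"KL {self.karyotype_length_um} != sum of means {kl}"
            )


@dataclass(frozen=True)
class MeasurementDataset:
    """A set of metaphase karyotypes sharing a diploid number."""

    metaphases: tuple[MetaphaseKaryotype, ...]
    ploidy_2n: int

    def __post_init__(self) -> None:
        for m in self.metaphases:
            if m.ploidy_2n != self.ploidy_2n:
                raise ValidationError(
                    f"specimen {m.specimen_id!r} has 2n={m.ploidy_2n}, "
                    f"dataset expects 2n={self.ploidy_2n}"
                )
            if not m.population_id:
                raise ValidationError(
                    f"specimen {m.specimen_id!r} has empty population id"
                )

    @property
    def population_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.metaphases:
            seen.setdefault(m.population_id, None)
        return list(seen)

    def metaphases_for(self, population_id: str) -> list[MetaphaseKaryotype]:
        return [m for m in self.metaphases if m.population_id == population_id]


def _sorted_chromosomes(
    chromosomes: Iterable[ChromosomeMeasurement],
) -> tuple[ChromosomeMeasurement, ...]:
    ordered = sorted(chromosomes, key=lambda c: -c.total_length_um)
    return tuple(
        replace(c, chromosome_index=i + 1) for i, c in enumerate(ordered)
    )


def make_metaphase(
    specimen_id: str,
    population_id: str,
    arms: Sequence[tuple[float, float]],
    colony_id: str = "",
) -> MetaphaseKaryotype:
    """Build a metaphase from (L, S) pairs; TL := L + S, ranks by TL."""
    chroms = [
        ChromosomeMeasurement(
            long_arm_um=max(l, s),
            short_arm_um=min(l, s),
            total_length_um=l + s,
            chromosome_index=i + 1,
        )
        for i, (l, s) in enumerate(arms)
    ]
    return MetaphaseKaryotype(
        specimen_id=specimen_id,
        colony_id=colony_id or specimen_id,
        population_id=population_id,
        chromosomes=_sorted_chromosomes(chroms),
    )


def read_measurements(
    path: str | Path,
    *,
    dialect: str = "auto",
    tl_tolerance: float = DEFAULT_TL_TOLERANCE_UM,
    arm_repair: str = "swap",
) -> MeasurementDataset:
    """Read a measurement table into a validated :class:`MeasurementDataset`.

    Parameters
    ----------
    path : str or Path
        CSV or TSV file with the measurement columns.
    dialect : {"auto", "csv", "tsv"}
        Field separator; "auto" sniffs from the extension / header line.
    tl_tolerance : float
        Allowed |TL - (L+S)| in μm when the TL column is present.
    arm_repair : {"swap", "strict"}
        Rows with L < S are silently swapped (and logged) or rejected.

    Raises
    ------
    FormatError
        Missing required column, unparseable numbers, or (in strict mode)
        a row with L < S.
    ValidationError
        Odd chromosome count in a metaphase, TL inconsistent beyond
        tolerance, or mixed diploid numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _resolve_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype={"population_id": str,
                                           "colony_id": str,
                                           "specimen_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if "colony_id" not in df.columns:
        df["colony_id"] = df["specimen_id"]
    has_tl = "total_length_um" in df.columns and df["total_length_um"].notna().all()

    metaphases: list[MetaphaseKaryotype] = []
    for (pop, spec), grp in df.groupby(["population_id", "specimen_id"], sort=True):
        chroms = []
        colony = str(grp["colony_id"].iloc[0])
        for row in grp.itertuples(index=False):
            L = float(row.long_arm_um)
            S = float(row.short_arm_um)
            if L < S:
                if arm_repair == "swap":
                    logger.warning(
                        "specimen %s chromosome %s: L < S, arms swapped",
                        spec, row.chromosome_index,
                    )
                    L, S = S, L
                else:
                    raise FormatError(
                        f"specimen {spec!r} chromosome {row.chromosome_index}: "
                        f"L ({L}) < S ({S}) in strict mode"
                    )
            if has_tl:
                tl = float(row.total_length_um)
                if abs(tl - (L + S)) > tl_tolerance:
                    raise ValidationError(
                        f"specimen {spec!r} chromosome {row.chromosome_index}: "
                        f"TL {tl} inconsistent with L+S {L + S:.4f} "
                        f"(tolerance {tl_tolerance})"
                    )
            else:
                tl = L + S
            chroms.append(
                ChromosomeMeasurement(
                    long_arm_um=L,
                    short_arm_um=S,
                    total_length_um=tl,
                    chromosome_index=int(row.chromosome_index),
                )
            )
        if len(chroms) % 2 != 0:
            raise ValidationError(
                f"specimen {spec!r}: odd chromosome count {len(chroms)}"
            )
        metaphases.append(
            MetaphaseKaryotype(
                specimen_id=str(spec),
                colony_id=colony,
                population_id=str(pop),
                chromosomes=_sorted_chromosomes(chroms),
            )
        )
    if not metaphases:
        raise FormatError(f"{path}: no measurement rows found")
    ploidy = metaphases[0].ploidy_2n
    return MeasurementDataset(metaphases=tuple(metaphases), ploidy_2n=ploidy)


def write_measurements(dataset: MeasurementDataset, path: str | Path) -> None:
    """Write a dataset to CSV with deterministic row and column order."""
    path = Path(path)
    records = []
    for m in sorted(
        dataset.metaphases, key=lambda m: (m.population_id, m.specimen_id)
    ):
        for c in m.chromosomes:
            records.append(
                {
                    "population_id": m.population_id,
                    "colony_id": m.colony_id,
                    "specimen_id": m.specimen_id,
                    "chromosome_index": c.chromosome_index,
                    "long_arm_um": c.long_arm_um,
                    "short_arm_um": c.short_arm_um,
                    "total_length_um": c.total_length_um,
                }
            )
    df = pd.DataFrame.from_records(records, columns=MEASUREMENT_COLUMNS)
    df.to_csv(path, index=False)


def validate_dataset(
    dataset: MeasurementDataset,
    tl_tolerance: float = DEFAULT_TL_TOLERANCE_UM,
) -> list[str]:
    """Report every invariant violation; empty list iff the dataset is valid."""
    report: list[str] = []
    for m in dataset.metaphases:
        loc = f"population {m.population_id!r} specimen {m.specimen_id!r}"
        if m.ploidy_2n % 2 != 0:
            report.append(f"{loc}: odd chromosome count {m.ploidy_2n}")
        if m.ploidy_2n != dataset.ploidy_2n:
            report.append(
                f"{loc}: 2n={m.ploidy_2n} differs from dataset 2n={dataset.ploidy_2n}"
            )
        tls = m.total_lengths()
        for i, (a, b) in enumerate(zip(tls, tls[1:])):
            if b > a + 1e-12:
                report.append(
                    f"{loc}: TL not descending at rank {i + 1} ({a} < {b})"
                )
        for c in m.chromosomes:
            if abs(c.total_length_um - (c.long_arm_um + c.short_arm_um)) > tl_tolerance:
                report.append(
                    f"{loc} chromosome {c.chromosome_index}: TL "
                    f"{c.total_length_um} vs L+S "
                    f"{c.long_arm_um + c.short_arm_um:.4f} exceeds tolerance "
                    f"{tl_tolerance}"
                )
    return report


def _resolve_sep(path: Path, dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect != "auto":
        raise FormatError(f"unknown dialect {dialect!r}")
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header and "," not in header else ","
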