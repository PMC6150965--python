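"""Genome size estimation from flow-cytometry fluorescence histograms.

Nuclei of the study species are co-stained with nuclei of an internal
standard of known genome size (*Drosophila melanogaster*, 1C = 0.18 pg).
Fluorescence is proportional to DNA content, so the unknown genome size is
the ratio of peak positions times the standard's value:

    sample 1C (pg) = (sample peak mean / standard peak mean) × standard 1C

Picograms convert to megabase pairs with 1 pg = 978 Mbp.  Quality control
follows common practice: a histogram is rejected when any used peak has a
coefficient of variation above 5% or when fewer than 10,000 nuclei were
recorded, and population values are means over at least three accepted
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .morphometry import DomainError

PG_PER_MBP = 978.0
DROSOPHILA_1C_PG = 0.18
DEFAULT_CV_MAX = 0.05
DEFAULT_MIN_NUCLEI = 10_000


@dataclass(frozen=True)
class FluorescenceHistogram:
    """Binned fluorescence intensities: channel bin centers and event counts."""

    channel_values: np.ndarray
    counts: np.ndarray
    warning: str = ""

    def __post_init__(self) -> None:
        ch = np.asarray(self.channel_values, dtype=float)
        ct = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "channel_values", ch)
        object.__setattr__(self, "counts", ct)
        if ch.size == 0 or ch.size != ct.size:
            raise DomainError("channels and counts must be equal-length, non-empty")
        if np.any(np.diff(ch) <= 0):
            raise DomainError("channel values must be strictly increasing")
        if np.any(ct < 0):
            raise DomainError("counts must be non-negative")

    @property
    def total_events(self) -> int:
        return int(round(float(self.counts.sum())))


@dataclass(frozen=True)
class PeakEstimate:
    """Event-weighted location and spread of one histogram peak."""

    mean_channel: float
    sd_channel: float
    event_count: int

    @property
    def cv(self) -> float:
        return self.sd_channel / self.mean_channel


@dataclass(frozen=True)
class GenomeSizeEstimate:
    """1C/2C nuclear DNA content with replicate statistics."""

    c1_pg: float
    standard_1c_pg: float = DROSOPHILA_1C_PG
    replicate_mean_pg: float = float("nan")
    replicate_sd_pg: float = float("nan")
    n_replicates: int = 1
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.c1_pg <= 0:
            raise DomainError("1C value must be positive")

    @property
    def c2_pg(self) -> float:
        return 2.0 * self.c1_pg

    @property
    def mbp(self) -> float:
        return pg_to_mbp(self.c1_pg)


@dataclass(frozen=True)
class QcReport:
    passed: bool
    reasons: tuple[str, ...] = field(default=())


def read_histogram(path: str | Path) -> FluorescenceHistogram:
    """Read a two-column CSV (channel, count) into a histogram."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "channel" not in cols or "count" not in cols:
        raise DomainError(f"{path}: expected 'channel' and 'count' columns")
    return FluorescenceHistogram(
        channel_values=df[cols["channel"]].to_numpy(dtype=float),
        counts=df[cols["count"]].to_numpy(dtype=float),
    )


def write_histogram(hist: FluorescenceHistogram, path: str | Path) -> None:
    pd.DataFrame(
        {"channel": hist.channel_values, "count": hist.counts.astype(int)}
    ).to_csv(path, index=False)


def find_peaks(
    hist: FluorescenceHistogram,
    min_fraction: float = 0.05,
    window_halfwidth: float = 30.0,
) -> list[PeakEstimate]:
    """Locate and summarize histogram peaks.

    Local maxima of the count profile are kept when the events inside
    ``±window_halfwidth`` channels of the maximum amount to at least
    ``min_fraction`` of all events; each kept peak is summarized by the
    event-weighted mean and SD within that window.  Maxima falling inside
    an already-claimed window are suppressed (tallest first).  Peaks are
    returned in ascending order of mean channel.
    """
    ch, ct = hist.channel_values, hist.counts
    total = float(ct.sum())
    if total <= 0:
        return []
    # strict local maxima with a little prominence to ignore counting noise
    idx, _ = signal.find_peaks(ct, prominence=max(1.0, 0.01 * float(ct.max())))
    if idx.size == 0:
        return []
    claimed: list[tuple[float, float]] = []
    peaks: list[PeakEstimate] = []
    for i in sorted(idx, key=lambda i: -ct[i]):
        lo, hi = ch[i] - window_halfwidth, ch[i] + window_halfwidth
        if any(lo <= c <= hi for c, _ in claimed):
            continue
        mask = (ch >= lo) & (ch <= hi)
        w = ct[mask]
        events = float(w.sum())
        if events < min_fraction * total:
            continue
        x = ch[mask]
        mean = float(np.average(x, weights=w))
        var = float(np.average((x - mean) ** 2, weights=w))
        claimed.append((ch[i], events))
        peaks.append(
            PeakEstimate(
                mean_channel=mean,
                sd_channel=float(np.sqrt(var)),
                event_count=int(round(events)),
            )
        )
    return sorted(peaks, key=lambda p: p.mean_channel)


def estimate_1c(
    sample_peak: PeakEstimate,
    standard_peak: PeakEstimate,
    standard_1c_pg: float = DROSOPHILA_1C_PG,
) -> float:
    """Internal-standard ratio estimate of the sample 1C value (pg).

    Uses the linear fluorescence-ratio relation: the sample's DNA content is
    the ratio of sample to standard peak fluorescence times the standard's
    known 1C.  Identical for G0/G1 (2C) peaks since the factor 2 cancels.
    """
    if standard_peak.mean_channel <= 0 or sample_peak.mean_channel <= 0:
        raise DomainError("peak means must be positive")
    if standard_1c_pg <= 0:
        raise DomainError("standard 1C must be positive")
    return sample_peak.mean_channel / standard_peak.mean_channel * standard_1c_pg


def pg_to_mbp(pg: float) -> float:
    """Convert a DNA mass in picograms to megabase pairs (1 pg = 978 Mbp)."""
    if pg < 0:
        raise DomainError("mass must be non-negative")
    return pg * PG_PER_MBP


def mbp_to_pg(mbp: float) -> float:
    if mbp < 0:
        raise DomainError("length must be non-negative")
    return mbp / PG_PER_MBP


def qc_histogram(
    hist: FluorescenceHistogram,
    peaks: list[PeakEstimate],
    cv_max: float = DEFAULT_CV_MAX,
    min_nuclei: int = DEFAULT_MIN_NUCLEI,
) -> QcReport:
    """Histogram acceptance: peak CVs ≤ cv_max and enough recorded nuclei."""
    if not peaks:
        raise DomainError("qc requires at least one detected peak")
    reasons = []
    for i, p in enumerate(peaks):
        if p.cv > cv_max:
            reasons.append(f"cv: peak {i} CV {p.cv:.4f} > {cv_max}")
    if hist.total_events < min_nuclei:
        reasons.append(
            f"nuclei: {hist.total_events} events < required {min_nuclei}"
        )
    return QcReport(passed=not reasons, reasons=tuple(reasons))


def estimate_from_histogram(
    hist: FluorescenceHistogram,
    standard_1c_pg: float = DROSOPHILA_1C_PG,
    expected_standard_channel: float | None = None,
    cv_max: float = DEFAULT_CV_MAX,
    min_nuclei: int = DEFAULT_MIN_NUCLEI,
    min_fraction: float = 0.05,
    window_halfwidth: float = 30.0,
) -> GenomeSizeEstimate:
    """Full single-histogram pipeline: peaks → QC → ratio estimate.

    The standard peak is the qualifying peak closest to
    ``expected_standard_channel`` when given; otherwise the
    lower-fluorescence peak is taken as the standard (correct whenever the
    sample genome exceeds the standard's, as with an 0.18 pg standard and
    0.30-0.35 pg samples).
    """
    peaks = find_peaks(hist, min_fraction=min_fraction,
                       window_halfwidth=window_halfwidth)
    if len(peaks) < 2:
        raise DomainError(
            f"need a sample and a standard peak, found {len(peaks)}"
        )
    if expected_standard_channel is not None:
        std = min(peaks, key=lambda p: abs(p.mean_channel - expected_standard_channel))
    else:
        std = peaks[0]
    candidates = [p for p in peaks if p is not std]
    sample = max(candidates, key=lambda p: p.event_count)
    qc = qc_histogram(hist, [std, sample], cv_max=cv_max, min_nuclei=min_nuclei)
    c1 = estimate_1c(sample, std, standard_1c_pg)
    return GenomeSizeEstimate(
        c1_pg=c1, standard_1c_pg=standard_1c_pg, qc_pass=qc.passed
    )


def aggregate_replicates(
    estimates: list[GenomeSizeEstimate], min_replicates: int = 3
) -> GenomeSizeEstimate:
    """Population-level genome size: mean ± SD over QC-passing replicates."""
    passing = [e for e in estimates if e.qc_pass]
    if len(passing) < min_replicates:
        raise DomainError(
            f"only {len(passing)} QC-passing replicates, "
            f"need at least {min_replicates}"
        )
    vals = np.array([e.c1_pg for e in passing])
    standards = {e.standard_1c_pg for e in passing}
    if len(standards) != 1:
        raise DomainError("replicates used different internal standards")
    return GenomeSizeEstimate(
        c1_pg=float(vals.mean()),
        standard_1c_pg=passing[0].standard_1c_pg,
        replicate_mean_pg=float(vals.mean()),
        replicate_sd_pg=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        n_replicates=len(passing),
        qc_pass=True,
    )
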