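"""Idiogram construction and deterministic SVG rendering.

An idiogram is the schematic haploid karyotype: one bar per homologue pair,
scaled to relative length, with the centromere drawn at the position implied
by the mean arm ratio (centromere fraction = S/(L+S) = 1/(1+r), so 0.5 for a
perfect metacentric).  Rendering writes plain SVG text directly so that the
same idiogram always produces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .karyodata import PopulationSummary
from .morphometry import DomainError


@dataclass(frozen=True)
class IdiogramEntry:
    pair_rank: int
    relative_length_pct: float
    centromere_position_fraction: float
    morphology_label: str


@dataclass(frozen=True)
class Idiogram:
    """Haploid idiogram: per-pair relative lengths and centromere positions."""

    population_id: str
    per_chromosome: tuple[IdiogramEntry, ...]

    def __post_init__(self) -> None:
        total = sum(e.relative_length_pct for e in self.per_chromosome)
        if abs(total - 100.0) > 1e-9 * 100.0:
            raise DomainError(f"relative lengths sum to {total}, expected 100")
        for e in self.per_chromosome:
            if not 0.0 <= e.centromere_position_fraction <= 0.5:
                raise DomainError(
                    f"centromere fraction {e.centromere_position_fraction} "
                    "outside [0, 0.5]"
                )


def build_idiogram(summary: PopulationSummary) -> Idiogram:
    """Idiogram from a population summary (pair means over homologue rows).

    Consecutive ranked chromosomes form a homologue pair; each pair's bar
    gets the pair-mean TL relative to the haploid karyotype length
    (KL / 2), so the ten bars sum to 100%.  The centromere position comes
    from the pair-mean arm ratio via 1/(1+r).
    """
    rows = summary.per_chromosome
    if len(rows) % 2:
        raise DomainError("summary must contain whole homologue pairs")
    haploid_kl = summary.karyotype_length_um / 2.0
    entries = []
    for p in range(len(rows) // 2):
        a, b = rows[2 * p], rows[2 * p + 1]
        pair_mean_tl = (a[1] + b[1]) / 2.0
        pair_mean_r = (a[3] + b[3]) / 2.0
        entries.append(
            IdiogramEntry(
                pair_rank=p + 1,
                relative_length_pct=pair_mean_tl * 100.0 / haploid_kl,
                centromere_position_fraction=1.0 / (1.0 + pair_mean_r),
                morphology_label=a[4],
            )
        )
    return Idiogram(population_id=summary.population_id,
                    per_chromosome=tuple(entries))


# --- SVG rendering ---------------------------------------------------------

_BAR_W = 22.0
_GAP = 14.0
_PLOT_H = 220.0
_MARGIN = 28.0
_CLASS_FILL = {"M": "#4878a8", "SM": "#6aa84f", "ST": "#e69138", "A": "#cc4125"}


def render_idiogram(idiogram: Idiogram, path: str | Path,
                    style: dict | None = None) -> None:
    """Write the idiogram to ``path`` as deterministic SVG.

    Bars are scaled so the longest pair fills the plot height; the
    centromere is a horizontal notch at its fractional position measured
    from the chromosome's short-arm end (top).  With a fixed ``style`` the
    output is byte-identical across renders.
    """
    style = dict(style or {})
    bar_w = float(style.get("bar_width", _BAR_W))
    gap = float(style.get("gap", _GAP))
    plot_h = float(style.get("plot_height", _PLOT_H))
    margin = float(style.get("margin", _MARGIN))
    fills = {**_CLASS_FILL, **style.get("class_fill", {})}

    n = len(idiogram.per_chromosome)
    width = margin * 2 + n * bar_w + (n - 1) * gap
    height = margin * 2 + plot_h + 18.0
    rl_max = max(e.relative_length_pct for e in idiogram.per_chromosome)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.1f}" '
        f'height="{height:.1f}" viewBox="0 0 {width:.1f} {height:.1f}">',
        f'<title>Idiogram {idiogram.population_id}</title>',
        f'<text x="{margin:.1f}" y="{margin - 10.0:.1f}" font-family="sans-serif" '
        f'font-size="12">{idiogram.population_id}</text>',
    ]
    for i, e in enumerate(idiogram.per_chromosome):
        x = margin + i * (bar_w + gap)
        h = plot_h * e.relative_length_pct / rl_max
        y = margin + (plot_h - h)
        fill = fills.get(e.morphology_label, "#888888")
        parts.append(
            f'<rect x="{x:.2f}" y="{y:.2f}" width="{bar_w:.2f}" '
            f'height="{h:.2f}" rx="6" fill="{fill}" stroke="#222222"/>'
        )
        cy = y + h * e.centromere_position_fraction
        parts.append(
            f'<line x1="{x - 3.0:.2f}" y1="{cy:.2f}" x2="{x + bar_w + 3.0:.2f}" '
            f'y2="{cy:.2f}" stroke="#111111" stroke-width="2"/>'
        )
        parts.append(
            f'<text x="{x + bar_w / 2.0:.2f}" y="{margin + plot_h + 14.0:.1f}" '
            f'font-family="sans-serif" font-size="10" text-anchor="middle">'
            f"{e.pair_rank}</text>"
        )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts) + "\n")
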