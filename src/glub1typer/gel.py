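"""Agarose gel band-pattern model.

Two products co-migrate when their size difference is below
``max(resolution_fraction * mean_size, floor_bp)``.  The defaults are
calibrated so that every marker of the panel is resolvable at its published
gel percentage: the 15/18 bp coding-region indels (run at 3%) are *not*
resolvable at 1% for the ~500 bp products they produce, while every >=43 bp
promoter indel is visible even at 1%.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GelModel:
    percent: int = 1
    resolution_fraction: float = None  # type: ignore[assignment]
    floor_bp: int = None  # type: ignore[assignment]

    _DEFAULTS = {1: (0.05, 10), 3: (0.02, 5)}

    def __post_init__(self) -> None:
        if self.percent not in (1, 3):
            raise ValueError("gel percent must be 1 or 3")
        frac, floor = self._DEFAULTS[self.percent]
        if self.resolution_fraction is None:
            object.__setattr__(self, "resolution_fraction", frac)
        if self.floor_bp is None:
            object.__setattr__(self, "floor_bp", floor)

    def comigrate(self, a: float, b: float) -> bool:
        """True when sizes a and b merge into one band."""
        mean = (a + b) / 2.0
        return abs(a - b) < max(self.resolution_fraction * mean, self.floor_bp)


@dataclass(frozen=True)
class Band:
    size_bp: int
    intensity: str  # strong | weak


@dataclass(frozen=True)
class BandPattern:
    """Gel-resolved bands of one primer set, largest first."""

    ps_id: str
    bands: tuple[Band, ...]

    @property
    def calls(self) -> str:
        if not self.bands:
            return "absent"
        return "single" if len(self.bands) == 1 else "multiple"

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(b.size_bp for b in self.bands)

    @property
    def principal(self) -> Band | None:
        """The dominant band: the smallest (most efficiently amplified)."""
        return self.bands[-1] if self.bands else None


def resolve_bands(amplicons, gel: GelModel, ps_id: str = "") -> BandPattern:
    """Collapse one primer set's amplicons into gel bands.

    Co-migrating sizes merge (single linkage over the sorted sizes) into a
    band at the rounded mean size; a band is *strong* if any merged amplicon
    was a perfect primer match, otherwise *weak*.
    """
    if not amplicons:
        return BandPattern(ps_id=ps_id, bands=())
    items = sorted(((a.length_bp, a.total_mismatches == 0) for a in amplicons))
    clusters: list[list[tuple[int, bool]]] = [[items[0]]]
    for size, perfect in items[1:]:
        if gel.comigrate(clusters[-1][-1][0], size):
            clusters[-1].append((size, perfect))
        else:
            clusters.append([(size, perfect)])
    bands = [
        Band(
            size_bp=round(sum(s for s, _ in cl) / len(cl)),
            intensity="strong" if any(p for _, p in cl) else "weak",
        )
        for cl in clusters
    ]
    bands.sort(key=lambda b: -b.size_bp)
    return BandPattern(ps_id=ps_id, bands=tuple(bands))
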