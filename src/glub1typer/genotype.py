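"""Genotype decision engine for the Glu-B1 marker panel.

The published discrimination logic is stored as a data matrix (allele x
primer set -> expected marker outcome) and inference is consistency-set
based: an observed band pattern is compared against every allele's expected
row, and the call is the set of alleles consistent with *all* observed
markers.  This handles partial marker data gracefully and reports the two
documented ambiguity classes ({Bx14(+), Bx20} and {By15, By20}) naturally
instead of through a hard-coded decision tree.

Glu-1By8*, whose sequence is not in public databases, is called purely by
elimination: PS15 negative, PS16 positive and strong, PS17/PS23 negative,
no 45 bp deletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .gel import BandPattern, GelModel, resolve_bands
from .panel import _load_yaml, load_panel, registry_by_name
from .pcr import MatchPolicy, Template, run_panel

AMBIGUOUS_PAIRS = (
    frozenset({"Glu-1Bx14(+)", "Glu-1Bx20"}),
    frozenset({"Glu-1By15", "Glu-1By20"}),
)


@dataclass(frozen=True)
class MarkerOutcome:
    """Expected or observed state of one marker.

    state is 'positive', 'negative' or 'size_class'; size_class carries the
    class label for co-dominant markers ('520', 'del18', 'two_bands', ...).
    """

    ps_id: str
    state: str
    size_class: str | None = None
    intensity: str = "n/a"  # strong | weak | n/a

    def summary(self) -> str:
        base = self.size_class if self.state == "size_class" else self.state
        return f"{base}:weak" if self.intensity == "weak" else str(base)


@dataclass(frozen=True)
class MarkerDef:
    """How one decision marker is scored."""

    ps_id: str
    locus: str
    mode: str  # presence | size | count
    classes: dict | None
    positive_size: int | None
    intensity_matters: bool


@dataclass(frozen=True)
class EvidenceRow:
    ps_id: str
    observed: str
    expected: str
    consistent: bool | None  # None: marker not in the decision table


@dataclass(frozen=True)
class GenotypeCall:
    locus: str
    compatible_alleles: frozenset
    ambiguous: bool
    evidence: tuple[EvidenceRow, ...]
    conflicts: int

    @property
    def is_no_call(self) -> bool:
        return not self.compatible_alleles

    def summary(self) -> str:
        if self.is_no_call:
            return f"{self.locus}: no_call ({self.conflicts} conflicting markers)"
        names = "/".join(sorted(self.compatible_alleles))
        tag = " (ambiguous pair)" if self.ambiguous else ""
        return f"{self.locus}: {names}{tag}"


class DecisionTable:
    """allele x primer-set matrix of expected marker outcomes."""

    def __init__(self, markers: dict[str, MarkerDef], rows: dict[str, dict[str, MarkerOutcome]]):
        self.markers = markers
        self.rows = rows
        panel_ids = {ps.id for ps in load_panel()}
        registry = registry_by_name()
        for ps_id in markers:
            if ps_id not in panel_ids:
                raise ValueError(f"decision marker {ps_id} not in panel")
        for allele in rows:
            if allele not in registry:
                raise ValueError(f"decision row for unknown allele {allele}")

    def alleles(self, locus: str) -> list[str]:
        return sorted(a for a, row in self.rows.items()
                      if registry_by_name()[a].locus == locus)

    def locus_markers(self, locus: str) -> list[str]:
        return sorted((p for p, m in self.markers.items() if m.locus == locus),
                      key=lambda p: int(p[2:]))

    def equivalence_classes(self, locus: str) -> list[frozenset]:
        """Groups of alleles with identical expected rows (indistinguishable)."""
        groups: dict[tuple, set] = {}
        for allele in self.alleles(locus):
            key = tuple(sorted((p, o.summary()) for p, o in self.rows[allele].items()))
            groups.setdefault(key, set()).add(allele)
        return sorted((frozenset(g) for g in groups.values()), key=lambda s: sorted(s)[0])


def _parse_cell(ps_id: str, cell: str, marker: MarkerDef) -> MarkerOutcome:
    text = str(cell)
    intensity = "n/a"
    if text.endswith(":weak"):
        text, intensity = text[: -len(":weak")], "weak"
    if marker.mode == "presence":
        state = {"pos": "positive", "neg": "negative"}[text]
        if state == "positive" and marker.intensity_matters and intensity == "n/a":
            intensity = "strong"
        return MarkerOutcome(ps_id, state, None, intensity)
    if text not in marker.classes:
        raise ValueError(f"{ps_id}: unknown size class {text!r}")
    if marker.intensity_matters and intensity == "n/a":
        intensity = "strong"
    return MarkerOutcome(ps_id, "size_class", text, intensity)


@lru_cache(maxsize=None)
def decision_table() -> DecisionTable:
    raw = _load_yaml("decision.yaml")
    markers = {
        ps_id: MarkerDef(
            ps_id=ps_id,
            locus=spec["locus"],
            mode=spec["mode"],
            classes=spec.get("classes"),
            positive_size=spec.get("positive_size"),
            intensity_matters=bool(spec.get("intensity_matters", False)),
        )
        for ps_id, spec in raw["markers"].items()
    }
    rows = {}
    for allele, cells in raw["rows"].items():
        rows[allele] = {
            ps_id: _parse_cell(ps_id, cell, markers[ps_id]) for ps_id, cell in cells.items()
        }
    return DecisionTable(markers, rows)


def expected_pattern(allele_name: str) -> dict[str, MarkerOutcome]:
    """Expected outcome of every decision marker for one allele."""
    table = decision_table()
    if allele_name not in table.rows:
        known = ", ".join(sorted(table.rows))
        raise KeyError(f"no decision row for {allele_name!r}; known alleles: {known}")
    return dict(table.rows[allele_name])


# ---------------------------------------------------------------------------
# consistency of an observation with an expected outcome

def _classify_size(marker: MarkerDef, size: int) -> str | None:
    """Nearest size class, or None when the size is far from every class."""
    best, best_d = None, None
    for label, value in marker.classes.items():
        d = abs(size - value)
        if best_d is None or d < best_d:
            best, best_d = label, d
    value = marker.classes[best]
    if best_d > max(10, 0.1 * value):  # sanity bound: not near any known class
        return None
    return best


def observation_consistent(
    marker: MarkerDef, expected: MarkerOutcome, observed: BandPattern | MarkerOutcome
) -> bool:
    if isinstance(observed, MarkerOutcome):
        if expected.state != observed.state:
            return False
        if expected.state == "size_class" and expected.size_class != observed.size_class:
            return False
        if (
            marker.intensity_matters
            and "n/a" not in (expected.intensity, observed.intensity)
            and expected.intensity != observed.intensity
        ):
            return False
        return True

    pattern = observed
    if expected.state == "negative":
        return pattern.calls == "absent"
    if not pattern.bands:
        return False
    if marker.mode == "count":
        return len(pattern.bands) == len(marker.classes[expected.size_class])
    band = pattern.principal
    if marker.intensity_matters and expected.intensity != "n/a" and band.intensity != expected.intensity:
        return False
    if expected.state == "positive":
        return True
    return _classify_size(marker, band.size_bp) == expected.size_class


def _observed_summary(marker: MarkerDef | None, observed) -> str:
    if isinstance(observed, MarkerOutcome):
        return observed.summary()
    if not observed.bands:
        return "absent"
    return ",".join(f"{b.size_bp}bp:{b.intensity}" for b in observed.bands)


# ---------------------------------------------------------------------------
# inference

def call_genotype(observed: dict, locus: str) -> GenotypeCall:
    """Infer the compatible allele set at one locus from observed markers.

    ``observed`` maps ps_id to either a :class:`BandPattern` or a
    :class:`MarkerOutcome`.  Markers of the panel that carry no decision row
    (PS5, PS6, PS9, PS20, PS21) are recorded as uninformative evidence;
    unknown ps_ids are rejected.
    """
    if locus not in ("Bx", "By"):
        raise ValueError("locus must be 'Bx' or 'By'")
    if not observed:
        raise ValueError("at least one observed marker is required")
    table = decision_table()
    valid = {ps.id for ps in load_panel()}
    unknown = sorted(set(observed) - valid)
    if unknown:
        raise KeyError(
            f"unknown primer set id(s) {unknown}; valid ids: {sorted(valid, key=lambda p: int(p[2:]))}"
        )

    alleles = table.alleles(locus)
    informative = [p for p in observed if p in table.markers and table.markers[p].locus == locus]
    consistency = {
        a: {
            p: observation_consistent(table.markers[p], table.rows[a][p], observed[p])
            for p in informative
        }
        for a in alleles
    }
    compatible = frozenset(a for a in alleles if all(consistency[a].values()))
    conflicts = sum(1 for p in informative if not any(consistency[a][p] for a in alleles))

    evidence = []
    for p in sorted(observed, key=lambda q: int(q[2:])):
        if p not in informative:
            evidence.append(EvidenceRow(p, _observed_summary(None, observed[p]), "-", None))
            continue
        marker = table.markers[p]
        ref = compatible if compatible else alleles
        expected_str = "/".join(sorted({table.rows[a][p].summary() for a in ref}))
        ok = any(consistency[a][p] for a in (compatible or alleles))
        evidence.append(EvidenceRow(p, _observed_summary(marker, observed[p]), expected_str, ok))

    return GenotypeCall(
        locus=locus,
        compatible_alleles=compatible,
        ambiguous=compatible in AMBIGUOUS_PAIRS,
        evidence=tuple(evidence),
        conflicts=conflicts,
    )


def bands_from_panel_run(
    amplicons_by_ps: dict, gel_percent: int | None = None
) -> dict[str, BandPattern]:
    """Resolve a run_panel result on gels (each marker's published % by default)."""
    panel = {ps.id: ps for ps in load_panel()}
    out = {}
    for ps_id, amplicons in amplicons_by_ps.items():
        percent = gel_percent if gel_percent is not None else panel[ps_id].gel_percent
        out[ps_id] = resolve_bands(amplicons, GelModel(percent), ps_id=ps_id)
    return out


def type_cultivar(
    templates: list[Template],
    policy: MatchPolicy = MatchPolicy(),
    gel_percent: int | None = None,
) -> tuple[GenotypeCall, GenotypeCall]:
    """Full pipeline: virtual PCR -> gel resolution -> allele calls.

    Runs the whole panel over the supplied templates (typically a cultivar's
    Bx and By haplotypes), resolves each marker on its published gel
    percentage, and returns the (Bx, By) genotype calls with per-marker
    evidence.
    """
    products = run_panel(templates, load_panel(), policy)
    patterns = bands_from_panel_run(products, gel_percent)
    bx_obs = {p: b for p, b in patterns.items() if int(p[2:]) <= 14}
    by_obs = {p: b for p, b in patterns.items() if int(p[2:]) >= 15}
    return call_genotype(bx_obs, "Bx"), call_genotype(by_obs, "By")
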