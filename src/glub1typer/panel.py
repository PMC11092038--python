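"""Packaged primer-panel and allele-registry data model.

The 23 primer sets (14 targeting *Glu-1Bx*, 9 targeting *Glu-1By*) and the
allele registry ship as structured YAML resources inside the package, so
that corrections to published content are data patches rather than code
changes.  Everything downstream of this module (virtual PCR, the gel model,
the genotype decision engine, the fixture generator) treats the objects
returned here as the single source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import yaml

DNA_ALPHABET = set("ACGT")

MARKER_TYPES = {"SNP_dominant", "SNP_negative", "indel_codominant", "duplication_junction"}
DETECTION_REGIONS = {"promoter", "CDS", "junction"}


class PanelError(ValueError):
    """Raised when a packaged panel/registry resource fails validation."""


@dataclass(frozen=True)
class PrimerSet:
    """One entry of the marker panel (a forward/reverse primer pair)."""

    id: str
    gene_target: str
    detection_region: str
    marker_name: str
    marker_type: str
    indel_size_bp: int | None
    forward_name: str
    forward_seq: str
    reverse_name: str
    reverse_seq: str
    annealing_temp_by_polymerase: dict = field(hash=False)
    gel_percent: int = 1
    source: str = "paper-new"

    def __post_init__(self) -> None:
        for label, seq in (("forward_seq", self.forward_seq), ("reverse_seq", self.reverse_seq)):
            if not seq or set(seq) - DNA_ALPHABET:
                raise PanelError(f"{self.id}.{label}: not a non-empty A/C/G/T string: {seq!r}")
        if self.gel_percent not in (1, 3):
            raise PanelError(f"{self.id}.gel_percent: must be 1 or 3, got {self.gel_percent!r}")
        if self.marker_type not in MARKER_TYPES:
            raise PanelError(f"{self.id}.marker_type: unknown type {self.marker_type!r}")
        if self.detection_region not in DETECTION_REGIONS:
            raise PanelError(f"{self.id}.detection_region: unknown region {self.detection_region!r}")


@dataclass(frozen=True)
class AlleleRecord:
    """One Glu-1Bx / Glu-1By allele with its structural feature flags."""

    name: str
    locus: str
    accession: str
    promoter_features: frozenset
    cds_features: frozenset
    in_decision_table: bool
    notes: str = ""

    def __post_init__(self) -> None:
        if self.locus not in ("Bx", "By"):
            raise PanelError(f"{self.name}.locus: must be 'Bx' or 'By', got {self.locus!r}")
        if not self.accession:
            raise PanelError(f"{self.name}.accession: empty (use 'unavailable')")


def _load_yaml(name: str) -> dict:
    path = resources.files("glub1typer.data").joinpath(name)
    with path.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def load_panel() -> tuple[PrimerSet, ...]:
    """Load and validate the packaged 23-primer-set panel.

    Returns the primer sets in panel order (PS1..PS23).  Malformed packaged
    data raises :class:`PanelError` naming the offending field.
    """
    raw = _load_yaml("panel.yaml")
    sets = []
    for entry in raw["primer_sets"]:
        try:
            sets.append(PrimerSet(**entry))
        except TypeError as exc:  # unexpected/missing key
            raise PanelError(f"{entry.get('id', '?')}: {exc}") from exc
    ids = [ps.id for ps in sets]
    if len(set(ids)) != len(ids):
        raise PanelError("panel ids are not unique")
    if len(sets) != 23:
        raise PanelError(f"expected 23 primer sets, found {len(sets)}")
    bx = [ps for ps in sets if int(ps.id[2:]) <= 14]
    if len(bx) != 14:
        raise PanelError("expected PS1-PS14 to form the 14-entry Bx panel")
    return tuple(sets)


def panel_by_id() -> dict[str, PrimerSet]:
    return {ps.id: ps for ps in load_panel()}


@lru_cache(maxsize=None)
def allele_registry() -> tuple[AlleleRecord, ...]:
    """Load the allele registry (13 Bx + 8 By records).

    The registry is a superset of the decision table: it also carries the
    phylogeny-only alleles (Glu-1Bx14*, Glu-1Bx17*, Glu-1Bx23, Glu-1Bx23*,
    Glu-1By15*) for which no marker outcomes were published.
    """
    raw = _load_yaml("alleles.yaml")
    records = []
    for entry in raw["alleles"]:
        records.append(
            AlleleRecord(
                name=entry["name"],
                locus=entry["locus"],
                accession=entry["accession"],
                promoter_features=frozenset(entry["promoter_features"]),
                cds_features=frozenset(entry["cds_features"]),
                in_decision_table=bool(entry["in_decision_table"]),
                notes=entry.get("notes", ""),
            )
        )
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        raise PanelError("allele names are not unique")
    return tuple(records)


def registry_by_name() -> dict[str, AlleleRecord]:
    return {r.name: r for r in allele_registry()}


@lru_cache(maxsize=None)
def cultivar_table() -> tuple[dict, ...]:
    """The validation cultivars with their corrected Glu-B1 genotypes."""
    raw = _load_yaml("cultivars.yaml")
    return tuple(raw["cultivars"])


def panel_tsv() -> str:
    """Dump the panel as TSV (used by the ``glub1 panel`` subcommand)."""
    header = "id\tmarker_name\tforward\treverse\tregion\ttype\tgel_percent"
    rows = [
        "\t".join(
            [ps.id, ps.marker_name, ps.forward_seq, ps.reverse_seq,
             ps.detection_region, ps.marker_type, str(ps.gel_percent)]
        )
        for ps in load_panel()
    ]
    return "\n".join([header, *rows]) + "\n"
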