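"""Readers and writers: FASTA / GenBank templates, TSV and JSON reports."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

from Bio import SeqIO

from .genotype import GenotypeCall
from .pcr import Amplicon, Template

REPORT_SCHEMA_VERSION = 1


class TemplateFileError(ValueError):
    pass


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".gb", ".gbk", ".genbank"):
        return "genbank"
    return "fasta"


def read_templates(path, fmt: str | None = None) -> list[Template]:
    """Load templates from a (multi-record) FASTA or GenBank flat file.

    Sequences are upper-cased; U is mapped to T with a warning.  Empty
    files, duplicate record ids and illegal characters are distinct errors.
    """
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt not in ("fasta", "genbank"):
        raise TemplateFileError(f"unsupported format {fmt!r} (use fasta or genbank)")
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise TemplateFileError(f"{path}: no records found")
    seen: set[str] = set()
    templates = []
    for rec in records:
        if rec.id in seen:
            raise TemplateFileError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "U" in seq:
            warnings.warn(f"{rec.id}: RNA-style U bases mapped to T", stacklevel=2)
            seq = seq.replace("U", "T")
        origin = "accession" if fmt == "genbank" else "user_fasta"
        templates.append(Template(id=rec.id, sequence=seq, origin=origin))
    return templates


def extract_cds(path) -> dict[str, str]:
    """CDS sub-sequences (id -> spliced sequence) from a GenBank flat file."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        for k, feature in enumerate(f for f in rec.features if f.type == "CDS"):
            key = rec.id if k == 0 else f"{rec.id}.cds{k + 1}"
            out[key] = str(feature.extract(rec.seq)).upper()
    if not out:
        raise TemplateFileError(f"{path}: no CDS features found")
    return out


# ---------------------------------------------------------------------------
# amplicon TSV

AMPLICON_COLUMNS = ("template_id", "ps_id", "start", "end", "length_bp", "fwd_mm", "rev_mm")


def amplicons_to_tsv(results: dict[str, list[Amplicon]]) -> str:
    lines = ["\t".join(AMPLICON_COLUMNS)]
    for ps_id in sorted(results, key=lambda p: int(p[2:])):
        for a in results[ps_id]:
            lines.append(
                "\t".join(
                    str(v)
                    for v in (a.template_id, ps_id, a.start, a.end, a.length_bp,
                              a.fwd_mismatches, a.rev_mismatches)
                )
            )
    return "\n".join(lines) + "\n"


def amplicons_from_tsv(text: str) -> dict[str, list[Amplicon]]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != list(AMPLICON_COLUMNS):
        raise ValueError("not an amplicon TSV (bad header)")
    out: dict[str, list[Amplicon]] = {}
    for ln in lines[1:]:
        tid, ps_id, start, end, length, fmm, rmm = ln.split("\t")
        out.setdefault(ps_id, []).append(
            Amplicon(
                length_bp=int(length), template_id=tid, start=int(start),
                end=int(end), fwd_mismatches=int(fmm), rev_mismatches=int(rmm),
            )
        )
    return out


# ---------------------------------------------------------------------------
# genotype report

def call_to_dict(call: GenotypeCall) -> dict:
    return {
        "locus": call.locus,
        "compatible_alleles": sorted(call.compatible_alleles) or "no_call",
        "ambiguous": call.ambiguous,
        "conflicts": call.conflicts,
        "evidence": [
            {
                "ps_id": row.ps_id,
                "observed": row.observed,
                "expected": row.expected,
                "consistent": row.consistent,
            }
            for row in call.evidence
        ],
    }


def write_report(bx: GenotypeCall, by: GenotypeCall, cultivar: str = "") -> str:
    """Serialize a typing result as stable-field-order JSON."""
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "cultivar": cultivar,
        "bx": call_to_dict(bx),
        "by": call_to_dict(by),
    }
    return json.dumps(doc, indent=2, sort_keys=False) + "\n"
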