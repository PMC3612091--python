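"""Readers/writers for FASTA, occurrence/module/attribute tables, motif
definitions and annotation maps."""

from __future__ import annotations

import csv
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    ModuleAttributes,
    ModuleInstance,
    MotifModel,
    MotifOccurrence,
    UpstreamRegion,
)

log = logging.getLogger(__name__)

#: Motifs shipped with the tool.  RRPE is A/T-rich and has no single agreed
#: consensus, so it must be supplied by the user.
DEFAULT_MOTIFS: dict[str, MotifModel] = {
    "PAC": MotifModel("PAC", "GATGAG", 0),
    "PAC2": MotifModel("PAC2", "GATAAG", 0),
}

OCCURRENCE_COLUMNS = (
    "gene_id", "motif", "start", "end", "strand", "mismatches",
    "distance_to_atg",
)

MODULE_COLUMNS = (
    "gene_id", "order", "gap", "same_strand", "midpoint_distance",
    "first_motif", "first_start", "first_end", "first_strand",
    "first_mismatches", "first_distance_to_atg",
    "second_motif", "second_start", "second_end", "second_strand",
    "second_mismatches", "second_distance_to_atg",
)

ATTRIBUTE_COLUMNS = ("gene_set", "order") + ModuleAttributes.NUMERIC_FIELDS


# ---------------------------------------------------------------------------
# FASTA

def read_upstream_fasta(
    path: str | Path, expected_length: int | None = None
) -> list[UpstreamRegion]:
    """Read one upstream region per FASTA record.

    Records shorter than ``expected_length`` are kept with their actual
    length (a warning is logged).  Duplicate ids and empty files are errors.
    """
    regions: list[UpstreamRegion] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate gene_id {record.id!r} in {path}")
        seen.add(record.id)
        region = UpstreamRegion(record.id, str(record.seq))
        if expected_length is not None and region.length != expected_length:
            log.warning(
                "region %s has length %d (expected %d); keeping actual length",
                region.gene_id, region.length, expected_length,
            )
        regions.append(region)
    if not regions:
        raise ValueError(f"no FASTA records found in {path}")
    return regions


def write_upstream_fasta(
    regions: Iterable[UpstreamRegion], path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description="")
        for r in regions
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Occurrence tables

def write_occurrences(
    occurrences: Iterable[MotifOccurrence], path: str | Path
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(OCCURRENCE_COLUMNS)
        for occ in occurrences:
            writer.writerow([
                occ.gene_id, occ.motif, occ.start, occ.end, occ.strand,
                occ.mismatches,
                "" if occ.distance_to_atg is None else occ.distance_to_atg,
            ])


def read_occurrences(path: str | Path) -> list[MotifOccurrence]:
    """Read a TSV of motif occurrences (header required).

    The first six columns of :data:`OCCURRENCE_COLUMNS` are mandatory;
    ``distance_to_atg`` is optional.
    """
    occurrences: list[MotifOccurrence] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = set(OCCURRENCE_COLUMNS[:6])
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(
                f"{path}: missing occurrence columns {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                dist = row.get("distance_to_atg")
                occurrences.append(MotifOccurrence(
                    gene_id=row["gene_id"],
                    motif=row["motif"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    mismatches=int(row["mismatches"]),
                    distance_to_atg=(
                        int(dist) if dist not in (None, "") else None
                    ),
                ))
            except (ValueError, TypeError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}")
    return occurrences


# ---------------------------------------------------------------------------
# Module tables

def write_modules(
    modules: Iterable[ModuleInstance], path: str | Path
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(MODULE_COLUMNS)
        for mod in modules:
            row = [mod.gene_id, mod.order_label, mod.gap,
                   int(mod.same_strand), mod.module_midpoint_distance]
            for occ in (mod.first, mod.second):
                row += [occ.motif, occ.start, occ.end, occ.strand,
                        occ.mismatches,
                        "" if occ.distance_to_atg is None
                        else occ.distance_to_atg]
            writer.writerow(row)


def read_modules(path: str | Path) -> list[ModuleInstance]:
    modules: list[ModuleInstance] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(MODULE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing module columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                occs = []
                for prefix in ("first", "second"):
                    dist = row[f"{prefix}_distance_to_atg"]
                    occs.append(MotifOccurrence(
                        gene_id=row["gene_id"],
                        motif=row[f"{prefix}_motif"],
                        start=int(row[f"{prefix}_start"]),
                        end=int(row[f"{prefix}_end"]),
                        strand=row[f"{prefix}_strand"],
                        mismatches=int(row[f"{prefix}_mismatches"]),
                        distance_to_atg=int(dist) if dist != "" else None,
                    ))
                modules.append(ModuleInstance(
                    gene_id=row["gene_id"],
                    first=occs[0],
                    second=occs[1],
                    order_label=row["order"],
                    gap=int(row["gap"]),
                    same_strand=bool(int(row["same_strand"])),
                    module_midpoint_distance=int(row["midpoint_distance"]),
                ))
            except (ValueError, TypeError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}")
    return modules


# ---------------------------------------------------------------------------
# Attribute tables

def write_attributes(
    attributes: Iterable[ModuleAttributes], path: str | Path
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(ATTRIBUTE_COLUMNS)
        for attrs in attributes:
            record = asdict(attrs)
            writer.writerow([record[col] for col in ATTRIBUTE_COLUMNS])


def read_attributes(path: str | Path) -> list[ModuleAttributes]:
    out: list[ModuleAttributes] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(ATTRIBUTE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(
                f"{path}: missing attribute columns {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                kwargs = {
                    col: float(row[col])
                    for col in ModuleAttributes.NUMERIC_FIELDS
                }
                kwargs["n_occurrences"] = int(row["n_occurrences"])
                out.append(ModuleAttributes(
                    order=row["order"], gene_set=row["gene_set"], **kwargs
                ))
            except (ValueError, TypeError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}")
    return out


# ---------------------------------------------------------------------------
# Motif definitions / annotations / gene lists

def load_motif_definitions(
    source: str | Path | Mapping | None = None,
) -> dict[str, MotifModel]:
    """Load motif models from a YAML file or an inline mapping.

    Entries are either ``name: CONSENSUS`` or
    ``name: {consensus: ..., max_mismatches: ...}``.  With no source, a copy
    of :data:`DEFAULT_MOTIFS` is returned.
    """
    if source is None:
        return dict(DEFAULT_MOTIFS)
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            mapping = yaml.safe_load(handle)
        if not isinstance(mapping, Mapping):
            raise ValueError(f"{source}: expected a mapping of motif names")
    else:
        mapping = source
    motifs: dict[str, MotifModel] = {}
    for name, value in mapping.items():
        if isinstance(value, str):
            motifs[name] = MotifModel(name, value)
        elif isinstance(value, Mapping):
            motifs[name] = MotifModel(
                name,
                value["consensus"],
                int(value.get("max_mismatches", 0)),
            )
        else:
            raise ValueError(f"motif {name!r}: unsupported definition {value!r}")
    return motifs


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column ``gene_id <tab> term`` table (header optional)."""
    annotations: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            gene_id, term = parts
            if lineno == 1 and (gene_id, term) == ("gene_id", "term"):
                continue
            if not term:
                raise ValueError(f"{path}:{lineno}: empty term")
            annotations.setdefault(gene_id, set()).add(term)
    return annotations


def read_gene_list(path: str | Path) -> list[str]:
    genes: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for gene in genes:
            handle.write(gene + "\n")
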