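"""Readers and writers for the pipeline's external formats.

Peptide identification tables are delimited text (PEAKS-style exports) with a
configurable column map; proteomes are FASTA; fragment spectra are MGF;
sample metadata is YAML. Standard formats go through the standard libraries
(Bio.SeqIO for FASTA, pyteomics for MGF); only the peptide-table dialect
handling is ours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from Bio import SeqIO
from pyteomics import mgf as _mgf

from .model import (
    CohortDataset,
    FormatError,
    Modification,
    PeptideRecord,
    ProteomeDB,
    SampleImmunopeptidome,
    Spectrum,
)


@dataclass
class TableDialect:
    """Column map for a delimited peptide table.

    Only ``sequence`` is mandatory in the file. ``modifications`` cells use
    the form ``pos:name:delta;pos:name:delta``; ``binders`` cells use
    ``allotype=strength;allotype=strength``.
    """

    sequence: str = "sequence"
    proteins: str = "proteins"
    area: str = "area"
    modifications: str = "modifications"
    binders: str = "binders"
    quality: str = "quality"
    protein_sep: str = ";"
    sep: str = ","


DEFAULT_DIALECT = TableDialect()


def _parse_modifications(cell: str, row_index: int) -> tuple[Modification, ...]:
    mods = []
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            pos, name, delta = token.split(":")
            mods.append(Modification(int(pos), name, float(delta)))
        except (ValueError, TypeError) as exc:
            raise FormatError(
                f"row {row_index}: malformed modification {token!r}"
            ) from exc
    return tuple(mods)


def _parse_binders(cell: str, row_index: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            allotype, strength = token.split("=")
        except ValueError as exc:
            raise FormatError(f"row {row_index}: malformed binder {token!r}") from exc
        out[allotype.strip()] = strength.strip()
    return out


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or value == ""


def read_peptide_table(
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
    on_bad_row: Optional[list] = None,
) -> list[PeptideRecord]:
    """Read one peptide table into records.

    Rows with an empty sequence are rejected; their indices are appended to
    ``on_bad_row`` when given, otherwise counted silently. Unknown columns
    are preserved in ``record.extras``.
    """
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    if dialect.sequence not in df.columns:
        raise FormatError(
            f"{path}: missing mandatory column {dialect.sequence!r}"
        )
    known = {
        dialect.sequence,
        dialect.proteins,
        dialect.area,
        dialect.modifications,
        dialect.binders,
        dialect.quality,
    }
    extra_cols = [c for c in df.columns if c not in known]
    records: list[PeptideRecord] = []
    for idx, row in df.iterrows():
        seq = row[dialect.sequence]
        if _is_missing(seq) or not str(seq).strip():
            if on_bad_row is not None:
                on_bad_row.append(int(idx))
            continue
        proteins: tuple[str, ...] = ()
        if dialect.proteins in df.columns and not _is_missing(row.get(dialect.proteins)):
            proteins = tuple(
                p.strip()
                for p in str(row[dialect.proteins]).split(dialect.protein_sep)
                if p.strip()
            )
        area = None
        if dialect.area in df.columns and not _is_missing(row.get(dialect.area)):
            area = float(row[dialect.area])
        mods: tuple[Modification, ...] = ()
        if dialect.modifications in df.columns and not _is_missing(
            row.get(dialect.modifications)
        ):
            mods = _parse_modifications(row[dialect.modifications], int(idx))
        binders = None
        if dialect.binders in df.columns and not _is_missing(row.get(dialect.binders)):
            binders = _parse_binders(row[dialect.binders], int(idx))
        quality = None
        if dialect.quality in df.columns and not _is_missing(row.get(dialect.quality)):
            quality = float(row[dialect.quality])
        extras = {
            c: row[c] for c in extra_cols if not _is_missing(row.get(c))
        }
        records.append(
            PeptideRecord(
                sequence=str(seq).strip(),
                modifications=mods,
                source_proteins=proteins,
                reported_area=area,
                binder_annotations=binders,
                quality_score=quality,
                extras=extras,
            )
        )
    return records


def write_peptide_table(
    records: Iterable[PeptideRecord],
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                dialect.sequence: rec.sequence,
                dialect.proteins: dialect.protein_sep.join(rec.source_proteins),
                dialect.area: "" if rec.reported_area is None else repr(rec.reported_area),
                dialect.modifications: ";".join(
                    f"{m.position}:{m.name}:{m.delta_mass!r}" for m in rec.modifications
                ),
                dialect.binders: ""
                if rec.binder_annotations is None
                else ";".join(f"{a}={s}" for a, s in sorted(rec.binder_annotations.items())),
                dialect.quality: "" if rec.quality_score is None else repr(rec.quality_score),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=dialect.sep, index=False)


def read_fasta(path: str | Path) -> ProteomeDB:
    """FASTA -> ProteomeDB; accession = first whitespace token after '>'."""
    db = ProteomeDB()
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n += 1
        accession = record.id
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {accession!r}")
        if "-" in seq or "*" in seq:
            raise FormatError(f"{path}: gap/stop characters in {accession!r}")
        if accession in db:
            raise FormatError(f"{path}: duplicate accession {accession!r}")
        db[accession] = seq
    if n == 0:
        raise FormatError(f"{path}: no FASTA records found")
    return db


def write_fasta(db: ProteomeDB, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for accession in db:
            fh.write(f">{accession}\n")
            seq = db[accession]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file; every block must carry PEPMASS."""
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise FormatError(f"{path}: block {i} lacks PEPMASS")
            pepmass = float(params["pepmass"][0])
            charge = int(params["charge"][0]) if "charge" in params else 1
            peaks = list(
                zip((float(m) for m in entry["m/z array"]),
                    (float(x) for x in entry["intensity array"]))
            )
            spectra.append(
                Spectrum(
                    precursor_mz=pepmass,
                    precursor_charge=charge,
                    peaks=peaks,
                    title=str(params.get("title", f"spectrum_{i}")),
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": [m for m, _ in s.peaks],
                "intensity array": [x for _, x in s.peaks],
                "params": {
                    "title": s.title,
                    "pepmass": s.precursor_mz,
                    "charge": f"{s.precursor_charge}+",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Sample metadata (YAML)
# ---------------------------------------------------------------------------

def load_cohort(path: str | Path, dialect: TableDialect = DEFAULT_DIALECT) -> CohortDataset:
    """Load a cohort from a YAML manifest.

    Layout::

        name: tumor
        il_collapsed: false
        samples:
          - sample_id: S1
            donor_id: D1
            tissue_label: PBMC
            cohort_label: tumor
            hla_class: I
            hla_typing: ["A*02", "B*07"]
            replicates:
              R1: peptides/S1_R1.csv   # relative to the manifest

    Replicate values are paths to peptide tables.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    samples = []
    for entry in doc["samples"]:
        replicates = {}
        for rep_id, rel in entry["replicates"].items():
            replicates[str(rep_id)] = read_peptide_table(path.parent / rel, dialect)
        samples.append(
            SampleImmunopeptidome(
                sample_id=str(entry["sample_id"]),
                donor_id=str(entry["donor_id"]),
                tissue_label=str(entry["tissue_label"]),
                cohort_label=str(entry["cohort_label"]),
                hla_class=str(entry["hla_class"]),
                hla_typing=tuple(entry["hla_typing"]),
                replicates=replicates,
            )
        )
    return CohortDataset(
        name=str(doc["name"]),
        samples=samples,
        il_collapsed=bool(doc.get("il_collapsed", False)),
    )


def dump_cohort(cohort: CohortDataset, out_dir: str | Path,
                dialect: TableDialect = DEFAULT_DIALECT) -> Path:
    """Write a cohort as a manifest + per-replicate peptide tables; returns
    the manifest path."""
    out_dir = Path(out_dir)
    pep_dir = out_dir / "peptides"
    pep_dir.mkdir(parents=True, exist_ok=True)
    doc = {"name": cohort.name, "il_collapsed": cohort.il_collapsed, "samples": []}
    for sample in cohort.samples:
        entry = {
            "sample_id": sample.sample_id,
            "donor_id": sample.donor_id,
            "tissue_label": sample.tissue_label,
            "cohort_label": sample.cohort_label,
            "hla_class": sample.hla_class,
            "hla_typing": list(sample.hla_typing),
            "replicates": {},
        }
        for rep_id in sorted(sample.replicates):
            rel = f"peptides/{sample.sample_id}_{rep_id}.csv"
            write_peptide_table(sample.replicates[rep_id], out_dir / rel, dialect)
            entry["replicates"][rep_id] = rel
        doc["samples"].append(entry)
    manifest = out_dir / f"{cohort.name}.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return manifest
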