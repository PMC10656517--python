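"""Core domain types shared by every stage of the pipeline.

The unit of identity throughout the package is the modification-stripped,
uppercase peptide sequence (optionally with isoleucine collapsed onto
leucine, since mass spectrometry cannot distinguish the two isomers).
Modifications and quantitative metadata are carried on :class:`PeptideRecord`
but never enter set comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

BINDER_STRENGTHS = ("strong", "medium", "weak", "none")
COHORT_LABELS = ("benign", "tumor", "cell_line")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def validate_sequence(sequence: str) -> str:
    """Return the sequence uppercased, or raise on non-standard residues."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    seq = sequence.upper()
    bad = set(seq) - _AA_SET
    if bad:
        raise ValueError(
            f"unknown residue(s) {sorted(bad)} in sequence {sequence!r}"
        )
    return seq


@dataclass(frozen=True)
class Modification:
    """A localized mass modification, e.g. methionine oxidation (+15.994915 Da)."""

    position: int  # 1-based residue index
    name: str
    delta_mass: float


@dataclass
class PeptideRecord:
    """One identified peptide in one sample.

    ``binder_annotations`` maps HLA allotype -> strength in
    {"strong", "medium", "weak", "none"}; ``quality_score`` carries the search
    engine's confidence (e.g. -10lgP) when present. Unknown input columns are
    preserved verbatim in ``extras``.
    """

    sequence: str
    modifications: tuple[Modification, ...] = ()
    source_proteins: tuple[str, ...] = ()
    reported_area: Optional[float] = None
    binder_annotations: Optional[Mapping[str, str]] = None
    quality_score: Optional[float] = None
    extras: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence)
        n = len(self.sequence)
        for mod in self.modifications:
            if not 1 <= mod.position <= n:
                raise ValueError(
                    f"modification position {mod.position} outside sequence "
                    f"{self.sequence!r} (length {n})"
                )
        if self.reported_area is not None and self.reported_area < 0:
            raise ValueError("reported_area must be nonnegative")
        if self.binder_annotations is not None:
            for allotype, strength in self.binder_annotations.items():
                if strength not in BINDER_STRENGTHS:
                    raise ValueError(
                        f"binder strength {strength!r} for {allotype!r} not in "
                        f"{BINDER_STRENGTHS}"
                    )

    def is_annotated_ligand(self) -> bool:
        """True if any allotype annotation is stronger than 'none'."""
        if not self.binder_annotations:
            return False
        return any(s != "none" for s in self.binder_annotations.values())


def canonical_sequence(record: "PeptideRecord | str", il_collapse: bool = False) -> str:
    """Identity string used for ALL set comparisons across the package.

    Modifications are stripped (identity is sequence-level); with
    ``il_collapse`` every I becomes L, reflecting that fragment spectra cannot
    separate the leucine/isoleucine isomers. Idempotent by construction.
    """
    seq = record.sequence if isinstance(record, PeptideRecord) else validate_sequence(record)
    return seq.replace("I", "L") if il_collapse else seq


@dataclass
class SampleImmunopeptidome:
    """A sample's replicate-resolved peptide sets plus metadata."""

    sample_id: str
    donor_id: str
    tissue_label: str
    cohort_label: str
    hla_class: str  # "I" or "II"
    hla_typing: tuple[str, ...]
    replicates: dict[str, list[PeptideRecord]]

    def __post_init__(self) -> None:
        if self.cohort_label not in COHORT_LABELS:
            raise ValueError(f"cohort_label must be one of {COHORT_LABELS}")
        if self.hla_class not in ("I", "II"):
            raise ValueError("hla_class must be 'I' or 'II'")
        if not self.replicates:
            raise ValueError(f"sample {self.sample_id}: at least one replicate required")
        if any(not a for a in self.hla_typing):
            raise ValueError("allotype strings must be non-empty")

    def union_records(self) -> list[PeptideRecord]:
        """All records across replicates, one per canonical identity (first wins)."""
        seen: dict[str, PeptideRecord] = {}
        for rep_id in sorted(self.replicates):
            for rec in self.replicates[rep_id]:
                seen.setdefault(canonical_sequence(rec), rec)
        return list(seen.values())

    def union_identities(self, il_collapse: bool = False) -> set[str]:
        """Union peptide identity set over replicates (a sample is 'positive'
        for a peptide if ANY replicate contains it)."""
        return {
            canonical_sequence(rec, il_collapse)
            for recs in self.replicates.values()
            for rec in recs
        }

    def replicate_identity_sets(self, il_collapse: bool = False) -> dict[str, set[str]]:
        return {
            rep_id: {canonical_sequence(r, il_collapse) for r in recs}
            for rep_id, recs in self.replicates.items()
        }


@dataclass
class CohortDataset:
    """A named collection of samples compared as one cohort."""

    name: str
    samples: list[SampleImmunopeptidome]
    il_collapsed: bool = False

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_ids in cohort {self.name!r}: {dupes}")

    def peptide_union(self) -> set[str]:
        out: set[str] = set()
        for s in self.samples:
            out |= s.union_identities(self.il_collapsed)
        return out


class ProteomeDB(dict):
    """Accession -> uppercase amino-acid sequence."""

    def __setitem__(self, accession: str, sequence: str) -> None:
        if not sequence:
            raise ValueError(f"empty sequence for accession {accession!r}")
        super().__setitem__(accession, sequence.upper())


@dataclass
class Spectrum:
    """A fragment spectrum: precursor plus an mz-sorted peak list."""

    precursor_mz: float
    precursor_charge: int
    peaks: list[tuple[float, float]]  # (mz Da, intensity)
    title: str = ""

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError("precursor_charge must be >= 1")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative peak intensity")
        self.peaks = sorted(self.peaks)

    @property
    def mz(self) -> "list[float]":
        return [m for m, _ in self.peaks]

    @property
    def intensity(self) -> "list[float]":
        return [i for _, i in self.peaks]
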