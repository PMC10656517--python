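"""Comparative immunopeptidome profiling.

Assembles filtered benign reference peptide sets, subtracts them from tumor
cohorts to obtain tumor-exclusive peptides, and computes presentation
frequencies — cohort-wide and restricted to HLA-allotype-matched samples —
plus replicate- and donor-level overlap statistics and rejection reports for
previously published tumor-associated antigens (TAAs).

All comparisons operate on canonical sequence identities (see
``model.canonical_sequence``); a sample is "positive" for a peptide when any
technical replicate contains it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import (
    CohortDataset,
    PeptideRecord,
    SampleImmunopeptidome,
    canonical_sequence,
)


# ---------------------------------------------------------------------------
# Benign reference assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterRule:
    """Per-dataset inclusion rules for benign-reference assembly.

    ``binder_whitelist``: keep only peptides annotated at one of these
    strengths for some allotype (None = keep all). ``column_equals``: exact
    matches required on ``extras`` metadata columns (e.g. disease=healthy).
    """

    binder_whitelist: Optional[frozenset[str]] = None
    column_equals: Mapping[str, str] = field(default_factory=dict)

    def admits(self, record: PeptideRecord) -> bool:
        if self.binder_whitelist is not None:
            anns = record.binder_annotations or {}
            if not any(s in self.binder_whitelist for s in anns.values()):
                return False
        for column, expected in self.column_equals.items():
            if column not in record.extras:
                raise KeyError(f"filter references missing column {column!r}")
            if str(record.extras[column]) != expected:
                return False
        return True


@dataclass
class BenignReference:
    """A named union of benign peptide identities with per-peptide provenance."""

    name: str
    identities: set[str]
    provenance: dict[str, set[str]]  # identity -> source dataset names
    il_collapsed: bool = False

    def __contains__(self, identity: str) -> bool:
        return identity in self.identities


def build_benign_reference(
    datasets: Mapping[str, Sequence[PeptideRecord]],
    filter_rules: Mapping[str, FilterRule],
    name: str = "benign_reference",
    il_collapse: bool = False,
) -> BenignReference:
    """Union of canonicalized identities passing each dataset's rules."""
    identities: set[str] = set()
    provenance: dict[str, set[str]] = {}
    for ds_name, records in datasets.items():
        rule = filter_rules.get(ds_name, FilterRule())
        kept = [r for r in records if rule.admits(r)]
        if not kept:
            warnings.warn(f"dataset {ds_name!r}: no peptides pass its filter")
        for rec in kept:
            ident = canonical_sequence(rec, il_collapse)
            identities.add(ident)
            provenance.setdefault(ident, set()).add(ds_name)
    return BenignReference(
        name=name, identities=identities, provenance=provenance, il_collapsed=il_collapse
    )


def reference_from_cohort(cohort: CohortDataset, name: Optional[str] = None) -> BenignReference:
    """Treat a measured benign cohort as a reference; provenance = sample ids."""
    identities: set[str] = set()
    provenance: dict[str, set[str]] = {}
    for sample in cohort.samples:
        for ident in sample.union_identities(cohort.il_collapsed):
            identities.add(ident)
            provenance.setdefault(ident, set()).add(sample.sample_id)
    return BenignReference(
        name=name or cohort.name,
        identities=identities,
        provenance=provenance,
        il_collapsed=cohort.il_collapsed,
    )


# ---------------------------------------------------------------------------
# Tumor exclusivity and presentation frequencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyRecord:
    peptide: str
    n_positive: int
    n_total: int
    frequency: float
    allotype_frequencies: Mapping[str, tuple[int, int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.frequency <= 1:
            raise ValueError("frequency outside [0,1]")


@dataclass
class ProfilingResult:
    exclusive: set[str]
    rejected: dict[str, set[str]]  # identity -> benign source tags
    frequencies: list[FrequencyRecord]
    display_min_frequency: float


def tumor_exclusive(
    tumor_cohort: CohortDataset,
    benign_reference: BenignReference,
    min_display_frequency: float = 0.05,
) -> ProfilingResult:
    """Split the tumor cohort's peptide union into benign-rejected and
    tumor-exclusive peptides and attach cohort-wide presentation frequencies
    for the exclusive set."""
    if tumor_cohort.il_collapsed != benign_reference.il_collapsed:
        raise ValueError(
            "inconsistent I/L collapsing between cohort "
            f"({tumor_cohort.il_collapsed}) and reference ({benign_reference.il_collapsed})"
        )
    union = tumor_cohort.peptide_union()
    rejected = {
        ident: set(benign_reference.provenance.get(ident, set()))
        for ident in union & benign_reference.identities
    }
    exclusive = union - benign_reference.identities
    freqs = presentation_frequencies(sorted(exclusive), tumor_cohort)
    return ProfilingResult(
        exclusive=exclusive,
        rejected=rejected,
        frequencies=freqs,
        display_min_frequency=min_display_frequency,
    )


def presentation_frequencies(
    peptides: Iterable[str], cohort: CohortDataset
) -> list[FrequencyRecord]:
    """f = (samples whose union set contains the peptide) / cohort size,
    ordered by (f desc, identity asc)."""
    if not cohort.samples:
        raise ValueError("cohort has no samples")
    sample_sets = [s.union_identities(cohort.il_collapsed) for s in cohort.samples]
    n_total = len(sample_sets)
    records = []
    for pep in peptides:
        n_pos = sum(pep in ss for ss in sample_sets)
        records.append(
            FrequencyRecord(
                peptide=pep,
                n_positive=n_pos,
                n_total=n_total,
                frequency=n_pos / n_total,
            )
        )
    records.sort(key=lambda r: (-r.frequency, r.peptide))
    return records


def allotype_frequencies(
    peptides: Iterable[str],
    cohort: CohortDataset,
    allotype_assignment: Mapping[str, Sequence[str]],
) -> tuple[list[FrequencyRecord], int]:
    """Presentation frequencies restricted to allotype-matched samples.

    For each peptide and each of its assigned allotypes, the denominator is
    the number of cohort samples carrying that allotype and the numerator the
    positives among them. Returns (records, n_excluded) where excluded
    peptides had no allotype assignment. An allotype carried by no sample is
    flagged with a (0, 0, nan) entry.
    """
    sample_sets = {
        s.sample_id: s.union_identities(cohort.il_collapsed) for s in cohort.samples
    }
    carriers: dict[str, list[str]] = {}
    for s in cohort.samples:
        for allotype in s.hla_typing:
            carriers.setdefault(allotype, []).append(s.sample_id)
    n_total = len(cohort.samples)
    records: list[FrequencyRecord] = []
    n_excluded = 0
    for pep in peptides:
        allotypes = allotype_assignment.get(pep, ())
        if not allotypes:
            n_excluded += 1
            continue
        n_pos = sum(pep in ss for ss in sample_sets.values())
        per_allotype: dict[str, tuple[int, int, float]] = {}
        for allotype in allotypes:
            matched = carriers.get(allotype, [])
            if not matched:
                per_allotype[allotype] = (0, 0, float("nan"))
                continue
            pos = sum(pep in sample_sets[sid] for sid in matched)
            per_allotype[allotype] = (pos, len(matched), pos / len(matched))
        records.append(
            FrequencyRecord(
                peptide=pep,
                n_positive=n_pos,
                n_total=n_total,
                frequency=n_pos / n_total,
                allotype_frequencies=per_allotype,
            )
        )
    records.sort(key=lambda r: (-r.frequency, r.peptide))
    return records, n_excluded


def frequency_display_filter(
    records: Sequence[FrequencyRecord], min_f: float = 0.05
) -> list[FrequencyRecord]:
    """Keep records with f >= min_f (peptides below the cutoff are not
    depicted; the boundary value itself is retained)."""
    return sorted(
        (r for r in records if r.frequency >= min_f),
        key=lambda r: (-r.frequency, r.peptide),
    )


# ---------------------------------------------------------------------------
# Replicate and donor-tissue overlap
# ---------------------------------------------------------------------------

def replicate_overlap(sample: SampleImmunopeptidome) -> dict[int, float]:
    """Over the sample's union set, the fraction of peptides seen in exactly
    k of the R replicates, for k = 1..R; fractions sum to 1."""
    rep_sets = list(sample.replicate_identity_sets().values())
    union = set().union(*rep_sets)
    if not union:
        raise ValueError(f"sample {sample.sample_id}: empty union peptide set")
    r = len(rep_sets)
    counts = {k: 0 for k in range(1, r + 1)}
    for pep in union:
        counts[sum(pep in rs for rs in rep_sets)] += 1
    return {k: counts[k] / len(union) for k in counts}


@dataclass(frozen=True)
class DonorOverlap:
    donor_id: str
    n_samples: int
    fraction_single_tissue: float
    fraction_all_tissues: float
    pairwise: "pd.DataFrame"  # tissue x tissue shared-peptide counts


def donor_tissue_overlap(cohort: CohortDataset) -> dict[str, DonorOverlap]:
    """Per multi-sample donor: fraction of the donor's peptide union found in
    exactly one tissue and in all tissues, plus the pairwise shared-peptide
    matrix (chord-plot input). Single-sample donors are skipped with a note."""
    by_donor: dict[str, list[SampleImmunopeptidome]] = {}
    for s in cohort.samples:
        by_donor.setdefault(s.donor_id, []).append(s)
    out: dict[str, DonorOverlap] = {}
    for donor, samples in sorted(by_donor.items()):
        if len(samples) < 2:
            warnings.warn(f"donor {donor}: single sample, skipped from overlap")
            continue
        sets = {s.sample_id: s.union_identities(cohort.il_collapsed) for s in samples}
        union = set().union(*sets.values())
        n_in = {pep: sum(pep in ss for ss in sets.values()) for pep in union}
        n_samples = len(samples)
        ids = sorted(sets)
        pairwise = pd.DataFrame(
            [[len(sets[a] & sets[b]) for b in ids] for a in ids],
            index=ids,
            columns=ids,
        )
        out[donor] = DonorOverlap(
            donor_id=donor,
            n_samples=n_samples,
            fraction_single_tissue=sum(1 for v in n_in.values() if v == 1) / len(union),
            fraction_all_tissues=sum(1 for v in n_in.values() if v == n_samples) / len(union),
            pairwise=pairwise,
        )
    return out


# ---------------------------------------------------------------------------
# TAA rejection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TAARejectionReport:
    table: "pd.DataFrame"  # peptide, rejected, benign_sources
    percent_rejected: float


def taa_rejection_report(
    published_taas: Sequence[PeptideRecord | str],
    benign_reference: BenignReference,
) -> TAARejectionReport:
    """Check previously published tumor-associated antigens against a benign
    reference; a TAA found in the reference is no longer tumor-exclusive."""
    rows = []
    n_rejected = 0
    for item in published_taas:
        ident = canonical_sequence(item, benign_reference.il_collapsed)
        rejected = ident in benign_reference
        n_rejected += rejected
        rows.append(
            {
                "peptide": ident,
                "rejected": rejected,
                "benign_sources": ";".join(sorted(benign_reference.provenance.get(ident, ()))),
            }
        )
    table = pd.DataFrame(rows)
    pct = 100.0 * n_rejected / len(rows) if rows else 0.0
    return TAARejectionReport(table=table, percent_rejected=pct)
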