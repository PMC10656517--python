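"""Physicochemical and compositional peptide characterization.

Monoisotopic masses come from the standard residue table (pyteomics);
hydropathy uses the Kyte–Doolittle scale (Biopython's ``kd`` table, the same
scale the common web GRAVY calculators implement). Modifications contribute
to mass but not to GRAVY.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from pyteomics import mass as _pt_mass
from scipy import stats

from .model import AMINO_ACIDS, Modification, PeptideRecord, SampleImmunopeptidome

#: Monoisotopic mass of water (Da), added once per peptide (termini).
WATER = 18.010565
#: Monoisotopic mass of a proton (Da).
PROTON = 1.007276

#: Monoisotopic residue masses, standard 20-letter alphabet.
RESIDUE_MASS: dict[str, float] = {aa: _pt_mass.std_aa_mass[aa] for aa in AMINO_ACIDS}


@dataclass(frozen=True)
class PeptideProperties:
    monoisotopic_mass: float
    gravy: float
    length: int


def monoisotopic_mass(
    sequence: str, modifications: Sequence[Modification] = ()
) -> float:
    """Sum of residue masses + water + modification deltas (Da)."""
    if not sequence:
        raise ValueError("cannot compute mass of an empty sequence")
    total = WATER
    for aa in sequence:
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} in {sequence!r}") from None
    return total + sum(m.delta_mass for m in modifications)


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value per residue."""
    if not sequence:
        raise ValueError("cannot compute GRAVY of an empty sequence")
    try:
        return sum(KYTE_DOOLITTLE[aa] for aa in sequence) / len(sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from None


def peptide_properties(record: PeptideRecord) -> PeptideProperties:
    return PeptideProperties(
        monoisotopic_mass=monoisotopic_mass(record.sequence, record.modifications),
        gravy=gravy(record.sequence),
        length=len(record.sequence),
    )


def length_distribution(sequences: Iterable[str]) -> dict[int, float]:
    """Relative frequency of each observed peptide length; sums to 1."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("length_distribution needs a nonempty peptide list")
    lengths, counts = np.unique([len(s) for s in seqs], return_counts=True)
    total = counts.sum()
    return {int(l): float(c) / total for l, c in zip(lengths, counts)}


@dataclass(frozen=True)
class CompositionProfile:
    """Relative amino-acid frequencies over a peptide set (20 keys, sum 1)."""

    freq: Mapping[str, float]
    n_peptides: int


def composition_profile(sequences: Iterable[str]) -> CompositionProfile:
    seqs = list(sequences)
    if not seqs:
        raise ValueError("composition_profile needs a nonempty peptide list")
    counts = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for s in seqs:
        for aa in s:
            counts[aa] += 1
            total += 1
    return CompositionProfile(
        freq={aa: counts[aa] / total for aa in AMINO_ACIDS}, n_peptides=len(seqs)
    )


def composition_r2(a: CompositionProfile, b: CompositionProfile) -> float:
    """Squared Pearson correlation of the 20 paired residue frequencies.

    Returns NaN (the undefined flag) when either profile has zero variance.
    """
    xa = np.array([a.freq[aa] for aa in AMINO_ACIDS])
    xb = np.array([b.freq[aa] for aa in AMINO_ACIDS])
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return float("nan")
    r = np.corrcoef(xa, xb)[0, 1]
    return float(r * r)


def normalized_area_ranks(
    records: "Sequence[PeptideRecord] | SampleImmunopeptidome",
) -> dict[str, float]:
    """Within-sample percentile rank of the reported area, in (0, 1].

    rank(area, ascending)/n with ties sharing the mean rank — a scale-free,
    device-agnostic normalization. Peptides without a reported area are
    ignored; an input with no areas at all is an error.
    """
    if isinstance(records, SampleImmunopeptidome):
        records = records.union_records()
    with_area = [(r.sequence, r.reported_area) for r in records if r.reported_area is not None]
    if not with_area:
        raise ValueError("no reported areas present")
    areas = np.array([a for _, a in with_area], dtype=float)
    ranks = stats.rankdata(areas, method="average") / len(areas)
    return {seq: float(rank) for (seq, _), rank in zip(with_area, ranks)}


def lower_rank_fraction(ranks: Mapping[str, float], split: float = 0.5) -> float:
    """Fraction of peptides whose percentile rank falls below ``split``."""
    if not ranks:
        raise ValueError("empty rank map")
    return sum(1 for v in ranks.values() if v < split) / len(ranks)


# ---------------------------------------------------------------------------
# HLA population coverage (Hardy–Weinberg, independent loci)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageResult:
    """PMF over the number of cohort-covered allotypes an individual carries."""

    pmf: Mapping[int, float]
    coverage_at_least_one: float


def population_coverage(
    cohort_allotypes_per_locus: Mapping[str, Iterable[str]],
    population_allele_freqs: Mapping[str, Mapping[str, float]],
) -> CoverageResult:
    """Population coverage of a cohort's allotype panel.

    Per locus, with covered-allele mass p = sum of population frequencies of
    the cohort's alleles at that locus, Hardy–Weinberg gives
    P(0)= (1-p)^2, P(1) = 2p(1-p), P(2) = p^2 carried copies; loci combine by
    convolution (independence). ``coverage_at_least_one`` is
    1 - prod_l (1-p_l)^2.
    """
    pmf = np.array([1.0])
    miss_all = 1.0
    for locus, freqs in population_allele_freqs.items():
        total = sum(freqs.values())
        if any(f < 0 for f in freqs.values()) or total > 1 + 1e-9:
            raise ValueError(f"locus {locus}: allele frequencies invalid (sum {total})")
        covered = set(cohort_allotypes_per_locus.get(locus, ()))
        p = sum(f for allele, f in freqs.items() if allele in covered)
        if not 0 <= p <= 1 + 1e-12:
            raise ValueError(f"locus {locus}: covered mass {p} outside [0,1]")
        p = min(p, 1.0)
        locus_pmf = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        pmf = np.convolve(pmf, locus_pmf)
        miss_all *= (1 - p) ** 2
    return CoverageResult(
        pmf={k: float(v) for k, v in enumerate(pmf)},
        coverage_at_least_one=float(1.0 - miss_all),
    )


# ---------------------------------------------------------------------------
# Hydropathy comparison between peptide sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HydropathyComparison:
    p_value: float
    test: str
    medians: tuple[float, ...]
    ranges: tuple[tuple[float, float], ...]


def compare_hydropathy(*groups: Sequence[float]) -> HydropathyComparison:
    """Two-sided rank test on GRAVY vectors: Mann–Whitney U for two groups,
    Kruskal–Wallis for more. Identical groups give the maximal p-value of
    scipy's tie handling (1.0 for Mann–Whitney)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    if len(arrays) == 2:
        if np.array_equal(np.sort(arrays[0]), np.sort(arrays[1])):
            p, test = 1.0, "mannwhitneyu"
        else:
            p = float(stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided").pvalue)
            test = "mannwhitneyu"
    else:
        p = float(stats.kruskal(*arrays).pvalue)
        test = "kruskal"
    return HydropathyComparison(
        p_value=p,
        test=test,
        medians=tuple(float(np.median(a)) for a in arrays),
        ranges=tuple((float(a.min()), float(a.max())) for a in arrays),
    )
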