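"""Spectral validation of eluted peptide identifications.

An identified peptide — in particular a mutation-derived neoepitope — is
validated by co-analyzing an isotopically labelled synthetic copy and
correlating the intensities of the b/y fragment ions the two spectra share.
The label shifts every fragment whose span contains the labelled residue,
which separates the synthetic ion series from the eluted one on the m/z axis
while leaving the fragmentation pattern comparable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import AMINO_ACIDS, Spectrum, validate_sequence
from .properties import PROTON, RESIDUE_MASS, WATER, monoisotopic_mass


@dataclass(frozen=True)
class IsotopeLabel:
    """A heavy-isotope residue substitution: +delta_mass Da at one position."""

    position: int  # 1-based
    delta_mass: float

    def __post_init__(self) -> None:
        if self.delta_mass <= 0:
            raise ValueError("label delta_mass must be positive")


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "b" or "y"
    ordinal: int  # 1 .. len-1
    charge: int
    theoretical_mz: float
    contains_label: bool

    @property
    def key(self) -> tuple[str, int]:
        return (self.series, self.ordinal)


def theoretical_fragments(
    sequence: str,
    labels: Sequence[IsotopeLabel] = (),
    charge: int = 1,
) -> list[FragmentIon]:
    """Singly charged b/y ion series (default): b_i covers residues 1..i,
    y_j covers residues n-j+1..n; a label adds its delta to every ion whose
    span contains the labelled position.

    b_i = sum(residues 1..i) + proton; y_j = sum(residues n-j+1..n) + water
    + proton. For charge z the neutral fragment mass gains z protons and is
    divided by z.
    """
    seq = validate_sequence(sequence)
    n = len(seq)
    for lab in labels:
        if not 1 <= lab.position <= n:
            raise ValueError(f"label position {lab.position} outside 1..{n}")
    masses = np.array([RESIDUE_MASS[aa] for aa in seq])
    prefix = np.cumsum(masses)  # prefix[i-1] = sum residues 1..i
    ions: list[FragmentIon] = []
    for i in range(1, n):
        b_neutral = float(prefix[i - 1])
        b_delta = sum(l.delta_mass for l in labels if l.position <= i)
        ions.append(
            FragmentIon(
                series="b",
                ordinal=i,
                charge=charge,
                theoretical_mz=(b_neutral + b_delta + charge * PROTON) / charge,
                contains_label=any(l.position <= i for l in labels),
            )
        )
    for j in range(1, n):
        y_neutral = float(prefix[n - 1] - prefix[n - j - 1]) + WATER
        y_delta = sum(l.delta_mass for l in labels if l.position > n - j)
        ions.append(
            FragmentIon(
                series="y",
                ordinal=j,
                charge=charge,
                theoretical_mz=(y_neutral + y_delta + charge * PROTON) / charge,
                contains_label=any(l.position > n - j for l in labels),
            )
        )
    return ions


@dataclass(frozen=True)
class PeakMatch:
    fragment: FragmentIon
    observed_mz: float
    observed_intensity: float
    delta_mz: float


def match_peaks(
    spectrum: Spectrum,
    fragments: Sequence[FragmentIon],
    tol_ppm: float = 20.0,
    tol_da: float = 0.02,
) -> list[PeakMatch]:
    """Match each fragment to its nearest peak within
    min(tol_ppm * mz * 1e-6, tol_da); a peak may serve several fragments.
    Ties on |delta| break toward the lower-mz peak."""
    if not spectrum.peaks:
        return []
    mz = np.array(spectrum.mz)
    intensity = np.array(spectrum.intensity)
    matches: list[PeakMatch] = []
    for frag in fragments:
        window = min(tol_ppm * frag.theoretical_mz * 1e-6, tol_da)
        idx = int(np.searchsorted(mz, frag.theoretical_mz))
        candidates = [i for i in (idx - 1, idx) if 0 <= i < mz.size]
        best: Optional[int] = None
        for i in candidates:
            d = abs(mz[i] - frag.theoretical_mz)
            if d <= window and (
                best is None
                or d < abs(mz[best] - frag.theoretical_mz) - 1e-15
                or (
                    abs(d - abs(mz[best] - frag.theoretical_mz)) <= 1e-15
                    and mz[i] < mz[best]
                )
            ):
                best = i
        if best is not None:
            matches.append(
                PeakMatch(
                    fragment=frag,
                    observed_mz=float(mz[best]),
                    observed_intensity=float(intensity[best]),
                    delta_mz=float(mz[best] - frag.theoretical_mz),
                )
            )
    return matches


@dataclass(frozen=True)
class SpectralMatchResult:
    """Outcome of correlating eluted vs labelled-synthetic b/y intensities."""

    matched_ions: tuple[tuple[str, int], ...]
    intensities_eluted: tuple[float, ...]
    intensities_synthetic: tuple[float, ...]
    r: float
    r_squared: float
    n_matched: int
    defined: bool


def spectral_correlation(
    spectrum_eluted: Spectrum,
    spectrum_synthetic: Spectrum,
    sequence: str,
    labels: Sequence[IsotopeLabel],
    tol_ppm: float = 20.0,
    tol_da: float = 0.02,
) -> SpectralMatchResult:
    """Pearson correlation of b/y ion intensities between an eluted spectrum
    and the labelled synthetic spectrum of the same peptide.

    Eluted fragments are computed without labels, synthetic fragments with
    them; the intensity vectors run over ions matched in BOTH spectra
    (intersection — zero-filling absent ions would inflate r). Raw
    intensities enter directly: Pearson r is scale-invariant, so no
    normalization is needed. Fewer than 2 shared ions, or a zero-variance
    intensity vector, yields ``defined=False`` rather than an error.
    """
    frags_plain = theoretical_fragments(sequence)
    frags_labelled = theoretical_fragments(sequence, labels)
    matched_eluted = {
        m.fragment.key: m for m in match_peaks(spectrum_eluted, frags_plain, tol_ppm, tol_da)
    }
    matched_synth = {
        m.fragment.key: m
        for m in match_peaks(spectrum_synthetic, frags_labelled, tol_ppm, tol_da)
    }
    shared = sorted(set(matched_eluted) & set(matched_synth))
    x = np.array([matched_eluted[k].observed_intensity for k in shared])
    y = np.array([matched_synth[k].observed_intensity for k in shared])
    if len(shared) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpectralMatchResult(
            matched_ions=tuple(shared),
            intensities_eluted=tuple(map(float, x)),
            intensities_synthetic=tuple(map(float, y)),
            r=float("nan"),
            r_squared=float("nan"),
            n_matched=len(shared),
            defined=False,
        )
    r = float(np.corrcoef(x, y)[0, 1])
    return SpectralMatchResult(
        matched_ions=tuple(shared),
        intensities_eluted=tuple(map(float, x)),
        intensities_synthetic=tuple(map(float, y)),
        r=r,
        r_squared=r * r,
        n_matched=len(shared),
        defined=True,
    )


# ---------------------------------------------------------------------------
# Neoepitope windows from mutation identifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationSpec:
    """A missense mutation and the peptide window observed around it,
    e.g. ``SFPQ_HUMAN_304-313_ I308V``: window 304..313 of SFPQ_HUMAN with
    I->V at protein position 308."""

    protein_id: str
    window_start: int
    window_end: int
    ref_residue: str
    position: int
    alt_residue: str

    def __post_init__(self) -> None:
        if not self.window_start <= self.position <= self.window_end:
            raise ValueError(
                f"mutation position {self.position} outside window "
                f"{self.window_start}-{self.window_end}"
            )

    @property
    def peptide_offset(self) -> int:
        """1-based offset of the mutated residue within the peptide window."""
        return self.position - self.window_start + 1


_MUTATION_RE = re.compile(
    r"^(?P<protein>.+?)_(?P<start>\d+)-(?P<end>\d+)_\s*"
    r"(?P<ref>[A-Z])(?P<pos>\d+)(?P<alt>[A-Z])$"
)


def parse_mutation_id(text: str) -> MutationSpec:
    """Parse ``PROTEIN_START-END_ REFposALT`` mutation identifiers."""
    m = _MUTATION_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed mutation identifier: {text!r}")
    ref, alt = m.group("ref"), m.group("alt")
    for residue in (ref, alt):
        if residue not in AMINO_ACIDS:
            raise ValueError(f"{text!r}: {residue!r} is not an amino acid")
    return MutationSpec(
        protein_id=m.group("protein"),
        window_start=int(m.group("start")),
        window_end=int(m.group("end")),
        ref_residue=ref,
        position=int(m.group("pos")),
        alt_residue=alt,
    )


def extract_neoepitope(protein_sequence: str, spec: MutationSpec) -> str:
    """Cut the mutation window out of the protein and apply the substitution.

    Coordinates are 1-based inclusive; the reference residue must match the
    protein at the mutation position.
    """
    seq = validate_sequence(protein_sequence)
    if spec.window_end > len(seq) or spec.window_start < 1:
        raise ValueError(
            f"window {spec.window_start}-{spec.window_end} outside protein "
            f"of length {len(seq)}"
        )
    found = seq[spec.position - 1]
    if found != spec.ref_residue:
        raise ValueError(
            f"reference mismatch at {spec.protein_id}:{spec.position}: "
            f"expected {spec.ref_residue}, found {found}"
        )
    window = list(seq[spec.window_start - 1 : spec.window_end])
    window[spec.peptide_offset - 1] = spec.alt_residue
    return "".join(window)
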