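"""Position-weight-matrix motif scoring for HLA allotypes.

A deliberately simple anchor-position model: each allotype prefers a short
ranked list of residues at the second position and at the C-terminus (the
canonical class I anchor positions). The ligand-likeness of a peptide is the
geometric mean, over anchors, of the residue's weight relative to the best
possible residue — 1.0 for a peptide with both modal anchors, near the
background floor for a peptide with non-preferred anchors.

The same matrices drive the synthetic-data generator (which samples
motif-satisfying windows from a proteome) and the default predictor behind
the proteolysis filter's non-ligand propensity score, so generated ligands
are scorable by construction. External predictors (netMHCpan-style
precomputed tables) plug in through :class:`TablePredictor`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

#: Relative weight assigned to a residue not on an anchor's preference list.
BACKGROUND_WEIGHT = 0.01


@dataclass(frozen=True)
class AnchorWeights:
    """Residue preferences at one anchor position.

    ``position`` is 1-based from the N-terminus; negative values count from
    the C-terminus (-1 = last residue). ``weights`` are relative preferences;
    the maximum defines the normalization.
    """

    position: int
    weights: Mapping[str, float]

    def relative(self, residue: str) -> float:
        w_max = max(self.weights.values())
        return self.weights.get(residue, BACKGROUND_WEIGHT * w_max) / w_max


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _ranked(residues: str) -> dict[str, float]:
    """Full-alphabet anchor weights: geometric decay over the preference
    list, then a slowly decaying background tail over the remaining
    residues (keeps the score distribution smooth rather than a few
    discrete spikes)."""
    weights = {aa: 0.8 ** i for i, aa in enumerate(residues)}
    tail = [aa for aa in AMINO_ACIDS if aa not in weights]
    for j, aa in enumerate(tail):
        weights[aa] = BACKGROUND_WEIGHT * (0.85 ** j)
    return weights


@dataclass(frozen=True)
class AllotypePWM:
    name: str
    anchors: tuple[AnchorWeights, ...]

    def score(self, sequence: str) -> float:
        """Ligand-likeness in (0, 1]; 1 for a peptide with all modal anchors."""
        if len(sequence) < 2:
            return 0.0
        prod = 1.0
        for anchor in self.anchors:
            idx = anchor.position - 1 if anchor.position > 0 else len(sequence) + anchor.position
            if not 0 <= idx < len(sequence):
                return 0.0
            prod *= anchor.relative(sequence[idx])
        return prod ** (1.0 / len(self.anchors))

    def anchor_indices(self, length: int) -> list[int]:
        return [
            (a.position - 1 if a.position > 0 else length + a.position)
            for a in self.anchors
        ]


def _pwm(name: str, second: str, cterm: str) -> AllotypePWM:
    return AllotypePWM(
        name=name,
        anchors=(
            AnchorWeights(2, _ranked(second)),
            AnchorWeights(-1, _ranked(cterm)),
        ),
    )


#: Built-in allotype library with field-typical anchor preferences.
DEFAULT_ALLOTYPE_LIBRARY: dict[str, AllotypePWM] = {
    pwm.name: pwm
    for pwm in (
        _pwm("A*01", "TSDE", "YF"),
        _pwm("A*02", "LMIV", "VLI"),
        _pwm("A*24", "YF", "FLI"),
        _pwm("B*07", "PA", "LF"),
        _pwm("B*35", "PAV", "YFML"),
        _pwm("C*07", "YFR", "YFL"),
    )
}


class LigandPredictor(Protocol):
    """Pluggable scorer: ligand-likeness in [0, 1] per (peptide, allotype)."""

    def __call__(self, sequence: str, allotype: str) -> float: ...


@dataclass
class PWMPredictor:
    """Default predictor backed by the allotype PWM library."""

    library: Mapping[str, AllotypePWM] = field(
        default_factory=lambda: dict(DEFAULT_ALLOTYPE_LIBRARY)
    )

    def __call__(self, sequence: str, allotype: str) -> float:
        try:
            pwm = self.library[allotype]
        except KeyError:
            raise KeyError(f"no PWM for allotype {allotype!r}") from None
        return pwm.score(sequence)


@dataclass
class TablePredictor:
    """Adapter over externally precomputed predictions.

    ``table`` maps (sequence, allotype) -> ligand-likeness in [0, 1];
    missing pairs score ``default``.
    """

    table: Mapping[tuple[str, str], float]
    default: float = 0.0

    def __call__(self, sequence: str, allotype: str) -> float:
        return float(self.table.get((sequence, allotype), self.default))
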