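"""Seeded synthetic immunopeptidome generation with ground-truth bookkeeping.

The generator emulates the statistical structure of measured immunopeptidome
cohorts at desk scale: motif-constrained HLA ligands drawn from a synthetic
proteome (class I lengths dominated by 9-mers), nested/overlapping
proteolytic ladder artifacts at degradation hotspots, technical-replicate
detection noise, cohorts sharing a housekeeping peptide pool with planted
tumor-exclusive peptides at exact presentation frequencies, and b/y fragment
spectrum pairs with isotope-label mass shifts.

Everything is driven by one integer seed; with a fixed seed every emitted
file is byte-identical across runs. Ground truth sufficient for oracle tests
(artifact labels, planted sets and frequencies, spectrum annotations) is
returned alongside the data and never hidden in generator state.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import dump_cohort, write_fasta, write_mgf
from .model import (
    AMINO_ACIDS,
    CohortDataset,
    PeptideRecord,
    ProteomeDB,
    SampleImmunopeptidome,
    Spectrum,
    canonical_sequence,
)
from .properties import PROTON, monoisotopic_mass
from .pwm import DEFAULT_ALLOTYPE_LIBRARY, AllotypePWM, PWMPredictor
from .spectra import IsotopeLabel, theoretical_fragments

#: Class I length weights: 9-mers dominate at 70%.
CLASS_I_LENGTH_WEIGHTS: dict[int, float] = {
    8: 0.08, 9: 0.70, 10: 0.12, 11: 0.05, 12: 0.02,
    13: 0.01, 14: 0.01, 15: 0.005, 16: 0.005,
}

#: Class II length weights: broad 8-30 aa distribution peaked near 15.
CLASS_II_LENGTH_WEIGHTS: dict[int, float] = {
    length: max(1.0 - abs(length - 15) / 12.0, 0.05) for length in range(8, 31)
}
_total = sum(CLASS_II_LENGTH_WEIGHTS.values())
CLASS_II_LENGTH_WEIGHTS = {k: v / _total for k, v in CLASS_II_LENGTH_WEIGHTS.items()}

#: Default per-locus allele panels (names resolve in the PWM library).
DEFAULT_LOCI: dict[str, tuple[str, ...]] = {
    "A": ("A*01", "A*02", "A*24"),
    "B": ("B*07", "B*35"),
    "C": ("C*07",),
}

TISSUES = (
    "spleen", "liver", "lung", "kidney", "PBMC",
    "thymus", "colon", "skin", "heart", "muscle",
)


@dataclass(frozen=True)
class PlantSpec:
    """A tumor-exclusive peptide to plant at an exact presentation frequency.

    With ``allotype`` set, the frequency applies to the allotype-matched
    subset of tumor samples and the peptide is planted only there.
    """

    frequency: float
    allotype: Optional[str] = None


@dataclass
class GeneratorConfig:
    seed: int = 0
    # proteome
    n_proteins: int = 3000
    protein_length_range: tuple[int, int] = (300, 400)
    #: background residue composition; None = uniform over the 20 residues
    background_composition: Optional[Mapping[str, float]] = None
    # HLA
    hla_class: str = "I"
    loci: Mapping[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_LOCI))
    motif_accept_threshold: float = 0.5
    # cohort shape
    n_benign_samples: int = 10
    n_tumor_samples: int = 20
    tissues_per_donor: int = 2
    replicates: int = 3
    p_detect: float = 0.8
    peptides_per_sample: int = 400
    shared_fraction: float = 0.5
    # proteolytic ladder artifacts
    artifact_fraction: float = 0.05
    hotspot_length: int = 50
    fragment_length_range: tuple[int, int] = (8, 16)
    ladder_min_fragments: int = 4
    ladder_typical_fragments: int = 15
    ladder_min_step: int = 2
    ladder_max_step: int = 3
    # planted tumor-exclusive peptides (exact-count planting)
    planted_exclusive: tuple[PlantSpec, ...] = (
        PlantSpec(0.50), PlantSpec(0.25), PlantSpec(0.20),
        PlantSpec(0.05), PlantSpec(1.00, "A*02"), PlantSpec(0.50, "B*35"),
    )
    # spectra
    label_delta: float = 8.014199  # heavy Lys (13C6, 15N2)
    intensity_noise_sigma: float = 0.3
    noise_peak_rate: float = 5.0

    def length_weights(self) -> dict[int, float]:
        return dict(
            CLASS_I_LENGTH_WEIGHTS if self.hla_class == "I" else CLASS_II_LENGTH_WEIGHTS
        )


@dataclass
class GroundTruth:
    """Everything an oracle test needs, recorded at generation time."""

    #: sample_id -> canonical identity -> "ligand" | "artifact" | "planted"
    labels: dict[str, dict[str, str]] = field(default_factory=dict)
    #: planted peptides with realized counts
    planted: list[dict] = field(default_factory=list)
    housekeeping: set[str] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)
    #: spectrum title -> annotation dict
    spectra: dict[str, dict] = field(default_factory=dict)

    def artifact_set(self, sample_id: str) -> set[str]:
        return {p for p, l in self.labels[sample_id].items() if l == "artifact"}

    def to_json(self) -> str:
        doc = {
            "labels": {s: dict(sorted(v.items())) for s, v in sorted(self.labels.items())},
            "planted": self.planted,
            "housekeeping": sorted(self.housekeeping),
            "warnings": self.warnings,
            "spectra": self.spectra,
        }
        return json.dumps(doc, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

def gen_proteome(config: GeneratorConfig, rng: Optional[np.random.Generator] = None) -> ProteomeDB:
    """Synthetic proteome: i.i.d. residues from the background composition."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    comp = config.background_composition or {aa: 1 / 20 for aa in AMINO_ACIDS}
    residues = np.array(list(AMINO_ACIDS))
    probs = np.array([comp[aa] for aa in AMINO_ACIDS], dtype=float)
    probs = probs / probs.sum()
    db = ProteomeDB()
    lo, hi = config.protein_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_proteins)
    flat = rng.choice(residues, size=int(lengths.sum()), p=probs)
    offset = 0
    for i, length in enumerate(lengths):
        db[f"SYNP{i + 1:04d}"] = "".join(flat[offset : offset + int(length)])
        offset += int(length)
    return db


# ---------------------------------------------------------------------------
# Ligand and artifact drawing
# ---------------------------------------------------------------------------

def _draw_length(rng: np.random.Generator, weights: Mapping[int, float]) -> int:
    lengths = sorted(weights)
    probs = np.array([weights[l] for l in lengths])
    return int(rng.choice(lengths, p=probs / probs.sum()))


def draw_ligand(
    rng: np.random.Generator,
    proteome: ProteomeDB,
    allotypes: Sequence[str],
    length_weights: Mapping[int, float],
    threshold: float,
    library: Mapping[str, AllotypePWM] = DEFAULT_ALLOTYPE_LIBRARY,
    max_tries: int = 20000,
) -> tuple[str, str]:
    """Rejection-sample a motif-satisfying proteome window.

    Returns (sequence, accession) with ligand-likeness >= threshold for at
    least one of the given allotypes.
    """
    accessions = sorted(proteome)
    pwms = [library[a] for a in allotypes if a in library]
    if not pwms:
        raise ValueError(f"no PWMs available for allotypes {list(allotypes)}")
    for _ in range(max_tries):
        acc = accessions[int(rng.integers(len(accessions)))]
        seq = proteome[acc]
        length = _draw_length(rng, length_weights)
        if len(seq) <= length:
            continue
        start = int(rng.integers(0, len(seq) - length + 1))
        window = seq[start : start + length]
        if max(p.score(window) for p in pwms) >= threshold:
            return window, acc
    raise RuntimeError("could not find a motif-satisfying window; proteome too small?")


def draw_ladder(
    rng: np.random.Generator,
    proteome: ProteomeDB,
    config: GeneratorConfig,
    n_fragments: int,
) -> list[tuple[str, str]]:
    """One proteolytic ladder: >= ladder_min_fragments overlapping fragments
    within a hotspot, adjacent start offsets <= ladder_max_step apart."""
    n_fragments = max(n_fragments, config.ladder_min_fragments)
    accessions = sorted(proteome)
    lo_len, hi_len = config.fragment_length_range
    for _ in range(1000):
        acc = accessions[int(rng.integers(len(accessions)))]
        seq = proteome[acc]
        span = config.hotspot_length + hi_len
        if len(seq) <= span:
            continue
        hotspot = int(rng.integers(0, len(seq) - span))
        fragments: list[tuple[str, str]] = []
        start = hotspot
        for _ in range(n_fragments):
            length = int(rng.integers(lo_len, hi_len + 1))
            fragments.append((seq[start : start + length], acc))
            start += int(rng.integers(config.ladder_min_step, config.ladder_max_step + 1))
            if start - hotspot > config.hotspot_length:
                start = hotspot + int(rng.integers(0, config.ladder_max_step))
        if len({f for f, _ in fragments}) >= config.ladder_min_fragments:
            return fragments
    raise RuntimeError("could not place a ladder hotspot; proteins too short?")


def _binder_annotations(
    sequence: str, typing: Sequence[str], predictor: PWMPredictor
) -> dict[str, str]:
    out = {}
    for allotype in typing:
        score = predictor(sequence, allotype)
        if score >= 0.5:
            out[allotype] = "strong"
        elif score >= 0.2:
            out[allotype] = "medium"
        elif score >= 0.1:
            out[allotype] = "weak"
        else:
            out[allotype] = "none"
    return out


def _draw_typing(rng: np.random.Generator, config: GeneratorConfig) -> tuple[str, ...]:
    typing: list[str] = []
    for locus in sorted(config.loci):
        panel = config.loci[locus]
        picks = {panel[int(rng.integers(len(panel)))] for _ in range(2)}
        typing.extend(sorted(picks))
    return tuple(typing)


# ---------------------------------------------------------------------------
# Samples and cohorts
# ---------------------------------------------------------------------------

def gen_sample(
    config: GeneratorConfig,
    proteome: ProteomeDB,
    rng: np.random.Generator,
    sample_id: str,
    donor_id: str,
    tissue_label: str,
    cohort_label: str,
    typing: tuple[str, ...],
    shared_pool: Sequence[tuple[str, str]] = (),
    labels_out: Optional[dict[str, str]] = None,
) -> SampleImmunopeptidome:
    """One synthetic sample: shared + private ligands plus ladder artifacts,
    each peptide independently detected per replicate with p_detect
    (peptides detected in no replicate are dropped)."""
    predictor = PWMPredictor()
    n_total = config.peptides_per_sample
    n_art = int(round(config.artifact_fraction * n_total))
    n_lig = n_total - n_art
    n_shared = min(int(round(config.shared_fraction * n_lig)), len(shared_pool))

    chosen: list[tuple[str, str, str]] = []  # (sequence, accession, label)
    if n_shared:
        idx = rng.choice(len(shared_pool), size=n_shared, replace=False)
        for i in sorted(idx):
            seq, acc = shared_pool[int(i)]
            chosen.append((seq, acc, "ligand"))
    weights = config.length_weights()
    seen = {seq for seq, _, _ in chosen}
    while sum(1 for _, _, l in chosen if l == "ligand") < n_lig:
        seq, acc = draw_ligand(
            rng, proteome, typing, weights, config.motif_accept_threshold
        )
        if seq in seen:
            continue
        seen.add(seq)
        chosen.append((seq, acc, "ligand"))
    n_art_drawn = 0
    while n_art_drawn < n_art:
        remaining = n_art - n_art_drawn
        size = max(
            config.ladder_min_fragments,
            min(remaining, config.ladder_typical_fragments),
        )
        ladder = draw_ladder(rng, proteome, config, size)
        for seq, acc in ladder:
            if seq in seen:
                continue
            seen.add(seq)
            chosen.append((seq, acc, "artifact"))
            n_art_drawn += 1

    replicates: dict[str, list[PeptideRecord]] = {
        f"R{i + 1}": [] for i in range(config.replicates)
    }
    for seq, acc, label in chosen:
        detected = rng.random(config.replicates) < config.p_detect
        if not detected.any():
            continue  # never observed in this sample
        record = PeptideRecord(
            sequence=seq,
            source_proteins=(acc,),
            reported_area=float(rng.lognormal(10.0, 1.0)),
            binder_annotations=_binder_annotations(seq, typing, predictor),
        )
        for i, hit in enumerate(detected):
            if hit:
                replicates[f"R{i + 1}"].append(record)
        if labels_out is not None:
            labels_out[canonical_sequence(seq)] = label
    return SampleImmunopeptidome(
        sample_id=sample_id,
        donor_id=donor_id,
        tissue_label=tissue_label,
        cohort_label=cohort_label,
        hla_class=config.hla_class,
        hla_typing=typing,
        replicates=replicates,
    )


def _shared_allotypes(typings: Sequence[tuple[str, ...]]) -> list[str]:
    shared = set(typings[0])
    for t in typings[1:]:
        shared &= set(t)
    return sorted(shared) if shared else sorted(DEFAULT_ALLOTYPE_LIBRARY)


def gen_cohorts(
    config: GeneratorConfig,
) -> tuple[CohortDataset, CohortDataset, ProteomeDB, GroundTruth]:
    """Benign + tumor cohorts over one proteome, with a shared housekeeping
    pool and exactly planted tumor-exclusive peptides."""
    rng = np.random.default_rng(config.seed)
    proteome = gen_proteome(config, rng)
    truth = GroundTruth()

    # typings: benign donors span tissues_per_donor tissues each
    n_benign_donors = -(-config.n_benign_samples // config.tissues_per_donor)
    benign_typings = [_draw_typing(rng, config) for _ in range(n_benign_donors)]
    tumor_typings = [_draw_typing(rng, config) for _ in range(config.n_tumor_samples)]
    shared = _shared_allotypes(benign_typings + tumor_typings)

    # housekeeping pool drawn against allotypes carried by every sample
    n_lig = config.peptides_per_sample - int(
        round(config.artifact_fraction * config.peptides_per_sample)
    )
    pool_size = max(int(config.shared_fraction * n_lig * 1.5), 1)
    weights = config.length_weights()
    pool: list[tuple[str, str]] = []
    pool_seqs: set[str] = set()
    while len(pool) < pool_size:
        seq, acc = draw_ligand(
            rng, proteome, shared, weights, config.motif_accept_threshold
        )
        if seq not in pool_seqs:
            pool_seqs.add(seq)
            pool.append((seq, acc))
    truth.housekeeping = {canonical_sequence(s) for s, _ in pool}

    benign_samples = []
    for i in range(config.n_benign_samples):
        donor = i // config.tissues_per_donor
        sid = f"BEN{i + 1:02d}"
        labels: dict[str, str] = {}
        benign_samples.append(
            gen_sample(
                config, proteome, rng,
                sample_id=sid,
                donor_id=f"BD{donor + 1:02d}",
                tissue_label=TISSUES[(i % config.tissues_per_donor
                                      + donor) % len(TISSUES)],
                cohort_label="benign",
                typing=benign_typings[donor],
                shared_pool=pool,
                labels_out=labels,
            )
        )
        truth.labels[sid] = labels
    benign = CohortDataset(name="benign_synthetic", samples=benign_samples)
    benign_union = benign.peptide_union()

    # tumor samples share only peptides actually realized in the benign
    # cohort, so every non-artifact tumor-only peptide is a deliberate plant
    pool_for_tumor = [
        (seq, acc) for seq, acc in pool if canonical_sequence(seq) in benign_union
    ]

    tumor_samples = []
    for i in range(config.n_tumor_samples):
        sid = f"TUM{i + 1:02d}"
        labels = {}
        tumor_samples.append(
            gen_sample(
                config, proteome, rng,
                sample_id=sid,
                donor_id=f"TD{i + 1:02d}",
                tissue_label="tumor_tissue",
                cohort_label="tumor",
                typing=tumor_typings[i],
                shared_pool=pool_for_tumor,
                labels_out=labels,
            )
        )
        truth.labels[sid] = labels
    tumor = CohortDataset(name="tumor_synthetic", samples=tumor_samples)

    # plant tumor-exclusive peptides at exact sample counts
    forbidden = benign_union | truth.housekeeping | tumor.peptide_union()
    for plant in config.planted_exclusive:
        if plant.allotype:
            eligible = [
                s for s in tumor_samples if plant.allotype in s.hla_typing
            ]
            draw_against: Sequence[str] = (plant.allotype,)
        else:
            eligible = list(tumor_samples)
            draw_against = shared
        if not eligible:
            truth.warnings.append(
                f"no tumor sample carries {plant.allotype}; plant skipped"
            )
            continue
        exact = plant.frequency * len(eligible)
        n_plant = int(round(exact))
        if abs(exact - n_plant) > 1e-9:
            truth.warnings.append(
                f"target frequency {plant.frequency} x {len(eligible)} samples "
                f"is non-integer; rounded to {n_plant}"
            )
        n_plant = max(n_plant, 0)
        for _ in range(10000):
            seq, acc = draw_ligand(
                rng, proteome, draw_against, weights, config.motif_accept_threshold
            )
            if canonical_sequence(seq) not in forbidden:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw a fresh plant sequence")
        forbidden.add(canonical_sequence(seq))
        picked = sorted(
            rng.choice(len(eligible), size=n_plant, replace=False).tolist()
        )
        for j in picked:
            sample = eligible[j]
            record = PeptideRecord(
                sequence=seq,
                source_proteins=(acc,),
                reported_area=float(rng.lognormal(10.0, 1.0)),
                binder_annotations=_binder_annotations(
                    seq, sample.hla_typing, PWMPredictor()
                ),
            )
            detected = rng.random(config.replicates) < config.p_detect
            if not detected.any():
                detected[int(rng.integers(config.replicates))] = True
            for k, hit in enumerate(detected):
                if hit:
                    sample.replicates[f"R{k + 1}"].append(record)
            truth.labels[sample.sample_id][canonical_sequence(seq)] = "planted"
        truth.planted.append(
            {
                "sequence": canonical_sequence(seq),
                "target_frequency": plant.frequency,
                "allotype": plant.allotype,
                "n_samples_planted": n_plant,
                "n_eligible": len(eligible),
                "planted_in": [eligible[j].sample_id for j in picked],
            }
        )
    return benign, tumor, proteome, truth


# ---------------------------------------------------------------------------
# Spectrum pairs
# ---------------------------------------------------------------------------

def gen_spectrum_pair(
    peptide: str,
    label: IsotopeLabel,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    noise_sigma: Optional[float] = None,
    noise_peak_rate: Optional[float] = None,
) -> tuple[Spectrum, Spectrum, dict]:
    """An (eluted, labelled-synthetic) spectrum pair for one peptide.

    Both spectra share one underlying b/y intensity profile; each gets
    independent multiplicative log-normal intensity noise and Poisson-rate
    uniform-mz noise peaks. The synthetic spectrum's fragment masses carry
    the isotope label shift.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sigma = config.intensity_noise_sigma if noise_sigma is None else noise_sigma
    rate = config.noise_peak_rate if noise_peak_rate is None else noise_peak_rate
    frags_plain = theoretical_fragments(peptide)
    frags_lab = theoretical_fragments(peptide, [label])
    base = {f.key: float(rng.lognormal(7.0, 1.0)) for f in frags_plain}

    def build(frags, shift_title) -> Spectrum:
        peaks = []
        for f in frags:
            noise = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
            peaks.append((f.theoretical_mz, base[f.key] * noise))
        n_noise = int(rng.poisson(rate)) if rate > 0 else 0
        for _ in range(n_noise):
            peaks.append(
                (float(rng.uniform(100.0, 1500.0)), float(rng.lognormal(4.0, 1.0)))
            )
        mass = monoisotopic_mass(peptide)
        return Spectrum(
            precursor_mz=(mass + 2 * PROTON) / 2,
            precursor_charge=2,
            peaks=peaks,
            title=f"{peptide}_{shift_title}",
        )

    eluted = build(frags_plain, "eluted")
    synthetic = build(frags_lab, "synthetic")
    annotations = {
        "peptide": peptide,
        "label_position": label.position,
        "label_delta": label.delta_mass,
        "n_fragments": len(frags_plain),
    }
    return eluted, synthetic, annotations


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulationBundle:
    config: GeneratorConfig
    proteome: ProteomeDB
    benign: CohortDataset
    tumor: CohortDataset
    truth: GroundTruth
    spectra: list[tuple[Spectrum, Spectrum]]


def simulate_bundle(config: GeneratorConfig) -> SimulationBundle:
    """Generate cohorts plus spectrum pairs for the planted peptides."""
    benign, tumor, proteome, truth = gen_cohorts(config)
    rng = np.random.default_rng(config.seed + 1)
    spectra = []
    for plant in truth.planted:
        peptide = plant["sequence"]
        label = IsotopeLabel(position=len(peptide) // 2 + 1, delta_mass=config.label_delta)
        eluted, synthetic, ann = gen_spectrum_pair(peptide, label, config, rng)
        truth.spectra[eluted.title] = ann
        spectra.append((eluted, synthetic))
    return SimulationBundle(
        config=config, proteome=proteome, benign=benign,
        tumor=tumor, truth=truth, spectra=spectra,
    )


def write_bundle(bundle: SimulationBundle, out_dir: str | Path) -> dict[str, str]:
    """Write the bundle as FASTA + cohort manifests + MGFs + ground truth
    JSON; returns a map of artifact names to paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.proteome, out / "proteome.fasta")
    paths = {
        "proteome": str(out / "proteome.fasta"),
        "benign_manifest": str(dump_cohort(bundle.benign, out / "benign")),
        "tumor_manifest": str(dump_cohort(bundle.tumor, out / "tumor")),
    }
    if bundle.spectra:
        flat: list[Spectrum] = [s for pair in bundle.spectra for s in pair]
        write_mgf(flat, out / "spectra.mgf")
        paths["spectra"] = str(out / "spectra.mgf")
    (out / "ground_truth.json").write_text(bundle.truth.to_json())
    paths["ground_truth"] = str(out / "ground_truth.json")
    config_doc = dataclasses.asdict(bundle.config)
    config_doc["planted_exclusive"] = [
        dataclasses.asdict(p) for p in bundle.config.planted_exclusive
    ]
    (out / "config.json").write_text(json.dumps(config_doc, indent=1, sort_keys=True, default=list))
    paths["config"] = str(out / "config.json")
    return paths
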