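"""Shared fixtures: small synthetic datasets built by the package's own
generator (no stored data files)."""

from __future__ import annotations

import pytest

from immunopep.model import PeptideRecord, ProteomeDB, SampleImmunopeptidome, CohortDataset
from immunopep.simulate import GeneratorConfig, gen_cohorts


@pytest.fixture(scope="session")
def small_cohorts():
    """A small benign/tumor cohort pair with ground truth (fast settings)."""
    cfg = GeneratorConfig(
        seed=11,
        n_proteins=500,
        peptides_per_sample=80,
        n_benign_samples=4,
        n_tumor_samples=6,
    )
    benign, tumor, proteome, truth = gen_cohorts(cfg)
    return cfg, benign, tumor, proteome, truth


@pytest.fixture(scope="session")
def artifact_cohort():
    """The 10-sample tumor cohort used for classifier recall/FDR checks."""
    cfg = GeneratorConfig(seed=1, n_tumor_samples=10)
    benign, tumor, proteome, truth = gen_cohorts(cfg)
    return cfg, tumor, proteome, truth


@pytest.fixture
def toy_proteome() -> ProteomeDB:
    db = ProteomeDB()
    db["P100"] = "A" * 30 + "SIINFEKLVW" + "C" * 60  # length 100
    db["P200"] = "MKVLDFEQEMTAYRQW" * 5
    return db


def make_sample(
    replicates: dict[str, list[str]],
    sample_id: str = "S1",
    donor_id: str = "D1",
    tissue: str = "PBMC",
    cohort_label: str = "tumor",
    typing: tuple[str, ...] = ("A*02", "C*07"),
) -> SampleImmunopeptidome:
    return SampleImmunopeptidome(
        sample_id=sample_id,
        donor_id=donor_id,
        tissue_label=tissue,
        cohort_label=cohort_label,
        hla_class="I",
        hla_typing=typing,
        replicates={
            rep: [PeptideRecord(sequence=s) for s in seqs]
            for rep, seqs in replicates.items()
        },
    )


def make_cohort(samples, name="toy", il_collapsed=False) -> CohortDataset:
    return CohortDataset(name=name, samples=list(samples), il_collapsed=il_collapsed)
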