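"""End-to-end orchestration: simulate -> proteolysis -> profile -> validate.

Every stage writes plain TSV keyed by auditable integer counts, and the run
ends in a single ``summary.json`` that is byte-identical across reruns with
the same config and inputs (keys sorted, no timestamps). Each output carries
the package version and a hash of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .model import CohortDataset, ProteomeDB, canonical_sequence
from .profiling import (
    allotype_frequencies,
    frequency_display_filter,
    presentation_frequencies,
    reference_from_cohort,
    replicate_overlap,
    tumor_exclusive,
)
from .proteolysis import (
    SCORE_NAMES,
    classify_proteolytic,
    fit_thresholds,
    proteolysis_report,
    score_sample,
)
from .simulate import GeneratorConfig, SimulationBundle, simulate_bundle, write_bundle
from .spectra import IsotopeLabel, spectral_correlation

log = logging.getLogger("immunopep")


@dataclass
class PipelineConfig:
    """Knobs for a full pipeline run.

    ``fdr_level`` is the per-score mixture-FDR target of the proteolysis
    filter; ``min_display_frequency`` hides peptides presented on fewer than
    5% of cohort samples; ``broad_presentation_threshold`` marks the
    broadly presented antigen tier (>= 20% of samples); fragment matching
    uses min(``tol_ppm``, ``tol_da``)-derived windows.
    """

    seed: int = 0
    il_collapse: bool = False
    fdr_level: float = 0.05
    min_display_frequency: float = 0.05
    broad_presentation_threshold: float = 0.20
    tol_ppm: float = 20.0
    tol_da: float = 0.02
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0,1)")
        for name in ("min_display_frequency", "broad_presentation_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        # one seed drives everything
        self.generator.seed = self.seed

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _provenance(config: PipelineConfig) -> dict:
    return {"tool_version": __version__, "config_hash": config.config_hash()}


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# immunopep {__version__} config={config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on a synthetic bundle and return the summary dict
    (also written to ``summary.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"provenance": _provenance(config), "seed": config.seed}

    # --- stage: simulate -------------------------------------------------
    try:
        bundle = simulate_bundle(config.generator)
        write_bundle(bundle, out / "inputs")
        summary["simulate"] = {
            "n_benign_samples": len(bundle.benign.samples),
            "n_tumor_samples": len(bundle.tumor.samples),
            "n_proteins": len(bundle.proteome),
            "n_planted": len(bundle.truth.planted),
        }
        log.info("simulate: %s", summary["simulate"])
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    # --- stage: proteolysis ---------------------------------------------
    try:
        calls_per_sample = {}
        rows = []
        for sample in bundle.tumor.samples:
            triples = score_sample(sample, bundle.proteome)
            tset = fit_thresholds(triples, alpha=config.fdr_level, seed=config.seed)
            calls = classify_proteolytic(triples, tset)
            calls_per_sample[sample.sample_id] = calls
            for c in calls:
                rows.append(
                    {
                        "sample_id": sample.sample_id,
                        "peptide": c.peptide,
                        **{n: getattr(c.scores, n) for n in SCORE_NAMES},
                        "is_proteolytic": c.is_proteolytic,
                    }
                )
        _write_tsv(pd.DataFrame(rows), out / "proteolysis_calls.tsv", config)
        report = proteolysis_report(bundle.tumor, calls_per_sample)
        _write_tsv(report.per_sample, out / "proteolysis_per_sample.tsv", config)
        summary["proteolysis"] = {
            "median_pct": round(report.median_pct, 6),
            "range_pct": [round(v, 6) for v in report.range_pct],
            "crosstab": report.crosstab,
        }
        log.info("proteolysis: %s", summary["proteolysis"])
    except Exception as exc:
        raise StageError("proteolysis", exc) from exc

    # --- stage: profile --------------------------------------------------
    try:
        bundle.benign.il_collapsed = config.il_collapse
        bundle.tumor.il_collapsed = config.il_collapse
        reference = reference_from_cohort(bundle.benign)
        result = tumor_exclusive(
            bundle.tumor, reference, config.min_display_frequency
        )
        shown = frequency_display_filter(
            result.frequencies, config.min_display_frequency
        )
        broad = [
            r for r in shown if r.frequency >= config.broad_presentation_threshold
        ]
        assignment = {}
        for sample in bundle.tumor.samples:
            for rec in sample.union_records():
                ident = canonical_sequence(rec, config.il_collapse)
                allos = [
                    a for a, s in (rec.binder_annotations or {}).items() if s != "none"
                ]
                if allos:
                    assignment.setdefault(ident, sorted(set(allos)))
        allo_records, n_unassigned = allotype_frequencies(
            sorted(result.exclusive), bundle.tumor, assignment
        )
        freq_df = pd.DataFrame(
            [
                {
                    "peptide": r.peptide,
                    "n_positive": r.n_positive,
                    "n_total": r.n_total,
                    "frequency": r.frequency,
                }
                for r in result.frequencies
            ]
        )
        _write_tsv(freq_df, out / "exclusive_frequencies.tsv", config)
        rep_rows = []
        for sample in bundle.tumor.samples:
            for k, frac in sorted(replicate_overlap(sample).items()):
                rep_rows.append(
                    {"sample_id": sample.sample_id, "n_replicates": k, "fraction": frac}
                )
        _write_tsv(pd.DataFrame(rep_rows), out / "replicate_overlap.tsv", config)
        planted = {p["sequence"] for p in bundle.truth.planted if p["n_samples_planted"] > 0}
        summary["profile"] = {
            "n_tumor_union": len(result.exclusive) + len(result.rejected),
            "n_exclusive": len(result.exclusive),
            "n_rejected": len(result.rejected),
            "n_displayed": len(shown),
            "n_broad": len(broad),
            "n_allotype_unassigned": n_unassigned,
            "planted_recovered": sorted(planted & result.exclusive) == sorted(planted),
        }
        log.info("profile: %s", summary["profile"])
    except Exception as exc:
        raise StageError("profile", exc) from exc

    # --- stage: validate-spectra -----------------------------------------
    try:
        rows = []
        for eluted, synthetic in bundle.spectra:
            ann = bundle.truth.spectra[eluted.title]
            res = spectral_correlation(
                eluted,
                synthetic,
                ann["peptide"],
                [IsotopeLabel(ann["label_position"], ann["label_delta"])],
                tol_ppm=config.tol_ppm,
                tol_da=config.tol_da,
            )
            rows.append(
                {
                    "peptide": ann["peptide"],
                    "n_matched": res.n_matched,
                    "r_squared": res.r_squared if res.defined else float("nan"),
                    "defined": res.defined,
                }
            )
        df = pd.DataFrame(rows)
        _write_tsv(df, out / "spectral_validation.tsv", config)
        defined = df[df["defined"]]
        summary["validate_spectra"] = {
            "n_pairs": int(len(df)),
            "n_defined": int(len(defined)),
            "median_r_squared": round(float(defined["r_squared"].median()), 6)
            if len(defined)
            else None,
        }
        log.info("validate-spectra: %s", summary["validate_spectra"])
    except Exception as exc:
        raise StageError("validate-spectra", exc) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
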