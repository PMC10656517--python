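"""Proteolytic-artifact classification.

Peptides generated by endogenous peptidase degradation during sample
handling, rather than by HLA presentation, typically occur as nested or
overlapping "ladder" fragment series along a stretch of their source
protein. Three per-peptide scores capture that phenomenology, each oriented
so that larger values are more artifact-like:

* **protein coverage ratio** — fraction of the source protein covered by the
  union of all identified peptides mapping to it (degradation blankets a
  region; presentation samples sparsely);
* **peptide coverage ratio** — fraction of the peptide's own residues also
  covered by at least one *other* identified peptide overlapping it (direct
  ladder/nesting evidence);
* **non-ligand propensity** — one minus the best ligand-likeness over the
  sample's HLA allotypes (artifacts need not satisfy any binding motif).

Per score, a two-component 1-D Gaussian mixture is deconvoluted by EM; the
lower-mean component is taken as the ligand-like null and an upper-tail
threshold is set at a target mixture-model FDR (default 5%). A peptide is
called proteolytic when it strictly exceeds at least two of the three
thresholds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .model import CohortDataset, PeptideRecord, ProteomeDB, SampleImmunopeptidome, canonical_sequence
from .pwm import LigandPredictor, PWMPredictor

SCORE_NAMES = ("protein_coverage", "peptide_coverage", "nonligand_propensity")


@dataclass(frozen=True)
class ScoreTriple:
    """The three artifact scores for one peptide, each in [0, 1]."""

    protein_coverage: float
    peptide_coverage: float
    nonligand_propensity: float

    def __post_init__(self) -> None:
        for name in SCORE_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.protein_coverage, self.peptide_coverage, self.nonligand_propensity)


# ---------------------------------------------------------------------------
# Coverage scores
# ---------------------------------------------------------------------------

class CoverageIndex:
    """Per-protein position coverage by a sample's identified peptides.

    Built once per sample; answers both coverage-ratio queries in O(peptide
    length). Peptides are placed by exact substring search; a peptide whose
    claimed source protein does not contain it is an error.
    """

    def __init__(self, peptides: Sequence[PeptideRecord], proteome: ProteomeDB):
        self._proteome = proteome
        # canonical identity -> {accession: union occurrence mask}
        self._placements: dict[str, dict[str, np.ndarray]] = {}
        self._counts: dict[str, np.ndarray] = {}
        seen: set[str] = set()
        for rec in peptides:
            ident = canonical_sequence(rec)
            if ident in seen:
                continue
            seen.add(ident)
            accs = rec.source_proteins or tuple(proteome)
            placements: dict[str, np.ndarray] = {}
            for acc in accs:
                if acc not in proteome:
                    if rec.source_proteins:
                        raise KeyError(f"accession {acc!r} not in proteome")
                    continue
                seq = proteome[acc]
                mask = np.zeros(len(seq), dtype=bool)
                start = seq.find(rec.sequence)
                while start != -1:
                    mask[start : start + len(rec.sequence)] = True
                    start = seq.find(rec.sequence, start + 1)
                if mask.any():
                    placements[acc] = mask
            if not placements:
                raise ValueError(
                    f"peptide {rec.sequence!r} is not a substring of any claimed "
                    f"source protein {list(rec.source_proteins)}"
                )
            self._placements[ident] = placements
        for placements in self._placements.values():
            for acc, mask in placements.items():
                if acc not in self._counts:
                    self._counts[acc] = np.zeros(mask.size, dtype=np.int32)
                self._counts[acc] += mask

    def protein_coverage_ratio(self, record: PeptideRecord) -> float:
        """Max over source proteins of (positions covered by all peptides) / length."""
        ident = canonical_sequence(record)
        best = 0.0
        for acc in self._placements[ident]:
            count = self._counts[acc]
            best = max(best, float((count > 0).sum()) / count.size)
        return best

    def peptide_coverage_ratio(self, record: PeptideRecord) -> float:
        """Max over placements of the fraction of own positions covered by
        at least one OTHER peptide; 0 for a lone peptide."""
        ident = canonical_sequence(record)
        best = 0.0
        for acc, own in self._placements[ident].items():
            count = self._counts[acc]
            others = count - own.astype(np.int32)
            seq = self._proteome[acc]
            n = len(record.sequence)
            start = seq.find(record.sequence)
            while start != -1:
                window = others[start : start + n]
                best = max(best, float((window > 0).sum()) / n)
                start = seq.find(record.sequence, start + 1)
        return best


def protein_coverage_ratio(
    record: PeptideRecord, all_peptides: Sequence[PeptideRecord], proteome: ProteomeDB
) -> float:
    return CoverageIndex(list(all_peptides), proteome).protein_coverage_ratio(record)


def peptide_coverage_ratio(
    record: PeptideRecord, all_peptides: Sequence[PeptideRecord], proteome: ProteomeDB
) -> float:
    return CoverageIndex(list(all_peptides), proteome).peptide_coverage_ratio(record)


def nonligand_propensity(
    record: "PeptideRecord | str",
    sample_allotypes: Sequence[str],
    predictor: Optional[LigandPredictor] = None,
) -> float:
    """1 − max over the sample's allotypes of predicted ligand-likeness."""
    if not sample_allotypes:
        raise ValueError("no allotypes supplied")
    predictor = predictor or PWMPredictor()
    seq = record if isinstance(record, str) else record.sequence
    try:
        best = max(predictor(seq, a) for a in sample_allotypes)
    except Exception as exc:
        raise RuntimeError(f"predictor failed for peptide {seq!r}: {exc}") from exc
    return min(1.0, max(0.0, 1.0 - best))


def score_sample(
    sample: SampleImmunopeptidome,
    proteome: ProteomeDB,
    predictor: Optional[LigandPredictor] = None,
) -> dict[str, ScoreTriple]:
    """ScoreTriple per canonical peptide identity of the sample's union set."""
    records = sample.union_records()
    index = CoverageIndex(records, proteome)
    out: dict[str, ScoreTriple] = {}
    for rec in records:
        out[canonical_sequence(rec)] = ScoreTriple(
            protein_coverage=index.protein_coverage_ratio(rec),
            peptide_coverage=index.peptide_coverage_ratio(rec),
            nonligand_propensity=nonligand_propensity(rec, sample.hla_typing, predictor),
        )
    return out


# ---------------------------------------------------------------------------
# Two-component Gaussian mixture EM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureFit:
    """A fitted 1-D two-component Gaussian mixture, components ordered by mean."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    loglik: float
    n_iter: int
    converged: bool
    collapsed: bool = False
    loglik_history: tuple[float, ...] = field(default=(), repr=False)


def _em_once(
    x: np.ndarray,
    w: np.ndarray,
    mu: np.ndarray,
    var: np.ndarray,
    tol: float,
    max_iter: int,
    variance_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool, list[float]]:
    history: list[float] = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step (log space)
        log_comp = (
            np.log(np.maximum(w, 1e-300))[:, None]
            - 0.5 * np.log(2 * np.pi * var)[:, None]
            - 0.5 * (x[None, :] - mu[:, None]) ** 2 / var[:, None]
        )
        log_norm = logsumexp(log_comp, axis=0)
        loglik = float(log_norm.sum())
        history.append(loglik)
        resp = np.exp(log_comp - log_norm[None, :])
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / x.size
        mu = (resp @ x) / nk
        var = (resp @ (x ** 2)) / nk - mu ** 2
        var = np.maximum(var, variance_floor)
        if loglik - prev < tol and it > 1:
            converged = True
            break
        prev = loglik
    return w, mu, var, history[-1], it, converged, history


def fit_gaussian_mixture(
    values: Iterable[float],
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    variance_floor: float = 1e-6,
    n_restarts: int = 0,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture by EM.

    Deterministic median-split initialization (each half moment-matched);
    ``seed`` only drives the optional random restarts. Variances are floored
    at ``variance_floor``; a component resting on the floor marks the fit
    ``collapsed`` (a point-mass component — common for scores with an exact
    spike, e.g. peptide coverage 0 for lone peptides) while ``converged``
    tracks log-likelihood convergence only. Fully degenerate input (all
    values identical) returns a collapsed, non-converged fit without
    crashing.
    """
    x = np.asarray(list(values), dtype=float).ravel()
    if x.size < 10:
        raise ValueError(f"need at least 10 values to fit a mixture, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in mixture input")
    sd_floor = math.sqrt(variance_floor)
    if np.ptp(x) == 0:
        mu = float(x[0])
        loglik = float(np.sum(norm.logpdf(x, mu, sd_floor)))
        return MixtureFit(
            weights=(0.5, 0.5), means=(mu, mu), sds=(sd_floor, sd_floor),
            loglik=loglik, n_iter=0, converged=False, collapsed=True,
            loglik_history=(loglik,),
        )

    def moments(part: np.ndarray) -> tuple[float, float]:
        if part.size == 0:
            return float(x.mean()), max(float(x.var()), variance_floor)
        return float(part.mean()), max(float(part.var()), variance_floor)

    med = float(np.median(x))
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # heavy ties at the median
        lo, hi = x[x < med], x[x >= med]
    inits = [
        (
            np.array([max(lo.size, 1), max(hi.size, 1)], dtype=float)
            / (max(lo.size, 1) + max(hi.size, 1)),
            np.array([moments(lo)[0], moments(hi)[0]]),
            np.array([moments(lo)[1], moments(hi)[1]]),
        )
    ]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        picks = rng.choice(x, size=2, replace=False)
        inits.append(
            (
                np.array([0.5, 0.5]),
                np.sort(picks).astype(float),
                np.array([max(float(x.var()), variance_floor)] * 2),
            )
        )

    best: Optional[tuple] = None
    for w0, mu0, var0 in inits:
        result = _em_once(x, w0.copy(), mu0.copy(), var0.copy(), tol, max_iter, variance_floor)
        if best is None or result[3] > best[3]:
            best = result
    assert best is not None
    w, mu, var, loglik, n_iter, converged, history = best
    order = np.argsort(mu)
    w, mu, var = w[order], mu[order], var[order]
    collapsed = bool(np.any(var <= variance_floor * (1 + 1e-9)))
    return MixtureFit(
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(math.sqrt(var[0])), float(math.sqrt(var[1]))),
        loglik=loglik,
        n_iter=n_iter,
        converged=converged,
        collapsed=collapsed,
        loglik_history=tuple(history),
    )


# ---------------------------------------------------------------------------
# FDR threshold from a fitted mixture
# ---------------------------------------------------------------------------

def mixture_fdr(fit: MixtureFit, t: float) -> float:
    """Model-based FDR of calling everything above t:
    w0*S0(t) / (w0*S0(t) + w1*S1(t)) with S the Gaussian survival function."""
    (w0, w1), (m0, m1), (s0, s1) = fit.weights, fit.means, fit.sds
    terms = []
    if w0 > 0:
        terms.append(math.log(w0) + norm.logsf(t, m0, s0))
    if w1 > 0:
        terms.append(math.log(w1) + norm.logsf(t, m1, s1))
    if not terms:
        return 0.0
    total = logsumexp(terms)
    if not np.isfinite(total):
        return 0.0
    if w0 == 0:
        return 0.0
    return float(np.exp(math.log(w0) + norm.logsf(t, m0, s0) - total))


def fdr_threshold(fit: MixtureFit, alpha: float = 0.05) -> float:
    """Smallest t with mixture-model FDR(t) <= alpha.

    Solved by bisection over [mu0 - 6*sd0, mu1 + 6*sd1], where FDR(t)
    decreases monotonically between the modes. Returns +inf when no
    threshold attains alpha (nothing callable), -inf when alpha >= 1.
    Collapsed (point-mass) components are fine; only a fit whose
    log-likelihood failed to converge is an error.
    """
    if not 0 < alpha:
        raise ValueError("alpha must be positive")
    if not fit.converged:
        raise ValueError("cannot derive a threshold from a non-converged fit")
    if alpha >= 1:
        return float("-inf")
    w0, w1 = fit.weights
    if w1 <= 0:
        return float("inf")
    if w0 <= 0:
        return float(fit.means[0] - 6 * fit.sds[0])
    lo = fit.means[0] - 6 * fit.sds[0]
    hi = fit.means[1] + 6 * fit.sds[1]
    if mixture_fdr(fit, hi) > alpha:
        return float("inf")
    if mixture_fdr(fit, lo) <= alpha:
        return float(lo)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mixture_fdr(fit, mid) <= alpha:
            hi = mid
        else:
            lo = mid
    return float(hi)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-score FDR thresholds plus the mixture fits behind them."""

    thresholds: Mapping[str, float]
    fdr_level: float
    fits: Mapping[str, MixtureFit]

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")


def fit_thresholds(
    triples: Mapping[str, ScoreTriple],
    alpha: float = 0.05,
    seed: int = 0,
    n_restarts: int = 0,
) -> ThresholdSet:
    """Fit per-score mixtures on a score population and derive thresholds."""
    thresholds: dict[str, float] = {}
    fits: dict[str, MixtureFit] = {}
    for name in SCORE_NAMES:
        values = [getattr(t, name) for t in triples.values()]
        fit = fit_gaussian_mixture(values, seed=seed, n_restarts=n_restarts)
        fits[name] = fit
        if fit.converged:
            thresholds[name] = fdr_threshold(fit, alpha)
        else:  # degenerate score distribution: nothing callable on this axis
            thresholds[name] = float("inf")
    return ThresholdSet(thresholds=thresholds, fdr_level=alpha, fits=fits)


# ---------------------------------------------------------------------------
# Classification and reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteolysisCall:
    peptide: str
    scores: ScoreTriple
    exceed_flags: tuple[bool, bool, bool]
    is_proteolytic: bool


def classify_proteolytic(
    triples: Mapping[str, ScoreTriple], threshold_set: ThresholdSet
) -> list[ProteolysisCall]:
    """Two-of-three rule: proteolytic iff the peptide strictly exceeds at
    least two of the per-score thresholds."""
    calls = []
    for peptide in sorted(triples):
        triple = triples[peptide]
        flags = tuple(
            getattr(triple, name) > threshold_set.thresholds[name]
            for name in SCORE_NAMES
        )
        calls.append(
            ProteolysisCall(
                peptide=peptide,
                scores=triple,
                exceed_flags=flags,  # type: ignore[arg-type]
                is_proteolytic=sum(flags) >= 2,
            )
        )
    return calls


@dataclass(frozen=True)
class ProteolysisReport:
    per_sample: "object"  # pandas.DataFrame: sample_id, n_peptides, n_proteolytic, pct
    median_pct: float
    range_pct: tuple[float, float]
    crosstab: Mapping[str, int]  # proteolytic x annotated-ligand counts


def proteolysis_report(
    cohort: CohortDataset, calls_per_sample: Mapping[str, Sequence[ProteolysisCall]]
) -> ProteolysisReport:
    """Per-sample artifact percentages plus the cohort median/range and the
    cross-tabulation of proteolytic calls against ligand annotation."""
    import pandas as pd

    rows = []
    crosstab = {
        "proteolytic_ligand": 0,
        "proteolytic_nonligand": 0,
        "retained_ligand": 0,
        "retained_nonligand": 0,
    }
    for sample in cohort.samples:
        calls = calls_per_sample.get(sample.sample_id, ())
        if not calls:
            warnings.warn(f"sample {sample.sample_id}: no calls, excluded from report")
            continue
        n = len(calls)
        n_prot = sum(c.is_proteolytic for c in calls)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "n_peptides": n,
                "n_proteolytic": n_prot,
                "pct_proteolytic": 100.0 * n_prot / n,
            }
        )
        annotated = {
            canonical_sequence(rec): rec.is_annotated_ligand()
            for rec in sample.union_records()
        }
        for c in calls:
            lig = annotated.get(c.peptide, False)
            key = ("proteolytic_" if c.is_proteolytic else "retained_") + (
                "ligand" if lig else "nonligand"
            )
            crosstab[key] += 1
    per_sample = pd.DataFrame(rows)
    if per_sample.empty:
        raise ValueError("no samples with calls to report")
    pct = per_sample["pct_proteolytic"]
    return ProteolysisReport(
        per_sample=per_sample,
        median_pct=float(pct.median()),
        range_pct=(float(pct.min()), float(pct.max())),
        crosstab=crosstab,
    )
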