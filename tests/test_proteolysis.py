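"""Coverage scores, EM mixture deconvolution, FDR thresholds, 2-of-3 rule."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from immunopep.model import PeptideRecord, ProteomeDB
from immunopep.proteolysis import (
    MixtureFit,
    ScoreTriple,
    ThresholdSet,
    classify_proteolytic,
    fdr_threshold,
    fit_gaussian_mixture,
    fit_thresholds,
    mixture_fdr,
    nonligand_propensity,
    peptide_coverage_ratio,
    protein_coverage_ratio,
    proteolysis_report,
    score_sample,
)
from immunopep.pwm import DEFAULT_ALLOTYPE_LIBRARY, PWMPredictor

from conftest import make_cohort, make_sample


def _proteome(**seqs) -> ProteomeDB:
    db = ProteomeDB()
    for acc, seq in seqs.items():
        db[acc] = seq
    return db


def _rec(seq: str, acc: str = "P1") -> PeptideRecord:
    return PeptideRecord(sequence=seq, source_proteins=(acc,))


class TestCoverageRatios:
    def setup_method(self):
        rng = np.random.default_rng(123)
        # a 100-mer with distinctive 10-mers at fixed offsets
        self.protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        self.db = _proteome(P1=self.protein)

    def test_single_peptide_protein_coverage(self):
        pep = _rec(self.protein[0:10])
        assert protein_coverage_ratio(pep, [pep], self.db) == pytest.approx(0.10)

    def test_two_disjoint_peptides(self):
        a, b = _rec(self.protein[0:10]), _rec(self.protein[50:60])
        for pep in (a, b):
            assert protein_coverage_ratio(pep, [a, b], self.db) == pytest.approx(0.20)

    def test_overlapping_peptides_union(self):
        # offsets 1 and 6 (1-based): union covers positions 1-15
        a, b = _rec(self.protein[0:10]), _rec(self.protein[5:15])
        assert protein_coverage_ratio(a, [a, b], self.db) == pytest.approx(0.15)

    def test_lone_peptide_has_zero_peptide_coverage(self):
        pep = _rec(self.protein[0:10])
        assert peptide_coverage_ratio(pep, [pep], self.db) == 0.0

    def test_nested_peptide_fully_covered(self):
        inner, outer = _rec(self.protein[2:10]), _rec(self.protein[0:14])
        assert peptide_coverage_ratio(inner, [inner, outer], self.db) == pytest.approx(1.0)

    def test_half_overlap(self):
        a, b = _rec(self.protein[0:10]), _rec(self.protein[5:15])
        assert peptide_coverage_ratio(a, [a, b], self.db) == pytest.approx(0.5)

    def test_unplaceable_peptide_errors(self):
        stray = PeptideRecord(sequence="W" * 12, source_proteins=("P1",))
        with pytest.raises(ValueError, match="not a substring"):
            protein_coverage_ratio(stray, [stray], self.db)

    def test_scores_invariant_to_accession_renaming_and_order(self):
        a, b = _rec(self.protein[0:10]), _rec(self.protein[5:15])
        base = peptide_coverage_ratio(a, [a, b], self.db)
        renamed_db = _proteome(ZZZ=self.protein)
        a2 = _rec(self.protein[0:10], "ZZZ")
        b2 = _rec(self.protein[5:15], "ZZZ")
        assert peptide_coverage_ratio(a2, [b2, a2], renamed_db) == pytest.approx(base)

    def test_adding_nested_copy_never_decreases_peptide_coverage(self):
        a, b = _rec(self.protein[0:10]), _rec(self.protein[5:15])
        before = peptide_coverage_ratio(a, [a, b], self.db)
        nested = _rec(self.protein[0:14])
        after = peptide_coverage_ratio(a, [a, b, nested], self.db)
        assert after >= before


class TestNonligandPropensity:
    def test_perfect_ligand_scores_zero(self):
        assert nonligand_propensity("AAAA", ["X"], predictor=lambda s, a: 1.0) == 0.0

    def test_nonligand_scores_one(self):
        assert nonligand_propensity("AAAA", ["X", "Y"], predictor=lambda s, a: 0.0) == 1.0

    def test_no_allotypes_errors(self):
        with pytest.raises(ValueError):
            nonligand_propensity("AAAA", [])

    def test_motif_peptides_score_below_shuffled(self):
        rng = np.random.default_rng(42)
        predictor = PWMPredictor()
        pwm = DEFAULT_ALLOTYPE_LIBRARY["A*02"]
        motif_scores, shuffled_scores = [], []
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(100):
            core = rng.choice(residues, size=9)
            core[1], core[-1] = "L", "V"  # A*02 anchors
            pep = "".join(core)
            motif_scores.append(nonligand_propensity(pep, ["A*02"], predictor))
            shuffled = "".join(rng.permutation(list(pep)))
            shuffled_scores.append(nonligand_propensity(shuffled, ["A*02"], predictor))
        assert np.mean(motif_scores) < np.mean(shuffled_scores)


class TestGaussianMixtureEM:
    def test_recovers_planted_mixture(self):
        rng = np.random.default_rng(7)
        n = 5000
        hot = rng.random(n) < 0.1
        x = np.where(hot, rng.normal(4, 0.5, n), rng.normal(0, 1, n))
        fit = fit_gaussian_mixture(x, seed=0)
        assert fit.converged
        assert fit.weights[0] == pytest.approx(0.9, abs=0.05)
        assert fit.means[0] == pytest.approx(0.0, abs=0.1)
        assert fit.means[1] == pytest.approx(4.0, abs=0.1)
        assert fit.sds[0] == pytest.approx(1.0, abs=0.1)
        assert fit.sds[1] == pytest.approx(0.5, abs=0.1)

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        for data in (
            rng.normal(0, 1, 200),
            np.concatenate([rng.normal(0, 1, 100), rng.normal(3, 0.3, 50)]),
            rng.exponential(1.0, 150),
        ):
            fit = fit_gaussian_mixture(data)
            h = np.array(fit.loglik_history)
            assert np.all(np.diff(h) >= -1e-7)

    def test_identical_values_collapse_without_crash(self):
        fit = fit_gaussian_mixture(np.full(25, 3.3))
        assert fit.collapsed
        assert not fit.converged

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            fit_gaussian_mixture([1.0] * 9)

    def test_matches_multi_restart_reference(self):
        """Independent reference: sklearn EM with 50 random restarts."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 120), rng.normal(5, 0.7, 60)])
        ours = fit_gaussian_mixture(x, seed=0)
        ref = GaussianMixture(
            n_components=2, n_init=50, random_state=0, tol=1e-8, reg_covar=1e-10
        ).fit(x.reshape(-1, 1))
        ref_loglik = float(ref.score(x.reshape(-1, 1))) * x.size
        assert ours.loglik >= ref_loglik - 1e-3


class TestFdrThreshold:
    def _fit(self, w=(0.5, 0.5), mu=(0.0, 10.0), sd=(1.0, 1.0)) -> MixtureFit:
        return MixtureFit(weights=w, means=mu, sds=sd, loglik=0.0, n_iter=1, converged=True)

    def test_matches_dense_grid_oracle(self):
        fit = self._fit()
        t = fdr_threshold(fit, 0.05)
        grid = np.linspace(-6, 16, 2_000_001)
        fdr = (0.5 * norm.sf(grid, 0, 1)) / (
            0.5 * norm.sf(grid, 0, 1) + 0.5 * norm.sf(grid, 10, 1)
        )
        oracle = grid[np.argmax(fdr <= 0.05)]
        assert abs(t - oracle) < 1e-3
        assert t == pytest.approx(1.62, abs=0.01)

    def test_alpha_one_gives_negative_infinity(self):
        assert fdr_threshold(self._fit(), 1.0) == float("-inf")

    def test_no_positive_component_gives_infinity(self):
        assert fdr_threshold(self._fit(w=(1.0, 0.0)), 0.05) == float("inf")

    def test_nonconverged_fit_errors(self):
        bad = MixtureFit(
            weights=(0.5, 0.5), means=(0, 1), sds=(1, 1),
            loglik=0.0, n_iter=1, converged=False,
        )
        with pytest.raises(ValueError):
            fdr_threshold(bad, 0.05)

    def test_empirical_fdr_near_alpha_at_large_n(self):
        fit = self._fit()
        t = fdr_threshold(fit, 0.05)
        rng = np.random.default_rng(11)
        n = 50_000
        hot = rng.random(n) < 0.5
        x = np.where(hot, rng.normal(10, 1, n), rng.normal(0, 1, n))
        called = x > t
        emp = float((~hot & called).sum() / called.sum())
        assert emp == pytest.approx(0.05, abs=0.02)

    def test_mixture_fdr_decreasing_between_modes(self):
        fit = self._fit()
        ts = np.linspace(0.0, 10.0, 50)
        vals = [mixture_fdr(fit, t) for t in ts]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestTwoOfThreeRule:
    def test_all_exceedance_patterns(self):
        """Brute force over the 2^3 exceedance patterns: proteolytic exactly
        for {110, 101, 011, 111}."""
        tset = ThresholdSet(
            thresholds={
                "protein_coverage": 0.5,
                "peptide_coverage": 0.5,
                "nonligand_propensity": 0.5,
            },
            fdr_level=0.05,
            fits={},
        )
        for pattern in itertools.product([0, 1], repeat=3):
            scores = ScoreTriple(*(0.9 if f else 0.1 for f in pattern))
            [call] = classify_proteolytic({"PEP": scores}, tset)
            assert call.exceed_flags == tuple(bool(f) for f in pattern)
            assert call.is_proteolytic == (sum(pattern) >= 2)

    def test_strict_inequality_at_threshold(self):
        tset = ThresholdSet(
            thresholds={
                "protein_coverage": 0.5,
                "peptide_coverage": 0.5,
                "nonligand_propensity": 0.5,
            },
            fdr_level=0.05,
            fits={},
        )
        [call] = classify_proteolytic({"PEP": ScoreTriple(0.5, 0.5, 0.5)}, tset)
        assert call.exceed_flags == (False, False, False)
        assert not call.is_proteolytic


class TestReport:
    def test_percent_and_crosstab(self):
        sample = make_sample({"R1": ["AAAW", "CCCW", "DDDW", "EEEW"]})
        cohort = make_cohort([sample])
        tset = ThresholdSet(
            thresholds={
                "protein_coverage": 0.5,
                "peptide_coverage": 0.5,
                "nonligand_propensity": 0.5,
            },
            fdr_level=0.05,
            fits={},
        )
        triples = {
            "AAAW": ScoreTriple(0.9, 0.9, 0.9),
            "CCCW": ScoreTriple(0.1, 0.1, 0.1),
            "DDDW": ScoreTriple(0.1, 0.1, 0.1),
            "EEEW": ScoreTriple(0.1, 0.1, 0.1),
        }
        calls = classify_proteolytic(triples, tset)
        report = proteolysis_report(cohort, {"S1": calls})
        assert report.median_pct == pytest.approx(25.0)
        assert report.crosstab["proteolytic_nonligand"] == 1
        assert report.crosstab["retained_nonligand"] == 3

    def test_empty_sample_excluded_with_warning(self):
        s1 = make_sample({"R1": ["AAAW"]}, sample_id="S1")
        s2 = make_sample({"R1": ["CCCW"]}, sample_id="S2")
        cohort = make_cohort([s1, s2])
        tset = ThresholdSet(
            thresholds={
                "protein_coverage": 0.5,
                "peptide_coverage": 0.5,
                "nonligand_propensity": 0.5,
            },
            fdr_level=0.05,
            fits={},
        )
        calls = classify_proteolytic({"AAAW": ScoreTriple(0, 0, 0)}, tset)
        with pytest.warns(UserWarning, match="S2"):
            report = proteolysis_report(cohort, {"S1": calls})
        assert list(report.per_sample["sample_id"]) == ["S1"]


class TestEndToEndClassifier:
    def test_recall_and_fdr_on_planted_ladders(self, artifact_cohort):
        """Planted ladder artifacts are recovered at low false-discovery cost
        on the 10-sample synthetic cohort."""
        _, tumor, proteome, truth = artifact_cohort
        recalls = []
        n_false = n_called = 0
        for sample in tumor.samples:
            triples = score_sample(sample, proteome)
            tset = fit_thresholds(triples, alpha=0.05, seed=0)
            calls = classify_proteolytic(triples, tset)
            artifacts = truth.artifact_set(sample.sample_id)
            called = {c.peptide for c in calls if c.is_proteolytic}
            tp = len(called & artifacts)
            recalls.append(tp / len(artifacts))
            n_called += len(called)
            n_false += len(called) - tp
        assert float(np.median(recalls)) >= 0.6
        assert n_false / n_called <= 0.15
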