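"""Benign reference assembly, exclusivity, frequencies, overlap statistics."""

from __future__ import annotations

import numpy as np
import pytest

from immunopep.model import PeptideRecord
from immunopep.profiling import (
    BenignReference,
    FilterRule,
    build_benign_reference,
    donor_tissue_overlap,
    frequency_display_filter,
    allotype_frequencies,
    presentation_frequencies,
    reference_from_cohort,
    replicate_overlap,
    taa_rejection_report,
    tumor_exclusive,
)

from conftest import make_cohort, make_sample


def _ref(identities, name="ref", il=False) -> BenignReference:
    return BenignReference(
        name=name,
        identities=set(identities),
        provenance={i: {name} for i in identities},
        il_collapsed=il,
    )


class TestBenignReference:
    def test_binder_whitelist_filters(self):
        datasets = {
            "atlas": [
                PeptideRecord(sequence="AAAW", binder_annotations={"A*02": "strong"}),
                PeptideRecord(sequence="CCCW", binder_annotations={"A*02": "weak"}),
            ]
        }
        rules = {"atlas": FilterRule(binder_whitelist=frozenset({"strong", "medium"}))}
        ref = build_benign_reference(datasets, rules)
        assert ref.identities == {"AAAW"}

    def test_shared_peptide_gets_both_provenance_tags(self):
        datasets = {
            "ds1": [PeptideRecord(sequence="AAAW")],
            "ds2": [PeptideRecord(sequence="AAAW"), PeptideRecord(sequence="CCCW")],
        }
        ref = build_benign_reference(datasets, {})
        assert ref.identities == {"AAAW", "CCCW"}
        assert ref.provenance["AAAW"] == {"ds1", "ds2"}

    def test_empty_post_filter_warns(self):
        datasets = {"ds": [PeptideRecord(sequence="AAAW")]}
        rules = {"ds": FilterRule(binder_whitelist=frozenset({"strong"}))}
        with pytest.warns(UserWarning, match="ds"):
            ref = build_benign_reference(datasets, rules)
        assert ref.identities == set()

    def test_metadata_filter_missing_column_errors(self):
        datasets = {"ds": [PeptideRecord(sequence="AAAW")]}
        rules = {"ds": FilterRule(column_equals={"disease": "healthy"})}
        with pytest.raises(KeyError, match="disease"):
            build_benign_reference(datasets, rules)


class TestTumorExclusive:
    def _tumor(self):
        return make_cohort(
            [make_sample({"R1": ["PEPTA", "PEPTC", "PEPTD"]}, sample_id="T1")],
            name="tumor",
        )

    def test_split(self):
        result = tumor_exclusive(self._tumor(), _ref(["PEPTC"]))
        assert result.exclusive == {"PEPTA", "PEPTD"}
        assert set(result.rejected) == {"PEPTC"}
        assert result.rejected["PEPTC"] == {"ref"}

    def test_reference_superset_empties_exclusive(self):
        result = tumor_exclusive(self._tumor(), _ref(["PEPTA", "PEPTC", "PEPTD", "EXTRA"]))
        assert result.exclusive == set()

    def test_inconsistent_il_flags_error(self):
        with pytest.raises(ValueError, match="I/L"):
            tumor_exclusive(self._tumor(), _ref(["PEPTC"], il=True))

    def test_enlarging_reference_never_enlarges_exclusive(self):
        small = tumor_exclusive(self._tumor(), _ref(["PEPTC"]))
        big = tumor_exclusive(self._tumor(), _ref(["PEPTC", "PEPTA"]))
        assert big.exclusive <= small.exclusive

    def test_exclusive_and_rejected_partition_union(self):
        result = tumor_exclusive(self._tumor(), _ref(["PEPTC", "ZZZZ"]))
        union = self._tumor().peptide_union()
        assert result.exclusive | set(result.rejected) == union
        assert result.exclusive & set(result.rejected) == set()


class TestPresentationFrequencies:
    def test_half_cohort(self):
        samples = [
            make_sample({"R1": ["PEPTA"]}, sample_id=f"S{i}") for i in range(11)
        ] + [make_sample({"R1": ["CCCW"]}, sample_id=f"S{i + 11}") for i in range(11)]
        cohort = make_cohort(samples)
        [rec] = presentation_frequencies(["PEPTA"], cohort)
        assert rec.n_positive == 11 and rec.n_total == 22
        assert rec.frequency == pytest.approx(0.50)

    def test_ubiquitous_peptide(self):
        cohort = make_cohort(
            [make_sample({"R1": ["PEPTA"]}, sample_id=f"S{i}") for i in range(4)]
        )
        [rec] = presentation_frequencies(["PEPTA"], cohort)
        assert rec.frequency == 1.0

    def test_ordering_deterministic(self):
        cohort = make_cohort(
            [
                make_sample({"R1": ["AAAW", "CCCW"]}, sample_id="S1"),
                make_sample({"R1": ["AAAW"]}, sample_id="S2"),
            ]
        )
        recs = presentation_frequencies(["CCCW", "AAAW"], cohort)
        assert [r.peptide for r in recs] == ["AAAW", "CCCW"]


class TestAllotypeFrequencies:
    def test_restricted_denominator(self):
        samples = [
            make_sample({"R1": ["PEPTA"]}, sample_id=f"A{i}", typing=("A*02",))
            for i in range(4)
        ] + [
            make_sample({"R1": ["CCCW"]}, sample_id=f"B{i}", typing=("B*07",))
            for i in range(6)
        ]
        cohort = make_cohort(samples)
        records, n_excl = allotype_frequencies(["PEPTA"], cohort, {"PEPTA": ["A*02"]})
        assert n_excl == 0
        [rec] = records
        assert rec.allotype_frequencies["A*02"] == (4, 4, pytest.approx(1.0))
        assert rec.frequency == pytest.approx(0.4)  # cohort-wide 4/10

    def test_uncarried_allotype_flagged(self):
        cohort = make_cohort([make_sample({"R1": ["PEPTA"]}, typing=("A*02",))])
        [rec], _ = allotype_frequencies(["PEPTA"], cohort, {"PEPTA": ["B*57"]})
        n_pos, n_matched, f = rec.allotype_frequencies["B*57"]
        assert (n_pos, n_matched) == (0, 0)
        assert np.isnan(f)

    def test_unassigned_peptides_counted(self):
        cohort = make_cohort([make_sample({"R1": ["PEPTA", "CCCW"]})])
        records, n_excl = allotype_frequencies(["PEPTA", "CCCW"], cohort, {})
        assert records == []
        assert n_excl == 2


class TestDisplayFilter:
    def _rec(self, f, pep="PEPTA"):
        from immunopep.profiling import FrequencyRecord

        return FrequencyRecord(
            peptide=pep, n_positive=int(f * 100), n_total=100, frequency=f
        )

    def test_boundary_retained_below_dropped(self):
        records = [self._rec(0.04, "LOWPEP"), self._rec(0.05, "EDGEPEP"), self._rec(0.5, "HIPEP")]
        kept = frequency_display_filter(records, min_f=0.05)
        assert [r.peptide for r in kept] == ["HIPEP", "EDGEPEP"]

    def test_counts_conserved(self):
        records = [self._rec(f, p) for f, p in [(0.01, "A"), (0.05, "B"), (0.9, "C")]]
        kept = frequency_display_filter(records)
        dropped = [r for r in records if r not in kept]
        assert len(kept) + len(dropped) == len(records)


class TestReplicateOverlap:
    def test_exact_counts(self):
        sample = make_sample({"R1": ["AAAW", "CCCW"], "R2": ["AAAW"], "R3": ["AAAW", "DDDW"]})
        frac = replicate_overlap(sample)
        assert frac[3] == pytest.approx(1 / 3)
        assert frac[1] == pytest.approx(2 / 3)
        assert frac[2] == 0.0
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_identical_replicates(self):
        sample = make_sample({"R1": ["AAAW"], "R2": ["AAAW"], "R3": ["AAAW"]})
        assert replicate_overlap(sample)[3] == 1.0

    def test_matches_binomial_closed_form(self):
        """Detection probability p per replicate, conditioned on >=1
        detection: fraction seen in all 3 replicates ~ p^3 / (1-(1-p)^3)."""
        rng = np.random.default_rng(17)
        p = 0.8
        reps: dict[str, list[str]] = {"R1": [], "R2": [], "R3": []}
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        peptides = [
            "".join(alphabet[(i // 20 ** k) % 20] for k in range(4)) + "AAAAA"
            for i in range(2000)
        ]
        for pep in peptides:
            hits = rng.random(3) < p
            if not hits.any():
                continue
            for rep, hit in zip(reps, hits):
                if hit:
                    reps[rep].append(pep)
        frac = replicate_overlap(make_sample(reps))
        expected = p ** 3 / (1 - (1 - p) ** 3)
        assert frac[3] == pytest.approx(expected, abs=0.04)


class TestDonorTissueOverlap:
    def test_disjoint_tissues(self):
        s1 = make_sample({"R1": ["AAAW"]}, sample_id="S1", donor_id="D1", tissue="liver")
        s2 = make_sample({"R1": ["CCCW"]}, sample_id="S2", donor_id="D1", tissue="lung")
        out = donor_tissue_overlap(make_cohort([s1, s2]))
        assert out["D1"].fraction_single_tissue == 1.0
        assert out["D1"].fraction_all_tissues == 0.0

    def test_identical_tissues(self):
        s1 = make_sample({"R1": ["AAAW"]}, sample_id="S1", donor_id="D1")
        s2 = make_sample({"R1": ["AAAW"]}, sample_id="S2", donor_id="D1")
        out = donor_tissue_overlap(make_cohort([s1, s2]))
        assert out["D1"].fraction_single_tissue == 0.0
        assert out["D1"].fraction_all_tissues == 1.0

    def test_shared_core_bookkeeping(self):
        core = ["AAAW", "CCCW"]
        s1 = make_sample({"R1": core + ["DDDW"]}, sample_id="S1", donor_id="D1")
        s2 = make_sample({"R1": core + ["EEEW"]}, sample_id="S2", donor_id="D1")
        s3 = make_sample({"R1": core}, sample_id="S3", donor_id="D1")
        out = donor_tissue_overlap(make_cohort([s1, s2, s3]))
        # union = 4 peptides: 2 in all three, 2 in exactly one
        assert out["D1"].fraction_all_tissues == pytest.approx(0.5)
        assert out["D1"].fraction_single_tissue == pytest.approx(0.5)
        assert out["D1"].pairwise.loc["S1", "S2"] == 2

    def test_single_sample_donor_skipped(self):
        s1 = make_sample({"R1": ["AAAW"]}, sample_id="S1", donor_id="D1")
        with pytest.warns(UserWarning, match="D1"):
            out = donor_tissue_overlap(make_cohort([s1]))
        assert out == {}


class TestTAARejection:
    def test_forty_percent_rejected(self):
        taas = [f"PEPT{aa}" for aa in "ACDEFGHIKL"]  # 10 TAAs
        ref = _ref(taas[:4])
        report = taa_rejection_report(taas, ref)
        assert report.percent_rejected == pytest.approx(40.0)
        assert report.table["rejected"].sum() == 4

    def test_none_rejected(self):
        report = taa_rejection_report(["PEPTA"], _ref(["ZZZZ"]))
        assert report.percent_rejected == 0.0

    def test_order_invariance(self):
        taas = [f"PEPT{aa}" for aa in "ACDEFGHIKL"]
        ref = _ref(taas[:3])
        a = taa_rejection_report(taas, ref).percent_rejected
        b = taa_rejection_report(list(reversed(taas)), ref).percent_rejected
        assert a == b


class TestEndToEndRecovery:
    def test_planted_truth_recovered(self, small_cohorts):
        _, benign, tumor, _, truth = small_cohorts
        reference = reference_from_cohort(benign)
        result = tumor_exclusive(tumor, reference)
        planted = {p["sequence"] for p in truth.planted if p["n_samples_planted"] > 0}
        assert planted <= result.exclusive
        # planted peptides never occur in benign
        assert not (planted & reference.identities)
        # observed frequencies equal the planted counts exactly
        for plant in truth.planted:
            [rec] = presentation_frequencies([plant["sequence"]], tumor)
            assert rec.n_positive == len(plant["planted_in"])
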