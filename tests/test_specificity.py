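"""Diplotype frequencies and mutant-specificity fractions."""

import numpy as np
import pandas as pd
import pytest

from pascrispr import (
    PamSite,
    PasRecord,
    Variant,
    assign_haplotypes,
    build_pam_map,
    consensus_alleles,
    diplotype_frequencies,
    mutant_specificity,
    scan_cds_pas,
    subject_eligibility,
)


def toy_subjects():
    rows = (
        [("hapA", "hapB")] * 5 + [("hapB", "hapA")] * 3 + [("hapA", "hapA")] * 2
    )
    return pd.DataFrame(rows, columns=["mutant_hap", "normal_hap"])


def pam_map_from(presence: dict[str, bool], pas_id="p1"):
    return pd.DataFrame({pas_id: pd.Series(presence)})


class TestDiplotypeFrequencies:
    def test_counting(self):
        table = diplotype_frequencies(toy_subjects())
        freqs = {(r.mutant_hap, r.normal_hap): r.frequency
                 for r in table.itertuples(index=False)}
        assert freqs == {("hapA", "hapB"): 0.5, ("hapB", "hapA"): 0.3, ("hapA", "hapA"): 0.2}

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no subjects"):
            diplotype_frequencies(pd.DataFrame(columns=["mutant_hap", "normal_hap"]))

    def test_unassigned_subjects_excluded(self):
        df = pd.concat([toy_subjects(),
                        pd.DataFrame([("unassigned", "hapA")],
                                     columns=["mutant_hap", "normal_hap"])])
        table = diplotype_frequencies(df)
        assert table["frequency"].sum() == pytest.approx(1.0)
        table_raw = diplotype_frequencies(df, renormalize=False)
        assert table_raw["frequency"].sum() == pytest.approx(10 / 11)

    def test_matches_product_of_planted_haplotype_freqs(self, config, population):
        """Diplotype frequencies follow the product of haplotype frequencies
        (mutant and normal chromosomes are drawn independently)."""
        table = diplotype_frequencies(population.subjects)
        names = config.haplotype_names()
        h8 = names[-1]
        q = config.haplotype_freqs[-1]
        expected = q * q
        got = float(table.loc[(table["mutant_hap"] == h8) & (table["normal_hap"] == h8),
                              "frequency"].sum())
        se = np.sqrt(expected * (1 - expected) / config.n_subjects)
        assert abs(got - expected) <= 3 * se


class TestMutantSpecificity:
    def test_cellwise_sums(self):
        table = diplotype_frequencies(toy_subjects())
        pam_map = pam_map_from({"hapA": True, "hapB": False})
        rep = mutant_specificity(table, pam_map, "p1")
        assert rep.as_dict() == pytest.approx(
            {"mutant_only": 0.5, "normal_only": 0.3, "both": 0.2, "neither": 0.0}
        )
        assert rep.eligible_diplotypes == [("hapA", "hapB")]

    def test_pam_on_all_haplotypes(self):
        table = diplotype_frequencies(toy_subjects())
        pam_map = pam_map_from({"hapA": True, "hapB": True})
        rep = mutant_specificity(table, pam_map, "p1")
        assert rep.fraction_both == pytest.approx(1.0)
        assert rep.fraction_mutant_only == 0.0

    def test_single_absent_haplotype_structure(self):
        """When exactly one haplotype H lacks the PAM, the eligible set is
        precisely {(m, H): m != H} -- the rs363099-like structure where the
        PAM is missing from the most common normal haplotype."""
        haps = [f"h{i}" for i in range(5)]
        rows = [(m, n) for m in haps for n in haps]
        df = pd.DataFrame(rows, columns=["mutant_hap", "normal_hap"])
        table = diplotype_frequencies(df)
        pam_map = pam_map_from({h: h != "h4" for h in haps})
        rep = mutant_specificity(table, pam_map, "p1")
        assert set(rep.eligible_diplotypes) == {(m, "h4") for m in haps if m != "h4"}

    def test_missing_haplotype_raises(self):
        table = diplotype_frequencies(toy_subjects())
        with pytest.raises(KeyError, match="hapB"):
            mutant_specificity(table, pam_map_from({"hapA": True}), "p1")

    def test_fractions_sum_to_one_and_monotonicity(self):
        rng = np.random.default_rng(5)
        haps = [f"h{i}" for i in range(4)]
        # h1..h3 occur only on the normal side
        df = pd.DataFrame(
            {"mutant_hap": ["h0"] * 300, "normal_hap": rng.choice(haps, size=300)}
        )
        table = diplotype_frequencies(df)
        presence = dict.fromkeys(haps, True)
        prev = 0.0
        # removing the PAM from one more normal-side haplotype never
        # decreases the mutant-only fraction
        for h in haps[1:]:
            presence[h] = False
            rep = mutant_specificity(table, pam_map_from(presence), "p1")
            assert sum(rep.as_dict().values()) == pytest.approx(1.0)
            assert rep.fraction_mutant_only >= prev - 1e-12
            prev = rep.fraction_mutant_only


def eligibility_record():
    v = Variant("c", 10, "G", "A", id="p1")
    return PasRecord(v, frozenset({PamSite(9, 12, "+", "c")}), frozenset(), "ref_generating")


class TestSubjectEligibility:
    def test_call_definitions(self):
        rec = eligibility_record()
        phased = pd.DataFrame(
            {"mutant_allele": ["G", "A", "G", "A"], "normal_allele": ["A", "G", "G", "A"]}
        )
        calls, _ = subject_eligibility(phased, rec)
        assert list(calls) == ["mutant_only", "normal_only", "both", "neither"]

    def test_planted_cohort_fractions_recovered_exactly(self):
        """A cohort built with 28.5% mutant-only and 2.8% normal-only
        subjects is reported at exactly those fractions."""
        rec = eligibility_record()
        n = 1000
        rows = ([("G", "A")] * 285 + [("A", "G")] * 28 + [("G", "G")] * 400
                + [("A", "A")] * 287)
        phased = pd.DataFrame(rows, columns=["mutant_allele", "normal_allele"])
        _, rep = subject_eligibility(phased, rec)
        assert rep.fraction_mutant_only == pytest.approx(0.285)
        assert rep.fraction_normal_only == pytest.approx(0.028)
        assert rep.n_subjects == n

    def test_missing_phase_raises(self):
        rec = eligibility_record()
        phased = pd.DataFrame({"mutant_allele": ["G", None], "normal_allele": ["A", "A"]})
        with pytest.raises(ValueError, match="missing phased allele"):
            subject_eligibility(phased, rec)

    def test_consistent_with_diplotype_route(self, clean_config, clean_gene,
                                             clean_population):
        """With zero within-haplotype noise every chromosome carries its
        haplotype's consensus allele, so the subject-level and the
        diplotype-weighted routes agree exactly."""
        pop = clean_population
        records, _ = scan_cds_pas(clean_gene.all_variants, clean_gene.sequence,
                                  clean_gene.transcript)
        labels = assign_haplotypes(pop.genotypes, pop.definitions)
        poly = records[clean_config.polymorphic_pas_index]
        cons = consensus_alleles(labels, pop.genotypes, [r.variant.id for r in records])
        pam_map = build_pam_map(cons, records)
        table = diplotype_frequencies(pop.subjects)
        rep_diplo = mutant_specificity(table, pam_map, poly.variant.id)

        per_subject = pop.genotypes.subject_alleles(poly.variant.id)
        mutant_is_b = pop.subjects["mutant_chrom"].to_numpy() == "B"
        phased = pd.DataFrame(
            {
                "mutant_allele": np.where(mutant_is_b, per_subject["hapB"],
                                          per_subject["hapA"]),
                "normal_allele": np.where(mutant_is_b, per_subject["hapA"],
                                          per_subject["hapB"]),
            }
        )
        _, rep_subject = subject_eligibility(phased, poly)
        for key, value in rep_diplo.as_dict().items():
            assert rep_subject.as_dict()[key] == pytest.approx(value, abs=1e-12)
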