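"""Substrate classification, domain preference, profiles, cleavage deduction."""

import pytest

from cpdpep.classify_specificity import (
    SubstrateCall,
    build_profile,
    call_domain_preference,
    classify_substrate,
    deduce_cleavage,
    drop_excluded,
)
from cpdpep.peptide_chem import Peptide, parse_peptide
from cpdpep.quantify import RatioProfile
from cpdpep.reference_data import Ratio, parse_ratio

TITRATION = ["r_0.1nM", "r_1nM", "r_10nM", "r_100nM"]  # increasing enzyme


def profile_from_values(values, conds=TITRATION, peptide="QQAAALAK"):
    return RatioProfile(
        peptide=parse_peptide(peptide),
        ratios={c: v if isinstance(v, Ratio) else Ratio(v) for c, v in zip(conds, values)},
        control_condition="0nM",
    )


class TestClassifySubstrate:
    @pytest.mark.parametrize(
        "values, category",
        [
            ((1.08, 1.05, 0.84, 0.40), "good"),   # boundary: 0.40 is good
            ((1.0, 1.0, 0.9, 0.54), "weak"),
            ((1.0, 1.0, 1.0, 0.80), "weak"),      # boundary: 0.80 is weak
            ((1.0, 1.0, 1.0, 1.0), "non"),
            ((1.0, 1.0, 1.0, 0.81), "non"),
            ((1.0, 1.3, 1.9, 2.6), "product"),
        ],
    )
    def test_threshold_boundaries(self, values, category):
        call = classify_substrate(profile_from_values(values), TITRATION)
        assert call.category == category

    def test_product_requires_monotone_rise(self):
        call = classify_substrate(profile_from_values((2.5, 0.6, 1.0, 1.6)), TITRATION)
        assert call.category != "product"

    def test_unquantifiable_propagates(self):
        rp = RatioProfile(
            peptide=Peptide("QQAAALAK"), ratios={}, control_condition="0nM",
            quantifiable=False,
        )
        assert classify_substrate(rp, TITRATION).category == "unquantifiable"

    def test_dose_consistency_flag(self):
        good = classify_substrate(
            profile_from_values((1.08, 1.05, 0.84, 0.10)), TITRATION
        )
        assert good.dose_consistent
        bumpy = classify_substrate(
            profile_from_values((0.5, 1.6, 0.9, 0.10)), TITRATION
        )
        assert not bumpy.dose_consistent

    def test_all_reference_good_substrates_classified_good(
        self, tryptic_good_table, hek_good_table
    ):
        """Every row of the two good-substrate titration tables is called good."""
        for table in (tryptic_good_table, hek_good_table):
            for _, row in table.iterrows():
                rp = profile_from_values(
                    [parse_ratio(row[c]) for c in TITRATION],
                    peptide=row["sequence"],
                )
                assert classify_substrate(rp, TITRATION).category == "good", row[
                    "sequence"
                ]

    def test_domain_experiment_rows_split_good_weak(self, domain_table):
        """The single-concentration comparison table contains only good
        (ratio <= 0.40) and weak (0.40-0.80) substrates of the full enzyme."""
        for _, row in domain_table.iterrows():
            r = parse_ratio(row["r_rhcpd"])
            rp = RatioProfile(
                peptide=parse_peptide(row["sequence"]),
                ratios={"rhCPD": r},
                control_condition="double_mutant",
            )
            call = classify_substrate(rp, ["rhCPD"])
            expected = "good" if r.value <= 0.40 else "weak"
            assert call.category == expected, row["sequence"]


class TestDomainPreference:
    def _profile(self, row):
        return RatioProfile(
            peptide=parse_peptide(row["sequence"]),
            ratios={
                "rhCPD": parse_ratio(row["r_rhcpd"]),
                "domain_I_active": parse_ratio(row["r_domain_i_active"]),
                "domain_II_active": parse_ratio(row["r_domain_ii_active"]),
            },
            control_condition="double_mutant",
        )

    def test_reference_calls(self, domain_table):
        expected = {
            "VDPVNFK": "domain_II_preferential",
            "LVNELTEFAK": "domain_II_preferential",
            "LRVDPVNFK": "domain_II_preferential",
            "LVTDLTK": "domain_II_preferential",
            "KQTALVELLK": "domain_II_preferential",
            "GQEFTITGQKR": "domain_I_preferential",
            "FAATSFR": "domain_I_preferential",
            "VVLQDR": "shared",
            "AFLGTVR": "shared",
        }
        rows = {row["sequence"]: row for _, row in domain_table.iterrows()}
        for seq, want in expected.items():
            pref = call_domain_preference(self._profile(rows[seq]))
            assert pref.call == want, seq

    def test_censoring_propagation(self, domain_table):
        rows = {row["sequence"]: row for _, row in domain_table.iterrows()}
        # censored-low numerator -> "<0.10"; censored-low denominator -> ">5.00"
        assert str(call_domain_preference(self._profile(rows["FAATSFR"])).dI_dII_ratio) == "<0.10"
        assert str(call_domain_preference(self._profile(rows["VDPVNFK"])).dI_dII_ratio) == ">5.00"

    def test_missing_condition_named(self):
        rp = RatioProfile(
            peptide=Peptide("VDPVNFK"),
            ratios={"domain_I_active": Ratio(1.0)},
            control_condition="double_mutant",
        )
        with pytest.raises(ValueError, match="domain_II_active"):
            call_domain_preference(rp)

    def test_double_censor_indeterminate(self):
        rp = RatioProfile(
            peptide=Peptide("VDPVNFK"),
            ratios={
                "domain_I_active": Ratio(0.10, censor="low"),
                "domain_II_active": Ratio(0.10, censor="low"),
            },
            control_condition="double_mutant",
        )
        pref = call_domain_preference(rp)
        assert pref.indeterminate and pref.call == "shared"


class TestProfiles:
    def test_good_substrate_p1prime_counts(self, tryptic_good_table):
        """C-terminal residue tally of the 13 good tryptic substrates: K=11, R=2."""
        calls = [
            (parse_peptide(s), SubstrateCall(category="good"))
            for s in tryptic_good_table["sequence"]
        ]
        prof = build_profile(calls, "P1'")
        assert prof.count("K", "good") == 11
        assert prof.count("R", "good") == 2
        assert prof.total() == 13

    def test_p1_restricted_to_permissive_cterm(self):
        calls = [
            (Peptide("AAFK"), SubstrateCall(category="good")),
            (Peptide("AASR"), SubstrateCall(category="weak")),
            (Peptide("AAGF"), SubstrateCall(category="non")),  # F C-terminus excluded
        ]
        prof = build_profile(calls, "P1")
        assert prof.count("F", "good") == 1
        assert prof.count("S", "weak") == 1
        assert prof.total() == 2

    def test_p1_total_never_exceeds_kr_terminated(self, tryptic_good_table):
        calls = [
            (parse_peptide(s), SubstrateCall(category="good"))
            for s in tryptic_good_table["sequence"]
        ]
        p1 = build_profile(calls, "P1")
        n_kr = sum(1 for s in tryptic_good_table["sequence"] if s[-1] in "KR")
        assert p1.total() <= n_kr

    def test_empty_profile(self):
        assert build_profile([], "P1'").total() == 0


class TestCleavageDeduction:
    def test_hemoglobin_product(self, precursor_index):
        hits = deduce_cleavage("LRVDPVNF", precursor_index)
        assert len(hits) == 1
        assert hits[0].precursor_name == "alpha-Hemoglobin"
        assert hits[0].cleaved_residue == "K"
        assert not hits[0].ambiguous

    def test_site_coordinates_consistent(self, precursor_index):
        hit = deduce_cleavage("LRVDPVNF", precursor_index)[0]
        prec = precursor_index[hit.precursor_name]
        assert prec[hit.site - 1] == hit.cleaved_residue
        assert prec[hit.site - 1 - len("LRVDPVNF") : hit.site - 1] == "LRVDPVNF"

    def test_full_precursor_has_no_downstream_residue(self):
        with pytest.raises(ValueError):
            deduce_cleavage("AAKGG", {"p": "AAKGG"})

    def test_repeated_occurrence_flagged_ambiguous(self):
        hits = deduce_cleavage("AGL", {"p": "AGLKAGLR"})
        assert len(hits) == 2
        assert all(h.ambiguous for h in hits)
        assert {h.cleaved_residue for h in hits} == {"K", "R"}

    def test_not_found_raises(self):
        with pytest.raises(ValueError):
            deduce_cleavage("WWWW", {"p": "AAK"})


def test_drop_excluded_removes_cys_tyr_his():
    peptides = [Peptide("AAK"), Peptide("ACK"), Peptide("AYR"), Peptide("AHR")]
    kept = drop_excluded(peptides)
    assert [p.sequence for p in kept] == ["AAK"]
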