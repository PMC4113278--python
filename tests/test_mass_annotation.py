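"""Formula parsing, monoisotopic masses, adduct m/z and peak annotation."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from netpharm.constants import MONOISOTOPIC_MASS, PROTON_MASS
from netpharm.mass_annotation import (
    ElementalFormula,
    FormulaError,
    annotate_peak,
    adduct_mz,
    format_mz,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
)


class TestParseFormula:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("C_18_H_20_O_5", {"C": 18, "H": 20, "O": 5}),
            ("C18H20O5", {"C": 18, "H": 20, "O": 5}),
            ("CO", {"C": 1, "O": 1}),
            ("CH3COO", {"C": 2, "H": 3, "O": 2}),
            ("C18H19NO4", {"C": 18, "H": 19, "N": 1, "O": 4}),
            ("Na Cl".replace("Cl", "H"), {"Na": 1, "H": 1}),
        ],
    )
    def test_parses_with_implicit_counts_and_underscores(self, text, expected):
        assert parse_formula(text).element_counts == expected

    @pytest.mark.parametrize("bad", ["C18H20Q5", "", "18C", "C0H2", "Cx3"])
    def test_rejects_malformed_input(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    def test_error_names_offending_token(self):
        with pytest.raises(FormulaError, match="Q"):
            parse_formula("C18H20Q5")

    @given(
        st.dictionaries(
            st.sampled_from(sorted(MONOISOTOPIC_MASS)),
            st.integers(min_value=1, max_value=99),
            min_size=1,
            max_size=5,
        )
    )
    def test_parse_serialize_roundtrip_is_idempotent(self, counts):
        formula = ElementalFormula.from_counts(counts)
        assert parse_formula(str(formula)) == formula
        assert str(parse_formula(str(formula))) == str(formula)


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "counts, expected_5dp",
        [
            ({"H": 2, "O": 1}, 18.01056),
            ({"C": 18, "H": 20, "O": 5}, 316.13107),
        ],
    )
    def test_frozen_hand_checked_sums(self, counts, expected_5dp):
        assert round(monoisotopic_mass(counts), 5) == expected_5dp

    def test_empty_formula_weighs_nothing(self):
        assert monoisotopic_mass({}) == 0.0

    @given(
        st.dictionaries(
            st.sampled_from(sorted(MONOISOTOPIC_MASS)),
            st.integers(min_value=1, max_value=50),
            min_size=1,
            max_size=4,
        ),
        st.dictionaries(
            st.sampled_from(sorted(MONOISOTOPIC_MASS)),
            st.integers(min_value=1, max_value=50),
            min_size=1,
            max_size=4,
        ),
    )
    def test_mass_is_additive_over_compositions(self, a, b):
        fa = ElementalFormula.from_counts(a)
        fb = ElementalFormula.from_counts(b)
        combined = monoisotopic_mass(fa + fb)
        assert combined == pytest.approx(
            monoisotopic_mass(fa) + monoisotopic_mass(fb), abs=1e-9
        )


class TestAdductMz:
    @pytest.mark.parametrize(
        "formula, adduct, expected",
        [
            ("C18H20O5", "[M+H]+", 317.13835),
            ("C18H19NO4", "[M+H]+", 314.13868),
            ("C15H14O5", "[M-H]-", 273.07685),
            ("C16H16O3", "[M+H]+", 257.11722),
            ("C16H16O3", "[M-H]-", 255.10267),
            ("C14H12O3", "[M+H]+", 229.08592),
        ],
    )
    def test_reproduces_published_expected_mz_at_5dp(
        self, formula, adduct, expected
    ):
        assert format_mz(adduct_mz(formula, adduct)) == f"{expected:.5f}"

    @given(
        st.dictionaries(
            st.sampled_from(sorted(MONOISOTOPIC_MASS)),
            st.integers(min_value=1, max_value=60),
            min_size=1,
            max_size=5,
        )
    )
    def test_protonated_deprotonated_gap_is_two_protons(self, counts):
        formula = ElementalFormula.from_counts(counts)
        gap = adduct_mz(formula, "[M+H]+") - adduct_mz(formula, "[M-H]-")
        assert gap == pytest.approx(2 * PROTON_MASS, abs=1e-9)

    def test_unknown_adduct_is_rejected(self):
        with pytest.raises(KeyError):
            adduct_mz("C6H6", "[M+NH4]+")


class TestPpmError:
    def test_identity_is_zero(self):
        assert ppm_error(317.13835, 317.13835) == 0.0

    @pytest.mark.parametrize(
        "measured, expected, ppm",
        [(317.13839, 317.13835, 0.126), (227.07154, 227.07137, 0.749)],
    )
    def test_direct_formula_values(self, measured, expected, ppm):
        assert round(ppm_error(measured, expected), 3) == ppm

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)


class TestAnnotatePeak:
    def test_retains_matching_candidate_with_correct_adduct(self):
        anns = annotate_peak(
            317.13839, "positive", [(27, "C18H20O5", True)]
        )
        assert len(anns) == 1
        assert anns[0].adduct == "[M+H]+"
        assert abs(anns[0].ppm_error) <= 5.0

    def test_rejects_grossly_wrong_candidate(self):
        anns = annotate_peak(
            317.13839, "positive", [(48, "C30H50O", True)]
        )
        assert anns == []

    def test_previously_reported_isomer_ranks_first(self):
        anns = annotate_peak(
            229.08608,
            "positive",
            [("b", "C14H12O3", False), ("a", "C14H12O3", True)],
        )
        assert [a.compound_id for a in anns] == ["a", "b"]
        assert anns[0].previously_reported

    def test_result_invariant_under_candidate_permutation(self):
        candidates = [
            ("x", "C14H12O3", False),
            ("y", "C14H12O3", True),
            ("z", "C15H14O2", False),
        ]
        baseline = annotate_peak(229.08608, "positive", candidates)
        for permuted in itertools.permutations(candidates):
            assert annotate_peak(
                229.08608, "positive", list(permuted)
            ) == baseline

    def test_isotope_hook_can_veto(self):
        anns = annotate_peak(
            317.13839,
            "positive",
            [(27, "C18H20O5", True)],
            isotope_filter=lambda ann: False,
        )
        assert anns == []


class TestReferenceTableRoundTrip:
    def test_named_conventional_ions_reannotate_to_printed_formula(
        self, reference_peaks
    ):
        """Measured m/z of identified ions recover their own formula.

        Rows whose printed expected m/z does not correspond to one of
        the four standard adducts (ammonium adducts, anion-composition
        rows) are outside the adduct model and skipped.
        """
        # the prev flag lives on the first ion row of each compound
        prev_by_no = (
            reference_peaks.dropna(subset=["previously_reported"])
            .set_index("no")["previously_reported"]
            .to_dict()
        )
        named = reference_peaks[
            reference_peaks["no"].map(prev_by_no).eq("yes")
            & reference_peaks["formula"].notna()
        ]
        # candidate pool: every distinct identified formula
        identified = reference_peaks[
            reference_peaks["previously_reported"] == "yes"
        ]
        candidates = [
            (row["no"], row["formula"], True)
            for _, row in identified.iterrows()
        ]
        checked = 0
        for _, row in named.iterrows():
            measured = float(row["mz_measured"])
            polarity = row["polarity"].strip().lower()
            formula = row["formula"]
            best = min(
                (
                    abs(ppm_error(measured, adduct_mz(formula, adduct)))
                    for adduct in (
                        ["[M+H]+", "[M+Na]+"]
                        if polarity == "positive"
                        else ["[M-H]-", "[M+CH3COO]-"]
                    )
                ),
            )
            if best > 5.0:
                continue  # not a conventional-adduct ion
            anns = annotate_peak(measured, polarity, candidates)
            assert anns, f"no annotation for row {row['no']}"
            # accept exact-isobar ties: e.g. [M-H]- of a formula and
            # [M+CH3COO]- of the formula minus C2H4O2 share one m/z
            matches = [
                a
                for a in anns
                if str(a.formula) == str(parse_formula(formula))
                and abs(a.expected_mz - anns[0].expected_mz) < 1e-6
            ]
            assert matches, f"row {row['no']} misannotated"
            checked += 1
        assert checked >= 25  # both polarity rows of most named compounds
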