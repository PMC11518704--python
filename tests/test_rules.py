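"""Diagnostic fragmentation rulebase: coverage, enumeration, scoring."""

import pytest

from phytoscreen.chem import IonSpecies, get_loss, ion_mz, parse_formula, ppm_error
from phytoscreen.rules import (
    COMPOUND_CLASSES,
    Tolerances,
    builtin_rulebase,
    expected_fragments,
    score_class,
)

from reference_values import FRAGMENT_LADDERS, fragment_matches


class _FakeSpectrum:
    def __init__(self, mzs):
        self.peaks = tuple((m, 1.0) for m in mzs)


class TestBuiltinRulebase:
    def test_every_class_has_a_rule(self, rulebase):
        assert set(rulebase) == set(COMPOUND_CLASSES)

    def test_losses_resolve_in_vocabulary(self, rulebase):
        for rule in rulebase.values():
            for entry in rule.entries:
                for name in entry.losses:
                    get_loss(name)  # raises on unknown

    def test_anthraquinone_loss_families(self, rulebase):
        chains = {e.losses for e in rulebase["anthraquinone"].entries}
        assert ("CH3",) in chains
        assert ("CO",) in chains
        assert ("CO2",) in chains
        assert ("CO", "CO2") in chains

    def test_coumarin_lactone_chains(self, rulebase):
        chains = {e.losses for e in rulebase["coumarin"].entries}
        assert {("CO",), ("CO2",), ("CO", "CO"), ("CO", "CO2")} <= chains

    def test_phenylethanoid_glycoside_residues(self, rulebase):
        alphabet = set(rulebase["phenylethanoid_glycoside"].loss_alphabet())
        assert {"caffeoyl", "Rha", "Glc", "H2O"} <= alphabet
        assert get_loss("caffeoyl").mass == pytest.approx(162.0317, abs=5e-4)
        assert get_loss("Rha").mass == pytest.approx(146.0579, abs=5e-4)
        assert get_loss("Glc").mass == pytest.approx(162.0528, abs=5e-4)


class TestExpectedFragments:
    def test_depth_zero_is_precursor_only(self, rulebase):
        f = parse_formula("C15H10O5")
        exp = expected_fragments(f, IonSpecies("[M-H]-"), rulebase["anthraquinone"], 0)
        loss_frags = [e for e in exp if e.kind == "loss"]
        assert loss_frags == []
        assert exp[0].kind == "precursor"
        assert exp[0].mz == pytest.approx(269.0455, abs=5e-4)

    def test_emodin_co_and_co2_losses(self, rulebase):
        f = parse_formula("C15H10O5")
        exp = expected_fragments(f, IonSpecies("[M-H]-"), rulebase["anthraquinone"], 2)
        mzs = [e.mz for e in exp]
        assert any(abs(ppm_error(241.0506, m)) <= 10 for m in mzs)
        assert any(abs(ppm_error(225.0557, m)) <= 10 for m in mzs)

    def test_geniposidic_acid_glycoside_then_decarboxylation(self, rulebase):
        f = parse_formula("C16H22O10")
        exp = expected_fragments(f, IonSpecies("[M-H]-"), rulebase["iridoid"], 2)
        by_path = {e.losses: e.mz for e in exp}
        assert by_path[("Glc",)] == pytest.approx(211.0612, abs=0.002)
        assert by_path[("Glc", "CO2")] == pytest.approx(167.0714, abs=0.002)

    def test_unsubtractable_losses_pruned(self, rulebase):
        # no nitrogen: amino-acid NH3 chains must be pruned, not raised
        f = parse_formula("C15H10O5")
        exp = expected_fragments(f, IonSpecies("[M-H]-"), rulebase["amino_acid"], 3)
        assert all("NH3" not in e.losses for e in exp)

    def test_no_duplicate_fragment_compositions(self, rulebase):
        f = parse_formula("C27H30O16")
        exp = expected_fragments(f, IonSpecies("[M-H]-"), rulebase["flavonol"], 3)
        forms = [e.formula for e in exp if e.kind != "product"]
        assert len(forms) == len(set(forms))

    @pytest.mark.parametrize(
        "name,formula,species,cls,fragments,depth", FRAGMENT_LADDERS
    )
    def test_reference_ladders_reproduced(
        self, rulebase, name, formula, species, cls, fragments, depth
    ):
        """Every observed product ion of the worked examples appears in
        the rule-expanded fragment list at printed precision."""
        exp = expected_fragments(
            parse_formula(formula), IonSpecies(species), rulebase[cls], depth
        )
        for obs in fragments:
            assert any(
                fragment_matches(obs, e.mz) for e in exp
            ), f"{name}: fragment {obs} not generated by the {cls} rule"


class TestScoreClass:
    def _emodin_entry_mzs(self, rulebase):
        f = parse_formula("C15H10O5")
        sp = IonSpecies("[M-H]-")
        prec = ion_mz(f, sp)
        rule = rulebase["anthraquinone"]
        from phytoscreen.rules import ion_formula

        ion = ion_formula(f, sp)
        return [
            prec - e.total_mass()
            for e in rule.entries
            if ion.subtract(e.total_formula()) is not None
        ]

    def test_all_applicable_entries_matched_scores_one(self, rulebase):
        mzs = self._emodin_entry_mzs(rulebase)
        score, hits = score_class(
            _FakeSpectrum(mzs),
            parse_formula("C15H10O5"),
            IonSpecies("[M-H]-"),
            rulebase["anthraquinone"],
        )
        assert score == 1.0
        assert len(hits) == len(mzs)

    def test_partial_ladder_scores_weight_fraction(self, rulebase):
        # CO, CO2 and CO+CO2 matched out of 7 applicable equal-weight entries
        score, hits = score_class(
            _FakeSpectrum([241.0506, 225.0557, 197.0608]),
            parse_formula("C15H10O5"),
            IonSpecies("[M-H]-"),
            rulebase["anthraquinone"],
        )
        assert score == pytest.approx(3 / 7)
        assert len(hits) == 3

    def test_wrong_class_scores_zero(self, rulebase):
        # anthraquinone ladder vs amino-acid rule: no applicable entry matches
        score, hits = score_class(
            _FakeSpectrum([241.0506, 225.0557, 197.0608]),
            parse_formula("C15H10O5"),
            IonSpecies("[M-H]-"),
            rulebase["amino_acid"],
        )
        assert score == 0.0
        assert hits == []

    def test_empty_spectrum_warns_and_scores_zero(self, rulebase):
        with pytest.warns(UserWarning):
            score, hits = score_class(
                _FakeSpectrum([]),
                parse_formula("C15H10O5"),
                IonSpecies("[M-H]-"),
                rulebase["anthraquinone"],
            )
        assert score == 0.0

    def test_adding_matched_peak_never_decreases_score(self, rulebase):
        mzs = self._emodin_entry_mzs(rulebase)
        f = parse_formula("C15H10O5")
        sp = IonSpecies("[M-H]-")
        rule = rulebase["anthraquinone"]
        prev = 0.0
        for k in range(1, len(mzs) + 1):
            score, _ = score_class(_FakeSpectrum(mzs[:k]), f, sp, rule)
            assert score >= prev
            prev = score

    def test_deterministic(self, rulebase):
        args = (
            _FakeSpectrum([241.0506, 225.0557]),
            parse_formula("C15H10O5"),
            IonSpecies("[M-H]-"),
            rulebase["anthraquinone"],
        )
        assert score_class(*args) == score_class(*args)

    def test_hits_carry_ppm_within_tolerance(self, rulebase):
        score, hits = score_class(
            _FakeSpectrum([241.0506]),
            parse_formula("C15H10O5"),
            IonSpecies("[M-H]-"),
            rulebase["anthraquinone"],
            Tolerances(fragment_ppm=10.0),
        )
        assert all(abs(h.ppm) <= 10.0 for h in hits)
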