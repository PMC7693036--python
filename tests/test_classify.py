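"""The rule engine: functional, spectral and cyclase calls, conservation."""

import pytest
from hypothesis import given, strategies as st

from modrhod import classify, io
from modrhod.classify import CyclaseClass, FunctionalClass, SpectralClass
from modrhod.records import (
    AMINO_ACIDS,
    BR_SCHEME,
    CHR2_SCHEME,
    GAP,
    MISSING,
    ResidueTableRow,
    ValidationError,
)


def chr2_row(entry_id, acceptor, donor, dc, stab, attach, **kw):
    return ResidueTableRow(
        entry_id=entry_id,
        scheme_name="ChR2",
        role_residues={
            "proton_acceptor": (acceptor, None),
            "proton_donor": (donor, None),
            "dc_gate": (dc, None),
            "stabilizer": (stab, None),
            "retinal_attachment": (attach, None),
        },
        **kw,
    )


def br_row(entry_id, residues, **kw):
    roles = [kp.role for kp in BR_SCHEME.key_positions]
    return ResidueTableRow(
        entry_id=entry_id,
        scheme_name="BR",
        role_residues={r: (res, None) for r, res in zip(roles, residues)},
        **kw,
    )


@pytest.fixture(scope="module")
def table1b():
    return io.load_fixture("table1B")


@pytest.fixture(scope="module")
def table2b_rows():
    _, rows = io.load_fixture("table2B")
    return rows


class TestChannelRule:

    def test_all_published_channel_rows_are_channel_competent(self, table1b):
        _, rows = table1b
        for row in rows:
            call = classify.classify_channel(row)
            assert call.functional_class is FunctionalClass.CHANNEL_COMPETENT
            assert all(call.evidence.values())

    def test_dc_gate_mutation_breaks_competence(self, table1b):
        _, rows = table1b
        knrh3 = next(r for r in rows if r.entry_id == "KnRh3")
        mutated = chr2_row("KnRh3_C126T", "D", "D", "T", "R", "K")
        assert knrh3.residue("dc_gate") == "C"
        call = classify.classify_channel(mutated)
        assert call.functional_class is FunctionalClass.SENSORY_ATYPICAL
        assert call.evidence["dc_gate"] is False

    def test_lost_attachment_lysine_is_non_retinylidene(self):
        call = classify.classify_channel(chr2_row("x", "D", "D", "C", "R", "R"))
        assert call.functional_class is FunctionalClass.NON_RETINYLIDENE

    def test_glutamate_acceptor_also_accepted(self):
        call = classify.classify_channel(chr2_row("x", "E", "D", "C", "R", "K"))
        assert call.functional_class is FunctionalClass.CHANNEL_COMPETENT

    def test_wrong_scheme_rejected(self):
        row = br_row("x", list("DTTDEEDK"))
        with pytest.raises(ValidationError):
            classify.classify_channel(row)


class TestPumpRule:
    def test_asrh4_is_pump_competent(self, table2b_rows):
        asrh4 = next(r for r in table2b_rows if r.entry_id == "AsRh4")
        call = classify.classify_pump(asrh4)
        assert call.functional_class is FunctionalClass.PUMP_COMPETENT
        # proton-release residues are evidence only: AsRh4 has Gly at 194
        assert call.evidence["proton_release_194"] is False

    def test_br_reference_row_is_pump_competent(self, table2b_rows):
        br = next(r for r in table2b_rows if r.entry_id == "BR")
        assert classify.classify_pump(br).functional_class is FunctionalClass.PUMP_COMPETENT

    def test_cop6_is_sensory_atypical(self, table2b_rows):
        cop6 = next(r for r in table2b_rows if r.entry_id == "Cop6")
        call = classify.classify_pump(cop6)
        assert call.functional_class is FunctionalClass.SENSORY_ATYPICAL
        assert not call.evidence["proton_acceptor"]
        assert not call.evidence["proton_donor"]
        assert not call.evidence["counterion"]

    def test_asrh4_unique_among_modular_entries(self, table2b_rows):
        modular = io.modular_rows(table2b_rows)
        pumps = [
            r.entry_id
            for r in modular
            if classify.classify_pump(r).functional_class is FunctionalClass.PUMP_COMPETENT
        ]
        assert pumps == ["AsRh4"]

    def test_rule_engine_is_pure(self, table2b_rows):
        row = next(r for r in table2b_rows if r.entry_id == "Cop5")
        first = classify.classify_pump(row).to_dict()
        for other in table2b_rows:
            classify.classify_pump(other)
        assert classify.classify_pump(row).to_dict() == first


class TestSpectralRule:
    @pytest.mark.parametrize(
        "residue, expected",
        [
            ("L", SpectralClass.GREEN),
            ("I", SpectralClass.GREEN),
            ("M", SpectralClass.GREEN),
            ("Q", SpectralClass.BLUE),
            ("D", SpectralClass.UNKNOWN),
            ("K", SpectralClass.UNKNOWN),
            (GAP, SpectralClass.UNSCORED),
            (MISSING, SpectralClass.UNSCORED),
        ],
    )
    def test_examples(self, residue, expected):
        assert classify.classify_spectral(residue) is expected

    @given(st.sampled_from(AMINO_ACIDS))
    def test_total_over_valid_residues(self, residue):
        result = classify.classify_spectral(residue)
        assert result is not SpectralClass.UNSCORED

    def test_invalid_code_rejected(self):
        with pytest.raises(ValidationError):
            classify.classify_spectral("Z")

    def test_agrees_with_every_published_spectral_cell(self):
        _, rows = io.load_fixture("table3")
        for row in rows:
            call = classify.classify_spectral(row.residue("spectral_tuning"))
            assert call.value.lower() == row.meta["shift"].lower(), row.entry_id


class TestCyclaseRule:
    def test_fixture_calls(self):
        _, rows = io.load_fixture("cyclase_synthetic")
        calls = {r.entry_id: classify.classify_cyclase(r) for r in rows}
        assert calls["CanonicalGC"] is CyclaseClass.ACTIVE
        assert calls["Cop5"] is CyclaseClass.DEGENERATE
        assert calls["Vop5"] is CyclaseClass.DEGENERATE

    def test_missing_domain_row_is_not_applicable(self):
        assert classify.classify_cyclase(None) is CyclaseClass.NOT_APPLICABLE


class TestConservation:
    @pytest.mark.parametrize(
        "position, residues, expected",
        [
            (85, "DE", 14),
            (85, "Q", 17),
            (212, "N", 6),
            (204, "E", 25),
            (216, "K", 46),
        ],
    )
    def test_published_counts(self, table2b_rows, position, residues, expected):
        result = classify.tabulate_conservation(table2b_rows, position, set(residues))
        assert result.count == expected
        assert result.denominator == 46

    def test_exhaustive_residue_set_counts_non_missing(self, table2b_rows):
        full = classify.tabulate_conservation(table2b_rows, 85, set(AMINO_ACIDS))
        assert full.count == full.denominator == 46

    def test_missing_cells_stay_in_denominator_but_never_count(self, table2b_rows):
        result = classify.tabulate_conservation(
            table2b_rows, 204, set(AMINO_ACIDS)
        )
        assert result.denominator == 46
        assert result.count == 43  # Cop6, Vop6, GpRh3 print no residue at 204

    def test_unknown_position_rejected(self, table2b_rows):
        with pytest.raises(KeyError):
            classify.tabulate_conservation(table2b_rows, 100, {"D"})


class TestAnnotate:
    def test_channel_fixture_yields_three_modular_channel_calls(self):
        scheme, rows = io.load_fixture("table1B")
        calls = classify.annotate_rows(io.modular_rows(rows), scheme)
        assert [c.functional_class for c in calls] == [FunctionalClass.CHANNEL_COMPETENT] * 3

    def test_sensory_fixture_yields_single_pump_call(self):
        scheme, rows = io.load_fixture("table2B")
        calls = classify.annotate_rows(io.modular_rows(rows), scheme)
        pumps = [c.entry_id for c in calls if c.functional_class is FunctionalClass.PUMP_COMPETENT]
        assert pumps == ["AsRh4"]

    def test_empty_input_empty_report(self):
        assert classify.annotate_rows([], BR_SCHEME) == []

    def test_spectral_and_cyclase_joined_into_call(self):
        scheme, rows = io.load_fixture("table2B")
        _, spectral = io.load_fixture("table3")
        _, cyclase = io.load_fixture("cyclase_synthetic")
        calls = classify.annotate_rows(
            io.modular_rows(rows),
            scheme,
            spectral_residues={r.entry_id: r.residue("spectral_tuning") for r in spectral},
            cyclase_rows={r.entry_id: r for r in cyclase if not r.is_reference},
        )
        by_id = {c.entry_id: c for c in calls}
        assert by_id["Cop5"].spectral_class is SpectralClass.GREEN
        assert by_id["Cop5"].cyclase_class is CyclaseClass.DEGENERATE
        assert by_id["Cop6"].cyclase_class is CyclaseClass.ACTIVE
        assert by_id["AsRh4"].cyclase_class is CyclaseClass.NOT_APPLICABLE
        assert by_id["GtRh1"].spectral_class is SpectralClass.UNKNOWN
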