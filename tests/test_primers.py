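"""Primer design: regeneration of published arrays, counter/overlap rules,
tags and outer primers."""

import warnings

import pytest

from midaskit.construct import resolve_target_region, substitution
from midaskit.fixtures import (
    D108_ARRAY,
    L560_ARRAY,
    MIDAS_MM_TAG,
    PRINTED_PRIMERS,
)
from midaskit.primers import (
    DesignConstraints,
    design_counter_primer,
    design_mutagenic_primer,
    design_outer_primers,
    design_saturation_array,
    generate_tag,
    longest_shared_substring,
    validate_tag,
)
from midaskit.seqcore import reverse_complement

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="module")
def d108_tr(d108_unit):
    return resolve_target_region(d108_unit, 108)


@pytest.fixture(scope="module")
def l560_tr(l560_unit):
    return resolve_target_region(l560_unit, 560)


class TestArrayRegeneration:
    """The tool must reproduce the printed saturation arrays byte-for-byte
    from the reconstructed local templates and the printed flank lengths."""

    def test_d108_forward_primers(self, d108_unit, d108_tr):
        arr = design_saturation_array(d108_unit, d108_tr, flank5=19, flank3=19)
        assert len(arr) == 20
        for p in arr:
            aa = p.payload_label[-1]
            assert p.display == D108_ARRAY.primers[aa]
            assert p.name == f"NanoLuc-D108{aa}-F"

    def test_d108_counter_primer(self, d108_unit, d108_tr):
        cp = design_counter_primer(d108_unit, d108_tr, length=19)
        assert cp.display == PRINTED_PRIMERS["NanoLuc-D108-R"]
        assert cp.name == "NanoLuc-D108-R"

    def test_l560_forward_primers(self, l560_unit, l560_tr):
        arr = design_saturation_array(l560_unit, l560_tr, flank5=21, flank3=30)
        for p in arr:
            aa = p.payload_label[-1]
            assert p.display == L560_ARRAY.primers[aa]
            assert p.display == PRINTED_PRIMERS[f"ACh NeuBI-L560{aa}-F"]

    def test_l560_counter_primer(self, l560_unit, l560_tr):
        cp = design_counter_primer(l560_unit, l560_tr, length=21)
        assert cp.display == PRINTED_PRIMERS["ACh NeuBI-L560-R"]

    def test_w_misprint_flagged_not_reproduced(self):
        # the printed W member drops one template base; the fixture stores
        # the regularized sequence and flags the discrepancy
        assert D108_ARRAY.typo_aas == ("W",)
        assert D108_ARRAY.verbatim["W"] != D108_ARRAY.primers["W"]
        assert len(D108_ARRAY.verbatim["W"]) == len(D108_ARRAY.primers["W"]) - 1
        assert L560_ARRAY.typo_aas == ()


class TestMutagenicPrimer:
    def test_identity_payload_equals_template_slice(self, d108_unit, d108_tr):
        p = design_mutagenic_primer(
            d108_unit, d108_tr, substitution({108: "D"}), flank5=19, flank3=19
        )
        s = d108_unit.sequence
        assert p.sequence == s[d108_tr.span.start - 19 : d108_tr.span.end + 19]

    def test_reverse_orientation_mirror(self, d108_unit, d108_tr):
        f = design_mutagenic_primer(
            d108_unit, d108_tr, substitution({108: "N"}), "forward", flank5=19, flank3=19
        )
        r = design_mutagenic_primer(
            d108_unit, d108_tr, substitution({108: "N"}), "reverse", flank5=19, flank3=19
        )
        assert r.sequence == reverse_complement(f.sequence)
        assert r.role == "R mutagenic"

    def test_auto_flanks_within_bounds_or_flagged(self, unit):
        tr = resolve_target_region(unit, 120)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arr = design_saturation_array(unit, tr)
        for p in arr:
            if not p.tm_extended:
                assert 18 <= p.flank5 <= 24 and 18 <= p.flank3 <= 24
            assert p.flank5 <= 40 and p.flank3 <= 40

    def test_array_members_share_flanks(self, unit):
        tr = resolve_target_region(unit, 120)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arr = design_saturation_array(unit, tr)
        f5 = {p.sequence[: p.flank5] for p in arr}
        f3 = {p.sequence[-p.flank3 :] for p in arr}
        assert len(f5) == 1 and len(f3) == 1
        # only the 3-nt payload differs
        assert len({len(p.sequence) for p in arr}) == 1

    def test_unreachable_tm_errors(self, unit):
        tr = resolve_target_region(unit, 120)
        tight = DesignConstraints(flank_hard_max=19, tm_window=(95.0, 99.0))
        with pytest.raises(ValueError, match="unreachable"):
            design_mutagenic_primer(unit, tr, substitution({120: "A"}), constraints=tight)


class TestCounterPrimer:
    def test_counter_rc_prefixes_every_sibling(self, d108_unit, d108_tr):
        arr = design_saturation_array(d108_unit, d108_tr, flank5=19, flank3=19)
        cp = design_counter_primer(d108_unit, d108_tr, length=19)
        for p in arr:
            assert p.sequence.startswith(reverse_complement(cp.sequence))

    def test_overlap_tm_recorded(self, d108_unit, d108_tr):
        cp = design_counter_primer(d108_unit, d108_tr, length=19)
        assert cp.overlap_tm is not None and cp.overlap_tm > 0

    def test_auto_length_hits_window_floor(self, unit):
        tr = resolve_target_region(unit, 150)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cp = design_counter_primer(unit, tr)
        assert cp.overlap_tm >= 60.0


class TestTags:
    def test_fixture_tag_unique_on_synthetic_template(self, unit):
        spec = validate_tag(MIDAS_MM_TAG, unit)
        assert spec.passed and spec.longest_shared < 12

    def test_planted_collision_detected(self, unit):
        tag = unit.sequence[300:323].lower()
        spec = validate_tag(tag, unit)
        assert not spec.passed and spec.longest_shared == 23

    def test_zero_tolerance_always_fails(self, unit):
        spec = validate_tag(MIDAS_MM_TAG, unit, stringency=0)
        assert not spec.passed  # some short substring is always shared

    def test_short_tag_rejected(self, unit):
        with pytest.raises(ValueError, match="15"):
            validate_tag("ACGTACGTACGT", unit)

    def test_generated_tag_deterministic_and_unique(self, unit):
        a = generate_tag(unit, seed=7)
        b = generate_tag(unit, seed=7)
        assert a.sequence == b.sequence
        # exhaustive substring scan: no exact match of 12 nt or more
        assert longest_shared_substring(a.sequence, unit.sequence) < 12
        gc = sum(a.sequence.count(b) for b in "GC") / len(a.sequence)
        assert 0.40 <= gc <= 0.60


class TestOuterPrimers:
    def test_monotemplated_fo_starts_with_tag(self, unit):
        out = design_outer_primers(
            unit, mode="monotemplated", tag_policy="fo", tags={"fo": MIDAS_MM_TAG}
        )
        assert out["Fo"].sequence.startswith(MIDAS_MM_TAG.upper())
        assert out["Fo_nested"].sequence == MIDAS_MM_TAG.upper()
        assert "Ro_nested" not in out

    def test_polytemplated_has_no_tags(self, unit):
        out = design_outer_primers(unit, mode="polytemplated")
        assert out["Fo"].tag is None and out["Ro"].tag is None
        assert "Fo_nested" not in out and "Ro_nested" not in out

    def test_both_policy_emits_two_nested(self, unit):
        out = design_outer_primers(unit, mode="monotemplated", tag_policy="both", seed=3)
        assert out["Fo_nested"].sequence == out["Fo"].tag.upper()
        assert out["Ro_nested"].sequence == out["Ro"].tag.upper()
        assert out["Fo"].tag != out["Ro"].tag

    def test_colliding_supplied_tag_rejected(self, unit):
        bad = unit.sequence[500:523]
        with pytest.raises(ValueError, match="collides"):
            design_outer_primers(
                unit, mode="monotemplated", tag_policy="fo", tags={"fo": bad}
            )

    def test_anneal_positions(self, unit):
        out = design_outer_primers(unit, mode="polytemplated")
        assert out["Fo"].anneal_span.start == unit.promoter.start
        assert out["Ro"].anneal_span.end == unit.polya.end
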