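"""Assembly plans, plate layout, in-silico PCR and overlap extension."""

import warnings

import pytest

from midaskit.assembly import (
    enumerate_variants,
    layout_plates,
    overlap_assemble,
    pcr,
    plan_assembly,
    simulate_secondary,
    wells,
)
from midaskit.construct import resolve_target_region, substitution, SubstitutionSet
from midaskit.fixtures import MIDAS_MM_TAG
from midaskit.seqcore import reverse_complement, translate

from conftest import saturation_sets


@pytest.fixture(autouse=True)
def _quiet_tm_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="module")
def two_tr_sets(unit):
    return saturation_sets(unit, (100, 220), ("ACDEFG", "HIKLMN"))


class TestEnumerateVariants:
    def test_counts(self, two_tr_sets):
        combos, n = enumerate_variants(two_tr_sets)
        assert n == 36 and len(combos) == 36

    def test_empty_product_is_parent(self):
        combos, n = enumerate_variants([])
        assert n == 1 and combos == [()]

    def test_deterministic_declared_order(self, two_tr_sets):
        combos, _ = enumerate_variants(two_tr_sets)
        labels = [tuple(p.label for p in c) for c in combos]
        assert len(set(labels)) == 36
        # leftmost TR varies slowest, payloads in declared order
        assert labels[0] == (
            two_tr_sets[0].payloads[0].label, two_tr_sets[1].payloads[0].label
        )
        assert labels[1][0] == labels[0][0]
        assert [l[0] for l in labels[::6]] == [p.label for p in two_tr_sets[0].payloads]


class TestPlanCounts:
    def test_per_segment_two_tr(self, unit, two_tr_sets):
        plan = plan_assembly(unit, two_tr_sets, scheme="per-segment")
        c = plan.counts
        assert c["segments"] == 3  # i + 1 segments for i = 2 TRs
        assert c["constant_primaries"] == 1
        assert c["mutagenic_primaries"] == 12  # 6 + 6
        assert c["secondary_reactions"] == 36

    def test_per_permutation_two_tr(self, unit, two_tr_sets):
        plan = plan_assembly(unit, two_tr_sets, scheme="per-permutation")
        c = plan.counts
        assert c["mutagenic_primaries"] == 36  # one primary per permutation
        assert c["secondary_reactions"] == 36  # one-to-one
        assert c["constant_primaries"] == 2

    def test_single_tr_single_variant(self, unit):
        sets = saturation_sets(unit, (100,), ("A",))
        plan = plan_assembly(unit, sets, scheme="per-segment")
        assert plan.counts["segments"] == 2
        assert plan.counts["secondary_reactions"] == 1

    def test_overlapping_trs_rejected(self, unit):
        tr = resolve_target_region(unit, 100, 101)
        s = SubstitutionSet(tr, (substitution({100: "A"}),))
        with pytest.raises(ValueError, match="overlap"):
            plan_assembly(unit, [s, s])

    def test_close_trs_merged(self, unit):
        # adjacent codons 100 and 102 cannot carry independent primer pairs;
        # they merge into one TR-spanning payload set
        sets = saturation_sets(unit, (100, 102), ("AC", "DE"))
        plan = plan_assembly(unit, sets)
        assert len(plan.substitution_sets) == 1
        assert plan.counts["secondary_reactions"] == 4
        assert plan.counts["segments"] == 2

    def test_tr_near_end_rejected(self, unit):
        sets = saturation_sets(unit, (1,), ("A",))
        # residue 1 sits right at the CDS start but far from the template
        # start; fabricate a TR close to the template end instead
        from midaskit.construct import TargetRegion, Span

        tr = TargetRegion(0, 1, 1, Span(len(unit.sequence) - 15, len(unit.sequence) - 12))
        s = SubstitutionSet(tr, (substitution({1: "A"}),))
        with pytest.raises(ValueError, match="close to template ends"):
            plan_assembly(unit, [s])


class TestPlateLayout:
    def test_36_on_one_plate(self):
        layout = layout_plates([f"v{i}" for i in range(36)], plate_size=96)
        assert len(layout.plates) == 1
        filled = layout.plates[0][1]
        assert set(filled) == set(wells(96)[:36])  # A1..C12 row-major
        assert len(set(filled.values())) == 36  # injective

    def test_400_needs_five_plates(self):
        layout = layout_plates([f"v{i}" for i in range(400)], plate_size=96)
        assert len(layout.plates) == 5
        assert len(layout.plates[-1][1]) == 16
        assert layout.n_assigned == 400

    def test_empty_layout(self):
        layout = layout_plates([], plate_size=96)
        assert layout.plates == () and layout.n_assigned == 0

    def test_controls_in_last_wells(self):
        layout = layout_plates(["a", "b"], controls=("parent", "no-template"))
        wm = layout.plates[-1][1]
        assert wm["H11"] == "parent" and wm["H12"] == "no-template"

    def test_384_grid(self):
        layout = layout_plates([f"v{i}" for i in range(400)], plate_size=384)
        assert len(layout.plates) == 2
        assert "P24" in wells(384)

    def test_bad_plate_size(self):
        with pytest.raises(ValueError):
            layout_plates(["a"], plate_size=48)


class TestInSilicoPcr:
    def test_simple_amplicon(self):
        t = "AAAA" + "ACGTACGTACGTACGTCCCG" + "T" * 40 + "GGGCATCATCATCATCATCA" + "TTTT"
        f = "ACGTACGTACGTACGTCCCG"
        r = reverse_complement("GGGCATCATCATCATCATCA")
        prods = pcr([t], f, r)
        assert prods == [t[4:-4]]

    def test_tagged_primer_carried_into_product(self):
        t = "A" * 10 + "ACGTACGTACGTACGTCCCG" + "T" * 40 + "GGGCATCATCATCATCATCA"
        tag = "TTGACCTTGACCTTGACC"
        f = tag + "ACGTACGTACGTACGTCCCG"
        r = reverse_complement("GGGCATCATCATCATCATCA")
        prods = pcr([t], f, r)
        assert len(prods) == 1 and prods[0].startswith(tag)

    def test_no_product_without_both_sites(self):
        t = "ACGTACGTACGTACGTCCCG" + "T" * 40
        assert pcr([t], "ACGTACGTACGTACGTCCCG", "G" * 20) == []

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError, match="k=15"):
            pcr(["A" * 50], "ACGTACG", "A" * 20)


class TestOverlapAssembly:
    def test_two_fragment_join(self):
        a = "A" * 30 + "CCGGTTAACCGGTTAACCGG"
        b = "CCGGTTAACCGGTTAACCGG" + "T" * 30
        assert overlap_assemble([a, b]) == [a + "T" * 30]

    def test_below_min_overlap_no_join(self):
        a = "A" * 30 + "CCGGTTAACC"
        b = "CCGGTTAACC" + "T" * 30
        assert len(overlap_assemble([a, b])) == 2

    def test_ambiguous_join_raises(self):
        ov = "CCGGTTAACCGGTTAACCGG"
        a = "A" * 30 + ov
        b1 = ov + "T" * 30
        b2 = ov + "G" * 30
        with pytest.raises(ValueError, match="ambiguous"):
            overlap_assemble([a, b1, b2])


class TestSimulation:
    def test_pm_secondary_with_residual_plasmid_is_mixed(self, unit):
        sets = saturation_sets(unit, (100,), ("W",))
        plan = plan_assembly(unit, sets, mode="polytemplated")
        prods = simulate_secondary(plan, plan.secondaries[0], residual_template=True)
        assert len(prods) == 2  # intended mutant + reamplified parent

    def test_mm_secondary_with_residual_plasmid_is_pure(self, unit):
        sets = saturation_sets(unit, (100,), ("W",))
        plan = plan_assembly(
            unit, sets, mode="monotemplated", tag_policy="both",
            tags={"fo": MIDAS_MM_TAG}, seed=5,
        )
        prods = simulate_secondary(plan, plan.secondaries[0], residual_template=True)
        assert len(prods) == 1

    def test_nested_primers_silent_on_raw_plasmid(self, unit):
        sets = saturation_sets(unit, (100,), ("W",))
        plan = plan_assembly(
            unit, sets, mode="monotemplated", tag_policy="both", seed=5
        )
        raw = pcr([unit.sequence], plan.outer["Fo_nested"], plan.outer["Ro_nested"])
        assert raw == []

    def test_product_length_parent_plus_indel(self, unit):
        from midaskit.construct import insertion, deletion

        tr = resolve_target_region(unit, 100)
        sets = [SubstitutionSet(tr, (
            substitution({100: "A"}),
            insertion(100, "GG"),
            deletion((100,)),
        ))]
        plan = plan_assembly(unit, sets, mode="polytemplated")
        parent_len = unit.polya.end - unit.promoter.start
        deltas = set()
        for s in plan.secondaries:
            (p,) = simulate_secondary(plan, s)
            deltas.add(len(p) - parent_len)
        assert deltas == {0, 6, -3}

    def test_scheme_equivalence(self, unit, two_tr_sets):
        per_seg = plan_assembly(unit, two_tr_sets, scheme="per-segment")
        per_perm = plan_assembly(unit, two_tr_sets, scheme="per-permutation")
        prods_seg = {simulate_secondary(per_seg, s)[0] for s in per_seg.secondaries}
        prods_perm = {simulate_secondary(per_perm, s)[0] for s in per_perm.secondaries}
        assert prods_seg == prods_perm and len(prods_seg) == 36

    def test_variant_protein_differs_only_at_targets(self, unit, two_tr_sets):
        plan = plan_assembly(unit, two_tr_sets, scheme="per-segment")
        parent = unit.protein()
        c = unit.cds[0]
        offset = unit.promoter.start  # product starts at Fo anneal start
        for s in plan.secondaries[:6]:
            (p,) = simulate_secondary(plan, s)
            prod_cds = p[c.start - offset : c.end - offset]
            prot = translate(prod_cds)
            diffs = {i + 1 for i, (a, b) in enumerate(zip(parent, prot)) if a != b}
            expected = {
                int(lab[1:-1]) for lab in s.variant_label.split("+")
                if lab[0] != lab[-1]
            }
            assert diffs == expected
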