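"""Assembly planning, plate layout and in-silico overlap-extension PCR.

Two combinatorial schemes are supported for multi-target designs:

* **per-segment** — each primary PCR carries at most one payload; for *i*
  target regions there are *i + 1* segments (one constant leftmost segment
  plus one mutagenic segment per TR), and the secondary PCRs are formed by
  the cross product of per-TR amplicon choices.
* **per-permutation** — the single TR-spanning middle segment carries the
  payloads of both TRs (forward-mutagenic at its left end, reverse-mutagenic
  at its right end), requiring one primary per full permutation but allowing
  one-to-one transfer of primaries into secondaries.

Both schemes yield identical final product sequence sets; they differ only
in how the liquid handling scales. In monotemplated protocols the secondary
reactions are wired to the tag-nested outer primers so residual plasmid
template cannot be reamplified.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from . import seqcore
from .construct import (
    Payload,
    Span,
    SubstitutionSet,
    TargetRegion,
    TranscriptionUnit,
    replacement,
)
from .primers import (
    DEFAULT_CONSTRAINTS,
    DesignConstraints,
    PrimerSpec,
    design_counter_primer,
    design_mutagenic_primer,
    design_outer_primers,
)
from .seqcore import CodonChoiceTable, MIDAS_CODON_TABLE, reverse_complement

__all__ = [
    "PrimaryReaction",
    "SecondaryReaction",
    "AssemblyPlan",
    "PlateLayout",
    "plan_assembly",
    "enumerate_variants",
    "layout_plates",
    "pcr",
    "overlap_assemble",
    "simulate_secondary",
]

# TRs closer than this cannot be given independent primer pairs: their
# flanks/overlaps would collide. Such TRs are merged into one TR-carrying
# primer when the combined span still fits an oligo payload window.
MIN_TR_GAP = 60


@dataclass(frozen=True)
class PrimaryReaction:
    """One primary PCR: a primer pair on the (plasmid) template."""

    id: str
    segment: int
    fwd: PrimerSpec
    rev: PrimerSpec
    template: str  # template name (the unit/plasmid)
    payload_labels: tuple[str, ...] = ()
    expected_span: Span | None = None

    @property
    def mutagenic(self) -> bool:
        return bool(self.payload_labels)


@dataclass(frozen=True)
class SecondaryReaction:
    """One overlap-extension secondary PCR assembling a full variant gene."""

    id: str
    variant_label: str
    amplicons: tuple[str, ...]  # primary reaction ids
    fwd: PrimerSpec
    rev: PrimerSpec


@dataclass(frozen=True)
class AssemblyPlan:
    scheme: str  # 'per-segment' | 'per-permutation'
    mode: str  # 'polytemplated' | 'monotemplated'
    unit: TranscriptionUnit
    substitution_sets: tuple[SubstitutionSet, ...]
    segments: int
    primaries: tuple[PrimaryReaction, ...]
    secondaries: tuple[SecondaryReaction, ...]
    outer: dict[str, PrimerSpec]
    counts: dict[str, int]

    def primary_by_id(self, rid: str) -> PrimaryReaction:
        return self._index()[rid]

    def _index(self) -> dict[str, PrimaryReaction]:
        if not hasattr(self, "_idx"):
            object.__setattr__(self, "_idx", {p.id: p for p in self.primaries})
        return self._idx


def enumerate_variants(
    substitution_sets: list[SubstitutionSet] | tuple[SubstitutionSet, ...],
) -> tuple[list[tuple[Payload, ...]], int]:
    """Cross product of payload choices, TRs left to right, payloads in
    declared order. The empty product is the parent (count 1)."""
    combos = list(itertools.product(*[s.payloads for s in substitution_sets]))
    return combos, len(combos)


def variant_label(combo: tuple[Payload, ...]) -> str:
    return "+".join(p.label for p in combo) if combo else "parent"


def _merge_close_trs(
    unit: TranscriptionUnit, sets: list[SubstitutionSet]
) -> list[SubstitutionSet]:
    """Merge adjacent TRs closer than MIN_TR_GAP into one TR when the
    combined span still fits a single payload window; otherwise reject."""
    sets = sorted(sets, key=lambda s: s.tr.span.start)
    for a, b in zip(sets, sets[1:]):
        if a.tr.span.overlaps(b.tr.span):
            raise ValueError(f"target regions overlap: {a.tr.span} vs {b.tr.span}")
    out: list[SubstitutionSet] = []
    for s in sets:
        if out and s.tr.span.start - out[-1].tr.span.end < MIN_TR_GAP:
            prev = out[-1]
            merged_span = Span(prev.tr.span.start, s.tr.span.end)
            if len(merged_span) > 2 * 12 + MIN_TR_GAP:  # sanity; practical limit below
                raise ValueError("adjacent TRs too close to separate, too wide to merge")
            gap = unit.sequence[prev.tr.span.end : s.tr.span.start]
            merged_tr = TargetRegion(
                prev.tr.cds_index,
                prev.tr.first_residue,
                s.tr.last_residue,
                merged_span,
                offset=prev.tr.offset,
                max_span=len(merged_span),
            )
            payloads = tuple(
                replacement(
                    pa.tr_replacement(unit, prev.tr) + gap + pb.tr_replacement(unit, s.tr),
                    label=f"{pa.label}+{pb.label}",
                )
                for pa in prev.payloads
                for pb in s.payloads
            )
            out[-1] = SubstitutionSet(merged_tr, payloads, name=f"{prev.name}+{s.name}")
        else:
            out.append(s)
    return out


def plan_assembly(
    unit: TranscriptionUnit,
    substitution_sets: list[SubstitutionSet],
    scheme: str = "per-segment",
    mode: str = "polytemplated",
    table: CodonChoiceTable = MIDAS_CODON_TABLE,
    constraints: DesignConstraints = DEFAULT_CONSTRAINTS,
    tag_policy: str = "both",
    tags: dict[str, str] | None = None,
    flank5: int | None = None,
    flank3: int | None = None,
    counter_length: int | None = None,
    outer_length: int | None = None,
    seed: int = 0,
) -> AssemblyPlan:
    """Turn target regions + substitution sets into a full PCR plan."""
    if scheme not in ("per-segment", "per-permutation"):
        raise ValueError("scheme must be 'per-segment' or 'per-permutation'")
    if not substitution_sets:
        raise ValueError("at least one substitution set required")
    sets = _merge_close_trs(unit, list(substitution_sets))
    for s in sets:
        if s.tr.span.start < constraints.flank_hard_max or (
            len(unit.sequence) - s.tr.span.end < constraints.flank_hard_max
        ):
            raise ValueError("TR too close to template ends")

    outer = design_outer_primers(
        unit, mode=mode, tag_policy=tag_policy, tags=tags,
        length=outer_length, seed=seed, constraints=constraints,
    )
    sec_f = outer.get("Fo_nested", outer["Fo"])
    sec_r = outer.get("Ro_nested", outer["Ro"])

    i = len(sets)
    primaries: list[PrimaryReaction] = []
    secondaries: list[SecondaryReaction] = []

    if scheme == "per-permutation" and i > 2:
        raise ValueError("per-permutation planning supports at most two target regions")

    if scheme == "per-segment" or i == 1:
        # counters R_t immediately upstream of each TR
        counters = [
            design_counter_primer(unit, s.tr, length=counter_length, constraints=constraints)
            for s in sets
        ]
        left = PrimaryReaction(
            id="P0", segment=0, fwd=outer["Fo"], rev=counters[0], template=unit.name
        )
        primaries.append(left)
        per_tr_ids: list[dict[str, str]] = []
        for t, s in enumerate(sets):
            rev = counters[t + 1] if t + 1 < i else outer["Ro"]
            ids = {}
            for p in s.payloads:
                f = design_mutagenic_primer(
                    unit, s.tr, p, "forward", table, flank5, flank3, constraints
                )
                rid = f"P{t + 1}.{p.label}"
                primaries.append(
                    PrimaryReaction(
                        id=rid, segment=t + 1, fwd=f, rev=rev,
                        template=unit.name, payload_labels=(p.label,),
                    )
                )
                ids[p.label] = rid
            per_tr_ids.append(ids)
        combos, _ = enumerate_variants(sets)
        for k, combo in enumerate(combos):
            amps = ("P0",) + tuple(
                per_tr_ids[t][p.label] for t, p in enumerate(combo)
            )
            secondaries.append(
                SecondaryReaction(
                    id=f"S{k}", variant_label=variant_label(combo),
                    amplicons=amps, fwd=sec_f, rev=sec_r,
                )
            )
        n_const, n_mut = 1, sum(len(s) for s in sets)
        segments = i + 1
    else:  # per-permutation, exactly 2 TRs
        s1, s2 = sets
        r1 = design_counter_primer(unit, s1.tr, length=counter_length, constraints=constraints)
        f2 = design_counter_primer(
            unit, s2.tr, length=counter_length, constraints=constraints, side="downstream"
        )
        left = PrimaryReaction(id="P0", segment=0, fwd=outer["Fo"], rev=r1, template=unit.name)
        right = PrimaryReaction(id="P2", segment=2, fwd=f2, rev=outer["Ro"], template=unit.name)
        primaries += [left, right]
        combos, _ = enumerate_variants(sets)
        for k, (pa, pb) in enumerate(combos):
            f = design_mutagenic_primer(
                unit, s1.tr, pa, "forward", table, flank5, flank3, constraints
            )
            r = design_mutagenic_primer(
                unit, s2.tr, pb, "reverse", table, flank5, flank3, constraints
            )
            rid = f"P1.{pa.label}+{pb.label}"
            primaries.append(
                PrimaryReaction(
                    id=rid, segment=1, fwd=f, rev=r, template=unit.name,
                    payload_labels=(pa.label, pb.label),
                )
            )
            secondaries.append(
                SecondaryReaction(
                    id=f"S{k}", variant_label=variant_label((pa, pb)),
                    amplicons=("P0", rid, "P2"), fwd=sec_f, rev=sec_r,
                )
            )
        n_const, n_mut = 2, len(combos)
        segments = 3

    counts = {
        "segments": segments,
        "constant_primaries": n_const,
        "mutagenic_primaries": n_mut,
        "primary_reactions": n_const + n_mut,
        "secondary_reactions": len(secondaries),
        "variants": len(secondaries),
    }
    return AssemblyPlan(
        scheme=scheme, mode=mode, unit=unit, substitution_sets=tuple(sets),
        segments=segments, primaries=tuple(primaries),
        secondaries=tuple(secondaries), outer=outer, counts=counts,
    )


# ---------------------------------------------------------------------------
# Plate layout
# ---------------------------------------------------------------------------

_GRIDS = {96: ("ABCDEFGH", 12), 384: ("ABCDEFGHIJKLMNOP", 24)}


@dataclass(frozen=True)
class PlateLayout:
    plate_size: int
    plates: tuple[tuple[str, dict[str, str]], ...]  # (plate id, well -> label)

    def well_of(self, label: str) -> tuple[str, str]:
        for pid, wells in self.plates:
            for w, lab in wells.items():
                if lab == label:
                    return pid, w
        raise KeyError(label)

    @property
    def n_assigned(self) -> int:
        return sum(len(w) for _, w in self.plates)


def wells(plate_size: int) -> list[str]:
    rows, ncol = _GRIDS[plate_size]
    return [f"{r}{c}" for r in rows for c in range(1, ncol + 1)]


def layout_plates(
    plan_or_labels,
    plate_size: int = 96,
    order_policy: str = "row-major",
    controls: tuple[str, ...] = (),
) -> PlateLayout:
    """Assign reactions/variants to wells, row-major, controls in the last
    wells of the last plate."""
    if plate_size not in _GRIDS:
        raise ValueError("plate_size must be 96 or 384")
    if order_policy != "row-major":
        raise ValueError("only row-major fill is implemented")
    labels = (
        [s.variant_label for s in plan_or_labels.secondaries]
        if isinstance(plan_or_labels, AssemblyPlan)
        else list(plan_or_labels)
    )
    grid = wells(plate_size)
    total = len(labels) + len(controls)
    n_plates = max(1, math.ceil(total / plate_size)) if total else 0
    plates = []
    it = iter(labels)
    for p in range(n_plates):
        wmap = {}
        for w in grid:
            try:
                wmap[w] = next(it)
            except StopIteration:
                break
        plates.append([f"plate{p + 1}", wmap])
    if controls:
        last_id, last_map = plates[-1]
        free = [w for w in grid if w not in last_map]
        for ctrl, w in zip(controls, free[len(free) - len(controls):]):
            last_map[w] = ctrl
    return PlateLayout(plate_size, tuple((pid, dict(m)) for pid, m in plates))


# ---------------------------------------------------------------------------
# In-silico PCR and overlap assembly
# ---------------------------------------------------------------------------


def _find_all(needle: str, hay: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def pcr(
    templates: list[str] | list[tuple[str, str]],
    fwd: str | PrimerSpec,
    rev: str | PrimerSpec,
    k: int = 15,
) -> list[str]:
    """Exact-3'-match in-silico PCR.

    A primer primes wherever its 3'-terminal ``k`` bases match the template
    exactly; the product carries the full primer sequence at each end (so 5'
    tags and payload mismatches are incorporated). All distinct products
    over all templates and site pairs are returned, sorted; multi-site
    priming therefore surfaces as multiple products rather than being
    silently resolved.
    """
    f = fwd.sequence if isinstance(fwd, PrimerSpec) else seqcore.DnaSeq(fwd)
    r = rev.sequence if isinstance(rev, PrimerSpec) else seqcore.DnaSeq(rev)
    if len(f) < k or len(r) < k:
        raise ValueError(f"primers shorter than priming seed k={k}")
    rc_r = reverse_complement(r)
    products = set()
    for t in templates:
        seq = seqcore.DnaSeq(t[1] if isinstance(t, tuple) else t)
        for fi in _find_all(f[-k:], seq):
            f_end = fi + k
            for ri in _find_all(rc_r[:k], seq):
                if ri >= f_end:
                    products.add(f + seq[f_end:ri] + rc_r)
    return sorted(products)


def _max_overlap(a: str, b: str, min_overlap: int, cap: int = 200) -> int:
    """Longest l ≥ min_overlap with a[-l:] == b[:l], searched down from cap."""
    for l in range(min(cap, len(a), len(b)), min_overlap - 1, -1):
        if a.endswith(b[:l]):
            return l
    return 0


def overlap_assemble(fragments: list[str], min_overlap: int = 18) -> list[str]:
    """Join amplicons by exact overlap extension.

    Fragments sharing a unique maximal suffix–prefix overlap of at least
    ``min_overlap`` nt are merged until no join remains. A fragment end that
    can join more than one partner is ambiguous and raises.
    """
    frags = [seqcore.DnaSeq(f) for f in fragments]
    while len(frags) > 1:
        joins = []
        for ia, a in enumerate(frags):
            for ib, b in enumerate(frags):
                if ia == ib:
                    continue
                l = _max_overlap(a, b, min_overlap)
                if l:
                    joins.append((ia, ib, l))
        if not joins:
            break
        suffixes = [j[0] for j in joins]
        prefixes = [j[1] for j in joins]
        ia, ib, l = joins[0]
        if suffixes.count(ia) > 1 or prefixes.count(ib) > 1:
            raise ValueError("ambiguous overlap: a fragment end joins multiple partners")
        merged = frags[ia] + frags[ib][l:]
        frags = [f for i, f in enumerate(frags) if i not in (ia, ib)] + [merged]
    return frags


def simulate_secondary(
    plan: AssemblyPlan,
    reaction: SecondaryReaction,
    residual_template: bool = False,
    k: int = 15,
    min_overlap: int = 18,
) -> list[str]:
    """All distinct full-length products a secondary reaction can make.

    The contributing primary amplicons are first produced in silico from the
    plasmid template, joined by overlap extension, and then amplified with
    the reaction's outer primer pair. With ``residual_template=True`` the
    undiluted plasmid template is left in the mix, modelling carry-over from
    unpurified mutagenic primaries: untagged outer primers then also amplify
    the parental gene, while tag-nested primers cannot.
    """
    template = [(plan.unit.name, plan.unit.sequence)]
    amp_seqs = []
    for rid in reaction.amplicons:
        prim = plan.primary_by_id(rid)
        prods = pcr(template, prim.fwd, prim.rev, k=k)
        if len(prods) != 1:
            raise ValueError(
                f"primary {rid} yields {len(prods)} products; expected exactly 1"
            )
        amp_seqs.append(prods[0])
    assembled = overlap_assemble(amp_seqs, min_overlap=min_overlap)
    pool = [("assembled", s) for s in assembled]
    if residual_template:
        pool.append((plan.unit.name, plan.unit.sequence))
    return pcr(pool, reaction.fwd, reaction.rev, k=k)
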