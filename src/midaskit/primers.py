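"""Mutagenic, counter, outer and tag-nested primer design.

The design rules implemented here produce the oligos for arrayed
overlap-extension mutagenesis:

* a *mutagenic* primer carries a 5' template-matching flank, the payload
  codons (from an explicit codon-choice table), and a 3' template-matching
  anneal arm, both arms 18–24 nt by default;
* its *counter* primer is the reverse complement of the template window
  ending immediately 5' of the target region, sized so the overlap with the
  mutagenic primer's 5' flank melts in a 60–66 °C window;
* *outer* primers bracket the whole transcription unit (promoter side and
  polyA side); in monotemplated protocols one or both carry a 5' tag absent
  from the template, and *nested* primers that prime only on the tag let the
  secondary PCR ignore residual plasmid template.

Primer display strings follow the order-sheet convention of lowercase
template-matching bases and UPPERCASE payload/tag bases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import seqcore
from .construct import Payload, Span, TargetRegion, TranscriptionUnit
from .seqcore import (
    CodonChoiceTable,
    DnaSeq,
    MIDAS_CODON_TABLE,
    TmParams,
    melting_temperature,
    reverse_complement,
)

__all__ = [
    "DesignConstraints",
    "PrimerSpec",
    "TagSpec",
    "design_mutagenic_primer",
    "design_counter_primer",
    "design_saturation_array",
    "design_outer_primers",
    "generate_tag",
    "validate_tag",
    "longest_shared_substring",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Tunable design bounds.

    flank_min/flank_max   preferred arm length window, nt
    flank_hard_max        absolute arm-length ceiling in auto mode, nt
    tm_window             overlap/anneal melt window, °C
    tm_params             duplex Tm settings
    tag_length            generated tag length, nt
    tag_max_shared        longest template substring a tag may share, nt
                          (exclusive bound: matches of this length fail)
    """

    flank_min: int = 18
    flank_max: int = 24
    flank_hard_max: int = 40
    tm_window: tuple[float, float] = (60.0, 66.0)
    tm_params: TmParams = field(default_factory=TmParams)
    tag_length: int = 23
    tag_max_shared: int = 12


DEFAULT_CONSTRAINTS = DesignConstraints()

_CASE_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def _rc_case(s: str) -> str:
    """Reverse complement preserving per-base case (for display strings)."""
    return s.translate(_CASE_RC)[::-1]


@dataclass(frozen=True)
class PrimerSpec:
    """A designed oligo.

    ``sequence`` is the canonical uppercase sequence; ``display`` keeps the
    lowercase-template / UPPERCASE-payload order-sheet convention.
    ``anneal_span`` is the template region the 3' portion of the primer
    hybridizes to (0-based half-open, forward-strand coordinates).
    """

    name: str
    display: str
    role: str  # Fo, Ro, Fo', Ro', F mutagenic, R counter, F counter, R mutagenic
    strand: str  # '+' or '-'
    anneal_span: Span | None = None
    payload_label: str | None = None
    flank5: int = 0
    flank3: int = 0
    tag: str | None = None
    overlap_partner: str | None = None
    overlap_tm: float | None = None
    tm_extended: bool = False  # an arm grew past flank_max to reach the Tm target

    @property
    def sequence(self) -> str:
        return DnaSeq(self.display)

    def __len__(self) -> int:
        return len(self.display)


def _auto_flank(
    window_source, lo_len: int, constraints: DesignConstraints, what: str
) -> int:
    """Smallest arm length whose duplex Tm reaches the window floor.

    ``window_source(L)`` returns the L-nt candidate arm. Arms above
    ``flank_max`` are allowed with a warning; above ``flank_hard_max`` the
    search fails.
    """
    lo, _hi = constraints.tm_window
    for L in range(max(lo_len, constraints.flank_min), constraints.flank_hard_max + 1):
        arm = window_source(L)
        if arm is None:
            break
        tm = melting_temperature(arm, constraints.tm_params)
        if tm >= lo:
            if L == constraints.flank_min and tm > constraints.tm_window[1]:
                warnings.warn(
                    f"{what}: Tm {tm:.1f} °C above window at minimum length "
                    f"{L} nt; arm not shortened below {constraints.flank_min} nt",
                    stacklevel=3,
                )
            if L > constraints.flank_max:
                warnings.warn(
                    f"{what}: arm extended to {L} nt to reach "
                    f"{lo:.0f} °C overlap Tm",
                    stacklevel=3,
                )
            return L
    raise ValueError(
        f"{what}: Tm window {constraints.tm_window} unreachable within "
        f"{constraints.flank_hard_max} nt"
    )


def design_mutagenic_primer(
    unit: TranscriptionUnit,
    tr: TargetRegion,
    payload: Payload,
    orientation: str = "forward",
    table: CodonChoiceTable = MIDAS_CODON_TABLE,
    flank5: int | None = None,
    flank3: int | None = None,
    constraints: DesignConstraints = DEFAULT_CONSTRAINTS,
    name: str | None = None,
) -> PrimerSpec:
    """Design the payload-carrying primer at ``tr``.

    Forward orientation: 5'-[upstream flank][payload][downstream arm]-3'.
    Reverse orientation mirrors it on the other strand (flank from the
    template immediately downstream of the TR, arm upstream). Explicit
    ``flank5``/``flank3`` lengths override the Tm-driven auto search.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError("orientation must be 'forward' or 'reverse'")
    t = unit.sequence
    new_dna = payload.tr_replacement(unit, tr, table)

    def up_window(L):  # template upstream of TR, ending at the TR
        return t[tr.span.start - L : tr.span.start] if tr.span.start - L >= 0 else None

    def down_window(L):  # template downstream of TR
        return t[tr.span.end : tr.span.end + L] if tr.span.end + L <= len(t) else None

    if orientation == "forward":
        five_src, three_src = up_window, down_window
    else:
        five_src, three_src = down_window, up_window

    ext = False
    if flank5 is None:
        flank5 = _auto_flank(five_src, constraints.flank_min, constraints, "5' flank")
        ext |= flank5 > constraints.flank_max
    if flank3 is None:
        flank3 = _auto_flank(three_src, constraints.flank_min, constraints, "3' anneal arm")
        ext |= flank3 > constraints.flank_max
    five, three = five_src(flank5), three_src(flank3)
    if five is None or three is None:
        raise ValueError("TR too close to template end for requested flanks")

    if orientation == "forward":
        display = five.lower() + new_dna.upper() + three.lower()
        anneal = Span(tr.span.start - flank5, tr.span.end + flank3)
        strand, role = "+", "F mutagenic"
    else:
        display = _rc_case(three.lower() + new_dna.upper() + five.lower())
        anneal = Span(tr.span.start - flank3, tr.span.end + flank5)
        strand, role = "-", "R mutagenic"

    wt = "".join(unit.codon(r, tr.cds_index) for r in tr.residues)
    pname = name or _mutagenic_name(unit, tr, payload, orientation)
    return PrimerSpec(
        name=pname,
        display=display,
        role=role,
        strand=strand,
        anneal_span=anneal,
        payload_label=payload.label,
        flank5=flank5,
        flank3=flank3,
        tm_extended=ext,
        overlap_tm=melting_temperature(five, constraints.tm_params)
        if len(five) >= 6
        else None,
    )


def _mutagenic_name(unit, tr, payload, orientation) -> str:
    prot = seqcore.translate(unit.cds_sequence(tr.cds_index))
    off = tr.offset
    wt_aa = "".join(prot[r - off - 1] for r in tr.residues)
    suffix = "F" if orientation == "forward" else "R"
    if payload.kind == "substitution" and len(tr.residues) == 1:
        r = tr.first_residue
        return f"{unit.name}-{wt_aa}{r}{payload.aa_by_residue.get(r, wt_aa)}-{suffix}"
    return f"{unit.name}-{tr.first_residue}_{tr.last_residue}-{payload.label}-{suffix}"


def design_counter_primer(
    unit: TranscriptionUnit,
    tr: TargetRegion,
    partner: PrimerSpec | None = None,
    length: int | None = None,
    constraints: DesignConstraints = DEFAULT_CONSTRAINTS,
    side: str = "upstream",
    name: str | None = None,
) -> PrimerSpec:
    """Design the non-mutagenic counter primer for the mutagenic primers at ``tr``.

    For forward-mutagenic arrays (the default), the counter is a reverse
    primer: the reverse complement of the template window ending immediately
    5' of the TR, so its reverse complement is a prefix of every sibling
    mutagenic primer. ``side='downstream'`` gives the mirror-image forward
    counter used with reverse-mutagenic arrays. The window grows from the
    minimum arm length until the overlap Tm reaches the window floor, unless
    ``length`` is explicit.
    """
    t = unit.sequence
    if side == "upstream":
        src = lambda L: t[tr.span.start - L : tr.span.start] if tr.span.start >= L else None
    elif side == "downstream":
        src = lambda L: t[tr.span.end : tr.span.end + L] if tr.span.end + L <= len(t) else None
    else:
        raise ValueError("side must be 'upstream' or 'downstream'")

    ext = False
    if length is None:
        length = _auto_flank(src, constraints.flank_min, constraints, "counter overlap")
        ext = length > constraints.flank_max
    window = src(length)
    if window is None:
        raise ValueError("TR too close to template end for counter primer")
    tm = melting_temperature(window, constraints.tm_params)
    if side == "upstream":
        display = _rc_case(window.lower())
        strand, role = "-", "R counter"
        anneal = Span(tr.span.start - length, tr.span.start)
    else:
        display = window.lower()
        strand, role = "+", "F counter"
        anneal = Span(tr.span.end, tr.span.end + length)
    prot = seqcore.translate(unit.cds_sequence(tr.cds_index))
    wt_aa = prot[tr.first_residue - tr.offset - 1]
    default = f"{unit.name}-{wt_aa}{tr.first_residue}-" + ("R" if strand == "-" else "F")
    return PrimerSpec(
        name=name or default,
        display=display,
        role=role,
        strand=strand,
        anneal_span=anneal,
        flank5=length,
        overlap_partner=partner.name if partner else None,
        overlap_tm=tm,
        tm_extended=ext,
    )


def design_saturation_array(
    unit: TranscriptionUnit,
    tr: TargetRegion,
    aa_set: str | None = None,
    table: CodonChoiceTable = MIDAS_CODON_TABLE,
    orientation: str = "forward",
    flank5: int | None = None,
    flank3: int | None = None,
    constraints: DesignConstraints = DEFAULT_CONSTRAINTS,
) -> list[PrimerSpec]:
    """One mutagenic primer per amino acid at a single-codon TR.

    All primers share identical flanks; only the 3-nt payload differs.
    Order is alphabetical by single-letter code.
    """
    if len(tr.residues) != 1:
        raise ValueError("saturation array targets a single residue")
    aas = sorted(set((aa_set or "ACDEFGHIKLMNPQRSTVWY").upper()))
    from .construct import substitution

    r = tr.first_residue
    wt_aa = seqcore.translate(unit.codon(r, tr.cds_index))
    out = []
    for aa in aas:
        p = substitution({r: aa}, label=f"{wt_aa}{r}{aa}")
        out.append(
            design_mutagenic_primer(
                unit, tr, p, orientation, table, flank5, flank3, constraints
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tags and outer primers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TagSpec:
    """A 5' tag with its template-uniqueness report."""

    sequence: str
    longest_shared: int
    threshold: int
    passed: bool


def longest_shared_substring(tag: str, template: str) -> int:
    """Length of the longest exact substring shared by ``tag`` (either strand)
    and ``template``."""
    tag = DnaSeq(tag)
    template = DnaSeq(template)
    candidates = (tag, reverse_complement(tag))
    for L in range(len(tag), 0, -1):
        for s in candidates:
            for i in range(len(s) - L + 1):
                if s[i : i + L] in template:
                    return L
    return 0


def validate_tag(
    tag: str, unit: TranscriptionUnit, stringency: int = 12
) -> TagSpec:
    """Report the longest exact match between tag and template.

    Passes iff the longest shared substring is shorter than ``stringency``
    nucleotides (both strands scanned).
    """
    if len(DnaSeq(tag)) < 15:
        raise ValueError("tags shorter than 15 nt cannot be unique priming sites")
    L = longest_shared_substring(tag, unit.sequence)
    return TagSpec(DnaSeq(tag), L, stringency, passed=L < stringency)


def generate_tag(
    unit: TranscriptionUnit,
    seed: int = 0,
    constraints: DesignConstraints = DEFAULT_CONSTRAINTS,
    max_tries: int = 200,
) -> TagSpec:
    """Seeded pseudo-random tag: 40–60 % GC, no shared template substring of
    ``tag_max_shared`` nt or more on either strand."""
    rng = np.random.default_rng(seed)
    n = constraints.tag_length
    for _ in range(max_tries):
        tag = "".join(rng.choice(list("ACGT"), size=n))
        gc = (tag.count("G") + tag.count("C")) / n
        if not 0.40 <= gc <= 0.60:
            continue
        spec = validate_tag(tag, unit, stringency=constraints.tag_max_shared)
        if spec.passed:
            return spec
    raise RuntimeError(f"no template-unique tag found in {max_tries} tries")


def design_outer_primers(
    unit: TranscriptionUnit,
    mode: str = "polytemplated",
    tag_policy: str = "fo",
    tags: dict[str, str] | None = None,
    length: int | None = None,
    seed: int = 0,
    nested_extension: int = 0,
    constraints: DesignConstraints = DEFAULT_CONSTRAINTS,
) -> dict[str, PrimerSpec]:
    """Design the outer primer set bracketing the transcription unit.

    Fo anneals at the 5' end of (or upstream of) the promoter; Ro at the 3'
    end of (or downstream of) the polyA signal. In monotemplated mode the
    primers named by ``tag_policy`` ('fo', 'ro' or 'both') get 5' tags
    (supplied via ``tags`` or generated from ``seed``), and nested Fo'/Ro'
    primers priming only on the tag are emitted; ``nested_extension`` adds
    that many template bases inward of the tag to the nested primers.
    """
    if mode not in ("polytemplated", "monotemplated"):
        raise ValueError("mode must be 'polytemplated' or 'monotemplated'")
    if tag_policy not in ("fo", "ro", "both"):
        raise ValueError("tag_policy must be 'fo', 'ro' or 'both'")
    t = unit.sequence
    fo_src = lambda L: t[unit.promoter.start : unit.promoter.start + L]
    ro_src = lambda L: t[unit.polya.end - L : unit.polya.end]
    Lf = length or _auto_flank(fo_src, constraints.flank_min, constraints, "Fo")
    Lr = length or _auto_flank(ro_src, constraints.flank_min, constraints, "Ro")
    fo_anneal, ro_anneal = fo_src(Lf), ro_src(Lr)
    out: dict[str, PrimerSpec] = {}

    fo_tag = ro_tag = None
    if mode == "monotemplated":
        want_fo = tag_policy in ("fo", "both")
        want_ro = tag_policy in ("ro", "both")
        tags = dict(tags or {})
        if want_fo:
            fo_tag = tags.get("fo") or generate_tag(unit, seed, constraints).sequence
            if not validate_tag(fo_tag, unit, constraints.tag_max_shared).passed:
                raise ValueError("supplied Fo tag collides with template")
        if want_ro:
            ro_tag = tags.get("ro") or generate_tag(unit, seed + 1, constraints).sequence
            if not validate_tag(ro_tag, unit, constraints.tag_max_shared).passed:
                raise ValueError("supplied Ro tag collides with template")

    fo_disp = (fo_tag.upper() if fo_tag else "") + fo_anneal.lower()
    ro_disp = (ro_tag.upper() if ro_tag else "") + _rc_case(ro_anneal.lower())
    out["Fo"] = PrimerSpec(
        name=f"{unit.name}-Fo",
        display=fo_disp,
        role="Fo",
        strand="+",
        anneal_span=Span(unit.promoter.start, unit.promoter.start + Lf),
        tag=fo_tag,
        flank3=Lf,
    )
    out["Ro"] = PrimerSpec(
        name=f"{unit.name}-Ro",
        display=ro_disp,
        role="Ro",
        strand="-",
        anneal_span=Span(unit.polya.end - Lr, unit.polya.end),
        tag=ro_tag,
        flank3=Lr,
    )
    if fo_tag:
        out["Fo_nested"] = PrimerSpec(
            name=f"{unit.name}-Fo'",
            display=fo_tag.upper() + fo_anneal[:nested_extension].lower(),
            role="Fo'",
            strand="+",
            tag=fo_tag,
        )
    if ro_tag:
        out["Ro_nested"] = PrimerSpec(
            name=f"{unit.name}-Ro'",
            display=ro_tag.upper() + _rc_case(ro_anneal.lower())[:nested_extension],
            role="Ro'",
            strand="-",
            tag=ro_tag,
        )
    return out
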