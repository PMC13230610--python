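"""Template transcription units, target regions and substitution sets.

A transcription unit is the linear PCR-product gene that gets transfected
directly: promoter, one or more CDS features (bicistronic layouts with an
intervening element are allowed), and a polyadenylation signal, all on the
forward strand. Internally all coordinates are 0-based half-open on the
template; users address residues 1-based with an explicit per-CDS numbering
offset (fusion constructs are often numbered over the whole fusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import seqcore
from .seqcore import CodonChoiceTable, DnaSeq, MIDAS_CODON_TABLE

__all__ = [
    "Span",
    "TranscriptionUnit",
    "TargetRegion",
    "Payload",
    "substitution",
    "insertion",
    "deletion",
    "replacement",
    "SubstitutionSet",
    "load_unit",
    "resolve_target_region",
]

# Hard cap on target-region width, nt. A TR must fit inside a single
# mutagenic oligo between its two template-matching arms.
TR_MAX_SPAN = 12


@dataclass(frozen=True)
class Span:
    """0-based half-open interval on the template forward strand."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start <= self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TranscriptionUnit:
    """Annotated template gene: promoter < CDS(s) < polyA on the forward strand."""

    sequence: str
    promoter: Span
    cds: tuple[Span, ...]
    polya: Span
    name: str = "unit"
    coordinate_system: str = "0-based half-open"
    residue_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", DnaSeq(self.sequence))
        cds = tuple(self.cds) if not isinstance(self.cds, Span) else (self.cds,)
        object.__setattr__(self, "cds", cds)
        if not cds:
            raise ValueError("at least one CDS feature required")
        offsets = tuple(self.residue_offsets) or (0,) * len(cds)
        if len(offsets) != len(cds):
            raise ValueError("one residue-numbering offset per CDS required")
        object.__setattr__(self, "residue_offsets", offsets)
        feats = [("promoter", self.promoter)] + [
            (f"CDS[{i}]", c) for i, c in enumerate(cds)
        ] + [("polyA", self.polya)]
        for name, span in feats:
            if span.end > len(self.sequence):
                raise ValueError(f"{name} extends past template end")
        for (na, a), (nb, b) in zip(feats, feats[1:]):
            if a.overlaps(b):
                raise ValueError(f"features {na} and {nb} overlap")
            if a.start > b.start:
                raise ValueError(f"features out of order: {na} after {nb}")
        for i, c in enumerate(cds):
            if len(c) % 3:
                raise ValueError(f"CDS[{i}] not codon-aligned (length {len(c)} nt)")

    def cds_sequence(self, cds_index: int = 0) -> str:
        c = self.cds[cds_index]
        return self.sequence[c.start : c.end]

    def protein(self, cds_index: int = 0) -> str:
        return seqcore.translate(self.cds_sequence(cds_index))

    def codon_span(self, residue: int, cds_index: int = 0, offset: int | None = None) -> Span:
        """Template span of the codon at 1-based ``residue`` (after offset)."""
        off = self.residue_offsets[cds_index] if offset is None else offset
        if residue < 1:
            raise ValueError("residue numbering is 1-based")
        r0 = residue - off  # internal 1-based index within this CDS
        c = self.cds[cds_index]
        if r0 < 1 or c.start + 3 * r0 > c.end:
            raise ValueError(
                f"residue {residue} (offset {off}) lies outside CDS[{cds_index}]"
            )
        start = c.start + 3 * (r0 - 1)
        return Span(start, start + 3)

    def codon(self, residue: int, cds_index: int = 0) -> str:
        s = self.codon_span(residue, cds_index)
        return self.sequence[s.start : s.end]


@dataclass(frozen=True)
class TargetRegion:
    """One codon or a few nearby codons (≤ 12 nt) selected for mutagenesis."""

    cds_index: int
    first_residue: int
    last_residue: int
    span: Span
    offset: int = 0
    max_span: int = TR_MAX_SPAN

    def __post_init__(self) -> None:
        if len(self.span) > self.max_span:
            raise ValueError(
                f"TR exceeds {self.max_span}-base span ({len(self.span)} nt)"
            )

    @property
    def residues(self) -> range:
        return range(self.first_residue, self.last_residue + 1)


def resolve_target_region(
    unit: TranscriptionUnit,
    first_residue: int,
    last_residue: int | None = None,
    cds_index: int = 0,
    offset: int | None = None,
    max_span: int = TR_MAX_SPAN,
) -> TargetRegion:
    """Map a 1-based residue range onto a codon-aligned template span.

    ``offset`` overrides the unit's per-CDS numbering offset; ``max_span``
    can be raised past the default 12 nt cap when a wider region is
    deliberately targeted.
    """
    last = first_residue if last_residue is None else last_residue
    if last < first_residue:
        raise ValueError("last residue before first")
    off = unit.residue_offsets[cds_index] if offset is None else offset
    a = unit.codon_span(first_residue, cds_index, offset=off)
    b = unit.codon_span(last, cds_index, offset=off)
    span = Span(a.start, b.end)
    if len(span) > max_span:
        raise ValueError(
            f"TR exceeds {max_span}-base span ({len(span)} nt); widen max_span to override"
        )
    return TargetRegion(cds_index, first_residue, last, span, offset=off, max_span=max_span)


# ---------------------------------------------------------------------------
# Payloads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Payload:
    """An edit applied to a target region.

    ``kind`` is one of substitution / insertion / deletion / replacement;
    ``label`` is the human-readable variant name used in plans and well maps.
    The edit is materialized as the replacement DNA for the TR span.
    """

    kind: str
    label: str
    aa_by_residue: dict[int, str] = field(default_factory=dict)
    insert_after: int | None = None
    insert_aa: str = ""
    delete_residues: tuple[int, ...] = ()
    dna: str | None = None

    def tr_replacement(
        self,
        unit: TranscriptionUnit,
        tr: TargetRegion,
        table: CodonChoiceTable = MIDAS_CODON_TABLE,
    ) -> str:
        """DNA that replaces the TR span of ``unit`` for this payload."""
        if self.kind == "replacement":
            return DnaSeq(self.dna or "")
        out: list[str] = []
        for r in tr.residues:
            wt = unit.codon(r, tr.cds_index)
            if self.kind == "substitution":
                out.append(table[self.aa_by_residue[r]] if r in self.aa_by_residue else wt)
            elif self.kind == "deletion":
                if r not in self.delete_residues:
                    out.append(wt)
            elif self.kind == "insertion":
                out.append(wt)
            else:
                raise ValueError(f"unknown payload kind {self.kind!r}")
            if self.kind == "insertion" and r == self.insert_after:
                out.append(table.encode(self.insert_aa))
        return "".join(out)


def substitution(aa_by_residue: dict[int, str], label: str | None = None) -> Payload:
    lab = label or "+".join(f"{r}{aa}" for r, aa in sorted(aa_by_residue.items()))
    return Payload("substitution", lab, aa_by_residue={**aa_by_residue})


def insertion(after_residue: int, aa: str, label: str | None = None) -> Payload:
    lab = label or f"ins{after_residue}{aa or '-'}"
    return Payload("insertion", lab, insert_after=after_residue, insert_aa=aa)


def deletion(residues: tuple[int, ...] | list[int], label: str | None = None) -> Payload:
    rs = tuple(residues)
    lab = label or "del" + "+".join(map(str, rs))
    return Payload("deletion", lab, delete_residues=rs)


def replacement(dna: str, label: str) -> Payload:
    return Payload("replacement", label, dna=DnaSeq(dna))


@dataclass(frozen=True)
class SubstitutionSet:
    """The payloads screened at one target region."""

    tr: TargetRegion
    payloads: tuple[Payload, ...]
    name: str = ""

    def __post_init__(self) -> None:
        labels = [p.label for p in self.payloads]
        if len(set(labels)) != len(labels):
            raise ValueError("payload labels must be unique within a substitution set")
        if not self.payloads:
            raise ValueError("substitution set must be nonempty")

    def __len__(self) -> int:
        return len(self.payloads)


def load_unit(
    sequence: str,
    promoter: tuple[int, int],
    cds: list[tuple[int, int]] | tuple[int, int],
    polya: tuple[int, int],
    name: str = "unit",
    residue_offsets: tuple[int, ...] = (),
) -> TranscriptionUnit:
    """Build a validated TranscriptionUnit from raw spans.

    Accepts one ``(start, end)`` pair per feature (0-based half-open);
    ``cds`` may be a single pair or a list for bicistronic layouts.
    """
    cds_list = [cds] if cds and isinstance(cds[0], int) else list(cds)
    return TranscriptionUnit(
        sequence=sequence,
        promoter=Span(*promoter),
        cds=tuple(Span(*c) for c in cds_list),
        polya=Span(*polya),
        name=name,
        residue_offsets=residue_offsets,
    )
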