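"""Readers and writers for templates, order sheets, plans and score matrices.

Templates come in as FASTA (features supplied alongside) or GenBank
(features read from the annotation). Everything written out is plain text —
CSV/TSV/JSON — and byte-stable given identical inputs and seeds.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .assembly import AssemblyPlan, PlateLayout, PrimaryReaction, SecondaryReaction
from .construct import Span, TranscriptionUnit, load_unit
from .primers import PrimerSpec

__all__ = [
    "read_template",
    "write_order_sheet",
    "write_plan_json",
    "read_plan_json",
    "write_plan_tsv",
    "write_plate_map",
    "write_score_matrix",
]

_GENBANK_FEATURE_TYPES = {
    "promoter": ("promoter", "regulatory"),
    "cds": ("CDS",),
    "polya": ("polyA_signal", "polyA_site"),
}


def read_template(
    path: str | Path,
    fmt: str | None = None,
    features: dict | None = None,
    name: str | None = None,
) -> TranscriptionUnit:
    """Load a transcription unit from FASTA or GenBank.

    GenBank records must annotate exactly one promoter, at least one CDS and
    one polyA signal. FASTA carries no features, so they must be supplied as
    ``features={"promoter": (a, b), "cds": [(a, b), ...], "polya": (a, b)}``
    (0-based half-open). Lowercase input is canonicalized.
    """
    path = Path(path)
    if fmt is None:
        fmt = {
            ".gb": "genbank", ".gbk": "genbank", ".genbank": "genbank",
            ".fa": "fasta", ".fasta": "fasta", ".fna": "fasta",
        }.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    record = SeqIO.read(str(path), fmt)
    if fmt == "fasta":
        if not features:
            raise ValueError(
                "FASTA input carries no annotations; supply features="
                "{'promoter': (a, b), 'cds': [(a, b), ...], 'polya': (a, b)}"
            )
        return load_unit(
            str(record.seq),
            promoter=tuple(features["promoter"]),
            cds=features["cds"],
            polya=tuple(features["polya"]),
            name=name or record.id,
        )
    promoter = cds = polya = None
    cds_list = []
    for f in record.features:
        if f.type in _GENBANK_FEATURE_TYPES["promoter"] and promoter is None:
            promoter = (int(f.location.start), int(f.location.end))
        elif f.type in _GENBANK_FEATURE_TYPES["cds"]:
            cds_list.append((int(f.location.start), int(f.location.end)))
        elif f.type in _GENBANK_FEATURE_TYPES["polya"] and polya is None:
            polya = (int(f.location.start), int(f.location.end))
    missing = [
        n for n, v in
        [("promoter", promoter), ("CDS", cds_list or None), ("polyA", polya)]
        if v is None
    ]
    if missing:
        raise ValueError(f"GenBank record lacks required features: {missing}")
    return load_unit(
        str(record.seq), promoter=promoter, cds=cds_list, polya=polya,
        name=name or record.id,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_order_sheet(
    primers: list[PrimerSpec],
    path: str | Path,
    layout: PlateLayout | None = None,
    lowercase: bool = False,
) -> None:
    """Primer order sheet: name, sequence, plate, well.

    The default sequence rendering keeps lowercase template bases and
    UPPERCASE payload/tag bases for human review; ``lowercase=True`` flattens
    it for vendors that reject mixed case.
    """
    wellmap = {}
    if layout is not None:
        for pid, wm in layout.plates:
            for w, lab in wm.items():
                wellmap[lab] = (pid, w)
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["name", "sequence", "plate", "well"])
        for p in primers:
            seq = p.display.lower() if lowercase else p.display
            pid, well = wellmap.get(p.name, ("", ""))
            w.writerow([p.name, seq, pid, well])


def _primer_dict(p: PrimerSpec) -> dict:
    d = dataclasses.asdict(p)
    if p.anneal_span is not None:
        d["anneal_span"] = [p.anneal_span.start, p.anneal_span.end]
    return d


def _primer_from_dict(d: dict) -> PrimerSpec:
    d = dict(d)
    if d.get("anneal_span") is not None:
        d["anneal_span"] = Span(*d["anneal_span"])
    return PrimerSpec(**d)


def write_plan_json(plan: AssemblyPlan, path: str | Path) -> None:
    """Serialize a plan (without the substitution-set payload closures —
    the reaction lists and primer sequences are the reproducible record)."""
    doc = {
        "scheme": plan.scheme,
        "mode": plan.mode,
        "unit": {
            "name": plan.unit.name,
            "sequence": plan.unit.sequence,
            "promoter": [plan.unit.promoter.start, plan.unit.promoter.end],
            "cds": [[c.start, c.end] for c in plan.unit.cds],
            "polya": [plan.unit.polya.start, plan.unit.polya.end],
        },
        "segments": plan.segments,
        "counts": plan.counts,
        "outer": {k: _primer_dict(v) for k, v in plan.outer.items()},
        "primaries": [
            {**dataclasses.asdict(p), "fwd": _primer_dict(p.fwd),
             "rev": _primer_dict(p.rev),
             "expected_span": None if p.expected_span is None
             else [p.expected_span.start, p.expected_span.end]}
            for p in plan.primaries
        ],
        "secondaries": [
            {**dataclasses.asdict(s), "fwd": _primer_dict(s.fwd),
             "rev": _primer_dict(s.rev)}
            for s in plan.secondaries
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_plan_json(path: str | Path) -> AssemblyPlan:
    doc = json.loads(Path(path).read_text())
    u = doc["unit"]
    unit = load_unit(
        u["sequence"], promoter=tuple(u["promoter"]),
        cds=[tuple(c) for c in u["cds"]], polya=tuple(u["polya"]), name=u["name"],
    )
    primaries = tuple(
        PrimaryReaction(
            id=p["id"], segment=p["segment"], fwd=_primer_from_dict(p["fwd"]),
            rev=_primer_from_dict(p["rev"]), template=p["template"],
            payload_labels=tuple(p["payload_labels"]),
            expected_span=None if p["expected_span"] is None else Span(*p["expected_span"]),
        )
        for p in doc["primaries"]
    )
    secondaries = tuple(
        SecondaryReaction(
            id=s["id"], variant_label=s["variant_label"],
            amplicons=tuple(s["amplicons"]),
            fwd=_primer_from_dict(s["fwd"]), rev=_primer_from_dict(s["rev"]),
        )
        for s in doc["secondaries"]
    )
    return AssemblyPlan(
        scheme=doc["scheme"], mode=doc["mode"], unit=unit,
        substitution_sets=(), segments=doc["segments"],
        primaries=primaries, secondaries=secondaries,
        outer={k: _primer_from_dict(v) for k, v in doc["outer"].items()},
        counts=doc["counts"],
    )


def write_plan_tsv(plan: AssemblyPlan, path: str | Path) -> None:
    """Flat reaction list, one row per PCR."""
    rows = []
    for p in plan.primaries:
        rows.append({
            "stage": "primary", "id": p.id, "segment": p.segment,
            "fwd": p.fwd.name, "fwd_seq": p.fwd.display,
            "rev": p.rev.name, "rev_seq": p.rev.display,
            "template": p.template, "variant": "+".join(p.payload_labels),
        })
    for s in plan.secondaries:
        rows.append({
            "stage": "secondary", "id": s.id, "segment": "",
            "fwd": s.fwd.name, "fwd_seq": s.fwd.display,
            "rev": s.rev.name, "rev_seq": s.rev.display,
            "template": "+".join(s.amplicons), "variant": s.variant_label,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_plate_map(layout: PlateLayout, path: str | Path) -> None:
    """Grid-form plate maps (one block per plate) as CSV."""
    rows_by_size = {96: "ABCDEFGH", 384: "ABCDEFGHIJKLMNOP"}
    ncol = {96: 12, 384: 24}[layout.plate_size]
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        for pid, wm in layout.plates:
            w.writerow([pid] + list(range(1, ncol + 1)))
            for r in rows_by_size[layout.plate_size]:
                w.writerow([r] + [wm.get(f"{r}{c}", "") for c in range(1, ncol + 1)])
            w.writerow([])


def write_score_matrix(matrix: pd.DataFrame, path: str | Path, long: bool = False) -> None:
    """Score matrix as TSV (wide) or long-form CSV."""
    if long:
        matrix.stack().rename("score").reset_index().to_csv(path, index=False)
    else:
        matrix.to_csv(path, sep="\t")
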