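"""In-package fixtures and synthetic-data generators.

Two kinds of data let every operation be exercised without downloads:

* the published saturation primer arrays (D108 on the NanoLuc luciferase
  CDS, L560 on the ACh indicator fusion), their shared counter primers and
  the monotemplated 5' tag, with local template fragments reconstructed from
  the primers' non-mutagenic portions;
* seeded generators for whole synthetic transcription units (optionally
  embedding a fixture fragment at a chosen residue) and for multiwell screen
  tables with planted ground truth, so recovery tests can compare scores
  against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._reagents import PRINTED_PRIMERS
from .assembly import PlateLayout, layout_plates
from .construct import Span, TranscriptionUnit
from .seqcore import DnaSeq, MIDAS_CODON_TABLE, reverse_complement, translate

__all__ = [
    "PRINTED_PRIMERS",
    "PrimerArrayFixture",
    "MIDAS_MM_TAG",
    "D108_ARRAY",
    "L560_ARRAY",
    "SyntheticScreenTruth",
    "synthetic_unit",
    "make_screen_truth",
    "simulate_screen",
    "simulate_dose_response",
]

# 5' tag added to the Fo outer primer in the monotemplated luciferase screen.
MIDAS_MM_TAG = "agttctgggggcagctctagagc"

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PrimerArrayFixture:
    """A published saturation array with its reconstructed local template.

    ``primers`` maps amino acid → printed forward primer (regularized:
    every member is flank + payload codon + flank). ``verbatim`` keeps the
    table strings exactly as printed; for arrays with a known misprint the
    affected member differs from ``primers`` and ``typo_aas`` names it.
    The local template is flank5 + wild-type codon + flank3, reconstructed
    from the non-mutagenic portions of the array.
    """

    gene: str
    residue: int
    wt_aa: str
    flank5: str
    flank3: str
    counter: str
    primers: dict[str, str]
    verbatim: dict[str, str]
    typo_aas: tuple[str, ...] = ()

    @property
    def wt_codon(self) -> str:
        return MIDAS_CODON_TABLE[self.wt_aa].lower()

    @property
    def local_template(self) -> str:
        return self.flank5 + self.wt_codon + self.flank3

    @property
    def flank_lengths(self) -> tuple[int, int]:
        return len(self.flank5), len(self.flank3)


def _build_array(gene: str, prefix: str, counter_name: str, residue: int, wt_aa: str):
    verbatim = {
        aa: PRINTED_PRIMERS[f"{prefix}{aa}-F"] for aa in _AA20
    }
    counter = PRINTED_PRIMERS[counter_name]
    flank5 = reverse_complement(counter).lower()
    # regularize: each member must be flank5 + CODON + flank3; infer flank3
    # from the identity (wild-type) member.
    wt = verbatim[wt_aa]
    assert wt.lower().startswith(flank5)
    flank3 = wt[len(flank5) + 3 :].lower()
    primers, typos = {}, []
    for aa, printed in verbatim.items():
        regular = flank5 + MIDAS_CODON_TABLE[aa].upper() + flank3
        if printed != regular:
            typos.append(aa)
        primers[aa] = regular
    return PrimerArrayFixture(
        gene=gene, residue=residue, wt_aa=wt_aa, flank5=flank5, flank3=flank3,
        counter=counter, primers=primers, verbatim=verbatim, typo_aas=tuple(typos),
    )


# The W member of the D108 array is printed one template base short
# (…TGGatttcgg… instead of …TGGtatttcgg…); it is regularized here and
# flagged via ``typo_aas``.
D108_ARRAY = _build_array("NanoLuc", "NanoLuc-D108", "NanoLuc-D108-R", 108, "D")
L560_ARRAY = _build_array("ACh NeuBI", "ACh NeuBI-L560", "ACh NeuBI-L560-R", 560, "L")


# ---------------------------------------------------------------------------
# Synthetic transcription units
# ---------------------------------------------------------------------------

_SENSE_CODONS = tuple(
    c for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
    if translate(c) != "*"
)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _fix_stops(cds: list[str], protected: range, rng: np.random.Generator) -> None:
    """Replace in-frame stop codons outside the protected nt range."""
    for i in range(0, len(cds) - 3, 3):
        codon = "".join(cds[i : i + 3])
        if translate(codon) == "*":
            free = [j for j in range(i, i + 3) if j not in protected]
            if not free:
                raise ValueError("embedded fragment contains an in-frame stop")
            for _ in range(50):
                for j in free:
                    cds[j] = str(rng.choice(list("ACGT")))
                if translate("".join(cds[i : i + 3])) != "*":
                    break
            else:  # pragma: no cover - 50 draws always suffice
                raise RuntimeError("could not remove in-frame stop")


def synthetic_unit(
    seed: int,
    cds_length: int = 900,
    promoter_length: int = 200,
    polya_length: int = 100,
    pad: int = 60,
    spacer: int = 20,
    name: str = "synthetic",
    avoid: tuple[str, ...] = (MIDAS_MM_TAG,),
) -> TranscriptionUnit:
    """Seeded random template with promoter/CDS/polyA annotations.

    The CDS starts with ATG, ends with a stop codon and contains no internal
    in-frame stop. Sequences in ``avoid`` (the monotemplated tag by default,
    both strands) are rejection-sampled away so tag-uniqueness checks stay
    meaningful. See :func:`synthetic_unit_with_fragment` for embedding a
    published local-template fragment at a chosen residue.
    """
    if cds_length % 3:
        raise ValueError("cds_length must be divisible by 3")
    rng = np.random.default_rng(seed)
    for _attempt in range(100):
        n_codons = cds_length // 3
        body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
        seq_cds = "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"
        full = (
            _random_dna(rng, pad)
            + _random_dna(rng, promoter_length)
            + _random_dna(rng, spacer)
            + seq_cds
            + _random_dna(rng, spacer)
            + _random_dna(rng, polya_length)
            + _random_dna(rng, pad)
        )
        bad = any(
            a.upper() in full or reverse_complement(a) in full for a in avoid
        )
        if not bad:
            break
    else:
        raise RuntimeError("could not sample a template avoiding the given motifs")
    p0 = pad
    c0 = pad + promoter_length + spacer
    a0 = c0 + cds_length + spacer
    return TranscriptionUnit(
        sequence=full,
        promoter=Span(p0, p0 + promoter_length),
        cds=(Span(c0, c0 + cds_length),),
        polya=Span(a0, a0 + polya_length),
        name=name,
    )


def synthetic_unit_with_fragment(
    seed: int,
    fragment_flank5: str,
    wt_codon: str,
    fragment_flank3: str,
    residue: int,
    cds_length: int | None = None,
    name: str = "synthetic",
    **kwargs,
) -> TranscriptionUnit:
    """Synthetic unit whose CDS carries ``flank5+wt_codon+flank3`` with the
    wild-type codon at 1-based ``residue``.

    Used to round-trip published arrays: designing a saturation array on the
    returned unit with the fixture's flank lengths regenerates the printed
    primers byte-for-byte.
    """
    f5, wt, f3 = DnaSeq(fragment_flank5), DnaSeq(wt_codon), DnaSeq(fragment_flank3)
    start_nt = (residue - 1) * 3 - len(f5)
    if start_nt < 3:
        raise ValueError("residue too close to CDS start for this flank")
    need = (residue - 1) * 3 + 3 + len(f3)
    if cds_length is None:
        cds_length = 3 * (need // 3 + 20)
    if cds_length < need + 3:
        raise ValueError("cds_length too short to hold the fragment")
    rng = np.random.default_rng(seed)
    base = synthetic_unit(seed, cds_length=cds_length, name=name, **kwargs)
    c = base.cds[0]
    seq = list(base.sequence)
    frag = f5 + wt + f3
    seq[c.start + start_nt : c.start + start_nt + len(frag)] = list(frag)
    # repair any in-frame stop introduced at the random/fragment boundaries
    cds_list = seq[c.start : c.end]
    _fix_stops(
        cds_list,
        protected=range(start_nt, start_nt + len(frag)),
        rng=rng,
    )
    seq[c.start : c.end] = cds_list
    return TranscriptionUnit(
        sequence="".join(seq),
        promoter=base.promoter,
        cds=base.cds,
        polya=base.polya,
        name=name,
    )


# ---------------------------------------------------------------------------
# Synthetic screens with planted truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticScreenTruth:
    """Ground truth behind a simulated screen.

    activities            substrate → site×substitution true relative
                          activity (parent ≡ 1)
    substrate_scale       substrate → raw-signal scale factor
    transfection_sd       lognormal sigma of per-well transfection
                          efficiency multipliers
    cv                    lognormal coefficient of variation of the
                          measurement noise (0 = noiseless)
    replicates            technical replicates per well
    seed                  generator seed
    """

    activities: dict[str, pd.DataFrame]
    substrate_scale: dict[str, float]
    transfection_sd: float = 0.3
    cv: float = 0.05
    replicates: int = 3
    n_parent_wells: int = 4
    seed: int = 0

    @property
    def sites(self):
        return list(next(iter(self.activities.values())).index)


def make_screen_truth(
    seed: int = 0,
    n_sites: int = 8,
    substrates: tuple[str, ...] = ("S1",),
    tolerant_sites: tuple[int, ...] = (0,),
    intolerant_sites: tuple[int, ...] = (1,),
    preferring: dict[tuple[str, str], str] | None = None,
    cv: float = 0.05,
    replicates: int = 3,
) -> SyntheticScreenTruth:
    """Planted truth: tolerant sites keep near-wild-type activity for all 20
    substitutions, intolerant sites lose essentially all activity, the rest
    are intermediate. ``preferring`` plants substrate-preferring variants,
    e.g. ``{("site3", "C"): "S2"}`` boosts that variant on substrate S2.
    """
    rng = np.random.default_rng(seed)
    sites = [f"site{i}" for i in range(n_sites)]
    subs = list(_AA20)
    base = pd.DataFrame(
        rng.uniform(0.3, 0.9, size=(n_sites, 20)), index=sites, columns=subs
    )
    for i in tolerant_sites:
        base.iloc[i] = rng.uniform(0.85, 1.15, size=20)
    for i in intolerant_sites:
        base.iloc[i] = rng.uniform(0.0, 0.03, size=20)
    activities = {s: base.copy() for s in substrates}
    for (site, sub), fav in (preferring or {}).items():
        for s in substrates:
            activities[s].loc[site, sub] = 1.5 if s == fav else 0.9
    scale = {s: float(rng.uniform(0.5, 2.0)) for s in substrates}
    return SyntheticScreenTruth(
        activities=activities, substrate_scale=scale, cv=cv,
        replicates=replicates, seed=seed,
    )


def simulate_screen(
    truth: SyntheticScreenTruth, layout: PlateLayout | None = None
) -> pd.DataFrame:
    """Tidy screen table from planted truth.

    signal = activity × substrate scale × per-well transfection multiplier ×
    lognormal noise; the co-expressed reference reporter sees the same
    transfection multiplier (its own noise draw), so expression
    normalization cancels the planted confounder exactly in the noiseless
    limit. Parent (wild-type, activity 1) and vehicle controls are included
    per condition.
    """
    rng = np.random.default_rng(truth.seed)
    sites = truth.sites
    subs = list(next(iter(truth.activities.values())).columns)
    # several parent-control wells per plate, as in real control columns:
    # averaging them keeps the parent-normalization noise well below the
    # per-variant noise
    parent_labels = [f"parent{i + 1}" for i in range(truth.n_parent_wells)]
    labels = [f"{site}:{sub}" for site in sites for sub in subs] + parent_labels
    if layout is None:
        layout = layout_plates(labels, plate_size=384 if len(labels) > 96 else 96)
    wellmap = {
        lab: (pid, w) for pid, wm in layout.plates for w, lab in wm.items()
    }
    missing = [l for l in labels if l not in wellmap]
    if missing:
        raise ValueError(f"layout does not cover all variants: {missing[:3]}...")
    sigma = np.sqrt(np.log1p(truth.cv**2)) if truth.cv > 0 else 0.0

    def noise(n):
        return rng.lognormal(0.0, sigma, size=n) if sigma else np.ones(n)

    # one transfection multiplier per well (shared by signal and reference)
    tmult = {
        lab: float(rng.lognormal(0.0, truth.transfection_sd)) for lab in labels
    }
    rows = []
    ref_scale = 100.0
    for substrate in truth.activities:
        scale = truth.substrate_scale[substrate] * 1000.0
        for lab in labels:
            if lab in parent_labels:
                site = sub = ""
                act, role = 1.0, "parent"
            else:
                site, sub = lab.split(":")
                act = float(truth.activities[substrate].loc[site, sub])
                role = "sample"
            pid, w = wellmap[lab]
            s = act * scale * tmult[lab] * noise(truth.replicates)
            r = ref_scale * tmult[lab] * noise(truth.replicates)
            for i in range(truth.replicates):
                rows.append(
                    (pid, w, lab, site, sub, substrate, np.nan, s[i], r[i], role)
                )
        # vehicle wells: background only
        bg = 0.01 * scale * noise(truth.replicates)
        bgr = ref_scale * noise(truth.replicates)
        for i in range(truth.replicates):
            rows.append(
                ("ctrl", "H12", "vehicle", "", "", substrate, 0.0, bg[i], bgr[i], "vehicle")
            )
    return pd.DataFrame(rows, columns=[
        "plate", "well", "variant", "site", "substitution",
        "condition", "concentration", "signal", "reference_signal", "role",
    ])


def simulate_dose_response(
    seed: int,
    bottom: float = 1.0,
    top: float = 7.4,
    ec50: float = 898.0,
    hill: float = 1.0,
    doses: np.ndarray | None = None,
    cv: float = 0.0,
    replicates: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic 4PL measurements (doses, responses), lognormal noise at the
    given CV, for fit-recovery tests."""
    from .screen import four_parameter_logistic

    rng = np.random.default_rng(seed)
    if doses is None:
        doses = np.geomspace(ec50 / 100, ec50 * 100, 8)
    d = np.repeat(np.asarray(doses, dtype=float), replicates)
    y = four_parameter_logistic(d, bottom, top, ec50, hill)
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        y = y * rng.lognormal(0.0, sigma, size=len(d))
    return d, y
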