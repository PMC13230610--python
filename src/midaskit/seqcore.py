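"""Exact DNA sequence primitives for enumerated mutagenesis design.

Every oligo in an arrayed deterministic-mutagenesis experiment is an exact,
enumerated sequence — no degenerate (NNS/NNK) positions — so this module is
deliberately strict: only A/C/G/T are accepted, IUPAC ambiguity codes are
rejected, and codon payloads come from an explicit 20-entry amino-acid →
codon choice table rather than a degeneracy scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "DnaSeq",
    "CodonChoiceTable",
    "TmParams",
    "MIDAS_CODON_TABLE",
    "reverse_complement",
    "translate",
    "melting_temperature",
    "min_codon_changes",
    "codons_for",
]

_VALID = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def DnaSeq(bases: str) -> str:
    """Canonicalize ``bases`` to an uppercase A/C/G/T string.

    Whitespace is stripped; case is folded. Any other character (including
    IUPAC ambiguity codes and U) raises ``ValueError`` — enumerated oligo
    design has no place for ambiguity.
    """
    s = "".join(str(bases).split()).upper()
    bad = set(s) - _VALID
    if bad:
        raise ValueError(
            f"invalid DNA character(s) {sorted(bad)}; only A/C/G/T accepted"
        )
    return s


def reverse_complement(s: str) -> str:
    """Watson–Crick reverse complement. Involution: rc(rc(s)) == s."""
    return DnaSeq(s).translate(_COMPLEMENT)[::-1]


def translate(s: str, frame: int = 0) -> str:
    """Standard-genetic-code translation of ``s`` starting at ``frame``.

    Stops are rendered ``*``; a trailing partial codon is dropped. The
    remaining sequence must contain at least one full codon.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    s = DnaSeq(s)
    if len(s) - frame < 3:
        raise ValueError("sequence too short to translate a single codon")
    trimmed = s[frame : frame + 3 * ((len(s) - frame) // 3)]
    return str(Seq(trimmed).translate())


# ---------------------------------------------------------------------------
# Codon choice tables
# ---------------------------------------------------------------------------

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# One codon per amino acid as used in the published saturation primer arrays
# (identical codon set in the D108 and L560 arrays).
_MIDAS_CODONS = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGG", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "AGA",
    "S": "TCC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}


@dataclass(frozen=True)
class CodonChoiceTable:
    """Mapping of the 20 amino acids to the single codon used in payloads."""

    codons: dict[str, str]
    name: str = "custom"

    def __post_init__(self) -> None:
        if set(self.codons) != set(_AA20):
            raise ValueError("codon choice table must cover exactly the 20 amino acids")
        canonical = {aa: DnaSeq(c) for aa, c in self.codons.items()}
        for aa, codon in canonical.items():
            if len(codon) != 3:
                raise ValueError(f"codon for {aa} is not 3 nt: {codon}")
            if translate(codon) != aa:
                raise ValueError(f"codon {codon} does not encode {aa}")
        object.__setattr__(self, "codons", canonical)

    def __getitem__(self, aa: str) -> str:
        aa = aa.upper()
        if aa not in self.codons:
            raise KeyError(f"unknown amino acid {aa!r}")
        return self.codons[aa]

    def encode(self, peptide: str) -> str:
        """Back-translate a peptide using this table."""
        return "".join(self[aa] for aa in peptide)


MIDAS_CODON_TABLE = CodonChoiceTable(_MIDAS_CODONS, name="midas-paper")


def codons_for(aa: str) -> tuple[str, ...]:
    """All standard sense codons (or stop codons for '*') encoding ``aa``."""
    aa = aa.upper()
    if aa == "*":
        return tuple(standard_dna_table.stop_codons)
    hits = tuple(
        sorted(c for c, a in standard_dna_table.forward_table.items() if a == aa)
    )
    if not hits:
        raise ValueError(f"unknown amino acid {aa!r}")
    return hits


# ---------------------------------------------------------------------------
# Melting temperature
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TmParams:
    """Nearest-neighbor duplex Tm settings.

    method          identifier recorded in output metadata
    monovalent_mm   monovalent cation concentration, mM
    oligo_nm        oligo concentration, nM (primer in excess over target)
    """

    method: str = "nn-santalucia-unified"
    monovalent_mm: float = 50.0
    oligo_nm: float = 500.0

    def __post_init__(self) -> None:
        if self.monovalent_mm <= 0 or self.oligo_nm <= 0:
            raise ValueError("Tm concentrations must be positive")


DEFAULT_TM_PARAMS = TmParams()


def melting_temperature(s: str, params: TmParams | None = None) -> float:
    """Nearest-neighbor duplex melting temperature in °C.

    Uses the unified NN parameter set with an entropic monovalent-salt
    correction. Valid for oligo lengths 6–60 nt, the regime of PCR primers
    and overlap regions.
    """
    p = params or DEFAULT_TM_PARAMS
    s = DnaSeq(s)
    if not 6 <= len(s) <= 60:
        raise ValueError(f"Tm defined for 6–60 nt oligos, got {len(s)} nt")
    return float(
        _mt.Tm_NN(
            s,
            nn_table=_mt.DNA_NN3,
            Na=p.monovalent_mm,
            dnac1=p.oligo_nm,
            dnac2=0,
            selfcomp=s == reverse_complement(s),
            saltcorr=5,
        )
    )


# ---------------------------------------------------------------------------
# Codon substitution paths
# ---------------------------------------------------------------------------


def _diff_pattern(src: str, dst: str) -> tuple[tuple[int, str, str], ...]:
    return tuple(
        (i, a, b) for i, (a, b) in enumerate(zip(src, dst)) if a != b
    )


def min_codon_changes(
    from_codon: str, to_aa: str
) -> tuple[int, set[tuple[str, tuple[tuple[int, str, str], ...]]]]:
    """Minimum base changes to convert ``from_codon`` into any codon of ``to_aa``.

    Returns ``(min_changes, paths)`` where each path is a
    ``(codon, changed-positions)`` pair and each changed position is a
    ``(index, from_base, to_base)`` triple. This is the quantity that decides
    whether an amino-acid change is reachable by single-base errors (as in
    error-prone PCR) or requires a multi-base substitution that only
    enumerated mutagenesis delivers — e.g. Asp(GAC)→Ser needs a GA→AG or
    GA→TC double change.
    """
    src = DnaSeq(from_codon)
    if len(src) != 3:
        raise ValueError("from_codon must be 3 nt")
    targets = codons_for(to_aa)
    best = min(sum(a != b for a, b in zip(src, t)) for t in targets)
    paths = {
        (t, _diff_pattern(src, t))
        for t in targets
        if sum(a != b for a, b in zip(src, t)) == best
    }
    return best, paths


def hamming(a: str, b: str) -> int:
    """Base differences between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))
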