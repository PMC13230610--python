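"""Library-economics models for mutagenesis screens.

Compares three routes to a multi-nucleotide variant:

* **error-prone PCR**: the chance that a specific codon picks up ``n``
  specific base changes while the gene stays functional is
  ``(rate × functional)**n × Π(aᵢ/4) × m`` — ``rate`` the per-nucleotide
  mutagenesis rate, ``functional`` the fraction of mutagenized clones
  retaining function at that rate, ``aᵢ`` the number of acceptable bases at
  change *i*, and ``m`` the number of distinct codon paths reaching the
  target amino acid;
* **degenerate-codon libraries** (NNS/NNK): ``32**P × oversampling`` clones
  for *P* saturated positions;
* **arrayed deterministic mutagenesis**: exactly one well per enumerated
  variant, i.e. the plain product (or sum, for independent sites) of the
  substitution-set sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EpcrModel",
    "EpcrResult",
    "DegenerateLibrary",
    "FoldResult",
    "epcr_recovery",
    "degenerate_library_samples",
    "midas_sample_count",
    "responsivity_fold",
    "round_sig",
]


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class EpcrModel:
    """Recovery of a specific multi-base change from error-prone PCR.

    rate         per-nucleotide mutagenesis rate (fraction)
    functional   fraction of clones retaining function at that rate
    n            number of required base changes
    acceptable   acceptable-base count per change, each in 1..4
                 (4 means any base at that position works)
    multiplicity number of distinct codon paths to the target amino acid
    strict_base_model  use acceptable/3 instead of acceptable/4 for the
                 probability a mutated base lands on an acceptable base
                 (a mutation cannot reproduce the original base); default
                 False, matching the published 1/4 convention.
    """

    rate: float
    functional: float
    n: int = 1
    acceptable: tuple[int, ...] = (4,)
    multiplicity: int = 1
    strict_base_model: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.rate < 1 or not 0 < self.functional < 1:
            raise ValueError("rate and functional fraction must be in (0, 1)")
        if self.n < 1 or self.multiplicity < 1:
            raise ValueError("n and multiplicity must be >= 1")
        if len(self.acceptable) != self.n:
            raise ValueError("one acceptable-base count per required change")
        if any(not 1 <= a <= 4 for a in self.acceptable):
            raise ValueError("acceptable-base counts must be in 1..4")


@dataclass(frozen=True)
class EpcrResult:
    frequency: float
    one_in: float
    one_in_rounded: float


def epcr_recovery(model: EpcrModel) -> EpcrResult:
    """Per-clone recovery frequency and its '1 in N' form.

    N is rounded to one significant figure below 10^5 and to two above,
    matching how such screen sizes are conventionally quoted.
    """
    denom = 3.0 if model.strict_base_model else 4.0
    freq = (model.rate * model.functional) ** model.n
    for a in model.acceptable:
        freq *= a / denom
    freq *= model.multiplicity
    one_in = 1.0 / freq
    sig = 1 if one_in < 1e5 else 2
    return EpcrResult(freq, one_in, round_sig(one_in, sig))


@dataclass(frozen=True)
class DegenerateLibrary:
    """NNS/NNK-style pooled library: codons**positions × oversampling."""

    positions: int
    codons: int = 32
    oversampling: int = 10

    def __post_init__(self) -> None:
        if self.positions < 0 or self.codons < 1 or self.oversampling < 1:
            raise ValueError("library parameters must be positive")


def degenerate_library_samples(lib: DegenerateLibrary) -> int:
    return lib.codons**lib.positions * lib.oversampling


def midas_sample_count(set_sizes, combinatorial: bool = True) -> int:
    """Wells needed for enumerated mutagenesis.

    ``combinatorial=True`` multiplies the per-site variant counts (all
    combinations built); ``False`` sums them (sites screened independently).
    """
    sizes = [int(s) for s in set_sizes]
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("set sizes must be nonempty positive integers")
    return math.prod(sizes) if combinatorial else sum(sizes)


@dataclass(frozen=True)
class FoldResult:
    exact: float
    rounded: int
    floored: int


def responsivity_fold(new: float, old: float) -> FoldResult:
    """Fold change new/old, with both nearest-integer and floored renderings
    (usage varies when quoting 'x-fold' figures)."""
    if old <= 0:
        raise ValueError("reference value must be positive")
    f = new / old
    return FoldResult(f, round(f), math.floor(f))
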