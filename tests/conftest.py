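import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from midaskit.construct import SubstitutionSet, resolve_target_region, substitution
from midaskit.fixtures import (
    D108_ARRAY,
    L560_ARRAY,
    synthetic_unit,
    synthetic_unit_with_fragment,
)


@pytest.fixture(scope="session")
def unit():
    """Plain seeded synthetic transcription unit (900 nt CDS)."""
    return synthetic_unit(1, cds_length=900, name="syn")


@pytest.fixture(scope="session")
def d108_unit():
    """Synthetic unit carrying the published D108 local template at residue 108."""
    return synthetic_unit_with_fragment(
        1, D108_ARRAY.flank5, D108_ARRAY.wt_codon, D108_ARRAY.flank3,
        D108_ARRAY.residue, name="NanoLuc",
    )


@pytest.fixture(scope="session")
def l560_unit():
    """Synthetic unit carrying the published L560 local template at residue 560."""
    return synthetic_unit_with_fragment(
        2, L560_ARRAY.flank5, L560_ARRAY.wt_codon, L560_ARRAY.flank3,
        L560_ARRAY.residue, name="ACh NeuBI",
    )


def saturation_sets(unit, residues, aas):
    """Substitution sets of single-residue saturation payloads."""
    prot = unit.protein()
    out = []
    for r, aa in zip(residues, aas):
        tr = resolve_target_region(unit, r)
        payloads = tuple(
            substitution({r: a}, label=f"{prot[r - 1]}{r}{a}") for a in aa
        )
        out.append(SubstitutionSet(tr, payloads, name=f"TR@{r}"))
    return out
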