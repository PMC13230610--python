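# midaskit

Toolkit for **arrayed deterministic deep mutagenesis by overlap-extension
PCR** (the MIDAS family of protocols: microbe-independent deep assembly and
screening). Instead of pooled degenerate libraries (NNS/NNK) or error-prone
PCR, every variant gene is built as its own linear transcription unit —
promoter, CDS, polyA signal — by two rounds of multiwell PCR, transfected
directly into mammalian cells, and read out by well position. midaskit
provides the computational side of that workflow:

* **Primer design** — mutagenic primers (`5'-flank + payload codons +
  3'-anneal arm`, arms 18–24 nt by default, extended when the 60–66 °C
  overlap-Tm window demands it), non-mutagenic counter primers whose 5'
  region is the reverse complement of the mutagenic primers' shared flank,
  outer primers bracketing the transcription unit, and — for monotemplated
  protocols — 5' tags absent from the template plus nested primers that
  prime only on the tag.
* **Assembly planning** — segmented primary/secondary PCR plans for one or
  many target regions under both combinatorial schemes (*per-segment*:
  *i*+1 segments for *i* target regions, secondaries from the cross
  product; *per-permutation*: one primary per permutation, one-to-one
  secondaries), 96/384-well plate layouts, and **in-silico PCR** (exact
  3'-seed priming, exact-overlap extension) to verify every planned product
  — including the template-reamplification hazard that tags eliminate.
* **Library economics** — recovery frequency of specific multi-base changes
  from error-prone PCR, `(rate × functional)ⁿ × Π(aᵢ/4) × m`; degenerate
  library sizing `32ᴾ × oversampling`; arrayed well counts; fold
  comparisons.
* **Screen scoring** — expression normalization against a co-expressed
  reference reporter, vehicle-control normalization (fold / %-increase),
  per-site mutational tolerance (mean and sum of activity relative to wild
  type), substrate-specificity preference matrices with censoring of
  variants below 25 % of parent activity, and variable-slope
  four-parameter-logistic dose-response fits.
* **Fixtures and simulators** — published saturation primer arrays with
  reconstructed local templates, seeded synthetic transcription units, and
  screen simulators with planted ground truth for recovery testing.

## Worked example

Regenerate a published 20-member saturation array and verify one
monotemplated assembly in silico:

```python
from midaskit.fixtures import (D108_ARRAY, MIDAS_MM_TAG,
                               synthetic_unit_with_fragment)
from midaskit.construct import resolve_target_region
from midaskit.primers import design_saturation_array, design_counter_primer
from midaskit.assembly import plan_assembly, simulate_secondary
from midaskit.construct import SubstitutionSet, substitution

unit = synthetic_unit_with_fragment(
    1, D108_ARRAY.flank5, D108_ARRAY.wt_codon, D108_ARRAY.flank3,
    residue=108, name="NanoLuc")
tr = resolve_target_region(unit, 108)

arr = design_saturation_array(unit, tr, flank5=19, flank3=19)
print(arr[11].name, arr[11].display)
print(design_counter_primer(unit, tr, length=19).display)

sets = [SubstitutionSet(tr, (substitution({108: "S"}, label="D108S"),))]
plan = plan_assembly(unit, sets, mode="monotemplated",
                     tag_policy="both", tags={"fo": MIDAS_MM_TAG}, seed=5)
products = simulate_secondary(plan, plan.secondaries[0],
                              residual_template=True)
print(len(products))
```

prints

```
NanoLuc-D108N-F ggttacgccgaacatgatcAACtatttcggacggccgtatg
gatcatgttcggcgtaacc
1
```

— the Asn-payload member of the array (lowercase = template-matching
flanks, uppercase = payload codon), the shared counter primer (the reverse
complement of the 19-nt upstream flank), and exactly **one** full-length
product from the tagged secondary reaction even with residual plasmid
template in the mix (an untagged design would yield two: mutant plus
reamplified parent).

The same library is available from a shell:

```bash
midas design --template unit.fasta --promoter 60 260 --cds 280 1180 \
      --polya 1200 1300 --residue 108 --out out/
midas lib-math --json
```

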