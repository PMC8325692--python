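# srnase

Tools for identifying S-RNase self-incompatibility determinants in wild
strawberry (*Fragaria*) and for the genetics that validates them.

Diploid *Fragaria viridis* is self-incompatible while close relatives such
as *F. vesca* are self-compatible. The style determinant of the underlying
gametophytic self-incompatibility (GSI) system is an S-RNase — a secreted,
basic ribonuclease of the RNase T2 family encoded at the S locus. This
package implements the complete in-silico workflow that pins the
determinant down:

1. **Candidate screen** (`srnase.candidate_screen`): a five-stage filter
   cascade over an RNase T2 family feature table — secretory signal
   peptide present, RNase T2 domain coverage > 60 %, isoelectric point
   pI ∈ [8, 10], intron count ≤ 2, no diagnostic "pattern 4" motif
   (CPSS[N/S]G, which marks non-S family members) — followed by allele
   pairing: S-RNase alleles within a species are strongly polymorphic
   (30–90 % amino-acid identity) yet more similar to each other than to
   S-RNases of other tribes.
2. **GSI genetics** (`srnase.si_genetics`): genotype calling from
   allele-specific amplicon band patterns (the two alleles differ by a
   fixed 9-bp offset), cross-outcome prediction under the GSI rule
   (pollen with a haplotype matching either style allele is rejected),
   progeny simulation, and χ² goodness-of-fit testing of genotype counts
   against Mendelian ratios.
3. **S-locus mapping** (`srnase.synteny_mapping`): flank the known
   S-RNase positions of related genomes, project them through collinear
   blocks, and intersect the projected spans to a candidate S-locus
   interval; query which genes reside in it.
4. **Expression** (`srnase.expression_quant`): relative expression by the
   2^−ΔΔCt method against an EF-1α reference.
5. **Synthetic data** (`srnase.synthetic_data`): seedable generators that
   plant a known truth behind every input — decoy feature tables with a
   hidden allele pair, band patterns with Gaussian size noise, block sets
   with a known overlap — so the whole pipeline is testable offline.

Packaged fixtures transcribe the published *F. vesca* (14 genes) and
*F. viridis* (13 genes) RNase T2 family tables, the 29-line S-genotype
panel, a 214-progeny selfing population, and the three chromosome-6
collinear blocks.

## Worked example

```python
from srnase.candidate_screen import run_screen
from srnase.datasets import (
    CROSSTRIBE_REF_IDS, load_fviridis_features,
    load_candidate_identities, load_crosstribe_identities,
)

report = run_screen(
    load_fviridis_features(),
    load_candidate_identities(),
    crosstribe=load_crosstribe_identities(),
    crosstribe_refs=CROSSTRIBE_REF_IDS,
)
sp = report.species_reports["F. viridis"]
print([len(s.kept_ids) for s in sp.stages])
print(sp.allele_pairs)
print(sp.final_candidates)
```

prints

```
[8, 7, 4, 4, 4]
[('Unigene23139.1', 'Unigene7320.1', 30.88), ('Unigene10929.1', 'Unigene7320.1', 56.48)]
['Unigene10929.1', 'Unigene7320.1']
```

— of 13 family members, 8 carry a signal peptide, 7 of those an intact
domain, 4 a basic pI, and all 4 pass the intron filter; two pairs fall in
the 30–90 % identity window, and only the 56.48 %-identical pair beats its
members' similarity to cross-tribe S-RNases, leaving Unigene10929.1 and
Unigene7320.1 (the Sa/Sb-RNase alleles) as the final candidates.

The genetics side, from the shell:

```sh
$ srnase segregation --counts 48,106,60 --ratio 1,2,1
{ ... "chi2": 1.3645, "df": 2, "p_value": 0.5055, "rejects": false ... }
$ srnase cross --style SaSb --pollen SaSa
{ ... "outcome": "incompatible", "compatible_fraction": 0.0 }
```

The 214 selfed progeny of a SaSb heterozygote (48:106:60) fit 1:2:1, and
a heterozygous style rejects every pollen haplotype of a SaSa donor —
the behavior that confirms Sa and Sb are alleles of one S locus.

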