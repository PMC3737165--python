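# pednull

Null-allele and deletion detection from SNP genotypes in three-generation
intercross families.

A **null allele** is a marker allele that fails to amplify during
genotyping — because of a deletion spanning the marker, a polymorphism
under the primer-annealing site, or a triallelic SNP site. An individual
heterozygous for a null is called homozygous for its other allele, and a
null homozygote yields a missing call. In family data this produces a
recognizable fingerprint: Mendelian incompatibilities between parents and
offspring, and clusters of missing genotypes. `pednull` scans SNP
genotypes from three-generation intercross families (F0 grandparents, F1
parents, F2 offspring — the classic experimental-cross design in
agricultural genetics), separates null alleles from genotyping errors, and
flags candidate deletions where adjacent markers show *linked* null
alleles in the same individuals.

## Method

For each SNP in each family the package:

1. finds every Mendelian incompatibility between a parent and one of its
   offspring (at both the F1–F2 and F0–F1 levels); at a biallelic marker a
   single pair can only conflict by being called *different homozygotes*;
2. enumerates null-allele assignments to the F1 parents that reproduce
   every observed call under the observation model (het-with-null → called
   homozygous, null homozygote → missing), subject to the grandparent
   filter: an F1 may carry a null only if one of its F0 parents is called
   homozygous or missing;
3. computes the minimum number of single-genotype substitutions that would
   instead restore Mendelian consistency without nulls (an exhaustive
   breadth-first edit search).

Each SNP × family lands in exactly one category: five null-allele classes
ordered by strength of evidence —

| class | evidence |
|-------|----------|
| 1 | >1 incompatibility, not explainable by one genotyping error |
| 2 | >1 incompatibility, explainable by one genotyping error |
| 3 | one F0–F1 incompatibility, no further incompatibilities expected |
| 4 | one incompatibility where more would be expected under a null |
| 5 | >5 F2 missing with both parents homozygous/missing, or both homozygotes but no heterozygote in the F2 |

— or a genotyping-error category (`err_diffhom` / `err_other`, when no
null assignment explains the calls), or `consistent`. Two families'
results are merged (lower class wins; class 4 defers to class 5; null
evidence beats error evidence).

Because the families share founders, true null alleles should appear at
similar rates in both families, whereas genotyping errors turn out to be
strongly family-biased. Modelling a class as a mixture of nulls (family
ratio 1) and a fraction *x* of errors (family ratio *r<sub>e</sub>*), the
observed family-1 : family-2 ratio is

&nbsp;&nbsp;&nbsp;&nbsp;*r* = (1 − *x*) + *x·r<sub>e</sub>*,&nbsp;&nbsp;so&nbsp;&nbsp;*x̂* = (*r* − 1)/(*r<sub>e</sub>* − 1).

Finally, a pair of *adjacent* markers with null alleles carried by the
same F1 parent and ≥3 common F2 individuals in one family is called a
candidate deletion, sized by the distance between the markers.

A gene-drop simulator reproduces the study design (one shared F0
grandfather, three grandmothers, two families of ~23–25 F2) with
injectable null alleles, multi-marker deletion runs, genotyping errors and
missingness, plus a truth table for measuring recall.

## Worked example

Simulate two families with a 2-marker deletion in the grandfather (markers
101–102), one extra single-marker null, a 0.1% genotyping error rate and
1% missingness; then scan and call deletions:

```
$ pednull simulate --out-dir sim --seed 42 --n-markers 500 \
    --null-marker GF:100:2 --null-marker GM2:300 \
    --error-rate 0.001 --missing-rate 0.01
$ pednull scan --ped sim/sim.ped --map sim/sim.map \
    --pedigree sim/sim.pedigree.tsv --out-dir scan
INFO category totals: {'consistent': 479, 'class4': 7, 'err_diffhom': 9,
                       'class1': 2, 'err_other': 2, 'class2': 1}
INFO null alleles: 0.6%, genotyping errors: 3.6%
$ pednull deletions --ped sim/sim.ped --map sim/sim.map \
    --pedigree sim/sim.pedigree.tsv --out-dir del
INFO called 1 candidate deletion region(s)
$ cat del/deletions.tsv
region   chrom  snps               classes  first_position  second_position  size_kb  families  carrier_parents  n_shared_f2  run
region_1 1      snp00101,snp00102  class1   10100000        10200000         100.0    1         F1_1             1:19         no
```

The injected deletion is recovered: both markers of the run are
null-classified in family 1 with the same carrier parent (`F1_1`) and 19
shared putative F2 carriers, giving one candidate region of 100 kb (the
marker spacing — the method can only size a deletion by its flanking
markers). The sporadic single-genotype errors injected by the noise model
land in class 4 and the error categories, which is exactly why class 4 is
counted with the errors in the headline percentages. `scan` also writes
`summary.tsv`/`summary.json` with per-family counts, family ratios, and
mixture error estimates per class.

## Layout

- `pednull.pedmodel` — markers, pedigree, genotype calls; PED/MAP,
  long-TSV, and pedigree-TSV readers/writers
- `pednull.nullscan` — incompatibility detection, null-hypothesis
  enumeration, minimum-error edit search
- `pednull.classify` — the five-class classifier and two-family
  integration
- `pednull.famstats` — summary table, family ratios, mixture estimator
- `pednull.delcall` — adjacent-marker deletion calling, BED/TSV output
- `pednull.simgen` — gene-drop simulator and truth tables
- `pednull.cli` — `pednull scan | summarize | deletions | simulate`

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
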