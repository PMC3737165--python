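# Methods

## The detection problem

At a biallelic SNP with alleles coded 1 and 2, a genotyping assay reports
an unordered allele pair or a missing call. A *null allele* (coded 0
internally) does not amplify, so the true genotype and the reported call
are related by a simple observation model:

    (a, b) -> (a, b)        ordinary genotype, called faithfully
    (a, 0) -> (a, a)        hemizygous carrier called homozygous
    (0, 0) -> missing       null homozygote fails entirely

Nothing in a single genotype reveals a null; the signal is relational. In
a three-generation intercross family (two F0 grandparent pairs, two F1
parents, a few dozen F2 offspring) a segregating null produces Mendelian
incompatibilities — most visibly a parent and offspring called homozygous
for *different* alleles — and clusters of missing F2 calls when both
parents transmit nulls. Genotyping errors produce superficially similar
conflicts, so the package's job is to separate the two mechanisms.

## Incompatibility detection

An incompatibility is counted per (parent, offspring) pair per marker, at
both the F1–F2 and F0–F1 levels; an offspring conflicting with both
parents counts twice. Missing calls never generate incompatibilities. At
a biallelic marker a lone parent-offspring pair can only conflict as
different homozygotes; violations that appear only when the offspring is
checked against both parents jointly (e.g. a heterozygous child of two
identical homozygotes) are recorded with kind `other` and attributed to
the first parent of the pair, a bookkeeping choice that matters only for
the per-pair counting unit, not for classification outcomes (any such
marker is never null-consistent, so it falls into an error category
regardless of the exact count).

## Null-hypothesis enumeration

A hypothesis assigns 0, 1, or 2 null alleles to each F1 parent (at least
one null overall). The observed call constrains the carrier's true
genotype: a one-null carrier must be called homozygous for its visible
allele or missing; a two-null carrier must be missing. A hypothesis is
accepted only if

1. every carrier passes the grandparent filter — one of its F0 parents is
   called homozygous or missing (a heterozygous F0 call means both of that
   grandparent's alleles amplify, so it cannot silently donate a null);
2. the F1 true genotypes are jointly derivable from some assignment of
   true genotypes to the F0 individuals, with nulls permitted only in the
   designated grandparental source(s) of each carrier's null. The F0
   layer is solved jointly because the two F1 parents share their sire
   (the intercross grandfather), so his true genotype must explain both;
3. every called offspring is producible as one allele from each parent's
   hypothesised genotype, read through the observation model.

Observed-missing individuals never block a hypothesis (a missing call may
be a null homozygote or ordinary assay dropout). The hypothesis records
its putative F2 carriers: called offspring whose calls *require* a
transmitted null, plus missing offspring wherever the hypothesis can make
them null homozygotes. These carrier sets are what the deletion caller
later intersects across adjacent markers.

The enumeration is exhaustive over the (at most eight) carrier
configurations and the small per-individual genotype domains, so no
heuristic search or tie-break is involved. When several hypotheses
survive, classification is unaffected — it depends only on
incompatibility counts and the edit search — and all hypotheses are kept
as evidence.

## Minimum-error explanation

The alternative explanation for conflicts is genotyping error. The
package computes the minimum number of single-genotype substitutions
(changing one individual's call to another concrete genotype) that makes
the whole three-generation family Mendelian-consistent without nulls,
searching breadth-first in edit count over all family members including
the F0 grandparents. Replacement by *missing* is excluded: it would erase
any conflict trivially, and the natural worked explanations of this kind
always substitute concrete genotypes. Consistency under a trial edit is
decided by an exact joint feasibility check (missing individuals are free
variables; the shared grandfather again couples the two F1 derivations).
The search is capped: classification only needs to distinguish 0, 1, and
≥2 edits, so it runs with cap 2 (the API allows a deeper cap).

## Classification

Each SNP × family receives exactly one category, decided in order:

* incompatibilities present but **no** accepted null hypothesis →
  `err_diffhom` if any incompatibility is a different-homozygote pair,
  else `err_other`;
* more than one incompatibility → `class1` if no single edit explains
  them, `class2` if one does;
* exactly one incompatibility → `class3` when it is F0–F1 and both F1
  parents share the same homozygous call (no further incompatibilities
  are then possible in the F2), else `class4` (more incompatibilities
  would have been expected under a real null);
* no incompatibilities, but more than `min_missing` (default 5) F2
  missing with both parents called homozygous or missing → `class5`;
  markers where fewer than two F2 have calls are excluded as likely
  whole-assay failures. Each *called* (homozygous) parent must also pass
  the grandparent filter; a missing parent is exempt, since it may itself
  be a null homozygote;
* no incompatibilities, both homozygotes but no heterozygote among the
  F2 (more than one of each homozygote), one parent missing and the other
  heterozygous → `class5` (the missing parent carrying two nulls). No
  grandparent condition is imposed here: the implicated parent is
  missing, so its grandparental evidence is unconstrained anyway;
* otherwise `consistent`.

Classes 1–2 carry direct multi-offspring evidence; classes 3–4 rest on a
single conflict; class 5 is inferred purely from missingness patterns.

### Two-family integration

When a SNP is classified in both families: identical categories stand;
two different null classes resolve to the numerically lower one, except
class 4 + class 5 → class 5 (class 4 proved by far the least reliable);
null evidence beats error evidence beats `consistent`; two error
categories resolve to `err_diffhom` whenever either family showed a
different-homozygote error. Pairs the original scheme never enumerated
(e.g. class 2 + class 5) follow the lower-class rule — a defined
extension, chosen because the lower classes carry the stronger direct
evidence. The *both-families* flag is set when both families
independently show any null class.

## Family-ratio mixture estimator

The two families descend from shared founders (common grandfather, one
shared grandmother, remaining grandmothers from the same line), so a
segregating null allele is roughly equally likely to be detected in
either family, while genotyping errors are empirically strongly enriched
in one family. Treating a null class as a mixture of nulls (family-1 :
family-2 ratio 1) and a fraction *x* of error SNPs (ratio r_e, measured
from the different-homozygotes error category), the class's observed
ratio is r = (1 − x) + x·r_e, giving the estimator x̂ = (r − 1)/(r_e − 1).
The estimate is computed only for classes with r ≥ 1 and requires
r_e > 1; it is reported as an integer percentage, with headline summary
percentages reported to one decimal. A family-2 count of zero leaves the
ratio undefined (reported as unavailable, never as zero). Point estimates
only; no interval is attached, since the estimator's input ratios come
from small counts whose sampling error is better judged from the
per-family counts that the summary table also prints.

## Deletion calling

Single-marker nulls cannot distinguish a deletion from a primer-site
polymorphism. The caller therefore requires *linked* nulls: two markers
adjacent in the sorted map (adjacency by map order, not a bp window —
regions are defined by SNP pairs on the panel in use), null-classified in
the same family, with some null hypothesis at each marker naming the same
carrier F1 parent and carrier sets sharing at least `min_f2_carriers`
(default 3) F2 individuals. Overlap, not identity, of carrier sets is
required: at either flanking marker some true carriers can be invisible
(their call context hides the null), so demanding identical sets would
discard real deletions. For class-5 markers whose evidence is purely the
missing pattern, the missing F2 are the putative carriers. Calls
supported by both families merge into one region; runs longer than two
markers are reported as overlapping pairwise calls with a `run` flag
rather than silently merged. Sizes are the inter-marker distance in kb
(one decimal) — a lower bound tied to panel density, not a breakpoint
estimate. BED output converts the 1-based marker positions to 0-based
half-open intervals.

## Gene-drop simulator

`simgen` emulates the targeted study design: one F0 grandfather siring
all four F1 parents, three grandmothers with the middle one shared
between the families' dams, and two families with 23 and 25 F2 offspring
(all counts configurable). Founder haplotypes are drawn i.i.d. per marker
with allele-1 frequency 0.5 by default — a deliberately simple stand-in
for two partially diverged founder lines; the detection method never uses
population allele frequencies, only within-family transmission, so this
choice affects how often informative genotype contexts arise, not the
correctness of any call. Markers are unlinked in transmission except
within an injected deletion run, which travels as a single haplotype
block — the candidate regions of interest are tens to hundreds of kb,
where recombination within a cross of this size is negligible.

Injected mechanisms: null alleles (single-marker or multi-marker runs on
one founder haplotype), forced single miscalls, whole-marker assay
failures (all F2 calls dropped), plus i.i.d. noise — each non-missing
call miscalled with probability `error_rate` (uniform over the other two
genotypes; no error model was given for the real assay, and the
classifier only needs errors to create non-null-consistent conflicts)
and then dropped with probability `missing_rate`. All randomness flows
from one integer seed; identical seeds give bit-identical outputs.

What the simulator does *not* emulate: linkage disequilibrium and
recombination along real chromosomes, locus-specific assay quality, the
family-biased error process observed in the real data (injected errors
hit both families at equal rates unless configured otherwise), and
fluorescence intensity values. Passing recall tests on simulated data
therefore demonstrates correctness of the inference logic under the
stated observation model, not robustness to every failure mode of a real
genotyping platform.

For testing the mixture estimator, `simulate_mixture_counts` simulates
detection counts directly: each marker is an error SNP with probability
x*, detected in family 1 at `detect_prob × r_e` and in family 2 at
`detect_prob` (null SNPs at `detect_prob` in both), which realizes the
mixture model's count-level assumptions exactly.

## Numerical and interface choices

* Allele codes are restricted to {1, 2} with 0 as the missing/null
  marker; a half-missing call ("1 0") is treated as fully missing, as the
  underlying model has no half-calls.
* Genotype calls are order-insensitive pairs; positions are 1-based bp.
* Test problem sizes: property suites run on families of 3–14 offspring,
  simulations of 12–40 markers with up to 100 replicates, and
  2,000-marker count simulations for estimator recovery — sizes at which
  the exhaustive oracles used for cross-checking remain exact.
* The CLI (`scan | summarize | deletions | simulate`) is a thin layer
  over the library; `summarize` recomputes the table from the per-SNP TSV
  so pipeline stages stay independently re-runnable. Exit codes: 0 ok,
  1 input error, 2 internal failure.

## Known limitations

* Only biallelic autosomal markers; no X/Z-specific inheritance.
* No probabilistic genotype-error model or likelihood peeling; the
  edit-count criterion is combinatorial by design.
* Deletion extent is bounded by panel density; breakpoints are not
  refined, and intensity-based validation of candidate regions is out of
  scope (per-SNP carrier annotations can be exported for external
  plotting).
* Pairs of integration categories never observed in the motivating data
  rely on the documented lower-class extension.
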