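# Methods

## Model

`codonflux` estimates per-codon translation rates from tRNA
availability using an adaptiveness-index formulation. For a pool of
isoacceptor concentrations `c_j` (units opaque — whatever the source
table reports is carried through unchanged, and every downstream rate,
time and threshold lives in the induced units), the adaptiveness of a
sense codon `i` is

    W_i = Σ_j (1 − s_ij) · c_j

over the isoacceptors recognizing `i`. Recognition is enumerated per
codon box from Crick wobble rules: the two codon prefix bases are the
reverse complement of anticodon positions 35–36, and the wobble base
(position 34) determines the readable third positions — A34 reads U
(and, as inosine, also C and weakly A), G34 reads C and U, U34 reads A
and G, C34 reads G only. Two bacterial exceptions are wired in: the
lysidine-modified Ile2 species (anticodon CAU) reads AUA and only AUA,
and AUG is read only by elongator Met. Initiator Met-tRNA is excluded
from pools — the model describes elongation only — and stop codons
carry no rate.

Rates and expected times follow by normalization over codon types and
rescaling by the pool total:

    r_i = (W_i / Σ W) · Σ c ,     t_i = 1 / r_i .

The sum of defined rates therefore always equals the pool total, and a
uniform scaling of the pool by `k` scales every rate by `k` and every
time by `1/k` (both properties are tested). The expected time is the
mean of an exponential waiting time for tRNA selection, which is why
codons served by scarce isoacceptors respond disproportionately to
small absolute availability changes.

### Selective constraints

The default `s` values are the standard prokaryotic adaptation-index
constraints: Watson–Crick pairings 0, G34:U3 = 0.41, I34:C3 = 0.28,
I34:A3 = 0.9999, U34:G3 = 0.68, L34:A3 = 0.89. The CGA codon read by
the ACG anticodon is special-cased to s = 0.9172: with the generic
I34:A3 value its rate sits two orders of magnitude below every other
codon and dominates any genome-wide statistic, and the override value
matches experimental elongation data far better. All constraints and
overrides are editable through a YAML config (`s_values.yaml` ships
the defaults); inosine treatment of A34 is switchable per species.

### Charging time courses

Starvation-style data sets report charged fractions per time point
rather than absolute availabilities. `effective_availability`
multiplies each species' charged fraction with its concentration under
the reference condition (the standard growth rate), yielding the
charged availability used for rate computation. Setting every fraction
to 1 reproduces the concentration-only rate table bit-for-bit (tested).
Collectively measured isoacceptor pairs are split by gene copy number
(`split_grouped_isoacceptors`; for *E. coli*, Gly1:Gly2 = 1:1 and
Ile1:Ile2 = 3:1), with the larger share defined by subtraction so the
pool total is conserved to within one float rounding.

## Profiles, threshold, features

A speed profile maps each codon of a CDS to its expected time and
smooths with a centered arithmetic-mean window of 19 codons (the
approximate ribosomal footprint; any odd width is accepted). Window
edges are truncated — the effective window shrinks near the termini —
so the smoothed profile keeps the codon-list length. Padding or
discarding edges were the alternatives; truncation was chosen because
it keeps the length normalization of the sensitivity measure well
defined and comparable across genes. The trailing stop codon is
stripped before profiling; the start codon is retained with its
elongator-Met time. DNA and RNA input are equivalent (T = U), codon
positions are 0-based internally and 1-based in exported tables.

The genome threshold is the mean over the *concatenation* of all
smoothed per-position values of the reference condition — i.e.
length-weighted, not a mean of per-gene means ("average codon speed"
reads as position-level averaging; the alternative is one switch away
since both interpretations are defensible). Thresholds can be computed
on the time or the speed scale; drops are evaluated with strict
inequality (slower than threshold), so positions exactly at the
threshold never count as below.

Per profile, four features are reported: (i) average time (mean of the
smoothed profile), (ii) slowest point (its maximum time), (iii) drop
count (number of maximal runs below threshold; defined as 1 when the
whole profile is below), and (iv) maximal drop length in codons
(undefined — and the gene excluded from this feature's distribution —
when the whole profile is below). A per-condition-threshold mode
recomputes the threshold from each condition's own profiles; under a
uniform rate scaling this leaves both drop features exactly invariant,
which separates overall speed changes from genuine shape changes.

A single codon `k×` slower than an otherwise uniform background
depresses the smoothed profile over exactly `window` positions, so the
maximal-drop-length distribution develops a spike at the window width
— a diagnostic that the tests assert analytically.

## Sensitivity and genome context

Between a reference condition and an alternative, a gene's sensitivity
is `S = (1/l) Σ |t_j^ref − t_j^alt|` over smoothed times, with `l` the
number of smoothed positions (the only length the two profiles share
by construction). S is a genuine metric up to the shared-gene
precondition — nonnegative, symmetric, zero iff the profiles coincide,
triangle inequality — and scales linearly under a uniform time
scaling; all four axioms are property-tested.

Ranking slices the top and bottom `fraction` (default 10%) of genes by
S, excluding untranslated and pseudo entries, with ties broken by
lexicographic gene id for run-to-run determinism. Group location
comparisons (e.g. essential vs non-essential) use the one-sided
Wilcoxon rank-sum test (Mann–Whitney U, alternative "greater") — a
deliberate choice, since sensitivity distributions are far from
normal; the test name is recorded in the result object. With singleton
groups the exact null has two orderings and the smallest attainable p
is 0.5. A seeded null-calibration test confirms the nominal rejection
rate.

Genome binning tiles the chromosome into `n_bins` equal stretches
(width = length // n_bins, last bin absorbing the remainder; for the
4,639,675 bp *E. coli* chromosome and 200 bins this gives 23,198 bp),
assigns each gene to the bin containing its start coordinate and
averages any per-gene metric (sensitivity per condition, CAI, GC%)
over members. CAI is the geometric mean of relative synonymous-codon
weights; weights are user-supplied because CAI is reference-set
dependent (a clearly labelled synthetic example table is bundled, plus
a helper to derive weights from codon counts). Zero weights are floored
at 0.01 to keep the geometric mean defined. Covariate–sensitivity
association uses Spearman's rank correlation with midrank ties; the
reported goodness of fit is the squared rank correlation.

Untranslated sequences are profiled "as if coding" in the annotation
frame so they can be compared against coding genes; in-frame stop
codons (which carry no rate in this model) are dropped from their codon
list rather than poisoning the profile. For regular genes, a codon that
nothing decodes at positive availability makes the profile unusable:
the gene is flagged and excluded from that condition with a warning.

## Synthetic data generator

The generator emulates the two experimental regimes at desk scale:

* **Growth-rate-like** (uniform): every concentration scales by a
  per-condition factor, default 1.0 / 0.85 / 0.7 / 0.6 / 0.5 — a
  2-fold slowdown at the deepest condition, the magnitude typical of a
  strong growth-rate shift.
* **Starvation-like** (targeted): charged fractions collapse for the
  targeted amino acid's isoacceptors. The default leucine schedule
  hits the minor isoacceptors (readers of CUU/CUC/CUA) much harder
  (fractions 0.04–0.08) than the major ones (CUG/UUA/UUG readers,
  0.5–0.7), and adds a broad transient dip of most other species at
  the middle time point. The differential collapse mirrors what
  starvation measurements show — codons of the same amino acid can
  slow by an order of magnitude more than their synonyms — and it is
  what makes synonym choice matter; a perfectly uniform collapse of
  all Leu species would affect both synonym triples alike.

The toy organism has 8 isoacceptors chosen so every wobble pairing
kind, both AUA/AUG exceptions and the CGA override are exercised. Two
of its concentrations are *solved* rather than chosen: Leu1 so the
synonym triples CUU/CUC/CUA and CUG/UUA/UUG have exactly equal summed
expected times under the reference pool (which, with leucine positions
placed in the window interior, makes the twin genes' sensitivities
exactly equal under any uniform scaling), and Arg2 so the Gly2
species' adaptiveness multiplicity equals the pool-wide ΣW/Σc ratio
(which makes a pure Gly2 availability shift leave every non-Gly rate
unchanged in exact arithmetic — the parameter-recovery construction
behind the "genes without the perturbed codons have S = 0" check,
exact up to one ulp in floats).

Gene generation draws codons from a configurable bias over the
readable alphabet (AUA down-weighted by default, as rare codons are in
real genomes), always starts with AUG, appends a stop, and emits the
leucine-twin pair. A single seeded generator stream per `FixtureSpec`
makes all outputs byte-identical across runs.

What the generator does **not** emulate: real codon usage frequencies,
operon structure, correlated noise between isoacceptors, measurement
error in charging data, or transient re-charging kinetics during a
shift. Passing tests therefore demonstrate the correctness and the
qualitative regime behavior of the method, not quantitative agreement
with any particular organism's measured tables — for that, users
supply their own concentration/charging TSVs.

## Problem sizes and numerics

The test suite and the acceptance script run entirely at desk scale:
200 random pools of 3–10 species for the rate-engine oracle, 500
random vectors for the smoothing/run-length oracles, 200 random
profile triples for the metric axioms, 40–100-gene synthetic sets for
pipeline-level checks. Oracle comparisons use 1e-9 relative tolerance
(engine and oracle differ only in summation order); exact-invariance
claims (uniform-scaling equalities, parameter recovery) are asserted
at float precision (~1 ulp). Degenerate inputs are defined rather than
left to chance: empty profile sets, all-zero adaptiveness and
mismatched species sets raise; constant input to the correlation is
returned flagged as undefined; even smoothing windows are rejected.

## Known limitations

* The model is deterministic and local: no ribosome–ribosome
  interactions, initiation/termination kinetics, mRNA secondary
  structure, or stochastic elongation.
* tRNA pools are piecewise-constant per condition; transient
  re-charging dynamics during a shift are out of scope.
* Only position-34 modifications that change wobble reading (inosine,
  lysidine) are represented; other modifications would enter as edited
  s-values.
* Thresholds and times inherit the units of the input tables, so
  absolute values are only comparable within one data set convention.
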