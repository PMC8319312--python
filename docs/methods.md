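# Methods

## Transmission model

Each transgene locus is autosomal and biallelic per chromosome with three
allele states: `wildtype` (no transgene), `dual` (unresolved cassette
showing both markers of the locus pair) and `single(m)` (Cre-resolved
cassette showing exactly one marker). Visible phenotype is the union of
marker sets over all alleles at all loci; zygosity is defined through
visible marker content — two transgene-bearing alleles with identical
marker sets are *homozygous*, with different sets *heterozygous*, which is
precisely what makes zygosity optically readable.

Gametes follow Mendel's first law (each parental allele transmitted with
probability 1/2) and loci assort independently; there is no recombination-
fraction parameter because all modeled loci are on different chromosomes
or treated as such. All probability propagation uses exact rationals
(`fractions.Fraction`); sums are checked to equal 1 exactly, and floats
appear only in display and statistics. Genotype classes are unordered
(mO/mC ≡ mC/mO); ordered maternal/paternal pairs exist only internally.

### Cre resolution

Cre action is modeled as a germline event on transmitted gametes of a
cross flagged `cre_active`: each dual allele resolves with probability
`efficiency` (default 1), the two single-marker outcomes being equally
likely. The equal 1/2:1/2 split is an assumption — no relative reactivity
of the two Lox pairs is published — and both the split's efficiency and
the step-level activation are configurable. Somatic mosaicism is not
modeled. When a step is `cre_active`, gametes of *both* parents are
resolved; a parent without dual cassettes is unaffected, so for the shipped
schemes this is equivalent to tracking helper carriage per mixture
component, at much lower complexity.

### Helper transgene

The Cre helper is a third locus carrying a single marker (a one-element
marker tuple); it can never be in the dual state. Its actual X-chromosome
insertion is not modeled as sex-linked — sex is a pure label throughout —
because none of the modeled selection steps depend on sex-specific
segregation. The marker-collision check flags any two scheme loci with
intersecting marker sets, the situation that forces recoloring a helper.

## Built-in schemes

* `agoc_acos_double` (F7→F10): two parallel F7 crosses of opposite single
  homozygotes give 100% double hemizygotes (F8); F8-OCe × F8-CVe gives the
  selectable all-four-marker double heterozygote (F9); the F9 sibling cross
  yields each double-homozygote marker combination at exactly 1/16 (F10),
  with every F10 phenotype identifying a unique genotype.
* `agoc_single` (F4→F7): a *reconstruction* of the single-transgene
  procedure — founder dual-cassette hemizygote × helper; carriers of
  cassette and helper outcrossed to wild type with germline Cre, producing
  resolved mCe- and mVe-hemizygotes; complementary hemizygotes mated and
  the both-marker heterozygotes sibling-crossed, segregating
  1/4 : 1/2 : 1/4 with homozygotes revealed by single-marker phenotypes.
  Step structure and labels follow the published generation numbering, but
  the intermediate selection order is our reading, not a transcription.
* `resegregation` (F12→F15): double hemizygotes outcrossed to wild type,
  single-transgene hemizygotes reassembled with swapped marker pairings,
  and the double-homozygote cross repeated; F15 reproduces the F10
  distribution exactly.

Selection rules act on phenotype only (required/forbidden marker sets) and
are conditioned exactly (renormalized rational distributions); a rule
matching nothing raises an "empty selection" error naming the step.
Ambiguity is reported, not resolved: the scoring map marks a phenotype
deterministic only when it hides a single genotype class.

## Production calculus

`binomial_tail(n, p, k)` is the exact complementary cumulative binomial,
summed over the smaller tail for efficiency. `min_required` finds the
smallest n with tail ≥ confidence by incremental search; "higher than 95%"
is read as tail ≥ 0.95 (non-strict — at the printed precision the strict
reading gives the same integers for the cases of interest).
`expected_deterministic` is the negative-binomial stopping mean k/p, and
waste reduction is 1 − (k/p)/n, i.e. produced-minus-needed progeny relative
to the stochastic plan. `scaling_with_transgenes` uses p_i = p^i for i
independently segregating transgenes. Default planner inputs mirror the
scheme probabilities (1/4 single, 1/16 double) but any selection rule's
probability can be piped in.

## Synthetic data

`simulate_vials` draws one multinomial sample per vial from an exact
phenotype distribution. Defaults: 6 vials (matching the up-to-six
female-male pairs mated per cross in the source husbandry protocol) of 100
scored progeny each — the published tables' actual per-vial totals are not
available in machine-readable form, so 100 is our choice of a realistic
vial yield, not a reproduction. A single top-level seed is expanded with
`numpy.random.SeedSequence.spawn`, one substream per vial in vial order, so
enlarging a table never changes earlier vials and a logged seed regenerates
the table exactly. Progeny sex, when needed by a selection label, is 1:1
independent of genotype.

The generator reproduces multinomial sampling noise only: no vial random
effects or overdispersion, no differential mortality or fertility, no
scoring error. Passing calibration tests therefore shows the statistics are
correct under ideal Mendelian sampling, not that real vials are free of
extra-multinomial variation.

## Ratio verification

Per phenotype class, per-vial proportions are tested against the
theoretical ratio with a one-sample two-tailed Student's t-test on their
arithmetic mean (n − 1 df). Proportions are left untransformed and no
multiple-testing correction is applied by default, matching the source
analysis; a Bonferroni option exists as an extension. α defaults to 0.05
(no level is printed in the source). Zero-variance samples follow a fixed
contract: t = 0, p = 1 when the mean equals the theoretical ratio; otherwise
the case is flagged `degenerate_variance` and reported significant with
p = 0.

## Numerical and design choices

* Exactness boundary: rationals end where statistics begin (t-tests,
  multinomial draws use floats); multinomial probabilities are renormalized
  in float only to absorb representation round-off after an exact sum-to-1
  check.
* Canonical orders: markers mO < mC < mCe < mVe everywhere; genotype-class
  strings sort loci lexicographically by id; distribution iteration is
  lexicographic in the class string, making all outputs deterministic.
* Degenerate inputs: n = 0 multinomial draws, probability-0/1 planner
  corners, and k > n binomial tails all have defined values rather than
  errors; truly invalid domains (p = 0, efficiency outside [0, 1]) raise.
* Problem sizes: the test suite's calibration batches use 1000 seeded
  6-vial tables and 10^5 Monte-Carlo workflow replicates — large enough
  that 3–4 standard-error acceptance bands are tight, small enough to run
  in seconds.

## Known limitations

Linked loci, X-linked segregation, maternal effects, fitness/viability
differences between genotypes, vial capacity and timing logistics, and
sequence-level Lox chemistry are all out of scope; the dual→single
resolution is an abstract event. The single-transgene scheme is a
reconstruction (above). The t-test layer inherits the usual small-sample
caveats of testing proportions with a normal-theory test; with 6 vials of
≥100 progeny its type-I error is within Monte-Carlo error of α in our
calibration.
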