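# crebreed

Exact transmission genetics and production planning for transgenic breeding
schemes built on **dual-marker Cre-Lox cassettes**.

## The problem

In diploid model organisms, an ordinary transformation marker tells you
whether a transgene is present but not whether it sits on one or both
homologous chromosomes: hemi- and homozygotes look identical, so zygosity
normally requires invasive genetic assays, and breeding programs overproduce
progeny to be safe. Dual-marker vector concepts solve this optically. Each
transgene carries **two** distinguishable eye-specific markers embedded in
interweaved, mutually incompatible Lox site pairs; a Cre helper cross
resolves the cassette so that each resolved allele keeps exactly **one** of
the two markers. Mating two complementary single-marker hemizygotes (e.g.
mCe and mVe) yields marker-**heterozygotes** selectable by showing both
markers; their sibling cross yields **homozygotes** revealed by the *lack*
of one marker. Two color-complementary cassette pairs (mO/mC and mCe/mVe)
extend this to double-transgenic lines with full visual genotype control.

`crebreed` is for transgenesis labs and quantitative geneticists who want to
design, check and size such schemes before going to the bench.

## What it computes

* **Exact crossing engine** (`crebreed.genetics`) — alleles are wildtype,
  unresolved `dual`, or Cre-resolved `single(marker)`; gamete formation and
  crossing follow Mendel's first law with free recombination across unlinked
  loci, propagated entirely in exact rational arithmetic
  (`fractions.Fraction`). For a marker-heterozygote sibling cross at one
  locus, P(specified homozygote) = 1/4; for two loci, 1/16; a two-transgene
  hemizygote sibling cross segregates into the classic 9 genotype classes.
* **Scheme engine** (`crebreed.schemes`) — declarative multi-generation
  schemes with phenotype-only selection rules (what a non-invasive marker
  screen can actually see), germline Cre activation per step, testcross
  expectations and genotype identifiability analysis, plus a marker-collision
  check. Ships three built-ins: `agoc_single`, `agoc_acos_double`,
  `resegregation`.
* **Production calculus** (`crebreed.economics`) — producing a suitable
  descendant is a Bernoulli(p) process. The *stochastic* workflow must
  pre-commit to the smallest n with
  P(X ≥ k) ≥ c for X ~ Binomial(n, p) (complementary cumulative binomial);
  the *deterministic* workflow, scoring genotypes at nascence, stops at the
  k-th success after negative-binomially distributed trials with mean k/p.
  For k = 1, c = 0.95: n = 11 vs E = 4 at p = 1/4, and n = 47 vs E = 16 at
  p = 1/16 — a reduction of produced progeny by about two-thirds, growing
  geometrically with each additional transgene.
* **Synthetic scoring tables** (`crebreed.simulate`) — seeded multinomial
  per-vial progeny draws from the exact phenotype distributions, plus
  Monte-Carlo twins of both workflows.
* **Ratio verification** (`crebreed.stats`) — one-sample two-tailed
  Student's t-tests of per-vial phenotype ratios against theoretical
  Mendelian ratios.

## Worked example

Plan the double-homozygote step (suitable genotype probability 1/16):

```
$ crebreed plan --p 1/16 --k 1 --confidence 0.95
   p  k confidence  n_stochastic  expected_deterministic  saving  reduction
1/16  1      19/20            47                    16.0    31.0     0.6596
```

47 descendants must be produced up front to reach 95% confidence of at
least one double homozygote, while scoring at nascence stops after 16 on
average — 31 animals saved, a 66% reduction.

Exact theoretical ratios of the double-homozygote procedure:

```
$ crebreed expect --scheme agoc_acos_double
generation     phenotype theoretical_ratio  ...  deterministic
    F8-OCe        mO+mCe                 1  ...           True
    F8-CVe        mC+mVe                 1  ...           True
        F9 mO+mC+mCe+mVe              1/16  ...           True
       F10        mO+mCe              1/16  ...           True
       ...
```

Both F8 crosses give 100% double hemizygotes; selecting the F9 progeny
showing all four markers isolates the double heterozygote; each of the four
double-homozygote marker combinations then appears at 1/16 in F10, and every
F10 phenotype identifies its genotype (`deterministic = True`) — full visual
control.

The same analysis in Python:

```python
from fractions import Fraction
from crebreed import (WorkflowParams, compare_workflows, cross, genotype,
                      single, MO, MC, MCE, MVE, TransgeneLocus)

AGOC = TransgeneLocus("AGOC", (MO, MC))
ACOS = TransgeneLocus("ACOS", (MCE, MVE))
het = genotype({AGOC: (single(MO), single(MC)),
                ACOS: (single(MCE), single(MVE))})
dist = cross(het, het)                       # exact, 9 classes
target = genotype({AGOC: (single(MO), single(MO)),
                   ACOS: (single(MCE), single(MCE))}).to_class()
print(dist.p(target))                        # 1/16

print(compare_workflows(WorkflowParams(p=Fraction(1, 16))).n_stochastic)  # 47
```

Simulate and verify a synthetic scoring table:

```bash
crebreed simulate --scheme agoc_single --generation F7 --seed 13 --out scored.tsv
crebreed verify --table scored.tsv --scheme agoc_single --generation F7
```

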