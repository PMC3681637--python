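# Methods

## Model

The simulator evolves a closed population of N males and N females over
discrete periods.  Each individual has a sex, an age class x ∈ {1, …, 18}
(one class ≈ five years) and a diploid genotype: a mutant-allele count in
{0, 1, 2} at each of L unlinked autosomal loci.  A locus ℓ carries an
effect type (mortality or fertility), a sex scope (both, male-only,
female-only), an age of onset x₀(ℓ), a selection strength e(ℓ), a dominance
coefficient h(ℓ) and a mutation rate μ(ℓ).

**Vital rates.**  Intrinsic survival s_sex(x) and fertility f_sex(x) come
from per-sex life tables.  A locus is *expressed* in an individual iff the
individual's age class is ≥ x₀ and its sex is in the locus's scope.
Expressed load acts multiplicatively on the affected rate: a heterozygote
contributes a factor (1 − h·e), a homozygote (1 − e)².  With the default
h = 1 this is the codominant per-copy model, (1 − e) per allele.  Mortality
and fertility loci are nonpleiotropic: each touches only its own rate.

**Period loop.**  (i) Every individual draws survival at its current age
class; survivors advance one class; the terminal class always dies.
(ii) Deaths are counted per sex and replaced by exactly that many newborns,
so the per-sex census is constant.  Each birth rejection-samples parents:
a candidate father and mother are drawn uniformly (with replacement) from
the surviving pools and the candidate pair succeeds with probability
M[i, j] · F_m · F_f — the mating-matrix entry at their (post-advance) age
classes times both effective fertilities.  Pair acceptance and the
fertility test are folded into a single Bernoulli draw, which is
distributionally identical to testing them sequentially.  Conditional on a
birth, the accepted-pair distribution is therefore proportional to
pool counts × M × fertilities (verified against exhaustive enumeration in
the test suite).  (iii) Offspring genotypes follow Mendelian segregation
per locus (homozygote transmits the mutant always, heterozygote with
probability ½, loci independent — free recombination), then each wild-type
allele copy mutates with probability μ; mutation is one-way (no back
mutation).  Newborns enter class 1 and neither die nor reproduce in their
birth period.

Because survivors mate *after* advancing, a mortality locus with onset x₀
first acts on the x₀ → x₀+1 transition: it can remove an individual before
it mates at class x₀ + 1 and beyond, but not before it mates at x₀ itself.
With the default young window 4–7, an onset-7 mortality allele is thus
exactly neutral under YP while onset-6 remains partially selected — the
boundary pattern the model is built to exhibit.

**Initialisation and burn-in.**  Individuals start at uniform-random age
classes with wild-type genotypes (optionally Bernoulli(init_freq) alleles
for drift experiments).  A mutation-free burn-in (default 200 periods)
lets the age distribution reach an approximate steady state before allele
dynamics begin; the reported period axis excludes burn-in.

**Randomness.**  One `numpy.random.Generator` per replicate, seeded from
the config; every stochastic draw flows through it, so a configuration is
bit-reproducible.  Replicate r of a batch uses seed `seed_base + r`.

## Default parameters

| quantity | default | rationale |
|---|---|---|
| age classes | 18 × 5 y | human lifespan to age 90; configurable (tests use 6) |
| N per sex | 1000 | headline census; scenario flag |
| intrinsic survival | Gompertz–Makeham A = 0.01, B = 10⁻⁴, C = 0.5 per class | >0.9 through ~class 10, collapsing before class 18 — schematic human survivorship |
| prolonged fertility | 0 (classes 1–3), 0.9 (4–17), 0 (18), both sexes | ancestral state for the infertility-mutation studies |
| declining female fertility | 0.9 (classes 4–9), 0 from 10 | mortality-only studies: intrinsically menopausal females, prolonged males |
| mating windows | young = classes 4–7, adult ≥ 3 | mating from the third class; youth ≈ ages 15–35 |
| μ | 0.005 per allele copy per birth | headline mutation rate of the preference-shift study |
| e | 0.025 | headline selection strength |
| h | 1 | codominant per-copy action |
| onsets | classes 6–10 | mid-life window, ages ~25–50 |
| burn-in | 200 periods | age distribution stabilises within ~100 periods at these survival rates |

Matrix entries are binary 0/1 by default ("allowed"/"forbidden"); the
loader accepts any values in [0, 1] for graded custom matrices.  The
mutation convention is configurable: `per_copy` (default) applies μ to
each of the two allele copies; `per_diploid` applies it once per locus per
newborn, halving the mutational input — exposed because published rates
are quoted in both conventions.

## Scenarios

* **mortality-only** (AP vs YP): five sex-indifferent mortality loci,
  onsets 6–10, declining female / prolonged male intrinsic fertility.
* **fertility-and-mortality** (AP vs YF): fifteen loci — the five mortality
  loci plus five male-limited and five female-limited infertility loci —
  on the prolonged-fertility ancestral state.
* **matrix-shift**: a single female-limited infertility locus (default
  onset 6); AP until the shift period (default 1000), YF afterwards;
  reports the replicate-mean female frequency trajectory.

Each scenario returns a tidy summary (locus × sex final mean frequency ±
SE over replicates, SE = sd/√n with ddof = 1, NaN for a single replicate)
and end-state curves: the mean effective survival and fertility of the
individuals present at the final period, by sex and age class (NaN for
empty classes).

## Numerical and design choices

* **Arrays, not objects.**  The engine stores the population as per-sex
  age and genotype arrays and vectorises survival, load, pair sampling and
  transmission; an `Individual` record view backs the scalar API.  At
  N = 1000 a period costs ~0.4 ms on one core.
* **Batched rejection sampling.**  The birth loop draws candidate pairs in
  batches; if a batch yields no success, an exact 18 × 18 bound on the
  best achievable pair probability is checked and a `NoFertilePairsError`
  is raised when it is zero (degenerate matrix/fertility configurations
  fail fast instead of deadlocking; the cap is 10⁶ candidate draws).
  Note that at very small N, demographic stochasticity can genuinely empty
  the fertile mating window for a period — that raises the same error and
  is a real feature of the model, not a numerical artifact.
* **Per-sex replacement.**  k male deaths beget k male newborns (likewise
  females), keeping both censuses exactly constant; random newborn sex
  would let the ratio drift.
* **Death-then-birth ordering** within a period, with post-advance mating
  ages, as derived above; the alternative (mate before advancing) shifts
  every onset boundary down one class but is otherwise equivalent.
* **Fixation is absorbing.**  With one-way mutation, a fixed locus never
  leaves frequency 1; "equilibrium" frequencies of weakly selected loci
  are quasi-stationary, and long runs let replicates leak into fixation.
  Reported means are therefore tied to the stated run length.

## Scale of the shipped analyses

The packaged studies run 10⁴ post-burn-in periods and 10–16 replicates at
N = 1000 per sex (the preference-shift study: 2500 periods, 20
replicates), which a single core completes in minutes.  Strongly selected
loci equilibrate well within this horizon; near-neutral loci are still
drifting slowly upward, so their replicate means are modestly below what
longer runs would give.  All qualitative contrasts (fixation vs
polymorphism across AP/YP/YF, onset-age monotonicity of equilibrium load,
shift-induced rises, N-insensitivity) are insensitive to this scale.

## What the synthetic conditions do and do not show

The simulator *is* the study system: there is no external data.  The
intrinsic tables are schematic (Gompertz–Makeham survival, plateau
fertility), mutation effects are multiplicative and nonpleiotropic, loci
are unlinked and biallelic, pair bonds last one period, and the population
is closed with a constant, equal-sex census.  Passing tests therefore
demonstrate the internal population-genetic logic — which mutations the
mating structure exposes to selection, and at what frequencies they
settle — not calibrated predictions for any real demography.  Absolute
equilibrium frequencies are sensitive to the chosen μ, e and tables;
orderings across matrices, onsets and sexes are the robust output.

## Limitations

No linkage or X-linkage, epistasis or pleiotropy; no pair-bond
persistence, genotype-assortative mating or separately modelled female
choice (role reversal is a relabelling); no density dependence, migration
or demographic growth; no inclusive-fitness (grandmother) effects — their
absence is the point: the mate-choice mechanism alone suffices to generate
a menopausal life history in the model.
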