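# matesim

An individual-based, two-sex, age-structured forward simulator of
age-dependent mutation accumulation under mate-choice matrices — a
computational laboratory for studying how mating preferences shape the
evolution of senescence, and in particular how male preference for younger
females can produce the evolutionary origin of menopause.

## The problem and the model

Classic one-sex mutation-accumulation theory predicts that deleterious
mutations acting only after the last age of female reproduction feel no
selection, accumulate to fixation, and erect a "death barrier" just beyond
that age.  Humans show no such barrier — and women additionally stop
reproducing long before they stop surviving.  Two-sex demography changes
the calculus: who mates with whom at which ages decides which late-acting
mutations selection can still see.

`matesim` simulates a population of N males and N females in 18 discrete
age classes (five years each).  Each individual carries a diploid genotype
over a set of unlinked, autosomal loci.  A locus is defined by its effect
(mortality or fertility), sex scope (both sexes, male-only, female-only),
an age-of-onset class x₀, a selection strength e and a mutation rate μ per
allele copy per birth.  Each period:

1. every individual survives with probability
   `s(x) · ∏ (1 − e_ℓ)^(copies at expressed mortality loci ℓ)`, where s(x)
   is the intrinsic Gompertz–Makeham survival of its age class
   (`s(x) = exp[−(A + B·e^{Cx})]`, default A = 0.01, B = 10⁻⁴, C = 0.5) and
   a locus is expressed only when x ≥ x₀ and the sex matches its scope;
   survivors advance one class, class 18 always dies;
2. deaths are replaced per sex, holding the census at N + N.  Each birth
   draws a candidate father and mother uniformly from the survivors and
   accepts the pair with probability `M[i, j] · F_m(i) · F_f(j)` — the
   mating-preference matrix entry for their age classes times both parents'
   effective fertilities (intrinsic table × expressed fertility load) —
   repeating until a birth occurs;
3. offspring receive alleles by Mendelian segregation and acquire new
   mutations at rate μ per wild-type copy (mutant alleles never revert).

Three canonical preference matrices: **AP** (age-indifferent: all adult
pairs), **YP** (both sexes restricted to a young window, default classes
4–7), and **YF** (males of any adult age with young females only).  Under
AP, extended male mating keeps purifying selection on late-onset mutations
and holds them at mutation–selection balance.  Under YP, mortality
mutations with onset past the mating window become neutral and fix (the
death barrier).  Under YF, *female-limited* infertility mutations with
onset past the female window become nearly neutral and fix — female
fertility then declines while female survival stays high: menopause —
while male-limited infertility remains under selection.

## Worked example

Five sex-indifferent mortality loci with onsets in classes 6–10
(μ = 0.005, e = 0.025) under young-pairs mating, at reduced scale:

```python
from matesim.experiments import scenario_mortality_only

summary, curves, _ = scenario_mortality_only(
    model="YP", N=300, n_periods=2000, n_reps=3, seed=1
)
print(summary[summary.sex == "female"][["onset_class", "mean_freq", "se"]]
      .to_string(index=False))
```

```
 onset_class  mean_freq       se
           6   0.722778 0.138612
           7   0.832778 0.167222
           8   0.663333 0.199877
           9   0.975556 0.013955
          10   0.859444 0.045147
```

`mean_freq` is the final mutant-allele frequency in females, averaged over
the three replicates, with its standard error.  Because mating stops after
class 7, these late-onset mortality alleles are effectively neutral and are
already drifting toward fixation after 2000 periods even in this small
population; at full scale (N = 1000, ≥10⁴ periods) the onset-7..10 loci fix
while under model AP the same loci stay at low mutation–selection-balance
frequencies.  The returned `curves` table holds the end-state survivorship
and fertility by sex and age class, in which the YP run shows the collapse
of late-life survival (the death barrier) that the AP run avoids.

The same studies run from the shell:

```
matesim scenario mortality-only --model YP --n 1000 --reps 10 --out out/
matesim scenario fertility-mortality --model YF --out out/
matesim scenario matrix-shift --onset 6 --shift-period 1000 --out out/
matesim simulate myconfig.yaml --out out/   # single run from a YAML config
```

Custom mating matrices and life tables are plain delimited text
(`read_matrix`, `read_life_tables`); every writer's output re-reads
losslessly.

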