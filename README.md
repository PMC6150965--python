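# karyometry

Quantitative karyotype analysis for population cytogenetics: from raw
per-metaphase chromosome arm measurements and flow-cytometry histograms to
karyotype formulas, among-population karyotype-length statistics, genome-size
estimates, and idiograms.

## The problem

Many taxa — fungus-farming ants are a striking case — show no variation in
chromosome number or morphology between populations, yet differ in the
*amount* of chromatin: every chromosome is a bit longer in some populations
than in others, and the nuclear DNA content shifts accordingly. Detecting
and quantifying that kind of cryptic chromosomal divergence takes three
ingredients this package provides:

1. **Karyomorphometry.** For each chromosome measured on a metaphase spread
   (long arm *L*, short arm *S*, total length *TL*, in μm):
   - arm ratio *r* = *L*/*S* and centromere-position class after Levan's
     nomenclature — metacentric (M, 1 ≤ *r* < 1.7), submetacentric
     (SM, 1.7 ≤ *r* < 3), subtelocentric (ST, 3 ≤ *r* < 7), acrocentric
     (A, *r* ≥ 7);
   - relative length RL = *TL* × 100 / Σ*TL*;
   - karyotype length KL = Σ*TL* and its coefficient of variation across
     specimens;
   - asymmetry index AI = Σ long arms / Σ total length × 100;
   - the diploid karyotype formula (e.g. `2K = 20M`) and arm number 2AN
     (M and SM count two arms, ST and A one).

2. **Analysis of deviance with level pooling.** Karyotype length (or any
   single chromosome's length) is compared across populations with a one-way
   Gaussian/identity GLM, where the deviance is the residual sum of squares
   and the factor effect is F-tested. Populations that do not differ are then
   pooled: among all groupings whose deviance increase over the
   all-populations-separate model is non-significant, the coarsest one is
   chosen and rendered as compact letter display ("a" = largest mean).

3. **Flow-cytometric genome size.** Sample nuclei are co-stained with an
   internal standard of known genome size (*Drosophila melanogaster*,
   1C = 0.18 pg); peak positions are detected in the fluorescence histogram
   and the unknown follows from the linear ratio
   `1C_sample = (peak_sample / peak_standard) × 1C_standard`, converted with
   1 pg = 978 Mbp. Histograms with peak CV > 5% or fewer than 10,000 nuclei
   are rejected, and population values average ≥ 3 accepted replicates.

A packaged table of per-population chromosome means ± SD for five ant
populations (CI, TO, BG, MC, CC; 2n = 20, all metacentric) parameterizes the
seeded simulators in `karyometry.synthdata`, so every stage of the pipeline
is testable without any external data.

## Worked example

```python
from karyometry import (table1_params, simulate_study, summarize_population,
                        karyotype_formula, karyotype_length_test,
                        FlowSimParams, simulate_histogram, estimate_from_histogram)

params = table1_params()                 # packaged means ± SD, 5 populations
study = simulate_study(params, seed=7)   # 5 × 10 metaphases, 2n = 20

for pop in study.population_ids:
    s = summarize_population(study, pop)
    f = karyotype_formula([row[4] for row in s.per_chromosome])
    print(f"{pop}: KL = {s.karyotype_length_um:6.2f} um   {f.formula_string}, 2AN = {f.arm_number_2AN}")

anodev, grouping = karyotype_length_test(study, alpha=0.05)
print(f"KL comparison: {anodev}")
print("groups:", " ".join(f"{p}={grouping.letters[p]}" for p in study.population_ids))

hist = simulate_histogram(FlowSimParams(true_1c_pg=0.35), seed=7)
est = estimate_from_histogram(hist, expected_standard_channel=200.0)
print(f"1C = {est.c1_pg:.3f} pg   2C = {est.c2_pg:.3f} pg   {est.mbp:.1f} Mbp   QC pass: {est.qc_pass}")
```

prints

```
CI: KL =  82.27 um   2K = 20M, 2AN = 40
TO: KL =  83.33 um   2K = 20M, 2AN = 40
BG: KL =  73.37 um   2K = 20M, 2AN = 40
MC: KL =  68.23 um   2K = 20M, 2AN = 40
CC: KL =  66.22 um   2K = 20M, 2AN = 40
KL comparison: Deviance(4,45) = 2474; p = 2.695e-24
groups: CI=a TO=a BG=b MC=c CC=c
1C = 0.350 pg   2C = 0.700 pg   342.4 Mbp   QC pass: True
```

Reading it: all five simulated populations share the same all-metacentric
karyotype (`2K = 20M`, 40 arms), but their karyotype lengths differ strongly
(F-test on 4 and 45 degrees of freedom). The letter display groups CI with
TO (statistically indistinguishable, ~83 μm), isolates BG (~73 μm), and
groups MC with CC (~66-68 μm). The flow-cytometry run recovers the simulated
0.35 pg genome as 2C = 0.70 pg ≈ 342 Mbp and passes QC.

The same analyses are available from the shell:

```sh
karyometry simulate --seed 7 --out study.csv
karyometry summarize study.csv
karyometry compare study.csv --per-chromosome
karyometry idiogram study.csv idiograms/
karyometry run config.yaml          # full pipeline from a YAML config
```

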