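# meioscope

Crossover calling and tetrad analysis for single-chromatid meiotic data.

In most species — *Drosophila* females included — only one of the four
chromatids produced by a meiosis is recovered, so the distribution of
crossovers among tetrads must be inferred from the crossover classes
observed on single chromatids (NCO, 1CO, 2CO, ...).  `meioscope` implements
the full analysis stack used in whole-genome-sequencing crossover studies of
F2 chromatids:

* **crossover calling** from per-chromatid diagnostic-SNP genotype streams,
  with the standard filter cascade (minimum SNP count, biased-window
  masking, 100-kb minimum block span, 250-kb event separation);
* **tetrad inference**: Weinstein's algebraic inversion of chromatid class
  frequencies `f_j` into tetrad frequencies `E_r`
  (`P(j|r) = C(r,j)/2^r`), and constrained maximum-likelihood fits of
  three forward models — Weinstein, crossover-associated meiotic drive
  (a recombinant chromatid enters the oocyte nucleus with probability
  `b >= 0.5` when its sister is non-recombinant), and positive chromatid
  interference (each successive crossover prefers the less-used sister
  with probability `b`) — with Monte-Carlo exact goodness of fit,
  likelihood-ratio tests and profile surfaces;
* **recombination landscape**: centromere/telomere-effect randomization
  tests and sliding binomial extent scans, cM/Mb rate profiles;
* **crossover interference**: inter-crossover distances on 2CO chromatids
  against a null resampled from 1CO positions, and gamma-shape (`nu`)
  estimation;
* **viability diagnostics**: two-marker haplotype frequency curves as a
  function of genetic distance;
* a **synthetic meiosis simulator** (tetrad frequencies, interference,
  suppression profiles, drive, chromatid interference, diagnostic-SNP
  emission) so every stage is testable with known truth.

The observed chromatid class-count table for the five *D. yakuba* chromosome
arms is bundled (`meioscope.load_yakuba_table1()`).

## Worked example

```python
import meioscope as ms

table = ms.load_yakuba_table1()
x = table.loc["X"].to_numpy(float)          # [447, 901, 200, 74, 0]

# Raw Weinstein inversion: note the impossible negative E0
print(ms.weinstein_invert(x).E)
# [-0.2022  0.8915 -0.0543  0.365   0.    ]

# Constrained fit (E_r >= 0, no drive) is pushed to the E0 = 0 boundary
con = ms.fit_tetrad_model(x, "constrained", compute_ci=False)
print(con.E_hat.E.round(4))                  # [0.     0.5336 0.1629 0.3036 0.]

# Meiotic drive explains the deficit of non-recombinant chromatids
fit = ms.fit_tetrad_model(x, "md_co", compute_ci=False)
print(round(fit.b_hat, 3), round(fit.e0_hat, 3))
# 0.819 0.138
print(tuple(round(v, 3) for v in fit.ridge["b"]))
# (0.638, 1.0)
stat, p = ms.likelihood_ratio(fit, ms.fit_tetrad_model(x, "pci",
                                                       compute_ci=False))
print(round(stat, 1))                        # 41.8
```

The negative `E0 = -0.202` from the raw inversion says the X chromosome has
*too few* NCO chromatids for any ordinary tetrad distribution.  The drive
model fits the table essentially perfectly along a whole ridge of
`(E0, b)` combinations (`fit.ridge`); the quoted point estimates are the
midpoints of the per-parameter maximum-likelihood intervals, here a drive
bias of ~0.82 with ~14% zero-crossover tetrads.  The likelihood-ratio
statistic of 41.8 rejects chromatid interference as an alternative
explanation.  See `docs/methods.md` for the models, the ridge handling and
known discrepancies with published point estimates.

A full synthetic pipeline run from the shell:

```
meioscope simulate --geometry arms.yaml --tetrad 0.2,0.6,0.2,0,0 \
    --n-meioses 1000 --seed 1 --out geno.tsv
meioscope call --genotypes geno.tsv --events-out events.tsv \
    --classes-out classes.tsv --seed 1
meioscope tetrad --counts classes.tsv --model md_co
meioscope scan --events events.tsv --geometry arms.yaml --side centromere
```

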