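# paleodecay

Degradation kinetics of biomolecule records in dated lake-sediment cores.

Sedimentary archives of DNA marker genes (*rbcL*, 18S rRNA genes), lipid
biomarkers, pigments and macromolecules let paleolimnologists reconstruct
past lake ecosystems — but only through the filter of degradation. The
empirical pattern across such records is that biomolecule content per gram
dry sediment declines with sediment age *t* following a power law,

```
Y(t) = a · t^b ,        k = −b   ("decay constant")
```

rather than a single exponential: apparent reactivity decreases as the
remaining pool ages. A direct consequence is that half-lives are not
constant but grow **linearly** with sediment age — under `Y = a·t^(−k)` the
halving time of the pool at age *t* is

```
D(t) = t · (2^(1/k) − 1)
```

so a compound with a half-life of 0.77 y in 1-year-old sediment has a
half-life of 77 y in 100-year-old sediment. `paleodecay` packages this
analysis end to end, for people working on sedimentary DNA taphonomy,
organic-matter diagenesis, or multiproxy core studies:

* **Decay models** — statsmodels-style model objects
  (`PowerDecayModel`, `ExponentialDecayModel`, `LinearDecayModel`) fitted to
  per-analyte `(age, value)` profiles; `fit()` returns a `DecayFit` results
  object with the amplitude, slope, decay constant, R², slope p-value, a
  reliability flag (p > 0.05 or R² < 0.2), `summary()`, and model comparison
  by R².
* **Half-life arithmetic** — age-dependent half-life schedules over the
  standard age ladder (1–1,000 y) and calibration of `k` from a published
  age-1 half-life.
* **Group statistics** — decay-constant averages per lake/station, exact
  small-sample Wilcoxon rank-sum contrasts, Pearson correlations.
* **Community tools** — relative abundances, partitioning of qPCR total
  gene copies by amplicon group fractions, Bray–Curtis dissimilarity,
  permutation ANOSIM, taxon-fraction-vs-age regressions.
* **Preservation scenarios** — an explicit decision rule classifying each
  organism group's biomolecule record as adsorption/complexation control,
  chemical-reactivity control, or biotic exclusion (physical shielding).
* **Synthetic cores** — a seeded generator of multiproxy profiles and
  Dirichlet-multinomial community tables with the statistical structure
  the analysis assumes, so the full pipeline runs at desk scale.

## Worked example

```python
from paleodecay import PowerDecayModel, simulate_core

series = simulate_core(seed=42)          # 12 synthetic analyte profiles
diatom = [s for s in series if s.analyte_id == "diatom_rbcL"][0]
fit = PowerDecayModel(diatom).fit()
print(fit.summary())
```

```
power decay fit: diatom_rbcL
  amplitude a      9.30491e+08
  slope b          -1.5549  (SE 0.0497)
  decay constant k 1.5549
  R-squared        0.9819
  p(slope)         3.823e-17
  n (excluded)     20 (0)
  flagged          False
```

The series was generated with `a = 1e9` gene copies g⁻¹ and `b = −1.57`;
the log–log OLS fit recovers both within sampling error, and the fit is
not flagged (slope significant, R² ≥ 0.2). Its half-life schedule shows
the linear growth with age:

```python
sched = fit.half_life_schedule()
# ages:        1     20    50    100   200  500  1000  (years)
# half-lives:  0.562 11.2  28.1  56.2  112  281  562   (years)
```

Averaging decay constants by organism group and contrasting them:

```python
from paleodecay import fit_power, summarize_decay, pairwise_contrasts
fits = [fit_power(s) for s in series]
for s in summarize_decay(fits, "organism_group"):
    print(f"{s.label:15s} k = {s.mean_k:.2f} +/- {s.sd_k:.2f} (n={s.n_fits})")
```

```
diatom          k = 1.19 +/- 0.53 (n=5)
green_alga      k = 0.65 +/- 0.11 (n=4)
vascular_plant  k = 0.09 +/- 0.02 (n=3)
```

Diatom biomolecules decay fastest, vascular-plant ones barely at all —
three orders of magnitude apart in half-life terms. With only three
profiles per group the exact Wilcoxon contrast cannot reach significance
(the smallest achievable two-sided p at n = 3 vs 3 is 0.1), which is why
cross-lake designs (n = 5) are needed for the scenario classifier.

A shell session covering the same pipeline:

```bash
paleodecay simulate --seed 42 --out core/
paleodecay fit --profiles core/profiles.csv --out fits.csv
paleodecay halflife --fits fits.csv --out halflife_table.csv
paleodecay contrast --fits fits.csv --group-by organism_group --seed 1 --out stats.csv
paleodecay classify --fits fits.csv --out scenarios.json
```

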