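# riverpress

Multi-pressure assessment of river sampling sites: ordinal harmonisation of
pressure data, non-compensatory pressure-type indices, and the additive
Global Pressure Index (GPI) with ecoregion / river-type summaries.

## The problem

European rivers are degraded by many co-occurring human pressures —
impoundment, hydropeaking, water abstraction, channelisation, embankments,
barriers, acidification, eutrophication, organic pollution.  Water Framework
Directive reporting requires a consistent, comparable classification of
these pressures across countries whose national databases code them very
differently (presence/absence flags, 3- to 5-level ordinal scales).
`riverpress` implements the full assessment pipeline for site-level survey
tables: it is written for freshwater ecologists and river-basin managers who
need reproducible pressure classification, and for methodologists studying
non-compensatory composite indicators.

## The method

Fifteen pressure variables in four groups — hydrology (H), morphology (M),
water quality (W), connectivity (C) — are harmonised onto an ordinal
gradient from 1 (nearly undisturbed) to 5 (strongly impacted).  The three
instream-morphology variables are averaged into `M_morph_instr`.  Each
group g with harmonised values v₁…vₖ gets a *non-compensatory* index

    PIg = mean{ vᵢ : vᵢ ≥ 3 }   if any vᵢ ≥ 3,   else   mean{ vᵢ },

so nearly-undisturbed values cannot compensate for impacted ones (values
1, 3, 5 give 4, not the naive mean 3).  A group is *impacted* when its
index ≥ 3.  The Global Pressure Index adds the impacted group indices,

    GPI = Σg PIg · 1[PIg ≥ 3]  ∈  {0} ∪ [3, 20],

and is binned into classes 0–4 (unimpacted, single [3, 6), double [6, 9),
triple [9, 12), quadruple [12, 20]).  Sites are also split into W / HMC /
W+HMC / NoP by whether water-quality and/or hydromorphological-plus-
connectivity groups are impacted.  A six-class river typology (A Headwater
… F Lowland) is derived from the 15 European Fish Types, and summaries are
produced per Illies ecoregion and river type.

Because the original multi-country survey data are not publicly available,
the package ships a calibrated synthetic-site generator (latent-severity
Gaussian copula over the ordinal marginals) whose defaults reproduce the
published European-level prevalences — water quality 59%, hydrology 41%,
morphology 39%, segment connectivity 35%, 21% unimpacted — together with
*exact* model-implied truth values for parameter-recovery experiments.
See `docs/methods.md` for the model details and limitations.

## Worked example

```python
from riverpress import (
    default_config, generate_frame, harmonize_frame, score_frame, group_index,
)
from riverpress.summaries import combination_proportions, gpi_statistics

group_index([1, 3, 5])        # -> 4.0   (threshold-conditional mean)

config = default_config(n_total=2000, seed=1)
sites, truth = generate_frame(config, seed=1)
scores = score_frame(harmonize_frame(sites))
print(scores[["site_id", "HPI", "MPI", "WQPI", "CPI",
              "GPI", "GPI_class", "combination"]].head(3))
print(combination_proportions(scores, by=None).table.round(3))
print(gpi_statistics(scores, by="river_type").display())
```

prints

```
site_id  HPI   MPI  WQPI  CPI  GPI  GPI_class combination
S000001  1.0 1.000   3.0  1.0  3.0          1           W
S000002  4.0 1.444   1.0  1.0  4.0          1         HMC
S000003  3.0 3.000   3.0  1.0  9.0          3       W+HMC

       NoP     W    HMC  W+HMC  n_sites
all  0.214  0.14  0.208  0.438   2000

   min   max  mean  median  n_sites
A  3.0  17.3   6.4     6.0      522
B  3.0  18.0   7.3     6.6      622
C  3.0  15.5   8.6     9.0       59
D  3.0  15.5   5.9     6.0      105
E  3.0  14.5   6.4     6.0       59
F  3.0  16.5   9.9    10.0      205
```

Site S000001 has a single impacted group (WQPI 3 → GPI 3, class 1,
category W); S000003 has three impacted groups summing to GPI 9 (class 3,
W+HMC).  The recovered combination shares match the generator's exact
truth (NoP 0.210, W 0.131, HMC 0.200, W+HMC 0.459) to within binomial
error, and impacted lowland sites (type F, mean GPI 9.9) are markedly more
degraded than headwaters (type A, 6.4) — the configured severity gradient.

The same pipeline runs from the shell:

```bash
riverpress simulate --seed 1 -n 2000 -o sites.csv --truth truth.json
riverpress run sites.csv -o results/            # validate→harmonize→score→summaries
riverpress summarize results/scores.csv --table fig3 --by ecoregion -o fig3.csv
riverpress oracle --check-extremes              # brute-force index bounds
```

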