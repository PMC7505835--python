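# retbench

Retention benchmarks for salvage logging in naturally disturbed forests,
estimated from paired species-by-plot incidence matrices.

## The problem

After a wildfire, windstorm or insect outbreak, the dead and dying trees of
a naturally disturbed forest are frequently removed by *salvage logging*.
The disturbed-but-unlogged habitat hosts species — many of them saproxylic
(dependent on dead wood) — that disappear from salvage-logged stands.  A
practical conservation question follows: **what proportion of a disturbed
area must be left unlogged to maintain a given fraction of the richness of
the species unique to that habitat?**

`retbench` answers this with a *mixture of two sample-based
rarefaction/extrapolation curves*.  Field studies supply two species-by-plot
matrices per dataset: T₁ plots surveyed in unlogged, disturbed forest and T₂
plots in the adjacent salvage-logged forest.  Counts are reduced to
incidence frequencies Qᵢ (the number of plots in which species *i* occurs),
which are less sensitive than abundances to clustering of individuals.

## The statistic

For a species with incidence frequency Qᵢ out of T plots, the probability
that a random subsample of *t* plots misses it is hypergeometric,

&nbsp;&nbsp;&nbsp;&nbsp;m(t; T, Qᵢ) = C(T−Qᵢ, t) / C(T, t),

extended to real *t* through log-Γ so that curves are continuous.  Expected
richness of *t* plots is Σᵢ [1 − m(t; T, Qᵢ)] (rarefaction); beyond T the
curve is extrapolated with the Chao2 estimate of undetected richness,
Q̂₀ = ((T−1)/T) Q₁²/(2Q₂), from the numbers of uniques (Q₁) and duplicates
(Q₂).

Salvage-logging a proportion of the area is modelled by *replacing* t₂ of
the T₁ unlogged plots with plots drawn from the logged sample (total effort
held fixed at T₁).  With t₁ = T₁ − t₂ retained plots, the expected richness
of the mixed sample decomposes over the species classes fixed by the
reference samples:

* unique to unlogged: Σᵢ [1 − m_U(t₁)]
* unique to logged:  Σᵢ [1 − m_L(t₂)]
* shared:            Σᵢ [1 − m_U(t₁)·m_L(t₂)]

The headline benchmarks come from the *normalized unique-to-unlogged
curve* u(p) at retention proportion p = t₁/T₁:

* **p\*** — the smallest p with u(p) ≥ q (default target q = 0.90), the
  proportion of area that must stay unlogged to maintain 90 % of the
  unique-species richness;
* **u(0.5)** — the fraction of unique richness that survives logging half
  of the area.

Benchmarks are averaged (mean ± SD, one equally weighted value per species
matrix) over all datasets and by disturbance type, saproxylic status, taxon
and year, and a beta regression (logit link, B-spline smooth in years since
disturbance, AIC-selected df) tests whether they drift with time since
disturbance.

## Worked example

The package ships a generator for a 24-dataset synthetic reference
collection (3 disturbance types × saproxylic/non-saproxylic × 4 taxon
labels, with plot counts and rare-species loads typical of field studies):

```python
from retbench import packaged_collection, run_pipeline, PipelineConfig

studies = packaged_collection()
result = run_pipeline([s.paired for s in studies], PipelineConfig())

summaries = result["summaries"]
overall = summaries[(summaries.response == "p_star") & (summaries.grouping == "all")].iloc[0]
at_half = summaries[(summaries.response == "frac_at_half") & (summaries.grouping == "all")].iloc[0]
print(f"retention for 90% unique richness: {100*overall['mean']:.1f} +/- {100*overall['sd']:.1f}% (n={overall['n']})")
print(f"unique richness kept at 50% retention: {100*at_half['mean']:.1f} +/- {100*at_half['sd']:.1f}%")
for _, row in summaries[(summaries.response == "p_star") & (summaries.grouping == "saproxylic")].iterrows():
    print(f"  {row['level']}: {100*row['mean']:.1f} +/- {100*row['sd']:.1f}%")
reg = result["regression"]["p_star"]
print(f"time since disturbance: edf={reg['edf']}, LRT p={reg['lrt_p_value']:.2f}")
```

prints

```
retention for 90% unique richness: 66.8 +/- 12.6% (n=24)
unique richness kept at 50% retention: 79.7 +/- 8.6%
  non_saproxylic: 56.6 +/- 8.7%
  saproxylic: 76.9 +/- 5.7%
time since disturbance: edf=1, LRT p=0.66
```

Read: across the 24 synthetic datasets, on average 66.8 % of a disturbed
area must remain unlogged to keep 90 % of the unique-species richness;
logging half the area keeps 79.7 % of it.  Saproxylic groups, whose species
are rarer plot-to-plot, demand markedly more retention than non-saproxylic
groups, and the benchmarks show no trend with time since disturbance (the
smooth collapses to a linear term, edf = 1, and is not significant).

The same pipeline runs from the shell on CSV inputs:

```bash
retbench simulate --out-dir data/            # write the collection as CSVs
retbench compute --metadata data/meta.csv --data-dir data --out-dir out/
retbench summarize --benchmarks out/benchmarks.csv --metadata data/meta.csv --group-by saproxylic
retbench regress --benchmarks out/benchmarks.csv --metadata data/meta.csv \
    --response p_star --out out/report.json
```

`out/` then contains `benchmarks.csv` (one row per dataset), `summaries.csv`
(group means ± SD), `curves.csv` (the mixture decompositions on a 201-point
retention grid) and `regression.json`.

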