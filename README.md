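# lulctraj

Land-use/land-cover **trajectory analysis** for dated stacks of categorical
maps, built for the post-classification study of tropical deforestation and
forest regrowth. Given a time-series of co-registered maps labelled mature
forest (MF), non-forest (NF, crops/pasture) and secondary forest (SF) — plus
permanent water and per-date cloud gaps — the package:

* enforces **temporal consistency** (relabelling implausible SF/NF → MF
  reversals as SF) and fills cloud gaps over persistent mature forest;
* derives per-pixel trajectory metrics at every date: the **age of secondary
  forest** (ASF, years continuously SF since the last clearance, censored
  when SF stands at the first date), the **period of active land use**
  (PALU, years of the NF run preceding the current regrowth) and the
  **frequency of clearance** (FC, count of observed MF→NF / SF→NF
  transitions), with the standard class bins
  (ASF ≤5 / 6–15 / ≥16 yr; PALU ≤2 / 3–4 / ≥5 yr; FC 1 / 2 / ≥3×);
* computes per-period transition areas, annual deforestation and regrowth
  rates — the logarithmic rate *r* = (100/Δt)·ln(A₂/A₁) % yr⁻¹ and the
  absolute rate *R* = (A₂−A₁)/Δt ha yr⁻¹, plus a transition-fraction
  convention *r* = 100·T/(A·Δt) for fluxes out of small classes — with
  distribution summaries and a six-way period typology (MF-only clearance,
  MF>SF clearance, … net abandonment);
* performs **accuracy assessment** (error matrix, overall accuracy,
  omission/commission errors) and **inverse calibration** of class areas,
  πᵢ = Σⱼ (nᵢⱼ/n·ⱼ)·pⱼ, which removes the bias of naive pixel counting using
  the validation error matrix;
* ships a **semi-Markov landscape simulator** (MF —clearance→ NF —use→ SF
  —reclearance→ NF …) with exact per-pixel truth, confusion-matrix noise
  injection and patch-based validation-point sampling, so the whole pipeline
  is testable end-to-end with known answers.

Bundled example data (`lulctraj.datasets`) include published validation
matrices and per-year class proportions for three Brazilian Amazon sites
(Manaus, Santarém, Machadinho d'Oeste).

## Worked example

Simulate a 100×100 landscape observed on a real 21-date 1984–2011 Landsat
calendar, compute metrics and rates:

```python
import lulctraj as lt

stack, truth = lt.simulate_stack(lt.SimulationConfig(shape=(100, 100), seed=7))
mm = lt.compute_metrics(stack)

print(lt.landcover_proportion_table(stack).tail(3).round(1).to_string(index=False))
print(lt.crosstab_palu_fc(mm, -1).round(1))
summary = lt.summarize_rates(lt.period_rate_table(stack))
```

which prints the land-cover proportions of the last dates,

```
    date  year   MF  NF   SF
20090809  2009 55.3 9.4 35.3
20100625  2010 54.4 9.3 36.3
20110612  2011 53.4 9.4 37.2
```

the PALU × FC cross-tabulation (% of the 2011 SF area; e.g. 38.9 % of
standing regrowth was used briefly (≤2 yr) and cleared only once),

```
         low  medium  high
short   38.9    25.3  14.0
medium   8.0     5.0   2.0
long     4.6     1.6   0.5
```

and relative-rate summaries per process (mean MF deforestation −1.81 % yr⁻¹
under the default 2 %/yr clearance hazard; SF reclearance and regrowth rates
are normalized by the smaller source areas, hence larger).

The same stages are scriptable from the shell:

```bash
lulctraj simulate --rows 100 --cols 100 --seed 7 --out sim/
lulctraj correct sim/manifest.csv --out corrected/
lulctraj metrics corrected/manifest.csv --out products/
lulctraj rates corrected/manifest.csv --out products/
lulctraj run --simulate-demo --seed 7 --out demo/
```

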