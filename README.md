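# recredit

Crediting-error analysis for improved-forest-management (IFM) carbon
offsets issued against regional "common practice" baselines.

## The problem

Cap-and-trade offset programs award large *upfront* credit tranches to IFM
projects based on the gap between a project's measured initial carbon
stocks and the 100-year average of its modeled baseline harvest scenario.
Protocol rules forbid that baseline average from falling below **common
practice** (CP): the average standing-live aboveground carbon density
(tCO₂e/acre) of a coarse regional stratum — an *assessment area* (a group
of forest types) averaged across a whole *supersection* (a group of
ecosections).  Because nearly all projects park their baselines exactly at
this floor, CP itself determines issuance.

Averaging ecologically dissimilar forests invites the ecological fallacy:
a parcel of carbon-dense Douglas-fir/tanoak forest compared against an
average that also contains arid ponderosa woodland looks "above average"
without any management change, and a developer who knows their forest can
select exactly such parcels (adverse selection).  `recredit` quantifies
the resulting crediting error:

1. **Replicate issuance** from digitized project components
   (onsite pools IFM-1/IFM-3, wood-product pools IFM-7/IFM-8, secondary
   effects, confidence deduction):
   `credits = [(IC + WPₚ) − (B·A + WP_b) + SE]·(1 − cd)`, floored at 0.
2. **Re-estimate CP** at species/forest-type resolution: a per-supersection
   radius-neighbors classifier maps each project's reported species
   composition (fractional basal area) to a probability distribution over
   forest-type codes; the alternative CP is the probability-weighted mean
   of per-forest-type CP estimates, where every CP is a design-based
   ratio-of-sums `Σ(density·expansion acres) / Σ(expansion acres)` with a
   delta-method variance.
3. **Recompute credits** after rescaling each project's reported CP by the
   assessment-area-weighted ratio `altCP / recomputedCP` (so the change is
   attributable purely to aggregation, not to reproduction error) and
   constraining a re-selected baseline by it.
4. **Propagate uncertainty**: 1000 Gaussian Monte Carlo draws of the
   forest-type densities, pushed coherently through steps 2–3, summarised
   at the 5th/25th/50th/75th/95th percentiles per project and program-wide
   (percentiles of per-draw program totals).

A first-class synthetic-data module generates FIA-style inventory
conditions and project portfolios with closed-form ground truth and a
tunable adverse-selection strength γ (enrollment probability ∝ exp(γ·z)
in standardized carbon density), so every stage is testable as a
parameter-recovery problem.

## Worked example

```python
from recredit import CreditingAnalysis, ProjectSimConfig, synthetic

land = synthetic.demo_landscape(seed=7)            # 2 supersections, mixed AAs
inv = synthetic.generate_inventory(land)           # 1200 inventory conditions
projects, _ = synthetic.generate_projects(
    ProjectSimConfig(n_projects=40, adverse_selection_strength=2.0, seed=7),
    land, inv)

res = CreditingAnalysis.from_landscape(land, inv, projects).fit(n_draws=1000, seed=7)
print(res.summary())
```

```
Crediting-error analysis
================================================================
projects analyzed                        40
credits analyzed (tCO2e)          7,366,854
net crediting error (tCO2e)       2,393,553
  percent of analyzed                 32.5%
  value at $13.67/tCO2e        32,719,873
  Monte Carlo (1000 draws): p5=2,193,171, p25=2,307,319, p50=2,394,726, p75=2,480,843, p95=2,599,041
issuance replication R^2             1.0000
classifier weighted F1                1.000 (median over supersections)
over-credited projects                   33 of 40
================================================================
```

Reading the output: this portfolio was generated with moderate adverse
selection (γ = 2) on a landscape whose assessment areas pool wet and arid
forest types, and the analysis attributes 32.5% of the issued credits to
the coarse averaging rather than to any change in management.  The narrow
Monte Carlo band reflects a well-sampled synthetic inventory.  Issuance
replication is exact (R² = 1) because the synthetic records are issued by
the same protocol formula the analysis replicates, and the classifier is
perfect because the demo forest types have distinct species signatures.
`res.project_error_table()` gives the per-project view (most over-credited
first; `SYN0019` is 100% over-credited — its species-specific CP exceeds
its measured initial stocks, so it would have earned nothing):

```
project_id  error_percent_p25  error_percent_p50  error_percent_p75
   SYN0019         100.000000         100.000000         100.000000
   SYN0013          82.772723          87.717731          92.866298
   SYN0027          83.725876          85.858935          87.725615
```

The same pipeline is scriptable from the shell:

```bash
recredit simulate --scenario stratified --n-projects 50 --gamma 2 --seed 7 --out sim/
recredit common-practice --inventory sim/inventory.csv --group-by forest-type --out cp.csv
recredit recredit --projects sim/projects.json --inventory sim/inventory.csv \
                  --map sim/assessment_map.json --seed 7 --out results/
recredit report --demo --seed 7 --out report/
```

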