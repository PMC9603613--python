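# ecofoot3d

Natural-capital accounting and sustainability assessment for regional
consumption panels, built around the improved three-dimensional ecological
footprint model. It is aimed at researchers assessing whether a region's
resource demand is met from renewable flows or by drawing down natural-capital
stocks — the kind of question provincial footprint studies answer from
statistical-yearbook data.

## What it computes

Starting from item-level consumption, land areas and population, the package
accounts per-capita ecological footprint (EF) and biocapacity (BC) by land
class (cropland, grassland, forest, water, construction, fossil-energy land):

    EF_i = eqf_i · Σ_j (C_j / Y_j) / N          BC_i = A_i · yf_i · eqf_i · (1 − d) / N

with equivalence factors `eqf`, yield factors `yf`, world-average yields `Y`,
population `N` and biodiversity deduction `d` (default 12%). On top of the
accounts it provides:

* **3D footprint** — depth `1 + Σ max(EF_i − BC_i, 0) / Σ BC_i` (multiples of
  annual flows consumed, ≥ 1), size `Σ min(EF_i, BC_i)` (flow capital actually
  occupied), EF3D = depth × size, and the flow/stock indicators γ_FLOW
  (= size/BC × 100%, where EF ≤ BC) and λ (= ED/BC, where EF > BC).
* **Security indices** — Shannon footprint diversity (EFDI), the comprehensive
  land pressure index (= depth), the ecological tension index ETI = ef′/ec with
  its six-level grading, and the ecological coordination coefficient
  ECC = (EPI + 1)/√(EPI² + 1), which peaks at √2 ≈ 1.414 when supply and
  demand balance.
* **Grey tools** — Deng grey relational degrees between land-class consumption
  and the total footprint, and GM(1,1) forecasting of the index series with the
  posterior-error test (C, p, four-level accuracy grade).
* **Synthetic panels** — a generator that inverts the accounting formulas so
  configured EF/BC trajectories are reproduced exactly at zero noise, including
  a packaged four-region (QH, GS, NX, NMG) 2011–2020 scenario.

## Worked example

```sh
ef3d simulate --out demo/in --seed 1 --noise 0.05
ef3d run --consumption demo/in/consumption.csv --context demo/in/context.csv \
         --factors demo/in/factors.csv --out demo/out --seed 1
```

`demo/out/indices.csv` then contains, for the final simulated year:

```
region,year,efdi,i_comprehensive,eti,eti_grade,ecc
GS,2020,1.2804,2.9195,1.2213,Moderately unsafe,1.4072
NMG,2020,1.4896,1.9451,1.0820,Moderately unsafe,1.4131
NX,2020,1.0776,4.4474,1.4470,Moderately unsafe,1.3912
QH,2020,1.5817,1.5222,0.8944,Slightly unsafe,1.4120
```

Every region's comprehensive pressure index exceeds 1 (renewable flows do not
cover demand) with footprint depth ordered NX > GS > NMG > QH, while the
footprint-size ordering (in `ef3d.csv`) is NMG > QH > GS > NX: the regions
with the largest biocapacity occupy the most flow capital but deplete stocks
the least. `forecast.csv` carries each index three years past the sample with
its GM(1,1) diagnostics, e.g. for ETI in 2023:

```
NX,eti,2023,forecast,1.4737,0.3098,1.0000,1
QH,eti,2023,forecast,0.9037,0.9102,0.5000,4
```

(the final columns are C, p and the accuracy grade — QH's near-flat, noisy
series is fitted poorly, grade 4, so its forecast should be discounted).

The same stages are available as library calls (`build_footprint_panel`,
`ef3d_result`, `security_indices`, `gm11_fit`, `grey_relation`, …) and as
stepwise subcommands `account`, `indices`, `grey`, `forecast`, `report`.

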