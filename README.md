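# nitroscape

Coupled land-use, ecosystem-carbon and biodiversity assessment of
nitrogen-fertilizer reduction policies on a European grid.

## The scientific problem

A policy that halves nitrogen-fertilizer input changes crop yields, and with
them the economics of land use. Two contrasting responses are plausible:

* **abandonment** — lower profitability pushes marginal cropland out of
  production, into fallow and pasture;
* **extensification** — to keep production up at lower yields, pasture is
  converted into (less intensively managed) cropland.

Each response reshapes the land surface and therefore two classes of
environmental outcome at once: ecosystem **carbon** (net primary production,
soil carbon, biomass carbon) and **biodiversity** (species richness,
abundance, compositional similarity, and the intactness index BII).
`nitroscape` models this one-way chain end to end on a synthetic but
structurally realistic European domain:

```
scenario generator ──► land-use crosswalk ──► biodiversity projection
        │                      │
        │                      └────────────► carbon fields + dynamics
        │
        └─► yield response to N input
                                              ──► differences, significance
                                              ──► LMDI area/intensity breakdown
                                              ──► win/loss quadrant maps
```

All data are generated by the package itself (Gaussian-random-field land-use
maps, Michaelis–Menten yield response, configured carbon densities), so the
whole analysis is reproducible from a single integer seed. A small reference
table of EU-scale annual-mean indicator levels from a full-scale coupled
model chain ships with the package for arithmetic cross-checks.

## Worked example

```python
from nitroscape import PipelineConfig, run_pipeline

cfg = PipelineConfig(domain=(40.0, 60.0, 0.0, 20.0), resolution=1.0, seed=3)
results = run_pipeline(cfg)

for family, res in results.items():
    print(family, res.regional_totals.loc["EU"].round(3).to_dict())
```

prints (EU totals, Halving-N minus Baseline):

```
abandonment     {'delta_npp_MtC': 15.849, 'delta_soil_c_MtC': 381.562,
                 'delta_biomass_c_MtC': 56.491, 'delta_bii_pct': 0.98,
                 'delta_sr_pct': 0.25}
extensification {'delta_npp_MtC': -28.706, 'delta_soil_c_MtC': -477.516,
                 'delta_biomass_c_MtC': -62.285, 'delta_bii_pct': 1.222,
                 'delta_sr_pct': -0.162}
```

The two archetypes bracket the policy's range: abandonment gains soil carbon
and species richness; extensification loses both carbon and richness (BII
still rises slightly because lower yields extensify crop management).
The LMDI breakdown attributes the abandonment soil-carbon gain to grassland
expansion:

```python
print(results["abandonment"].breakdown["soil_c"].round(2))
#            E_baseline  E_policy  ...  dE_area  dE_intensity
# cropland      7900.90   6530.73  ... -1169.17       -200.99
# grassland     9375.60  11139.66  ...  1762.69          1.38
# forest       15307.21  15307.21  ...     0.00          0.00
```

and the quadrant classification shows the joint carbon–biodiversity outcome
per grid cell (soil carbon vs species richness):

```python
print(results["abandonment"].quadrants["soil_c_vs_sr"].percentages)
# {'I_win_win': 80.25, 'II_loss_win': 3.75, 'III_loss_loss': 0.0,
#  'IV_win_loss': 16.0, 'no_change': 0.0}
print(results["extensification"].quadrants["soil_c_vs_sr"].percentages)
# {'I_win_win': 0.0, 'II_loss_win': 26.25, 'III_loss_loss': 73.25,
#  'IV_win_loss': 0.5, 'no_change': 0.0}
```

Roughly 80% of cells are win–win under abandonment and ~73% loss–loss under
extensification at this problem size.

The same run is available from the command line:

```bash
nitroscape run-all --seed 3 --out results/run
nitroscape tables --levels src/nitroscape/data/eu_annual_means.csv --out diffs.csv
```

## Reproduction

`scripts/acceptance.py` recomputes every headline quantity from scratch and
writes them to JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It reports the reference-table differences (e.g. soil carbon +1014.13 MtC
under abandonment, NPP −2.71 MtC/yr under extensification), the LMDI and
aggregation residuals (machine precision), the type-I error of the
serial-correlation-corrected t-test (0.05 at seed 1), the EU scenario
deltas, and the win–win / loss–loss quadrant shares. All randomness derives
from `--seed`; two runs with the same seed are identical.

The pytest suite (`tests/`) contains ~150 unit and property tests plus
`tests/test_acceptance.py`, one test per headline claim.

## Layout

| Path | Contents |
| --- | --- |
| `src/nitroscape/scenarios.py` | synthetic Baseline / Halving-N land-use pairs, yield response |
| `src/nitroscape/crosswalk.py` | economic categories → biodiversity classes and PFTs |
| `src/nitroscape/biodiversity.py` | SR / abundance / similarity / BII projection |
| `src/nitroscape/fields.py` | per-PFT carbon densities, relaxation dynamics |
| `src/nitroscape/accounting.py` | differencing, regional totals, significance test |
| `src/nitroscape/lmdi.py` | exact area/intensity decomposition |
| `src/nitroscape/quadrants.py` | win/loss quadrant classification |
| `src/nitroscape/pipeline.py`, `cli.py` | orchestration and CLI |
| `docs/methods.md` | model description, parameter tables, limitations |
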