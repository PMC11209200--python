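# nemascreen

Comparative ecotoxicological screening of nematicidal plant volatiles
versus synthetic nematicides, as a reusable pipeline:

1. **Registry** (`nemascreen.registry`) — validated compound property and
   toxicity-endpoint tables (CAS-checked, `>`-qualifier aware, lossless
   CSV/JSON round trips), including a bundled reference dataset of 25
   compounds: 5 synthetic nematicides and 20 plant volatiles across four
   biosynthetic classes.
2. **Property estimation** (`nemascreen.properties`) — Seth relation
   `Koc = 0.35 * Kow`, Henry's law constant `H = P * M / S`, solid
   fugacity ratio `F = exp(6.79 * (1 - Tm/T))`, and reconciliation of
   printed vs derived Henry's law constants with configurable policy.
3. **Level I fugacity engine** (`nemascreen.fugacity`) — equilibrium
   distribution of a fixed 100,000 kg emission across a closed
   seven-compartment evaluative world (air, water, soil, sediment,
   suspended particles, biota, aerosols) at 25 °C. Rows whose tabulated
   inputs cannot reproduce a supplied published distribution are flagged
   `non_reconstructable` rather than silently reported.
4. **Hazard classification** (`nemascreen.hazard`) — GHS acute oral and
   dermal categories (1–5), the six-band toxicity-class scheme, and
   cross-trophic aquatic minimum summaries. Intervals are left-open /
   right-closed; `>`-qualified values classify immediately above their
   bound.
5. **Screening report** (`nemascreen.screening`) — joins exposure
   (distribution) with hazard, applies transparent configurable flag
   rules (`water_affine`, `aquatic_concern`, `mammalian_concern`, ...),
   computes fold-difference comparisons, and writes bit-stable
   CSV/JSON/markdown reports plus per-class summaries.
6. **Synthetic data** (`nemascreen.synthetic`) — seedable generators for
   internally consistent compound sets with controlled partitioning
   behaviour (air/water/soil-seeking profiles) and class-structured
   log-normal endpoint tables, enabling parameter-recovery tests.

## Test

```sh
python -m pytest -q tests/
```

## CLI

```sh
nemascreen ped --out ped.csv --check-reference --audit audit.json
nemascreen classify --out classification.csv
nemascreen screen --out-dir report/
nemascreen synth --n 50 --seed 7 --profile air_seeking --out-dir synthetic/
```

All commands default to the bundled dataset; pass `--compounds`,
`--ecotox`, `--tox` to use your own tables in the documented CSV schema
(see `nemascreen.registry.COMPOUND_CSV_COLUMNS`). `ped` accepts a
YAML/JSON environment override file; `screen` accepts a combined
`--config` with `environment:` and `thresholds:` sections.

## Library quick start

```python
from nemascreen import bundled_paper_dataset, distribute, default_environment

dataset = bundled_paper_dataset()
fluopyram = dataset.compound("658066-35-4")
result = distribute(fluopyram, default_environment())
print(result.rounded())   # {'soil': 59.3, 'water': 39.3, 'sediment': 1.3, ...}
```
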