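# simpull

Quantitative analysis of **single-molecule pull-down (SiMPull)** experiments:
protein complexes are immunoprecipitated onto a passivated, antibody-coated
slide surface and imaged one complex at a time by TIRF microscopy. From the
resulting movies this package computes the three readouts the assay is used
for:

1. **Molecules per imaging area** — diffraction-limited spots are detected on
   an average projection and counted per 5000 µm² field of view
   (mean ± s.d. across replicate areas), with an enrichment ratio against a
   control-antibody pull-down and dilution normalization for comparing
   lysates.
2. **Subunit stoichiometry from photobleaching** — each spot's intensity
   trace is a staircase whose downward steps are single-fluorophore bleaching
   events. Steps are counted by greedy change-point fitting with a
   Schwarz-type penalty, and the population step histogram is inverted into a
   copy-number mixture through the dark-fraction observation model
   P(*j* steps | *n* copies, maturation *m*) =
   C(*n*, *j*) *m*ʲ (1−*m*)ⁿ⁻ʲ / (1 − (1−*m*)ⁿ), fitted by maximum
   likelihood (EM).
3. **Two-color colocalization** — spots matched one-to-one across channels
   within 2 px (≈300 nm, one diffraction-limited spot), reported as the
   percentage of the lower-density channel with the Poisson chance-overlap
   null 100 (1 − e^(−λπr²)) alongside, plus dark-fraction correction of the
   co-complex fraction (observed / *m*) and a z-test for changes between
   conditions.

Because public SiMPull deposits rarely include raw movies, the package ships
a **synthetic TIRF-field simulator** with full ground truth — surface
densities, per-subunit chromophore maturation, geometric photobleaching,
Poisson shot noise + Gaussian read noise, channel offsets, nonspecific
binders — so every stage of the pipeline is validated by parameter recovery.
It is aimed at single-molecule labs that want a tested, scriptable
replacement for ad-hoc per-experiment analysis code.

## Worked example

The packaged demo where 20% of complexes carry two labeled copies of the
bait (the "1:1 or 1:2" stoichiometry pattern):

```python
from simpull.demo import dimer_subpopulation
from simpull.pipeline import run_pipeline

report = run_pipeline(dimer_subpopulation(seed=0))
dist = report["step_distribution"]["counts"]
print(dist)
print(report["stoichiometry"]["call"])
print({n: round(w, 3) for n, w in report["stoichiometry"]["weights"].items()})
```

prints

```
{'1': 184, '2': 30}
monomer + dimer
{'1': 0.766, '2': 0.234, '3': 0.0, '4': 0.0}
```

Of 214 accepted trajectories, 86% bleach in one step and 14% in two. Naively
that reads as a 14% dimer fraction — but a dimer whose second chromophore
never matured bleaches in one step, so the raw histogram undercounts
dimers. Inverting the observation model at maturation 0.75 attributes 23%
of complexes to the two-copy species, close to the generating truth of 20%
(the report also carries the uncorrected fit under `stoichiometry_raw`).

The same run from the shell:

```bash
simpull run --config examples/dimer_subpopulation.yaml --out-dir out/
```

writes `spots.csv`, `step_fits.csv` and a self-contained `report.json`
(seed, config hash and all stage summaries; same config + seed reproduces
it byte-identically). `simpull simulate|detect|steps|stoich|coloc` expose
the individual stages on TIFF/CSV/JSON files.

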