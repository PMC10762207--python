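# domcascade

Analysis toolkit for tracking the **degradation cascade** of dissolved
organic matter (DOM) in ultrahigh-resolution mass-spectrometry surveys of
soils and streams.

As DOM is progressively reworked by microbes along environmental gradients
(soil depth, hillslope position, downstream flowpaths), its molecular
composition converges toward a shared, difficult-to-degrade pool of
compounds — formulas detected in *every* sample, the "universal" pool. This
package implements the full desk-side analysis for FT-ICR-MS data of that
process, for biogeochemists and environmental metabolomicists:

- **Formula assignment** (`domcascade.assignment`): calibrated negative-mode
  peak lists → molecular formulas, by exhaustive CHNOSP enumeration within
  element bounds (C 0–100, H 2–200, O 0–70, N 0–3, S 0–2, P 0–2) at a 0.2 ppm
  tolerance over 150–1000 m/z, with duplicate-measurement retention, a
  method detection limit, and per-sample intensity normalisation.
- **Chemistry core** (`domcascade.chem_core`): exact monoisotopic masses,
  H/C–O/C–N/C ratios, double-bond equivalents, the modified aromaticity
  index, and a fully configurable van-Krevelen compound-class table
  (lignin-, tannin-, carbohydrate-, condensed-aromatic-like, ...).
- **Cascade statistics** (`domcascade.cascade_stats`): universal-pool
  detection at any occupancy threshold, per-sample universal fractions by
  richness and intensity, class-composition profiles, and the
  intensity-weighted mean mass
  `m/z_wm = Σ(m/z_i · I_i) / Σ I_i`.
- **Rarefied similarity** (`domcascade.rarefied_similarity`): percentage of
  formulas shared with a reference DOM pool (e.g. deep-sea DOM) under
  repeated rarefaction to a fixed depth (default 6000 formulas × 1000
  iterations), for fair cross-study comparison.
- **Gradient inference** (`domcascade.gradient_inference`): GLM trends with
  estimated marginal means and Tukey-adjusted contrasts; Pearson-|r|>0.80
  collinearity pruning; permutation-tested stepwise selection; PCNM spatial
  eigenvectors; adjusted-R² variance partitioning over 2–3 predictor
  matrices; hierarchical (Shapley) partitioning.
- **Synthetic data** (`domcascade.synthetic_data`): gradient-structured DOM
  worlds with known ground truth — a universal core, class-specific
  depletion, mass-biased removal, lognormal intensities, duplicate peak
  lists with ppm jitter and sub-detection-limit noise.
- **Pipeline & CLI** (`domcascade.pipeline`, `dom-cascade ...`):
  reproducible end-to-end runs with a hashed artifact manifest.

## Worked example

```python
import pandas as pd
from domcascade import (SimulationConfig, simulate_dataset, universal_set,
                        universal_fractions, fit_trend, GradientDesign)

cfg = SimulationConfig(seed=42)          # 4 catchments x (16 soil + 1 stream)
dataset, truth = simulate_dataset(cfg)
pool = universal_set(dataset)            # formulas present in all 68 samples
print(f"{dataset.n_formulas} formulas x {dataset.n_samples} samples; "
      f"universal pool: {len(pool)}")

frac = universal_fractions(dataset, pool).join(dataset.metadata)
soil = frac[frac.sample_type == "soil"].copy()
soil["depth"] = pd.Categorical(soil.depth_cm.astype(int),
                               categories=[5, 15, 30, 60], ordered=True)
soil["share"] = soil.intensity_pct / 100

trend = fit_trend(GradientDesign(data=soil, response="share", focal="depth",
                                 covariates=("position", "catchment"),
                                 family="gaussian-logit"))
print(trend.emmeans.round(3).to_string(index=False))
```

Output:

```
3000 formulas x 68 samples; universal pool: 400
 level  emmean  ci_low  ci_high
     5   0.545   0.536    0.555
    15   0.590   0.581    0.599
    30   0.623   0.614    0.632
    60   0.659   0.651    0.668
```

The marginal means are the estimated share of total signal intensity carried
by universal compounds at each soil depth, averaged over hillslope positions
and catchments and back-transformed from the logit scale. The simulated
world plants a +10 percentage-point increase per gradient axis, and the
model recovers it: 54.5% at 5 cm rising to 65.9% at 60 cm, with all
Tukey-adjusted contrasts against the 5 cm baseline significant. This is the
signature of a degradation cascade: deeper, longer-processed DOM is
increasingly dominated by the same universal compounds.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's headline quantities from scratch — it simulates
the default synthetic world from the given seed, runs universal-pool
statistics, non-universal weighted-mass shifts, and the depth-trend model
end to end — and writes the target JSON to `--out`.

## Layout

```
src/domcascade/        library modules (see above)
tests/                 pytest suite, incl. tests/test_acceptance.py
scripts/acceptance.py  end-to-end acceptance runner
docs/methods.md        models, assumptions, numerical choices
```
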