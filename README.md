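# asgard-ogt

Inference of optimal growth temperature (OGT) from the temperature
dependence of GDP binding by translation elongation factor EF-1A/EF-Tu.

The optimal temperature at which EF-1A binds GDP closely tracks the growth
optimum of the organism carrying it. Measuring that binding optimum on a
purified protein — including a *resurrected ancestral* protein inferred by
ancestral sequence reconstruction — therefore gives a thermometer for
organisms and ancestors that cannot be cultured, such as Asgard archaea and
the archaeal ancestor of eukaryotes. This package implements the complete
analysis chain for such a study:

1. **Thermal stability** (`thermostability`): locate the unfolding
   transition in a ThermoFluor melt (argmax of replicate-mean fluorescence)
   and derive the stable temperature range, one grid step below the
   transition.
2. **Peak fitting** (`peak_model`): fit binding fluorescence inside the
   stable range with a skewed bell curve
   F′(t) = F₀ + (F* − F₀)·exp(−((t − t\*)/s(t))²), where the width
   s(t) = s_L + (s_R − s_L)/(1 + e^−(t−t\*)/w) interpolates logistically
   between a left and a right width around the peak temperature t\*
   (w = 5 °C, fixed). Five parameters (F₀, F*, t\*, s_L, s_R), least squares
   on the individual replicates, multi-started Nelder–Mead.
3. **Bootstrap CI** (`bootstrap`): resample the replicates at each
   temperature with replacement, refit, and take the 5th/95th percentiles
   of 1000 bootstrap peak temperatures as the 90 % confidence interval.
4. **OGT and lifestyle** (`ogt`): use the binding optimum as the OGT proxy,
   classify mesophile (< 45 °C) / moderate thermophile (45–80 °C) /
   hyperthermophile (≥ 80 °C), and quantify the calibration against
   organisms of known OGT by Pearson correlation.
5. **Ancestral consensus** (`consensus`): combine ancestral sequences from
   several reconstruction engines into a majority-vote consensus with
   posterior-probability tie-breaking.
6. **Trait mapping** (`trees`): attach OGT estimates to a phylogeny and
   compute the evolutionary trajectory (per-node OGT change relative to the
   nearest annotated ancestor).
7. **Synthetic data** (`simulate`): generate every input with known ground
   truth — binding assays from the peak model, melt curves, ASR sets,
   trait trees — so the whole chain is testable without laboratory data.

See `docs/methods.md` for model details, assumptions, and limitations.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study: a
15-node phylogeny whose root protein has a thermophilic optimum of 65.5 °C,
with per-node binding assays (3 replicates × 11 temperatures, 2 % noise)
and melt curves.

```bash
python analysis/01_simulate_assays.py --seed 1
python analysis/02_stability_ranges.py
python analysis/03_fit_peaks_bootstrap.py --n-boot 1000 --seed 1
python analysis/04_consensus_ancestor.py --seed 1
python analysis/05_ogt_trajectory.py
```

Step 03 prints, per protein, the fitted optimum, its 90 % bootstrap CI and
lifestyle next to the generating truth, e.g.

```
protein_id  t_star  ci_lower  ci_upper  n_boot  n_failed            lifestyle  true_ogt
        N2   50.14     46.61     53.21    1000         3 moderate_thermophile     49.72
      root   65.36     65.11     65.56    1000         0 moderate_thermophile     65.50

mean |fitted - true| = 1.13 degC (max 3.15)
```

The root estimate recovers the generating 65.5 °C within 0.15 °C; the mean
absolute error of 1.13 °C is dominated by proteins whose stable range
truncates the curve close to the optimum (the restriction that makes the
fit honest also costs precision there). Step 05 maps the estimates onto the
tree and reports

```
root OGT estimate 65.4 degC (moderate_thermophile)
64% of branches decrease in OGT (trend toward cooler lifestyles)
calibration: Pearson r = 0.8894 over 4 organisms
```

i.e. the simulated clade descends from a moderate thermophile and cools over
time, and the four-organism calibration table (known OGT vs measured binding
optimum) correlates at r ≈ 0.889.

The same stages are available as a CLI (`asgard-ogt simulate|stability|
fitpeak|bootstrap|ogt|consensus|annotate|run`); `asgard-ogt run --config
run.yaml` executes the whole pipeline with per-protein error isolation and
writes a manifest recording the configuration hash and every seed used.

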