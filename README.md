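# chromofoci

Quantitative tools for asking whether a nuclear protein accumulates at
chromocenters by liquid–liquid phase separation or simply by binding what is
underneath — built around the mouse MeCP2 / pericentromeric-heterochromatin
system, where methyl-CpG–binding protein concentrates in bright DNA-dense
foci over heavily methylated major-satellite arrays.

The package is aimed at cell biologists analysing live-cell fluorescence
data.  It bundles four analysis stages plus a synthetic-data generator that
provides ground truth for all of them, so every stage is testable without
any microscope:

1. **Chromocenter quantification** (`foci`): nucleus segmentation from the
   DNA channel, per-nucleus thresholding of DNA-dense foci, and per-channel
   measurements — areas (µm²), mean intensities in foci and nucleoplasm,
   and the enrichment ratio

   $$r_c = \frac{\langle I_c \rangle_\text{foci}}{\langle I_c \rangle_\text{nucleoplasm}},$$

   with a spotty / mixed / diffuse call per nucleus.
2. **FRAP analysis** (`frap`): double normalization of
   fluorescence-recovery time series,

   $$v(t) = \frac{F(t) - B(t)}{C(t) - B(t)} \cdot
            \frac{\bar C_\text{pre} - \bar B_\text{pre}}
                 {\bar F_\text{pre} - \bar B_\text{pre}},$$

   two-phase association fitting
   $Y(t) = y_0 + a\,(1 - e^{-k_f t}) + b\,(1 - e^{-k_s t})$, and extraction
   of the mobile fraction (fitted curve at the last time point), the
   immobile fraction ($100\% -$ mobile) and $T_{50}$ (time to recover 50% of
   the pre-bleach level).
3. **Buffering diagnostic** (`buffering`): the phase-separation test.
   Concentration buffering (foci grow, internal concentration pinned at
   $c_\text{sat}$) versus size buffering (foci fixed, concentrations scale
   with expression) are distinguished by the $R^2$ of focus concentration,
   focus area and focus count regressed on log total expression.
4. **Satellite-DNA sequence analysis** (`satseq`): GC content,
   methylation-sensitive restriction digestion (HpyCH4IV/ApoI and the
   HpaII/MspI isoschizomer pair), probe matching and tandem-repeat
   structure.  The satellite probe sequences used for Southern blots and
   FISH ship as packaged FASTA fixtures.
5. **Group statistics** (`stats`): Welch t test, Welch one-way ANOVA with
   Games-Howell post-hoc comparisons, and Tukey 1.5 × IQR outlier flagging.

## Worked example

```python
import chromofoci as cf

# simulate a FRAP acquisition in the slow regime and analyse it
import dataclasses
params = dataclasses.replace(cf.SLOW_REGIME, noise_sd=0.02, seed=4,
                             acquisition_bleach_rate=0.001,
                             background_level=10.0, amplitude=100.0)
nt = cf.normalize_frap(cf.simulate_frap_trace(params))
fit = cf.fit_two_phase(nt)
summary = cf.summarize_fit(fit, float(nt.time_rel_s[-1]))
print(f"mobile {summary.mobile_pct:.1f}%  immobile {summary.immobile_pct:.1f}%"
      f"  T50 {summary.t50_s:.1f} s")
```

prints

```
mobile 75.2%  immobile 24.8%  T50 75.5 s
```

i.e. three quarters of the bleached pool exchanged within the observation
window, a quarter stayed stably bound, and half of the pre-bleach
fluorescence returned after 75.5 s — the signature of a protein with a
long-lived bound fraction.  `examples/` contains one narrative script per
capability (foci quantification, FRAP, buffering test, satellite digestion,
group statistics); each builds a small input, runs the method and explains
the numbers it prints.

A thin command-line interface mirrors the library for batch runs:

```sh
chromofoci simulate frap --regime slow --n-traces 10 --out traces/
chromofoci frap-batch --manifest traces/traces_manifest.csv --out frap_out/
chromofoci quantify --images 'scenes/*.tif' --out quant_out/
```

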