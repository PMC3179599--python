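# ktperf

First-pass contrast-enhanced myocardial perfusion MRI in mice, end to end
and fully synthetic: a dynamic short-axis mouse-heart phantom with known
ground truth, a k-t undersampled single-coil acquisition simulator, a
k-t PCA constrained reconstruction, and semiquantitative plus
Fermi-deconvolution quantification of myocardial blood flow (MBF).

## The problem

Measuring myocardial blood flow in mice with bolus-based first-pass MRI
requires one image per cardiac cycle at ~500 beats/min and ~0.2 mm in-plane
resolution — far beyond conventional Cartesian acquisition. The acquisition
strategy modelled here undersamples k-space 10-fold on a sheared lattice
(frame *t* acquires the phase-encode lines *k* with *k* ≡ *t* mod *R*) plus
three central training profiles acquired every heartbeat, and recovers the
dynamic series by restricting each pixel's time-course to a few temporal
principal components learned from the training data (k-t PCA):

    s(x, y, t) = μ(x, y) + Σ_p w(x, y, p) · b_p(t),

with the weight maps estimated by variance-regularized least squares.
Perfusion is then quantified from signal-intensity/time curves of the LV
blood pool and three myocardial sectors (septal, anterolateral,
inferolateral, counted counterclockwise from the anterior septal RV
insertion):

* enhancement ratio `(SI_max − SI_baseline) / SI_baseline`,
* maximal upslope by five-point least-squares fitting, normalized by the
  LV upslope,
* absolute MBF by Fermi-constrained deconvolution: fit
  `tissue(t) = Δt · (lv ⊛ h)(t)` with `h(t) = F / (1 + exp(k (t − τ₀)))`
  and report `MBF = h(0) · 60 / ρ`, ρ = 1.05 g/mL.

Because no public mouse perfusion data exist, the package ships a seeded
digital phantom (saturation-recovery signal model, gamma-variate arterial
input, Fermi tissue response, Rician noise via complex k-space noise) whose
ground-truth flow, contours and input function make every stage testable.

## Worked example

```sh
python examples/04_quantify_perfusion.py
```

runs the full pipeline on the infarct phantom (anterolateral MBF 1.2,
remote 7.3 mL/g/min; 10-fold undersampling, 3 training profiles, acquisition
noise) and prints:

```
          roi  baseline_si  peak_si  enhancement_ratio  normalized_upslope  mbf_ml_g_min
lv_blood_pool       50.285  375.172              6.461                 NaN           NaN
       septal       62.236  123.675              0.987               0.089         7.845
anterolateral       61.318   70.732              0.154               0.019         1.532
inferolateral       61.843  124.074              1.006               0.101         8.028

reconstruction NRMSE vs fully sampled reference: 0.0302
```

Reading the numbers: the LV enhancement ratio (~6.5) sits in the healthy
in-vivo range; the infarcted anterolateral sector barely enhances (ratio
0.15, normalized upslope ~2% of the LV) and its estimated flow is sharply
reduced relative to the remote sectors, mirroring the true 1.2 vs 7.3
contrast. Estimates run slightly high because the deconvolution — like
standard practice — treats signal as proportional to concentration while
the LV signal is T1-saturated at peak (see `docs/methods.md`).

The other examples show the phantom (`01`), the undersampled encoding and
reconstruction fidelity (`02`), and sector/curve extraction with CSV export
(`03`). The same stages are scriptable from the shell via the thin CLI:

```sh
ktperf run --infarct --seed 1 --out myrun    # or: simulate / encode / recon /
ktperf report myrun                          #     curves / quantify / report
```

## Layout

| path | contents |
| --- | --- |
| `src/ktperf/phantom.py` | phantom physics: AIF, Fermi response, saturation-recovery signal, geometry |
| `src/ktperf/ktspace.py` | sheared-lattice sampling patterns, Fourier encoding, training extraction |
| `src/ktperf/ktpca.py` | temporal-basis learning and the k-t PCA unfolding solver |
| `src/ktperf/sectors.py` | contours, three-sector partition, SI curve extraction |
| `src/ktperf/quant.py` | baseline/crop, enhancement ratio, upslopes, Fermi deconvolution |
| `src/ktperf/pipeline.py`, `cli.py`, `io.py` | orchestration, CLI, NIfTI/HDF5/CSV/JSON/YAML I/O |
| `docs/methods.md` | model assumptions, parameter choices, limitations |
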