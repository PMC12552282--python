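# ctiq

Objective image-quality analysis for CT regions of interest, radiation-dose
accounting, and chance-corrected interrater agreement — with a synthetic
phantom generator so every estimator is validated by parameter recovery.

## Who this is for

Radiology and medical-physics groups comparing reconstruction algorithms or
dose protocols need three recurring pieces of analysis:

1. **Reference-free image quality.** Given an ROI drawn on a soft-tissue
   region (one or two tissue types), quantify noise, signal, SNR, CNR,
   grey-value entropy and edge sharpness — without a noise-free reference
   image.
2. **Dose accounting.** Turn scanner-reported CTDIvol values into DLP and
   effective dose under a weight-adapted kV protocol, and report protocol
   comparisons.
3. **Reader agreement.** Summarize multi-reader ordinal (Likert) ratings with
   Gwet's AC₂, which stays well-behaved where kappa statistics collapse under
   skewed marginals.

Patient images are rarely shareable, so the package ships a phantom factory
that emulates the statistical structure these estimators assume (two tissue
plateaus, controlled noise magnitude/correlation, controlled edge blur) with
exact ground truth.

## The method

For an ROI image $I$:

- a lowpass (Gaussian, mask-aware) copy $G * I$ is subtracted to isolate the
  noise-dominated high frequencies: $R = I - G * I$;
- a circular local-STD filter over $R$ yields a noise map;
- the minimum-noise estimate is the mean of the **five lowest** mean noise
  values over circles of **12 px diameter** — an order statistic that ignores
  anatomy leaking into the highpass band,
  $\mathrm{STD}_{\min}$;
- each tissue's signal intensity $\mathrm{SI}$ is the mode of its bin-width-20
  histogram; a bimodal ROI is split into low/high tissues at the histogram
  valley;
- then

$$\mathrm{SNR} = \frac{\mathrm{SI}}{\mathrm{STD}_{\min}}, \qquad
  \mathrm{CNR} = \frac{\Delta \mathrm{SI}}{\overline{\mathrm{STD}}_{\min}},$$

  plus Shannon entropy of the grey values and the 10–90 % edge-transition
  width from an error-function fit across the tissue boundary
  (width $= 2.563\,\sigma_{\mathrm{edge}}$).

Dose chain: $\mathrm{DLP} = \mathrm{CTDI_{vol}} \times L$ (default
$L = 25$ cm), $E = k \cdot \mathrm{DLP}$ with $k = 0.0058$ mSv/(mGy·cm) for
head/neck; tube voltage 80/100/120 kV for weight ≤ 70 / (70, 80] / > 80 kg.

Agreement: Gwet's AC₂ with linear ordinal weights,
$\mathrm{AC}_2 = (P_a - P_e)/(1 - P_e)$, normal-approximation CI from Gwet's
linearized variance, and Fleiss benchmarks (poor < 0.40, good 0.40–0.75,
excellent > 0.75).

Details, defaults and numerical choices are in `docs/methods.md`.

## Worked example

```python
from ctiq import PhantomSpec, generate_phantom, assess_roi

truth = generate_phantom(PhantomSpec(si_low=50, si_high=150, noise_sigma=10,
                                     edge_blur_sigma=1.0, seed=1))
q = assess_roi(truth.image)
print(f"low tissue : SI={q.low.si:6.2f}  STDmin={q.low.std_min:5.2f}  "
      f"SNR={q.low.snr:5.2f}  H={q.low.entropy_bits:4.2f} bits")
print(f"high tissue: SI={q.high.si:6.2f}  STDmin={q.high.std_min:5.2f}  "
      f"SNR={q.high.snr:5.2f}  H={q.high.entropy_bits:4.2f} bits")
print(f"dSI={q.delta_si:6.2f}  CNR={q.cnr:5.2f}  edge width={q.sharpness_width:4.2f} px")
```

prints

```
low tissue : SI= 50.57  STDmin= 7.89  SNR= 6.41  H=1.30 bits
high tissue: SI=148.76  STDmin= 7.82  SNR=19.01  H=1.27 bits
dSI= 98.20  CNR=12.50  edge width=2.61 px
```

The phantom's true plateaus are 50/150 HU with noise σ = 10: the modal SI
estimates land within ~1 HU, STDmin reads σ times the highpass attenuation
times the order-statistic factor (≈ 0.79 σ at these defaults, see
`docs/methods.md`), and the edge width 2.61 px ≈ 2.563 × 1.0 px of applied
boundary blur. SNR/CNR then follow from the two displayed ratios.

The same pipeline runs from the shell:

```bash
ctiq simulate --spec spec.json --out phantoms/
ctiq iq --image phantoms/phantom_000.npy --out results.csv
ctiq dose --in exams.csv --out summary.csv
ctiq agree --in ratings.csv --weights linear --out agreement.csv
```

Every output file gets a `.provenance.json` sidecar (version, parameters,
seed, input digests); payloads are byte-identical across reruns.

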