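# scarseg

Interactive, prompt-conditioned segmentation and quantification of
myocardial scar on short-axis late-gadolinium-enhancement (LGE) cardiac
MR — as a backbone-agnostic Python library with a built-in synthetic
phantom for validation.

After myocardial infarction, the mass of irreversibly injured myocardium
(scar) measured on LGE-CMR is a powerful prognostic marker, but manual
delineation is slow and poorly reproducible, and the semi-automated
full-width-at-half-maximum (FWHM) rule is sensitive to operator input.
`scarseg` implements the computational core of an interactive alternative:
a segmentation model conditioned on cheap human prompts (a bounding box
and/or a few clicks inside the lesion), trained with an uncertainty-aware
composite loss, and wrapped in the quantification and agreement
statistics a clinical validation needs.

The core training objective combines region overlap, per-voxel
classification, and divergence from Gaussian-smoothed soft labels
s = G_σ ∗ g (σ = 2):

    L_total = λ_Dice·L_Dice + λ_BCE·L_BCE + λ_KL·L_KL
    L_Dice  = 1 − (2Σᵢ pᵢgᵢ + ε)/(Σᵢ pᵢ + Σᵢ gᵢ + ε)
    L_BCE   = −(1/N) Σᵢ [gᵢ log pᵢ + (1−gᵢ) log(1−pᵢ)]
    L_KL    = Σᵢ sᵢ log( sᵢ/(pᵢ + ε) )

with λ_Dice = 0.60, λ_BCE = 0.62, λ_KL = 0.64.  Scar mass is quantified
from voxel geometry as |mask|·Δx·Δy·Δz·1.05 g/cm³, and repeatability is
analysed with Bland–Altman limits of agreement, Pearson r, Lin's CCC,
two-way random-effects ICC, within-subject CV, paired t-tests, and
Bonett's ICC sample-size formula.

Because patient imaging cannot be redistributed, the package ships a
seeded phantom generator — annular myocardium with a hyperenhanced
subendocardial scar wedge, bias field and noise corruption, exact masks,
simulated raters — on which every component is validated against analytic
or brute-force oracles.

## Worked example

```bash
python examples/03_train_and_segment.py
```

trains the built-in tiny prompt-conditioned backbone on a small phantom
cohort and prints:

```
epoch  lr       loss     val_dsc
    1  1.0e-02  +0.9154  0.183
    4  1.0e-02  +0.4344  0.912
    7  1.0e-02  +0.2008  0.877
   10  1.0e-02  +0.1739  0.859
   12  5.0e-03  +0.1417  0.900
held-out mean DSC (box+points prompts): 0.868
```

The `val_dsc` column is the mean Dice overlap between thresholded
predictions and ground-truth scar on validation slices — rising from near
0 to ~0.9 within a few epochs on this small run; the final line is the
fair estimate on unseen phantom subjects (the full benchmark in
`scarseg.benchmark` uses 200 training slices and 30 epochs; typical
combined-prompt scores are ≈0.85–0.90).  The other examples cover cohort generation and burden-stratified
splitting (`01`), the loss anatomy (`02`), FWHM and mass quantification
(`04`), an in-silico two-rater repeatability study (`05`), and
image-quality clustering (`06`).

A thin CLI mirrors the library for shell pipelines:

```bash
scarseg phantom --n 10 --seed 7 --out cohort/
scarseg train --manifest cohort/manifest.csv --epochs 30 --out run/
scarseg segment --image cohort/subj-0000_s00.png --prompt prompt.json \
                --checkpoint run/checkpoint.npz --out mask.png
scarseg quantify --pred mask.png --gt cohort/subj-0000_s00_scar.png \
                 --geometry '{"row_spacing_mm":1.5,"col_spacing_mm":1.5,"thickness_mm":8}'
scarseg agreement --csv pairs.csv --compare rater1:rater2
```

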