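# lungtarget

Quantitative mass spectrometry imaging (MSI) analysis of where an inhaled
drug is retained in the lung, and how much local exposure the inhaled route
buys compared with systemic dosing.

Inhaled therapy is assumed to concentrate drug at its airway target site, but
whole-organ pharmacokinetics cannot say *where* in the lung a drug sits.
MALDI/DESI imaging of tissue sections can: every pixel carries a mass
spectrum, so drug and endogenous histology markers are mapped together at
10–50 µm resolution. `lungtarget` implements the analysis chain for the
dual-isotope experiment design — the drug given by inhalation and its
deuterated isotopologue given intravenously *to the same animal* — in which
both routes are imaged in one section and separated by mass shift, removing
all section-to-section confounding. It is written for imaging scientists and
inhalation DMPK groups working with imzML data.

## What it computes

For a histological compartment *c* (alveolar bed, bronchiolar
sub-epithelium, bronchiolar epithelium) and route *r* ∈ {inhaled, iv}:

* **TIC normalization** — each pixel spectrum is rescaled so its total ion
  count is constant, removing per-pixel acquisition drift.
* **Ion images** — I_r(x, y): summed intensity in an m/z window around the
  drug (e.g. salmeterol [M+H]⁺) or a marker ion (Heme b — vessels, PC(32:0)
  — alveolar, PC(36:4) — bronchiolar).
* **Heterogeneity** — pixel-to-pixel relative standard deviation,
  RSD% = 100·σ/μ over the tissue mask; patchy aerosol deposition gives the
  inhaled channel a several-fold higher RSD than the IV channel.
* **Colocalization** — Pearson r (in %) between drug and marker images.
* **Segmentation** — bisecting k-means on weakly denoised, binned pixel
  spectra under correlation distance d(u, v) = 1 − ρ(u, v); segments are
  named as compartments by marker enrichment, yielding ROIs without any
  manual annotation.
* **Lung targeting factor** — with plasma concentration P_r,

      E_r(c)  = mean_{pixels in c} I_r / P_r          (normalized exposure)
      TF(c)   = E_inhaled(c) / E_iv(c)                (targeting factor)

  the fold gain in local exposure attributable to inhaled delivery at
  matched systemic exposure, computed per replicate section and averaged.

A first-class synthetic generator (`lungtarget.synthetic_lung`) builds
virtual rat-lung sections — alveolar field, airways (lumen + epithelium +
sub-epithelium rings), vessels, off-tissue background — with known
compartment labels, known targeting factors and a realistic noise model, so
the whole pipeline is testable end-to-end with no external data.

## Worked example

```bash
python examples/04_targeting_factors.py
```

simulates three replicate dual-dosed sections (200×200 px at 10 µm),
segments each one, names ROIs from marker enrichment and recovers the
targeting factors (scenario ground truth 5 / 31 / 45):

```
n = 3 replicate sections
  alveolar         TF =   4.8 ±  0.0   (truth 5)
  sub_epithelium   TF =  28.1 ±  1.6   (truth 31)
  epithelium       TF =  48.7 ±  5.9   (truth 45)
  whole section    TF =   5.9
```

The factors are read as: at equal plasma exposure, inhalation delivered ~49×
more drug to the bronchiolar epithelium than IV dosing did, ~28× more to the
sub-epithelium, and ~5× more to the alveolar bed — the quantitative form of
"inhaled drug is selectively retained in bronchial tissue". The other
examples cover simulation + normalization (`01`), segmentation (`02`, ARI
0.977 vs ground truth), heterogeneity and the drug–marker correlation table
(`03`: inhaled RSD 87% vs IV 33%), and the full configured pipeline plus a
biphasic kinetic profile (`05`).

A thin CLI wraps the same calls:

```bash
lungtarget simulate --seed 42 --out section/
lungtarget run --config run.yaml
lungtarget rsd --input section/section.imzML --mz 416.2795
```

## Layout

```
src/lungtarget/
  analytes.py        analyte m/z windows; default dual-isotope table
  msi_core.py        MSIDataset, imzML I/O, TIC normalization, ion images, masks
  segmentation.py    feature binning, weak denoising, bisecting k-means, ROI naming
  spatial_stats.py   RSD, Pearson correlation, ROI means, Student t-test
  targeting.py       plasma normalization, targeting factors, kinetic profiles
  synthetic_lung.py  virtual lung scenarios, geometry, spectrum simulation
  pipeline.py        configured end-to-end runs with manifests
  cli.py             thin click wrapper
docs/methods.md      model, noise model, parameter choices, limitations
examples/            one narrative script per capability
```
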