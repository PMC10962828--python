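# Methods

## Vision model

The contrast machinery follows the quantum-catch → adaptation → distance
chain standard in insect colour-vision modelling, with a brightness term
kept alongside the chromatic coordinates (segment-classification style)
rather than discarded (hexagon style):

1. **Receptor sensitivities.** Each of the three bee classes (peaks 347,
   424, 539 nm) is reconstructed with the Govardovskii A1 α-band template;
   only the peak positions are treated as data. The β-band is a config
   flag, off by default: for the UV class it lies below the 300 nm window
   edge, and for blue/green its contribution is dwarfed by the α-band.
   Curves are normalised to the template's *continuous* peak (dense
   evaluation around λmax) so a curve is independent of the evaluation
   grid; on a 1 nm grid the discrete maximum can fall ~1e-4 short of 1.

2. **Illuminant.** Default is CIE D65 restricted to 300–700 nm and
   converted from energy to relative photon flux (×λ), since flowers in
   the use case grow outdoors under natural light; a flat equal-energy
   illuminant is selectable (`illuminant: equal_energy`). The choice is
   recorded in every report's config snapshot. Because the adaptation step
   divides by background catches, all ΔS values are exactly invariant to
   illuminant rescaling, and only mildly sensitive to its shape.

3. **Quantum catch.** Trapezoid integration of I·S·R on the common 1 nm
   grid over 300–700 nm, matching the 1 nm measurement pitch of benchtop
   spectrophotometers. Against a 0.1 nm Riemann evaluation of the same
   smooth integrands the quadrature error is ~1e-5 relative.

4. **Adaptation and transduction.** Von Kries normalisation by the
   adaptation background's catches followed by the hyperbolic
   (Michaelis–Menten) response E = q/(q+1), giving E ∈ [0, 1) with
   E = 0.5 at the background. The default background is the *same
   cultivar's* measured upper-leaf spectrum (`background: own_leaf`) — a
   foraging bee is adapted to the foliage the flower is seen against; a
   fixed reference green can be supplied instead.

5. **Contrast.** ΔS = s·√(Σᵢ ΔEᵢ² + ΔB²) with unit chromatic and
   brightness weights. This is a true metric (verified by property tests);
   pairs are reported in the canonical order A/S, A/P, S/P, L/P, A+S/P.
   The joint anther+sepal disk (A+S) is always a directly measured
   spectrum, never synthesised by averaging A and S.

### The scale factor

The underlying excitation-space distances live in [0, 2]; published
bee-contrast work reports ΔS values in the 0.25–33 range against a
behavioural detection threshold of 2.3. The bridge is a single scale
factor, the model's only calibrated constant. It was fixed **once, at
design time**, by anchoring the noiseless synthetic wild-strawberry
leaf/petal contrast (excitation distance 0.4767) at the ΔS ≈ 8.9 magnitude
reported for that flower, giving s = 18.6. It is an ordinary config field
(`scale:`) so users with their own behavioural anchor can recalibrate; all
detectability calls scale with it, so the threshold and scale must be
calibrated against the same reference frame. The threshold is inclusive:
ΔS exactly at 2.3 counts as detectable.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| receptor peaks | 347 / 424 / 539 | nm | generic trichromatic bee |
| integration span | 300–700 | nm | bee visual range & instrument window |
| illuminant | D65 photon flux | relative | outdoor daylight |
| background | own upper leaf | — | foliage adaptation convention |
| scale s | 18.6 | — | anchored as described above |
| threshold | 2.3 | ΔS | behavioural 75 % detection contrast |
| noise sd | 0.005 | reflectance fraction | benchtop repeat-scan scatter |

## Synthetic generator

Archetypes are parametric idealisations (baseline + logistic edges +
Gaussian bumps, clipped to [0, 1]), *not* digitised curves: white petal
(plateau 0.45–0.90 above ~410 nm, <0.1 in the near-UV), green leaf
(baseline 0.05 + 0.18 bump at 550 nm), yellow anther (plateau above
~505 nm), bee-dark red petal (baseline 0.06, edge 585 nm, plateau 0.66 —
parameters chosen so that, like real red-flowering cultivars, its bee
catches nearly match foliage), and a UV-bullseye pair built with a
compact-support raised-cosine UV feature so the pair is *exactly* equal
outside 300–380 nm. Scenario recipes step petal amplitude down from
bright-white through wild-type to red, which is what makes the
leaf/petal contrast ordering recoverable on every seed.

Noise is independent zero-mean Gaussian per wavelength, clipped to [0, 1].
Real spectrophotometer noise is wavelength-correlated and
amplitude-dependent; tests passing on this generator therefore demonstrate
the pipeline's arithmetic and its ordinal robustness, not instrument-level
realism. Fluorescence, specular glare and angular (BRDF) effects are not
modelled at all.

Scenario datasets are seeded through `numpy.random.SeedSequence` keyed on
(CRC32 of the scenario name, user seed), so identical inputs reproduce
byte-identical spectra across processes.

## Review tabulation

The packaged record table is transcribed verbatim from the source review
table, one row per species × part × reference measurement (95 rows; one
verbatim duplicated row is dropped with a warning before counting).
Categorisation is longest-keyword-first and case-insensitive; imaging line
scanners are classed with cameras (they are self-contained image-recording
devices); an unmatched label raises an explicit error, never a silent
default.

Counts and denominators — the source never states them, so the package's
reading is documented here and in each summary's metadata:

* **references** = distinct reference keys (51 in the shipped table);
* **species entries** = distinct (family, species, common name, part)
  tuples (73), matching how such tables list one species per measured
  crop/part;
* **instrument shares** are over measurement rows (one instrument per
  measurement event);
* **part shares** are over part components after exploding compound labels
  ("bark/leaf" → stem + leaf): one event can measure two parts but uses
  one instrument.

Shares are kept unrounded internally and rounded to one decimal on export;
every share mapping sums to 100 within rounding by construction.

## Numerical choices and degenerate inputs

* Linear interpolation for resampling (spectra are smooth at 1 nm pitch;
  splines can overshoot steep red edges); extrapolation is refused.
* Percent-vs-fraction autodetection threshold 1.5 on the column maximum;
  negative artefacts clip to 0, overshoots clip to 1, with warnings; the
  normalisation is idempotent.
* Band means are trapezoid means with interpolated band edges, exact for
  the piecewise-linear curve the grid implies.
* Spectral-range bins use closed-interval overlap at the adjacent-integer
  edges (380|381, 520|521, 625); the red/IR bin is open at 625.
* A background with zero catch in any class (e.g. an all-black spectrum)
  is rejected — adaptation is undefined there.
* Replicates are averaged pointwise after resampling (the analysis reports
  one ΔS per pair); because catches are linear in R, averaging replicates
  then computing ΔS equals computing on the mean spectrum, which is
  asserted as a regression guard.
* Problem sizes: analyses run on the 401-point 300–700 nm grid; property
  sweeps use 1000 random point triples, 100 random spectra and 20 noise
  seeds, which keeps the full suite under a few minutes on one CPU.

## Known limitations

* The NSC-style transduction/adaptation forms above are this package's
  explicit, documented choice of substrate; printed ΔS values from other
  implementations can differ by calibration, so only magnitude-anchored
  and ordinal comparisons are meaningful across tools.
* The "P" used for leaf/petal contrast is the petal-only spectrum by
  default; manifests decide (a full-flower spectrum can be labelled in).
* No receptor-noise-limited (JND) contrasts, no tetrachromatic viewers,
  no behavioural foraging model, no statistics across replicates.
* The Zenodo fetcher requires a network; all shipped tests and the
  acceptance script run offline on the synthetic generator and the
  packaged record table.
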