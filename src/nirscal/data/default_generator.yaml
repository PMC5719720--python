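# Default synthetic-population configuration.
#
# Trait means/SDs follow published summary statistics for a transgenic rice
# straw population (n = 247): seven wall-polymer features (% dry matter,
# % total hemicellulose monosaccharides, or ratio) and ten saccharification
# yields from alkali pretreatment and enzymatic hydrolysis.  Everything the
# printed statistics do not pin down — the trait-trait correlation matrix,
# the linear coefficients tying sugar yields to polymer features, the
# pure-component NIR band library, and the scatter-artifact scales — is
# SYNTHETIC: values chosen to be realistic for rice straw NIR data and to
# reproduce the published sign structure of polymer-saccharification
# correlations by construction.

wavelength_grid:
  start: 408.0
  stop: 2492.0
  step: 2.0

polymer_traits:
  # order here fixes the correlation-matrix order
  cellulose: {mean: 25.11, sd: 4.45}
  ara:       {mean: 13.22, sd: 1.37}
  xyl:       {mean: 75.08, sd: 2.63}
  xa:        {mean: 5.75,  sd: 0.77}
  asl:       {mean: 3.13,  sd: 0.41}
  ail:       {mean: 8.20,  sd: 1.40}
  lignin_total: {mean: 11.33, sd: 1.55}
  # bounds default to mean +/- 4*sd unless min/max given explicitly

# synthetic trait-trait correlations (symmetric, unit diagonal, PSD):
# X/A strongly anti-correlated with Ara (it is an inverse substitution-degree
# ratio); total lignin nearly collinear with AIL (its dominant part).
polymer_correlation:
  - [ 1.00, -0.15,  0.10,  0.15,  0.10,  0.20,  0.20]
  - [-0.15,  1.00, -0.30, -0.85,  0.05, -0.10, -0.08]
  - [ 0.10, -0.30,  1.00,  0.40,  0.00,  0.05,  0.05]
  - [ 0.15, -0.85,  0.40,  1.00,  0.00,  0.05,  0.05]
  - [ 0.10,  0.05,  0.00,  0.00,  1.00,  0.30,  0.55]
  - [ 0.20, -0.10,  0.05,  0.05,  0.30,  1.00,  0.95]
  - [ 0.20, -0.08,  0.05,  0.05,  0.55,  0.95,  1.00]

# Saccharification yields: linear in standardized polymer features plus
# independent noise.  `weights` are synthetic relative loadings (their signs
# fix the correlation structure: cellulose and lignin depress hexose yields,
# Ara raises them, X/A depresses them; cellulose raises pentose yields);
# `explained` is the fraction of the trait's variance carried by the polymer
# features, the remainder being noise.
sacch_traits:
  pent_pre:
    mean: 9.64
    sd: 1.26
    explained: 0.90
    weights: {cellulose: 0.50, ara: 0.30, xa: -0.30, asl: -0.20, ail: -0.30}
  hex_pre:
    mean: 19.34
    sd: 7.95
    explained: 0.96
    weights: {cellulose: -0.50, ara: 0.40, xa: -0.20, asl: -0.30, ail: -0.50}
  total_pre:
    mean: 29.26
    sd: 6.81
    explained: 0.95
    weights: {cellulose: -0.40, ara: 0.40, xa: -0.20, asl: -0.30, ail: -0.45}
  pent_enz:
    mean: 23.90
    sd: 4.01
    explained: 0.90
    weights: {cellulose: 0.45, ara: 0.35, xa: -0.30, asl: -0.20, ail: -0.35}
  hex_enz:
    mean: 46.62
    sd: 3.40
    explained: 0.94
    weights: {cellulose: -0.45, ara: 0.40, xa: -0.20, asl: -0.35, ail: -0.50}
  total_enz:
    mean: 70.74
    sd: 6.81
    explained: 0.95
    weights: {cellulose: -0.40, ara: 0.40, xa: -0.20, asl: -0.30, ail: -0.45}
  pent_total:
    mean: 15.21
    sd: 1.59
    explained: 0.90
    weights: {cellulose: 0.50, ara: 0.30, xa: -0.25, asl: -0.20, ail: -0.30}
  hex_total:
    mean: 30.38
    sd: 4.88
    explained: 0.95
    weights: {cellulose: -0.50, ara: 0.40, xa: -0.20, asl: -0.30, ail: -0.50}
  sugar_total:
    mean: 45.31
    sd: 3.97
    explained: 0.94
    weights: {cellulose: -0.45, ara: 0.40, xa: -0.20, asl: -0.30, ail: -0.45}
  ferm_hex:
    mean: 71.17
    sd: 10.11
    min: 52.8
    max: 95.9
    explained: 0.96
    weights: {cellulose: -0.50, ara: 0.40, xa: -0.20, asl: -0.30, ail: -0.50}

# Pure-component absorptivity curves: Gaussian bands (center nm, sigma nm,
# height in absorbance per unit concentration).  Band positions loosely
# follow common NIR overtone/combination assignments for polysaccharides and
# lignin, with deliberate overlap between components (realistic
# collinearity); heights are synthetic.
component_library:
  cellulose:
    - {center: 1200.0, sigma: 60.0, height: 0.004}
    - {center: 1490.0, sigma: 50.0, height: 0.010}
    - {center: 1780.0, sigma: 70.0, height: 0.006}
    - {center: 2100.0, sigma: 60.0, height: 0.012}
    - {center: 2280.0, sigma: 45.0, height: 0.008}
    - {center: 2340.0, sigma: 50.0, height: 0.009}
  ara:
    - {center: 1440.0, sigma: 55.0, height: 0.008}
    - {center: 1930.0, sigma: 75.0, height: 0.010}
    - {center: 2090.0, sigma: 55.0, height: 0.012}
    - {center: 2270.0, sigma: 50.0, height: 0.007}
  xyl:
    - {center: 1470.0, sigma: 60.0, height: 0.0030}
    - {center: 1580.0, sigma: 70.0, height: 0.0020}
    - {center: 2080.0, sigma: 65.0, height: 0.0035}
    - {center: 2330.0, sigma: 60.0, height: 0.0025}
  asl:
    - {center: 1410.0, sigma: 45.0, height: 0.015}
    - {center: 1668.0, sigma: 40.0, height: 0.020}
    - {center: 2200.0, sigma: 55.0, height: 0.018}
    - {center: 2470.0, sigma: 60.0, height: 0.010}
  ail:
    - {center: 1143.0, sigma: 50.0, height: 0.006}
    - {center: 1680.0, sigma: 55.0, height: 0.008}
    - {center: 2200.0, sigma: 60.0, height: 0.007}
    - {center: 2380.0, sigma: 65.0, height: 0.005}

# Per-sample scatter artifacts on the Beer-Lambert mixture: multiplicative
# path-length factor (mean 1), additive baseline offset, linear wavelength
# slope, and i.i.d. measurement noise.  Scales chosen to emulate a
# well-maintained bench reflectance instrument.
scatter:
  multiplicative_sd: 0.05     # unitless
  offset_sd: 0.02             # absorbance
  slope_sd: 1.0e-05           # absorbance per nm
  noise_sd: 5.0e-04           # absorbance
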