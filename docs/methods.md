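# Methods

This note records the models, estimators and numerical conventions the
package implements, the choices made where the method leaves room, and
what the synthetic-data generator does and does not establish.

## Exact-mass chemistry

All mass arithmetic is monoisotopic, using a shipped IUPAC/CODATA table
(`chemmass.ISOTOPES`). Constants: proton 1.00727646 Da, electron
0.00054858 Da. Ion m/z values are reported to five decimals, the
precision at which an Orbitrap at R = 70,000 is usually quoted in this
mass range.

**Adducts.** Only singly charged species are supported: [M+H]⁺ (+proton),
[M−H]⁻ (−proton) and [M+Na]⁺ (+Na − electron = +22.98922070 Da). The
registry (`chemmass.ADDUCTS`) is a plain dict and extensible.

**Fragment cations** are even-electron species: the atomic monoisotopic
sum minus one electron mass. For a cation whose atoms are M+H this
coincides with [M+H]⁺ of M, because the proton constant already nets
out the electron.

**ppm errors.** `ppm_error(observed, theoretical)` is signed,
(obs − theo)/theo × 10⁶. By default the theoretical value is first
rounded to five decimals, matching how errors are quoted against
printed reference m/z values (an error quoted against the full-precision
theoretical mass can differ by ~0.01 ppm); `rounded=False` uses the
value as given. The match criterion throughout the package is
|error| ≤ 5 ppm.

**Isotope patterns.** Per-element multinomial distributions are built by
repeated convolution and convolved across elements, pruning below
10⁻¹⁰ relative probability. Isotopologues closer than 0.01 Da are
merged with abundance-weighted centroids — an Orbitrap at R = 70,000
cannot resolve finer spacings below m/z ~700 (e.g. ³⁴S vs ¹³C₂). The
pattern is normalized to base peak = 100 % and pruned below a relative
floor (default 1 %, 5 % for verification). An independent brute-force
implementation (`isotope_pattern_bruteforce`, explicit isotopologue
enumeration) exists purely as a test oracle and agrees with the fast
path within 0.5 % absolute for ≤ 30-atom formulas.

**Formula enumeration** is an exhaustive depth-first search over element
count bounds (default C≤50, H≤100, N≤6, O≤20, P≤4, S≤4; Cl and Na are
opt-in), solving the hydrogen count analytically from the residual
mass. Chemical-plausibility filters: ring-plus-double-bond equivalents
≥ 0 and, when carbon is present, H/C ∈ [0.1, 4]. Candidates are sorted
by absolute ppm error. The defaults follow the unknown-analysis
convention of allowing only C, H, N, O, P, S.

## mzML I/O

A minimal mzML 1.1 subset written and read with the standard library:
centroid spectra only (profile data raise), MS1/MS2, scan start times
(seconds converted to minutes on read), precursor selected-ion m/z,
isolation half-width and collision energy, 64-bit little-endian
uncompressed base64 arrays. This subset round-trips every
(rt, m/z, intensity) at float64 precision and twice-written files are
byte-identical. Runs carry their acquisition role (sample, blank,
solvent-standard, spiked-sample) and dilution factor as attributes so
downstream back-calculation needs no side channel. A one-row-per-
centroid tabular form (`run_to_table`) serves as a plain-text fixture
format.

## Synthetic runs: the stated world

`synthetic_data.generate_run` emulates a 30-min gradient acquisition
(defaults): MS1 every 2 s over m/z 50–750, top-5 ddMS² above a 10⁴
intensity floor with 10-s dynamic exclusion and a 5.0-wide isolation
window. Each spiked compound elutes as a pure Gaussian (no tailing);
the default peak sigma of 0.05 min gives ≥ 15 points across a 0.5-min
peak at the 2-s cycle. Every centroid's m/z is multiplied by
(1 + ε), ε ~ N(0, jitter·10⁻⁶), default jitter 1 ppm — representative
of an externally calibrated Orbitrap. Isotopologues are planted from
the chemmass pattern (floor 0.5 %). Noise centroids are Poisson per
scan (default 20) at uniform m/z with lognormal intensities
(scale 300 counts). Homolog spikes expand into co-eluting ladders with
a discretized-Gaussian abundance profile over the repeat count,
emulating the bell-shaped single-spectrum ladders of technical
ethoxylate mixtures. A fixed seed makes runs bit-reproducible.

What the generator does **not** model: electrospray response factors
(intensities are response-scaled, not physical), peak tailing,
saturation, retention-time drift, or chimeric MS2. A green test on
synthetic data therefore establishes the correctness of the
*algorithms* under stated noise, not instrument-level robustness.

Dynamic exclusion (10 s) is a free choice documented here: it mimics
how top-N acquisition spreads MS2 coverage over co-eluting precursors.

## Feature extraction

EICs sum centroid intensities within ±tol ppm (default 5) per MS1
scan. Peaks are local maxima above the height threshold with
boundaries at the surrounding minima; area is trapezoidal over rt in
minutes. S/N = apex height / (1.4826 × MAD of the off-peak trace);
when the off-peak segment is degenerate (all-identical, e.g. an
all-zero baseline) the whole-trace MAD is used. The shape score is the
coefficient of determination of a least-squares Gaussian fit over the
peak span, clamped to [0, 1]; spans under 4 points score 0. These
estimators are declared conventions — vendor software does not
document its own.

Untargeted detection groups all MS1 centroids by m/z, splitting where
consecutive sorted values differ by > 5 ppm, keeps traces covering
≥ 5 consecutive scans, and de-duplicates features within 5 ppm and
0.1 min keeping the larger area. Filters follow the unknown-analysis
convention: minimum peak intensity 1,000 counts, S/N ≥ 3, minimum area
10⁶ counts, no matching peak in any blank. The RT match tolerance is
0.1 min everywhere.

## Screening rules

The evidence-to-level mapping is this package's codification of the
1–5 confidence scale (the scale itself is standard; the exact rule
table is not): 5 exact mass only; 4 isotope-verified; 3 ≥ 2 matched
fragments; 2 fragments + isotope; 1 standard-confirmed (RT delta
< 0.1 min and the fragment rule). The two-fragment minimum follows
SANTE guidance; a suspect whose theoretical fragments all fail to
match in available ddMS² data is rejected outright (structural-isomer
rule-out), and a predicted Cl/S/Br M+2 that is absent from the
averaged apex spectrum refutes the match without needing MS2. Isotope
verification requires every predicted isotopologue ≥ 5 % relative to
be present within 5 ppm and within ±30 % (relative) of its predicted
abundance; the 5 % floor means weak C-only M+1 peaks are not mandatory
at low S/N. [M+Na]⁺ is searched only when the database entry allows it.

MS2 events are associated to a precursor within ±2.5 Da (half the
isolation window) and ±0.2 min.

**Homolog series.** Within the averaged apex spectrum (3 scans,
centroids merged at 0.01 Da), ladders are extended greedily in
repeat-unit steps (default C₂H₄O = 44.02621 Da; configurable, e.g.
CH₂ = 14.01565 for alkyl families) within 5 ppm, ties broken toward
the more intense centroid, requiring each member's own EIC apex to
co-elute within 0.05 min; ≥ 3 members make a series. A printed spacing
of 44.02567 sometimes circulates for ethoxylates; the exact C₂H₄O mass
is 44.02621 and is the default here.

## Quantitation and validation

Calibration is unweighted OLS (no weighting is standard for this
concentration range, 1–600 μg/L). Standard addition extrapolates to
the x-intercept: extract concentration = intercept/slope, requiring a
positive slope. Matrix effect = (m_matrix/m_solvent − 1)·100, |ME| <
20 % negligible. Interday precision is the %RSD of replicate
responses (sample sd, ddof = 1). The LOQ estimator is a declared
convention: the lowest calibration level with S/N ≥ 10 (when S/N per
level is supplied) and back-calculated accuracy within 20 %, scaled by
the dilution factor — g/L for liquids, mg/g for solids via the initial
dissolution mass/volume (e.g. 2 g in 2 mL ⇒ 1 g/mL). R² acceptance
defaults to 0.99 rather than hard-coding any observed study value.
Responses outside 0.5×–1.5× of the calibrated range are flagged as
extrapolated, not rejected.

## Risk screening

Banned co-formulants are tested against the 0.1 % w/w unintentional-
impurity threshold. g/L concentrations convert to % w/w assuming
density 1 g/mL unless a density is supplied; the flag records when the
assumption was used. RfD fold comparisons report both the half-up-
rounded integer (for narrative use) and the exact ratio, which
satisfies fold(a,b)·fold(b,a) = 1.

## Known limitations

- No profile→centroid conversion, vendor RAW parsing, lock-mass
  recalibration or ion mobility.
- No deconvolution of co-eluting isomers and no cross-run RT alignment
  (single-run study design).
- Fragment matching is presence-based within tolerance; no in-silico
  fragmentation or spectral-library cosine scoring.
- Charge states |z| > 1 are out of scope throughout.
- The candidate table is a local stand-in for online compound
  libraries; ranking quality is only as good as the supplied table.
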