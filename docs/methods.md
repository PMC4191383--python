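# Methods

## Model of the measurement

Each injected nucleoside `n` produces a mean MS signal `rf(n) · a · φ`,
where `a` is the injected amount (pmol), `rf(n)` the response factor
(counts/pmol) and `φ` the ion-suppression factor of the chromatographic
peak. Because the ¹²C analyte and its uniformly ¹³C-labeled isotopomer
co-elute and ionize identically, they share `rf` and `φ`; their signal
ratio (the NIF) therefore equals the amount ratio `a12/a13` exactly, at
any suppression and any instrument state. With a constant internal-standard
spike `a13 = s`, NIF is proportional to the analyte amount with slope
`rRFN = 1/s` — operationally, the slope of the external calibration of NIF
versus weighed amount — and `amount = NIF / rRFN` inverts the measurement.

The UV channel at 254 nm is treated as linear and stable: area =
`UVF(c) · pmol` for each canonical nucleoside `c`, with `UVF` the
operational extinction coefficient. The injected RNA amount is the
standard-corrected UV area of a reference canonical (guanosine by default,
configurable, including a four-canonical mean) divided by `UVF` and by the
residue count from the sequence. Yields follow as mod/RNA (per molecule),
per site (occupancy), per parent residue (%) and per total residues (mol%).

### Isotopologue chemistry

Carbons are labeled independently, so the isotopologue intensity at mass
offset `k` is Binomial(n_carbon, p) with `p` the per-atom ¹³C probability;
monoisotopic masses come from standard atomic-mass tables (pyteomics).
The leading-ratio inverse `p = n/(n + I(M−1)/I(M))` estimates the labeling
efficiency from a labeled spectrum. MRM transitions are derived as the
protonated nucleoside losing its sugar (132.0423 for ribose, 146.0579 for
2′-O-methylribose); C-glycosides (pseudouridine, whose base–sugar bond
survives collision-induced dissociation) have no derivable sugar-loss
transition and must be given one explicitly — the shipped registry leaves
it unset on purpose. Only carbon labeling is modeled: ¹⁵N shifts give
poorer mass separation and deuterium exchanges in water, so neither is
supported beyond room in the registry schema. Natural-abundance cross-talk
between the ¹²C and ¹³C channels is ignored (< 0.2% at 99% labeling and
≤ 12 carbons).

## The simulator and what it does (not) emulate

`simulate` is the package's test bed. Its suppression model is the simplest
shared-capacity form, `φ = 1/(1 + (a12 + a13)/K)`: a hyperbola whose raw
calibration flattens above ~0.1·K while the isotopomer ratio stays exact.
Session-to-session drift is a lognormal factor (mean 1) applied to the
response of *both* channels of a nucleoside — near-total sharing is what a
real detector/source drift does and what makes the rRFN stable while raw
signals swing by tens of percent. Per-injection noise is proportional
(independent per channel) plus additive baseline. Blank injections have a
small positive mean area (3·σ_add), as real peak integrators produce, so
areas stay non-negative and blank sd estimates the additive σ faithfully.

Reference study conditions (defaults, chosen once): response factor
10⁶ counts/pmol; suppression capacity K = 5 pmol (saturation onset in the
1–10 pmol region); additive σ = 3 counts (LOD ≈ 4–9 amol, LOQ ≈ 0.01–0.03
fmol — the regime of a sensitive triple quadrupole); proportional noise
CV 1% per channel (isotopomer-ratio CV ≈ 1.4%); session drift CV 24%;
UV response factors 540/600/800/900 area/pmol for C/U/G/A with 0.5% noise;
calibration grid blank + 15 half-decade levels, 0.01 fmol–100 pmol
injected; internal-standard spike 0.1 pmol per nucleoside, 20 pmol per
canonical in digest scenarios; 3 replicate injections.

Not emulated: chromatographic peak shapes, retention-time drift,
carryover, matrix-specific suppression differing between samples, and
instrument-specific response-factor spreads. Passing tests therefore
demonstrate the *mechanics* of isotope-dilution calibration — suppression
and drift cancellation, range extension, parameter recovery — not the
instrument-specific magnitudes (LODs, individual rRFN values), which are
fixtures of a given machine and standard batch.

## Calibration numerics

* **Linear window search**: replicates are aggregated by median per level;
  every contiguous run of ≥ 4 positive levels is fitted by weighted
  (1/x) least squares in linear space and accepted when back-calculated
  levels are within ±15% (interior) / ±20% (edges) — standard
  bioanalytical acceptance, since "linear" needs an operational
  definition. Longest window wins; ties break toward higher R². Raw-signal
  fits carry an intercept (integration baseline); NIF fits go through the
  origin.
* **Blank subtraction**: the per-session median blank ¹²C area is
  subtracted before NIFs are formed (clipped at zero). This is what makes
  NIF(0) = 0 hold in practice and lets the through-origin NIF calibration
  reach the noise floor. The additive baseline is negligible on the large
  ¹³C standard signal.
* **Low-edge caveat**: isotope normalization provably extends the *upper*
  end of the linear range (suppression cancels exactly). At the lower end
  both channels face the same counting noise; since the through-origin NIF
  fit has one fewer free parameter than the intercept-carrying raw fit,
  the two windows may start one half-decade grid step apart in either
  direction on a given noise realization. The property tests assert exact
  upper-edge dominance and low-edge agreement within one grid step.
* **rRFN**: weighted (1/x) through-origin slope of median NIF per level
  versus amount, fitted inside the NIF linear window; standard error from
  the weighted regression; R² computed on the fitted points.
* **LOD/LOQ**: 3·sd(blanks)/slope and 10·sd(blanks)/slope; zero blank
  variance returns (0, 0) with a warning rather than an error.
* **Stability**: cross-session RSD = 100·sd/mean with the n−1 sd, on
  per-session rRFN fits.
* **UVF**: through-origin OLS of standard-corrected UV area versus amount;
  defined only for the four canonicals.

## Quantification and comparison choices

* Replicate variability propagates to standard errors of amounts
  (sd/√n of per-replicate amounts); no bootstrap.
* The internal standard's UV contribution is subtracted using a measured
  standard-only reference injection (`SILIS_REF` run), not a theoretical
  estimate.
* Amounts below the validity window are *flagged* (`below_loq`), never
  censored to zero — the comparison module needs them to detect
  background artifacts.
* Fold changes divide doubly normalized levels (isotopomer ratio over
  canonical UV sum). The canonical UV sum is standard-corrected when a
  reference injection is available; this makes the fold change exactly
  invariant to scaling one sample's injected amount, which a raw sum is
  not (its standard-derived offset does not scale with the sample).
  Values below 1 mean higher in the reference (second) sample; a zero
  reference level yields NaN plus a flag, never infinity.
* Background flagging: a nucleoside whose per-molecule level is below
  0.01 mol/mol RNA (configurable) in *all* compared samples is marked
  background; its fold change is kept but not interpretable. The 1%
  default is a pragmatic choice for "present in traces".
* Multi-sample comparisons designate one reference sample (the second of
  a pair by default) and report every fold change against it.

## Problem sizes

Tests and the acceptance script run single- to ten-nucleoside simulations
of the default 16-level grid with 3 replicates and up to 6 sessions, and
200-iteration Monte-Carlo loops for spike recovery — a few seconds in
total. These sizes give sampling errors comfortably below the asserted
margins (e.g. rRFN standard errors ≈ 0.1% of the true value).

## Known limitations

* The registry ships derived transitions and illustrative retention
  windows, not instrument-validated ones; a real dMRM method must supply
  its own (and must supply the pseudouridine transition explicitly).
* Nucleosides without weighable standards (D, m3C, m2A, m1G, m2G) are
  detectable and comparable but cannot be converted to pmol; requesting
  absolute amounts for them raises an error naming them.
* No significance testing on fold changes: point estimates with replicate
  SEs only.
* Peak integration is upstream: the package starts at peak-area tables
  and does not read raw or mzML data.
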