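# Methods

This note documents the models implemented in `protconf`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
generator does and does not emulate.

## 1. PIE smFRET burst analysis

**Measurement model.** Freely diffusing molecules carrying a donor (AF555)
and an acceptor (AF647) produce photon bursts as they transit the confocal
volume. Pulsed interleaved excitation alternates donor and acceptor lasers,
so each detected photon carries a detection channel (donor/acceptor
emission) and an excitation slot (donor/acceptor excitation). The package
represents PIE by the slot label only; no ns-resolved lifetimes are modelled
(the hardware's 25 ns interleave is an implementation detail below the
abstraction used by the analysis).

**Burst search.** All-photon burst search (APBS): a photon is in a burst
region when the centred window of width 0.5 ms (default) contains at least
m = 10 photons; maximal runs of in-region photons are formed, runs closer
than one window width are concatenated, and only runs with strictly more
than 35 photons are kept ("more than 35 counts" read literally as ≥ 36).
The m parameter is not part of the printed measurement conditions and is
exposed in configuration. Whether the 0.5 ms "integration time" means a
sliding search window or a fixed binning time is ambiguous; both
readings are implemented (`find_bursts`, `find_bursts_binned`) with the
sliding window as default.

**Corrections.** Per burst, F_DD/F_DA/F_AA are the channel × slot tallies
(donor emission under acceptor excitation carries no FRET information and is
reported as a diagnostic only). Corrected efficiency and stoichiometry use
the standard three-parameter inversion with defaults
(Lk, DE, γ) = (0.08, 0.15, 0.85), the calibration values for this
instrument class. The S-gate [0.25, 0.75] is inclusive at both ends.
Corrected E may fall slightly outside [0, 1]; the histogram range
[−0.1, 1.1] accommodates that.

## 2. Synthetic photon streams

The generator produces bursts directly — arrivals as a Poisson process
(default 40 bursts/s), per-burst brightness from a log-normal size law
(mean 100 excitation events, shape 0.4; a geometric law is available) —
rather than simulating 3-D diffusion: downstream analysis only ever sees
photon clusters, and burst-wise generation keeps the ground truth exact.
Per-burst species are dual-labelled (default 80 %), donor-only (10 %) and
acceptor-only (10 %); dual bursts draw a conformational state from the
two-state default mixture: closed at E\* = 0.58 with 80 % occupancy, open at
E\* = 0.16 with 20 % — the solution-state population parameters of
prothrombin that the package ships as its reference conditions. Background
is Poisson per detection channel (200 photons/s each by default).

**Forward corruption order** is fixed as FRET partition → leakage → direct
excitation → γ → background, realized so that the standard inversion is
exact in expectation:

- a donor-slot excitation takes the FRET pathway with probability E\*;
- donor-pathway photons are detected with efficiency η_D and then routed to
  the acceptor channel with probability Lk/(1+Lk), making
  E[leak] = Lk · E[F_DD] exactly;
- FRET-pathway photons are detected with efficiency η_A = γ·η_D/(1+Lk)
  (η_D = 1 unless γ > 1+Lk, in which case both are rescaled), which embeds
  the γ imbalance;
- direct acceptor excitation adds Binomial(F_AA, DE) photons to F_DA;
- acceptor-slot photons are detected with unit reference efficiency.

With these choices the median corrected E of gated bursts converges to E\*
(verified to 3 standard errors in the tests).

**What the generator does not emulate:** diffusion kinetics and burst-shape
profiles, photophysics (blinking, bleaching), detector dead time and
afterpulsing, and multi-molecule coincidence beyond what random burst-time
overlap produces. Passing tests therefore demonstrate the correctness of
the analysis chain under the stated generative model, not robustness to
photophysical artifacts absent from it.

## 3. Population fitting and model selection

Histograms of gated burst E (bin width 0.025 over [−0.1, 1.1]; values
outside are clipped into the end bins and counted) are fitted by nonlinear
least squares to sums of k Gaussians — histogram curve fitting, matching
the procedure used on the measured data. Numerical choices:

- **Weighting.** Residuals are weighted by 1/√max(count, 1): bin counts are
  Poisson, and the AICc below assumes homoscedastic residuals. The
  unweighted variant makes selection unusable (peak-region noise dominates).
- **Fit support.** Only bins between the first and last occupied bin enter
  the fit and the AICc n; padding the range with empty bins does not change
  the result.
- **Initialization.** Component centers are seeded at local maxima of the
  3-bin-smoothed histogram (falling back to weighted quantiles), with
  jittered restarts (10 by default, seeded). Naive seeding reliably strands
  k = 3 fits in k = 2-quality local minima.
- **Identifiability.** Widths are bounded below at one full bin width: a
  narrower Gaussian is indistinguishable from a single-bin spike and exists
  only to absorb counting noise. Components are reported sorted by center.
- **AICc.** AICc = n ln(RSS/n) + 2k_p + 2k_p(k_p+1)/(n−k_p−1) with
  k_p = 3k+1 (three parameters per component plus the residual variance).
  k values with n − k_p − 1 ≤ 0 are skipped with a warning.
- **Selection rule.** Among fitted k, all models within 2 AICc units of the
  minimum are treated as equally supported (the conventional ΔAICc ≤ 2
  equivalence band) and the smallest such k is selected; a margin of 0
  recovers the bare minimum-AICc rule. The band matters: for nested Gaussian
  mixtures the likelihood-gain null is boundary-irregular, and bare
  minimum-AICc overfits by one component in ~6–10 % of in-model replicates.
  With the band, the generating component count is recovered in ≥ 95 % of
  5,000-burst replicates when the data are draws from a Gaussian mixture.
- **Known limitation.** Corrected per-burst E for a single state is a ratio
  of correlated count statistics and is slightly skewed (≈ −0.1 to −0.25
  depending on the correction set, dominated by the direct-excitation
  subtraction). At ≥ 5,000 bursts a histogram resolves this skew, and AICc
  may legitimately add a skew-absorbing component to photon-level
  single-state data. Population centers and area fractions remain accurate
  (centers to ±0.03, dominant fraction to ±0.05 in the tests); only the
  literal component count is affected. Model-selection consistency is
  therefore validated on mixture-level data, where the model class contains
  the truth.

Population fractions use the Gaussian-area convention
(amplitude × σ, normalized); "dominant" means largest area.

## 4. Accessible-volume FRET prediction

Single-radius AV model: the dye is a sphere of radius 3.5 Å on a flexible
linker of length L = 20 Å and width 4.5 Å attached at Cβ (Cα when absent).
On a cubic lattice (0.9 Å spacing) centred at the attachment atom, a
position is allowed if (a) the dye sphere clears every protein atom's van
der Waals radius and (b) it is reachable from the attachment point through
free space with clearance w/2 by a geodesic of length ≤ L (Dijkstra flood
fill over the 26-connected lattice). The linker-width treatment — requiring
path clearance w/2 along the whole path — is a simplification of the full
three-radius dye model. Defaults are conventional values for maleimide-
linked AF555/AF647; all are configuration-exposed. The 26-neighbour lattice
metric overestimates Euclidean path length by up to ~8 %, so the outer
shell of a free cloud is slightly shaved; this affects both dyes of a pair
equally and is far below the dye-size uncertainty.

⟨E⟩ averages 1/(1+(R/R₀)⁶) over donor–acceptor position pairs (dynamic
averaging, the convention of the coarse-grained dye-simulation tools this
follows); E(⟨R⟩) is available via the reported mean R. Averaging is
exhaustive when |D|×|A| ≤ n_samples, otherwise uniformly sampled
Monte-Carlo pairs (seeded); R₀ = 51 Å default for AF555/AF647. Residue
numbering follows the prothrombin 1–579 scheme with domains Gla 1–46,
kringle-1 65–143, kringle-2 170–248, protease 285–579; a renumbering map
can be supplied when deposited author numbering differs — it is never
guessed.

## 5. Surface areas

Shrake–Rupley SASA with a Fibonacci sphere (960 points/atom, probe 1.4 Å),
van der Waals radii by element. Buried surface area between residue groups
A and B is SASA(A) + SASA(B) − SASA(A∪B) — the total over both sides; the
one-sided value (÷2) is reported alongside since either convention appears
in the literature. Sphere-point discretization gives ~1 % area error; the
point set is not reflection-symmetric, so mirror-symmetric dimers split
the buried area equally only to that tolerance.

## 6. SAXS forward model and ranking

One dummy bead per residue at Cα with uniform form factor; Debye formula
evaluated directly (exact double sum, vectorized over pair distances — no
binning approximation). No excluded-volume or hydration-layer terms: at
q ≤ 0.3 Å⁻¹ the shape term dominates and suffices for closed-vs-open model
discrimination, which is the scope here; absolute χ against real measured
profiles would require the hydration corrections of full-atom tools.
χ is the uncertainty-weighted RMS residual after a closed-form optimal
scale; experimental profiles are interpolated linearly onto the model grid
within their measured q range only (no extrapolation). Ranking is stable
(ties keep input order).

## 7. Activation kinetics

The chromogenic assay couples prothrombin activation by prothrombinase to
reporter hydrolysis by the thrombin generated. With substrate far below the
activation K_M (10 nM prothrombin), activation is pseudo-first-order:
thrombin(t) = S₀(1 − e^(−k_spec·E₀·t)). Reporter consumption follows
Michaelis–Menten kinetics in the reporter (dC/dt = −k_cat·thr(t)·C/(K_M+C)),
integrated with LSODA at rtol 1e-9, and absorbance is
A = baseline + ε·(C₀ − C). The early-time limit is parabolic,
A ≈ ½·ε·v_c·k_spec·E₀·S₀·t², with v_c the initial reporter velocity per
molar thrombin.

Defaults are the assay conditions — E₀ = 2.5 pM, S₀ = 10 nM, C₀ = 24 µM —
while the thrombin constants on the FPF-pNA reporter (k_cat = 50 s⁻¹,
K_M = 10 µM) and ε = 9920 A/M (pNA at 405 nm, 1 cm path) are placeholders
in the plausible literature range that must be supplied from calibration
for quantitative work; k_spec estimation is invariant to joint rescaling of
(A, ε) and, in the pseudo-first-order regime, insensitive to v_c up to a
time rescaling. An `activity_factor` multiplier on k_cat models constructs
whose activation product hydrolyses the reporter at reduced efficiency
(e.g. a disulfide-locked closed form retaining fragment-1 on the autolysis
loop). `fit_specificity_constant` does weighted nonlinear least squares in
(k_spec, baseline) over the full progress curve (default), with standard
errors from the Jacobian; an initial-slope (parabola) linearization is
available and also seeds the full fit. A flat curve returns estimate 0
flagged with infinite relative error.

## 8. Pipeline and reproducibility

`run_smfret_pipeline` chains burst search → gating → histogram → AICc
mixture → fractions per dye pair, predicts theoretical E by AV simulation
on the configured structure, and emits a comparison table with
ΔE = E_exp − E_theo and the significance flag |ΔE| > 0.1 (the convention
that experimental centers carry ~10 % standard deviations). All randomness
derives from the configured seed; a rerun is byte-identical, and every run
writes a manifest (package/numpy/python versions, full config including
defaults, per-stage counts). Configs are YAML validated against typed
models.

## 9. Problem sizes used in the tests

Synthetic measurements in the test- and acceptance suites use 60–120 s
streams at 40–50 bursts/s (~2,000–5,300 bursts, ~0.6 M photons), 100-point
SAXS profiles at 2 % noise, 120-point progress curves, and 5,000-burst
histograms × 102 replicates for selection consistency — sizes at which
every statistical tolerance asserted (3 SE round-trips, ±0.03 centers,
±0.05 fractions, χ = 1 ± 0.2, 1 % kinetic recovery) is comfortably
resolved by the corresponding estimator.
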