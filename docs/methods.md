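# Methods

This note records the models implemented in `sfm`, the defaults and why they
were chosen, the construction of the synthetic data, and the numerical and
design decisions a maintainer would want to know. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Structural connectome preprocessing

Raw probabilistic-tractography streamline counts `F` between N cortical
regions are turned into the structural connectivity matrix `S` in a fixed
order:

1. **Size normalization.** Streamline counts scale with the seed and target
   region volumes. Modes: `product` (`F_ij / v_i v_j`, the reference,
   normalizing strength per unit volume), `sum` (`F_ij / (v_i + v_j)`),
   `target` (`F_ij / v_j`, symmetrized by averaging the two directed values
   because all downstream models assume symmetric `S`), `none`.
2. **Fiber-length weighting** (optional): entrywise multiplication by the
   mean tract length, up-weighting long tracts to compensate the progressive
   loss of probabilistic streamlines with distance. The operation is stated
   in the literature only as "weighted by fiber length"; multiplication is
   the reading implemented.
3. **Zero diagonal** — no self-connections.
4. **Homotopic augmentation.** Tractography systematically under-recovers
   transcallosal connections between mirror-symmetric regions. For each
   homotopic pair (i, j), `h ×` (node i's total pre-augmentation input
   strength) is added to `S_ij` and symmetrically for j, then the matrix is
   re-symmetrized by averaging. Interpreting the added weight as a fraction
   of the node's *total input strength* keeps `h` dimensionless and
   comparable across nodes. Reference value `h = 0.1`.
5. **Input normalization** (optional, on in the reference configuration):
   each row is scaled to unit sum, encoding the assumption that tractography
   informs only about *relative* input composition per region. Rows with no
   connections are left all-zero and flagged in the provenance. Augmentation
   happens before normalization; the provenance records the order so either
   reading can be audited.

The **shuffled-connectome baseline** permutes the strict-upper-triangle
values uniformly (seeded) and mirrors them, preserving the value multiset,
symmetry and zero diagonal while destroying all topology. Row normalization
is *not* reapplied after shuffling — the shuffle is a baseline for the
information in the arrangement of weights, not a new connectome.

**Sparsity statistic.** `Kurt[X] = <X⁴>_ij / <X²>_ij²` over the strict upper
triangle, with raw (about-the-origin) moments. A constant matrix gives 1; a
single nonzero among m entries gives m. Structural matrices are heavily
kurtotic; SAR-model correlation matrices derived from them are not — the
ordering (tested, not the specific values, which are data-dependent) is the
qualitative signature that modeling densifies the sparse anatomical skeleton.

## The SAR model

`y = k S y + σ ν` with uncorrelated Gaussian noise. Equilibrium:
`Q = (I − kS)⁻¹`, `Cov = σ² Q Qᵀ`, correlation by normalizing with the
diagonal. The correlation is independent of σ (σ defaults to 1). Solving
requires spectral radius `ρ(kS) < 1`; the solver raises an error naming the
radius otherwise. With input-normalized `S` (row sums 1) the radius is 1, so
`k < 1` is the stable range — the grid default `k ∈ {0.05, …, 0.95}` spans
it. The model FC is `|Corr|`, mapping onto the [0, 1] scale of the coupling
metrics.

## The delayed Kuramoto model

Eq. above (README). Defaults and reasons:

| parameter | default | why |
|---|---|---|
| ω | 8 Hz | center of the analyzed alpha band; the mean coherence of resting EEG peaks near 8 Hz |
| dt | 0.1 ms | Euler step fine enough for delay rounding at the velocities of interest |
| d | 1.25 ms, v = 1.7 m/s, k = 700, h = 0.12 | reference operating point reported for group-level DTI/EEG data, exposed as `KURAMOTO_REFERENCE`; data-specific, no claim that synthetic optima land there |
| duration / burn-in | 30 s / 5 s | coherence estimates stabilize at desk scale; tests use shorter runs at N = 20 |
| noise_sd | 0 | the model itself is deterministic; optional phase noise exists only for synthetic-data realism |

Delays `d + D_ij/v` are rounded to the nearest integer step of dt (the
convention is not standardized; documented here). History before t = 0 is
back-extrapolated along the intrinsic drift, `φ_i(0) − 2πω·t`. With seeds
fixed the integration is bit-reproducible; `v → ∞, d = 0` reduces exactly
(bit for bit) to a zero-delay run. Downstream, phases become unit-amplitude
signals `cos(φ)`; with unit amplitudes every implemented metric is
amplitude-insensitive, so the choice of cos over sin or `e^{iφ}` is
immaterial and was made for realism of the real-valued signal path.

## Analytic signals and coupling metrics

Signals are bandpass filtered (order-4 Butterworth, zero-phase
forward-backward application, default 8 ± 2 Hz — the stated analysis names
only the 8 Hz center; ±2 Hz is this package's choice) and Hilbert
transformed. One effective filter length, `⌈4 fs / bandwidth⌉` samples, is
trimmed from each edge to drop filter and Hilbert transients; inputs too
short to leave `2 fs / bandwidth` samples are rejected.

Metric definitions operate on the analytic cross-spectrum
`s_mn(t) = A_m(t) conj(A_n(t))`:

- `COH = |⟨s_mn⟩| / √(⟨s_mm⟩⟨s_nn⟩)` (standard convention: time-averaged
  spectra).
- `COH_instant = |⟨s_mn/√(s_mm s_nn)⟩|`: the same formula with the
  normalization inside the average, as coherence is sometimes written. That
  expression is algebraically identical to the PLV; both conventions are
  implemented so the degeneracy is explicit, and `coh` (the standard
  convention) is the default.
- `PLV = |⟨e^{i(φ_m−φ_n)}⟩|`.
- `ICOH = |ℑ(C)|` for complex coherency C.
- `PLI = |⟨sgn ℑ(s_mn)⟩|`, with `sgn(0) = 0`; imaginary parts below 1e-12
  of `|s_mn|` count as zero so that numerically real cross-spectra (e.g.
  identical channels) give exactly 0.
- `WPLI = |⟨ℑ s_mn⟩| / ⟨|ℑ s_mn|⟩`, defined as 0 when the denominator is 0.
- `LPC = ℑ(C)² / (1 − ℜ(C)²)`, clipped to [0, 1], defined as 0 when
  `ℜ(C)² = 1`. The published table entry for this metric is typographically
  garbled; the implementation follows its cited definition (quotient of
  residual variances after partialling the zero-lag component).

Sampling floors matter for interpretation: a band-limited analytic signal
decorrelates over ~1/bandwidth, so a T-second record carries roughly
`bw·T` independent samples and the null floor of the magnitude metrics is
`≈ √(π/4)/√(bw·T)` (0.057 at 60 s × 4 Hz). Tests that compare estimated and
analytic FC set their tolerances from this arithmetic, not from wishes.

## Leadfield, forward and inverse

`forward_project` maps source time series (`G X`) or covariances
(`G C Gᵀ`). `leadfield_fc_baseline` is the correlation-normalized `G Gᵀ`:
the sensor-space FC produced by volume conduction acting on *independent*
sources. On synthetic scenes this baseline alone explains the large majority
of sensor-space FC variance (computed by the acceptance script), which is
why sensor space is a poor place to test structure–function specificity.

**LCMV beamformer** (sklearn transformer): data covariance over a single
window, diagonal loading `C + reg·mean(diag C)·I` (default reg 0.05; not
specified in the source literature), per-source orientation from the
generalized eigenvalue problem on the 3-axis gain block (max output power =
smallest eigenvector of `Lᵀ C⁻¹ L`; rank-deficient blocks fall back to the
dominant singular vector with a warning), unit-gain weights
`w = (gᵀC⁻¹g)⁻¹ C⁻¹ g`.

**Minimum-norm estimate**: `W = Gᵀ(GGᵀ + λI)⁻¹`,
`λ = trace(GGᵀ)/(n_sensors · snr²)`, default snr 3 (conventional; for
band-limited data the *in-band* SNR is the relevant number and is much
higher than the broadband one).

Pipelines band-limit the sensor data to the analysis band before computing
the inverse (configurable, on by default): with narrowband signals the
broadband noise otherwise dominates the covariance and the regularization
needed against it swamps the low-variance spatial modes that distinguish
neighboring sources.

**Comparison spaces.** `source` compares raw model FC against
inverse-reconstructed empirical FC (the conventional comparison);
`sensor` compares forward-projected model FC against sensor FC;
`reconstructed` passes the model covariance through the same resolution
operator `R = W G` as the data. Linear inverses leave spatial leakage — each
reconstructed source mixes its neighbors — and comparing a leakage-free
model against leakage-contaminated data biases fitted couplings upward. The
resolution-matched comparison removes that bias exactly (both sides live in
the same observation space) and is therefore used for the parameter-recovery
experiments; the conventional `source` comparison remains the default for
descriptive fits.

## Fit evaluation

- Global performance: Pearson r over the strict upper triangle; p-values by
  the usual t-approximation with n = number of edges, which treats edges as
  independent — they are not, so p-values are optimistic and reported raw,
  uncorrected.
- Variance explained `100 r²`; additional variance
  `100 (r_m² − r_s²)/(1 − r_s²)` — the share of FC variance unexplained by
  structure alone that the model captures.
- Local error: both FC vectors z-transformed, TLS line = first principal
  axis of the 2-D cloud, residual = signed orthogonal distance, positive
  when the empirical coupling exceeds the modeled one (under-predicted
  edge). The centroid lies on the line, so signed residuals sum to zero.
- `error_vs_edge_distance` correlates `log |residual|` with fiber or
  Euclidean distance; exact-zero residuals are excluded before the log and
  counted (the handling is not standardized; exclusion is this package's
  choice).
- Node metrics: betweenness on shortest paths with edge length `1/weight`
  (exposed option `unit` for unweighted paths), strength (row sum),
  eigenvector centrality (Perron vector, unit norm), Onnela-style weighted
  clustering (geometric mean of max-normalized triangle weights). Computed
  via networkx; the test suite checks them against brute-force path
  enumeration on all graphs up to N = 7.
- Grid search rebuilds `S` for every h (h changes the matrix, hence the
  stability region), skips unstable SAR points as NaN, and breaks exact
  performance ties toward the smallest k, then smallest h (first occurrence
  in C-order iteration).

## Synthetic data: what it emulates, what it does not

`generate_geometry`: two mirrored hemispheric shells (~65 mm radius, ±8 mm
jitter) with ROI centers on a jittered quasi-uniform spherical grid
restricted to the upper, off-midline region — parcellation centers are well
separated in real atlases, and the cortex sits under the sensor montage.
Sizes log-normal (median ~2000, σ_log 0.5). Homotopic pairs by mirror
construction. Fiber distances are Euclidean distances inflated by
`1 + Gamma(2, 0.15)` (mean +30 %), so tracts never undercut straight lines.

`generate_connectome`: edge presence Bernoulli with probability
`c·exp(−d/60 mm)`, with c solved by bisection so the expected unconnected
fraction matches the observed 262/2145 ≈ 12.2 %. Present edges get
log-normal counts with mean log strength falling at 0.02/mm; the log-noise
sd is calibrated analytically so the log-strength–distance correlation sits
near the observed −0.37 (floor 0.5 so that `strength_decay = 0` produces
distance-independent strengths rather than a constant matrix). The resulting
size-normalized matrix has raw-moment kurtosis ≫ 10.

`generate_leadfield`: sensors on a spherical cap at 1.3× the source-shell
radius; 3-axis gain = unit source→sensor vector over `(dist² + s²)` with
smoothness s = 40 mm; orientations outward with Gaussian tilt (sd 0.25);
per-source columns scaled to unit norm. This is a deliberately synthetic
stand-in for a boundary-element head model: it reproduces smooth
distance-decaying, orientation-dependent mixing, but no tissue
conductivities, no realistic electrode montage, and its null space differs
from a physical head's.

`generate_empirical_like_recording`: for the SAR truth, independent
band-limited unit-variance noise streams are mixed with Q, which imposes the
model covariance `QQᵀ` on band-limited signals — the SAR model has no time
axis, so any time-domain realization is a construction; this one makes the
analytic correlation the exact ground truth at every frequency in the band.
For the Kuramoto truth, simulated `cos(φ)` trajectories are used. Sources
are forward-projected and white sensor noise added at a stated amplitude
SNR (default 10).

**What passing tests show / do not show.** The synthetic scenes verify the
machinery: closed-form solutions, estimator identities, calibrated
generators, recovery of known parameters under a known observation model.
They do not show that real cortical dynamics follow either model, and real
EEG brings artifacts (muscle, blinks, non-stationarity), head-model error
and inter-subject variability that no test here touches.

## Known limitations

- With 66 sources and 64 sensors the inverse problem is at the edge of
  underdetermination; raw (non-resolution-matched) round-trip FC recovery is
  leakage-limited at roughly r ≈ 0.8 for the minimum-norm inverse at high
  SNR, and lower for the LCMV beamformer, whose minimum-variance criterion
  partially cancels correlated sources — a known property, measured here on
  the default scene, independent of sensor noise. Conclusions about inverse
  methods on real data should not be read off these synthetic numbers.
- Coherence-type estimates at 60 s × 4 Hz carry a null floor near 0.06;
  experiments needing finer discrimination must lengthen the recording.
- The Euler integrator is first-order; delay rounding to 0.1 ms quantizes
  velocities. Both are adequate for the tested regimes but unvalidated for
  stiff/chaotic corners of the Kuramoto parameter space.
- p-values for edge-level correlations ignore edge dependence (documented
  above); no multiple-testing control is applied.
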