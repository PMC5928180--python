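# Methods

## Model

The package treats a hyperspectral dataset as realizations of the linear
mixing model: the spectrum measured at pixel x is a non-negative
superposition of k endmember spectra plus noise,
`S(x, R) = Σᵢ aᵢ(x) wᵢ(R) + N`. In matrix form the data are
`X (m × n)` — m spectral channels (features) by n pixels (samples), one
column per pixel — and unmixing is the low-rank factorization `X ≈ U V`
with endmembers `U (m × k)` and abundances `V (k × n)`. This orientation is
fixed globally; every reshape between cube `(ny, nx, m)` and matrix uses
one raster convention (row-major, y slow / x fast), enforced by a single
shared helper. The assumptions that matter: the mixture is linear (finite
probe resolution does not break linearity), the number of constituents k
is small, and for the non-negative solvers the data are count-like
(preprocessed to be ≥ 0).

## Solvers and numerical choices

**Orthogonal family.** Truncated SVD gives the Frobenius-optimal rank-k
approximation; PCA is SVD of the mean-centered matrix with explained
variance fractions reported. Component signs are fixed by making each
component's largest-magnitude spectral coordinate positive — the
decomposition is sign-ambiguous and a convention is needed for
reproducible outputs.

**NMF family.** The default solver is multiplicative updates (Lee–Seung
style). Each update is a majorize–minimize step, so the objective —
including all penalty terms — is non-increasing; the solver records the
trace every iteration and the suite asserts monotonicity (relative
tolerance 1e-10) on every run. A denominator floor of ε = 1e-12 guards
against division by zero. Initialization is seeded uniform random entries
scaled by sqrt(mean(X)/k), or deterministic NNDSVD (zeros filled with
mean(X)/100 so multiplicative updates are not trapped at exact zeros).
Convergence is declared when the relative objective change drops below
`tol` (default 1e-6) or at `max_iter` (default 500). HALS (exact
block-coordinate updates, Frobenius loss, supports λ₁) is provided for
fast tight convergence; it is also monotone but that is not the asserted
contract. Solvers are bit-reproducible given seed, config and input.

**Penalties.** The sparsity penalty is λ₁‖V‖₁ (update denominator gains
λ₁/2 under the unit-free convention ‖X−UV‖² without the ½ factor). The
spatial penalty is the graph-Laplacian quadratic form
λ₂·tr(V L Vᵀ) = λ₂·½ Σᵢⱼ Wᵢⱼ‖vᵢ−vⱼ‖², which directly penalizes abundance
differences across edges of a pixel-similarity graph; its multiplicative
update adds λ₂VW to the numerator and λ₂VD to the denominator and remains
monotone. A literal alternative penalty λ₂‖V W Vᵀ‖²_F with the similarity
matrix itself is available behind `literal_penalty=True`: it shrinks
similarity-weighted co-activation rather than roughness and carries no
monotonicity guarantee, so it exists for fidelity and comparison, not as
the default. Both forms are echoed in the run report.

**Scale convention.** Scale and permutation ambiguity is resolved only at
reporting time: columns of U are normalized to unit ℓ2 on exit with the
scales folded into V, leaving UV unchanged. The reconstruction term of the
objective is invariant to this normalization (asserted in tests); the
penalty terms are not, which is inherent to penalties placed on one factor.

**Sum-to-one.** The simplex constraint is solved by the pLSI route: the
data matrix is column-normalized (per-pixel totals stored for
reconstruction), and an EM iteration — multiplicative KL updates with
per-iteration column normalization of both factors — keeps every column of
U and V exactly on the simplex while monotonically decreasing
KL(X_norm ‖ UV). Because this route is intrinsically KL, requesting
sum-to-one with the Frobenius loss is a configuration error rather than a
silently different algorithm. All-zero pixel columns have no defined
composition; they are assigned the uniform abundance 1/k and a warning is
raised.

**Generalized KL.** The KL loss is the generalized divergence
Σ P log(P/Q) − P + Q with 0·log 0 ≡ 0, which is bounded below and monotone
under the standard updates; the plain Σ P log(P/Q) form differs only by a
constant when both sides are normalized.

## Pixel graphs

The default graph is the 4-neighbor grid adjacency — cheap, sparse, and
aligned with the motivation that neighboring pixels mix similarly; an
8-neighbor variant adds diagonals. A feature-similarity graph
`Wᵢⱼ = exp(−dᵢⱼ²/2σ²)` on Euclidean spectral distances is also available:
dense (float32, chunked; 1 GiB at 16384 pixels) or kNN-truncated sparse
with symmetrization `W ← max(W, Wᵀ)`. The bandwidth σ defaults to the
median pairwise distance of a seeded 1000-pixel subsample, a standard
heuristic the data scale justifies. Invariants checked at construction:
symmetry, zero diagonal, non-negative weights; the Laplacian D − W has
zero row sums and is PSD.

Tuning guidance implemented in the docs and defaults: start regularization
near 0.001 and increase multiplicatively; tune λ₁ before λ₂, since
sparsity is the easier constraint to satisfy.

## Rank selection

Three diagnostics are scanned over candidate ranks. (1) *Consensus
dispersion*: NMF is rerun from `n_restarts` (default 20) seeded random
starts; each run labels pixels by dominant endmember (ties → lowest
index), runs are averaged into a consensus matrix C̄, and
ρ = (1/n²) Σ 4(C̄ᵢⱼ−½)² ∈ [0,1] measures restart stability. (2) *Elbow*:
the rank maximizing the discrete second difference of the error curve
(ties → smallest k; a zero-curvature curve returns the smallest k with a
warning). (3) *Saturation*: the first rank at which two fitted endmembers
exceed a cosine threshold (default 0.95). `scan_k` reuses one restart
ensemble per rank for both the consensus and a seed-best error curve, and
reports `chosen_k` from the elbow criterion — deterministic given the
curve — with the other two alongside for the analyst. Information-criterion
(AIC/BIC) selection is out of scope: no likelihood is specified.
On the default synthetic cubes the elbow lands on the true rank k = 3 and
saturation appears only above it; the exact first-saturation rank
fluctuates with the generator seed (observed 4–6), so the suite asserts
the ordering rather than a knife-edge threshold crossing.

## Sliding-window FFT

For atomically resolved images, a `w × w` window anchored at the top-left
advances by `s` pixels; trailing pixels not covered by a full window are
dropped (no padding — padding would fabricate data). Each patch
contributes the fftshift-centered magnitude of its 2-D FFT, flattened, as
one feature column; magnitude (not power, not the complex transform) keeps
features non-negative as NMF requires, and the zero-frequency bin is
retained. The window count is `(⌊(H−w)/s⌋+1)·(⌊(W−w)/s⌋+1)`. Loading maps
from NMF on the stack are rendered at window-grid resolution without
interpolation back to image resolution. No taper (Hann etc.) is applied.

## Synthetic generator

The generator is the verification bed: it realizes exactly the model the
solvers assume. Endmembers are sums of Gaussian peaks (random centers,
widths 1–4 % of the axis, heights 0.3–1) on a small smooth baseline —
the visual motif of classical mass spectra; draws are rejected until all
pairwise cosines are ≤ 0.9 (resampling capped at 100 attempts) so that
recovery is well-posed. Abundance fields are standardized Gaussian random
fields (length scale `smoothness_scale` pixels) passed through exp —
positive, log-normal, spatially smooth; a `sparsity` fraction of pixels is
made single-endmember dominant; optional per-pixel simplex normalization.
Noise is additive Gaussian at a target SNR (negative values clipped at
zero with the clipped fraction logged — at 30 dB this touches ~3 % of
entries) or Poisson counts with mean scale·UV.

Frozen defaults: 32 × 32 grid, m = 200 channels, k = 3, 30 dB SNR, seeds
0–4. Under these conditions the suite requires mean matched endmember
cosine ≥ 0.98 and abundance RMSE ≤ 0.05; the HALS solver with NNDSVD
initialization is used for this check because it converges tightly within
500 sweeps (measured: mean cosine 0.9999, mean RMSE 0.035), whereas
multiplicative updates approach the same fixed point much more slowly.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: instrument artifacts (dead pixels, detector
saturation, mass-calibration drift), correlated or heteroscedastic noise,
baseline drift, nonlinear mixing, and endmember variability across the
field of view. Recovery numbers on real instrument data will be worse and
should be judged by the physical interpretability loop, not by these
thresholds.

## Recovery scoring

`recovery_report` matches recovered to true endmembers by maximizing total
cosine over permutations (optimal assignment; a brute-force enumeration
cross-checks it on small k), then scores per-component cosine and
abundance RMSE after a per-component optimal non-negative rescaling, so
the report is invariant to the factorization's inherent permutation and
scale ambiguity.

## Problem sizes

The verification suite and the reproduction script run on the frozen
default cubes (200 × 1024 matrices), a 16384-pixel dataset for the
similarity-matrix structure (dense float32 path in the script, kNN path in
the suite), and the 2048 px / 500 px / 100 px sliding-FFT geometry —
sizes chosen to exercise the full-scale printed geometries where they are
the point, and compact synthetic conditions everywhere else.

## Known limitations

* Multiplicative updates converge slowly near fixed points; use HALS for
  tight Frobenius fits.
* The ℓ1 penalty on V is not scale-invariant during optimization (only the
  exit normalization makes it comparable across runs); extremely long runs
  can partially absorb it into factor scales.
* The literal similarity-penalty form is heuristic (no monotonicity proof).
* The dense similarity graph at 16384 pixels costs ~1 GiB in float32;
  beyond that use the kNN path.
* 3-D (x, y, z) cubes are handled by flattening the spatial axes upstream;
  the containers are 2-D-grid native.
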