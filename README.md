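# hsunmix — physically constrained linear unmixing of hyperspectral images

Spectroscopic imaging modalities — ToF-SIMS chemical imaging, STEM, current
imaging tunneling spectroscopy, hyperspectral X-ray microscopy — record a
full spectrum at every pixel. To good approximation the measured signal is a
linear superposition of a few basic constituent spectra:

    S(x, R) = Σᵢ aᵢ(x) wᵢ(R) + N

where the *endmembers* wᵢ(R) are the pure spectra (chemical species,
structural phases, electronic states) and the *abundance maps* aᵢ(x) give
their local weighting. **Linear unmixing** recovers both from the data.
`hsunmix` implements this as constrained matrix factorization of the
channels-by-pixels matrix `X (m × n)` — a 128 × 128 image with 1535 mass
channels becomes a 1535 × 16384 matrix — into `X ≈ U V` with endmembers in
`U (m × k)` and abundances in `V (k × n)`:

| method | constraint | objective |
|---|---|---|
| truncated SVD / PCA | orthonormal factors | ‖X − UΣVᵀ‖²_F |
| NMF | U ≥ 0, V ≥ 0 | ‖X − UV‖²_F or generalized KL |
| sparse NMF | + ℓ1 on V | + λ₁‖V‖₁ |
| graph-regularized NMF | + spatial smoothness | + λ₂ tr(V L Vᵀ), L the pixel-graph Laplacian |
| sum-to-one NMF (pLSI) | abundance columns on the simplex | KL divergence |

Matching the constraints to the physics (counts are non-negative, phases
rarely coexist in one pixel, neighboring pixels mix similarly, fractional
weights sum to one) is what turns a generic decomposition into an
interpretable one.

The package also provides rank-selection diagnostics (consensus dispersion
over random restarts, reconstruction-error elbow, component-similarity
saturation), a sliding-window FFT feature stack for segmenting atomically
resolved images by local structure factor, readers/writers for HDF5 / TIFF /
CSV, and a seeded synthetic-cube generator with ground truth used to verify
every solver contract.

## Worked example

```python
import hsunmix as h

gt   = h.default_ground_truth(seed=0)          # 32x32 grid, 200 channels, k=3, 30 dB
cube = h.make_cube(gt)
dm   = h.cube_to_matrix(cube)                  # (200, 1024) channels x pixels

cfg   = h.UnmixingConfig(k=3, seed=0, solver="hals", init="nndsvd", tol=1e-9, max_iter=500)
model = h.nmf(dm, cfg)
rep   = h.recovery_report(model, gt)
print(rep.cosines, rep.abundance_rmse)
```

Running `python examples/unmix_synthetic_cube.py` prints:

```
cube (32, 32, 200) -> matrix (200, 1024) (channels x pixels)
converged=False after 500 iterations, final objective 564.7123
matched endmember cosines: ['1.0000', '0.9998', '0.9998']
abundance RMSE after matching/rescaling: 0.0315
relative reconstruction error vs noiseless truth: 0.0043
```

Cosines ≈ 1 say the three recovered spectra are essentially identical to the
generating endmembers after permutation matching; the abundance RMSE of
0.03 (on fields of order 1) says the spatial maps are recovered too; the
final objective is the residual sum of squares against the noisy cube, which
cannot reach zero at 30 dB SNR.

The other scripts in `examples/` each demonstrate one capability: sparsity
and spatial smoothing (`constrained_unmixing.py`), rank selection
(`rank_selection.py`), sliding-FFT phase segmentation
(`sliding_fft_segmentation.py`), and the PCA/NMF interpretability contrast
(`pca_vs_nmf.py`).

## Command line

```bash
hsunmix synth --seed 0 --out cube.h5
hsunmix unmix cube.h5 --k 3 --lambda1 0.01 --graph grid4 --lambda2 0.1 --out run/
hsunmix scan-k cube.h5 --k-min 2 --k-max 6 --out scan/
hsunmix pca cube.h5 --k 4 --out pca/
hsunmix slidefft image.tif --window 500 --step 100 --out stack.h5
```

Each run writes endmember spectra as CSV, abundance maps as float32 TIFF
with PNG previews, and a JSON run report (config, seed, objective trace,
diagnostics, file manifest).

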