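# connnlm — connectome-weighted non-local means denoising for PET

`connnlm` post-filters 3D PET volumes by combining non-local means (NLM)
intensity similarity with structural connectivity derived from diffusion-MRI
tractography. It is aimed at PET-MR neuroimaging workflows — for example
tau-PET in dementia research — where lesions connected by white-matter
pathways should reinforce each other during smoothing while anatomically
disconnected regions should not contaminate one another.

## The method

Classic NLM replaces a voxel intensity x_i by a weighted average of all
voxels x_j in a search window, weighting each pair by patch similarity:

    w_ij = (1 / Z(i)) · exp( −‖p_i − p_j‖²_{2,a} / h² )

where p_i is the M×M (2D axial) intensity patch around voxel i,
‖·‖_{2,a} is the Euclidean patch distance weighted by a Gaussian kernel of
standard deviation `a` (the centre voxel counts most), h² sets the smoothing
strength, and Z(i) normalizes the weights to sum to one.

The connectome-weighted filter multiplies this similarity by a hybrid
local/distant connectivity over a brain parcellation:

    A_ij = 1            if voxels i, j lie in the same node
    A_ij = λ · SC_ab    if i ∈ node a, j ∈ node b, a ≠ b

`SC` is the node×node structural connectivity matrix (e.g. SIFT2-weighted
streamline counts), log-transformed and min-max normalized to [0, 1]. The
connectivity ratio λ balances distant against local smoothing: λ = 0
restricts smoothing to within-node voxels, larger λ lets strongly connected
regions share information. The filtered value is

    x̂_i = Σ_j (1 / Z′(i)) · exp( −‖p_i − p_j‖²_{2,a} / h² ) · A_ij · x_j

with the search window spanning the whole (masked) volume by default. Both
tuning parameters have noise-proportional starting rules: h² = C·σ²(PET)
from a background-noise region, and λ = B·σ²(TDI) from the track-density
image, so that less trustworthy data (noisier PET, poorer tractography)
receives correspondingly weaker weighting.

The package also ships Gaussian, total-variation and plain-NLM baseline
filters, evaluation metrics (MSE, lesion CNR, lesion CRC, region variances),
and a seeded synthetic phantom (tissue shells, angular-sector parcellation,
lesions with controlled connectivity, calibrated noise) so the entire
pipeline runs end-to-end with no external data.

## Worked example

```python
from connnlm import (
    PhantomConfig, generate_phantom, normalize_sc, HybridConnectivity,
    FilterParams, conn_nlm_filter, estimate_h2, evaluate,
)

# synthetic PET + connectome bundle: 3 lesions, two joined by a strong edge
bundle = generate_phantom(PhantomConfig(shape=(32, 32, 24), n_nodes=6, seed=1))

# smoothing strength from the noise-proportional rule h² = C·σ²
h2 = estimate_h2(bundle.noisy, bundle.masks.gm, C=8.0)
print(f"estimated h2 = {h2:.3f}")

hybrid = HybridConnectivity(sc_norm=normalize_sc(bundle.sc), lam=1.0)
filtered = conn_nlm_filter(bundle.noisy, bundle.parc, hybrid,
                           FilterParams(h2=h2, patch_size=5, a=1.0))

for label, img in [("noisy   ", bundle.noisy), ("filtered", filtered)]:
    report = evaluate(img, bundle.truth, bundle.masks,
                      mse_mask=bundle.truth.effective_mask())
    print(f"{label}: MSE={report.mse:.4f}  "
          f"CNR(iso)={report.cnr['isolated_lesion']:.1f}  "
          f"CRC(iso)={report.crc_percent['isolated_lesion']:.1f}%  "
          f"var(GM)={report.variances['gm']:.2e}")
```

Output:

```
estimated h2 = 0.174
noisy   : MSE=0.0224  CNR(iso)=10.7  CRC(iso)=105.2%  var(GM)=2.18e-02
filtered: MSE=0.0049  CNR(iso)=89.8  CRC(iso)=67.3%  var(GM)=1.27e-04
```

Filtering cuts the whole-brain mean squared error about fourfold and the
grey-matter noise variance by two orders of magnitude, raising the isolated
lesion's contrast-to-noise ratio from 10.7 to 89.8. The contrast recovery
coefficient drops from ~105% (noise makes the raw ratio overshoot) to 67%,
the usual resolution/contrast trade-off of aggressive smoothing at this
small phantom scale.

The same estimators compose with scikit-learn conventions
(`ConnNLMDenoiser`, `NLMDenoiser`, `GaussianDenoiser`, `TVDenoiser` expose
`fit` / `transform` / `get_params`), and everything is scriptable from the
shell:

```sh
connnlm phantom --seed 1 --out-dir bundle/
connnlm filter --pet bundle/noisy.nii.gz --parc bundle/parc.nii.gz \
    --sc bundle/sc.csv --mask bundle/truth.nii.gz \
    --h2 0.25 --lam 1.0 --out filtered.nii.gz
connnlm evaluate --img filtered.nii.gz --truth bundle/truth.nii.gz \
    --masks bundle/masks.yaml --out report.json
connnlm sweep   --bundle bundle/ --h2-grid 0.1,0.25 --lam-grid 0,1,10 --out sweep.csv
connnlm compare --bundle bundle/ --out compare.csv
```

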