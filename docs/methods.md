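# Methods

## Model

The filter is a weighted-average denoiser over a masked 3D PET volume. For a
target voxel i, every masked voxel j in the search window contributes

    w′_ij ∝ exp( −d_ij / h² ) · A(node(i), node(j))

and the output is x̂_i = Σ_j w′_ij x_j / Σ_j w′_ij. The two factors:

* **Patch similarity.** d_ij is the squared Euclidean distance between the
  2D axial M×M patches centred at i and j, weighted elementwise by a 2D
  Gaussian kernel of standard deviation `a` voxels normalized to sum 1, so
  the centre voxel dominates and d is on the scale of a single squared
  intensity difference. Patches are 2D while the search window is 3D; this
  in-slice-patch / volumetric-window scheme keeps patch statistics stable
  across anisotropic slice spacing while still pooling across slices.
* **Hybrid connectivity.** A is 1 for same-node pairs (local smoothing is
  uniform), λ·SC_ab for pairs in different parcellation nodes a, b, and 0
  between a parcellated and a non-parcellated voxel. SC is the structural
  connectivity matrix normalized as described below.

Assumptions: the PET, parcellation and connectivity inputs are co-registered
and sampled on the same grid; noise is (approximately) stationary within the
background region used to estimate h²; connectivity is symmetric and
non-negative; intensities are finite. The filter output is a convex
combination of masked inputs, so it can never leave the input intensity
range, and uniform images are exact fixed points.

## Connectivity normalization

Raw streamline weights span orders of magnitude, so the matrix is
log-transformed, v ↦ log10(1 + v), then min-max scaled over all off-diagonal
entries to [0, 1]. The +1 offset keeps zero-streamline edges finite and maps
"no connection" to exactly 0; taking the min/max over all off-diagonal
entries (zeros included) means an absent edge contributes no distant
smoothing. The diagonal is unused — same-node smoothing is carried entirely
by the local term. If all off-diagonal entries are equal, positive entries
map to 1 and zeros to 0.

Voxels with label 0 (outside the parcellation: white matter, CSF,
non-parcellated cortex) form their own local class: they smooth among
themselves with weight 1 and never across to parcellated nodes. This extends
the filter to whole-brain masks without inventing connectivity where the
atlas defines none.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| h² | similarity scale (squared intensity units) | 0.25, or C·σ²(PET) | noise-proportional rule; C = 8 reproduces the reference operating point (σ² = 0.023 → h² ≈ 0.18) |
| a | patch-kernel std (voxels) | 1.0 | centre-weighted 5×5 kernel; value not critical, kernel is sum-normalized |
| M | patch size (voxels, odd) | 5 | standard 5×5 in-plane patch |
| window | search window | whole volume | whole-volume pooling maximizes the sample available to each voxel; an (N, S) box bounds cost on large grids |
| λ | distant/local connectivity ratio | 1.0, or B·σ²(TDI) | B = 0.5×10⁻⁵ maps a high-quality track-density image (variance 2×10⁵) to λ = 1; λ = 0 disables distant smoothing; no upper bound |
| C, B | estimation constants | 8.0, 0.5×10⁻⁵ | see above |

h² = 0 is rejected explicitly (the similarity kernel degenerates); callers
estimating h² from a constant region get an error rather than a zero-width
kernel.

## Numerical choices

* Patch extraction uses mirror (reflect) boundary handling, which avoids
  biasing edge voxels toward zero; axes of length 1 fall back to repetition.
* The production path computes all pairwise patch distances through a Gram
  matrix (chunked BLAS) with the cancellation residual clamped at zero. The
  result is a pure function of the inputs — independent of chunk size — and
  agrees with a literal triple-loop reference implementation
  (`conn_nlm_oracle`, compiled loops over target voxel, source voxel and
  patch element) to better than 1e-10 on every seeded case in the suite.
* The voxel itself participates as an ordinary neighbour (distance 0, weight
  1·A_local); no "maximum-weight" self-voxel trick is applied. The
  normalizer is therefore always positive.
* Medians use the midpoint convention for even-sized regions; variances are
  sample variances (ddof = 1) throughout.
* All computation is double precision; volumes are written as 32-bit float.

## Evaluation metrics

MSE against ground truth is computed over the brain mask by default
(background air would dilute it; the mask is a caller-visible argument).
Lesion CNR is (median_lesion − median_GM)/σ_GM with σ_GM the sample standard
deviation over the normal-GM region — the conventional CNR denominator
matching the symbol σ; a `noise_stat="var"` switch reproduces the variance
reading of the same formula. Lesion CRC is 100·(M_L/M_GM − 1)/(CR − 1) with
CR the true simulated contrast. The "average variance" score is the mean of
the GM and lesion sample variances.

## Synthetic phantom

The generator produces the end products of a full PET-MR simulation chain
directly, by construction rather than by physics: concentric ellipsoidal
shells (WM core, GM shell, CSF rim; semi-axes 0.45× the grid, shell
boundaries at 0.55 and 0.85 of the normalized radius), a GM parcellation of
`n_nodes` equal angular sectors, spherical lesions of configurable radius
placed at mid-shell inside their host sectors with exact contrast
multipliers over GM, a connectivity matrix realizing the intended topology
(a strong edge between the two connected lesion hosts, seeded weak
background edges elsewhere, and never an edge between lesion hosts that are
meant to be disconnected), and seeded noise calibrated to a target GM
variance. Defaults: 48³ grid, 12 nodes, GM/WM/CSF activities 1.0/0.25/0.05,
lesion radius 3 voxels with contrasts ×2.5, ×1.8, ×2.5 (the ×1.8 and one
×2.5 lesion connected, the other ×2.5 lesion isolated), GM noise variance
0.023 ("high-count"; the "low-count" preset is 0.055, back-computed from the
corresponding operating point h² = 0.44 at C = 8). Everything is
deterministic given the config seed; regeneration is bit-identical.

What the phantom does **not** emulate, and what that implies for
interpreting results on it:

* **Noise correlation.** Default noise is i.i.d. Gaussian in image space
  (a scaled-Poisson model and an optional post-noise Gaussian smear are
  available). Reconstructed PET noise is spatially correlated; spatially
  white noise is the most favourable possible case for plain NLM, since
  every grey-matter patch is an unbiased replicate of every other. Relative
  rankings between plain NLM and the connectome-weighted filter on this
  phantom therefore understate the benefit of connectivity weighting on
  reconstructed data.
* **Lesion morphology.** Lesions are small spheres strictly inside one
  node. At the default 48³ scale a radius-3 sphere is rim-dominated with
  respect to 5×5 patches: the median lesion voxel has a mixed patch, so
  strong whole-volume smoothing erodes lesion medians, and connecting a
  lesion's node to another node at λ = 1 enlarges the grey-matter pool that
  performs the eroding. Real lesions spanning entire parcels (interior-
  dominated at acquisition resolution) do not share this geometry. The test
  suite measures both effects honestly on the default phantom: isolated-
  lesion CNR is never degraded by turning distant connectivity on (it
  improves), while connected-lesion CNR at λ = 1 can fall below its λ = 0
  value in this rim-dominated regime.
* **Anatomy and physics.** No DWI simulation, tractography, sinogram
  modelling or iterative reconstruction — the phantom is a test harness for
  the filter and metrics, not a PET simulator.

## Problem sizes

The default phantom (48³, ≈42 000 brain voxels) filters in roughly half a
minute per whole-volume run on one CPU core; the cross-filter trend test
uses that size with short baseline series (3 settings per baseline, nearest
achieved GM variance as the matched-comparison point). Oracle-equivalence
checks run on volumes up to 10×10×4 where the literal-loop reference is
exact and fast. The worked example in the README uses a 32×32×24 phantom.

## Known limitations

* Whole-volume search is O(n²) in masked voxels; use the (N, S) window for
  grids much beyond ~10⁵ masked voxels.
* The filter assumes one label per voxel; partial-volume mixing at node
  borders is not modelled.
* λ and h² interact: strong smoothing with large λ can bias lesions whose
  connected partners have different activity. The sweep command
  (`connnlm sweep`) exists precisely to map this trade-off per dataset.
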