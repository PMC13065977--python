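# Methods

This note documents the models, parameter choices, numerics and known
limitations of `gastrumap`, in the order of the pipeline.

## Radial phenotyping

A colony is reduced to 3 × 50 features: the mean nuclear intensity of
GATA3, BRA and SOX2 in 50 concentric annuli of width `radius/50`
(5 µm for the default 250 µm radius), ordered edge → center. Conventions
that the rest of the pipeline relies on:

* The colony center is the mean of all nucleus positions, not the image
  center — robust to imperfect well placement.
* Annuli are half-open in distance-from-edge, `[(i−1)w, i·w)`; a nucleus
  exactly at the center falls in the innermost bin; a nucleus outside the
  nominal radius is clamped into bin 1 with a warning. These tie-breaks
  make binning deterministic and exactly reproducible by a brute-force
  oracle (tested property).
* Empty annuli (possible at low density) are filled by linear interpolation
  between the nearest non-empty bins, flat at the ends, keeping every
  vector finite.
* Per-plate robust scaling `(x − p25)/(p75 − p25)` is fitted within each
  plate and returned as a reusable scaler; features with zero IQR are
  centered only (denominator 1, warning). Note that scaling amplifies
  noise on screen-wide-constant features to an SD of ≈ 0.74 regardless of
  the raw noise level — an intrinsic property of the normalization that
  sets the error floor of everything trained on scaled vectors (see the
  parametric-embedding section).
* Cytotoxicity: a treatment is flagged when its mean viable nucleus count
  is strictly below 0.5 × the untreated control ("below" ⇒ strict
  inequality; a treatment at exactly 50% is kept).

Nuclei detection (`imaging.detect_nuclei`) is a deliberately simple
pipeline — Gaussian smooth, Otsu (or fixed) threshold, hole filling,
dilation, connected components, distance-transform watershed splitting
seeded at regional maxima. It recovers synthetic renders to sub-pixel
centroid accuracy but is not tuned for real micrographs; structuring sizes
and thresholds are config entries. β-catenin activity extraction removes
the membrane-bound pool by adaptive thresholding (block 21, offset 5% of
the dynamic range), dilation (radius 2) and subtraction; a uniform frame
yields no membrane mask and passes through unchanged.

## Morphospace

Scaled 150-d profiles are embedded with t-SNE (perplexity 30, PCA
initialization, fixed seed; the seed is stored on the model). The embedding
is partitioned by a Gaussian KDE followed by watershed on the negated
density, seeded at the density maxima that survive an h-maxima prominence
prune (5% of the peak density). The cluster count is therefore data-driven.

**Bandwidth.** The KDE bandwidth is the median distance to the 10th nearest
neighbour (× a configurable factor, default 1), not a global Scott's rule:
t-SNE output is multi-scale — tight clusters separated by gaps an order of
magnitude larger than their width — and a global-variance bandwidth
over-smooths exactly the local structure the watershed must resolve.

**Failure modes.** A region is a failure mode if (i) its *raw* (unscaled)
composite profile's peak SOX2 or BRA falls below 50% of the screen-wide
peak for that marker, or (ii) its members' mean angular asymmetry exceeds
0.25. The asymmetry statistic is the circular resultant length of the mean
BRA intensity over 12 angular sectors in a ±5-bin annulus around the BRA
peak radius: 0 for a radially symmetric ring, ≈ 0.5+ for a one-sided
crescent. Raw composites are used because robust scaling destroys the
"marker absent" semantics (a scaled zero is not zero). Both thresholds are
configurable; they were fixed once against the synthetic generator's
canonical/crescent classes.

**Frozen boundaries.** New points (simulated or predicted phenotypes,
projected by ψ) are classified by nearest-grid-pixel lookup in the 512×512
watershed label map; points outside the grid snap to the border with a
warning. A teratogen call is membership of the failure-mode region set.

## Reaction–diffusion model

Explicit forward-Euler with a 5-point Laplacian on a 101×101 grid over the
500 µm square, masked to the disc; zero-flux (mirror) boundaries for Wnt
and Nodal at the disc edge. The default time step is 0.8 × the 2-D
stability bound `dx²/(4·max D)`; a user-supplied `dt` above the bound is
rejected with the bound in the message. (A coefficient of 0.4·dx²/max D —
i.e. 1.6 × the bound — is unstable for 2-D forward Euler; hence 0.2.)
Non-negativity of all fields and `b ∈ [0, 1]` are asserted every 50 steps.

BMP: `b = 1` everywhere until `t_loc`; at `t_loc` the interior
`r ≤ r_loc` is reset to 0 and evolves by pure diffusion, while the
peripheral ring `r > r_loc` is held at 1 (Dirichlet). This realizes
BMP signalling that collapses centrally but persists at the colony edge
and leaves a non-trivial edge-high gradient; a no-reset variant is
config-selectable (`bmp_interior_reset`). Initial conditions `u = v = 0`
(configurable `u0`, `v0`); Nodal is nucleated by its basal source `c_v`
since the relay term vanishes at `v = 0`.

**Parameter calibration.** Units are hours, µm and cells/colony; the full
coefficient table lives in `ModelParams` and round-trips through JSON. The
defaults were calibrated — once, before freezing — so that at the reference
density `c_d = 950` the decoded pattern is canonical, and so that Wnt/Nodal
penetration and mesoderm depth decrease with density across 750–1150
cells. The load-bearing choices:

* `a = 1.4e-3` puts `r_loc` at 162–200 µm across 750–1150 cells: denser
  colonies confine the active BMP ring to a thinner rim (less Wnt
  induction), on top of `h(d)` (with `c_m = 1`) scaling all Wnt sources
  from 1.21 down to 0.79 over the same span.
* `s_u = 1.2, K_u = 1, k_u = 0.35` make the Wnt kinetics bistable with an
  ignition threshold ≈ 0.3 and an excited branch ≈ 1.3–1.5: the BMP rim
  ignites an autocatalytic front that travels inward at a density-dependent
  speed, while `k_b = 0.08, t_loc = 4 h` keep the pre-localization uniform
  phase below the ignition threshold (no global ignition).
* The interior BRA ring requires the *edge* Nodal pool to finish rising
  before the Wnt gate opens there: `s_v = 6, k_v = 0.8, c_v = 0.1` make the
  Nodal relay fast relative to the edge Wnt rise, and `Wnt_thresh = 1.2`
  (σ-gate steepness `k_2 = 12`) opens the gate late at the edge but
  promptly behind the sharp interior front. BRA, the gated integral of
  ∂v/∂t, is then small at the rim (Nodal already saturated), large in the
  annulus the front sweeps, and zero in the never-reached core.

Grid-halving (101 → 201, dt/4) changes the final radial profiles by < 2%
in L2 (≈ 0.04% for Wnt/Nodal, ≈ 1% for BMP); intermediate-time profiles are
more sensitive because the moving front position carries the discretization
error.

## Fate decoding

GATA3 is the trapezoidal time-integral of BMP divided by
`1 + e^{−k₁(r − r_loc)}`; BRA integrates `σ(k₂(u − Wnt_thresh))·∂v/∂t`
with ∂v/∂t by centered differences on snapshots (one-sided at the ends);
SOX2 `= C_s(c₁ − c₂·GATA3 − c₃·BRA)` clamped at 0, with the GATA3/BRA
inputs normalized to [0, 1] (switchable) so `c₂, c₃` are scale-free.

For the 150-d simulated vector, GATA3 and BRA maps are normalized by their
own maxima, but SOX2 is divided by its fixed basal ceiling `c₁`:
normalizing SOX2 by its own maximum would cancel `C_s` out of the profile
entirely, flattening the SOX2-stability axis and contradicting the
monotonicity the parameter analysis depends on (every SOX2 bin increases
with `C_s` — a tested invariant).

## Parametric embedding ψ

150→128→64→2, ReLU after the hidden layers, trained full-batch with a
numpy Adam (lr 1e-3) on an 80/20 split, MSE loss, up to 1000 epochs, early
stopping (patience 50) and reduce-on-plateau lr decay (factor 0.5, window
20). Targets are standardized internally and de-standardized at the output;
weights use seeded uniform fan-in initialization, so retraining with one
seed is bit-stable.

ψ's per-point accuracy has a floor: replicate colonies of one treatment
differ only in noise, yet t-SNE scatters them over a blob of radius
~0.3–0.7 embedding units whose internal arrangement is noise-driven;
validation-based early stopping (correctly) refuses to memorize it. Median
held-in error therefore sits near the blob radius — roughly 7–14 × the
512-grid pixel — while cluster-membership preservation (≥ 95–100%) and
density-level agreement (JSD < 0.001, natural-log scale, shared-bandwidth
isotropic KDEs computed in log space) are excellent. Conclusions that
depend on *which region* a projection lands in are robust; conclusions at
sub-pixel coordinate precision are not supported by this architecture and
protocol.

## Structure → phenotype

The fallback molecular embedder hashes character 3-grams of the SMILES
string (md5, 4096 bins) and projects with a seeded Gaussian matrix to
768-d — deterministic, dependency-free, chemistry-blind; the transformer
backend is a hook for externally supplied pretrained weights and raises a
clear error otherwise. Classifier: 768→512→256→K, ReLU, inverted dropout
0.3, class-weighted cross-entropy with weight 3 on failure-mode clusters
(the cost-sensitive term), Adam lr 1e-3, 5-fold CV with early stopping on
the fold-out accuracy (patience 30); inference averages the five folds'
logits. 10% of compounds are held out (seeded) before any training. Ridge
residual models (α = 1) are fit per cluster on all training compounds of
that cluster, mapping embedding → (phenotype − cluster mean); a
single-member cluster degenerates to zero residual with a warning.
Prediction = cluster mean + ridge residual; scoring reports RMSE and cosine
against the replicate mean and the fraction of features within one
replicate SD (undefined for a single replicate).

## Parameter axes and the closed loop

The default grid is densities {750…1150, step 100} × C_s {0.6…1.4,
step 0.2}, one simulation per density (decoding re-run per C_s, which is
exact because C_s enters only the decoder). Each iso-density and
iso-stability contour of the projected grid is fitted with a degree-2
polynomial in chord-length parameterization; C_s at a point is
inverse-distance interpolated between the two nearest stability contours,
and a LinearNDInterpolator over the grid nodes (nearest-node fallback with
an extrapolation warning) inverts coordinates → (d, C_s) exactly at nodes.
For the self-contained analyses here, the grid is projected through a ψ
trained on the grid phenotypes' own 2-D principal components (×10) — the
recovery property is independent of which fixed 2-D map ψ approximates.
Closed-loop validation simulates from (measured density, inferred C_s) and
reports the distance to the original centroid plus RMSE/cosine against the
experimental profile; on off-grid probes the median C_s recovery error is
≈ 1% with phenotype cosine > 0.999.

## Synthetic data: what it does and does not emulate

The generator reproduces the *statistical structure* the pipeline assumes:
logistic-edged radial bands (smooth, differentiable ground truth), exact
per-colony nucleus counts on a jittered grid (quasi-uniform, so density is
read directly from counts), the four perturbation classes plus an
undifferentiated no-BMP4 control, replicate-level band-radius (SD 0.005 R)
and amplitude (log-normal SD 0.03) variability, per-nucleus Gaussian noise
(SD 5 on an amplitude of 100), per-plate affine batch effects (gain
0.85–1.15, offset 0–8), and compound libraries whose 768-d embeddings form
cluster Gaussians at separation `sep` (sep = 0 ⇒ label-free). The
asymmetric class displaces the whole fate pattern off-center by 0.25 R and
restricts the mesoderm to a crescent — both characteristic of real
symmetry-broken colonies and both visible to the radial features and the
angular statistic.

It does **not** emulate nuclear morphology, optics, z-structure, cell
crowding at domain boundaries, density-dependent band shifts, or
chemically meaningful SMILES. Passing tests therefore certify the
*pipeline* — binning, scaling, clustering, training, recovery — under
realistic noise, not performance on real micrographs or real chemistry.

## Known limitations

* The PDE coefficients are a calibrated working point, not fitted to
  measurements; only the qualitative density orderings and the canonical
  geometry are claimed.
* ψ cannot localize a projection below the replicate-scatter scale (see
  above).
* `detect_nuclei` and `bcat_activity` are validated on synthetic renders
  only.
* The teratogenicity confusion metrics are computed from supplied calls
  and truth labels; the package makes no claim about real-compound risk
  from the fallback embedder.
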