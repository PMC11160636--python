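# Methods

`mpfm` implements a multiscale analysis of resting-state fMRI built around
a hierarchical probabilistic matrix factorisation, a ground-truth
simulator of overlapping distributed and localised brain modes, a
group-ICA + dual-regression baseline, and the network-matrix, taxonomy and
subcomponent analyses that sit downstream of any mode decomposition. This
note records the models, the parameters that matter, the numerical
choices, and the limits of what the synthetic experiments can show.

## The generative model

Each subject-run BOLD matrix is modelled as

    D_sr = P_s · diag(h_sr) · A_sr + eps_sr

with `D_sr` of shape (voxels × time), `P_s` the subject's spatial maps
(voxels × modes), `h_sr` positive per-mode amplitudes, `A_sr` mode
timecourses (modes × time, unit variance per row), and `eps_sr` Gaussian
observation noise. Three hierarchies tie subjects to a group consensus:

* **Spatial maps — double-Gaussian mixture (DGMM).** Each voxel-mode
  weight is either *signal*, Gaussian around a group-level mean map with
  group-level variance, or *background*, zero-mean Gaussian with a shared
  variance. The group carries a per-voxel membership probability. This
  lets maps overlap freely while shrinking non-reproducible weights to
  zero — the property that separates the model from spatial ICA, which
  forbids overlap by construction.
* **Functional connectivity — Wishart hierarchy.** The precision matrix
  of each subject's timecourses has a Wishart prior whose scale carries
  the group's consensus connectivity; the subject posterior combines it
  with the timecourse scatter.
* **Amplitudes.** Gaussian hierarchy on log-amplitude; positivity is
  enforced by construction (signs live in the timecourses/maps).

Timecourses are *HRF-constrained*: after each regression update they are
projected onto the span of cosines convolved with a canonical
haemodynamic response function (double-gamma), with the cosine band
limited by the HRF magnitude spectrum (cutoff at 10% of peak magnitude).
This encodes that BOLD dynamics are slow and haemodynamically filtered.

## Inference

Fitting uses stochastic variational updates across subject batches:

1. **Initialisation.** A streaming incremental group PCA (MIGP) pass over
   subjects (default internal dimension 4 × n_modes) followed by seeded
   fixed-point ICA on the basis gives initial group maps; per-column
   two-Gaussian scale-mixture fits of the ICA maps give initial
   membership probabilities and the background variance; remaining
   hyperparameters start at weakly informative defaults (log-amplitude
   mean 0, variance 0.25; Wishart scale I/dof; observation variance 0.5
   on variance-normalised data).
2. **Batched updates.** Subjects are divided into batches (default batch
   size 50, each subject visited ≈ 2.5 times over the schedule; subjects
   are drawn with probability inversely weighted by visit count). Within
   a batch, subject coordinate updates (timecourses → amplitudes →
   precision → maps → residual variance, `inner_iters = 3` sweeps)
   alternate with a group update blended at the decaying step size
   `rho_t = (t + tau)^(-beta)` with `beta = 0.6`, `tau = 5`.
3. **Convergence.** The group model is updated at least
   `min_group_updates` times (default 200 — a desk-scale default; the
   reference cluster-scale runs of this model family use thousands) and
   stops early within a batch once the relative change of the group mean
   maps falls below `convergence_tol` (5e-5). Free-energy bookkeeping is
   replaced by reconstruction-error monitoring (recorded per subject
   sweep) and the group-map change criterion.
4. **Final pass.** Every subject's posterior is recomputed under the
   final group model. Reported group and subject maps are the posterior
   signal means gated by membership probability (the mixture-expected
   map); the ungated means are kept in memory as `raw_*` attributes.

Per-voxel map updates are Gauss–Seidel over modes with the DGMM prior:
each voxel-mode weight gets a Gaussian posterior under the signal and
background components and a responsibility from their marginal
likelihoods. The subject residual variance is a single scalar per run —
a per-voxel noise model was evaluated and discarded (it sharpened
localised timecourses but degraded distributed map recovery).

## The simulator

The generator emulates a multi-subject study in which six *distributed*
modes (2–3 contiguous voxel blocks each) coexist with six *localised*
modes that are sub-nodes of the distributed ones but carry distinct
timecourses:

* Per-mode coverage is solved so that, among covered voxels, the mean
  number of distributed modes covering a voxel is ≈ 1.3 (independent
  uniform block placement; `target_modes_per_voxel ≤ 1` switches to
  disjoint placement).
* Block weights are Gamma(3, 0.5) draws smoothed within each block
  (moving average, window 25% of block length). Smoothing keeps the
  support — and hence all overlap statistics — unchanged while making
  the weight profile parcel-like; with unsmoothed i.i.d. weights, any
  consensus group-map estimate is capped near |r| ≈ 0.8 against the
  generating maps once subject misalignment is present, which
  contradicts the recovery levels this kind of study reports.
* Localised blocks sit 95–100% inside one parent block, sized 30–60% of
  it, positioned so at least 25% of their voxels are also covered by a
  second distributed mode: sub-nodes live in genuinely shared cortical
  territory. This deep nesting is what makes localised modes hard for
  spatial ICA (they are spatially correlated with their hosts) while the
  DGMM decomposition can still separate them.
* Subject maps warp each block's endpoints with Gaussian jitter (sigma =
  (1 − target_overlap)/0.8 × block length, from the half-normal mean of
  the endpoint erosion), resample the weight profile onto the warped
  support, and add background Gaussian noise (sd 0.05). The calibration
  yields a mean support Dice of ≈ 0.83 between subject and group modes.
* Subject precisions are Wishart(dof = 100, Psi/dof) draws around a
  group precision; by default the group correlation between each
  localised mode and its parent is set to 0.3 (sub-nodes co-fluctuate
  moderately with their network) before SPD projection.
* Neural timecourses are correlated Gaussian draws, spectrally
  reweighted (smooth gain 3× below 0.1 Hz), soft-rectified
  (`x · sigmoid(x)`, approximating positivity-skewed activity; a flag
  disables it), and convolved with a random unit-norm draw dominated by
  the canonical double-gamma HRF (derivative weights ~N(0, 0.06²),
  canonical weight ≥ 0.8 of total). Amplitudes are lognormal(0, 0.2²).
  Observation noise is Gaussian with sd 1.0 — comparable to the
  per-voxel signal scale, chosen so that the ICA baseline's recovery
  sits in the published range for this kind of study.

Defaults describe the full study (10 datasets × 50 subjects × 2 runs,
10,000 voxels × 300 timepoints at TR 0.72 s). The evaluation harness and
acceptance script run a reduced *desk* size (3 datasets × 20 subjects,
2,000 voxels) chosen so a full two-method study completes in minutes on
one CPU; accuracy cells at desk size track the full-size values to
within roughly ±0.1.

What the simulator does **not** emulate: spatial autocorrelation of
noise, physiological/motion artefacts, multi-band sampling, registration
error, and 3-D geometry (voxels are a flat strip; blocks are 1-D
contiguous). Passing recovery tests therefore shows that the inference
separates overlapping multiscale modes under controlled misalignment and
noise — not that it is robust to every artefact of real scanner data.

## Evaluation

Estimated modes are matched to ground truth by Hungarian assignment on
absolute group-map correlations (greedy matching available for
sensitivity checks); matched-pair accuracy is mean |Pearson r|, split by
mode class: group maps; subject maps (averaged over subjects before
modes); timecourses (averaged over subject-runs before modes, compared
against the BOLD-convolved truth, since both methods estimate BOLD-space
timecourses; a flag switches to the neural-space reference). True modes
left unmatched score 0. The ICA baseline shares the MIGP basis with the
probabilistic fit so that method differences are not initialisation
differences.

## Netmats, taxonomy, subcomponents

* Temporal netmats are Tikhonov-regularised partial correlations
  (`rho = 0.01`, scaled by trace(C)/n_modes so the penalty is
  covariance-scale-invariant); runs are concatenated per subject.
  Spatial netmats are full map correlations. Between-subject consistency
  is each subject's vectorised upper triangle correlated with the mean
  of the others (leave-one-out; an all-pairs variant is available).
* Mode pairing across decompositions uses the same Hungarian assignment;
  reproducibility tiers count |r| ≥ 0.7 / 0.5–0.7 / < 0.5 with boundary
  values assigned to the higher tier. Binarisation is strict (> 0.3 by
  default) and overlap is Dice.
* Subcomponent extraction per low-order mode: weight the data by the
  mode's subject map; 5 spatial PCs per subject; group PCA of the
  concatenated PCs; regression of the group PCs onto each subject's
  weighted data; temporal ICA across subjects; winner-takes-all
  attribution of each subcomponent timecourse to low-order, primary or
  secondary candidates by highest subject-mean |r|. Significance is an
  unpaired t-test of the winner's per-subject |r| sample against the
  best candidate outside the winner's category, Bonferroni-corrected
  over subcomponents (the comparand is configurable). The
  temporally-exclusive variant regresses the other modes' timecourses
  out of the weighted data first; the spatially-exclusive variant
  regresses the other modes' maps out of both the weighting map and
  each timepoint's voxel pattern.

## Property-test regimes

Two downstream properties are exercised in regimes where the effect they
probe is expressed strongly enough to survive estimation noise at desk
problem sizes:

* **Planted-subcomponent attribution.** Localised sub-modes are given
  timecourses that co-fluctuate (r = 0.9) with a *non-parent* distributed
  mode and amplitudes 1.5× their hosts. Subcomponents extracted from the
  raw weighted data are then mostly attributed to the fine-scale
  (secondary) candidates; after temporally-exclusive processing the
  majority shifts to the large-scale modes themselves — the qualitative
  reversal that motivates the multiscale decomposition.
* **Consistency direction.** With sub-mode amplitudes 3× their hosts, a
  6-mode fit of 12-mode data mixes sub-mode signals into its timecourses
  in a subject-specific way and its temporal netmats lose
  between-subject consistency, while the 12-mode fit resolves them:
  consistency is higher at the higher model order. At default (equal)
  amplitudes this direction holds for netmats computed from the *true*
  timecourses but is masked in fitted netmats by localised-timecourse
  estimation noise at desk problem sizes — the high-amplitude regime is
  the one where the fitted decomposition can express the effect.

## Known limitations

* The inference is a compact re-derivation, not a port: free energy is
  not tracked, subject noise is a scalar per run, and the HRF constraint
  is a hard subspace projection rather than a learned autocorrelation
  model.
* Group maps estimated by consensus inherit a blur floor from subject
  misalignment; with the default warp level this caps group-map recovery
  around |r| ≈ 0.93–0.95 even for a perfect fit.
* Recovery of localised modes varies noticeably across simulated
  datasets (geometry draws differ in difficulty); means over few
  datasets carry sampling error of a few hundredths.
* NIfTI support covers 4-D volumes + binary masks; CIFTI is out of
  scope, and no spatial smoothing is applied to volumetric input.
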