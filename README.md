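# mpfm — multiscale probabilistic functional modes for resting-state fMRI

Resting-state fMRI is usually decomposed either into a handful of
large-scale networks (low-dimensional ICA or probabilistic modes) or into
hundreds of small parcels — but not both at once. `mpfm` is built around
the multiscale alternative: a single hierarchical decomposition in which
distributed networks and the localised sub-nodes living inside them
coexist as separate modes, each with its own spatial map, amplitude and
timecourse per subject and run.

The package is aimed at methods researchers who want to study when and
why multiscale decompositions beat single-scale ones, under fully known
ground truth. It provides:

* **`mpfm.synthetic_data`** — a seeded simulator of multi-subject studies:
  overlapping distributed modes (Gamma-weighted contiguous blocks,
  ~1.3 modes per covered voxel), localised modes nested inside them with
  distinct timecourses, subject-specific spatial warps (~83% support
  overlap with the group), a Wishart hierarchy linking subject functional
  connectivity to a group consensus, low-frequency-amplified semi-Gaussian
  neural timecourses convolved with randomly drawn HRFs, and additive
  noise — with the full ground truth retained.
* **`mpfm.pfm_inference`** — the hierarchical Bayesian decomposition
  `D_sr = P_s · diag(h_sr) · A_sr + eps_sr` with a double-Gaussian
  mixture spatial prior, HRF-constrained timecourses, Wishart-linked
  precisions and log-Gaussian amplitudes, fitted by stochastic
  variational updates over subject batches (step size
  `(t + tau)^(-beta)`, MIGP + ICA initialisation).
* **`mpfm.ica_baseline`** — group spatial ICA + dual regression on the
  same MIGP basis, the standard single-scale comparison.
* **`mpfm.netmats`** — spatial netmats, Tikhonov-regularised partial
  temporal netmats, Fisher transform, between-subject consistency,
  primary/secondary feature blocks and SVD feature reduction.
* **`mpfm.mode_taxonomy`** — Hungarian mode pairing across
  decompositions, primary/secondary labelling, reproducibility tiers,
  binarised-support Dice overlap.
* **`mpfm.subcomponents`** — temporally distinct subcomponents within
  each large-scale mode (weighted PCA → temporal ICA), winner-takes-all
  attribution, and the temporally/spatially exclusive variants.
* **`mpfm.evaluation`** — recovery scoring against ground truth and the
  full two-method simulation study.

See `docs/methods.md` for the model details, parameter choices and
limitations.

## Worked example

```python
from mpfm.synthetic_data import SimulationConfig, simulate_dataset
from mpfm.pfm_inference import InferenceConfig, fit
from mpfm.evaluation import recovery_accuracy
from mpfm.core_io import preprocess

cfg = SimulationConfig(n_subjects=20, n_voxels=2000, seed=0)
dataset, truth = simulate_dataset(cfg, rng_seed=1000)

pre = dataset.map(preprocess)
dec = fit(pre, InferenceConfig(n_modes=12, seed=1), preprocess_data=False)

cells = recovery_accuracy(dec, truth)
for quantity in ("group_map", "subject_map", "timecourse"):
    d = cells[quantity]["distributed"]
    l = cells[quantity]["localised"]
    print(f"{quantity:12s}  distributed {d:.2f}   localised {l:.2f}")
```

Output from this exact script:

```
group_map     distributed 0.86   localised 0.70
subject_map   distributed 0.87   localised 0.66
timecourse    distributed 0.89   localised 0.47
```

Each number is the mean absolute Pearson correlation between estimated
and true quantities after optimal mode matching: this 12-mode fit
recovered the distributed networks at |r| ≈ 0.86–0.89 at both group and
subject level, and the localised sub-modes at ≈ 0.66–0.70 spatially with
noisier timecourses (≈ 0.47) — the hardest quantity, as expected for
modes nested inside a stronger host network. Accuracies vary by several
hundredths across simulated dataset draws.

The same pipeline is scriptable from the shell:

```bash
mpfm simulate --seed 0 --out study/
mpfm fit-pfm  --data study/ --modes 12 --seed 1 --out decomp_pfm/
mpfm fit-ica  --data study/ --modes 12 --seed 1 --out decomp_ica/
mpfm netmats  --decomp decomp_pfm/ --flavour temporal --rho 0.01 --out netmats/
mpfm taxonomy --high decomp_pfm/ --low decomp_ica/ --out taxonomy.json
mpfm evaluate --scale desk --seed 0 --out report/
```

All commands are deterministic given `--seed`: re-running one reproduces
its outputs byte for byte.

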