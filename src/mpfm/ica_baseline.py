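"""Group spatial ICA + dual regression: the standard single-scale baseline.

Group maps come from fixed-point spatial ICA on the shared incremental
group-PCA (MIGP) basis — the same spatial basis the probabilistic
decomposition is initialised from, so method differences are not driven by
initialisation. Subject timecourses and maps come from the two stages of
dual regression; mode amplitudes are the timecourse standard deviations.
"""

from __future__ import annotations

import numpy as np

from mpfm._ica import fixed_point_ica
from mpfm.core_io import BOLDDataset, ModeDecomposition

__all__ = ["group_ica", "dual_regression", "fit_ica_dr"]


def group_ica(basis: np.ndarray, n_modes: int, rng_seed: int) -> np.ndarray:
    """Fixed-point spatial ICA on a (components x voxels) basis.

    Returns group spatial maps of shape ``(n_voxels, n_modes)`` scaled to
    unit variance across voxels. Deterministic given the seed; restarts on
    non-convergence.
    """
    basis = np.asarray(basis, float)
    if basis.shape[0] < n_modes:
        raise ValueError("basis must have at least n_modes rows")
    maps = fixed_point_ica(basis.T, n_modes, rng_seed)
    return maps


def dual_regression(group_maps: np.ndarray,
                    dataset: BOLDDataset) -> ModeDecomposition:
    """Two-stage dual regression of a dataset on group spatial maps.

    Stage 1 regresses each run (voxels x time) on the group maps to obtain
    subject timecourses; stage 2 regresses each run on the
    variance-normalised timecourses to obtain subject maps (averaged over
    runs per subject). Amplitudes are the per-mode standard deviation of
    the stage-1 timecourses.
    """
    G = np.asarray(group_maps, float)
    if G.shape[0] != dataset.n_voxels:
        raise ValueError("group maps and data must share the voxel dimension")
    rank = np.linalg.matrix_rank(G)
    if rank < G.shape[1]:
        corr = np.corrcoef(G.T)
        bad = [(i, j) for i in range(G.shape[1]) for j in range(i + 1, G.shape[1])
               if abs(corr[i, j]) > 0.999]
        raise ValueError(f"rank-deficient group maps; collinear pairs: {bad}")

    pinv_G = np.linalg.pinv(G)
    dec = ModeDecomposition(method="ica_dr", group_maps=G.copy())
    per_subject_maps: dict[str, list[np.ndarray]] = {}
    for run in dataset.runs:
        tc = pinv_G @ run.data  # stage 1: (modes, time)
        amp = tc.std(axis=1)
        sd = np.where(amp == 0, 1.0, amp)
        tc_norm = tc / sd[:, None]
        # stage 2: regress each voxel's timeseries on normalised timecourses
        if np.allclose(tc_norm, 0):
            maps = np.zeros_like(G)
        else:
            maps = run.data @ np.linalg.pinv(tc_norm)
        key = (run.subject_id, run.run_id)
        dec.timecourses[key] = tc
        dec.amplitudes[key] = amp
        per_subject_maps.setdefault(run.subject_id, []).append(maps)
    for sid, stack in per_subject_maps.items():
        dec.subject_maps[sid] = np.mean(stack, axis=0)
    return dec


def fit_ica_dr(dataset: BOLDDataset, n_modes: int, rng_seed: int,
               basis: np.ndarray | None = None,
               migp_dim: int | None = None) -> ModeDecomposition:
    """Full baseline pipeline: (shared) MIGP basis -> group spatial ICA ->
    dual regression. ``basis`` may be supplied to reuse the initialisation
    of a probabilistic fit on the same data."""
    from mpfm.pfm_inference import migp

    if basis is None:
        basis = migp(dataset, migp_dim or 4 * n_modes, rng_seed)
    maps = group_ica(basis, n_modes, rng_seed)
    dec = dual_regression(maps, dataset)
    dec.meta.update({"seed": int(rng_seed), "n_modes": int(n_modes)})
    return dec
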