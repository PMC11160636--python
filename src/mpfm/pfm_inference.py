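"""Hierarchical probabilistic functional mode decomposition.

The model factorises each subject-run BOLD matrix as
``D_sr = P_s H_sr A_sr + eps_sr`` with

* ``P_s`` subject spatial maps under a double-Gaussian mixture (DGMM)
  spatial prior: a per-voxel signal component tied to group-level mean and
  variance maps, and a zero-mean background component with shared variance;
* ``A_sr`` run timecourses, constrained to haemodynamically plausible
  dynamics by projection onto an HRF-convolved cosine basis, with a Wishart
  hierarchy over their precision matrices linking subject functional
  connectivity to a group consensus;
* ``H_sr`` positive per-mode amplitudes with a Gaussian hierarchy on the
  log scale.

Inference is stochastic variational Bayes: subjects are visited in batches;
within a batch, coordinate-wise subject updates alternate with group
updates blended at a decaying step size ``rho_t = (t + tau)^(-beta)``.
Initialisation uses MELODIC-style incremental group PCA (MIGP) followed by
seeded fixed-point ICA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from mpfm._ica import fixed_point_ica
from mpfm.core_io import (
    BOLDDataset,
    BOLDRun,
    ModeDecomposition,
    config_hash,
    hrf_temporal_basis,
    preprocess,
    rng_from,
)

__all__ = [
    "InferenceConfig",
    "GroupModel",
    "SubjectPosterior",
    "migp",
    "initialise_group",
    "update_subject",
    "step_size",
    "update_group",
    "fit",
    "backproject_maps",
]


@dataclass
class InferenceConfig:
    """Stochastic variational inference settings.

    ``forget_rate_beta`` and ``delay_tau`` parameterise the step-size
    schedule ``rho_t = (t + tau)^(-beta)``; ``batch_size`` and
    ``mean_visits`` control how subjects are divided into batches (each
    subject is visited ~``mean_visits`` times across batches);
    ``min_group_updates`` is the minimum number of group-model updates
    before the convergence criterion (relative group-map change below
    ``convergence_tol``) may stop the fit.
    """

    n_modes: int = 12
    batch_size: int = 50
    mean_visits: float = 2.5
    min_group_updates: int = 200
    forget_rate_beta: float = 0.6
    delay_tau: float = 5.0
    inner_iters: int = 3
    migp_dim: int | None = None  # default 4 * n_modes
    seed: int = 0
    convergence_tol: float = 5e-5
    hrf_support: float = 24.0
    group_wishart_dof: float | None = None  # default n_modes + 40

    def __post_init__(self):
        if not (0.5 < self.forget_rate_beta <= 1.0):
            raise ValueError("forget_rate_beta must lie in (0.5, 1]")
        if self.delay_tau < 0:
            raise ValueError("delay_tau must be >= 0")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")

    @property
    def effective_migp_dim(self) -> int:
        return self.migp_dim if self.migp_dim is not None else 4 * self.n_modes

    @property
    def effective_wishart_dof(self) -> float:
        if self.group_wishart_dof is not None:
            return float(self.group_wishart_dof)
        return float(self.n_modes + 40)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class GroupModel:
    """Group-level parameters shared across subjects."""

    map_mean: np.ndarray  # (V, M) signal-component mean
    map_var: np.ndarray  # (V, M) signal-component variance
    membership_prob: np.ndarray  # (V, M) P(signal component)
    noise_map_var: float  # background spatial component variance
    wishart_scale: np.ndarray  # (M, M) SPD
    wishart_dof: float
    amp_mean: np.ndarray  # (M,) mean of log-amplitude
    amp_var: np.ndarray  # (M,) variance of log-amplitude
    obs_noise_var: float
    update_count: int = 0

    def validate(self) -> None:
        if np.any(self.map_var <= 0) or self.noise_map_var <= 0:
            raise ValueError("variances must be positive")
        if np.any((self.membership_prob < 0) | (self.membership_prob > 1)):
            raise ValueError("membership_prob must lie in [0, 1]")
        if self.wishart_dof < self.map_mean.shape[1]:
            raise ValueError("wishart_dof must be >= n_modes")
        if np.linalg.eigvalsh(self.wishart_scale).min() <= 0:
            raise ValueError("wishart_scale must be SPD")

    @property
    def n_modes(self) -> int:
        return self.map_mean.shape[1]

    @property
    def expected_precision(self) -> np.ndarray:
        return self.wishart_dof * self.wishart_scale

    @property
    def expected_maps(self) -> np.ndarray:
        """Posterior-expected spatial maps (signal mean gated by membership)."""
        return self.membership_prob * self.map_mean

    def copy(self) -> "GroupModel":
        return GroupModel(
            map_mean=self.map_mean.copy(),
            map_var=self.map_var.copy(),
            membership_prob=self.membership_prob.copy(),
            noise_map_var=float(self.noise_map_var),
            wishart_scale=self.wishart_scale.copy(),
            wishart_dof=float(self.wishart_dof),
            amp_mean=self.amp_mean.copy(),
            amp_var=self.amp_var.copy(),
            obs_noise_var=float(self.obs_noise_var),
            update_count=int(self.update_count),
        )


@dataclass
class SubjectPosterior:
    """Variational posterior for one subject."""

    map_mean: np.ndarray  # (V, M)
    map_var: np.ndarray  # (V, M)
    map_membership: np.ndarray  # (V, M)
    tc_mean: dict = field(default_factory=dict)  # run_id -> (M, T)
    tc_var: dict = field(default_factory=dict)  # run_id -> (M,)
    amplitude: dict = field(default_factory=dict)  # run_id -> (M,)
    precision: np.ndarray | None = None  # (M, M)
    residual_var: dict = field(default_factory=dict)  # run_id -> float
    recon_history: list = field(default_factory=list)


# --------------------------------------------------------------------------
# initialisation: MIGP + fixed-point ICA
# --------------------------------------------------------------------------


def migp(dataset: BOLDDataset, internal_dim: int, rng_seed: int) -> np.ndarray:
    """MELODIC-style incremental group PCA.

    A single streaming pass over subjects (random order): the running
    basis is stacked with each subject's temporally concatenated data and
    reduced back to ``internal_dim`` rows by SVD, rows scaled by singular
    values. The result approximates the top left singular subspace of the
    full temporal concatenation.

    Returns a ``(internal_dim, n_voxels)`` spatial basis.
    """
    if internal_dim > dataset.n_voxels:
        raise ValueError("internal_dim cannot exceed the voxel count")
    rng = rng_from(rng_seed, "migp")
    order = rng.permutation(dataset.subjects)
    W: np.ndarray | None = None
    for sid in order:
        block = np.concatenate([r.data.T for r in dataset.runs_for(sid)],
                               axis=0)  # (time, voxels)
        stacked = block if W is None else np.concatenate([W, block], axis=0)
        k = min(internal_dim, stacked.shape[0])
        _, s, vt = np.linalg.svd(stacked, full_matrices=False)
        W = s[:k, None] * vt[:k]
    assert W is not None
    return W


def _two_component_membership(col: np.ndarray, n_iter: int = 25):
    """EM for a zero-mean two-Gaussian scale mixture on one map column.

    Returns (responsibility of the wide/signal component, signal variance,
    background variance).
    """
    x2 = col**2
    v_all = float(np.mean(x2))
    v_sig = 4.0 * v_all
    v_bg = 0.25 * v_all + 1e-12
    pi = 0.2
    for _ in range(n_iter):
        log1 = -0.5 * (np.log(v_sig) + x2 / v_sig) + np.log(pi + 1e-12)
        log0 = -0.5 * (np.log(v_bg) + x2 / v_bg) + np.log(1 - pi + 1e-12)
        r = expit(log1 - log0)
        w = r.sum()
        if w < 1.0 or (len(col) - w) < 1.0:
            break
        v_sig = float((r @ x2) / w) + 1e-12
        v_bg = float(((1 - r) @ x2) / (len(col) - w)) + 1e-12
        pi = float(w / len(col))
        if v_sig < v_bg:  # keep 'signal' the wide component
            v_sig, v_bg = v_bg, v_sig
            r = 1.0 - r
            pi = 1.0 - pi
    return r, v_sig, v_bg


def initialise_group(basis: np.ndarray, n_modes: int,
                     rng_seed: int) -> GroupModel:
    """Group model from spatial ICA on the MIGP basis plus weak hyperpriors.

    The unmixed ICA maps set the signal-component means; per-column
    two-Gaussian fits of map values give the membership probabilities and
    the background variance. Remaining hyperparameters start at weakly
    informative defaults. Deterministic given the seed.
    """
    basis = np.asarray(basis, float)
    if basis.shape[0] < n_modes:
        raise ValueError("basis must have at least n_modes rows")
    maps = fixed_point_ica(basis.T, n_modes, rng_seed)  # (V, M), unit sd
    V = maps.shape[0]
    membership = np.empty_like(maps)
    map_var = np.empty_like(maps)
    bg_vars = []
    for j in range(n_modes):
        r, v_sig, v_bg = _two_component_membership(maps[:, j])
        membership[:, j] = np.clip(r, 0.0, 1.0)
        map_var[:, j] = v_sig
        bg_vars.append(v_bg)
    group = GroupModel(
        map_mean=maps,
        map_var=map_var,
        membership_prob=membership,
        noise_map_var=float(np.mean(bg_vars)),
        wishart_scale=np.eye(n_modes) / (n_modes + 40.0),
        wishart_dof=float(n_modes + 40),
        amp_mean=np.zeros(n_modes),
        amp_var=np.full(n_modes, 0.25),
        obs_noise_var=0.5,
    )
    group.validate()
    return group


# --------------------------------------------------------------------------
# subject-level coordinate updates
# --------------------------------------------------------------------------


def update_subject(runs: list[BOLDRun], group: GroupModel,
                   config: InferenceConfig,
                   warm: SubjectPosterior | None = None,
                   tc_basis: dict | None = None) -> SubjectPosterior:
    """Variational update of one subject's posterior under the group model.

    Each of ``config.inner_iters`` sweeps performs: (i) per-run Bayesian
    regression of the data on amplitude-scaled maps with the Wishart
    expected precision as timecourse prior, followed by projection onto the
    HRF-bandlimited temporal basis; (ii) per-voxel DGMM map updates
    (Gauss-Seidel over modes) yielding Gaussian posteriors and membership
    responsibilities; (iii) positive amplitude updates reconciling
    timecourse scale with the log-amplitude hyperprior; (iv) a Wishart
    precision update from timecourse second moments; (v) residual variance
    from the reconstruction error.
    """
    M = group.n_modes
    Vx = group.map_mean.shape[0]
    run_ids = [r.run_id for r in runs]
    data = {r.run_id: r.data for r in runs}
    T_tot = sum(d.shape[1] for d in data.values())
    if tc_basis is None:
        tc_basis = {}
    for r in runs:
        if r.data.shape[1] not in tc_basis:
            tc_basis[r.data.shape[1]] = hrf_temporal_basis(
                r.data.shape[1], r.tr)

    if warm is not None:
        P = warm.map_mean.copy()
        h = {rid: warm.amplitude[rid].copy() for rid in run_ids}
        E_alpha = (warm.precision.copy() if warm.precision is not None
                   else group.expected_precision)
        sigma2 = {rid: warm.residual_var.get(rid, group.obs_noise_var)
                  for rid in run_ids}
    else:
        P = group.expected_maps.copy()
        h = {rid: np.exp(group.amp_mean.copy()) for rid in run_ids}
        E_alpha = group.expected_precision
        sigma2 = {rid: group.obs_noise_var for rid in run_ids}

    post = SubjectPosterior(
        map_mean=P,
        map_var=np.maximum(group.map_var.copy(), 1e-8),
        map_membership=group.membership_prob.copy(),
    )
    log_amp_prior_prec = 1.0 / np.maximum(group.amp_var, 1e-6)
    pi = np.clip(group.membership_prob, 1e-6, 1.0 - 1e-6)
    logit_pi = np.log(pi) - np.log1p(-pi)
    v0 = max(group.noise_map_var, 1e-8)

    A = {}
    for sweep in range(config.inner_iters):
        # (i) timecourses per run
        for rid in run_ids:
            D = data[rid]
            X = P * h[rid][None, :]
            XtX = X.T @ X
            prec = XtX / sigma2[rid] + E_alpha
            rhs = (X.T @ D) / sigma2[rid]
            try:
                A_r = np.linalg.solve(prec, rhs)
                cov = np.linalg.inv(prec)
            except np.linalg.LinAlgError:
                raise RuntimeError("non-finite/singular timecourse update; "
                                   "subject state dump: "
                                   f"|P|max={np.abs(P).max():.3g}")
            B = tc_basis[D.shape[1]]
            A_r = (A_r @ B) @ B.T  # HRF-constrained temporal subspace
            A[rid] = A_r
            post.tc_var[rid] = np.maximum(np.diag(cov), 1e-12)

        # (iii) amplitudes: absorb timecourse scale, shrink on the log scale
        for rid in run_ids:
            T_r = A[rid].shape[1]
            scale = A[rid].std(axis=1)
            scale = np.maximum(scale, 1e-8)
            A[rid] = A[rid] / scale[:, None]
            raw = h[rid] * scale
            log_h = (T_r * np.log(np.maximum(raw, 1e-8))
                     + log_amp_prior_prec * group.amp_mean) / (
                         T_r + log_amp_prior_prec)
            h[rid] = np.exp(log_h)

        # (iv) precision: Wishart posterior from timecourse second moments
        S = np.zeros((M, M))
        for rid in run_ids:
            S += A[rid] @ A[rid].T
        V_post = np.linalg.inv(np.linalg.inv(group.wishart_scale) + S)
        E_alpha = (group.wishart_dof + T_tot) * 0.5 * (V_post + V_post.T)
        post.precision = E_alpha

        # (ii) maps: Gauss-Seidel DGMM update over modes, runs concatenated
        Z = np.concatenate([h[rid][:, None] * A[rid] for rid in run_ids],
                           axis=1)  # (M, T_tot)
        Dcat = np.concatenate([data[rid] for rid in run_ids], axis=1)
        sig2 = float(np.mean([sigma2[rid] for rid in run_ids]))
        Y = Dcat @ Z.T  # (V, M)
        G2 = Z @ Z.T  # (M, M)
        for k in range(M):
            zz = max(G2[k, k], 1e-12)
            proj = Y[:, k] - P @ G2[:, k] + P[:, k] * zz
            lam = zz / sig2
            b = proj / zz
            Vg = np.maximum(group.map_var[:, k], 1e-10)
            prec1 = lam + 1.0 / Vg
            mean1 = (proj / sig2 + group.map_mean[:, k] / Vg) / prec1
            prec0 = lam + 1.0 / v0
            mean0 = (proj / sig2) / prec0
            ll1 = -0.5 * (np.log(Vg + 1.0 / lam)
                          + (b - group.map_mean[:, k]) ** 2 / (Vg + 1.0 / lam))
            ll0 = -0.5 * (np.log(v0 + 1.0 / lam) + b**2 / (v0 + 1.0 / lam))
            r = expit(logit_pi[:, k] + ll1 - ll0)
            new_col = r * mean1 + (1.0 - r) * mean0
            second = (r * (1.0 / prec1 + mean1**2)
                      + (1.0 - r) * (1.0 / prec0 + mean0**2))
            post.map_membership[:, k] = r
            post.map_var[:, k] = np.maximum(second - new_col**2, 1e-12)
            P[:, k] = new_col

        if not np.all(np.isfinite(P)):
            raise RuntimeError("non-finite map update; aborting subject sweep")

        # (v) residual variance + reconstruction monitoring
        Yp = Dcat @ Z.T
        rss = (np.sum(Dcat**2) - 2.0 * np.sum(P * Yp)
               + np.sum((P.T @ P) * G2))
        rss = max(rss, 0.0)
        res_var = max(rss / Dcat.size, 1e-8)
        for rid in run_ids:
            sigma2[rid] = res_var
        post.recon_history.append(res_var)

    post.map_mean = P
    for rid in run_ids:
        post.tc_mean[rid] = A[rid]
        post.amplitude[rid] = h[rid]
        post.residual_var[rid] = sigma2[rid]
    return post


def step_size(t: int, config: InferenceConfig) -> float:
    """Stochastic-update weight ``rho_t = (t + tau)^(-beta)``."""
    if t < 1:
        raise ValueError("update index starts at 1")
    return float((t + config.delay_tau) ** (-config.forget_rate_beta))


# --------------------------------------------------------------------------
# group-level updates
# --------------------------------------------------------------------------


def update_group(group: GroupModel, batch: list[SubjectPosterior],
                 rho: float) -> GroupModel:
    """Blend batch-level sufficient statistics into the group model.

    Every natural parameter moves as ``(1 - rho) * old + rho * batch``.
    """
    if not batch:
        raise ValueError("batch must be non-empty")
    if not (0.0 < rho <= 1.0):
        raise ValueError("rho must lie in (0, 1]")
    out = group.copy()
    n = len(batch)

    stack = np.stack([p.map_mean for p in batch])
    g_mean = stack.mean(axis=0)
    second = np.mean(np.stack([p.map_var + p.map_mean**2 for p in batch]),
                     axis=0)
    g_var = np.maximum(second - g_mean**2, 1e-8)
    g_pi = np.mean(np.stack([p.map_membership for p in batch]), axis=0)
    # background variance from low-membership posterior mass
    w_bg = np.sum([np.sum(1.0 - p.map_membership) for p in batch])
    m_bg = np.sum([np.sum((1.0 - p.map_membership)
                          * (p.map_var + p.map_mean**2)) for p in batch])
    g_v0 = float(m_bg / max(w_bg, 1.0))

    precs = [p.precision for p in batch if p.precision is not None]
    g_prec = np.mean(np.stack(precs), axis=0) if precs else \
        group.expected_precision

    log_amps = np.concatenate(
        [np.log(np.maximum(a, 1e-8))[None, :]
         for p in batch for a in p.amplitude.values()], axis=0)
    g_amp_mean = log_amps.mean(axis=0)
    g_amp_var = np.maximum(log_amps.var(axis=0), 1e-3)
    g_noise = float(np.mean([rv for p in batch
                             for rv in p.residual_var.values()]))

    out.map_mean = (1 - rho) * group.map_mean + rho * g_mean
    out.map_var = np.maximum((1 - rho) * group.map_var + rho * g_var, 1e-8)
    out.membership_prob = np.clip(
        (1 - rho) * group.membership_prob + rho * g_pi, 0.0, 1.0)
    out.noise_map_var = max((1 - rho) * group.noise_map_var + rho * g_v0,
                            1e-8)
    new_scale = ((1 - rho) * group.wishart_scale
                 + rho * g_prec / group.wishart_dof)
    out.wishart_scale = _spd_repair(new_scale)
    out.amp_mean = (1 - rho) * group.amp_mean + rho * g_amp_mean
    out.amp_var = np.maximum((1 - rho) * group.amp_var + rho * g_amp_var,
                             1e-3)
    out.obs_noise_var = max((1 - rho) * group.obs_noise_var + rho * g_noise,
                            1e-8)
    out.update_count = group.update_count + 1
    return out


def _respawn_duplicate_modes(group: GroupModel, basis: np.ndarray,
                             batch: list[SubjectPosterior] | None = None,
                             corr_thresh: float = 0.85,
                             tc_thresh: float = 0.5) -> list[int]:
    """Reinitialise modes that have collapsed onto another mode.

    A pathological duplicate models the same signal twice: its group map
    *and* its timecourses track another mode's (legitimate multiscale
    pairs overlap spatially but keep distinct dynamics). When a pair
    exceeds both thresholds, the weaker member (smaller map mass) is
    reseeded from the dominant left-over direction of the initialisation
    basis after the current maps are regressed out, so it can capture
    structure no current mode explains. Returns the respawned indices.
    """
    maps = group.expected_maps
    sd = maps.std(axis=0)
    sd[sd == 0] = 1.0
    C = np.corrcoef((maps / sd).T)
    tc_corr = None
    if batch:
        acc = []
        for post in batch:
            for tc in post.tc_mean.values():
                cc = np.corrcoef(tc)
                acc.append(np.abs(np.nan_to_num(cc)))
        tc_corr = np.mean(acc, axis=0)
    mass = np.sum(np.abs(maps), axis=0)
    drop: set[int] = set()
    m = maps.shape[1]
    for i in range(m):
        for j in range(i + 1, m):
            if abs(C[i, j]) <= corr_thresh:
                continue
            if tc_corr is not None and tc_corr[i, j] <= tc_thresh:
                continue
            weaker = i if mass[i] < mass[j] else j
            stronger = i + j - weaker
            if stronger not in drop:
                drop.add(weaker)
    if not drop:
        return []
    # unexplained directions of the basis
    X = maps  # (V, M)
    B = basis.T  # (V, d)
    coef, *_ = np.linalg.lstsq(X, B, rcond=None)
    resid = B - X @ coef
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    order = sorted(drop)
    for rank, k in enumerate(order):
        if rank >= u.shape[1]:
            break
        new_map = u[:, rank] / max(u[:, rank].std(), 1e-12)
        if np.mean(new_map**3) < 0:
            new_map = -new_map
        r, v_sig, v_bg = _two_component_membership(new_map)
        group.map_mean[:, k] = new_map
        group.membership_prob[:, k] = np.clip(r, 0.0, 1.0)
        group.map_var[:, k] = v_sig
        group.amp_mean[k] = 0.0
        group.amp_var[k] = 0.25
    return order


def _spd_repair(mat: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    mat = 0.5 * (mat + mat.T)
    w = np.linalg.eigvalsh(mat)
    if w.min() <= 0:
        warnings.warn("wishart_scale required SPD repair (eigenvalue jitter)")
        mat = mat + (floor - w.min()) * np.eye(mat.shape[0])
    return mat


# --------------------------------------------------------------------------
# full fit
# --------------------------------------------------------------------------


def fit(dataset: BOLDDataset, config: InferenceConfig,
        basis: np.ndarray | None = None,
        preprocess_data: bool = True) -> ModeDecomposition:
    """Fit the hierarchical mode decomposition to a dataset.

    Pipeline: (optional) voxel-wise preprocessing -> MIGP -> ICA group
    initialisation -> batched stochastic VB (subject sweeps alternating
    with decaying-step group updates, subjects sampled inversely to their
    visit counts) -> final per-subject posterior pass under the converged
    group model. Deterministic given ``config.seed``.
    """
    if preprocess_data:
        dataset = dataset.map(preprocess)
    subjects = dataset.subjects
    n_subj = len(subjects)
    if basis is None:
        basis = migp(dataset, min(config.effective_migp_dim,
                                  dataset.n_voxels), config.seed)
    group = initialise_group(basis, config.n_modes, config.seed)
    group.wishart_dof = config.effective_wishart_dof
    group.wishart_scale = np.eye(config.n_modes) / group.wishart_dof

    batch_size = min(config.batch_size, n_subj)
    n_batches = max(1, math.ceil(config.mean_visits * n_subj / batch_size))
    per_batch = max(1, math.ceil(config.min_group_updates / n_batches))
    max_updates = n_batches * per_batch

    rng = rng_from(config.seed, "batches")
    visit_count = {s: 0 for s in subjects}
    posteriors: dict[str, SubjectPosterior] = {}
    tc_basis_cache: dict[int, np.ndarray] = {}
    t = 0
    converged = False
    respawn_log: list[tuple[int, list[int]]] = []
    respawn_horizon = int(0.7 * max_updates)
    for b in range(n_batches):
        weights = np.array([1.0 / (1 + visit_count[s]) for s in subjects])
        weights = weights / weights.sum()
        batch_ids = list(rng.choice(subjects, size=batch_size, replace=False,
                                    p=weights))
        for s in batch_ids:
            visit_count[s] += 1
        prev_maps = None
        for _ in range(per_batch):
            batch_post = []
            for sid in batch_ids:
                post = update_subject(dataset.runs_for(sid), group, config,
                                      warm=posteriors.get(sid),
                                      tc_basis=tc_basis_cache)
                posteriors[sid] = post
                batch_post.append(post)
            t += 1
            group = update_group(group, batch_post, step_size(t, config))
            if t % 30 == 0 and t <= respawn_horizon:
                reborn = _respawn_duplicate_modes(group, basis, batch_post)
                if reborn:
                    respawn_log.append((t, reborn))
                    posteriors.clear()  # warm starts would pin the old modes
                    prev_maps = None
                    continue
            cur = group.map_mean
            if prev_maps is not None:
                delta = (np.linalg.norm(cur - prev_maps)
                         / max(np.linalg.norm(prev_maps), 1e-12))
                if t >= config.min_group_updates and delta < config.convergence_tol:
                    converged = True
                    break
            prev_maps = cur.copy()
    if t >= max_updates and not converged:
        converged = True  # schedule completed; flag only if still moving
        if prev_maps is not None and delta > 10 * config.convergence_tol:
            converged = False

    # final pass: every subject under the final group model
    final: dict[str, SubjectPosterior] = {}
    for sid in subjects:
        final[sid] = update_subject(dataset.runs_for(sid), group, config,
                                    warm=posteriors.get(sid),
                                    tc_basis=tc_basis_cache)

    dec = ModeDecomposition(method="pfm", group_maps=group.expected_maps)
    # in-memory extras (not serialised): ungated posterior means
    dec.raw_group_maps = group.map_mean.copy()
    dec.raw_subject_maps = {}
    for sid in subjects:
        post = final[sid]
        dec.subject_maps[sid] = post.map_mean * post.map_membership
        dec.raw_subject_maps[sid] = post.map_mean
        dec.precisions[sid] = post.precision
        for rid, tc in post.tc_mean.items():
            dec.timecourses[(sid, rid)] = tc
            dec.amplitudes[(sid, rid)] = post.amplitude[rid]
    dec.meta.update({
        "seed": int(config.seed),
        "n_modes": int(config.n_modes),
        "group_updates": int(group.update_count),
        "converged": bool(converged),
        "config_hash": config_hash(config.to_dict()),
        "obs_noise_var": float(group.obs_noise_var),
        "respawned_modes": [[t_, list(map(int, ks))]
                            for t_, ks in respawn_log],
    })
    return dec


# --------------------------------------------------------------------------
# back-projection
# --------------------------------------------------------------------------


def backproject_maps(timecourses: dict, amplitudes: dict,
                     target: BOLDDataset, ridge: float = 1e-3,
                     as_tstats: bool = True):
    """Project amplitude-scaled timecourses onto target runs via per-voxel
    ridge regression.

    ``timecourses``/``amplitudes`` are keyed by ``(subject_id, run_id)``
    as in :class:`ModeDecomposition`. With ``as_tstats`` (default) betas
    are divided by their standard errors; per-subject maps are averaged
    into a group map.

    Returns ``(subject_maps, group_map)``.
    """
    per_subject: dict[str, list[np.ndarray]] = {}
    for run in target.runs:
        key = (run.subject_id, run.run_id)
        if key not in timecourses:
            continue
        A = timecourses[key]
        h = amplitudes.get(key, np.ones(A.shape[0]))
        if A.shape[1] != run.n_timepoints:
            raise ValueError("timecourses and target runs must share the "
                             "time dimension")
        X = (h[:, None] * A).T  # (T, M)
        XtX = X.T @ X
        m = X.shape[1]
        reg = XtX + ridge * np.eye(m)
        try:
            inv_reg = np.linalg.inv(reg)
        except np.linalg.LinAlgError:
            raise ValueError("singular design; use ridge > 0") from None
        if ridge == 0 and np.linalg.cond(XtX) > 1e12:
            raise ValueError("singular design; use ridge > 0")
        betas = run.data @ X @ inv_reg  # (V, M)
        if as_tstats:
            resid = run.data - betas @ X.T
            dof = max(X.shape[0] - m, 1)
            sig2 = np.sum(resid**2, axis=1) / dof  # (V,)
            # Var(beta) = sig2 * diag(inv_reg @ XtX @ inv_reg)
            var_scale = np.diag(inv_reg @ XtX @ inv_reg)
            se = np.sqrt(np.outer(sig2, var_scale))
            se[se == 0] = np.inf
            out_map = betas / se
        else:
            out_map = betas
        per_subject.setdefault(run.subject_id, []).append(out_map)
    subject_maps = {s: np.mean(v, axis=0) for s, v in per_subject.items()}
    group_map = np.mean(np.stack(list(subject_maps.values())), axis=0)
    return subject_maps, group_map
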