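"""Ground-truth simulator of multiscale resting-state fMRI datasets.

The generator emulates a multi-subject study in which localised modes are
spatial sub-nodes of distributed modes yet carry their own timecourses:

* group spatial maps built from contiguous voxel blocks with Gamma signal
  weights, smoothed within each block into parcel-like weight profiles;
  distributed modes occupy >= 2 blocks and overlap each other so that on
  average ~1.3 distributed modes cover any covered voxel;
* localised modes occupy a single block placed strictly inside one
  distributed ("parent") mode while also intersecting a second one;
* subject maps derived from the group maps by warping block boundaries
  (random translation/dilation) plus background Gaussian noise, calibrated
  to ~83% subject-group support overlap;
* subject functional connectivity tied to a group precision matrix through
  a Wishart hierarchy;
* semi-Gaussian neural timecourses with amplified power below 0.1 Hz,
  convolved with randomly drawn haemodynamic response kernels;
* data assembled as maps x amplitudes x timecourses plus Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit
from scipy.stats import wishart

from mpfm.core_io import (
    BOLDDataset,
    BOLDRun,
    ModeDecomposition,
    canonical_hrf,
    rng_from,
    sample_hrf,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_group_modes",
    "simulate_subject_maps",
    "simulate_connectivity",
    "simulate_timecourses",
    "assemble_dataset",
    "simulate_dataset",
    "simulate_study",
    "distributed_modes_per_covered_voxel",
    "support_dice",
]

# Calibration constant for the boundary-warp magnitude: with segment
# endpoints jittered by N(0, sigma^2), the expected support dice of a
# segment of length L is approximately 1 - 0.8*sigma/L (half-normal mean of
# each endpoint's erosion). sigma is chosen per segment to hit the target
# mean overlap.
_WARP_DICE_SLOPE = 0.8

# Localised-mode placement: fraction of the block lying inside the parent
# block ("primarily a spatial sub-node" of the parent, the rest spilling
# over into neighbouring territory).
_INSIDE_LO = 0.95
_INSIDE_HI = 1.0

# Minimum fraction of a localised block that must also be covered by a
# second distributed mode (sub-nodes sit in genuinely shared territory).
_SECOND_OVERLAP = 0.25


@dataclass
class SimulationConfig:
    """Study-level parameters of the simulator (defaults = study conditions).

    Defaults describe the simulated validation study: 10 datasets of 50
    subjects x 2 runs, 10,000 voxels x 300 timepoints at TR 0.72 s, with 6
    distributed + 6 localised modes, ~1.3 distributed modes per covered
    voxel and ~83% subject-group spatial overlap.
    """

    n_datasets: int = 10
    n_subjects: int = 50
    n_runs: int = 2
    n_voxels: int = 10_000
    n_timepoints: int = 300
    tr: float = 0.72
    n_distributed: int = 6
    n_localised: int = 6
    signal_weight_shape: float = 3.0
    signal_weight_scale: float = 0.5
    weight_smooth_frac: float = 0.25
    target_modes_per_voxel: float = 1.3
    target_subject_overlap: float = 0.83
    parent_child_corr: float = 0.3
    wishart_dof: float = 100.0
    neural_lowpass_hz: float = 0.1
    lowfreq_gain: float = 3.0
    rectify: bool = True
    noise_sd: float = 1.0
    map_background_sd: float = 0.05
    amplitude_log_sd: float = 0.2
    hrf_support: float = 24.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_datasets", "n_subjects", "n_runs", "n_voxels",
                     "n_timepoints", "n_distributed", "n_localised"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.target_subject_overlap <= 1.0):
            raise ValueError("target_subject_overlap must be in (0, 1]")
        if self.target_modes_per_voxel < 1.0:
            raise ValueError("target_modes_per_voxel must be >= 1")
        if self.target_subject_overlap < 0.5:
            warnings.warn(
                "target_subject_overlap below 0.5 clamped to 0.5 "
                "(warp would destroy mode identity)"
            )
            self.target_subject_overlap = 0.5

    @property
    def n_modes(self) -> int:
        return self.n_distributed + self.n_localised

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    group_maps: np.ndarray  # (n_voxels, n_modes)
    mode_labels: list[str]  # 'distributed' | 'localised' per mode
    parent_links: np.ndarray  # localised -> parent mode index, -1 otherwise
    subject_maps: dict = field(default_factory=dict)  # sid -> (V, M)
    subject_supports: dict = field(default_factory=dict)  # sid -> bool (V, M)
    subject_overlaps: dict = field(default_factory=dict)  # sid -> (M,)
    neural_timecourses: dict = field(default_factory=dict)  # (sid, rid) -> (M, T)
    bold_timecourses: dict = field(default_factory=dict)  # (sid, rid) -> (M, T)
    amplitudes: dict = field(default_factory=dict)  # (sid, rid) -> (M,)
    group_netmat: np.ndarray | None = None  # (M, M) correlation
    subject_precisions: dict = field(default_factory=dict)  # sid -> (M, M)
    hrf_draws: dict = field(default_factory=dict)  # (sid, rid) -> kernel
    config: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return self.group_maps.shape[1]

    def validate(self) -> None:
        labels = np.asarray(self.mode_labels)
        n_dist = int(np.sum(labels == "distributed"))
        n_loc = int(np.sum(labels == "localised"))
        if n_dist + n_loc != self.n_modes:
            raise ValueError("mode_labels must partition the modes")
        dist_support = self.group_maps[:, labels == "distributed"] > 0
        for j in np.nonzero(labels == "localised")[0]:
            sup = self.group_maps[:, j] > 0
            parent = int(self.parent_links[j])
            psup = self.group_maps[:, parent] > 0
            inside = (sup & psup).sum() / max(sup.sum(), 1)
            if inside < 0.7 or sup.sum() >= psup.sum():
                raise ValueError(f"localised mode {j} is not primarily a "
                                 f"sub-node of its parent {parent}")
            touched = (dist_support[sup, :]).any(axis=0).sum()
            if touched < 2:
                raise ValueError(f"localised mode {j} intersects < 2 "
                                 "distributed modes")
        for sid, prec in self.subject_precisions.items():
            if not np.allclose(prec, prec.T, atol=1e-8):
                raise ValueError(f"precision of {sid} not symmetric")
            if np.linalg.eigvalsh(prec).min() <= 0:
                raise ValueError(f"precision of {sid} not positive definite")

    def as_decomposition(self) -> ModeDecomposition:
        """Expose the truth in the common decomposition container (for
        self-tests and truth-based taxonomy/subcomponent analyses)."""
        return ModeDecomposition(
            method="truth",
            group_maps=self.group_maps.copy(),
            subject_maps={s: m.copy() for s, m in self.subject_maps.items()},
            timecourses={k: v.copy() for k, v in self.bold_timecourses.items()},
            amplitudes={k: v.copy() for k, v in self.amplitudes.items()},
            precisions={s: p.copy() for s, p in self.subject_precisions.items()},
            meta={"labels": list(self.mode_labels)},
        )


# --------------------------------------------------------------------------
# group-level spatial maps
# --------------------------------------------------------------------------


def _coverage_fraction(target: float, k: int) -> float:
    """Per-mode coverage fraction c with mean modes-per-covered-voxel =
    target under independent uniform placement: target = k*c/(1-(1-c)^k)."""
    if target <= 1.0:
        return 0.8 / k  # disjoint placement; fraction only bounds total size
    lo, hi = 1e-6, 1.0 - 1e-6
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        val = k * mid / (1.0 - (1.0 - mid) ** k)
        if val < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _block_weights(rng, length: int, config: SimulationConfig) -> np.ndarray:
    """Gamma voxel weights smoothed within the block into a parcel-like
    profile (smoothing preserves the support, hence overlap metrics)."""
    w = rng.gamma(config.signal_weight_shape, config.signal_weight_scale,
                  size=length)
    window = int(round(config.weight_smooth_frac * length))
    if window > 1:
        from scipy.ndimage import uniform_filter1d

        w = uniform_filter1d(w, window, mode="nearest")
    return w


def _place_block(rng, n_voxels, length, forbidden):
    """Uniform random contiguous block of `length` avoiding `forbidden`
    (valid start positions enumerated exactly)."""
    if length > n_voxels:
        raise RuntimeError(
            f"cannot place a contiguous block of {length} voxels in "
            f"{n_voxels} voxels"
        )
    csum = np.concatenate([[0], np.cumsum(forbidden.astype(int))])
    starts = np.arange(0, n_voxels - length + 1)
    valid = starts[csum[starts + length] - csum[starts] == 0]
    if valid.size == 0:
        raise RuntimeError(
            f"cannot place a contiguous block of {length} voxels: "
            f"insufficient free space in {n_voxels} voxels"
        )
    return int(rng.choice(valid))


def simulate_group_modes(config: SimulationConfig, rng_seed: int):
    """Generate group spatial maps, mode class labels and parent links.

    Distributed modes are unions of >= 2 disjoint contiguous blocks; the
    per-mode coverage is chosen so that, among covered voxels, the mean
    number of distributed modes covering a voxel approximates
    ``target_modes_per_voxel``. Localised modes occupy a single block
    placed primarily (70-90% of its voxels) inside one parent distributed
    mode, positioned so its support includes at least one voxel of a
    second distributed mode. In-support weights are Gamma draws;
    everything else is exactly zero.

    Returns ``(group_maps, mode_labels, parent_links)``.
    """
    rng = rng_from(rng_seed, "group_modes")
    nv, kd, kl = config.n_voxels, config.n_distributed, config.n_localised
    disjoint = config.target_modes_per_voxel <= 1.0
    c = _coverage_fraction(config.target_modes_per_voxel, kd)
    min_len = max(6, nv // 250)

    for attempt in range(30):
        maps = np.zeros((nv, kd + kl))
        labels = ["distributed"] * kd + ["localised"] * kl
        parent = np.full(kd + kl, -1, dtype=int)
        global_used = np.zeros(nv, dtype=bool)  # only used when disjoint
        mode_blocks: list[list[tuple[int, int]]] = []
        ok = True
        last_err = None
        try:
            for j in range(kd):
                total = int(round(c * nv))
                n_blocks = int(rng.integers(2, 4))
                props = rng.dirichlet(np.ones(n_blocks) * 4.0)
                lengths = np.maximum(min_len, np.round(props * total).astype(int))
                own = np.zeros(nv, dtype=bool)
                blocks = []
                for L in lengths:
                    forbidden = own | global_used if disjoint else own
                    s = _place_block(rng, nv, int(L), forbidden)
                    own[s:s + L] = True
                    blocks.append((s, s + int(L)))
                    maps[s:s + L, j] = _block_weights(rng, int(L), config)
                if disjoint:
                    global_used |= own
                mode_blocks.append(blocks)
        except RuntimeError as err:
            last_err = err
            continue  # fragmentation; retry the whole layout

        dist_support = maps[:, :kd] > 0
        cover_count = dist_support.sum(axis=1)
        # localised placement: round-robin over shuffled parents for balance
        parents_order = rng.permutation(kd)
        for i in range(kl):
            j = kd + i
            pj = int(parents_order[i % kd])
            placed = False
            for (a, b) in rng.permutation(mode_blocks[pj]).tolist():
                a, b = int(a), int(b)
                blk_len = b - a
                L = max(min_len // 2 + 1,
                        int(round(rng.uniform(0.3, 0.6) * blk_len)))
                if L >= blk_len:
                    L = blk_len - 1
                if L < 3:
                    continue
                other = (dist_support[:, [m for m in range(kd) if m != pj]]
                         .any(axis=1))
                csum = np.concatenate([[0], np.cumsum(other)])
                # candidate starts with 70-90% of the block inside the
                # parent block and >= 1 voxel covered by a second mode
                lo = max(0, a - int((1.0 - _INSIDE_LO) * L))
                hi = min(nv - L, b - int(_INSIDE_LO * L))
                if hi < lo:
                    continue
                starts = np.arange(lo, hi + 1)
                inside = (np.minimum(starts + L, b)
                          - np.maximum(starts, a)) / L
                hits = csum[starts + L] - csum[starts]
                valid = starts[(inside >= _INSIDE_LO) & (inside <= _INSIDE_HI)
                               & (hits >= max(1, int(_SECOND_OVERLAP * L)))]
                if valid.size == 0:
                    continue
                s = int(rng.choice(valid))
                maps[s:s + L, j] = _block_weights(rng, L, config)
                parent[j] = pj
                placed = True
                break
            if not placed and not disjoint:
                ok = False
                break
            if not placed and disjoint:
                # disjoint distributed modes cannot host a doubly-covered
                # localised block; fall back to a strict sub-block of the
                # parent only
                a, b = mode_blocks[pj][0]
                L = max(2, (b - a) // 2)
                s = a + int(rng.integers(0, b - a - L))
                maps[s:s + L, j] = rng.gamma(config.signal_weight_shape,
                                             config.signal_weight_scale,
                                             size=L)
                parent[j] = pj
        if ok:
            return maps, labels, parent
    if last_err is not None:
        raise RuntimeError(str(last_err))
    raise RuntimeError(
        "could not place localised modes overlapping two distributed modes; "
        "distributed coverage too sparse for the requested geometry"
    )


def distributed_modes_per_covered_voxel(group_maps: np.ndarray,
                                        mode_labels) -> float:
    """Mean number of distributed modes covering a voxel, among voxels
    covered by at least one distributed mode."""
    labels = np.asarray(mode_labels)
    support = group_maps[:, labels == "distributed"] > 0
    counts = support.sum(axis=1)
    covered = counts > 0
    if not covered.any():
        return 0.0
    return float(counts[covered].mean())


# --------------------------------------------------------------------------
# subject-level maps
# --------------------------------------------------------------------------


def _segments(support: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous [start, end) runs of a boolean support vector."""
    idx = np.nonzero(support)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def support_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient of two boolean supports (0 if both empty)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (a & b).sum() / denom)


def simulate_subject_maps(group_maps: np.ndarray, config: SimulationConfig,
                          rng_seed: int):
    """Warp + noise the group maps into per-subject maps.

    Each contiguous block of each mode's support has its boundaries
    randomly translated/dilated (Gaussian endpoint jitter scaled to the
    block length, magnitude set from ``target_subject_overlap``); block
    weights are resampled onto the warped support and small background
    Gaussian noise is added everywhere.

    Returns ``(maps, supports, overlaps)`` with shapes
    ``(n_subjects, n_voxels, n_modes)`` (maps, boolean supports) and
    ``(n_subjects, n_modes)`` (support dice vs the group).
    """
    rng = rng_from(rng_seed, "subject_maps")
    nv, nm = group_maps.shape
    ns = config.n_subjects
    sigma_rel = (1.0 - config.target_subject_overlap) / _WARP_DICE_SLOPE

    maps = np.zeros((ns, nv, nm))
    supports = np.zeros((ns, nv, nm), dtype=bool)
    overlaps = np.zeros((ns, nm))
    mode_segments = [_segments(group_maps[:, j] > 0) for j in range(nm)]
    for s in range(ns):
        for j in range(nm):
            col = np.zeros(nv)
            for (a, b) in mode_segments[j]:
                L = b - a
                sigma = sigma_rel * L
                d1 = int(round(rng.normal(0.0, sigma)))
                d2 = int(round(rng.normal(0.0, sigma)))
                na = max(0, min(nv - 2, a + d1))
                nb = max(na + 2, min(nv, b + d2))
                w = group_maps[a:b, j]
                newL = nb - na
                xs = np.linspace(0.0, 1.0, newL)
                xg = np.linspace(0.0, 1.0, L)
                col[na:nb] = np.maximum(col[na:nb], np.interp(xs, xg, w))
            sup = col > 0
            supports[s, :, j] = sup
            overlaps[s, j] = support_dice(group_maps[:, j] > 0, sup)
            maps[s, :, j] = col
        maps[s] += rng.normal(0.0, config.map_background_sd, size=(nv, nm))
    return maps, supports, overlaps


# --------------------------------------------------------------------------
# connectivity + timecourses
# --------------------------------------------------------------------------


def simulate_connectivity(config: SimulationConfig, rng_seed: int,
                          target_correlation: np.ndarray | None = None,
                          parent_links: np.ndarray | None = None):
    """Group precision + Wishart-linked subject precisions.

    A random SPD group precision ``Psi`` is drawn once (or derived from an
    explicit target timecourse correlation matrix); each subject's
    precision is a ``Wishart(dof, Psi/dof)`` draw, so the subject-mean
    precision equals ``Psi`` and larger ``wishart_dof`` concentrates
    subjects around the group.

    When ``parent_links`` is given, the group correlation of each
    localised mode with its parent distributed mode is set to
    ``config.parent_child_corr`` (sub-nodes co-fluctuate with their
    network) before SPD projection.

    Returns ``(group_netmat, subject_precisions)`` where ``group_netmat``
    is the group timecourse correlation matrix and ``subject_precisions``
    is an ``(n_subjects, n_modes, n_modes)`` stack.
    """
    m = config.n_modes
    if config.wishart_dof < m:
        raise ValueError("wishart_dof must be >= n_modes")
    rng = rng_from(rng_seed, "connectivity")
    if target_correlation is not None:
        cov = np.asarray(target_correlation, dtype=float)
        if cov.shape != (m, m):
            raise ValueError("target_correlation has wrong shape")
    else:
        a = rng.standard_normal((m, 2 * m)) / np.sqrt(2 * m)
        cov = a @ a.T + 0.5 * np.eye(m)
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        if parent_links is not None and config.parent_child_corr != 0.0:
            for j in range(m):
                p = int(parent_links[j])
                if p >= 0:
                    r = config.parent_child_corr
                    cov[j, p] = cov[p, j] = r
            w, v = np.linalg.eigh(cov)
            cov = (v * np.clip(w, 0.05, None)) @ v.T
            d = np.sqrt(np.diag(cov))
            cov = cov / np.outer(d, d)
    psi = np.linalg.inv(cov)
    psi = 0.5 * (psi + psi.T)

    group_netmat = _cov_to_corr(np.linalg.inv(psi))
    precs = np.empty((config.n_subjects, m, m))
    for s in range(config.n_subjects):
        for jitter in (0.0, 1e-8, 1e-6):
            scale = psi / config.wishart_dof + jitter * np.eye(m)
            draw = wishart.rvs(df=config.wishart_dof, scale=scale,
                               random_state=rng)
            draw = 0.5 * (draw + draw.T)
            if np.linalg.eigvalsh(draw).min() > 0:
                break
            warnings.warn("non-SPD Wishart draw; retrying with jitter")
        precs[s] = draw
    return group_netmat, precs


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _lowfreq_gain_profile(freqs: np.ndarray, f0: float, gain: float) -> np.ndarray:
    """Smooth gain: ~`gain` below f0, rolling off to 1 above."""
    return 1.0 + (gain - 1.0) * expit((f0 - freqs) / (0.15 * f0))


def simulate_timecourses(config: SimulationConfig,
                         subject_precision: np.ndarray,
                         hrf: np.ndarray, rng_seed: int,
                         lowfreq_gain: float | None = None,
                         rectify: bool | None = None):
    """Neural + BOLD mode timecourses for one subject-run.

    Neural timecourses are correlated Gaussian draws (covariance = inverse
    of ``subject_precision``), spectrally reweighted to amplify components
    below ``neural_lowpass_hz``, then soft-rectified (``x * sigmoid(x/s)``
    with s = the timecourse sd) to skew activity positive; BOLD
    timecourses are the causal convolution with ``hrf`` truncated to the
    run length. All rows are standardised to zero mean, unit sd.

    Returns ``(neural, bold)``, each ``(n_modes, n_timepoints)``.
    """
    T = config.n_timepoints
    hrf = np.asarray(hrf, float)
    if T < hrf.size:
        raise ValueError("n_timepoints shorter than the HRF support")
    gain = config.lowfreq_gain if lowfreq_gain is None else lowfreq_gain
    do_rect = config.rectify if rectify is None else rectify

    rng = rng_from(rng_seed, "timecourses")
    m = subject_precision.shape[0]
    cov = np.linalg.inv(subject_precision)
    L = np.linalg.cholesky(0.5 * (cov + cov.T))
    x = L @ rng.standard_normal((m, T))

    if gain != 1.0:
        freqs = np.fft.rfftfreq(T, d=config.tr)
        g = _lowfreq_gain_profile(freqs, config.neural_lowpass_hz, gain)
        x = np.fft.irfft(np.fft.rfft(x, axis=1) * g[None, :], n=T, axis=1)
    x = _standardise_rows(x)
    if do_rect:
        x = x * expit(x)  # scale s = 1 after standardisation
        x = _standardise_rows(x)
    neural = x

    bold = np.stack([np.convolve(row, hrf)[:T] for row in neural])
    bold = _standardise_rows(bold)
    return neural, bold


def _standardise_rows(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------


def assemble_dataset(truth: SimulationTruth, config: SimulationConfig,
                     rng_seed: int) -> BOLDDataset:
    """Build the observed BOLD dataset from a populated truth bundle:
    ``D_sr = P_s diag(h_sr) A_sr + noise`` per subject-run."""
    rng = rng_from(rng_seed, "assemble")
    runs = []
    for sid in truth.subject_maps:
        P = truth.subject_maps[sid]
        for rid in _run_ids(config.n_runs):
            key = (sid, rid)
            A = truth.bold_timecourses[key]
            h = truth.amplitudes[key]
            if P.shape[1] != A.shape[0] or h.shape[0] != A.shape[0]:
                raise ValueError(
                    f"dimension mismatch assembling {key}: maps {P.shape}, "
                    f"timecourses {A.shape}, amplitudes {h.shape}"
                )
            data = (P * h[None, :]) @ A
            if config.noise_sd > 0:
                data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
            runs.append(BOLDRun(data=data, tr=config.tr,
                                subject_id=sid, run_id=rid))
    return BOLDDataset(runs=runs)


def _run_ids(n_runs: int) -> list[str]:
    return [f"run{r + 1}" for r in range(n_runs)]


def _subject_ids(n_subjects: int) -> list[str]:
    return [f"sub{s:03d}" for s in range(n_subjects)]


def simulate_dataset(config: SimulationConfig, rng_seed: int,
                     target_correlation: np.ndarray | None = None):
    """One full dataset: group maps, subject maps, connectivity,
    timecourses, amplitudes, assembled data.

    Returns ``(BOLDDataset, SimulationTruth)``.
    """
    group_maps, labels, parent = simulate_group_modes(config, rng_seed)
    maps, supports, overlaps = simulate_subject_maps(group_maps, config,
                                                     rng_seed)
    group_netmat, precs = simulate_connectivity(config, rng_seed,
                                                target_correlation,
                                                parent_links=parent)
    basis = canonical_hrf(config.tr, config.hrf_support)
    amp_rng = rng_from(rng_seed, "amplitudes")

    truth = SimulationTruth(
        group_maps=group_maps,
        mode_labels=labels,
        parent_links=parent,
        group_netmat=group_netmat,
        config=config.to_dict(),
    )
    sids = _subject_ids(config.n_subjects)
    for s, sid in enumerate(sids):
        truth.subject_maps[sid] = maps[s]
        truth.subject_supports[sid] = supports[s]
        truth.subject_overlaps[sid] = overlaps[s]
        truth.subject_precisions[sid] = precs[s]
        for r, rid in enumerate(_run_ids(config.n_runs)):
            hseed = rng_from(rng_seed, "hrf", s, r).integers(2**31 - 1)
            hrf = sample_hrf(basis, int(hseed))
            tseed = int(rng_from(rng_seed, "tc", s, r).integers(2**31 - 1))
            neural, bold = simulate_timecourses(config, precs[s], hrf, tseed)
            key = (sid, rid)
            truth.hrf_draws[key] = hrf
            truth.neural_timecourses[key] = neural
            truth.bold_timecourses[key] = bold
            truth.amplitudes[key] = np.exp(
                amp_rng.normal(0.0, config.amplitude_log_sd,
                               size=config.n_modes))
    dataset = assemble_dataset(truth, config, rng_seed)
    return dataset, truth


def simulate_study(config: SimulationConfig):
    """Generate ``config.n_datasets`` independent datasets (fresh group maps
    in each), with per-dataset seeds derived from ``config.seed``.

    Returns a list of ``(BOLDDataset, SimulationTruth)`` pairs.
    """
    out = []
    for d in range(config.n_datasets):
        dseed = int(rng_from(config.seed, "dataset", d).integers(2**31 - 1))
        out.append(simulate_dataset(config, dseed))
    return out
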