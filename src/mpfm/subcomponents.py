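"""Temporally distinct subcomponents within large-scale modes.

Pipeline (per low-dimensional mode): weight each subject's data by the
mode's subject spatial map; per-subject spatial PCA; group-level PCA of
the concatenated subject PCs; regression of the group PCs onto each
subject's weighted data to obtain temporal components; temporal ICA on
the subject-concatenated components; winner-takes-all attribution of each
subcomponent timecourse to low-dimensional, primary or secondary modes.

Two variants probe what the subcomponents are made of: the
temporally-exclusive variant regresses the other modes' timecourses out
of the weighted data first (leaving each mode's private temporal space);
the spatially-exclusive variant regresses the other modes' spatial maps
out of both the weighting map and the weighted data (leaving each mode's
private spatial territory).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mpfm._ica import fixed_point_ica
from mpfm.core_io import BOLDDataset, BOLDRun, ModeDecomposition

__all__ = [
    "SubcomponentSet",
    "WinnerTable",
    "weight_data",
    "mode_pca",
    "extract_subcomponents",
    "winner_takes_all",
    "temporally_exclusive",
    "spatially_exclusive",
]


@dataclass
class SubcomponentSet:
    """Subcomponents of one low-dimensional mode."""

    parent_mode: int
    variant: str  # original | temporally_exclusive | spatially_exclusive
    k: int
    group_maps: np.ndarray  # (V, k)
    subject_timecourses: dict = field(default_factory=dict)  # sid -> (k, T)
    subject_maps: dict = field(default_factory=dict)  # sid -> (V, k)
    explained_variance: np.ndarray | None = None
    empty: bool = False  # set when the residual map vanished (sexcl)


@dataclass
class WinnerTable:
    """Winner-takes-all attribution of subcomponents to mode categories."""

    winner_category: list  # per subcomponent: lowD | primary | secondary
    winner_mode: list  # index within the winning category's timecourse set
    margin_stats: list  # per subcomponent: dict(t, p_corrected, significant)
    counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.counts:
            self.counts = {c: self.winner_category.count(c)
                           for c in ("lowD", "primary", "secondary")}


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------


def weight_data(run: BOLDRun, subject_map_column: np.ndarray) -> BOLDRun:
    """Multiply each voxel's timeseries by its spatial-map weight."""
    w = np.asarray(subject_map_column, float).ravel()
    if w.shape[0] != run.n_voxels:
        raise ValueError("map column length must equal the voxel count")
    return BOLDRun(data=run.data * w[:, None], tr=run.tr,
                   subject_id=run.subject_id, run_id=run.run_id)


def _spatial_pcs(data: np.ndarray, k: int) -> np.ndarray:
    """Top-k spatial principal components (V, k) of a voxels x time matrix,
    scaled by singular values."""
    U, s, _ = np.linalg.svd(data - data.mean(axis=1, keepdims=True),
                            full_matrices=False)
    k = min(k, s.size)
    return U[:, :k] * s[:k]


def mode_pca(weighted: dict, k_subject: int = 10, k_group: int = 10):
    """Two-level PCA of mode-weighted data.

    ``weighted`` maps subject id -> (V, T) weighted timeseries. Per
    subject the top ``k_subject`` spatial PCs are extracted; the PC maps
    are concatenated across subjects and a group PCA returns ``k_group``
    spatial PCs with the variance fraction per PC.

    Returns ``(group_pcs (V, k_group), explained_variance (k_group,))``.
    """
    pcs = []
    for sid, data in weighted.items():
        if np.allclose(data, 0.0):
            warnings.warn(f"subject {sid}: weighted data is zero; skipped")
            continue
        pcs.append(_spatial_pcs(data, k_subject))
    if not pcs:
        raise ValueError("no usable subjects for mode PCA")
    concat = np.concatenate(pcs, axis=1)
    U, s, _ = np.linalg.svd(concat - concat.mean(axis=1, keepdims=True),
                            full_matrices=False)
    k_group = min(k_group, s.size)
    ev = (s[:k_group] ** 2) / np.sum(s**2)
    return U[:, :k_group] * s[:k_group], ev


# --------------------------------------------------------------------------
# exclusivity variants
# --------------------------------------------------------------------------


def _regress_out(data: np.ndarray, regressors: np.ndarray,
                 axis: str = "time") -> np.ndarray:
    """Least-squares residual of ``data`` after regression on
    ``regressors``.

    axis="time": regressors (T, q), data (V, T) -> per-voxel residuals.
    axis="space": regressors (V, q), data (V, T) -> per-timepoint
    residuals.
    """
    X = np.asarray(regressors, float)
    if axis == "space":
        return data - X @ np.linalg.lstsq(X, data, rcond=None)[0]
    B = np.linalg.lstsq(X, data.T, rcond=None)[0]  # (q, V)
    return data - (X @ B).T


def temporally_exclusive(dataset: BOLDDataset, lowD: ModeDecomposition,
                         mode: int) -> dict:
    """Weighted data with the other modes' timecourses regressed out.

    Returns subject id -> (V, T) residual weighted timeseries; residuals
    are orthogonal to the removed timecourses.
    """
    if lowD.n_modes < 2:
        raise ValueError("need >= 2 modes to regress out the others")
    out = {}
    others = [m for m in range(lowD.n_modes) if m != mode]
    for sid in lowD.subjects:
        col = lowD.subject_maps[sid][:, mode]
        chunks = []
        for run in dataset.runs_for(sid):
            w = weight_data(run, col)
            tcs = lowD.timecourses[(sid, run.run_id)][others].T  # (T, q)
            if np.allclose(tcs, 0.0):
                chunks.append(w.data)
                continue
            rank = np.linalg.matrix_rank(tcs)
            if rank < tcs.shape[1]:
                warnings.warn("collinear regressor timecourses; ridge "
                              "fallback")
                gram = tcs.T @ tcs + 1e-8 * np.trace(tcs.T @ tcs) * np.eye(
                    tcs.shape[1]) / tcs.shape[1]
                B = np.linalg.solve(gram, tcs.T @ w.data.T)
                chunks.append(w.data - (tcs @ B).T)
            else:
                chunks.append(_regress_out(w.data, tcs, axis="time"))
        out[sid] = np.concatenate(chunks, axis=1)
    return out


def spatially_exclusive(dataset: BOLDDataset, lowD: ModeDecomposition,
                        mode: int) -> tuple[dict, dict]:
    """Weighted data built from spatially exclusive maps.

    Per subject: (i) the mode's map is replaced by its residual after
    regression (across voxels) on the other modes' maps; (ii) the data is
    weighted by the residual map; (iii) each timepoint's voxel pattern is
    replaced by its residual after regression on the other maps.

    Returns ``(weighted, residual_maps)`` keyed by subject id.
    """
    if lowD.n_modes < 2:
        raise ValueError("need >= 2 modes to regress out the others")
    others = [m for m in range(lowD.n_modes) if m != mode]
    weighted, residual_maps = {}, {}
    for sid in lowD.subjects:
        maps = lowD.subject_maps[sid]
        X = maps[:, others]  # (V, q)
        col = maps[:, mode:mode + 1]
        res_col = _regress_out(col, X, axis="space").ravel()
        residual_maps[sid] = res_col
        if np.linalg.norm(res_col) < 1e-10 * max(np.linalg.norm(col), 1e-30):
            warnings.warn(f"subject {sid}: map lies in the span of the "
                          "others; empty residual")
        chunks = []
        for run in dataset.runs_for(sid):
            w = run.data * res_col[:, None]
            chunks.append(_regress_out(w, X, axis="space"))
        weighted[sid] = np.concatenate(chunks, axis=1)
    return weighted, residual_maps


# --------------------------------------------------------------------------
# extraction + winners
# --------------------------------------------------------------------------


def extract_subcomponents(dataset: BOLDDataset, lowD: ModeDecomposition,
                          mode: int, k: int = 5, rng_seed: int = 0,
                          variant: str = "original",
                          k_subject: int = 5) -> SubcomponentSet:
    """Extract ``k`` temporally independent subcomponents of one mode.

    Steps: weight each subject's data by the mode's subject map (variant
    pre-processing applied as requested); ``k_subject`` spatial PCs per
    subject; group PCA to ``k`` spatial PCs; regression of the group PCs
    onto each subject's weighted data (temporal components); temporal ICA
    across the subject-concatenated components; per-subject subcomponent
    timecourses and maps by back-regression.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if variant == "original":
        weighted = {}
        for sid in lowD.subjects:
            col = lowD.subject_maps[sid][:, mode]
            chunks = [weight_data(run, col).data
                      for run in dataset.runs_for(sid)]
            weighted[sid] = np.concatenate(chunks, axis=1)
        empty = False
    elif variant == "temporally_exclusive":
        weighted = temporally_exclusive(dataset, lowD, mode)
        empty = False
    elif variant == "spatially_exclusive":
        weighted, res_maps = spatially_exclusive(dataset, lowD, mode)
        empty = all(np.linalg.norm(m) < 1e-12 for m in res_maps.values())
    else:
        raise ValueError(f"unknown variant {variant!r}")

    group_pcs, ev = mode_pca(weighted, k_subject=k_subject, k_group=k)
    # temporal components per subject: regress group PC maps onto data
    sids = list(weighted)
    temp = {sid: np.linalg.lstsq(group_pcs, weighted[sid], rcond=None)[0]
            for sid in sids}  # (k, T_s)
    lengths = [temp[sid].shape[1] for sid in sids]
    concat = np.concatenate([temp[sid] for sid in sids], axis=1)  # (k, sumT)
    sources = fixed_point_ica(concat.T, k, rng_seed).T  # (k, sumT)

    subset = SubcomponentSet(parent_mode=int(mode), variant=variant,
                             k=int(k), group_maps=group_pcs,
                             explained_variance=ev, empty=empty)
    off = 0
    for sid, T_s in zip(sids, lengths):
        tc = sources[:, off:off + T_s]
        tc = tc - tc.mean(axis=1, keepdims=True)
        subset.subject_timecourses[sid] = tc
        # subcomponent maps: regress subject tcs onto the weighted data
        subset.subject_maps[sid] = np.linalg.lstsq(tc.T, weighted[sid].T,
                                                   rcond=None)[0].T
        off += T_s
    return subset


def _per_subject_concat(decomp: ModeDecomposition, sid: str) -> np.ndarray:
    tcs = [tc for (s, r), tc in sorted(decomp.timecourses.items())
           if s == sid]
    return np.concatenate(tcs, axis=1)


def winner_takes_all(subset: SubcomponentSet, lowD: ModeDecomposition,
                     primary: dict, secondary: dict,
                     alpha: float = 0.05,
                     n_tests: int | None = None) -> WinnerTable:
    """Attribute each subcomponent to the candidate mode with the highest
    subject-mean absolute timecourse correlation.

    ``primary`` and ``secondary`` map subject id -> (n_candidates, T)
    timecourse stacks (runs concatenated, same order as the subcomponent
    timecourses); the low-dimensional candidates come from ``lowD``.
    Significance: unpaired t-test between the winner's per-subject |r|
    sample and that of the best candidate outside the winner's category,
    Bonferroni-corrected over ``n_tests`` (default: the number of
    subcomponents).
    """
    sids = list(subset.subject_timecourses)
    cats = {"lowD": {sid: _per_subject_concat(lowD, sid) for sid in sids},
            "primary": primary, "secondary": secondary}
    # drop categories with no candidate modes (e.g. no secondary modes)
    cats = {cat: tcset for cat, tcset in cats.items()
            if tcset and next(iter(tcset.values())).shape[0] > 0}
    if not cats:
        raise ValueError("no candidate timecourses supplied")
    n_tests = n_tests or subset.k

    winner_category, winner_mode, margin_stats = [], [], []
    for i in range(subset.k):
        # |r| per subject per candidate, per category
        cat_r: dict[str, np.ndarray] = {}
        for cat, tcset in cats.items():
            rs = []
            for sid in sids:
                x = subset.subject_timecourses[sid][i]
                cand = tcset[sid]
                xc = x - x.mean()
                cc = cand - cand.mean(axis=1, keepdims=True)
                num = cc @ xc
                den = (np.linalg.norm(xc)
                       * np.linalg.norm(cc, axis=1))
                den[den == 0] = np.inf
                rs.append(np.abs(num / den))
            cat_r[cat] = np.stack(rs)  # (S, n_candidates)
        means = {cat: cat_r[cat].mean(axis=0) for cat in cat_r}
        best = {cat: (float(means[cat].max()), int(means[cat].argmax()))
                for cat in means}
        w_cat = max(best, key=lambda c: best[c][0])
        w_idx = best[w_cat][1]
        winner_category.append(w_cat)
        winner_mode.append(w_idx)

        rivals = [c for c in best if c != w_cat]
        if not rivals:
            margin_stats.append({"t": None, "p_corrected": None,
                                 "significant": None})
            continue
        rival_cat = max(rivals, key=lambda c: best[c][0])
        win_sample = cat_r[w_cat][:, w_idx]
        riv_sample = cat_r[rival_cat][:, best[rival_cat][1]]
        if len(sids) < 3:
            margin_stats.append({"t": None, "p_corrected": None,
                                 "significant": None})
        else:
            t, p = stats.ttest_ind(win_sample, riv_sample)
            p_corr = min(1.0, float(p) * n_tests)
            margin_stats.append({"t": float(t), "p_corrected": p_corr,
                                 "significant": bool(p_corr < alpha)})
    return WinnerTable(winner_category=winner_category,
                       winner_mode=winner_mode, margin_stats=margin_stats)
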