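"""Network matrices: spatial (full) and temporal (Tikhonov-regularised
partial) correlations between modes, Fisher transform, between-subject
consistency, and primary/secondary edge-feature blocks."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from mpfm.core_io import ModeDecomposition

__all__ = [
    "NetMat",
    "spatial_netmat",
    "temporal_netmat",
    "fisher_z",
    "consistency",
    "split_blocks",
    "reduce_features",
    "subject_netmats",
]


@dataclass
class NetMat:
    """A modes x modes network matrix.

    ``flavour`` is ``"spatial_full"`` (Pearson correlation of mode maps
    across voxels) or ``"temporal_partial"`` (Tikhonov-regularised partial
    correlation of mode timecourses). The diagonal is zeroed after
    construction; ``fisher_z`` records whether values are r-to-z
    transformed.
    """

    values: np.ndarray
    flavour: str
    fisher_z: bool = False
    tikhonov_rho: float | None = None
    subject_id: str = "group"

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("netmat must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("netmat must be symmetric")
        if not self.fisher_z and np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v

    @property
    def n_modes(self) -> int:
        return self.values.shape[0]

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.n_modes, k=1)
        return self.values[iu]


def spatial_netmat(subject_maps: np.ndarray,
                   subject_id: str = "group") -> NetMat:
    """Full spatial correlation between mode maps (columns), diagonal
    zeroed; zero-variance maps get zero rows/columns with a warning."""
    maps = np.asarray(subject_maps, float)
    if maps.shape[1] < 2 or maps.shape[0] < 3:
        raise ValueError("need >= 2 modes and >= 3 voxels")
    sd = maps.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"zero-variance maps {np.nonzero(dead)[0].tolist()}; "
                      "their netmat rows set to 0")
    safe = maps.copy()
    safe[:, dead] = 0.0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(safe.T)
    corr[dead, :] = 0.0
    corr[:, dead] = 0.0
    np.fill_diagonal(corr, 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    return NetMat(values=corr, flavour="spatial_full", subject_id=subject_id)


def temporal_netmat(timecourses: np.ndarray, rho: float = 0.01,
                    subject_id: str = "group") -> NetMat:
    """Tikhonov-regularised partial correlation between mode timecourses.

    ``timecourses`` is ``(n_modes, n_time)`` (runs concatenated). The
    covariance C of the demeaned timecourses is inverted with ridge
    ``rho * trace(C)/n_modes`` on the diagonal; partial correlations are
    ``-Omega_ij / sqrt(Omega_ii Omega_jj)`` with zeroed diagonal.
    """
    tc = np.asarray(timecourses, float)
    m = tc.shape[0]
    tc = tc - tc.mean(axis=1, keepdims=True)
    C = tc @ tc.T / max(tc.shape[1] - 1, 1)
    lam = rho * np.trace(C) / m
    if rho <= 0:
        if np.linalg.cond(C) > 1e12:
            raise ValueError("singular covariance; use rho > 0")
        lam = 0.0
    omega = np.linalg.inv(C + lam * np.eye(m))
    d = np.sqrt(np.diag(omega))
    pc = -omega / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    pc = np.clip(0.5 * (pc + pc.T), -1.0, 1.0)
    return NetMat(values=pc, flavour="temporal_partial", tikhonov_rho=rho,
                  subject_id=subject_id)


def fisher_z(netmat: NetMat) -> NetMat:
    """Elementwise r-to-z (atanh) transform; |r| = 1 is clipped with a
    warning."""
    if netmat.fisher_z:
        raise ValueError("netmat already Fisher-transformed")
    v = netmat.values.copy()
    lim = 1.0 - 1e-7
    if np.any(np.abs(v) >= 1.0):
        warnings.warn("|r| = 1 clipped before Fisher transform")
        v = np.clip(v, -lim, lim)
    return NetMat(values=np.arctanh(v), flavour=netmat.flavour,
                  fisher_z=True, tikhonov_rho=netmat.tikhonov_rho,
                  subject_id=netmat.subject_id)


def consistency(netmats: list[NetMat], method: str = "loo"):
    """Between-subject consistency of netmat edges.

    ``method="loo"``: each subject's vectorised upper triangle is
    correlated with the mean of all other subjects' (leave-one-out).
    ``method="pairs"``: mean correlation with every other subject.
    Returns ``(scores, {"mean": .., "sd": ..})``; constant netmats yield
    NaN scores.
    """
    if len(netmats) < 3:
        raise ValueError("need >= 3 subjects")
    flavours = {n.flavour for n in netmats}
    dims = {n.n_modes for n in netmats}
    if len(flavours) > 1 or len(dims) > 1:
        raise ValueError("netmats must share flavour and dimension")
    edges = np.stack([n.upper() for n in netmats])  # (S, E)
    S = edges.shape[0]
    scores = np.full(S, np.nan)
    for s in range(S):
        x = edges[s]
        if method == "loo":
            y = edges[np.arange(S) != s].mean(axis=0)
            scores[s] = _safe_corr(x, y)
        elif method == "pairs":
            vals = [_safe_corr(x, edges[t]) for t in range(S) if t != s]
            scores[s] = float(np.nanmean(vals))
        else:
            raise ValueError("method must be 'loo' or 'pairs'")
    summary = {"mean": float(np.nanmean(scores)),
               "sd": float(np.nanstd(scores))}
    return scores, summary


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def split_blocks(netmat: NetMat, primary_idx, secondary_idx):
    """Edge-feature vectors for the primary/secondary partition.

    Returns ``(pri2pri, sec2sec, pri2sec)``: the upper triangles of the
    two symmetric within-class blocks, and the flattened rectangular
    between-class block.
    """
    p = np.asarray(primary_idx, int)
    s = np.asarray(secondary_idx, int)
    if np.intersect1d(p, s).size:
        raise ValueError("primary and secondary index sets overlap")
    if sorted(p.tolist() + s.tolist()) != list(range(netmat.n_modes)):
        raise ValueError("index sets must partition the modes")
    v = netmat.values
    pp = v[np.ix_(p, p)][np.triu_indices(len(p), k=1)]
    ss = v[np.ix_(s, s)][np.triu_indices(len(s), k=1)]
    ps = v[np.ix_(p, s)].ravel()
    return pp, ss, ps


def reduce_features(features: np.ndarray, k: int) -> np.ndarray:
    """SVD dimension reduction of a subjects x edges matrix to subjects x k
    (left singular vectors scaled by singular values; column signs fixed
    by making each column's largest-magnitude entry positive)."""
    X = np.asarray(features, float)
    if k > min(X.shape):
        raise ValueError("k exceeds the rank bound min(subjects, edges)")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    out = U[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def subject_netmats(decomp: ModeDecomposition, flavour: str = "temporal_partial",
                    rho: float = 0.01) -> list[NetMat]:
    """Per-subject netmats from a decomposition (runs concatenated per
    subject for the temporal flavour)."""
    out = []
    for sid in decomp.subjects:
        if flavour == "spatial_full":
            out.append(spatial_netmat(decomp.subject_maps[sid], sid))
        elif flavour == "temporal_partial":
            tcs = [tc for (s, r), tc in sorted(decomp.timecourses.items())
                   if s == sid]
            out.append(temporal_netmat(np.concatenate(tcs, axis=1), rho, sid))
        else:
            raise ValueError(f"unknown flavour {flavour!r}")
    return out
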