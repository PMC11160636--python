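"""Shared data types, preprocessing, HRF machinery and file formats.

Conventions used throughout the package:

* BOLD matrices are stored voxels-major, i.e. shape ``(n_voxels, n_time)``.
* Voxel indexing is 0-based into a flat masked vector; an optional NIfTI
  mask maps flat indices back to 3-D coordinates.
* Every stochastic operation takes an explicit seed and is reproducible
  given it.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "BOLDRun",
    "BOLDDataset",
    "HRFBasis",
    "ModeDecomposition",
    "preprocess",
    "canonical_hrf",
    "sample_hrf",
    "hrf_temporal_basis",
    "rng_from",
    "load_config",
    "load_nifti_run",
    "flat_to_volume",
]

# --------------------------------------------------------------------------
# seeding helpers
# --------------------------------------------------------------------------


def _subkey_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    return zlib.crc32(str(key).encode("utf-8")) & 0x7FFFFFFF


def rng_from(seed: int, *subkeys) -> np.random.Generator:
    """Deterministic generator derived from a master seed and named subkeys.

    Subkeys may be strings or integers; the same (seed, subkeys) pair always
    yields the same stream, and distinct subkeys yield independent streams.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_subkey_to_int(k) for k in subkeys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# --------------------------------------------------------------------------
# BOLD containers
# --------------------------------------------------------------------------


@dataclass
class BOLDRun:
    """A single voxels x time BOLD recording.

    Parameters
    ----------
    data
        Array of shape ``(n_voxels, n_time)`` in arbitrary units.
    tr
        Repetition time in seconds.
    subject_id, run_id
        Identifiers used to group runs into datasets.
    constant_voxels
        Indices of voxels that were constant before variance normalisation
        (set by :func:`preprocess`; such rows are mapped to all-zeros).
    """

    data: np.ndarray
    tr: float
    subject_id: str
    run_id: str
    constant_voxels: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("BOLD data must be 2-D (voxels x time)")
        if self.data.shape[0] < 1 or self.data.shape[1] < 2:
            raise ValueError(
                f"need >=1 voxel and >=2 timepoints, got {self.data.shape}"
            )
        bad = ~np.isfinite(self.data)
        if bad.any():
            idx = np.unique(np.nonzero(bad)[0])
            raise ValueError(
                f"non-finite BOLD values in voxels {idx[:20].tolist()}"
                + ("..." if idx.size > 20 else "")
            )
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.subject_id = str(self.subject_id)
        self.run_id = str(self.run_id)

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class BOLDDataset:
    """Multi-subject, multi-run collection of :class:`BOLDRun`."""

    runs: list[BOLDRun]

    def __post_init__(self):
        if not self.runs:
            raise ValueError("dataset must contain at least one run")
        v0, tr0 = self.runs[0].n_voxels, self.runs[0].tr
        for r in self.runs:
            if r.n_voxels != v0:
                raise ValueError("all runs must share the voxel count")
            if abs(r.tr - tr0) > 1e-12:
                raise ValueError("all runs must share the TR")

    @property
    def n_voxels(self) -> int:
        return self.runs[0].n_voxels

    @property
    def tr(self) -> float:
        return self.runs[0].tr

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.runs:
            seen.setdefault(r.subject_id, None)
        return list(seen)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_runs_per_subject(self) -> int:
        counts = [len(self.runs_for(s)) for s in self.subjects]
        return int(round(sum(counts) / len(counts)))

    def runs_for(self, subject_id: str) -> list[BOLDRun]:
        out = [r for r in self.runs if r.subject_id == str(subject_id)]
        if not out:
            raise KeyError(f"no runs for subject {subject_id!r}")
        return out

    def map(self, fn) -> "BOLDDataset":
        return BOLDDataset(runs=[fn(r) for r in self.runs])

    # -- serialisation -----------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        index = []
        for r in self.runs:
            stem = f"{r.subject_id}_{r.run_id}"
            np.save(out / f"{stem}.npy", r.data)
            sidecar = {
                "tr": r.tr,
                "subject_id": r.subject_id,
                "run_id": r.run_id,
                "constant_voxels": None
                if r.constant_voxels is None
                else [int(i) for i in r.constant_voxels],
            }
            _write_json(out / f"{stem}.json", sidecar)
            index.append(stem)
        _write_json(out / "dataset.json", {"runs": index})

    @classmethod
    def load(cls, in_dir: str | Path) -> "BOLDDataset":
        src = Path(in_dir)
        index = json.loads((src / "dataset.json").read_text())
        runs = []
        for stem in index["runs"]:
            meta = json.loads((src / f"{stem}.json").read_text())
            cv = meta.get("constant_voxels")
            runs.append(
                BOLDRun(
                    data=np.load(src / f"{stem}.npy"),
                    tr=meta["tr"],
                    subject_id=meta["subject_id"],
                    run_id=meta["run_id"],
                    constant_voxels=None if cv is None else np.asarray(cv, dtype=int),
                )
            )
        return cls(runs=runs)


def preprocess(run: BOLDRun) -> BOLDRun:
    """Voxel-wise de-meaning and variance normalisation.

    Each voxel timeseries is mapped to zero mean and unit standard
    deviation. Voxels with (numerically) zero variance are mapped to
    all-zero rows and their indices recorded in ``constant_voxels`` so the
    flat voxel indexing stays aligned with any mask.
    """
    data = run.data
    mean = data.mean(axis=1, keepdims=True)
    centred = data - mean
    sd = centred.std(axis=1, keepdims=True)
    const = sd[:, 0] <= 1e-12 * (1.0 + np.abs(mean[:, 0]))
    sd_safe = np.where(const[:, None], 1.0, sd)
    out = centred / sd_safe
    out[const, :] = 0.0
    return BOLDRun(
        data=out,
        tr=run.tr,
        subject_id=run.subject_id,
        run_id=run.run_id,
        constant_voxels=np.nonzero(const)[0],
    )


# --------------------------------------------------------------------------
# HRF machinery
# --------------------------------------------------------------------------


@dataclass
class HRFBasis:
    """Haemodynamic response basis sampled on a regular lag grid.

    ``kernels`` has shape ``(n_lags, n_basis)``; each column is unit
    Euclidean norm. Column 0 is the canonical response (peak 3-9 s
    post-stimulus); the remaining columns span plausible latency/width
    variation.
    """

    dt: float
    kernels: np.ndarray
    support_seconds: float

    def __post_init__(self):
        self.kernels = np.asarray(self.kernels, dtype=np.float64)
        if self.kernels.ndim != 2:
            raise ValueError("kernels must be lags x n_basis")
        if not np.all(np.isfinite(self.kernels)):
            raise ValueError("non-finite HRF kernels")
        norms = np.linalg.norm(self.kernels, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("each kernel must have unit Euclidean norm")
        peak = np.argmax(self.kernels[:, 0]) * self.dt
        if not (3.0 <= peak <= 9.0):
            raise ValueError(f"canonical peak {peak:.2f}s outside 3-9s")

    @property
    def n_lags(self) -> int:
        return self.kernels.shape[0]

    @property
    def n_basis(self) -> int:
        return self.kernels.shape[1]

    @property
    def canonical(self) -> np.ndarray:
        return self.kernels[:, 0]


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    from scipy.stats import gamma

    return gamma.pdf(t, a=shape, scale=scale)


def _double_gamma(t: np.ndarray, peak_delay: float = 6.0, under_delay: float = 16.0,
                  dispersion: float = 1.0, under_ratio: float = 6.0) -> np.ndarray:
    pos = _gamma_pdf(t, peak_delay / dispersion, dispersion)
    und = _gamma_pdf(t, under_delay / dispersion, dispersion)
    return pos - und / under_ratio


def canonical_hrf(tr: float, support: float = 32.0) -> HRFBasis:
    """Three-kernel haemodynamic basis: double-gamma + derivatives.

    The basis holds the canonical double-gamma difference response, its
    temporal derivative (latency variation) and its dispersion derivative
    (width variation), sampled every ``tr`` seconds over ``support``
    seconds, each normalised to unit Euclidean norm.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if support < 20.0:
        raise ValueError("support must be >= 20 s to contain the undershoot")
    if tr >= support:
        raise ValueError("tr must be smaller than the kernel support")
    n_lags = int(np.ceil(support / tr))
    t = np.arange(n_lags) * tr
    h = _double_gamma(t)
    # temporal derivative: finite-difference in onset shift of 1 s
    h_shift = _double_gamma(np.clip(t - 1.0, 0.0, None)) * (t >= 1.0)
    dtemp = h - h_shift
    # dispersion derivative: finite difference in the dispersion parameter
    ddisp = (h - _double_gamma(t, dispersion=1.01)) / 0.01
    kernels = np.stack([h, dtemp, ddisp], axis=1)
    kernels = kernels / np.linalg.norm(kernels, axis=0, keepdims=True)
    return HRFBasis(dt=tr, kernels=kernels, support_seconds=float(support))


def sample_hrf(basis: HRFBasis, rng_seed: int) -> np.ndarray:
    """Random plausible HRF: a unit-norm draw dominated by the canonical kernel.

    The canonical kernel carries weight 1; derivative kernels receive small
    Gaussian weights, rescaled if needed so the canonical weight is at least
    0.8 of the total absolute weight. The result has unit norm and a
    non-negative peak. Deterministic given the seed.
    """
    rng = rng_from(rng_seed, "sample_hrf")
    w = np.zeros(basis.n_basis)
    w[0] = 1.0
    if basis.n_basis > 1:
        extra = rng.normal(0.0, 0.06, size=basis.n_basis - 1)
        # enforce canonical dominance: |w0| >= 0.8 * sum |w|
        budget = 0.25  # sum|extra| <= 0.25 implies 1/(1+0.25) = 0.8
        tot = np.sum(np.abs(extra))
        if tot > budget:
            extra *= budget / tot
        w[1:] = extra
    kern = basis.kernels @ w
    if kern[np.argmax(np.abs(kern))] < 0:
        kern = -kern
    return kern / np.linalg.norm(kern)


def hrf_temporal_basis(n_time: int, tr: float, hrf: np.ndarray | None = None,
                       rel_cutoff: float = 0.1) -> np.ndarray:
    """Orthonormal basis of HRF-convolved cosines spanning BOLD-plausible
    timecourses.

    Discrete cosines up to the frequency where the HRF magnitude spectrum
    falls below ``rel_cutoff`` of its maximum are convolved with the HRF and
    orthonormalised (QR). Projecting a timecourse onto the span of the
    returned columns band-limits it to haemodynamically plausible dynamics.

    Returns an array of shape ``(n_time, k)`` with orthonormal columns.
    """
    if hrf is None:
        hrf = canonical_hrf(tr).canonical
    # band limit from the HRF magnitude spectrum
    nfft = max(256, 2 * len(hrf))
    mag = np.abs(np.fft.rfft(hrf, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=tr)
    keep = mag >= rel_cutoff * mag.max()
    f_max = freqs[keep].max() if keep.any() else freqs[1]
    # cosine basis up to f_max
    t = np.arange(n_time)
    dur = n_time * tr
    n_cos = max(2, int(np.floor(2.0 * dur * f_max)))  # DCT index k <-> freq k/(2*dur)
    n_cos = min(n_cos, n_time - 1)
    cols = [np.ones(n_time)]
    for k in range(1, n_cos + 1):
        cols.append(np.cos(np.pi * k * (t + 0.5) / n_time))
    C = np.stack(cols, axis=1)
    # convolve each cosine with the HRF (causal, truncated)
    full = np.apply_along_axis(lambda c: np.convolve(c, hrf)[:n_time], 0, C)
    Q, R = np.linalg.qr(full)
    # drop numerically null directions
    keep_cols = np.abs(np.diag(R)) > 1e-10 * np.abs(R[0, 0])
    return Q[:, keep_cols]


# --------------------------------------------------------------------------
# decomposition bundles
# --------------------------------------------------------------------------


@dataclass
class ModeDecomposition:
    """Result bundle of a mode decomposition (any method).

    Attributes
    ----------
    method
        Tag such as ``"pfm"`` or ``"ica_dr"``.
    group_maps
        ``(n_voxels, n_modes)`` group-level spatial maps.
    subject_maps
        Mapping subject_id -> ``(n_voxels, n_modes)``.
    timecourses
        Mapping ``(subject_id, run_id)`` -> ``(n_modes, n_time)``.
    amplitudes
        Mapping ``(subject_id, run_id)`` -> ``(n_modes,)`` positive scales.
    precisions
        Mapping subject_id -> ``(n_modes, n_modes)`` SPD precision of the
        mode timecourses (may be empty for methods that do not model it).
    meta
        Manifest information (seed, config hash, convergence details...).
    """

    method: str
    group_maps: np.ndarray
    subject_maps: dict = field(default_factory=dict)
    timecourses: dict = field(default_factory=dict)
    amplitudes: dict = field(default_factory=dict)
    precisions: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return self.group_maps.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.group_maps.shape[0]

    @property
    def subjects(self) -> list[str]:
        return list(self.subject_maps)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "subject_maps").mkdir(parents=True, exist_ok=True)
        (out / "timecourses").mkdir(exist_ok=True)
        (out / "amplitudes").mkdir(exist_ok=True)
        (out / "precisions").mkdir(exist_ok=True)
        np.save(out / "group_maps.npy", self.group_maps)
        for s, m in self.subject_maps.items():
            np.save(out / "subject_maps" / f"{s}.npy", m)
        for (s, r), tc in self.timecourses.items():
            np.save(out / "timecourses" / f"{s}_{r}.npy", tc)
        for (s, r), a in self.amplitudes.items():
            np.save(out / "amplitudes" / f"{s}_{r}.npy", a)
        for s, p in self.precisions.items():
            np.save(out / "precisions" / f"{s}.npy", p)
        manifest = {
            "method": self.method,
            "n_modes": int(self.n_modes),
            "subjects": list(self.subject_maps),
            "run_keys": sorted([list(k) for k in self.timecourses]),
            "meta": _jsonable(self.meta),
        }
        _write_json(out / "manifest.json", manifest)

    @classmethod
    def load(cls, in_dir: str | Path) -> "ModeDecomposition":
        src = Path(in_dir)
        man = json.loads((src / "manifest.json").read_text())
        dec = cls(
            method=man["method"],
            group_maps=np.load(src / "group_maps.npy"),
            meta=man.get("meta", {}),
        )
        for s in man["subjects"]:
            dec.subject_maps[s] = np.load(src / "subject_maps" / f"{s}.npy")
        for s, r in man["run_keys"]:
            dec.timecourses[(s, r)] = np.load(src / "timecourses" / f"{s}_{r}.npy")
            apath = src / "amplitudes" / f"{s}_{r}.npy"
            if apath.exists():
                dec.amplitudes[(s, r)] = np.load(apath)
        for p in sorted((src / "precisions").glob("*.npy")):
            dec.precisions[p.stem] = np.load(p)
        return dec


# --------------------------------------------------------------------------
# config + NIfTI helpers
# --------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON configuration file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    import yaml

    out = yaml.safe_load(text)
    return {} if out is None else out


def load_nifti_run(img_path: str | Path, mask_path: str | Path | None,
                   tr: float | None, subject_id: str, run_id: str) -> BOLDRun:
    """Read a 4-D NIfTI volume (+ optional 3-D binary mask) into a BOLDRun."""
    import nibabel as nib

    img = nib.load(str(img_path))
    vol = np.asarray(img.dataobj, dtype=np.float64)
    if vol.ndim != 4:
        raise ValueError("expected a 4-D NIfTI volume")
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.ones(vol.shape[:3], dtype=bool)
    data = vol[mask, :]
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    return BOLDRun(data=data, tr=tr, subject_id=subject_id, run_id=run_id)


def flat_to_volume(flat: np.ndarray, shape: tuple[int, int, int] | None = None
                   ) -> np.ndarray:
    """Tile a flat voxel vector/matrix into a dummy 3-D grid (for NIfTI export)."""
    flat = np.asarray(flat)
    n = flat.shape[0]
    if shape is None:
        side = int(np.ceil(n ** (1.0 / 3.0)))
        shape = (side, side, int(np.ceil(n / side**2)))
    out = np.zeros((int(np.prod(shape)),) + flat.shape[1:], dtype=flat.dtype)
    out[:n] = flat
    return out.reshape(shape + flat.shape[1:])


# --------------------------------------------------------------------------
# small shared utilities
# --------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True) + "\n")


def config_hash(cfg: Mapping) -> str:
    blob = json.dumps(_jsonable(cfg), sort_keys=True).encode()
    return f"{zlib.crc32(blob):08x}"
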