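"""Seeded fixed-point ICA with automatic restarts (internal helper)."""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from mpfm.core_io import rng_from


def fixed_point_ica(X: np.ndarray, n_components: int, seed: int,
                    max_attempts: int = 5, max_iter: int = 1000,
                    tol: float = 1e-5) -> np.ndarray:
    """Run FastICA on ``X`` (samples x channels); returns sources
    (samples x n_components), unit variance, sign fixed by positive skewness.

    Non-convergence triggers up to ``max_attempts`` seeded restarts before
    raising.
    """
    last_sources = None
    for attempt in range(max_attempts):
        rs = int(rng_from(seed, "ica", attempt).integers(2**31 - 1))
        ica = FastICA(n_components=n_components, random_state=rs,
                      max_iter=max_iter, tol=tol, whiten="unit-variance")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            sources = ica.fit_transform(X)
        converged = not any(issubclass(w.category, ConvergenceWarning)
                            for w in caught)
        last_sources = sources
        if converged:
            break
    else:
        raise RuntimeError(
            f"ICA failed to converge after {max_attempts} seeded restarts"
        )
    sources = last_sources
    sd = sources.std(axis=0)
    sd[sd == 0] = 1.0
    sources = sources / sd
    # fix sign: positive skewness per component
    skew = np.mean(sources**3, axis=0)
    sources = sources * np.where(skew < 0, -1.0, 1.0)
    return sources
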