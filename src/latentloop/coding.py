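"""Task-coding dimensions from condition-averaged trajectories.

Three directions in N-dimensional activity space separate left and right
trials at different stages of the task: a *sample* direction (first 600 ms
of the sample period), a *choice* direction (last 600 ms of the delay) and
a *response* direction (first 350 ms after the go cue).  Each is the
two-class LDA discriminant computed with the per-time-bin condition
averages inside its window as observations; the three raw directions are
then Gram–Schmidt orthogonalized (sample -> choice -> response) into an
orthonormal coding basis.

Because the neuron count usually exceeds the number of (heavily
autocorrelated, 50 ms-smoothed) time bins in a window, the within-class
scatter has far too few effective degrees of freedom to whiten against:
inverting it rotates the discriminant into sampling-noise directions that
change from session to session.  The default therefore shrinks the scatter
fully to a scaled identity (``shrinkage=1.0``), which reduces the
discriminant to the class-mean difference — the standard "coding
direction" estimator in this field.  ``shrinkage='ledoit-wolf'`` or any
intermediate intensity is available, and ``shrinkage=None`` recovers the
plain pseudo-inverse discriminant for small, well-conditioned problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.covariance import LedoitWolf

from .network import SAMPLE_PERIOD

__all__ = [
    "CodingBasis",
    "extract_coding_dimension",
    "default_windows",
    "orthogonalize_basis",
    "coding_basis_from_averages",
]

_DIM_NAMES = ("sample", "choice", "response")


@dataclass
class CodingBasis:
    """Orthonormalized sample/choice/response directions.

    ``vectors`` is N x C with columns in the order sample, choice, response;
    ``windows`` maps each dimension name to its defining time interval
    (seconds relative to the go cue); ``source`` tags whether the basis came
    from data (LDA) or from a fitted model's U columns.
    """

    vectors: np.ndarray
    windows: dict[str, tuple[float, float]]
    source: str = "data-derived"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        defect = np.linalg.norm(
            np.eye(self.vectors.shape[1]) - self.vectors.T @ self.vectors
        )
        if defect > 1e-8:
            raise ValueError(
                f"coding basis columns not orthonormal (defect {defect:.2e})"
            )

    @property
    def n_coding(self) -> int:
        return self.vectors.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.vectors[:, _DIM_NAMES.index(name)]


def default_windows(
    sample_period: tuple[float, float] = SAMPLE_PERIOD,
    go_time: float = 0.0,
) -> dict[str, tuple[float, float]]:
    """Defining windows: first 600 ms of sample, last 600 ms of delay,
    first 350 ms after the go cue."""
    return {
        "sample": (sample_period[0], sample_period[0] + 0.600),
        "choice": (go_time - 0.600, go_time),
        "response": (go_time, go_time + 0.350),
    }


def _window_mask(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    mask = (time >= window[0] - 1e-9) & (time < window[1] - 1e-9)
    if not mask.any():
        raise ValueError(f"window {window} contains no time samples")
    return mask


def extract_coding_dimension(
    avg_left: np.ndarray,
    avg_right: np.ndarray,
    time: np.ndarray,
    window: tuple[float, float],
    shrinkage: str | float | None = 1.0,
) -> np.ndarray:
    """Unit-norm two-class LDA direction for one window.

    Time bins of the two condition-averaged trajectories inside ``window``
    are the observations, labeled by condition; the discriminant is
    Sw^{-1} (mu_R - mu_L) with Sw the (optionally shrunk) pooled
    within-class scatter.  Raises if the class means coincide (no
    separation to discriminate).
    """
    avg_left = np.asarray(avg_left, dtype=float)
    avg_right = np.asarray(avg_right, dtype=float)
    time = np.asarray(time, dtype=float)
    if avg_left.shape != avg_right.shape or avg_left.shape[0] != time.size:
        raise ValueError("condition averages must share the (T, N) time grid")
    mask = _window_mask(time, window)
    XL, XR = avg_left[mask], avg_right[mask]
    mu_L, mu_R = XL.mean(axis=0), XR.mean(axis=0)
    delta = mu_R - mu_L
    scale = max(np.abs(XL).max(), np.abs(XR).max(), 1.0)
    if np.linalg.norm(delta) < 1e-10 * scale:
        raise ValueError("zero between-class separation in window; LDA undefined")

    centered = np.vstack([XL - mu_L, XR - mu_R])
    if shrinkage == "ledoit-wolf":
        Sw = LedoitWolf(assume_centered=True).fit(centered).covariance_
    else:
        Sw = centered.T @ centered / centered.shape[0]
        if shrinkage:  # scalar shrinkage toward the scaled identity
            gamma = float(shrinkage)
            mu = np.trace(Sw) / Sw.shape[0]
            Sw = (1 - gamma) * Sw + gamma * mu * np.eye(Sw.shape[0])
    w = np.linalg.lstsq(Sw, delta, rcond=None)[0]
    return w / np.linalg.norm(w)


def orthogonalize_basis(
    raw_vectors: np.ndarray,
    windows: dict[str, tuple[float, float]] | None = None,
    source: str = "data-derived",
) -> CodingBasis:
    """Gram–Schmidt orthonormalization preserving column order and span.

    The first column's direction is unchanged up to sign; a rank-deficient
    input raises an error naming the offending column.
    """
    V = np.array(raw_vectors, dtype=float)
    N, C = V.shape
    Q = np.zeros_like(V)
    for j in range(C):
        v = V[:, j].copy()
        for i in range(j):
            v -= (Q[:, i] @ V[:, j]) * Q[:, i]
        nrm = np.linalg.norm(v)
        if nrm < 1e-10 * max(np.linalg.norm(V[:, j]), 1e-30):
            name = _DIM_NAMES[j] if j < len(_DIM_NAMES) else str(j)
            raise ValueError(
                f"column {j} ({name}) is linearly dependent on earlier columns"
            )
        Q[:, j] = v / nrm
    if windows is None:
        windows = default_windows()
    return CodingBasis(vectors=Q, windows=dict(windows), source=source)


def coding_basis_from_averages(
    avg_left: np.ndarray,
    avg_right: np.ndarray,
    time: np.ndarray,
    windows: dict[str, tuple[float, float]] | None = None,
    shrinkage: str | float | None = 1.0,
) -> CodingBasis:
    """Full pipeline: per-window LDA directions, then Gram–Schmidt.

    Sign convention: the choice column is oriented so that the right
    condition's delay-period average projects positively on it.
    """
    if windows is None:
        windows = default_windows()
    raw = np.column_stack(
        [
            extract_coding_dimension(
                avg_left, avg_right, time, windows[name], shrinkage=shrinkage
            )
            for name in _DIM_NAMES
        ]
    )
    basis = orthogonalize_basis(raw, windows=windows)
    V = basis.vectors
    mask = _window_mask(np.asarray(time, float), windows["choice"])
    delay_diff = (avg_right[mask] - avg_left[mask]).mean(axis=0)
    if delay_diff @ V[:, 1] < 0:
        V[:, 1] *= -1
    return CodingBasis(vectors=V, windows=basis.windows, source=basis.source)
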