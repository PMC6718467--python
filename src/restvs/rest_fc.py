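"""Resting-state cleaning and Pearson functional connectivity.

Cleaning is a single combined OLS regression per ROI: six motion parameters,
the top principal components of the white-matter and CSF signal pools
(aCompCor-style), an intercept, and sine/cosine regressors at every discrete
Fourier frequency outside the 0.01-0.1 Hz passband.  Removing the stop-band
Fourier columns in the same model implements bandpass filtering by
regression, which keeps the filter and the nuisance projection consistent
with each other.  Connectivity is the plain Pearson correlation between the
residual ROI series; negative correlations are kept as they are.

Group-level inference on the mean connectivity matrix uses a sign-flip
permutation test of the elementwise mean against zero, with family-wise
error control through the permutation distribution of the maximum absolute
statistic over edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NuisanceModel",
    "ConnectivityMatrix",
    "GroupFcInference",
    "pca_components",
    "spectral_regressors",
    "make_nuisance_model",
    "clean_timeseries",
    "fc_matrix",
    "group_fc_inference",
]


def pca_components(signal_matrix: np.ndarray, k: int) -> np.ndarray:
    """Scores of the top-k principal components of a T x q signal pool.

    Columns are mean-centred internally; components are ordered by explained
    variance.  Used for the white-matter and CSF nuisance pools.
    """
    M = np.asarray(signal_matrix, dtype=float)
    T, q = M.shape
    if k > min(T, q):
        raise ValueError(f"k={k} exceeds min(T, q)={min(T, q)}")
    Mc = M - M.mean(axis=0)
    U, s, _ = np.linalg.svd(Mc, full_matrices=False)
    return U[:, :k] * s[:k]


def spectral_regressors(
    T: int, tr: float, f_lo: float = 0.01, f_hi: float = 0.1
) -> np.ndarray:
    """Sine/cosine columns at every grid frequency outside ``[f_lo, f_hi]``.

    Frequencies live on the discrete grid m/(T*tr), m = 1..floor(T/2).
    Regressing these columns out is bandpass filtering by regression: the
    stop-band is modelled as nuisance, the passband is untouched.  The
    all-zero sine column at the Nyquist frequency (even T) is dropped.
    """
    if not (0 <= f_lo < f_hi):
        raise ValueError("need 0 <= f_lo < f_hi")
    nyquist = 1.0 / (2.0 * tr)
    if f_hi >= nyquist:
        raise ValueError(f"f_hi={f_hi} must be below Nyquist {nyquist:.4f} Hz")
    t = np.arange(T) * tr
    cols = []
    for m in range(1, T // 2 + 1):
        f = m / (T * tr)
        if f_lo < f < f_hi or np.isclose(f, f_lo) or np.isclose(f, f_hi):
            continue
        w = 2.0 * np.pi * f * t
        cos = np.cos(w)
        sin = np.sin(w)
        cols.append(cos)
        if np.abs(sin).max() > 1e-10:  # sine vanishes exactly at Nyquist
            cols.append(sin)
    if not cols:
        return np.empty((T, 0))
    return np.column_stack(cols)


@dataclass
class NuisanceModel:
    """Combined nuisance design for a single cleaning regression."""

    motion: np.ndarray
    wm_pcs: np.ndarray
    csf_pcs: np.ndarray
    spectral: np.ndarray
    include_intercept: bool = True

    def matrix(self) -> np.ndarray:
        T = self.motion.shape[0]
        parts = []
        if self.include_intercept:
            parts.append(np.ones((T, 1)))
        parts += [self.motion, self.wm_pcs, self.csf_pcs, self.spectral]
        X = np.hstack([np.atleast_2d(p).reshape(T, -1) for p in parts])
        if X.shape[1] >= T:
            raise ValueError(
                f"nuisance model has {X.shape[1]} columns for T={T} volumes"
            )
        return X


def make_nuisance_model(
    motion: np.ndarray,
    wm_signals: np.ndarray,
    csf_signals: np.ndarray,
    tr: float,
    n_pcs: int = 3,
    band: tuple[float, float] = (0.01, 0.1),
) -> NuisanceModel:
    """Standard nuisance model: motion + k WM PCs + k CSF PCs + stop-band.

    ``n_pcs`` components are taken from each tissue pool (3 per tissue by
    default, 6 in total).
    """
    T = motion.shape[0]
    return NuisanceModel(
        motion=np.asarray(motion, dtype=float),
        wm_pcs=pca_components(wm_signals, min(n_pcs, np.asarray(wm_signals).shape[1])),
        csf_pcs=pca_components(csf_signals, min(n_pcs, np.asarray(csf_signals).shape[1])),
        spectral=spectral_regressors(T, tr, *band),
    )


def clean_timeseries(Y: np.ndarray, nuisance: NuisanceModel) -> np.ndarray:
    """Residuals of each ROI column regressed on the full nuisance matrix."""
    Y = np.asarray(Y, dtype=float)
    X = nuisance.matrix()
    if X.shape[0] != Y.shape[0]:
        raise ValueError("nuisance and data must have the same number of volumes")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Pearson correlation matrix."""

    r: np.ndarray
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.r, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if np.abs(R - R.T).max() > 1e-12:
            raise ValueError("connectivity matrix must be symmetric")
        self.r = R

    @property
    def n_roi(self) -> int:
        return self.r.shape[0]


def fc_matrix(clean_ts: np.ndarray, roi_names: list[str] | None = None) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of the cleaned ROI series.

    Negative correlations are kept; nothing is thresholded.
    """
    Y = np.asarray(clean_ts, dtype=float)
    sd = Y.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = (
            [roi_names[i] for i in dead] if roi_names is not None else dead.tolist()
        )
        raise ValueError(f"zero-variance ROI column(s): {names}")
    R = np.corrcoef(Y, rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return ConnectivityMatrix(r=R, roi_names=roi_names)


@dataclass
class GroupFcInference:
    """Elementwise group inference on the mean connectivity matrix."""

    mean_r: np.ndarray
    p_fwe: np.ndarray
    sig_mask: np.ndarray
    alpha: float
    n_perm: int
    fisher_z: bool = False
    extras: dict = field(default_factory=dict)


def group_fc_inference(
    matrices: list[ConnectivityMatrix] | list[np.ndarray],
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    fisher_z: bool = False,
) -> GroupFcInference:
    """Sign-flip permutation test of the mean FC matrix against zero.

    The statistic per edge is the across-subject mean correlation (optionally
    Fisher z-transformed first).  The null flips the sign of each subject's
    whole matrix independently; family-wise error is controlled by comparing
    each |mean| with the permutation distribution of the maximum |mean| over
    all edges: p = (1 + #{perm max >= observed}) / (1 + n_perm), two-sided.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mats = [m.r if isinstance(m, ConnectivityMatrix) else np.asarray(m, float) for m in matrices]
    if len(mats) < 2:
        raise ValueError("group inference needs at least 2 subjects")
    n = mats[0].shape[0]
    iu = np.triu_indices(n, k=1)
    V = np.stack([m[iu] for m in mats])  # subjects x edges
    if fisher_z:
        V = np.arctanh(np.clip(V, -1 + 1e-12, 1 - 1e-12))
    obs = V.mean(axis=0)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, V.shape[0]))
    max_null = np.abs(signs @ V / V.shape[0]).max(axis=1)
    p_edge = (1 + (max_null[:, None] >= np.abs(obs)[None, :]).sum(axis=0)) / (1 + n_perm)
    mean_mat = np.zeros((n, n))
    mean_mat[iu] = obs
    mean_mat = mean_mat + mean_mat.T
    if not fisher_z:
        np.fill_diagonal(mean_mat, 1.0)
    p_mat = np.ones((n, n))
    p_mat[iu] = p_edge
    p_mat = np.minimum(p_mat, p_mat.T)
    sig = np.zeros((n, n), dtype=bool)
    sig[iu] = p_edge <= alpha
    sig = sig | sig.T
    return GroupFcInference(
        mean_r=mean_mat, p_fwe=p_mat, sig_mask=sig, alpha=alpha,
        n_perm=n_perm, fisher_z=fisher_z,
    )
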