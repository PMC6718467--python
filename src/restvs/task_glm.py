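"""First-level modelling of the monetary incentive delay (MID) task.

The MID task presents a cue announcing a potential monetary gain or loss
(0, 20, 100 or 500 yen), an anticipation period, a speeded target response
and a feedback screen.  The first-level general linear model convolves one
boxcar regressor per condition with the canonical double-gamma hemodynamic
response function, adds the six realignment (motion) parameters and per-run
intercepts, and estimates condition amplitudes by ordinary least squares.
Gain-anticipation contrasts (20/100/500 vs. 0 yen, plus their average) are
the inputs to the reward-sensitivity measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "TaskDesign",
    "GlmResult",
    "ContrastSet",
    "canonical_hrf",
    "build_design_matrix",
    "fit_glm",
    "contrasts",
    "sphere_roi_values",
    "scheme_condition_labels",
    "TWO_RUN_GAIN_LOSS",
    "ONE_RUN_GAIN",
    "GAIN_AMOUNTS",
    "ant_gain_label",
]

TWO_RUN_GAIN_LOSS = "two_run_gain_loss"
ONE_RUN_GAIN = "one_run_gain"

GAIN_AMOUNTS = (0, 20, 100, 500)
LOSS_AMOUNTS = (0, 20, 100, 500)


def ant_gain_label(amount: int) -> str:
    """Regressor label for anticipation of a given gain amount (yen)."""
    return f"ant_gain_{amount:03d}"


def _ant_loss_label(amount: int) -> str:
    return f"ant_loss_{amount:03d}"


def scheme_condition_labels(scheme: str) -> list[str]:
    """Ordered condition-regressor labels for a design scheme.

    ``two_run_gain_loss``: 8 anticipation conditions (gain/loss x 4 amounts),
    2 control events (neutral cue / neutral feedback) and 14 outcome
    regressors (gain/loss x 20/100/500 x hit/miss, plus one common feedback
    each for +-0 yen) -- 24 in total.  ``one_run_gain``: 4 gain-anticipation
    conditions, 8 feedback regressors (4 amounts x hit/miss) and the 2
    control events -- 14 in total.
    """
    if scheme == TWO_RUN_GAIN_LOSS:
        labels = [ant_gain_label(a) for a in GAIN_AMOUNTS]
        labels += [_ant_loss_label(a) for a in LOSS_AMOUNTS]
        labels += ["neutral_cue", "neutral_fb"]
        for sign in ("gain", "loss"):
            labels.append(f"fb_{sign}_000")
        for sign in ("gain", "loss"):
            for a in (20, 100, 500):
                for out in ("hit", "miss"):
                    labels.append(f"fb_{sign}_{a:03d}_{out}")
        return labels
    if scheme == ONE_RUN_GAIN:
        labels = [ant_gain_label(a) for a in GAIN_AMOUNTS]
        labels += ["neutral_cue", "neutral_fb"]
        for a in GAIN_AMOUNTS:
            for out in ("hit", "miss"):
                labels.append(f"fb_gain_{a:03d}_{out}")
        return labels
    raise ValueError(f"unknown design scheme: {scheme!r}")


@dataclass
class TaskDesign:
    """Event list for one subject's MID session.

    events: list of ``(onset_s, duration_s, condition)`` tuples; onsets are
    relative to the start of the (concatenated) session.  run_boundaries
    holds the first volume index of each run.
    """

    events: list[tuple[float, float, str]]
    scheme: str
    run_boundaries: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        valid = set(scheme_condition_labels(self.scheme))
        for onset, duration, cond in self.events:
            if onset < 0:
                raise ValueError(f"negative onset {onset}")
            if cond not in valid:
                raise ValueError(f"condition {cond!r} not in scheme {self.scheme!r}")

    @property
    def condition_labels(self) -> list[str]:
        return scheme_condition_labels(self.scheme)


@dataclass
class GlmResult:
    """Condition amplitude estimates from a first-level fit."""

    betas: dict[str, np.ndarray]  # condition label -> value per ROI/voxel
    residual_variance: np.ndarray
    design_rank: int


@dataclass
class ContrastSet:
    """The four gain-anticipation contrasts (amount vs. 0 yen)."""

    small: np.ndarray
    medium: np.ndarray
    maximal: np.ndarray
    average: np.ndarray


def canonical_hrf(tr: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled every `tr` seconds.

    Difference of two gamma densities: peak delay 6 s, undershoot delay 16 s,
    dispersions 1, peak-to-undershoot ratio 6.  Scaled to unit peak.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration_s + tr / 2, tr)
    h = _gamma_dist.pdf(t, a=6.0, scale=1.0) - _gamma_dist.pdf(t, a=16.0, scale=1.0) / 6.0
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def build_design_matrix(
    design: TaskDesign,
    tr: float,
    T: int,
    motion: np.ndarray | None = None,
    oversample: int = 16,
) -> tuple[np.ndarray, list[str]]:
    """HRF-convolved design matrix: condition columns, motion, run intercepts.

    Boxcars are built on a grid of ``tr/oversample`` seconds, convolved with
    the canonical HRF, and sampled at the volume acquisition times.  Returns
    ``(X, labels)`` with condition columns first (in scheme order), then the
    six motion columns (omitted when ``motion`` is None), then one intercept
    per run.
    """
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != T:
            raise ValueError("motion must have T rows")
    cond_labels = design.condition_labels
    dt = tr / oversample
    n_fine = T * oversample
    hrf = canonical_hrf(dt)
    scan_end = T * tr
    cols = np.zeros((T, len(cond_labels)))
    boxcars: dict[str, np.ndarray] = {c: np.zeros(n_fine) for c in cond_labels}
    for onset, duration, cond in design.events:
        if onset >= scan_end:
            raise ValueError(f"event onset {onset} s beyond scan end {scan_end} s")
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, int(round((onset + duration) / dt)))
        boxcars[cond][i0:min(i1, n_fine)] = 1.0
    for j, cond in enumerate(cond_labels):
        conv = np.convolve(boxcars[cond], hrf)[:n_fine]
        cols[:, j] = conv[::oversample]
    labels = list(cond_labels)
    X = [cols]
    if motion is not None:
        labels += [f"motion_{k}" for k in range(1, 7)]
        X.append(motion)
    bounds = list(design.run_boundaries) + [T]
    for r in range(len(design.run_boundaries)):
        col = np.zeros(T)
        col[bounds[r]:bounds[r + 1]] = 1.0
        X.append(col[:, None])
        labels.append(f"intercept_run{r + 1}")
    return np.hstack(X), labels


def fit_glm(Y: np.ndarray, X: np.ndarray, labels: list[str] | None = None) -> GlmResult:
    """Ordinary-least-squares fit of every data column on the design.

    Rank-deficient designs are solved with the minimum-norm (pseudoinverse)
    solution and a warning.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and X.shape[0] != 1:
        Y = Y.T
    T, p = X.shape
    rank = int(np.linalg.matrix_rank(X))
    if T <= rank:
        raise ValueError(f"T={T} must exceed design rank {rank}")
    if rank < p:
        warnings.warn(
            f"design matrix rank-deficient ({rank} < {p} columns); "
            "minimum-norm solution used",
            stacklevel=2,
        )
    beta = np.linalg.pinv(X) @ Y
    resid = Y - X @ beta
    dof = max(T - rank, 1)
    resid_var = (resid**2).sum(axis=0) / dof
    if labels is None:
        labels = [f"col_{j}" for j in range(p)]
    betas = {lab: beta[j] for j, lab in enumerate(labels)}
    return GlmResult(betas=betas, residual_variance=resid_var, design_rank=rank)


def contrasts(glm: GlmResult) -> ContrastSet:
    """Gain-anticipation contrasts: each amount's beta minus the 0-yen beta.

    ``average`` uses equal 1/3 weights on the 20/100/500-yen betas minus the
    0-yen beta, i.e. the mean of the three pairwise contrasts.
    """
    needed = {a: ant_gain_label(a) for a in GAIN_AMOUNTS}
    for a, lab in needed.items():
        if lab not in glm.betas:
            raise KeyError(f"missing anticipation condition {lab!r} in GLM result")
    b0 = np.asarray(glm.betas[needed[0]], dtype=float)
    small = np.asarray(glm.betas[needed[20]], dtype=float) - b0
    medium = np.asarray(glm.betas[needed[100]], dtype=float) - b0
    maximal = np.asarray(glm.betas[needed[500]], dtype=float) - b0
    average = (small + medium + maximal) / 3.0
    return ContrastSet(small=small, medium=medium, maximal=maximal, average=average)


def sphere_roi_values(
    values_on_grid: np.ndarray,
    grid_affine: np.ndarray,
    centers_mm: np.ndarray,
    radius_mm: float,
    mask: np.ndarray | None = None,
) -> float:
    """Mean of a gridded field over the union of spheres around `centers_mm`.

    Membership is inclusive (Euclidean distance in mm <= radius); overlapping
    spheres are unioned before averaging, so shared voxels count once.  An
    optional boolean mask is intersected before averaging.
    """
    vals = np.asarray(values_on_grid, dtype=float)
    centers = np.atleast_2d(np.asarray(centers_mm, dtype=float))
    idx = np.stack(np.meshgrid(*(np.arange(s) for s in vals.shape), indexing="ij"), axis=-1)
    idx = idx.reshape(-1, 3)
    mm = idx @ np.asarray(grid_affine)[:3, :3].T + np.asarray(grid_affine)[:3, 3]
    member = np.zeros(len(mm), dtype=bool)
    for c in centers:
        member |= np.linalg.norm(mm - c, axis=1) <= radius_mm
    if mask is not None:
        member &= np.asarray(mask, dtype=bool).reshape(-1)
    if not member.any():
        raise ValueError("ROI is empty: no grid point within radius of any center")
    return float(vals.reshape(-1)[member].mean())
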