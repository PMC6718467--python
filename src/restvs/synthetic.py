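"""Seeded synthetic cohorts with known ground truth.

The generator emulates the data the analysis consumes: per-subject ROI-level
resting BOLD series with block-structured network covariance and AR(1)
temporal autocorrelation, six motion parameters and low-rank WM/CSF signal
pools mixed linearly into the ROI series, MID-task BOLD built from a trial
design through the canonical HRF, and a sparse linear ground-truth mapping
from connectivity edges to the three ventral-striatum targets.  Every record
carries its simulation truth so recovery can be checked against it.

Default cohort: 45 subjects in three groups (14/15/16), 40 ROIs over the
nine network labels, resting TR/volumes mirroring the three acquisition
sites (2.5 s x 120, 2.0 s x 143, 2.7 s x 107), task TR 2.0 s with the
two-run gain/loss scheme for groups 1 and 3 and the one-run gain scheme for
group 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import rest_fc
from .networks import NETWORKS
from .reward import VsMeasures
from .task_glm import (
    GAIN_AMOUNTS,
    ONE_RUN_GAIN,
    TWO_RUN_GAIN_LOSS,
    TaskDesign,
    ant_gain_label,
    build_design_matrix,
    scheme_condition_labels,
)

__all__ = [
    "RoiSet",
    "GroundTruth",
    "SubjectRecord",
    "Cohort",
    "CohortConfig",
    "TrialTiming",
    "make_roi_set",
    "make_rest_cov",
    "simulate_rest_ts",
    "make_mid_design",
    "simulate_task_ts",
    "link_targets",
    "betas_for_targets",
    "make_cohort",
]

# MNI-like bounding box (mm) for sampling ROI centres
_MNI_BOX = np.array([[-70.0, 70.0], [-105.0, 70.0], [-45.0, 75.0]])


@dataclass
class RoiSet:
    """ROI centres (MNI mm), sphere radius and one network label per ROI."""

    coordinates: np.ndarray
    radius_mm: float
    network_labels: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.network_labels = np.asarray(self.network_labels)
        if self.coordinates.shape[0] < 2:
            raise ValueError("need at least 2 ROIs")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("ROI coordinates must be finite")
        unknown = set(self.network_labels) - set(NETWORKS)
        if unknown:
            raise ValueError(f"unknown network labels: {sorted(unknown)}")

    @property
    def n_roi(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_edges(self) -> int:
        n = self.n_roi
        return n * (n - 1) // 2


def make_roi_set(
    n_roi: int,
    networks: dict[str, int] | None = None,
    radius_mm: float = 6.0,
    seed: int | None = 0,
) -> RoiSet:
    """Desk-scale ROI set: random MNI-box centres, contiguous network blocks.

    ``networks`` maps label -> ROI count (must sum to n_roi); by default ROIs
    are split as evenly as possible over the nine labels, remainders going to
    the later labels so DM/BG/CB get the extras.
    """
    if n_roi < 2:
        raise ValueError("n_roi must be >= 2")
    if networks is None:
        base, extra = divmod(n_roi, len(NETWORKS))
        networks = {
            lab: base + (1 if i >= len(NETWORKS) - extra else 0)
            for i, lab in enumerate(NETWORKS)
        }
    if sum(networks.values()) != n_roi or any(v < 0 for v in networks.values()):
        raise ValueError("network counts must be non-negative and sum to n_roi")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(_MNI_BOX[:, 0], _MNI_BOX[:, 1], size=(n_roi, 3))
    labels = np.concatenate([
        np.repeat(lab, networks.get(lab, 0)) for lab in NETWORKS
    ])
    return RoiSet(coordinates=coords, radius_mm=radius_mm, network_labels=labels)


def _nearest_pd_correlation(R: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped PD repair, renormalised to unit diagonal."""
    w, V = np.linalg.eigh(R)
    w = np.maximum(w, min_eig)
    R2 = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    return (R2 + R2.T) / 2.0


def make_rest_cov(
    roi_set: RoiSet | np.ndarray,
    within_net_r: float = 0.5,
    between_net_r: float = 0.1,
) -> np.ndarray:
    """Block-structured correlation matrix over the ROI networks.

    ``within_net_r`` inside each network block, ``between_net_r`` elsewhere,
    1 on the diagonal.  A nearest-PD eigenvalue repair is applied (with a
    warning) if the block construction is not positive definite.
    """
    if not (-1 < between_net_r <= within_net_r < 1):
        raise ValueError("need -1 < between_net_r <= within_net_r < 1")
    labels = roi_set.network_labels if isinstance(roi_set, RoiSet) else np.asarray(roi_set)
    same = labels[:, None] == labels[None, :]
    R = np.where(same, within_net_r, between_net_r).astype(float)
    np.fill_diagonal(R, 1.0)
    min_eig = float(np.linalg.eigvalsh(R).min())
    if min_eig <= 0:
        warnings.warn(
            f"block correlation not PD (min eig {min_eig:.3g}); nearest-PD repair applied",
            stacklevel=2,
        )
        R = _nearest_pd_correlation(R)
        if np.linalg.eigvalsh(R).min() <= 0:
            raise np.linalg.LinAlgError("correlation matrix not PD after repair")
    return R


@dataclass
class RestSim:
    """One subject's simulated rest session with recorded confound mixing."""

    ts: np.ndarray          # confounded ROI series (what the scanner 'sees')
    clean: np.ndarray       # pre-mixing ROI series
    motion: np.ndarray      # T x 6 realignment parameters
    wm_signals: np.ndarray  # T x q white-matter pool (low-rank)
    csf_signals: np.ndarray
    mixing: dict[str, np.ndarray] = field(default_factory=dict)


def _smooth_noise(rng: np.random.Generator, T: int, n: int, width: int) -> np.ndarray:
    """Gaussian-smoothed white noise columns (slow fluctuations)."""
    z = rng.standard_normal((T + 2 * width, n))
    k = np.exp(-0.5 * (np.arange(-width, width + 1) / max(width / 2, 1)) ** 2)
    k /= k.sum()
    sm = np.apply_along_axis(lambda c: np.convolve(c, k, mode="same"), 0, z)
    return sm[width:width + T]


def simulate_rest_ts(
    cov: np.ndarray,
    T: int,
    tr: float,
    ar_coef: float = 0.3,
    seed: int | None = None,
    n_tissue_cols: int = 5,
    tissue_rank: int = 2,
    confound_strength: float = 0.3,
) -> RestSim:
    """AR(1)-filtered multivariate Gaussian rest series plus confounds.

    Innovations have spatial covariance ``cov``; the AR(1) filter uses
    x_t = a x_{t-1} + sqrt(1-a^2) z_t so the stationary spatial covariance
    stays exactly ``cov``.  Motion parameters are smooth random walks; the
    WM/CSF pools are exactly low rank so their top principal components span
    the injected confound directions, making regression-based removal exact.
    """
    if T < 20:
        raise ValueError("T must be >= 20")
    if not abs(ar_coef) < 1:
        raise ValueError("|ar_coef| must be < 1")
    cov = np.asarray(cov, dtype=float)
    n_roi = cov.shape[0]
    rng = np.random.default_rng(seed)
    try:
        Lc = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("rest covariance is not positive definite") from e
    Z = rng.standard_normal((T, n_roi)) @ Lc.T
    X = np.empty_like(Z)
    X[0] = Z[0]
    a, b = ar_coef, np.sqrt(1.0 - ar_coef**2)
    for t in range(1, T):
        X[t] = a * X[t - 1] + b * Z[t]

    motion = np.cumsum(0.05 * rng.standard_normal((T, 6)), axis=0)
    wm_latent = _smooth_noise(rng, T, tissue_rank, width=5)
    csf_latent = _smooth_noise(rng, T, tissue_rank, width=5)
    wm_load = rng.standard_normal((tissue_rank, n_tissue_cols))
    csf_load = rng.standard_normal((tissue_rank, n_tissue_cols))
    wm_signals = wm_latent @ wm_load
    csf_signals = csf_latent @ csf_load

    A_mot = confound_strength * 0.5 * rng.standard_normal((6, n_roi))
    A_wm = confound_strength * rng.standard_normal((tissue_rank, n_roi))
    A_csf = confound_strength * rng.standard_normal((tissue_rank, n_roi))
    ts = X + motion @ A_mot + wm_latent @ A_wm + csf_latent @ A_csf
    return RestSim(
        ts=ts, clean=X, motion=motion,
        wm_signals=wm_signals, csf_signals=csf_signals,
        mixing={"motion": A_mot, "wm": A_wm, "csf": A_csf},
    )


@dataclass(frozen=True)
class TrialTiming:
    """Per-event durations (seconds).  The anticipation regressor spans the
    cue-to-target interval; its length is jittered per trial."""

    cue_s: float = 0.5
    ant_min_s: float = 2.0
    ant_max_s: float = 2.5
    target_s: float = 0.5
    feedback_s: float = 1.65
    iti_min_s: float = 2.5
    iti_max_s: float = 3.5
    hit_rate: float = 0.66


def _one_run_trials(scheme: str, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Shuffled (kind, amount) trial list for one run of a scheme."""
    trials: list[tuple[str, int]] = []
    if scheme == TWO_RUN_GAIN_LOSS:
        # 90 trials: 40 gain + 40 loss (10 per amount) + 10 neutral
        for amt in GAIN_AMOUNTS:
            trials += [("gain", amt)] * 10 + [("loss", amt)] * 10
        trials += [("neutral", 0)] * 10
    elif scheme == ONE_RUN_GAIN:
        # stated as 90 trials but 62 win + 18 neutral (= 80); the explicit
        # counts are followed
        per_amt = [16, 16, 15, 15]
        for amt, c in zip(GAIN_AMOUNTS, per_amt):
            trials += [("gain", amt)] * c
        trials += [("neutral", 0)] * 18
    else:
        raise ValueError(f"unknown design scheme: {scheme!r}")
    rng.shuffle(trials)
    return trials


def make_mid_design(
    scheme: str,
    seed: int | None = None,
    timing: TrialTiming = TrialTiming(),
    tr: float = 2.0,
) -> TaskDesign:
    """Pseudo-randomised MID trial sequence as an event table.

    Two concatenated runs for ``two_run_gain_loss`` (run boundaries recorded
    in volumes); hit/miss feedback drawn at the staircase-adjusted 66% hit
    rate.  Anticipation events span cue onset to target onset.
    """
    rng = np.random.default_rng(seed)
    events: list[tuple[float, float, str]] = []
    n_runs = 2 if scheme == TWO_RUN_GAIN_LOSS else 1
    run_boundaries = [0]
    t_run_start = 0.0
    for run in range(n_runs):
        t = t_run_start + 4.0  # lead-in
        for kind, amt in _one_run_trials(scheme, rng):
            ant = rng.uniform(timing.ant_min_s, timing.ant_max_s)
            cue_to_target = timing.cue_s + ant
            fb_onset = t + cue_to_target + timing.target_s
            if kind == "neutral":
                events.append((t, timing.cue_s, "neutral_cue"))
                events.append((fb_onset, timing.feedback_s, "neutral_fb"))
            else:
                events.append((t, cue_to_target, f"ant_{kind}_{amt:03d}"))
                hit = rng.random() < timing.hit_rate
                if scheme == TWO_RUN_GAIN_LOSS and amt == 0:
                    fb = f"fb_{kind}_000"  # common feedback for +-0 yen
                else:
                    fb = f"fb_{kind}_{amt:03d}_{'hit' if hit else 'miss'}"
                events.append((fb_onset, timing.feedback_s, fb))
            t = fb_onset + timing.feedback_s + rng.uniform(timing.iti_min_s, timing.iti_max_s)
        run_len_vol = int(np.ceil((t + 8.0 - t_run_start) / tr))
        t_run_start += run_len_vol * tr
        if run < n_runs - 1:
            run_boundaries.append(run_boundaries[-1] + run_len_vol)
    return TaskDesign(events=events, scheme=scheme, run_boundaries=run_boundaries)


def required_volumes(design: TaskDesign, tr: float, pad_s: float = 8.0) -> int:
    """Smallest volume count that contains every event plus padding."""
    end = max(onset + dur for onset, dur, _ in design.events)
    return int(np.ceil((end + pad_s) / tr))


def simulate_task_ts(
    design: TaskDesign,
    true_task_betas: dict[str, float | np.ndarray],
    tr: float,
    T: int,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Task series = HRF-convolved design x true betas + Gaussian noise."""
    X, labels = build_design_matrix(design, tr, T)
    cond_labels = design.condition_labels
    beta = np.zeros((len(labels), np.atleast_1d(
        np.asarray(next(iter(true_task_betas.values())), dtype=float)).size))
    for lab, val in true_task_betas.items():
        if lab not in cond_labels:
            raise KeyError(f"beta given for unknown condition {lab!r}")
        beta[labels.index(lab)] = np.atleast_1d(np.asarray(val, dtype=float))
    Y = X @ beta
    if noise_sd > 0:
        Y = Y + np.random.default_rng(seed).normal(0.0, noise_sd, size=Y.shape)
    return Y


def betas_for_targets(
    sensitivity: float, maximal: float, average: float, baseline: float = 0.0
) -> dict[str, float]:
    """Gain-anticipation amplitudes whose contrasts reproduce the targets.

    Inverts the measure definitions: with contrasts c_s, c_m, c_x (20/100/500
    vs 0 yen), sensitivity = (c_x - c_s)/2 and average = (c_s + c_m + c_x)/3,
    so c_x = maximal, c_s = maximal - 2*sensitivity and
    c_m = 3*average - c_s - c_x.
    """
    c_x = maximal
    c_s = maximal - 2.0 * sensitivity
    c_m = 3.0 * average - c_s - c_x
    return {
        ant_gain_label(0): baseline,
        ant_gain_label(20): baseline + c_s,
        ant_gain_label(100): baseline + c_m,
        ant_gain_label(500): baseline + c_x,
    }


@dataclass
class GroundTruth:
    """Simulation truth: sparse edge weights per target and noise levels."""

    true_edge_weights: dict[str, np.ndarray]
    noise_sd_target: float
    rest_cov: dict[int, np.ndarray]
    true_task_betas: dict[str, dict[str, float]]
    support_edges: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    support_network: str = "DM"
    modes: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    mode_amps: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    fc_features: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))


@dataclass
class SubjectRecord:
    """One synthetic (or ingested) subject."""

    subject_id: str
    cohort: int
    rest_ts: np.ndarray
    tr_rest: float
    motion: np.ndarray
    wm_signals: np.ndarray
    csf_signals: np.ndarray
    task_ts: np.ndarray
    tr_task: float
    design: TaskDesign | None
    targets_true: VsMeasures | None = None
    rest_clean_true: np.ndarray | None = None


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    roi_set: RoiSet
    ground_truth: GroundTruth | None = None

    @property
    def cohort_labels(self) -> np.ndarray:
        return np.array([s.cohort for s in self.subjects])

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the default desk-scale cohort."""

    n_per_cohort: tuple[int, ...] = (14, 15, 16)
    n_roi: int = 40
    radius_mm: float = 6.0
    # per-cohort rest acquisition (tr_s, volumes), mirroring the three sites
    rest_acq: tuple[tuple[float, int], ...] = ((2.5, 120), (2.0, 143), (2.7, 107))
    tr_task: float = 2.0
    schemes: tuple[str, ...] = (TWO_RUN_GAIN_LOSS, ONE_RUN_GAIN, TWO_RUN_GAIN_LOSS)
    within_net_r: float = 0.5
    between_net_r: float = 0.1
    ar_coef: float = 0.3
    # between-subject connectivity variation: a few latent modes (one aligned
    # with the true weight pattern, the rest distractors on other networks)
    # plus a small edgewise jitter
    mode_strength: float = 0.2
    n_distractor_modes: int = 4
    mode_amp_clip: float = 2.5
    subject_jitter_sd: float = 0.03
    # true-weight support: within-network edges of the support network plus a
    # few edges from it into every other network (a dominant network with
    # cross-network involvement)
    n_nonzero_edges: int = 10
    n_cross_per_network: int = 5
    weight_scale: float = 0.07
    noise_sd_target: float = 0.5
    task_noise_sd: float = 1.0
    support_network: str = "DM"
    band: tuple[float, float] = (0.01, 0.1)
    n_pcs: int = 3
    simulate_task: bool = True  # False: rest-only cohort (targets still linked)


def link_targets(
    fc_features: np.ndarray,
    ground_truth: GroundTruth,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Targets = features . true weights + Gaussian noise, per measure."""
    F = np.atleast_2d(np.asarray(fc_features, dtype=float))
    rng = np.random.default_rng(seed)
    out = {}
    for name, w in ground_truth.true_edge_weights.items():
        if F.shape[1] != w.size:
            raise ValueError(
                f"feature length {F.shape[1]} != weight length {w.size} for {name!r}"
            )
        y = F @ w
        if ground_truth.noise_sd_target > 0:
            y = y + rng.normal(0.0, ground_truth.noise_sd_target, size=y.shape)
        out[name] = y
    return out


def _make_true_weights(
    roi_set: RoiSet, config: CohortConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Sparse weight vectors sharing one support, concentrated in one network."""
    n = roi_set.n_roi
    iu = np.triu_indices(n, k=1)
    in_net = roi_set.network_labels == config.support_network
    within = np.flatnonzero(in_net[iu[0]] & in_net[iu[1]])
    parts = [rng.choice(within, size=min(config.n_nonzero_edges, within.size),
                        replace=False)]
    for lab in NETWORKS:
        if lab == config.support_network:
            continue
        in_other = roi_set.network_labels == lab
        cross = np.flatnonzero((in_net[iu[0]] & in_other[iu[1]])
                               | (in_other[iu[0]] & in_net[iu[1]]))
        if cross.size:
            parts.append(rng.choice(
                cross, size=min(config.n_cross_per_network, cross.size), replace=False))
    support = np.concatenate(parts)
    # equal-magnitude random-sign weights on the support
    base = rng.choice([-1.0, 1.0], size=support.size) * config.weight_scale
    alt1 = rng.choice([-1.0, 1.0], size=support.size) * config.weight_scale
    alt2 = rng.choice([-1.0, 1.0], size=support.size) * config.weight_scale
    d = roi_set.n_edges
    weights = {}
    # shared support and strongly overlapping values: the three measures'
    # weight patterns correlate, as do the resulting targets
    for name, vec in (
        ("sensitivity", base),
        ("maximal", 0.8 * base + 0.2 * alt1),
        ("average", 0.6 * base + 0.4 * alt2),
    ):
        w = np.zeros(d)
        w[support] = vec
        weights[name] = w
    return weights, support


def _make_connectivity_modes(
    roi_set: RoiSet,
    base_weights: np.ndarray,
    support: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent between-subject connectivity modes (edge space).

    Individual differences in FC are dominated by a handful of shared
    connectivity patterns rather than independent edgewise noise; the first
    mode here is sign-aligned with the true weight support (the expression
    of that pattern is what drives the VS targets), the remaining modes are
    distractors living on other networks' within-network edges.
    """
    d = roi_set.n_edges
    iu = np.triu_indices(roi_set.n_roi, k=1)
    modes = []
    m0 = np.zeros(d)
    m0[support] = config.mode_strength * np.sign(base_weights[support])
    modes.append(m0)
    others = [lab for lab in NETWORKS if lab != config.support_network]
    for j in range(config.n_distractor_modes):
        lab = others[j % len(others)]
        in_net = roi_set.network_labels == lab
        edges = np.flatnonzero(in_net[iu[0]] | in_net[iu[1]])
        pick = rng.choice(edges, size=min(config.n_nonzero_edges, edges.size), replace=False)
        m = np.zeros(d)
        m[pick] = config.mode_strength * rng.choice([-1.0, 1.0], size=pick.size)
        modes.append(m)
    return np.stack(modes)


def _fc_features_for_subject(
    rest: RestSim, tr: float, config: CohortConfig
) -> np.ndarray:
    """The pipeline's own cleaning + Pearson path, vectorised to edges."""
    nuis = rest_fc.make_nuisance_model(
        rest.motion, rest.wm_signals, rest.csf_signals, tr,
        n_pcs=config.n_pcs, band=config.band,
    )
    clean = rest_fc.clean_timeseries(rest.ts, nuis)
    C = rest_fc.fc_matrix(clean)
    iu = np.triu_indices(C.n_roi, k=1)
    return C.r[iu]


def make_cohort(config: CohortConfig = CohortConfig(), seed: int = 0) -> Cohort:
    """Generate a full seeded cohort with recorded ground truth.

    Targets are linked to the connectivity features obtained by the package's
    own cleaning + Pearson path, so with ``noise_sd_target = 0`` the
    feature-to-target map is exactly linear.  Task series are then generated
    whose gain-anticipation contrasts reproduce those targets, closing the
    loop from rest FC through the task GLM back to the linked truth.
    """
    ss = np.random.SeedSequence(seed)
    rng_global, rng_subjects = [np.random.default_rng(s) for s in ss.spawn(2)]
    roi_set = make_roi_set(config.n_roi, radius_mm=config.radius_mm,
                           seed=rng_global.integers(2**31))
    base_R = make_rest_cov(roi_set, config.within_net_r, config.between_net_r)
    weights, support = _make_true_weights(roi_set, config, rng_global)
    modes = _make_connectivity_modes(roi_set, weights["sensitivity"], support,
                                     config, rng_global)
    iu = np.triu_indices(config.n_roi, k=1)

    sims: list[RestSim] = []
    features = []
    cohorts = []
    trs = []
    amps = []
    for c, n_c in enumerate(config.n_per_cohort, start=1):
        tr_rest, T_rest = config.rest_acq[(c - 1) % len(config.rest_acq)]
        for _ in range(n_c):
            srng = np.random.default_rng(rng_subjects.integers(2**31))
            # subject covariance: group blocks + latent modes + edge jitter
            amp = np.clip(srng.standard_normal(modes.shape[0]),
                          -config.mode_amp_clip, config.mode_amp_clip)
            amps.append(amp)
            dv = amp @ modes + srng.normal(0.0, config.subject_jitter_sd,
                                           size=modes.shape[1])
            D = np.zeros_like(base_R)
            D[iu] = dv
            D = D + D.T
            R_i = _nearest_pd_correlation(np.clip(base_R + D, -0.9, 0.9))
            rest = simulate_rest_ts(
                R_i, T_rest, tr_rest, ar_coef=config.ar_coef,
                seed=srng.integers(2**31),
            )
            sims.append(rest)
            features.append(_fc_features_for_subject(rest, tr_rest, config))
            cohorts.append(c)
            trs.append(tr_rest)

    F = np.vstack(features)
    gt = GroundTruth(
        true_edge_weights=weights,
        noise_sd_target=config.noise_sd_target,
        rest_cov={c: base_R for c in range(1, len(config.n_per_cohort) + 1)},
        true_task_betas={},
        support_edges=support,
        support_network=config.support_network,
        modes=modes,
        mode_amps=np.vstack(amps),
        fc_features=F,
    )
    targets = link_targets(F, gt, seed=rng_global.integers(2**31))

    subjects = []
    for i, (rest, c) in enumerate(zip(sims, cohorts)):
        sid = f"sub-{i + 1:03d}"
        scheme = config.schemes[(c - 1) % len(config.schemes)]
        srng = np.random.default_rng(rng_subjects.integers(2**31))
        if config.simulate_task:
            design = make_mid_design(scheme, seed=srng.integers(2**31),
                                     tr=config.tr_task)
            betas = betas_for_targets(
                targets["sensitivity"][i], targets["maximal"][i],
                targets["average"][i],
            )
            # modest amplitudes on the remaining regressors for realism
            for lab in design.condition_labels:
                if lab not in betas:
                    betas[lab] = float(srng.normal(0.0, 0.5))
            T_task = required_volumes(design, config.tr_task)
            task_ts = simulate_task_ts(
                design, betas, config.tr_task, T_task,
                noise_sd=config.task_noise_sd, seed=srng.integers(2**31),
            )
            gt.true_task_betas[sid] = betas
        else:
            design = None
            task_ts = np.zeros((0, 1))
        subjects.append(SubjectRecord(
            subject_id=sid, cohort=c,
            rest_ts=rest.ts, tr_rest=trs[i], motion=rest.motion,
            wm_signals=rest.wm_signals, csf_signals=rest.csf_signals,
            task_ts=task_ts, tr_task=config.tr_task, design=design,
            targets_true=VsMeasures(
                sensitivity=float(targets["sensitivity"][i]),
                maximal=float(targets["maximal"][i]),
                average=float(targets["average"][i]),
                intercept=0.0,
            ),
            rest_clean_true=rest.clean,
        ))
    return Cohort(subjects=subjects, roi_set=roi_set, ground_truth=gt)
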