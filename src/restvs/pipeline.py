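"""Cross-validated prediction of VS measures from connectivity edges.

The cohort is split once into an estimation set (n = 30) and a held-out set
(n = 15), allocated proportionally over the three recruitment cohorts by
largest-remainder rounding.  Within the estimation set a 10-fold
cross-validation (27 train / 3 test per fold) fits one relevance vector
regression per fold and per VS measure; the primal weight vectors of the ten
fold models and of the model refit on the complete estimation set are
averaged into a single predictor.  Because kernel regression scores are not
automatically on the target scale, an affine scaling regression of the
actual values on the out-of-fold raw scores (estimation set only) maps any
raw score to the target scale.  Performance is Pearson's r and the mean
squared error, with significance from permutation of the estimation-set
targets (the fold structure, kernels and scaling procedure are rerun per
permutation).  Held-out subjects never influence kernel centring, fold
models or the scaling regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import rest_fc, task_glm
from .reward import MEASURE_NAMES, vs_measures
from .rvr import KernelSpec, RvrConfig, build_kernel, fit_rvr_kernel, predict, primal_weights

__all__ = [
    "SplitPlan",
    "PredictionResult",
    "PipelineConfig",
    "FcPredictionModel",
    "FcPredictionResults",
    "vectorize_fc",
    "make_split",
    "run_cv",
    "averaged_weights",
    "scaling_correction",
    "evaluate",
    "permutation_significance",
    "run_full_analysis",
]


def vectorize_fc(matrix) -> np.ndarray:
    """Strict upper triangle of a connectivity matrix, row-major.

    Feature j of an n-ROI matrix is edge (i1, i2) in the order produced by
    ``numpy.triu_indices(n, 1)``: (0,1), (0,2), ..., (0,n-1), (1,2), ...
    """
    R = matrix.r if hasattr(matrix, "r") else np.asarray(matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if np.abs(R - R.T).max() > 1e-8:
        raise ValueError("matrix is asymmetric beyond tolerance")
    return R[np.triu_indices(R.shape[0], k=1)]


@dataclass
class SplitPlan:
    """Estimation/held-out split and fold assignment within estimation."""

    estimation_ids: list
    holdout_ids: list
    fold_assignment: dict  # estimation id -> fold index 0..k-1
    k: int
    seed: int | None = None

    def fold_members(self, fold: int) -> list:
        return [s for s in self.estimation_ids if self.fold_assignment[s] == fold]


def make_split(
    subject_ids,
    cohort_labels,
    n_holdout: int = 15,
    k: int = 10,
    seed: int | None = None,
) -> SplitPlan:
    """Cohort-proportional held-out allocation + random folds.

    Held-out counts per cohort follow largest-remainder rounding of
    ``n_holdout * n_c / n``; with cohorts of 14/15/16 and n_holdout = 15 this
    gives 5/5/5.  Folds are drawn uniformly within the estimation set; with
    30 estimation subjects and k = 10 every fold has exactly 3.
    """
    subject_ids = list(subject_ids)
    cohort_labels = np.asarray(cohort_labels)
    n = len(subject_ids)
    if n_holdout >= n:
        raise ValueError("n_holdout must leave at least one estimation subject")
    rng = np.random.default_rng(seed)
    uniq = sorted(set(cohort_labels.tolist()))
    quota = {c: n_holdout * (cohort_labels == c).sum() / n for c in uniq}
    counts = {c: int(np.floor(quota[c])) for c in uniq}
    short = n_holdout - sum(counts.values())
    for c in sorted(uniq, key=lambda c: -(quota[c] - np.floor(quota[c])))[:short]:
        counts[c] += 1
    holdout: list = []
    for c in uniq:
        members = [s for s, lab in zip(subject_ids, cohort_labels) if lab == c]
        if counts[c] > len(members):
            raise ValueError(f"cohort {c} smaller than its holdout quota {counts[c]}")
        holdout += list(rng.choice(members, size=counts[c], replace=False))
    holdout_set = set(holdout)
    estimation = [s for s in subject_ids if s not in holdout_set]
    if len(estimation) % k != 0:
        warnings.warn(
            f"estimation size {len(estimation)} not divisible by k={k}; "
            "fold sizes differ by at most 1",
            stacklevel=2,
        )
    order = list(rng.permutation(estimation))
    folds = {s: i % k for i, s in enumerate(order)}
    return SplitPlan(
        estimation_ids=estimation, holdout_ids=holdout,
        fold_assignment=folds, k=k, seed=seed,
    )


# ---------------------------------------------------------------------------
# cross-validation core


@dataclass
class _CvStructures:
    """Precomputed per-fold kernels; reused across target permutations."""

    F_est: np.ndarray
    fold_train_idx: list[np.ndarray]
    fold_test_idx: list[np.ndarray]
    K_train: list[np.ndarray]
    K_test: list[np.ndarray]
    K_full: np.ndarray
    kernel: KernelSpec


def _cv_structures(F_est: np.ndarray, plan: SplitPlan, kernel: KernelSpec) -> _CvStructures:
    pos = {s: i for i, s in enumerate(plan.estimation_ids)}
    fold_train, fold_test, Ktr, Kte = [], [], [], []
    for f in range(plan.k):
        test = np.array([pos[s] for s in plan.fold_members(f)], dtype=int)
        train = np.array([i for i in range(len(plan.estimation_ids)) if i not in set(test)],
                         dtype=int)
        fold_train.append(train)
        fold_test.append(test)
        Ktr.append(build_kernel(F_est[train], F_est[train], kernel))
        Kte.append(build_kernel(F_est[train], F_est[test], kernel))
    K_full = build_kernel(F_est, F_est, kernel)
    return _CvStructures(F_est, fold_train, fold_test, Ktr, Kte, K_full, kernel)


@dataclass
class CvResult:
    raw_oof: np.ndarray              # out-of-fold raw scores, estimation order
    fold_weights: list[tuple[np.ndarray, float]]
    full_weights: tuple[np.ndarray, float]
    fold_models: list = field(default_factory=list)
    full_model: object = None


def _run_cv_structs(
    structs: _CvStructures, y: np.ndarray, rvr_config: RvrConfig,
    keep_models: bool = False, fit_full: bool = True,
) -> CvResult:
    n = y.size
    raw = np.full(n, np.nan)
    fold_w, models = [], []
    for train, test, Ktr, Kte in zip(
        structs.fold_train_idx, structs.fold_test_idx, structs.K_train, structs.K_test
    ):
        if np.var(y[train]) == 0:
            warnings.warn("fold with zero target variance; fit proceeds", stacklevel=2)
        m = fit_rvr_kernel(Ktr, y[train], rvr_config)
        raw[test] = predict(m, Kte[:, m.retained_samples])
        fold_w.append(primal_weights(m, structs.F_est[train], structs.kernel))
        if keep_models:
            models.append(m)
    full_w, full_m = (np.zeros(structs.F_est.shape[1]), 0.0), None
    if fit_full:
        full_m = fit_rvr_kernel(structs.K_full, y, rvr_config)
        full_w = primal_weights(full_m, structs.F_est, structs.kernel)
    return CvResult(raw_oof=raw, fold_weights=fold_w, full_weights=full_w,
                    fold_models=models, full_model=full_m)


def run_cv(
    features: np.ndarray,
    targets: np.ndarray,
    plan: SplitPlan,
    rvr_config: RvrConfig = RvrConfig(),
    kernel: KernelSpec = KernelSpec(),
) -> CvResult:
    """10-FCV over the estimation set: out-of-fold raw scores + fold weights.

    ``features``/``targets`` rows must align with ``plan.estimation_ids``.
    Also fits the complete-estimation-set model used in weight averaging.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    if F.shape[0] != len(plan.estimation_ids) or y.size != F.shape[0]:
        raise ValueError("features/targets rows must match plan.estimation_ids")
    structs = _cv_structures(F, plan, kernel)
    return _run_cv_structs(structs, y, rvr_config, keep_models=True)


def averaged_weights(fold_weights, full_set_weights) -> tuple[np.ndarray, float]:
    """Unweighted mean of the 10 fold weight vectors and the full-set vector."""
    ws = [np.asarray(w, dtype=float) for w, _ in fold_weights]
    ws.append(np.asarray(full_set_weights[0], dtype=float))
    lengths = {w.size for w in ws}
    if len(lengths) != 1:
        raise ValueError(f"weight vector length mismatch: {sorted(lengths)}")
    bs = [b for _, b in fold_weights] + [full_set_weights[1]]
    return np.mean(ws, axis=0), float(np.mean(bs))


def scaling_correction(raw_scores_est, actual_est) -> tuple[float, float]:
    """OLS of actual on raw over the estimation set: ``(intercept, slope)``."""
    raw = np.asarray(raw_scores_est, dtype=float).ravel()
    act = np.asarray(actual_est, dtype=float).ravel()
    if raw.size < 3:
        raise ValueError("need at least 3 estimation subjects")
    if np.var(raw) == 0:
        raise ValueError("raw scores are constant; scaling regression undefined")
    slope = np.cov(raw, act, bias=True)[0, 1] / np.var(raw)
    intercept = act.mean() - slope * raw.mean()
    return float(intercept), float(slope)


def evaluate(predicted, actual) -> tuple[float, float]:
    """Pearson r and mean squared error between predicted and actual."""
    p = np.asarray(predicted, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.size != a.size or p.size < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    mse = float(np.mean((p - a) ** 2))
    if np.var(p) == 0 or np.var(a) == 0:
        warnings.warn("zero variance in predicted or actual; r undefined", stacklevel=2)
        return float("nan"), mse
    r = float(np.corrcoef(p, a)[0, 1])
    return r, mse


@dataclass
class PermutationResult:
    p_r: float
    p_mse: float
    p_r_holdout: float | None = None
    p_mse_holdout: float | None = None
    perm_r: np.ndarray = field(default_factory=lambda: np.empty(0))
    perm_mse: np.ndarray = field(default_factory=lambda: np.empty(0))


def permutation_significance(
    features: np.ndarray,
    targets: np.ndarray,
    plan: SplitPlan,
    n_perm: int,
    seed: int | None = None,
    rvr_config: RvrConfig = RvrConfig(),
    kernel: KernelSpec = KernelSpec(),
    holdout_features: np.ndarray | None = None,
    holdout_targets: np.ndarray | None = None,
) -> PermutationResult:
    """Permutation p-values for the estimation-set r and MSE.

    Targets are permuted across estimation subjects only; each permutation
    reruns the full CV + scaling + evaluation with the same fold structure
    (kernels are reused, as the features are unchanged).
    p = (1 + #{perm stat beats observed}) / (1 + n_perm), with >= for r and
    <= for MSE.  When held-out data are supplied, held-out p-values from the
    permuted averaged-weight predictor are reported as well.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    F = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    structs = _cv_structures(F, plan, kernel)
    with_holdout = holdout_features is not None and holdout_targets is not None

    def _stats(y_perm):
        cv = _run_cv_structs(structs, y_perm, rvr_config, fit_full=with_holdout)
        intercept, slope = scaling_correction(cv.raw_oof, y_perm)
        r, mse = evaluate(intercept + slope * cv.raw_oof, y_perm)
        hr = hmse = None
        if with_holdout:
            w_bar, b_bar = averaged_weights(cv.fold_weights, cv.full_weights)
            raw_h = np.asarray(holdout_features, dtype=float) @ w_bar + b_bar
            hr, hmse = evaluate(intercept + slope * raw_h,
                                np.asarray(holdout_targets, dtype=float))
        return r, mse, hr, hmse

    obs_r, obs_mse, obs_hr, obs_hmse = _stats(y)
    rng = np.random.default_rng(seed)
    perm_r = np.empty(n_perm)
    perm_mse = np.empty(n_perm)
    ge_h = le_h = 0
    for j in range(n_perm):
        yp = y[rng.permutation(y.size)]
        r, mse, hr, hmse = _stats(yp)
        perm_r[j] = r
        perm_mse[j] = mse
        if with_holdout:
            ge_h += hr >= obs_hr
            le_h += hmse <= obs_hmse
    p_r = float((1 + np.sum(perm_r >= obs_r)) / (1 + n_perm))
    p_mse = float((1 + np.sum(perm_mse <= obs_mse)) / (1 + n_perm))
    res = PermutationResult(p_r=p_r, p_mse=p_mse, perm_r=perm_r, perm_mse=perm_mse)
    if with_holdout:
        res.p_r_holdout = float((1 + ge_h) / (1 + n_perm))
        res.p_mse_holdout = float((1 + le_h) / (1 + n_perm))
    return res


# ---------------------------------------------------------------------------
# orchestration


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the full analysis."""

    n_holdout: int = 15
    k: int = 10
    n_perm: int = 1000  # desk-scale default; 10_000 reproduces the study setting
    band: tuple[float, float] = (0.01, 0.1)
    n_pcs: int = 3
    # CV/permutation fits use a looser stopping rule than the standalone RVR
    # default: predictions are converged long before the slowest log-alpha
    # trajectories settle, and the permutation loop repeats thousands of fits
    rvr: RvrConfig = field(default_factory=lambda: RvrConfig(tol=1e-3, max_iter=300))
    kernel: KernelSpec = field(default_factory=KernelSpec)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        rvr = RvrConfig(**raw.pop("rvr", {}))
        kernel = KernelSpec(**raw.pop("kernel", {}))
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(rvr=rvr, kernel=kernel, **raw)


@dataclass
class PredictionResult:
    """Everything the pipeline reports for one VS measure."""

    measure: str
    table: pd.DataFrame  # subject_id, set, raw, corrected, actual
    r_train: float
    mse_train: float
    r_holdout: float
    mse_holdout: float
    p_r: float | None
    p_mse: float | None
    p_r_holdout: float | None
    p_mse_holdout: float | None
    scaling: tuple[float, float]  # (intercept, slope)
    averaged_weight_vector: np.ndarray
    averaged_bias: float


class FcPredictionModel:
    """Predict VS reward-anticipation measures from resting FC edges.

    Parameters
    ----------
    features : (n_subjects, n_edges) vectorised connectivity.
    targets : mapping measure name -> (n_subjects,) actual values.
    subject_ids, cohort_labels : aligned with the feature rows.
    """

    def __init__(self, features, targets: dict, subject_ids, cohort_labels,
                 config: PipelineConfig = PipelineConfig()):
        self.features = np.atleast_2d(np.asarray(features, dtype=float))
        self.targets = {k: np.asarray(v, dtype=float).ravel() for k, v in targets.items()}
        self.subject_ids = list(subject_ids)
        self.cohort_labels = np.asarray(cohort_labels)
        self.config = config
        n = self.features.shape[0]
        for name, y in self.targets.items():
            if y.size != n:
                raise ValueError(f"target {name!r} length {y.size} != {n} subjects")

    @classmethod
    def from_cohort(cls, cohort, config: PipelineConfig = PipelineConfig(),
                    use_true_targets: bool = False) -> "FcPredictionModel":
        """Compute FC features and task-GLM targets from SubjectRecords.

        The rest path is: combined nuisance + stop-band regression, Pearson
        FC, upper-triangle vectorisation.  The task path fits the first-level
        GLM, forms the gain contrasts and the three VS measures.  With
        ``use_true_targets`` the recorded simulation truth is used instead of
        the task path (for recovery analyses).
        """
        feats, targ = [], {m: [] for m in MEASURE_NAMES}
        for s in cohort.subjects:
            nuis = rest_fc.make_nuisance_model(
                s.motion, s.wm_signals, s.csf_signals, s.tr_rest,
                n_pcs=config.n_pcs, band=config.band,
            )
            clean = rest_fc.clean_timeseries(s.rest_ts, nuis)
            feats.append(vectorize_fc(rest_fc.fc_matrix(clean)))
            if use_true_targets:
                m = s.targets_true
            else:
                T = s.task_ts.shape[0]
                X, labels = task_glm.build_design_matrix(s.design, s.tr_task, T)
                glm = task_glm.fit_glm(s.task_ts, X, labels)
                m = vs_measures(task_glm.contrasts(glm))
            for name in MEASURE_NAMES:
                targ[name].append(float(np.asarray(getattr(m, name)).ravel()[0]))
        return cls(np.vstack(feats), {k: np.array(v) for k, v in targ.items()},
                   cohort.subject_ids, cohort.cohort_labels, config)

    def fit(self, seed: int | None = 0, n_perm: int | None = None,
            plan: SplitPlan | None = None) -> "FcPredictionResults":
        """Run split, CV, scaling, evaluation and permutation per measure."""
        cfg = self.config
        if n_perm is None:
            n_perm = cfg.n_perm
        ss = np.random.SeedSequence(seed)
        split_seed, perm_seed = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
        if plan is None:
            plan = make_split(self.subject_ids, self.cohort_labels,
                              n_holdout=cfg.n_holdout, k=cfg.k, seed=split_seed)
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        est_idx = np.array([pos[s] for s in plan.estimation_ids])
        hold_idx = np.array([pos[s] for s in plan.holdout_ids])
        F_est, F_hold = self.features[est_idx], self.features[hold_idx]

        results = {}
        for name in self.targets:
            y = self.targets[name]
            y_est, y_hold = y[est_idx], y[hold_idx]
            cv = run_cv(F_est, y_est, plan, cfg.rvr, cfg.kernel)
            intercept, slope = scaling_correction(cv.raw_oof, y_est)
            corrected_est = intercept + slope * cv.raw_oof
            r_tr, mse_tr = evaluate(corrected_est, y_est)
            w_bar, b_bar = averaged_weights(cv.fold_weights, cv.full_weights)
            raw_hold = F_hold @ w_bar + b_bar
            corrected_hold = intercept + slope * raw_hold
            r_ho, mse_ho = evaluate(corrected_hold, y_hold)
            p_r = p_mse = p_rh = p_mseh = None
            if n_perm > 0:
                perm = permutation_significance(
                    F_est, y_est, plan, n_perm, seed=perm_seed,
                    rvr_config=cfg.rvr, kernel=cfg.kernel,
                    holdout_features=F_hold, holdout_targets=y_hold,
                )
                p_r, p_mse = perm.p_r, perm.p_mse
                p_rh, p_mseh = perm.p_r_holdout, perm.p_mse_holdout
            table = pd.DataFrame({
                "subject_id": list(plan.estimation_ids) + list(plan.holdout_ids),
                "set": ["estimation"] * len(est_idx) + ["holdout"] * len(hold_idx),
                "raw": np.concatenate([cv.raw_oof, raw_hold]),
                "corrected": np.concatenate([corrected_est, corrected_hold]),
                "actual": np.concatenate([y_est, y_hold]),
            })
            results[name] = PredictionResult(
                measure=name, table=table,
                r_train=r_tr, mse_train=mse_tr,
                r_holdout=r_ho, mse_holdout=mse_ho,
                p_r=p_r, p_mse=p_mse, p_r_holdout=p_rh, p_mse_holdout=p_mseh,
                scaling=(intercept, slope),
                averaged_weight_vector=w_bar, averaged_bias=b_bar,
            )
        return FcPredictionResults(self, results, plan)


class FcPredictionResults:
    """Per-measure prediction results plus the split they came from."""

    def __init__(self, model: FcPredictionModel, results: dict, plan: SplitPlan):
        self.model = model
        self.results = results
        self.plan = plan

    def __getitem__(self, measure: str) -> PredictionResult:
        return self.results[measure]

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for name, r in self.results.items():
            rows.append({
                "measure": name,
                "r_train": r.r_train, "mse_train": r.mse_train,
                "p_r": r.p_r, "p_mse": r.p_mse,
                "r_holdout": r.r_holdout, "mse_holdout": r.mse_holdout,
                "p_r_holdout": r.p_r_holdout, "p_mse_holdout": r.p_mse_holdout,
            })
        return pd.DataFrame(rows).set_index("measure")

    def summary(self) -> str:
        df = self.metrics_frame()
        lines = [
            "VS Measure Prediction from Resting Functional Connectivity",
            "=" * 62,
            f"subjects: {len(self.model.subject_ids)} "
            f"(estimation {len(self.plan.estimation_ids)}, "
            f"holdout {len(self.plan.holdout_ids)}); "
            f"edges: {self.model.features.shape[1]}; folds: {self.plan.k}",
            "-" * 62,
            df.round(4).to_string(),
        ]
        return "\n".join(lines)


def run_full_analysis(cohort, config: PipelineConfig = PipelineConfig(),
                      seed: int = 0, n_perm: int | None = None,
                      use_true_targets: bool = False) -> FcPredictionResults:
    """Convenience wrapper: cohort -> features/targets -> fitted results."""
    model = FcPredictionModel.from_cohort(cohort, config, use_true_targets=use_true_targets)
    return model.fit(seed=seed, n_perm=n_perm)
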