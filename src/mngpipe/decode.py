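"""Force and velocity decoding from sorted motoneuron activity.

The decoder operates on the average firing rate (AFR): the pointwise mean of
the sorted units' boxcar rates, normalized to its maximum over the training
trials and resampled on a 1 ms grid. Three features drive it:

* Feat1 (force):  -1 + 1/(AFR(t) - 1.5)^2, a monotone transform chosen to
  linearize the saturating (quasi-logarithmic) rate-force relation;
* Feat1 (velocity): the AFR slope (AFR(t) - AFR(t_min)) / (t - t_min), with
  t_min the pre-activity AFR minimum (magnitude-positive convention);
* Feat2/Feat3: binary activity/rest flags from a threshold pair (T_u1, T_l1)
  with hysteresis - the decoder only emits level predictions while active.

The custom classifier assigns the level whose Feat1 centroid is nearest in
Euclidean (absolute) distance; centroids are learned with leave-one-out
folding. Linear-discriminant comparators run on the same gating with three
feature sets: the custom features, single-unit firing rates, or multi-unit
activity (MNG envelope + AFR). Accuracy is the mean over classes of the
per-class fraction of correctly predicted events (balanced accuracy), and
confusion matrices aggregate as sums of per-subject row-normalized matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "compute_afr", "feat1_force", "feat1_velocity", "activity_gate",
    "DecodingTrial", "make_trials", "DecoderModel", "train_custom",
    "predict_custom", "leave_one_out", "lda_variants", "balanced_accuracy",
    "ConfusionMatrix", "chance_level",
]

REST = 0.0          # class label for the rest state
DT = 0.001          # decoder grid, 1 ms


def compute_afr(fr_matrix, norm: float | None = None):
    """Average firing rate: pointwise mean across units, normalized.

    ``fr_matrix`` has shape (n_units, n_t) on a common 1 ms grid. ``norm``
    freezes the normalization maximum (training convention); default is the
    series' own maximum. All-zero input is flagged (returned flag False) and
    left at zero.
    """
    fr = np.atleast_2d(np.asarray(fr_matrix, dtype=float))
    afr = fr.mean(axis=0)
    m = afr.max() if norm is None else float(norm)
    if m <= 0:
        return afr * 0.0, False
    return afr / m, True


def feat1_force(afr):
    """Force feature: -1 + 1/(AFR - 1.5)^2 for normalized AFR in [0, 1]."""
    a = np.asarray(afr, dtype=float)
    if np.any(a < -1e-9) or np.any(a > 1.0 + 1e-9):
        raise ValueError("normalized AFR must lie in [0, 1]")
    return -1.0 + 1.0 / (np.clip(a, 0.0, 1.0) - 1.5) ** 2


def feat1_velocity(afr, t_grid, t_min: float, guard_s: float = 0.0):
    """Velocity feature: AFR slope from the pre-activity minimum.

    Returns the series (AFR(t) - AFR(t_min)) / (t - t_min) for
    t > t_min + guard_s, 0 before (magnitude-positive sign convention).
    The guard interval keeps the vanishing denominator right after t_min
    from amplifying estimation noise into the gate thresholds.
    """
    a = np.asarray(afr, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    a_min = float(np.interp(t_min, t, a))
    out = np.zeros_like(a)
    m = t > t_min + guard_s
    out[m] = (a[m] - a_min) / (t[m] - t_min)
    return out


def activity_gate(feat1, T_u1: float, T_l1: float):
    """Hysteresis rest/activity gate.

    feat1 >= T_u1 -> active, feat1 <= T_l1 -> rest, in between the previous
    state is held; initial state is rest. Returns a boolean array (True =
    active).
    """
    if not T_l1 < T_u1:
        raise ValueError("thresholds must satisfy T_l1 < T_u1")
    f = np.asarray(feat1, dtype=float)
    active = np.zeros(len(f), dtype=bool)
    state = False
    up, down = f >= T_u1, f <= T_l1
    for i in range(len(f)):
        if up[i]:
            state = True
        elif down[i]:
            state = False
        active[i] = state
    return active


@dataclass
class DecodingTrial:
    """One repetition window: pre-activity rest plus the cued movement."""

    t: np.ndarray                 # 1 ms grid, seconds (session time)
    fr_matrix: np.ndarray         # (n_units, n_t) boxcar rates
    label: float                  # commanded level (kPa or deg/s)
    onset: float                  # cue start (s)
    rest_mask: np.ndarray         # pre-activity samples
    extra: dict = field(default_factory=dict)   # e.g. mng envelope


def make_trials(session, units, t_pad: float | None = None,
                mng_env=None) -> list[DecodingTrial]:
    """Cut a session into per-repetition decoding trials.

    Each trial spans the rest period preceding the cue plus the repetition
    itself. ``mng_env`` (10 kHz envelope) is attached downsampled for the
    multi-unit feature set.
    """
    proto = session.protocol
    pad = proto.rest_duration if t_pad is None else t_pad
    trials = []
    for (start, stop), level in zip(proto.cue_times, proto.rep_levels):
        a = max(start - pad, 0.0)
        t = np.arange(a, stop, DT)
        fr = np.stack([u.firing_rate(t) for u in units])
        extra = {}
        if mng_env is not None:
            idx = np.minimum((t * session.fs).astype(int), len(mng_env) - 1)
            extra["mng_env"] = mng_env[idx]
        trials.append(DecodingTrial(t=t, fr_matrix=fr, label=float(level),
                                    onset=start, rest_mask=t < start,
                                    extra=extra))
    return trials


@dataclass
class DecoderModel:
    task: str                               # "force" | "velocity"
    centroids: dict[float, float]           # level -> Feat1 centroid
    T_u1: float
    T_l1: float
    afr_norm: float                         # frozen AFR normalization max
    variant: str = "custom"
    shrinkage_applied: bool = False

    def to_dict(self):
        return {"task": self.task, "variant": self.variant,
                "centroids": {str(k): v for k, v in self.centroids.items()},
                "T_u1": self.T_u1, "T_l1": self.T_l1,
                "afr_norm": self.afr_norm,
                "shrinkage_applied": self.shrinkage_applied}


def _trial_feat1(trial: DecodingTrial, task: str, afr_norm: float):
    afr, _ok = compute_afr(trial.fr_matrix, norm=afr_norm)
    afr = np.clip(afr, 0.0, 1.0)
    if task == "force":
        return feat1_force(afr)
    # velocity: slope from the pre-activity AFR minimum
    rest_idx = np.flatnonzero(trial.rest_mask)
    if rest_idx.size:
        i_min = rest_idx[np.argmin(afr[rest_idx])]
    else:
        i_min = 0
    # 1 s guard: the vanishing denominator right after t_min would turn
    # boxcar quantization noise into spurious rest-period feature spikes
    return feat1_velocity(afr, trial.t, float(trial.t[i_min]), guard_s=1.0)


def _calibrate_thresholds(feats_rest):
    """T_l1 = rest mean + 1 SD, T_u1 = rest mean + 3 SD (config default)."""
    pooled = np.concatenate(feats_rest)
    mu, sd = pooled.mean(), pooled.std()
    if sd == 0.0:
        sd = max(abs(mu), 1.0) * 1e-3
    return mu + 3.0 * sd, mu + 1.0 * sd


def train_custom(trials: list[DecodingTrial], task: str) -> DecoderModel:
    """Per-class Feat1 centroids + rest-calibrated activity thresholds."""
    if task not in ("force", "velocity"):
        raise ValueError(f"unknown task {task!r}")
    labels = sorted({tr.label for tr in trials})
    for lv in labels:
        if sum(tr.label == lv for tr in trials) < 1:
            raise ValueError(f"class {lv} has no trials")
    afr_norm = max(tr.fr_matrix.mean(axis=0).max() for tr in trials)
    if afr_norm <= 0:
        raise ValueError("all-zero firing rates; AFR normalization undefined")
    feats = [_trial_feat1(tr, task, afr_norm) for tr in trials]
    T_u1, T_l1 = _calibrate_thresholds(
        [f[tr.rest_mask] for f, tr in zip(feats, trials) if tr.rest_mask.any()])
    centroids = {}
    for lv in labels:
        vals = []
        for f, tr in zip(feats, trials):
            if tr.label != lv:
                continue
            active = activity_gate(f, T_u1, T_l1)
            if active.any():
                vals.append(f[active])
        if not vals:                       # class never crosses the gate
            vals = [f[~tr.rest_mask] for f, tr in zip(feats, trials)
                    if tr.label == lv]
        centroids[lv] = float(np.concatenate(vals).mean())
    return DecoderModel(task=task, centroids=centroids, T_u1=T_u1,
                        T_l1=T_l1, afr_norm=afr_norm)


def predict_custom(model: DecoderModel, trial: DecodingTrial) -> np.ndarray:
    """Per-1 ms class series: REST while gated off, else the level of the
    nearest Feat1 centroid (ties broken toward the lowest level)."""
    f = _trial_feat1(trial, model.task, model.afr_norm)
    active = activity_gate(f, model.T_u1, model.T_l1)
    levels = np.array(sorted(model.centroids))          # ascending: tie->low
    cents = np.array([model.centroids[lv] for lv in levels])
    d = np.abs(f[:, None] - cents[None, :])
    pred = levels[np.argmin(d, axis=1)]
    pred[~active] = REST
    return pred


def _lda_features(trial: DecodingTrial, task: str, afr_norm: float,
                  feature_set: str):
    afr, _ = compute_afr(trial.fr_matrix, norm=afr_norm)
    if feature_set == "custom":
        f1 = _trial_feat1(trial, task, afr_norm)
        return f1[:, None]
    if feature_set == "single_unit":
        return trial.fr_matrix.T
    if feature_set == "multi_unit":
        env = trial.extra.get("mng_env")
        if env is None:
            env = np.zeros_like(afr)
        return np.column_stack([env, afr])
    raise ValueError(f"unknown feature_set {feature_set!r}")


def lda_variants(train_trials: list[DecodingTrial], task: str,
                 feature_set: str,
                 gate_model: DecoderModel | None = None) -> tuple:
    """Fit the linear-discriminant comparator on per-1 ms active samples.

    Returns ``(sklearn LDA, DecoderModel)`` where the model carries the
    shared gate and normalization. Singular within-class scatter triggers
    shrinkage (reported via ``shrinkage_applied``).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    gate = gate_model or train_custom(train_trials, task)
    X, y = [], []
    for tr in train_trials:
        f1 = _trial_feat1(tr, task, gate.afr_norm)
        active = activity_gate(f1, gate.T_u1, gate.T_l1)
        feats = _lda_features(tr, task, gate.afr_norm, feature_set)
        X.append(feats[active])
        y.append(np.full(int(active.sum()), tr.label))
    X = np.concatenate(X)
    y = np.concatenate(y)
    shrink = False
    # zero within-class variance in any feature makes the scatter singular
    for lv in np.unique(y):
        if np.any(X[y == lv].var(axis=0) < 1e-18):
            shrink = True
            break
    if shrink:
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    else:
        lda = LinearDiscriminantAnalysis()
    lda.fit(X, y)
    model = DecoderModel(task=task, centroids=dict(gate.centroids),
                         T_u1=gate.T_u1, T_l1=gate.T_l1,
                         afr_norm=gate.afr_norm,
                         variant=f"lda_{feature_set}",
                         shrinkage_applied=shrink)
    return lda, model


def predict_lda(lda, model: DecoderModel, trial: DecodingTrial,
                feature_set: str) -> np.ndarray:
    f1 = _trial_feat1(trial, model.task, model.afr_norm)
    active = activity_gate(f1, model.T_u1, model.T_l1)
    pred = np.full(len(f1), REST)
    if active.any():
        feats = _lda_features(trial, model.task, model.afr_norm, feature_set)
        pred[active] = lda.predict(feats[active])
    return pred


@dataclass
class ConfusionMatrix:
    """Counts[i, j] = events of true class i predicted as class j; classes
    include rest (index 0) and the levels in ascending order."""

    classes: list[float]
    counts: np.ndarray

    @classmethod
    def empty(cls, levels):
        classes = [REST] + sorted(levels)
        return cls(classes=classes,
                   counts=np.zeros((len(classes), len(classes))))

    def add_events(self, true_series, pred_series):
        idx = {c: i for i, c in enumerate(self.classes)}
        for t, p in zip(np.asarray(true_series).ravel(),
                        np.asarray(pred_series).ravel()):
            self.counts[idx[float(t)], idx[float(p)]] += 1

    def normalized(self) -> np.ndarray:
        rs = self.counts.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        return self.counts / rs

    @staticmethod
    def aggregate(matrices: list["ConfusionMatrix"]) -> np.ndarray:
        """Sum of row-normalized per-subject matrices."""
        return np.sum([m.normalized() for m in matrices], axis=0)


def balanced_accuracy(counts) -> float:
    """Mean over classes of per-class recall (correct events / events)."""
    c = np.asarray(counts, dtype=float)
    row = c.sum(axis=1)
    if np.any(row == 0):
        raise ValueError("every class needs at least one event")
    return float(np.mean(np.diag(c) / row))


def chance_level(n_levels: int, include_rest: bool = True) -> float:
    """Chance balanced accuracy; both conventions (with/without the rest
    class) are in use, so the caller picks."""
    return 1.0 / (n_levels + (1 if include_rest else 0))


def true_series(trial: DecodingTrial) -> np.ndarray:
    """Ground-truth per-1 ms class labels for a trial window."""
    out = np.full(len(trial.t), REST)
    out[~trial.rest_mask] = trial.label
    return out


def leave_one_out(trials: list[DecodingTrial], task: str,
                  variant: str = "custom"):
    """Leave-one-trial-out evaluation.

    Returns ``(confusion, models)``: one model per fold, each trained with
    exactly one trial held out, and the pooled event-level confusion matrix.
    """
    levels = sorted({tr.label for tr in trials})
    cm = ConfusionMatrix.empty(levels)
    models = []
    for i, held in enumerate(trials):
        rest = trials[:i] + trials[i + 1:]
        if variant == "custom":
            model = train_custom(rest, task)
            pred = predict_custom(model, held)
        else:
            feature_set = variant.removeprefix("lda_")
            lda, model = lda_variants(rest, task, feature_set)
            pred = predict_lda(lda, model, held, feature_set)
        models.append(model)
        cm.add_events(true_series(held), pred)
    return cm, models
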