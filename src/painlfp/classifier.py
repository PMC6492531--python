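"""Band-power SVM classification of spontaneous pain-like episodes.

Each [-5, 5] s episode yields 20 features: integrated LFP power (dB) in
five bands (theta, alpha, beta, low gamma, high gamma) x two regions
(ACC, S1) x two periods (pre [-5, 0] s and post [0, 5] s around the
behavior onset).  Negative controls are count-matched non-overlapping
windows tiled in the pain-free period before the first stimulus.

A polynomial-kernel SVM (degree 3, C = 1) is evaluated by stratified
5-fold cross-validation; features are standardized to zero mean and unit
variance on the training folds only.  AUROC is computed from the pooled
decision values across folds.  A linear-kernel run additionally reports
per-feature weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .session import RecordingSession
from .signal_ops import CANONICAL_BANDS
from .spectral import band_power


class ClassifierError(ValueError):
    pass


PERIODS = (("pre", (-5.0, 0.0)), ("post", (0.0, 5.0)))


def feature_names(regions: tuple[str, ...] = ("ACC", "S1")) -> list[str]:
    return [
        f"{band.name}_{region}_{period}"
        for band in CANONICAL_BANDS
        for region in regions
        for period, _ in PERIODS
    ]


@dataclass
class EpisodeFeatures:
    episode_id: str
    label: int  # +1 spontaneous pain-like, -1 control
    features: np.ndarray  # 20 band-power values, dB
    standardized: bool = False


@dataclass
class CvReport:
    fold_accuracies: list[float]
    mean_accuracy: float  # percent
    auroc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    weights: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=feature_names)


def control_windows(
    session: RecordingSession, n: int, duration: float = 10.0
) -> np.ndarray:
    """Centers of non-overlapping control windows tiled before the first stimulus."""
    stim = session.events.loc[session.events["kind"] == "stimulus", "onset_s"]
    t_max = float(stim.min()) - duration / 2 if len(stim) else session.t_end
    starts = np.arange(session.t0, t_max - duration + 1e-9, duration)
    if starts.size < n:
        raise ClassifierError(
            f"pain-free period fits only {starts.size} control windows, need {n}"
        )
    return starts[:n] + duration / 2


def extract_features(
    session: RecordingSession,
    episode_onsets: np.ndarray,
    control_onsets: np.ndarray,
    regions: tuple[str, ...] = ("ACC", "S1"),
) -> list[EpisodeFeatures]:
    """Band-power feature vectors for positive episodes and controls.

    Episodes whose [-5, 5] s window is truncated by the session edge are
    skipped with a warning.  Standardization is NOT applied here; it happens
    inside cross-validation on training folds only.
    """
    import warnings

    fs = session.fs_lfp
    out: list[EpisodeFeatures] = []
    for label, onsets in ((1, episode_onsets), (-1, control_onsets)):
        for k, onset in enumerate(np.asarray(onsets, dtype=float)):
            if onset - 5.0 < session.t0 or onset + 5.0 > session.t_end:
                warnings.warn(f"episode at {onset:.1f} s truncated; skipped", stacklevel=2)
                continue
            power: dict[tuple[str, str], dict[str, float]] = {}
            for region in regions:
                lfp = session.region_lfp[region].mean(axis=0)
                for period, (lo, hi) in PERIODS:
                    i0 = int(round((onset + lo - session.t0) * fs))
                    i1 = int(round((onset + hi - session.t0) * fs))
                    power[(region, period)] = band_power(lfp[i0:i1], fs)
            feats = [
                power[(region, period)][band.name]
                for band in CANONICAL_BANDS
                for region in regions
                for period, _ in PERIODS
            ]
            tag = "pain" if label == 1 else "ctrl"
            out.append(EpisodeFeatures(f"{tag}{k:03d}", label, np.asarray(feats)))
    return out


def _design(features: list[EpisodeFeatures]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([f.features for f in features])
    y = np.array([f.label for f in features])
    const = np.flatnonzero(X.std(axis=0) == 0)
    if const.size:
        names = [feature_names()[i] if i < 20 else str(i) for i in const]
        raise ClassifierError(f"constant feature column(s): {names}")
    return X, y


def crossval_svm(
    features: list[EpisodeFeatures],
    kernel: str = "poly",
    degree: int = 3,
    c_reg: float = 1.0,
    k: int = 5,
    seed: int = 0,
    n_repeats: int = 1,
    permute_labels: bool = False,
) -> CvReport:
    """Stratified k-fold SVM cross-validation with pooled-decision AUROC.

    Standardization (zero mean, unit variance) and the SVM fit see only the
    training folds.  With ``n_repeats > 1`` the folds are reshuffled and
    accuracies/AUROCs averaged.  ``permute_labels`` shuffles labels once per
    repeat (chance calibration).
    """
    X, y = _design(features)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ClassifierError("need both classes for classification")
    if counts.min() < k:
        raise ClassifierError(f"minority class has {counts.min()} examples < k={k} folds")
    rng = np.random.default_rng(seed)

    accs: list[float] = []
    aurocs: list[float] = []
    last_fpr = last_tpr = None
    weights = None
    for rep in range(n_repeats):
        y_rep = rng.permutation(y) if permute_labels else y
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        pooled_scores = np.empty(len(y_rep))
        fold_acc = []
        for train_idx, test_idx in skf.split(X, y_rep):
            scaler = StandardScaler().fit(X[train_idx])
            svm = SVC(kernel=kernel, degree=degree, C=c_reg, gamma="scale")
            svm.fit(scaler.transform(X[train_idx]), y_rep[train_idx])
            Xt = scaler.transform(X[test_idx])
            fold_acc.append(float((svm.predict(Xt) == y_rep[test_idx]).mean()))
            pooled_scores[test_idx] = svm.decision_function(Xt)
            if kernel == "linear":
                weights = svm.coef_.ravel().copy()
        accs.extend(fold_acc)
        aurocs.append(float(roc_auc_score(y_rep, pooled_scores)))
        last_fpr, last_tpr, _ = roc_curve(y_rep, pooled_scores)
    return CvReport(
        fold_accuracies=accs,
        mean_accuracy=100.0 * float(np.mean(accs)),
        auroc=float(np.mean(aurocs)),
        roc_fpr=last_fpr,
        roc_tpr=last_tpr,
        weights=weights,
    )


def features_to_frame(features: list[EpisodeFeatures]) -> pd.DataFrame:
    df = pd.DataFrame([f.features for f in features], columns=feature_names())
    df.insert(0, "episode_id", [f.episode_id for f in features])
    df.insert(1, "label", [f.label for f in features])
    return df
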