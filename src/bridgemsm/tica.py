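"""Time-lagged independent component analysis (tICA).

tICA finds the linear combinations of input features that decorrelate
most slowly: the generalized eigenproblem

    C_tau v = lambda (C_0 + eps I) v,

where C_0 is the instantaneous covariance and C_tau the symmetrized
time-lagged covariance at lag tau. The leading eigenvectors (tICs)
approximate the slowest collective motions and are the coordinates in
which microstates are clustered. Estimators are symmetrized (averaging
the t and t+tau marginals) so the spectrum is real — the standard
reversible tICA estimator.

Fitting on one dataset and projecting another is supported: ``fit_tica``
on the reference ensemble, then ``transform`` on anything sharing its
feature labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

from .features import FeatureTrajectory

__all__ = ["TICAModel", "fit_tica", "transform"]


@dataclass
class TICAModel:
    mean: np.ndarray
    C0: np.ndarray
    Ctau: np.ndarray
    lag: float  # physical time units
    lag_frames: int
    frame_interval: float
    eigenvalues: np.ndarray  # descending
    components: np.ndarray  # d x m, columns are tIC1..tICm, unit C0-norm
    epsilon: float
    feature_labels: list[str]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def timescales(self) -> np.ndarray:
        """Implied relaxation timescales -lag/ln(lambda) of positive eigenvalues."""
        lam = self.eigenvalues
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where((lam > 0) & (lam < 1), -self.lag / np.log(lam), np.nan)
        return t

    def to_json(self, path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "C0": self.C0.tolist(),
            "Ctau": self.Ctau.tolist(),
            "lag": self.lag,
            "lag_frames": self.lag_frames,
            "frame_interval": self.frame_interval,
            "eigenvalues": self.eigenvalues.tolist(),
            "components": self.components.tolist(),
            "epsilon": self.epsilon,
            "feature_labels": self.feature_labels,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "TICAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.array(d["mean"]),
            C0=np.array(d["C0"]),
            Ctau=np.array(d["Ctau"]),
            lag=d["lag"],
            lag_frames=d["lag_frames"],
            frame_interval=d["frame_interval"],
            eigenvalues=np.array(d["eigenvalues"]),
            components=np.array(d["components"]),
            epsilon=d["epsilon"],
            feature_labels=list(d["feature_labels"]),
        )


def _as_frames(lag: float, frame_interval: float) -> int:
    lagf = int(round(lag / frame_interval))
    if lagf < 1:
        raise ValueError(f"lag {lag} is below one frame interval {frame_interval}")
    return lagf


def fit_tica(
    trajs: Sequence[FeatureTrajectory],
    lag: float,
    epsilon: float | None = None,
) -> TICAModel:
    """Fit a tICA model at physical lag time ``lag``.

    Covariances are accumulated over all (t, t+lag) frame pairs of every
    trajectory independently (no cross-trajectory pairs) with the
    symmetrized estimator, then the generalized eigenproblem is solved
    with ridge regularization eps (default 1e-10 tr(C0)/d). Each
    component's largest-magnitude entry is made positive so projections
    are reproducible.
    """
    if not trajs:
        raise ValueError("no trajectories")
    labels = trajs[0].feature_labels
    interval = trajs[0].frame_interval
    for tr in trajs:
        if tr.feature_labels != labels:
            raise ValueError("trajectories must share feature labels")
    lagf = _as_frames(lag, interval)
    d = trajs[0].n_features
    s = np.zeros(d)
    c0 = np.zeros((d, d))
    ct = np.zeros((d, d))
    n_pairs = 0
    for tr in trajs:
        if tr.n_frames <= lagf:
            raise ValueError(
                f"trajectory of {tr.n_frames} frames is not longer than lag "
                f"{lagf} frames"
            )
        a = tr.values[:-lagf]
        b = tr.values[lagf:]
        s += a.sum(axis=0) + b.sum(axis=0)
        c0 += a.T @ a + b.T @ b
        ct += a.T @ b + b.T @ a
        n_pairs += len(a)
    norm = 2.0 * n_pairs
    mean = s / norm
    C0 = c0 / norm - np.outer(mean, mean)
    Ctau = ct / norm - np.outer(mean, mean)
    C0 = 0.5 * (C0 + C0.T)
    Ctau = 0.5 * (Ctau + Ctau.T)
    if epsilon is None:
        epsilon = 1e-10 * np.trace(C0) / d
    try:
        lam, V = scipy.linalg.eigh(Ctau, C0 + epsilon * np.eye(d))
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "instantaneous covariance is rank deficient; set epsilon > 0"
        ) from exc
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    V = V[:, order]
    # scipy.eigh normalizes v' (C0+eps I) v = 1; fix the sign convention
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    V = V * flip
    return TICAModel(
        mean=mean,
        C0=C0,
        Ctau=Ctau,
        lag=lagf * interval,
        lag_frames=lagf,
        frame_interval=interval,
        eigenvalues=lam,
        components=V,
        epsilon=float(epsilon),
        feature_labels=list(labels),
    )


def transform(
    model: TICAModel,
    traj: FeatureTrajectory | np.ndarray,
    n_components: int = 2,
) -> np.ndarray:
    """Project frames onto the first ``n_components`` tICs."""
    if isinstance(traj, FeatureTrajectory):
        if traj.feature_labels != model.feature_labels:
            missing = sorted(
                set(model.feature_labels) - set(traj.feature_labels)
            )
            raise ValueError(f"feature labels do not match model; missing {missing}")
        X = traj.values
    else:
        X = np.atleast_2d(np.asarray(traj, dtype=float))
        if X.shape[1] != len(model.feature_labels):
            raise ValueError("feature dimension does not match model")
    if not 1 <= n_components <= model.n_components:
        raise ValueError("n_components out of range")
    return (X - model.mean) @ model.components[:, :n_components]
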