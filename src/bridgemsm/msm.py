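"""Microstate Markov state models and their validation machinery.

Covers transition counting, connectivity trimming, maximum-likelihood
estimation (reversible via count symmetrization by default), implied
timescales, GMRQ cross-validation for hyperparameter selection, the
residence probability test, Markov-chain Monte Carlo estimation of
MSM-weighted observables and mean first-passage times, and block
bootstrapping of trajectory statistics.

The MSM transition matrix T at lag tau is row stochastic; its stationary
distribution pi and eigenvalues 1 = lambda_1 > lambda_2 >= ... encode
equilibrium populations and relaxation (implied) timescales
t_k = -tau / ln lambda_k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
import scipy.stats
from scipy.sparse.csgraph import connected_components

from .synthgen import sample_markov_chains

__all__ = [
    "CountMatrix",
    "MarkovModel",
    "GMRQReport",
    "ResidenceReport",
    "count_transitions",
    "trim_to_connected",
    "estimate_markov_model",
    "implied_timescales_scan",
    "gmrq_score",
    "gmrq_cross_validate",
    "residence_probability_test",
    "sample_observable_mcmc",
    "mcmc_mfpt",
    "block_bootstrap",
]


@dataclass
class CountMatrix:
    counts: np.ndarray  # (k, k) nonnegative, sliding-window
    lag_frames: int
    active_set: np.ndarray  # original state index of each row
    n_states_original: int
    mode: str = "sliding"


@dataclass
class MarkovModel:
    T: np.ndarray
    lag_frames: int
    frame_interval: float
    pi: np.ndarray
    eigenvalues: np.ndarray  # descending by real part, lambda_1 = 1
    right_eigenvectors: np.ndarray  # columns, pi-orthonormal for reversible models
    left_eigenvectors: np.ndarray  # rows l_k = pi * r_k for reversible models
    active_set: np.ndarray
    reversible: bool

    @property
    def tau(self) -> float:
        """Lag time in physical units."""
        return self.lag_frames * self.frame_interval

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def implied_timescales(self, n: int | None = None) -> np.ndarray:
        lam = np.real(self.eigenvalues[1:])
        if n is not None:
            lam = lam[:n]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where((lam > 0) & (lam < 1), -self.tau / np.log(lam), np.nan)


def count_transitions(
    dtrajs: Sequence[np.ndarray], lag: int, n_states: int | None = None
) -> CountMatrix:
    """Sliding-window transition counts at integer lag (frames)."""
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    if n_states is None:
        n_states = int(max(d.max() for d in dtrajs)) + 1
    C = np.zeros((n_states, n_states), dtype=np.int64)
    any_pairs = False
    for d in dtrajs:
        if len(d) <= lag:
            continue
        any_pairs = True
        np.add.at(C, (d[:-lag], d[lag:]), 1)
    if not any_pairs:
        raise ValueError(f"all trajectories are shorter than lag {lag}")
    return CountMatrix(C, lag, np.arange(n_states), n_states)


def trim_to_connected(cm: CountMatrix) -> CountMatrix:
    """Restrict to the largest strongly connected component of the count graph."""
    adj = scipy.sparse.csr_matrix((cm.counts > 0).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    sizes = np.bincount(labels, minlength=n_comp)
    # prefer larger components; among ties, the one containing the lowest state
    best = int(np.argmax(sizes))
    keep = np.flatnonzero(labels == best)
    sub = cm.counts[np.ix_(keep, keep)]
    if sub.sum() == 0:
        raise ValueError("no transitions inside the largest connected component")
    return CountMatrix(
        sub, cm.lag_frames, cm.active_set[keep], cm.n_states_original, cm.mode
    )


def _spectral_decomposition_reversible(T: np.ndarray, pi: np.ndarray):
    """Real eigen-decomposition of a reversible T via the symmetric conjugate."""
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] * T) / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    lam, U = scipy.linalg.eigh(S)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    U = U[:, order]
    right = U / sqrt_pi[:, None]  # pi-orthonormal: sum_i pi_i r_ki r_li = delta
    left = U.T * sqrt_pi[None, :]
    # sign convention: stationary eigenvector positive
    for k in range(right.shape[1]):
        j = np.abs(right[:, k]).argmax()
        if right[j, k] < 0:
            right[:, k] *= -1
            left[k] *= -1
    return lam, right, left


def estimate_markov_model(
    cm: CountMatrix,
    frame_interval: float = 1.0,
    reversible: bool = True,
) -> MarkovModel:
    """Maximum-likelihood MSM from a trimmed count matrix.

    Reversible mode (default) row-normalizes the symmetrized counts
    (C + C')/2, which guarantees detailed balance and a real spectrum;
    pi is then proportional to the symmetrized row sums. Non-reversible
    mode row-normalizes C directly and takes pi as the leading left
    eigenvector, warning if complex eigenvalue pairs appear.
    """
    C = np.asarray(cm.counts, dtype=float)
    if (C.sum(axis=1) == 0).any():
        raise RuntimeError("zero count row; trim to the connected set first")
    if reversible:
        S = 0.5 * (C + C.T)
        rows = S.sum(axis=1)
        T = S / rows[:, None]
        pi = rows / rows.sum()
        lam, right, left = _spectral_decomposition_reversible(T, pi)
    else:
        T = C / C.sum(axis=1)[:, None]
        lam_c, vl, vr = scipy.linalg.eig(T, left=True, right=True)
        order = np.argsort(-lam_c.real)
        lam_c, vl, vr = lam_c[order], vl[:, order], vr[:, order]
        if np.abs(lam_c.imag).max() > 1e-12:
            warnings.warn(
                "non-reversible estimator produced complex eigenvalue pairs",
                stacklevel=2,
            )
        pi = np.abs(vl[:, 0].real)
        pi = pi / pi.sum()
        lam, right, left = lam_c, vr, vl.T.conj()
    return MarkovModel(
        T=T,
        lag_frames=cm.lag_frames,
        frame_interval=frame_interval,
        pi=pi,
        eigenvalues=lam,
        right_eigenvectors=right,
        left_eigenvectors=left,
        active_set=cm.active_set.copy(),
        reversible=reversible,
    )


def implied_timescales_scan(
    dtrajs: Sequence[np.ndarray],
    lags: Sequence[int],
    n_timescales: int = 5,
    frame_interval: float = 1.0,
    reversible: bool = True,
) -> pd.DataFrame:
    """Top implied timescales (time units) as a function of lag (frames).

    The standard lag-selection diagnostic: pick the smallest lag at which
    the timescales level off. Lags at which estimation fails are skipped
    with a warning; lags leaving fewer than ~2 transitions per state pair
    are flagged in the ``low_counts`` column.
    """
    rows = []
    for lag in lags:
        try:
            cm = trim_to_connected(count_transitions(dtrajs, lag))
            model = estimate_markov_model(cm, frame_interval, reversible)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"lag {lag}: estimation failed ({exc})", stacklevel=2)
            continue
        total_counts = cm.counts.sum()
        row = {
            "lag_frames": lag,
            "lag_time": lag * frame_interval,
            "low_counts": bool(total_counts < 10 * cm.counts.shape[0]),
        }
        ts = model.implied_timescales(n_timescales)
        for i, t in enumerate(ts, start=2):
            row[f"t{i}"] = t
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GMRQ cross-validation
# ---------------------------------------------------------------------------


@dataclass
class GMRQReport:
    table: pd.DataFrame  # columns: param, split, train_score, test_score, flags
    m: int
    n_splits: int
    best_param: object

    def mean_test_scores(self) -> pd.Series:
        return self.table.groupby("param", sort=False)["test_score"].mean()


def gmrq_score(
    model: MarkovModel,
    dtrajs: Sequence[np.ndarray],
    m: int,
) -> tuple[float, bool]:
    """Generalized matrix Rayleigh quotient of a model's top-m eigenvectors
    against held-out data.

    Builds the held-out correlation matrices on the model's state space:
    C00 = diag of the symmetrized state frequencies and C0t the
    symmetrized lagged correlation; scores trace[(V' C00 V)^-1 V' C0t V]
    for the first m estimated eigenvectors V. On the training data this
    equals the sum of the top-m transition-matrix eigenvalues; by the
    variational principle the population value bounds it from above.

    Returns (score, flagged) where ``flagged`` marks test sets missing
    training states (scored on the intersection).
    """
    n_orig = max(
        int(model.active_set.max()),
        max(int(np.max(d)) for d in dtrajs if len(d)),
    ) + 1
    cm = count_transitions(dtrajs, model.lag_frames, n_states=n_orig)
    C = cm.counts[np.ix_(model.active_set, model.active_set)].astype(float)
    S = 0.5 * (C + C.T)
    present = np.flatnonzero(S.sum(axis=1) > 0)
    flagged = len(present) < model.n_states
    S = S[np.ix_(present, present)]
    S /= S.sum()
    freq = S.sum(axis=1)
    V = np.real(model.right_eigenvectors[present, :m])
    A = V.T * freq @ V  # V' C00 V with diagonal C00
    B = V.T @ S @ V
    score = float(np.trace(np.linalg.pinv(A) @ B))
    return score, flagged


def gmrq_cross_validate(
    trajs: Sequence[object],
    grid: Sequence[object],
    make_discretizer: Callable[[object, Sequence[object]], Callable[[object], np.ndarray]],
    msm_lag: int,
    n_splits: int = 5,
    m: int = 5,
    seed: int = 0,
    frame_interval: float = 1.0,
) -> GMRQReport:
    """Cross-validated GMRQ over a hyperparameter grid.

    Trajectories are the splitting unit: each of ``n_splits`` random 1:1
    splits assigns whole trajectories to train and test. For each grid
    point, ``make_discretizer(param, train_trajs)`` fits the
    dimensionality-reduction/clustering stage on the training set and
    returns a function mapping one trajectory to a discrete trajectory;
    an MSM estimated on the training half is then scored on both halves.
    The winning parameter maximizes the mean test score.
    """
    if len(trajs) < 2:
        raise ValueError("need at least 2 trajectories to split")
    rng = np.random.default_rng(seed)
    n = len(trajs)
    rows = []
    for split in range(n_splits):
        perm = rng.permutation(n)
        half = max(1, n // 2)
        train_idx, test_idx = perm[:half], perm[half:]
        train = [trajs[i] for i in train_idx]
        test = [trajs[i] for i in test_idx]
        for param_index, param in enumerate(grid):
            discretize = make_discretizer(param, train)
            dtrain = [discretize(t) for t in train]
            dtest = [discretize(t) for t in test]
            cm = trim_to_connected(count_transitions(dtrain, msm_lag))
            model = estimate_markov_model(cm, frame_interval, reversible=True)
            train_score, _ = gmrq_score(model, dtrain, m)
            test_score, flagged = gmrq_score(model, dtest, m)
            rows.append(
                {
                    "param_index": param_index,
                    "param": repr(param),
                    "split": split,
                    "train_score": train_score,
                    "test_score": test_score,
                    "missing_states": flagged,
                }
            )
    table = pd.DataFrame(rows)
    best_idx = int(table.groupby("param_index")["test_score"].mean().idxmax())
    return GMRQReport(
        table=table, m=m, n_splits=n_splits, best_param=grid[best_idx]
    )


# ---------------------------------------------------------------------------
# Residence probability test
# ---------------------------------------------------------------------------


@dataclass
class ResidenceReport:
    states: np.ndarray  # original state labels tested
    lag_multiples: np.ndarray
    model_curves: np.ndarray  # (n_states, n_multiples)
    data_curves: np.ndarray
    lower: np.ndarray  # 95% bootstrap band
    upper: np.ndarray
    passed: np.ndarray  # bool per state
    excluded: list[int] = field(default_factory=list)

    @property
    def all_passed(self) -> bool:
        return bool(self.passed.all()) if len(self.passed) else False


def _residence_sums(
    d: np.ndarray,
    state: int,
    lag_frames: int,
    multiples: np.ndarray,
    min_start_spacing: int,
    smoothing_window: int,
) -> tuple[np.ndarray, int]:
    """Per-trajectory smoothed residence sums and start count.

    Sufficient statistics for one trajectory: the full-data curve and any
    trajectory-bootstrap curve are weighted aggregates of these, so the
    bootstrap never rescans the trajectories.
    """
    horizon = int(max(multiples)) * lag_frames
    hw = smoothing_window // 2
    sums = np.zeros(len(multiples))
    if len(d) <= horizon:
        return sums, 0
    ind = (d == state).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(ind)])
    hits = np.flatnonzero(ind[: len(d) - horizon])
    last = -(10**12)
    starts = []
    for t in hits:
        if t - last >= min_start_spacing:
            starts.append(t)
            last = t
    if not starts:
        return sums, 0
    starts = np.asarray(starts)
    for j, k in enumerate(multiples):
        if k == 0:
            sums[j] = len(starts)
            continue
        centers = starts + int(k) * lag_frames
        lo = np.maximum(centers - hw, 0)
        hi = np.minimum(centers + hw + 1, len(d))
        sums[j] = np.sum((csum[hi] - csum[lo]) / (hi - lo))
    return sums, len(starts)


def residence_probability_test(
    model: MarkovModel,
    dtrajs: Sequence[np.ndarray],
    n_top: int = 12,
    lag_multiples: Sequence[int] = (0, 1, 2),
    min_start_spacing: int = 45,
    smoothing_window: int = 10,
    n_boot: int = 200,
    min_starts: int = 10,
    simultaneous: bool = True,
    seed: int = 0,
) -> ResidenceReport:
    """Compare model-propagated self-residence (T^k)_ii with the data.

    For each of the ``n_top`` most populated microstates, the model curve
    is the state's diagonal entry of T raised to the k-th power; the data
    curve is the window-smoothed fraction of starts (occurrences of the
    state spaced at least ``min_start_spacing`` frames apart) still/again
    in the state after k lag times. A state passes when the model curve
    lies inside the 95% band of a trajectory-level bootstrap of the data
    curve. At k = 0 both curves are exactly 1 by construction. Because
    the verdict requires every tested state to pass at every lag
    multiple, the default band is Bonferroni-adjusted for simultaneous
    95% coverage over the whole family of comparisons (``simultaneous``
    False reverts to pointwise 95% bands). States with fewer than
    ``min_starts`` qualifying starts are excluded with a warning.
    """
    multiples = np.asarray(lag_multiples, dtype=int)
    order = np.argsort(-model.pi)[:n_top]
    states_orig = model.active_set[order]
    rng = np.random.default_rng(seed)
    n_traj = len(dtrajs)
    boot_idx = rng.integers(0, n_traj, size=(n_boot, n_traj))
    n_comparisons = max(1, len(order) * int(np.count_nonzero(multiples)))
    alpha = 0.05 / n_comparisons if simultaneous else 0.05

    kept, model_curves, data_curves, lowers, uppers, passed = [], [], [], [], [], []
    excluded = []
    Tk = {0: np.eye(model.n_states)}
    for k in multiples:
        if k not in Tk:
            Tk[k] = np.linalg.matrix_power(model.T, int(k))
    for local, orig in zip(order, states_orig):
        per_traj = [
            _residence_sums(
                np.asarray(d), int(orig), model.lag_frames, multiples,
                min_start_spacing, smoothing_window,
            )
            for d in dtrajs
        ]
        sums = np.array([s for s, _ in per_traj])  # (n_traj, n_multiples)
        counts = np.array([c for _, c in per_traj], dtype=float)
        n_starts = int(counts.sum())
        if n_starts < min_starts:
            warnings.warn(
                f"state {orig}: only {n_starts} qualifying starts; excluded",
                stacklevel=2,
            )
            excluded.append(int(orig))
            continue
        mc = np.array([1.0 if k == 0 else Tk[k][local, local] for k in multiples])
        data = sums.sum(axis=0) / n_starts
        data = np.where(multiples == 0, 1.0, data)
        boot_counts = counts[boot_idx].sum(axis=1)  # (n_boot,)
        with np.errstate(invalid="ignore", divide="ignore"):
            boots = sums[boot_idx].sum(axis=1) / boot_counts[:, None]
        boots = np.where(multiples[None, :] == 0, 1.0, boots)
        # Student-t band from the bootstrap SD: percentile bands of a few
        # hundred resamples cannot resolve Bonferroni-tail quantiles, and
        # the SD of a 10-trajectory mean is itself noisy, so the band is
        # data +/- t_{n-1} * SD with the n/(n-1) small-sample inflation
        # of the trajectory-level bootstrap
        z = scipy.stats.t.ppf(1 - alpha / 2, df=max(n_traj - 1, 1))
        sd = np.nanstd(boots, axis=0) * np.sqrt(n_traj / max(n_traj - 1, 1))
        lo = np.where(multiples == 0, 1.0, data - z * sd)
        hi = np.where(multiples == 0, 1.0, data + z * sd)
        ok = bool(np.all((mc >= lo - 1e-12) & (mc <= hi + 1e-12)))
        kept.append(int(orig))
        model_curves.append(mc)
        data_curves.append(data)
        lowers.append(lo)
        uppers.append(hi)
        passed.append(ok)
    return ResidenceReport(
        states=np.array(kept),
        lag_multiples=multiples,
        model_curves=np.array(model_curves),
        data_curves=np.array(data_curves),
        lower=np.array(lowers),
        upper=np.array(uppers),
        passed=np.array(passed, dtype=bool),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# MCMC observable sampling, MFPT, block bootstrap
# ---------------------------------------------------------------------------


def _start_states(model: MarkovModel, n_chains: int, rng: np.random.Generator):
    return rng.choice(model.n_states, size=n_chains, p=model.pi)


def sample_observable_mcmc(
    model: MarkovModel,
    per_state_values: np.ndarray,
    n_chains: int = 10,
    n_steps: int = 100_000,
    burn_in_fraction: float = 0.2,
    seed: int = 0,
    n_boot: int = 0,
):
    """MSM-weighted observable means from MCMC chains of the model.

    ``per_state_values`` maps each active-set state to one value (shape
    (k,)) or several observables at once (shape (k, p)). Chains start
    from pi, the first ``burn_in_fraction`` of steps is discarded, and
    each chain contributes one time-average; reported are the
    across-chain mean and SD, plus a 95% percentile band over ``n_boot``
    bootstrap resamples of chains when requested. This is the estimation
    protocol used for macrostate populations, H-bond percentages and
    straight-helix fractions.
    """
    if n_chains < 2:
        raise ValueError("need at least 2 chains for an SD")
    vals = np.asarray(per_state_values, dtype=float)
    squeeze = vals.ndim == 1
    if squeeze:
        vals = vals[:, None]
    if vals.shape[0] != model.n_states:
        raise ValueError("per_state_values must be defined on the active set")
    rng = np.random.default_rng(seed)
    starts = _start_states(model, n_chains, rng)
    chains = sample_markov_chains(
        model.T, n_chains, n_steps, starts, int(rng.integers(2**31 - 1))
    )
    burn = int(burn_in_fraction * n_steps)
    chain_means = vals[chains[:, burn:]].mean(axis=1)  # (n_chains, p)
    mean = chain_means.mean(axis=0)
    sd = chain_means.std(axis=0, ddof=1)
    result = {"mean": mean, "sd": sd, "chain_means": chain_means}
    if n_boot:
        idx = rng.integers(0, n_chains, size=(n_boot, n_chains))
        boot = chain_means[idx].mean(axis=1)  # (n_boot, p)
        result["ci_low"] = np.percentile(boot, 2.5, axis=0)
        result["ci_high"] = np.percentile(boot, 97.5, axis=0)
    if squeeze:
        result = {
            k: (v[..., 0] if isinstance(v, np.ndarray) and v.shape[-1] == 1 else v)
            for k, v in result.items()
        }
    return result


def mcmc_mfpt(
    model: MarkovModel,
    source: Sequence[int],
    target: Sequence[int],
    n_chains: int = 10,
    n_steps: int = 100_000,
    seed: int = 0,
) -> dict:
    """Mean first-passage time source -> target from MCMC chains.

    Averages, over every source-occupied frame with a later target visit,
    the time to the next target visit — the chain analogue of the
    pi-weighted linear-solve MFPT it is cross-checked against. States are
    active-set indices; the result is in physical time via tau.
    """
    source = np.asarray(sorted(set(map(int, source))))
    target = np.asarray(sorted(set(map(int, target))))
    if len(source) == 0 or len(target) == 0:
        raise ValueError("source and target must be nonempty")
    if np.intersect1d(source, target).size and not np.array_equal(source, target):
        raise ValueError("source and target must be disjoint (or identical)")
    rng = np.random.default_rng(seed)
    starts = _start_states(model, n_chains, rng)
    chains = sample_markov_chains(
        model.T, n_chains, n_steps, starts, int(rng.integers(2**31 - 1))
    )
    in_target = np.isin(chains, target)
    in_source = np.isin(chains, source)
    per_chain = []
    for c in range(n_chains):
        t_target = np.flatnonzero(in_target[c])
        t_source = np.flatnonzero(in_source[c])
        if len(t_target) == 0 or len(t_source) == 0:
            continue
        pos = np.searchsorted(t_target, t_source, side="left")
        ok = pos < len(t_target)
        if not ok.any():
            continue
        waits = t_target[pos[ok]] - t_source[ok]
        per_chain.append(waits.mean())
    if not per_chain:
        raise RuntimeError(
            "no completed source->target passages in any chain; "
            "increase n_steps or check connectivity"
        )
    per_chain = np.array(per_chain) * model.tau
    return {
        "mfpt": float(per_chain.mean()),
        "sd": float(per_chain.std(ddof=1)) if len(per_chain) > 1 else 0.0,
        "n_chains_used": len(per_chain),
    }


def block_bootstrap(
    series: Sequence[np.ndarray] | np.ndarray,
    block_length: int,
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_resamples: int = 1000,
    seed: int = 0,
) -> dict:
    """Moving-free block bootstrap of a trajectory statistic.

    Each series is split into contiguous blocks of ``block_length``
    frames (the final partial block is kept); blocks are resampled with
    replacement up to the original total length, the statistic applied to
    the concatenation, and the mean plus the 2.5/97.5 percentile interval
    reported over ``n_resamples`` draws. Respects temporal correlation up
    to the block length.
    """
    if isinstance(series, np.ndarray) and series.ndim == 1:
        series = [series]
    blocks = []
    total = 0
    for s in series:
        s = np.asarray(s, dtype=float)
        total += len(s)
        for start in range(0, len(s), block_length):
            blocks.append(s[start : start + block_length])
    if not blocks:
        raise ValueError("no data")
    if block_length > total:
        raise ValueError("block_length exceeds the total series length")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_resamples)
    n_blocks = len(blocks)
    n_draw = int(np.ceil(total / block_length)) + 1
    for b in range(n_resamples):
        idx = rng.integers(0, n_blocks, size=n_draw)
        cat = np.concatenate([blocks[i] for i in idx])[:total]
        while len(cat) < total:  # short partial blocks drawn: top up
            cat = np.concatenate(
                [cat, blocks[int(rng.integers(0, n_blocks))]]
            )[:total]
        try:
            stats[b] = statistic(cat)
        except Exception as exc:
            raise RuntimeError(f"statistic failed on resample {b}: {exc}") from exc
    return {
        "mean": float(stats.mean()),
        "ci_low": float(np.percentile(stats, 2.5)),
        "ci_high": float(np.percentile(stats, 97.5)),
        "n_blocks": n_blocks,
    }
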