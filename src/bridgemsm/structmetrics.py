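"""Structural observables: helix kinking, hydrogen bonds, odds ratios.

Helix kinking is measured Kink-Finder style: cylinders are fit by
nonlinear least squares to 6-residue windows of the C-alpha trace on
either side of each residue, and the kink angle is the angle between the
two cylinder axes; a conformation with no kink angle above the 35 deg
threshold is classified straight. Hydrogen bonds follow the geometric
criterion (donor-acceptor distance < 0.35 nm and hydrogen deviation
< 30 deg from the donor-acceptor line). The coupling between kinking and
a given hydrogen bond is quantified by the odds ratio
OR = (B_s/B_k)/(NB_s/NB_k) over the straight/kinked x bond/no-bond
populations. Per-microstate frame averages feed the MSM-weighted (MCMC)
macrostate percentages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .kinetics import MacroModel
from .msm import MarkovModel
from .tica import TICAModel, transform

__all__ = [
    "CylinderFit",
    "KinkProfile",
    "HingeMap",
    "HBondCriterion",
    "KinkHBondTable",
    "fit_cylinder",
    "kink_profile",
    "aggregate_hinges",
    "detect_hbond",
    "detect_hbond_array",
    "per_state_observable",
    "odds_ratio",
    "tic_shift_histogram",
    "barrier_start_selection",
]


# ---------------------------------------------------------------------------
# Cylinder fitting and kink profiles
# ---------------------------------------------------------------------------


@dataclass
class CylinderFit:
    axis_direction: np.ndarray  # unit vector, oriented along residue order
    axis_point: np.ndarray
    radius: float
    residual_rms: float


def _orthonormal_complement(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def fit_cylinder(points: np.ndarray) -> CylinderFit:
    """Least-squares cylinder through >= 6 points.

    Minimizes sum (dist(p_i, axis) - r)^2 over axis position, axis
    direction and radius. The solver is started from each of the three
    principal axes of the point cloud and the lowest-residual solution
    kept: a single principal-axis start can land in a spurious local
    minimum when the cylinder is short relative to its radius or the
    segment is bent. The returned direction is unit norm and oriented so
    its dot product with the first-to-last point direction is positive.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 6 or pts.shape[1] != 3:
        raise ValueError("need at least 6 points in 3D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, Vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-10 * max(svals[0], 1.0):
        raise ValueError("points are collinear; cylinder fit is degenerate")

    def initial_cost(d0):
        perp = centered - np.outer(centered @ d0, d0)
        dist = np.linalg.norm(perp, axis=1)
        return np.sum((dist - dist.mean()) ** 2)

    # the cylinder-fit cost surface of a short helical segment is
    # multi-modal, and for a bent segment the global optimum can be an
    # oblique interpolating cylinder with no geometric meaning; start from
    # the principal axis that best explains the points as a cylinder
    # already and keep the local solution continuous with it
    d0 = min((Vt[i] for i in range(3)), key=initial_cost)
    # rotation-covariant complement basis (built from the data, not from a
    # fixed laboratory vector) so the fit is exactly equivariant under
    # rigid motion of the input
    ref = centered[0] - (centered[0] @ d0) * d0
    if np.linalg.norm(ref) < 1e-9:
        ref = centered[-1] - (centered[-1] @ d0) * d0
    e1 = ref / np.linalg.norm(ref)
    e2 = np.cross(d0, e1)

    def unpack(p):
        t1, t2, s1, s2, r = p
        d = d0 + t1 * e1 + t2 * e2
        d = d / np.linalg.norm(d)
        a = centroid + s1 * e1 + s2 * e2
        return d, a, r

    def residuals(p):
        d, a, r = unpack(p)
        rel = pts - a
        dist = np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)
        return dist - r

    perp0 = centered - np.outer(centered @ d0, d0)
    r0 = float(np.linalg.norm(perp0, axis=1).mean())
    sol = least_squares(
        residuals, x0=[0.0, 0.0, 0.0, 0.0, r0], method="lm",
        ftol=1e-15, xtol=1e-15, gtol=1e-15,
    )
    d, a, r = unpack(sol.x)
    fun = sol.fun
    span = pts[-1] - pts[0]
    if d @ span < 0:
        d = -d
    rms = float(np.sqrt(np.mean(fun**2)))
    return CylinderFit(d, a, abs(float(r)), rms)


@dataclass
class KinkProfile:
    residues: np.ndarray  # residue indices with full windows on both sides
    kink_angles: np.ndarray  # degrees, in [0, 180)
    wobble_azimuths: np.ndarray  # degrees, bend direction in the upstream frame
    threshold: float = 35.0

    @property
    def max_angle(self) -> float:
        return float(self.kink_angles.max())

    @property
    def max_residue(self) -> int:
        return int(self.residues[self.kink_angles.argmax()])

    @property
    def straight(self) -> bool:
        """True when no kink angle reaches the classification threshold."""
        return bool(self.max_angle < self.threshold)


def kink_profile(
    coords: np.ndarray, window: int = 6, threshold: float = 35.0
) -> KinkProfile:
    """Per-residue kink/wobble angles of one helix conformation.

    For each residue with a full ``window``-residue segment on both sides
    (sharing the residue itself), cylinders are fit to the upstream and
    downstream segments; the kink angle is the inter-axis angle and the
    wobble azimuth the direction of the downstream axis in the plane
    normal to the upstream axis, measured from the helix radial vector at
    the residue.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2 * window - 1:
        raise ValueError(f"helix of {n} residues too short for window {window}")
    residues, angles, azimuths = [], [], []
    for r in range(window - 1, n - window + 1):
        up = fit_cylinder(coords[r - window + 1 : r + 1])
        down = fit_cylinder(coords[r : r + window])
        cosang = float(np.clip(up.axis_direction @ down.axis_direction, -1.0, 1.0))
        angle = math.degrees(math.acos(cosang))
        # radial vector of residue r with respect to the upstream axis
        rel = coords[r] - up.axis_point
        radial = rel - (rel @ up.axis_direction) * up.axis_direction
        nr = np.linalg.norm(radial)
        if nr < 1e-12:
            az = 0.0
        else:
            e1 = radial / nr
            e2 = np.cross(up.axis_direction, e1)
            dproj = down.axis_direction - (
                down.axis_direction @ up.axis_direction
            ) * up.axis_direction
            az = math.degrees(math.atan2(dproj @ e2, dproj @ e1)) % 360.0
        residues.append(r)
        angles.append(angle)
        azimuths.append(az)
    return KinkProfile(
        np.array(residues), np.array(angles), np.array(azimuths), threshold
    )


@dataclass
class HingeMap:
    """Named hinges mapped to inclusive residue index ranges."""

    hinges: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        spans = sorted(self.hinges.values())
        for (a1, b1), (a2, b2) in zip(spans[:-1], spans[1:]):
            if b1 < a1 or b2 < a2:
                raise ValueError("hinge range reversed")
            if a2 <= b1:
                raise ValueError("hinge ranges overlap")


@dataclass
class HingeAggregate:
    hinge_histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # (density, edges)
    residue_kink_frequency: dict[int, float]
    hinge_kink_frequency: dict[str, float]


def aggregate_hinges(
    profiles: Sequence[KinkProfile],
    hinge_map: HingeMap,
    bins: int = 36,
    angle_range: tuple[float, float] = (0.0, 180.0),
) -> HingeAggregate:
    """Pool kink statistics of an ensemble over hinge regions.

    Per hinge: the normalized histogram of all member angles in the
    hinge's residue range, and the fraction of conformations whose
    maximal angle within the hinge exceeds the threshold. Per residue:
    the fraction of conformations whose within-hinge maximum both falls
    on that residue and exceeds the threshold.
    """
    if not profiles:
        raise ValueError("empty ensemble")
    hists: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    res_freq: dict[int, float] = {}
    hinge_freq: dict[str, float] = {}
    n_prof = len(profiles)
    for name, (lo, hi) in hinge_map.hinges.items():
        pooled = []
        counts: dict[int, int] = {r: 0 for r in range(lo, hi + 1)}
        kinked = 0
        for p in profiles:
            mask = (p.residues >= lo) & (p.residues <= hi)
            if not mask.any():
                raise ValueError(
                    f"hinge {name!r} range ({lo},{hi}) outside profile support"
                )
            ang = p.kink_angles[mask]
            res = p.residues[mask]
            pooled.append(ang)
            jmax = ang.argmax()
            if ang[jmax] > p.threshold:
                kinked += 1
                counts[int(res[jmax])] += 1
        pooled = np.concatenate(pooled)
        density, edges = np.histogram(
            pooled, bins=bins, range=angle_range, density=True
        )
        hists[name] = (density, edges)
        hinge_freq[name] = kinked / n_prof
        for r, c in counts.items():
            res_freq[r] = c / n_prof
    return HingeAggregate(hists, res_freq, hinge_freq)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond criterion (strict inequalities).

    Defaults: donor-acceptor distance < 0.35 nm and hydrogen deviation
    from the donor-acceptor line < 30 degrees.
    """

    max_distance: float = 0.35
    max_angle: float = 30.0

    def __post_init__(self) -> None:
        if self.max_distance <= 0 or self.max_angle <= 0:
            raise ValueError("criterion thresholds must be positive")


def detect_hbond(
    donor: np.ndarray,
    hydrogen: np.ndarray,
    acceptor: np.ndarray,
    criterion: HBondCriterion = HBondCriterion(),
) -> bool:
    """True iff the donor/hydrogen/acceptor triple satisfies the criterion."""
    donor = np.asarray(donor, dtype=float)
    hydrogen = np.asarray(hydrogen, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    for v in (donor, hydrogen, acceptor):
        if not np.isfinite(v).all():
            raise ValueError("non-finite coordinates")
    da = acceptor - donor
    dh = hydrogen - donor
    n_dh = np.linalg.norm(dh)
    if n_dh < 1e-12:
        raise ValueError("zero-length donor->hydrogen vector")
    d = np.linalg.norm(da)
    if d < 1e-12:
        raise ValueError("donor and acceptor coincide")
    cosang = float(np.clip(dh @ da / (n_dh * d), -1.0, 1.0))
    theta = math.degrees(math.acos(cosang))
    return bool(d < criterion.max_distance and theta < criterion.max_angle)


def detect_hbond_array(
    donors: np.ndarray,
    hydrogens: np.ndarray,
    acceptors: np.ndarray,
    criterion: HBondCriterion = HBondCriterion(),
) -> np.ndarray:
    """Vectorized criterion over (n, 3) coordinate arrays."""
    da = np.asarray(acceptors, float) - np.asarray(donors, float)
    dh = np.asarray(hydrogens, float) - np.asarray(donors, float)
    d = np.linalg.norm(da, axis=1)
    n_dh = np.linalg.norm(dh, axis=1)
    if (n_dh < 1e-12).any():
        raise ValueError("zero-length donor->hydrogen vector")
    cosang = np.clip(np.sum(dh * da, axis=1) / (n_dh * d), -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    return (d < criterion.max_distance) & (theta < criterion.max_angle)


# ---------------------------------------------------------------------------
# Observable aggregation, odds ratio, tIC shifts, barrier starts
# ---------------------------------------------------------------------------


def per_state_observable(
    dtrajs: Sequence[np.ndarray],
    frame_values: Sequence[np.ndarray],
    n_states: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of a per-frame observable over the frames of each microstate.

    Returns (means, counts); states with no frames get NaN means and are
    flagged with a warning. Feed the means (restricted to the model's
    active set) to :func:`bridgemsm.msm.sample_observable_mcmc` for
    MSM-weighted macrostate percentages.
    """
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    frame_values = [np.asarray(v, dtype=float) for v in frame_values]
    if len(dtrajs) != len(frame_values) or any(
        len(d) != len(v) for d, v in zip(dtrajs, frame_values)
    ):
        raise ValueError("frame_values must align 1:1 with dtraj frames")
    if n_states is None:
        n_states = int(max(d.max() for d in dtrajs)) + 1
    sums = np.zeros(n_states)
    counts = np.zeros(n_states, dtype=np.int64)
    for d, v in zip(dtrajs, frame_values):
        np.add.at(sums, d, v)
        np.add.at(counts, d, 1)
    empty = counts == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} microstates have no frames; means set to NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        means = np.where(empty, np.nan, sums / np.maximum(counts, 1))
    return means, counts


@dataclass
class KinkHBondTable:
    """Populations of straight/kinked conformations with/without a bond."""

    B_s: float  # bond present, straight helix
    B_k: float  # bond present, kinked helix
    NB_s: float  # no bond, straight
    NB_k: float  # no bond, kinked

    def __post_init__(self) -> None:
        cells = (self.B_s, self.B_k, self.NB_s, self.NB_k)
        if any(not np.isfinite(c) or c < 0 for c in cells):
            raise ValueError("populations must be finite and nonnegative")


def odds_ratio(table: KinkHBondTable) -> float:
    """OR = (B_s/B_k)/(NB_s/NB_k): bond association with straight helices.

    OR > 1 means the bond co-occurs with straight conformations more
    often than chance; swapping bond/no-bond labels maps OR -> 1/OR.
    """
    for name in ("B_k", "NB_s", "NB_k"):
        if getattr(table, name) == 0:
            raise ZeroDivisionError(f"odds ratio undefined: cell {name} is zero")
    return (table.B_s / table.B_k) / (table.NB_s / table.NB_k)


def tic_shift_histogram(
    model: TICAModel,
    trajs: Sequence,
    component: int = 0,
    bins: int | np.ndarray = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of per-frame tIC shifts from each start frame.

    For each trajectory, Delta(t) = tIC(frame t) - tIC(frame 0) on the
    chosen component; shifts are pooled over trajectories and returned as
    a unit-area histogram (density, edges). The perturbation-run
    diagnostic: a drift of the distribution off zero signals net motion
    along the component.
    """
    deltas = []
    for tr in trajs:
        proj = transform(model, tr, n_components=component + 1)[:, component]
        if len(proj) == 0:
            warnings.warn("empty trajectory skipped", stacklevel=2)
            continue
        deltas.append(proj - proj[0])
    if not deltas:
        raise ValueError("no usable trajectories")
    pooled = np.concatenate(deltas)
    return np.histogram(pooled, bins=bins, density=True)


def barrier_start_selection(
    model: MarkovModel,
    macro: MacroModel,
    state_a: int,
    state_b: int,
    n: int = 5,
) -> dict[int, np.ndarray]:
    """Barrier-adjacent microstates: top-n per macrostate by one-step
    probability of hopping into the other macrostate (ties by higher pi).

    The selection rule for seeding perturbation (mutant) simulations from
    conformations near the inter-state barrier.
    """
    if state_a == state_b:
        raise ValueError("macrostates must be distinct")
    out: dict[int, np.ndarray] = {}
    for here, there in ((state_a, state_b), (state_b, state_a)):
        members = macro.members(here)
        if members.size == 0:
            raise ValueError(f"macrostate {here} is empty")
        other = macro.members(there)
        score = model.T[np.ix_(members, other)].sum(axis=1)
        if len(members) < n:
            warnings.warn(
                f"macrostate {here} has only {len(members)} members (< {n})",
                stacklevel=2,
            )
            order = np.lexsort((-model.pi[members], -score))
            out[here] = members[order]
        else:
            order = np.lexsort((-model.pi[members], -score))
            out[here] = members[order[:n]]
    return out
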