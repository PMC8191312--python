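"""Synthetic inputs with known ground truth.

The molecular trajectories behind translocation-pausing MSMs are not
something a test suite can regenerate, so every downstream operator is
exercised on synthetic stand-ins whose true answer is known in closed
form or by quadrature:

* overdamped Langevin trajectories on closed-form multi-well landscapes
  (the stand-in for MD sampling of a free-energy surface),
* discrete Markov chains drawn from known transition matrices,
* ideal and programmably kinked alpha-helix C-alpha ensembles
  (the stand-in for bridge-helix geometry),
* donor/hydrogen/acceptor triples constructed at exact distance/angle
  coordinates straddling the geometric hydrogen-bond criterion.

All generators draw from one seeded `numpy` Generator per call; identical
seeds reproduce outputs bit for bit.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .features import FeatureTrajectory

__all__ = [
    "Landscape",
    "LangevinConfig",
    "HelixSpec",
    "simulate_overdamped",
    "sample_markov_chain",
    "make_helix",
    "make_hbond_geometry",
    "boltzmann_weights_1d",
    "boltzmann_well_weights_2d",
    "TRIPLE_WELL_CENTERS",
    "TRIPLE_WELL_DEPTHS",
    "TRIPLE_WELL_SIGMA",
]

# Default triple-well constants: three Gaussian wells of unequal depth
# (kT units) along a bent path, plus a quartic confinement and a
# repulsive ridge that blocks the direct 1<->3 shortcut across the
# inside of the bend. Chosen so adjacent barriers are ~3 kT (many
# crossings per 1e4 steps at D=1, dt=0.01) while the direct 1<->3
# channel lies several kT higher, giving a linear 1->2->3 kinetic
# topology with unequal populations.
TRIPLE_WELL_CENTERS = np.array([[-1.7, -0.6], [0.0, 0.6], [1.7, -0.6]])
TRIPLE_WELL_DEPTHS = np.array([4.5, 4.1, 3.7])
TRIPLE_WELL_SIGMA = 0.6
TRIPLE_WELL_RIDGES = (
    {"center": (0.0, -1.3), "height": 5.0, "sigma": 0.8},
    {"center": (0.0, -2.4), "height": 5.0, "sigma": 0.8},
)
_TRIPLE_WELL_CONF = 2.0  # confinement length scale (also seals the route around the ridge)

_DOUBLE_WELL_2D_CENTERS = np.array([[-1.4, 0.0], [1.4, 0.0]])
_DOUBLE_WELL_2D_DEPTHS = np.array([4.0, 3.4])


@dataclass
class Landscape:
    """A closed-form potential U(x) in kT units on a 1D or 2D domain.

    Construct through the named-family classmethods; ``potential`` and
    ``gradient`` take (n, dim) arrays.
    """

    dimension: int
    name: str
    potential: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    minima: np.ndarray  # (n_minima, dim), used for default start points

    @classmethod
    def flat(cls, dimension: int = 1) -> "Landscape":
        return cls(
            dimension,
            "flat",
            lambda x: np.zeros(len(x)),
            lambda x: np.zeros_like(x),
            np.zeros((1, dimension)),
        )

    @classmethod
    def harmonic(cls, kappa: float = 2.0, dimension: int = 1) -> "Landscape":
        return cls(
            dimension,
            "harmonic",
            lambda x: 0.5 * kappa * np.sum(x**2, axis=1),
            lambda x: kappa * x,
            np.zeros((1, dimension)),
        )

    @classmethod
    def double_well(cls, barrier: float = 4.0, tilt: float = 0.0) -> "Landscape":
        """1D quartic double well U = h (x^2-1)^2 + tilt*x (kT units)."""

        def U(x):
            return barrier * (x[:, 0] ** 2 - 1) ** 2 + tilt * x[:, 0]

        def dU(x):
            g = 4 * barrier * x[:, 0] * (x[:, 0] ** 2 - 1) + tilt
            return g[:, None]

        return cls(1, "double_well", U, dU, np.array([[-1.0], [1.0]]))

    @classmethod
    def _gaussian_wells(
        cls,
        name: str,
        centers: np.ndarray,
        depths: np.ndarray,
        sigma: float,
        conf: float,
        ridges: tuple = (),
    ) -> "Landscape":
        centers = np.asarray(centers, dtype=float)
        depths = np.asarray(depths, dtype=float)
        r_centers = np.array([r["center"] for r in ridges], dtype=float)
        r_heights = np.array([r["height"] for r in ridges], dtype=float)
        r_sigmas = np.array([r["sigma"] for r in ridges], dtype=float)

        def U(x):
            r2 = np.sum((x[:, None, :] - centers[None]) ** 2, axis=2)
            out = -(depths[None] * np.exp(-r2 / (2 * sigma**2))).sum(axis=1)
            out = out + (np.sum(x**2, axis=1) / conf**2) ** 2
            for rc, rh, rs in zip(r_centers, r_heights, r_sigmas):
                rr2 = np.sum((x - rc) ** 2, axis=1)
                out = out + rh * np.exp(-rr2 / (2 * rs**2))
            return out

        def dU(x):
            diff = x[:, None, :] - centers[None]  # (n, w, d)
            r2 = np.sum(diff**2, axis=2)
            w = depths[None] * np.exp(-r2 / (2 * sigma**2)) / sigma**2
            g = (w[:, :, None] * diff).sum(axis=1)
            r2tot = np.sum(x**2, axis=1)
            # d/dx (r^2/c^2)^2 = 4 r^2 x / c^4
            g = g + 4 * r2tot[:, None] * x / conf**4
            for rc, rh, rs in zip(r_centers, r_heights, r_sigmas):
                rdiff = x - rc
                rr2 = np.sum(rdiff**2, axis=1)
                g = g - (
                    rh * np.exp(-rr2 / (2 * rs**2)) / rs**2
                )[:, None] * rdiff
            return g

        return cls(centers.shape[1], name, U, dU, centers.copy())

    @classmethod
    def triple_well_2d(cls) -> "Landscape":
        """The default bent three-well 2D landscape (documented constants)."""
        return cls._gaussian_wells(
            "triple_well_2d",
            TRIPLE_WELL_CENTERS,
            TRIPLE_WELL_DEPTHS,
            TRIPLE_WELL_SIGMA,
            _TRIPLE_WELL_CONF,
            ridges=TRIPLE_WELL_RIDGES,
        )

    @classmethod
    def double_well_2d(cls) -> "Landscape":
        """Two unequal Gaussian wells in 2D (the two-state control topology)."""
        return cls._gaussian_wells(
            "double_well_2d",
            _DOUBLE_WELL_2D_CENTERS,
            _DOUBLE_WELL_2D_DEPTHS,
            TRIPLE_WELL_SIGMA,
            _TRIPLE_WELL_CONF,
        )

    @classmethod
    def by_name(cls, name: str, **kwargs) -> "Landscape":
        factories = {
            "flat": cls.flat,
            "harmonic": cls.harmonic,
            "double_well": cls.double_well,
            "double_well_2d": cls.double_well_2d,
            "triple_well_2d": cls.triple_well_2d,
        }
        if name not in factories:
            raise KeyError(f"unknown landscape family {name!r}")
        return factories[name](**kwargs)


@dataclass
class LangevinConfig:
    """Parameters of the overdamped (Brownian) integrator."""

    dt: float = 0.01
    diffusion: float = 1.0
    kT: float = 1.0
    n_steps: int = 10000
    n_trajectories: int = 10
    seed: int = 0
    x0: np.ndarray | None = None  # (n_trajectories, dim); default: minima round-robin

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.diffusion <= 0 or self.kT <= 0:
            raise ValueError("dt, diffusion and kT must be positive")
        if self.n_steps < 2 or self.n_trajectories < 1:
            raise ValueError("need n_steps >= 2 and n_trajectories >= 1")


def simulate_overdamped(
    landscape: Landscape, config: LangevinConfig
) -> list[FeatureTrajectory]:
    """Euler-Maruyama integration of overdamped Langevin dynamics.

    Update: x <- x - (D/kT) grad U(x) kT dt + sqrt(2 D dt) xi, with U in
    kT units (so the drift is -D grad U dt) and xi standard normal. The
    stationary density is exp(-U)/Z, which the tests verify against
    quadrature. Returns one FeatureTrajectory of ``n_steps`` frames per
    requested trajectory, with the frame interval set to dt.
    """
    rng = np.random.default_rng(config.seed)
    dim = landscape.dimension
    n = config.n_trajectories
    if config.x0 is not None:
        x = np.array(config.x0, dtype=float).reshape(n, dim)
    else:
        x = landscape.minima[np.arange(n) % len(landscape.minima)].astype(float)
    drift = config.diffusion * config.dt  # D dt, multiplies grad of U-in-kT
    noise_scale = math.sqrt(2 * config.diffusion * config.dt)
    out = np.empty((config.n_steps, n, dim))
    out[0] = x
    for t in range(1, config.n_steps):
        g = landscape.gradient(x)
        if not np.isfinite(g).all():
            bad = x[~np.isfinite(g).any(axis=1)][0] if np.isfinite(x).all() else x[0]
            raise FloatingPointError(
                f"non-finite potential gradient at coordinate {bad}"
            )
        x = x - drift * g + noise_scale * rng.standard_normal((n, dim))
        out[t] = x
    labels = [f"x{i + 1}" for i in range(dim)]
    return [
        FeatureTrajectory(out[:, i, :].copy(), config.dt, list(labels))
        for i in range(n)
    ]


def _check_stochastic(T: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if (T < -tol).any():
        raise ValueError("negative transition probabilities")
    dev = np.abs(T.sum(axis=1) - 1.0)
    if dev.max() > tol:
        raise ValueError(
            f"row sums deviate from 1 by up to {dev.max():.3g} (> {tol:g})"
        )
    return T


def sample_markov_chain(
    T: np.ndarray,
    n_steps: int,
    start: int | Sequence[float],
    seed: int,
) -> np.ndarray:
    """Sample a discrete trajectory of ``n_steps`` states from row-stochastic T.

    ``start`` is either a state index or a probability vector over states.
    Reproducible under a fixed seed.
    """
    T = _check_stochastic(T)
    k = T.shape[0]
    rng = np.random.default_rng(seed)
    if np.isscalar(start):
        s = int(start)
        if not 0 <= s < k:
            raise ValueError("start state out of range")
    else:
        p = np.asarray(start, dtype=float)
        p = p / p.sum()
        s = int(rng.choice(k, p=p))
    # cumulative rows as plain lists: bisect beats per-step numpy dispatch
    cum = [row.cumsum().tolist() for row in T]
    u = rng.random(n_steps - 1)
    out = np.empty(n_steps, dtype=np.int64)
    out[0] = s
    for t in range(1, n_steps):
        s = bisect_right(cum[s], u[t - 1])
        if s >= k:  # guard against cumulative rounding at 1.0
            s = k - 1
        out[t] = s
    return out


def sample_markov_chains(
    T: np.ndarray,
    n_chains: int,
    n_steps: int,
    starts: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Vectorized multi-chain sampler: (n_chains, n_steps) state array.

    Steps all chains in lockstep, so the cost per step is one vectorized
    draw rather than ``n_chains`` python-level iterations.
    """
    T = _check_stochastic(T)
    cum = T.cumsum(axis=1)
    cum[:, -1] = 1.0
    rng = np.random.default_rng(seed)
    s = np.asarray(starts, dtype=np.int64).copy()
    out = np.empty((n_chains, n_steps), dtype=np.int64)
    out[:, 0] = s
    for t in range(1, n_steps):
        u = rng.random(n_chains)
        s = (u[:, None] < cum[s]).argmax(axis=1)
        out[:, t] = s
    return out


@dataclass
class HelixSpec:
    """Geometry of an ideal alpha-helix C-alpha trace with optional kinks.

    Defaults are canonical alpha-helix parameters: 1.5 A rise/residue,
    100 deg twist/residue, 2.3 A radius. ``kinks`` lists
    (residue_index, kink_angle_deg, wobble_azimuth_deg) with 0-based
    residue indices; each kink bends the downstream segment about an axis
    perpendicular to the local helix axis, oriented by the azimuth.
    """

    n_residues: int = 30
    rise: float = 1.5
    twist: float = 100.0
    radius: float = 2.3
    kinks: list[tuple[int, float, float]] = field(default_factory=list)
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.kinks and self.n_residues < 12:
            raise ValueError("kinked helices need n_residues >= 12")
        for idx, _, _ in self.kinks:
            if idx < 6 or idx > self.n_residues - 7:
                raise ValueError(
                    f"kink residue {idx} is closer than 6 residues to a terminus; "
                    "cylinder windows would not fit"
                )


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    th = math.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)


def make_helix(spec: HelixSpec, seed: int = 0) -> np.ndarray:
    """C-alpha coordinates (n_residues, 3) of the specified helix.

    With no kinks and no noise the points lie exactly on the ideal
    helical curve about the z axis. Kinks are applied in residue order:
    residues strictly downstream of the kink residue are rotated by the
    kink angle about an axis perpendicular to the local helix axis
    (oriented by the wobble azimuth) through the hinge C-alpha, so the
    inter-segment cylinder-axis angle equals the requested kink angle by
    construction.
    """
    n = spec.n_residues
    omega = math.radians(spec.twist)
    i = np.arange(n)
    coords = np.column_stack(
        [
            spec.radius * np.cos(i * omega),
            spec.radius * np.sin(i * omega),
            spec.rise * i,
        ]
    )
    R_cum = np.eye(3)
    for idx, angle, azimuth in sorted(spec.kinks):
        # anchor the bend at the hinge C-alpha so that residue lies exactly
        # on both the upstream and the rotated downstream cylinder surface
        anchor = coords[idx].copy()
        phi = math.radians(azimuth)
        axis = R_cum @ np.array([math.cos(phi), math.sin(phi), 0.0])
        R = _rotation_about_axis(axis, angle)
        coords[idx + 1 :] = (coords[idx + 1 :] - anchor) @ R.T + anchor
        R_cum = R @ R_cum
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
    return coords


def make_hbond_geometry(
    d_DA: float, theta_HDA: float, d_DH: float = 0.10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Donor/hydrogen/acceptor coordinates realizing exact (d_DA, theta_HDA).

    Distances in nm, angle in degrees; the covalent D-H length defaults
    to 0.10 nm. The donor sits at the origin, the acceptor on the +x
    axis, and the hydrogen in the xy-plane at the requested deviation
    from the D->A line.
    """
    if d_DA <= 0:
        raise ValueError("d_DA must be positive")
    if not 0 <= theta_HDA < 90:
        raise ValueError("theta_HDA must be in [0, 90)")
    donor = np.zeros(3)
    acceptor = np.array([d_DA, 0.0, 0.0])
    th = math.radians(theta_HDA)
    hydrogen = np.array([d_DH * math.cos(th), d_DH * math.sin(th), 0.0])
    return donor, hydrogen, acceptor


def boltzmann_weights_1d(
    landscape: Landscape,
    edges: Sequence[float],
    lo: float,
    hi: float,
    n_grid: int = 20001,
) -> np.ndarray:
    """Quadrature Boltzmann weights of 1D regions split at ``edges``.

    Independent oracle for the Langevin sampler: exp(-U) integrated by
    the trapezoid rule over [lo, hi], partitioned at the given edges,
    normalized to sum to 1.
    """
    x = np.linspace(lo, hi, n_grid)
    dens = np.exp(-landscape.potential(x[:, None]))
    bounds = [lo, *edges, hi]
    weights = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        mask = (x >= a) & (x <= b)
        weights.append(np.trapezoid(dens[mask], x[mask]))
    w = np.array(weights)
    return w / w.sum()


def boltzmann_well_weights_2d(
    landscape: Landscape,
    lo: float = -4.0,
    hi: float = 4.0,
    n_grid: int = 401,
) -> np.ndarray:
    """Quadrature Boltzmann weight of each well's nearest-minimum region.

    Partitions the plane by nearest landscape minimum and integrates
    exp(-U) by the 2D trapezoid rule; the oracle the recovered macrostate
    populations are tested against.
    """
    g = np.linspace(lo, hi, n_grid)
    X, Y = np.meshgrid(g, g, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    dens = np.exp(-landscape.potential(pts)).reshape(n_grid, n_grid)
    d2 = ((pts[:, None, :] - landscape.minima[None]) ** 2).sum(axis=2)
    region = d2.argmin(axis=1).reshape(n_grid, n_grid)
    weights = []
    for w in range(len(landscape.minima)):
        masked = np.where(region == w, dens, 0.0)
        weights.append(np.trapezoid(np.trapezoid(masked, g, axis=1), g))
    w = np.array(weights)
    return w / w.sum()
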