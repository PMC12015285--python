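"""Leukocyte segmentation by Levy-flight dung beetle optimization (DBO-LF).

The segmenter searches for K intensity thresholds that partition a
preprocessed smear image into K+1 regions.  Candidate thresholds are scored
either by the global within-region squared error or by a localized
region-based contour energy, and the search is driven by the dung beetle
optimization metaheuristic: a population of candidate solutions split into
four behavioural roles — ball **rollers** (global exploration), **breeders**
(exploitation around the iteration's best), **foragers** (exploitation
around the global best) and **thieves** (jumps toward the global best).
The rolling step is enhanced with Levy-flight increments: heavy-tailed
random step lengths (tail exponent ``delta``) that mix many short moves
with occasional long jumps, which keeps the rollers exploring globally.

The localized energy follows the local region-based active-contour idea:
for every pixel in a narrow band around the contour, interior and exterior
mean intensities are estimated inside a disk of radius ``s`` and the energy
accumulates the squared residuals of neighbours against those local means,
weighted by a smoothed Heaviside interior indicator of the level-set field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LevelSet",
    "LocalRegionConfig",
    "Candidate",
    "DBOConfig",
    "smooth_heaviside",
    "local_window_mask",
    "localized_energy",
    "sample_levy_steps",
    "roll_update",
    "dance_update",
    "breed_update",
    "forage_update",
    "steal_update",
    "optimize",
    "threshold_fitness",
    "segment_image",
    "mask_from_thresholds",
    "extract_boundary",
    "signed_distance",
]

ROLES = ("roller", "breeder", "forager", "thief")


# ---------------------------------------------------------------------------
# Level-set machinery and the localized region energy
# ---------------------------------------------------------------------------


@dataclass
class LevelSet:
    """Signed-distance field whose zero crossing is the contour.

    Sign convention: negative inside the foreground.  ``epsilon`` is the
    half-width of the smoothed Heaviside transition.
    """

    phi: np.ndarray
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 2:
            raise ValueError("phi must be 2-D")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class LocalRegionConfig:
    """Window radius ``radius_s`` and contour band half-width for the energy."""

    radius_s: float = 4.0
    band_width: float = 2.0

    def __post_init__(self) -> None:
        if self.radius_s < 1.0:
            raise ValueError("radius_s must be at least 1 pixel")
        if self.band_width <= 0:
            raise ValueError("band_width must be positive")


def smooth_heaviside(eta, epsilon: float):
    """Smoothed interior indicator of a signed-distance value.

    Returns 1 for ``eta < -epsilon``, 0 for ``eta > epsilon`` and the smooth
    sinusoidal blend ``(1 + η/ε + sin(πη/ε)/π)/2`` in between (evaluated with
    the sign flipped so the function decreases from inside to outside).
    Accepts scalars or arrays.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    eta = np.asarray(eta, dtype=float)
    # middle branch of the smoothed step, oriented interior=1
    mid = 0.5 * (1.0 - eta / epsilon - np.sin(np.pi * eta / epsilon) / np.pi)
    out = np.where(eta < -epsilon, 1.0, np.where(eta > epsilon, 0.0, mid))
    if out.ndim == 0:
        return float(out)
    return out


def local_window_mask(y, y_prime, s: float) -> int:
    """Disk membership indicator: 1 iff ``||y - y'|| < s`` (strict)."""
    if s <= 0:
        raise ValueError("s must be positive")
    dy = float(y[0]) - float(y_prime[0])
    dx = float(y[1]) - float(y_prime[1])
    return 1 if math.hypot(dy, dx) < s else 0


def _disk_footprint(s: float) -> np.ndarray:
    r = int(math.ceil(s - 1e-12)) - 1 if float(s).is_integer() else int(math.floor(s))
    r = max(r, 0)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) < s**2 - 1e-12


def localized_energy(
    image: np.ndarray, levelset: LevelSet, cfg: LocalRegionConfig
) -> float:
    """Localized region energy of a contour over an intensity grid.

    For each pixel ``y`` in the narrow band ``|phi| < band_width``, local
    interior/exterior means ``v_y`` / ``u_y`` are the Heaviside-weighted
    means of the image inside the strict disk of radius ``radius_s``, and
    the energy accumulates, over neighbours ``y'`` in that disk,

        H(y')·(J(y') − v_y)² + (1 − H(y'))·(J(y') − u_y)²

    where ``H`` is the smoothed Heaviside interior indicator.  The result
    is nonnegative and vanishes exactly when the contour separates a
    two-level image in the sharp-Heaviside limit.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != levelset.phi.shape:
        raise ValueError("image and level set shapes differ")
    h = smooth_heaviside(levelset.phi, levelset.epsilon)
    foot = _disk_footprint(cfg.radius_s)

    def disk_sum(a: np.ndarray) -> np.ndarray:
        return ndimage.correlate(a, foot.astype(float), mode="constant", cval=0.0)

    sh = disk_sum(h)
    shj = disk_sum(h * image)
    shj2 = disk_sum(h * image**2)
    sg = disk_sum(1.0 - h)
    sgj = disk_sum((1.0 - h) * image)
    sgj2 = disk_sum((1.0 - h) * image**2)

    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(sh > 0, shj / np.maximum(sh, 1e-300), 0.0)
        u = np.where(sg > 0, sgj / np.maximum(sg, 1e-300), 0.0)
    # sum of squared residuals against the local means, per window centre
    e_in = shj2 - 2.0 * v * shj + v**2 * sh
    e_out = sgj2 - 2.0 * u * sgj + u**2 * sg
    band = np.abs(levelset.phi) < cfg.band_width
    return float(np.sum((e_in + e_out)[band]))


def signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary, negative inside."""
    mask = np.asarray(mask, dtype=bool)
    if mask.all() or not mask.any():
        # no boundary: constant field with the appropriate sign
        return np.full(mask.shape, -1.0 if mask.all() else 1.0)
    outside = ndimage.distance_transform_edt(~mask)
    inside = ndimage.distance_transform_edt(mask)
    return outside - inside


# ---------------------------------------------------------------------------
# Levy-flight step sampler
# ---------------------------------------------------------------------------


def levy_scale_sigma(delta: float) -> float:
    """Mantegna scale factor sigma_u for tail exponent ``delta``."""
    num = math.gamma(1.0 + delta) * math.sin(math.pi * delta / 2.0)
    den = math.gamma((1.0 + delta) / 2.0) * delta * 2.0 ** ((delta - 1.0) / 2.0)
    return (num / den) ** (1.0 / delta)


def sample_levy_steps(
    n: int, delta: float = 1.5, scale: float = 1.0, seed=None
) -> np.ndarray:
    """Draw symmetric heavy-tailed Levy-flight steps (Mantegna construction).

    Steps are ``u / |v|^(1/delta)`` with ``u ~ N(0, sigma_u²)`` and
    ``v ~ N(0, 1)``; their magnitude distribution has tail exponent
    ``delta`` (density ~ ``t^(−1−delta)``).  ``delta = 2`` is the Gaussian
    limit and is returned as plain Gaussian steps.  ``seed`` may be an int
    or a ``numpy.random.Generator``.
    """
    if not 0.0 < delta <= 2.0:
        raise ValueError(f"delta must lie in (0, 2], got {delta}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if delta == 2.0:
        return scale * rng.standard_normal(n)
    sigma = levy_scale_sigma(delta)
    u = rng.normal(0.0, sigma, size=n)
    v = rng.standard_normal(n)
    return scale * u / np.abs(v) ** (1.0 / delta)


def walk_displacement_variance(
    n_steps: int, n_walkers: int = 100, delta: float = 2.0, seed=None
) -> np.ndarray:
    """Displacement variance of a free random walk driven by the sampler.

    Diagnostic for the diffusion regime: at ``delta = 2`` (Gaussian steps)
    the variance across walkers grows linearly with step count — ordinary
    Brownian diffusion with a constant diffusion coefficient — whereas
    heavy-tailed steps (``delta < 2``) give superdiffusive growth.
    Returns the variance at each of the ``n_steps`` times.
    """
    rng = np.random.default_rng(seed)
    steps = sample_levy_steps(n_steps * n_walkers, delta, 1.0, rng).reshape(
        n_walkers, n_steps
    )
    paths = np.cumsum(steps, axis=1)
    return paths.var(axis=0)


# ---------------------------------------------------------------------------
# Dung beetle optimization with Levy flight
# ---------------------------------------------------------------------------


@dataclass
class Candidate:
    """One population member: a real position vector with a behavioural role."""

    position: np.ndarray
    role: str
    fitness: float = math.inf

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class DBOConfig:
    """Population and update-rule parameters of DBO-LF.

    ``role_counts`` gives (rollers, breeders, foragers, thieves) and must sum
    to ``pop_size``.  ``deflection_l`` is the rolling deflection coefficient,
    ``roll_b`` the fixed rolling constant, ``steal_Q`` the stealing constant
    and ``levy_delta`` the Levy tail exponent of the roller steps.
    """

    pop_size: int = 30
    role_counts: tuple[int, int, int, int] = (6, 6, 7, 11)
    max_iter: int = 100
    bounds: tuple[float, float] | list[tuple[float, float]] = (0.0, 1.0)
    deflection_l: float = 0.1
    roll_b: float = 0.3
    steal_Q: float = 0.5
    levy_delta: float = 1.5
    levy_scale: float = 0.1
    dance_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if sum(self.role_counts) != self.pop_size:
            raise ValueError("role_counts must sum to pop_size")
        if not 0.0 < self.deflection_l <= 0.2:
            raise ValueError("deflection_l must lie in (0, 0.2]")
        if not 0.0 < self.levy_delta <= 2.0:
            raise ValueError("levy_delta must lie in (0, 2]")

    def bounds_arrays(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        b = self.bounds
        if isinstance(b, tuple) and np.isscalar(b[0]):
            lb = np.full(dim, float(b[0]))
            ub = np.full(dim, float(b[1]))
        else:
            arr = np.asarray(b, dtype=float)
            lb, ub = arr[:, 0], arr[:, 1]
        if np.any(lb >= ub):
            raise ValueError("lower bounds must be below upper bounds")
        return lb, ub


def _clip(x: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    return np.minimum(np.maximum(x, lb), ub)


def roll_update(
    cand: Candidate,
    prev_position: np.ndarray,
    worst: np.ndarray,
    cfg: DBOConfig,
    rng: np.random.Generator,
    a: float | None = None,
    lam: np.ndarray | None = None,
) -> Candidate:
    """Ball-rolling step with a Levy-flight multiplier on the exploration term.

    ``Y ← Y + b·l·Y_prev + a·|Y − worst|·λ`` with ``a`` a random sign and
    ``λ`` a Levy step; ``a`` and ``lam`` can be forced for testing.
    """
    if cand.role != "roller":
        raise ValueError("roll_update applies to rollers")
    y = cand.position
    lb, ub = cfg.bounds_arrays(y.size)
    if a is None:
        a = 1.0 if rng.random() < 0.5 else -1.0
    if lam is None:
        lam = sample_levy_steps(y.size, cfg.levy_delta, cfg.levy_scale, rng)
    delta_y = np.abs(y - worst)
    new = y + cfg.roll_b * cfg.deflection_l * np.asarray(prev_position) + a * delta_y * lam
    return Candidate(_clip(new, lb, ub), "roller")


def dance_update(
    cand: Candidate,
    prev_position: np.ndarray,
    cfg: DBOConfig,
    rng: np.random.Generator,
    beta: float | None = None,
) -> Candidate:
    """Obstacle-dance step: ``Y ← Y + tan(β)·|Y − Y_prev|`` with β ~ U[0, π].

    β ∈ {0, π/2, π} leaves the position unchanged (tan is zero or singular).
    """
    if cand.role != "roller":
        raise ValueError("dance_update applies to rollers")
    y = cand.position
    lb, ub = cfg.bounds_arrays(y.size)
    if beta is None:
        beta = rng.uniform(0.0, math.pi)
    if beta in (0.0, math.pi) or abs(beta - math.pi / 2.0) < 1e-12:
        return Candidate(y.copy(), "roller")
    new = y + math.tan(beta) * np.abs(y - np.asarray(prev_position))
    return Candidate(_clip(new, lb, ub), "roller")


def _shrinking_bounds(
    anchor: np.ndarray, t: int, cfg: DBOConfig, lb: np.ndarray, ub: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    r = 1.0 - t / cfg.max_iter
    lo = _clip(anchor * (1.0 - r), lb, ub)
    hi = _clip(anchor * (1.0 + r), lb, ub)
    return np.minimum(lo, hi), np.maximum(lo, hi)


def breed_update(
    cand: Candidate,
    local_best: np.ndarray,
    t: int,
    cfg: DBOConfig,
    rng: np.random.Generator,
    A1: np.ndarray | None = None,
    A2: np.ndarray | None = None,
) -> Candidate:
    """Brood-ball step inside a region shrinking around the iteration best."""
    if cand.role != "breeder":
        raise ValueError("breed_update applies to breeders")
    y = cand.position
    lb, ub = cfg.bounds_arrays(y.size)
    la1, ua1 = _shrinking_bounds(np.asarray(local_best), t, cfg, lb, ub)
    if A1 is None:
        A1 = rng.random(y.size)
    if A2 is None:
        A2 = rng.random(y.size)
    new = np.asarray(local_best) + A1 * (y - la1) + A2 * (y - ua1)
    return Candidate(_clip(new, la1, ua1), "breeder")


def forage_update(
    cand: Candidate,
    global_best: np.ndarray,
    t: int,
    cfg: DBOConfig,
    rng: np.random.Generator,
    D1: np.ndarray | None = None,
    D2: np.ndarray | None = None,
) -> Candidate:
    """Foraging step inside a region shrinking around the global best."""
    if cand.role != "forager":
        raise ValueError("forage_update applies to foragers")
    y = cand.position
    lb, ub = cfg.bounds_arrays(y.size)
    la2, ua2 = _shrinking_bounds(np.asarray(global_best), t, cfg, lb, ub)
    if D1 is None:
        D1 = rng.standard_normal(y.size)
    if D2 is None:
        D2 = rng.random(y.size)
    new = y + D1 * (y - la2) + D2 * (y - ua2)
    return Candidate(_clip(new, lb, ub), "forager")


def steal_update(
    cand: Candidate,
    global_best: np.ndarray,
    local_best: np.ndarray,
    worst: np.ndarray,
    cfg: DBOConfig,
    rng: np.random.Generator,
    e: np.ndarray | None = None,
) -> Candidate:
    """Thieving step: jump near the global best, scaled by distance to
    the worst and the iteration best."""
    if cand.role != "thief":
        raise ValueError("steal_update applies to thieves")
    y = cand.position
    lb, ub = cfg.bounds_arrays(y.size)
    if e is None:
        e = rng.standard_normal(y.size)
    new = np.asarray(global_best) + cfg.steal_Q * e * (
        np.abs(y - np.asarray(worst)) + np.abs(y - np.asarray(local_best))
    )
    return Candidate(_clip(new, lb, ub), "thief")


def _assign_roles(cfg: DBOConfig) -> list[str]:
    roles = []
    for role, count in zip(ROLES, cfg.role_counts):
        roles.extend([role] * count)
    return roles


def optimize(fitness, dim: int, cfg: DBOConfig):
    """Run DBO-LF on a bounded real domain.

    Parameters
    ----------
    fitness : callable
        Maps a position vector to a finite float (lower is better).
    dim : int
        Search-space dimension.
    cfg : DBOConfig
        Population, role and update parameters; ``cfg.seed`` fixes the run.

    Returns
    -------
    best_position : ndarray
    best_fitness : float
    trace : ndarray
        Best-so-far fitness per iteration (monotone non-increasing).
    """
    rng = np.random.default_rng(cfg.seed)
    lb, ub = cfg.bounds_arrays(dim)
    roles = _assign_roles(cfg)

    def evaluate(x: np.ndarray) -> float:
        f = float(fitness(x))
        if not math.isfinite(f):
            raise ValueError(f"non-finite fitness {f} at position {x.tolist()}")
        return f

    positions = lb + rng.random((cfg.pop_size, dim)) * (ub - lb)
    fits = np.array([evaluate(p) for p in positions])
    prev_positions = positions.copy()

    best_idx = int(np.argmin(fits))
    gbest = positions[best_idx].copy()
    gbest_fit = float(fits[best_idx])
    trace = []

    for t in range(1, cfg.max_iter + 1):
        it_best = positions[int(np.argmin(fits))].copy()  # iteration-local best
        worst = positions[int(np.argmax(fits))].copy()
        new_positions = positions.copy()
        for i, role in enumerate(roles):
            cand = Candidate(positions[i], role)
            if role == "roller":
                if rng.random() < cfg.dance_prob:
                    cand = dance_update(cand, prev_positions[i], cfg, rng)
                else:
                    cand = roll_update(cand, prev_positions[i], worst, cfg, rng)
            elif role == "breeder":
                cand = breed_update(cand, it_best, t, cfg, rng)
            elif role == "forager":
                cand = forage_update(cand, gbest, t, cfg, rng)
            else:
                cand = steal_update(cand, gbest, it_best, worst, cfg, rng)
            new_positions[i] = cand.position
        prev_positions = positions
        positions = new_positions
        fits = np.array([evaluate(p) for p in positions])
        j = int(np.argmin(fits))
        # elitism: the archive best never worsens; ties keep the earlier find
        if fits[j] < gbest_fit:
            gbest_fit = float(fits[j])
            gbest = positions[j].copy()
        trace.append(gbest_fit)

    return gbest, gbest_fit, np.asarray(trace)


# ---------------------------------------------------------------------------
# Threshold-based image segmentation
# ---------------------------------------------------------------------------

_NLEVELS = 256


def _histogram(image: np.ndarray) -> np.ndarray:
    idx = np.clip((np.asarray(image, dtype=float) * (_NLEVELS - 1)).round().astype(int), 0, _NLEVELS - 1)
    return np.bincount(idx.ravel(), minlength=_NLEVELS).astype(float)


def threshold_fitness(image: np.ndarray):
    """Return a fast within-region squared-error objective over K thresholds.

    The image is quantized to 256 levels; region sums are evaluated from
    prefix arrays so one call costs O(256).  Thresholds are sorted before
    evaluation, so the objective is symmetric in its arguments.
    """
    hist = _histogram(image)
    levels = np.arange(_NLEVELS) / (_NLEVELS - 1)
    c_n = np.concatenate([[0.0], np.cumsum(hist)])
    c_s = np.concatenate([[0.0], np.cumsum(hist * levels)])
    c_s2 = np.concatenate([[0.0], np.cumsum(hist * levels**2)])

    def sse(thresholds: np.ndarray) -> float:
        t = np.sort(np.clip(np.atleast_1d(thresholds), 0.0, 1.0))
        cuts = np.concatenate([[0], np.floor(t * (_NLEVELS - 1)).astype(int) + 1, [_NLEVELS]])
        total = 0.0
        for a, b in zip(cuts[:-1], cuts[1:]):
            n = c_n[b] - c_n[a]
            if n <= 0:
                continue
            s = c_s[b] - c_s[a]
            s2 = c_s2[b] - c_s2[a]
            total += s2 - s * s / n
        return float(total)

    return sse


def exhaustive_threshold_search(image: np.ndarray) -> tuple[float, float]:
    """Brute-force single-threshold minimizer of the within-region SSE.

    Scans all 256 quantized threshold positions; returns (threshold, sse).
    Serves as the independent oracle for the K=1 optimizer route.
    """
    sse = threshold_fitness(image)
    cands = np.arange(_NLEVELS) / (_NLEVELS - 1)
    vals = np.array([sse(np.array([c])) for c in cands])
    i = int(np.argmin(vals))
    return float(cands[i]), float(vals[i])


def mask_from_thresholds(image: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Foreground mask of the threshold partition.

    The K sorted thresholds split intensity into K+1 regions; the foreground
    is the region whose mean intensity lies farthest from the histogram's
    dominant mode (taken as the background level).
    """
    image = np.asarray(image, dtype=float)
    t = np.sort(np.clip(np.atleast_1d(thresholds), 0.0, 1.0))
    labels = np.digitize(image, t)
    hist = _histogram(image)
    bg_level = float(np.argmax(hist)) / (_NLEVELS - 1)
    best_region, best_sep = 0, -1.0
    for r in range(t.size + 1):
        sel = labels == r
        if not sel.any():
            continue
        sep = abs(float(image[sel].mean()) - bg_level)
        if sep > best_sep:
            best_sep, best_region = sep, r
    return labels == best_region


def segment_image(
    image: np.ndarray,
    K: int = 1,
    cfg: DBOConfig | None = None,
    region_cfg: LocalRegionConfig | None = None,
    fitness_mode: str = "global",
    refine_iters: int = 0,
) -> np.ndarray:
    """Segment a preprocessed image with DBO-LF over K intensity thresholds.

    ``fitness_mode="global"`` scores a candidate by the within-region squared
    error of its intensity partition; ``"localized"`` scores the contour of
    the induced foreground mask by the localized region energy.  Optional
    ``refine_iters`` rounds of local mean-reassignment polish the partition.
    """
    image = np.asarray(image, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    n_levels = np.unique(np.round(image * (_NLEVELS - 1))).size
    if K >= n_levels:
        raise ValueError(f"K={K} requires more distinct intensity levels than {n_levels}")
    if cfg is None:
        cfg = DBOConfig(max_iter=60)
    if fitness_mode == "global":
        fitness = threshold_fitness(image)
    elif fitness_mode == "localized":
        rc = region_cfg or LocalRegionConfig()

        def fitness(th):
            mask = mask_from_thresholds(image, th)
            if not mask.any() or mask.all():
                return float(image.size)  # degenerate partition: worst case
            return localized_energy(image, LevelSet(signed_distance(mask)), rc)

    else:
        raise ValueError(f"unknown fitness_mode {fitness_mode!r}")

    best, _, _ = optimize(fitness, K, cfg)
    thresholds = np.sort(best)
    if refine_iters > 0:
        thresholds = _refine_thresholds(image, thresholds, refine_iters)
    return mask_from_thresholds(image, thresholds)


def _refine_thresholds(image: np.ndarray, thresholds: np.ndarray, iters: int) -> np.ndarray:
    """Lloyd-style polish: move each threshold to the midpoint of the means
    of its two adjacent regions."""
    t = thresholds.copy()
    for _ in range(iters):
        labels = np.digitize(image, t)
        means = []
        for r in range(t.size + 1):
            sel = labels == r
            means.append(float(image[sel].mean()) if sel.any() else None)
        new_t = t.copy()
        for k in range(t.size):
            if means[k] is not None and means[k + 1] is not None:
                new_t[k] = 0.5 * (means[k] + means[k + 1])
        if np.allclose(new_t, t):
            break
        t = np.sort(new_t)
    return t


def extract_boundary(mask: np.ndarray) -> np.ndarray:
    """1-pixel inner boundary of a binary mask (8-connected contour).

    A foreground pixel is on the boundary iff its 4-neighbourhood leaves the
    mask (or the frame); an empty mask yields an empty boundary.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("expected a nonempty 2-D mask")
    if not mask.any():
        return np.zeros_like(mask)
    eroded = ndimage.binary_erosion(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]), border_value=0)
    return mask & ~eroded
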