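"""Two-state Lévy-like walkers conditioned on resistance surfaces.

A walker alternates between a *random* state (uniform headings) and a
*correlated* state (headings concentrated around the previous one) following
a 2-state Markov chain whose switching probabilities favour long correlated
runs — short frequent moves interleaved with occasional long directed bursts,
the Lévy-like foraging mix.  Turning angles in the correlated state follow a
wrapped Cauchy distribution whose concentration rho equals the mean resultant
length of the turning angles.

Movement decisions see the landscape: candidate headings are drawn from the
state's turning prior and weighted by ``(1 − mean resistance)**gamma``, the
mean taken along the ray out to the perceptual range.  The stringency
exponent gamma makes the walker *minimise* resistance within its perceptual
range rather than merely prefer it in proportion; under uniform resistance
the weights are equal whatever gamma, so the turning-angle calibration is
unaffected.  If every ray is fully blocked the choice falls back to the
prior alone.  Candidates are drawn *from* the prior rather than taken on a
fixed fan because discretising a rho = 0.95 wrapped Cauchy onto a coarse fan
would inflate the realised turning concentration.  The realised step is
``max_step × (1 − resistance at the current cell)``, truncated at the last
non-barrier cell along the segment, so barriers (ocean, lakes) are never
entered.

Two equivalent engines are provided: a pure-Python reference built from the
public per-step functions, and a numba kernel.  Both consume the same
Mersenne-Twister stream in the same order, so their trajectories are
bit-identical for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

from .errors import InvalidInputError
from .resistance import ResistanceMap

RANDOM, CORRELATED = 0, 1


@dataclass
class MovementParams:
    """Walker configuration (lengths in km).

    Defaults are the full-scale study conditions: switching probabilities
    0.01 (random → correlated) and 0.002 (correlated → random), turning
    concentration 0.95, a 1 km step cap, a 10 km perceptual range, 10 million
    steps per realisation, and a resistance-map update every 250,000 steps
    (1 kyr at 250 steps/yr).  Desk-scale runs override ``n_steps``.
    """

    p_random_to_correlated: float = 0.01
    p_correlated_to_random: float = 0.002
    turning_concentration: float = 0.95
    max_step: float = 1.0
    perceptual_range: float = 10.0
    n_steps: int = 10_000_000
    resistance_update_steps: int = 250_000
    n_candidate_headings: int = 24
    n_ray_samples: int = 10
    perception_stringency: float = 6.0

    def __post_init__(self) -> None:
        for p in (self.p_random_to_correlated, self.p_correlated_to_random):
            if not 0.0 <= p <= 1.0:
                raise InvalidInputError("switching probabilities must lie in [0, 1]")
        if not 0.0 <= self.turning_concentration < 1.0:
            raise InvalidInputError("turning_concentration must lie in [0, 1)")
        if self.max_step <= 0:
            raise InvalidInputError("max_step must be positive")
        if self.perceptual_range < self.max_step:
            raise InvalidInputError("perceptual_range must be at least max_step")

    @property
    def stationary_correlated_fraction(self) -> float:
        """Long-run fraction of steps in the correlated state (closed form)."""
        p, q = self.p_random_to_correlated, self.p_correlated_to_random
        return p / (p + q) if p + q > 0 else float("nan")


def movement_bookkeeping(
    params: MovementParams,
    duration_kyr: float = 40.0,
    residential_move_length: float = 50.0,
) -> dict[str, float]:
    """The bookkeeping quantities implied by a movement configuration.

    For the full-scale defaults (10 million steps over a 40 kyr run, 1 km
    step cap): 250 walks/yr, an upper travel limit of 250 km/yr, at most 5
    residential moves of ``residential_move_length`` km per year, and a
    resistance-map update every 250,000 steps (1 kyr).
    """
    steps_per_year = params.n_steps / (duration_kyr * 1000.0)
    km_per_year = steps_per_year * params.max_step
    return {
        "steps_per_year": steps_per_year,
        "max_km_per_year": km_per_year,
        "max_residential_moves_per_year": km_per_year / residential_move_length,
        "steps_per_resistance_update": float(params.resistance_update_steps),
    }


@dataclass
class Trajectory:
    """Ordered walker record: ``positions`` has n_steps + 1 rows (x, y in km);
    ``states``, ``step_lengths`` and ``cumulative_distance`` one row per step."""

    positions: np.ndarray = field(repr=False)
    states: np.ndarray = field(repr=False)
    step_lengths: np.ndarray = field(repr=False)
    cumulative_distance: np.ndarray = field(repr=False)
    entry_label: str = "custom"
    seed: int = 0

    @property
    def n_steps(self) -> int:
        return len(self.states)

    @property
    def total_distance(self) -> float:
        return float(self.cumulative_distance[-1]) if self.n_steps else 0.0

    def thin(self, every: int) -> np.ndarray:
        """Every ``every``-th position (plus the final one), for density maps."""
        pts = self.positions[::every]
        if (len(self.positions) - 1) % every:
            pts = np.vstack([pts, self.positions[-1]])
        return pts


# ---------------------------------------------------------------------------
# numba kernel (fast path)

@njit(cache=False)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=False, inline="always")
def _res_at(cost, x, y, x0, y0, cell, nrows, ncols, wrap):
    if wrap:
        w = ncols * cell
        h = nrows * cell
        x = (x - (x0 - 0.5 * cell)) % w + (x0 - 0.5 * cell)
        y = (y0 + 0.5 * cell) - ((y0 + 0.5 * cell) - y) % h
    col = int(round((x - x0) / cell))
    row = int(round((y0 - y) / cell))
    if row < 0 or row >= nrows or col < 0 or col >= ncols:
        return 1.0
    return cost[row, col]


@njit(cache=False)
def _walk_segment(
    cost, barrier_thr, x0, y0, cell, nrows, ncols,
    x, y, state, heading, n_steps,
    p_rc, p_cr, rho, max_step, prange, n_cand, n_ray, gamma, wrap,
    xs, ys, states, step_lengths, offset,
):
    """Advance ``n_steps`` steps on one resistance map, recording into the
    output arrays starting at ``offset``.  Uses the module-global Mersenne
    Twister state (seed once via ``_seed_rng``)."""
    cauchy_f = (1.0 - rho) / (1.0 + rho)
    cand = np.empty(n_cand)
    wts = np.empty(n_cand)
    for i in range(n_steps):
        # -- state transition (1 uniform)
        u = np.random.random()
        if state == RANDOM:
            if u < p_rc:
                state = CORRELATED
        else:
            if u < p_cr:
                state = RANDOM
        # -- candidate headings from the turning prior (n_cand uniforms)
        total = 0.0
        for j in range(n_cand):
            uj = np.random.random()
            if state == CORRELATED:
                theta = heading + 2.0 * math.atan(cauchy_f * math.tan(math.pi * (uj - 0.5)))
            else:
                theta = 2.0 * math.pi * uj
            msum = 0.0
            ct = math.cos(theta)
            st = math.sin(theta)
            for s in range(1, n_ray + 1):
                d = prange * s / n_ray
                msum += _res_at(cost, x + d * ct, y + d * st, x0, y0, cell, nrows, ncols, wrap)
            w = 1.0 - msum / n_ray
            if w < 0.0:
                w = 0.0
            w = w**gamma
            cand[j] = theta
            wts[j] = w
            total += w
        # -- selection (1 uniform)
        usel = np.random.random()
        if total <= 0.0:
            idx = int(usel * n_cand)
            if idx >= n_cand:
                idx = n_cand - 1
        else:
            target = usel * total
            acc = 0.0
            idx = n_cand - 1
            for j in range(n_cand):
                acc += wts[j]
                if target < acc:
                    idx = j
                    break
        heading = cand[idx]
        # -- advance: step scaled by local resistance, truncated at barriers
        local = _res_at(cost, x, y, x0, y0, cell, nrows, ncols, wrap)
        step_max = max_step * (1.0 - local)
        realised = 0.0
        cx, cy = x, y
        if step_max > 0.0:
            n_sub = int(math.ceil(step_max / (0.25 * cell)))
            if n_sub < 1:
                n_sub = 1
            ct = math.cos(heading)
            st = math.sin(heading)
            sub = step_max / n_sub
            for s in range(1, n_sub + 1):
                px = x + sub * s * ct
                py = y + sub * s * st
                if _res_at(cost, px, py, x0, y0, cell, nrows, ncols, wrap) >= barrier_thr:
                    break
                if wrap:
                    w = ncols * cell
                    h = nrows * cell
                    px = (px - (x0 - 0.5 * cell)) % w + (x0 - 0.5 * cell)
                    py = (y0 + 0.5 * cell) - ((y0 + 0.5 * cell) - py) % h
                cx, cy = px, py
                realised += sub
        if realised > 0.0:
            x, y = cx, cy
        k = offset + i
        xs[k + 1] = x
        ys[k + 1] = y
        states[k] = state
        step_lengths[k] = realised
    return x, y, state, heading


# ---------------------------------------------------------------------------
# pure-Python reference path (public per-step operations)

def transition_state(current: int, params: MovementParams, rng) -> int:
    """One Markov transition of the behavioural state (consumes 1 uniform)."""
    u = rng.random_sample()
    if current == RANDOM:
        return CORRELATED if u < params.p_random_to_correlated else RANDOM
    return RANDOM if u < params.p_correlated_to_random else CORRELATED


def _sample_prior_heading(prev_heading: float, state: int, rho: float, u: float) -> float:
    if state == CORRELATED:
        f = (1.0 - rho) / (1.0 + rho)
        return prev_heading + 2.0 * math.atan(f * math.tan(math.pi * (u - 0.5)))
    return 2.0 * math.pi * u


def _ray_mean_resistance(
    resistance: ResistanceMap, x: float, y: float, theta: float,
    prange: float, n_ray: int, wrap: bool,
) -> float:
    geom = resistance.geometry
    x0, y0 = geom.origin
    total = 0.0
    for s in range(1, n_ray + 1):
        d = prange * s / n_ray
        total += _res_at(
            resistance.cost, x + d * math.cos(theta), y + d * math.sin(theta),
            x0, y0, geom.cell_size, geom.n_rows, geom.n_cols, wrap,
        )
    return total / n_ray


def choose_heading(
    pos: tuple[float, float],
    prev_heading: float,
    state: int,
    resistance: ResistanceMap,
    params: MovementParams,
    rng,
    wrap: bool = False,
) -> float:
    """Sample the next heading: candidates drawn from the turning prior,
    weighted by (1 − mean ray resistance)**perception_stringency out to the
    perceptual range, one chosen with probability proportional to weight
    (prior alone if all rays are blocked).  Consumes
    n_candidate_headings + 1 uniforms."""
    x, y = pos
    geom = resistance.geometry
    if _res_at(resistance.cost, x, y, *geom.origin, geom.cell_size,
               geom.n_rows, geom.n_cols, wrap) >= resistance.barrier_threshold:
        raise InvalidInputError("walker position lies on a barrier cell")
    n_cand = params.n_candidate_headings
    cand = np.empty(n_cand)
    wts = np.empty(n_cand)
    for j in range(n_cand):
        u = rng.random_sample()
        theta = _sample_prior_heading(prev_heading, state, params.turning_concentration, u)
        w = 1.0 - _ray_mean_resistance(
            resistance, x, y, theta, params.perceptual_range, params.n_ray_samples, wrap
        )
        cand[j] = theta
        wts[j] = max(w, 0.0) ** params.perception_stringency
    total = wts.sum()
    usel = rng.random_sample()
    if total <= 0.0:
        idx = min(int(usel * n_cand), n_cand - 1)
    else:
        idx = int(np.searchsorted(np.cumsum(wts), usel * total, side="right"))
        idx = min(idx, n_cand - 1)
    return float(cand[idx])


def advance(
    pos: tuple[float, float],
    heading: float,
    resistance: ResistanceMap,
    params: MovementParams,
    wrap: bool = False,
) -> tuple[tuple[float, float], float]:
    """Move along ``heading``: step = max_step × (1 − local resistance),
    truncated at the last non-barrier cell along the segment and clamped to
    the grid.  Returns (new position, realised step length); consumes no
    randomness."""
    geom = resistance.geometry
    x0, y0 = geom.origin
    cell = geom.cell_size
    x, y = pos
    local = _res_at(resistance.cost, x, y, x0, y0, cell, geom.n_rows, geom.n_cols, wrap)
    step_max = params.max_step * (1.0 - local)
    if step_max <= 0.0:
        return pos, 0.0
    n_sub = max(int(math.ceil(step_max / (0.25 * cell))), 1)
    sub = step_max / n_sub
    ct, st = math.cos(heading), math.sin(heading)
    cx, cy = x, y
    realised = 0.0
    for s in range(1, n_sub + 1):
        px = x + sub * s * ct
        py = y + sub * s * st
        if _res_at(resistance.cost, px, py, x0, y0, cell, geom.n_rows, geom.n_cols, wrap) >= resistance.barrier_threshold:
            break
        if wrap:
            w = geom.n_cols * cell
            h = geom.n_rows * cell
            px = (px - (x0 - 0.5 * cell)) % w + (x0 - 0.5 * cell)
            py = (y0 + 0.5 * cell) - ((y0 + 0.5 * cell) - py) % h
        cx, cy = px, py
        realised += sub
    return ((cx, cy), realised) if realised > 0.0 else (pos, 0.0)


# ---------------------------------------------------------------------------
# full walks

def _as_stack(resistance_stack) -> list[ResistanceMap]:
    if isinstance(resistance_stack, ResistanceMap):
        return [resistance_stack]
    return list(resistance_stack)


def _rescue_position(pos: tuple[float, float], rmap: ResistanceMap) -> tuple[float, float]:
    """Nearest non-barrier cell centre (used if a map update strands the
    walker, e.g. the shelf it stood on drowned)."""
    geom = rmap.geometry
    barrier = rmap.barrier_mask
    row, col = geom.xy_to_rowcol(*pos)
    if not barrier[row, col]:
        return pos
    _, idx = ndimage.distance_transform_edt(barrier, return_indices=True)
    return geom.rowcol_to_xy(int(idx[0][row, col]), int(idx[1][row, col]))


def simulate_walker(
    entry: tuple[float, float],
    resistance_stack,
    params: MovementParams,
    seed: int = 0,
    engine: str = "numba",
    wrap: bool = False,
    entry_label: str = "custom",
) -> Trajectory:
    """Simulate one walker: n_steps iterations of transition → heading choice
    → advance, switching the active resistance map every
    ``resistance_update_steps`` steps (held at the last map when the stack is
    exhausted).  Deterministic for a fixed seed; ``engine`` selects the numba
    kernel or the bit-identical pure-Python reference."""
    stack = _as_stack(resistance_stack)
    geom = stack[0].geometry
    row, col = geom.xy_to_rowcol(*entry)
    if stack[0].barrier_mask[row, col]:
        raise InvalidInputError("entry point lies on a barrier cell in the first map")

    n = params.n_steps
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    states = np.empty(n, dtype=np.int8)
    step_lengths = np.empty(n)
    xs[0], ys[0] = entry

    x, y = float(entry[0]), float(entry[1])
    state = RANDOM
    heading = 0.0
    if engine == "numba":
        _seed_rng(seed)
    elif engine == "python":
        rng = np.random.RandomState(seed)
    else:
        raise InvalidInputError(f"unknown engine {engine!r}")

    done = 0
    seg = 0
    while done < n:
        rmap = stack[min(seg, len(stack) - 1)]
        if seg > 0:
            x, y = _rescue_position((x, y), rmap)
            xs[done] = x
            ys[done] = y
        n_seg = min(params.resistance_update_steps, n - done)
        if engine == "numba":
            x, y, state, heading = _walk_segment(
                rmap.cost, rmap.barrier_threshold,
                geom.origin[0], geom.origin[1], geom.cell_size,
                geom.n_rows, geom.n_cols,
                x, y, state, heading, n_seg,
                params.p_random_to_correlated, params.p_correlated_to_random,
                params.turning_concentration, params.max_step,
                params.perceptual_range, params.n_candidate_headings,
                params.n_ray_samples, params.perception_stringency, wrap,
                xs, ys, states, step_lengths, done,
            )
        else:
            for i in range(n_seg):
                state = transition_state(state, params, rng)
                heading = choose_heading((x, y), heading, state, rmap, params, rng, wrap)
                (x, y), realised = advance((x, y), heading, rmap, params, wrap)
                k = done + i
                xs[k + 1] = x
                ys[k + 1] = y
                states[k] = state
                step_lengths[k] = realised
        done += n_seg
        seg += 1

    return Trajectory(
        positions=np.column_stack([xs, ys]),
        states=states,
        step_lengths=step_lengths,
        cumulative_distance=np.cumsum(step_lengths),
        entry_label=entry_label,
        seed=seed,
    )


def step_vectors(traj: Trajectory, wrap_geometry=None) -> np.ndarray:
    """Per-step displacement vectors; with ``wrap_geometry`` the shortest
    (minimum-image) displacement on the torus, so realized headings are
    meaningful for walks simulated with ``wrap=True``."""
    d = np.diff(traj.positions, axis=0)
    if wrap_geometry is not None:
        w = wrap_geometry.n_cols * wrap_geometry.cell_size
        h = wrap_geometry.n_rows * wrap_geometry.cell_size
        d[:, 0] = (d[:, 0] + w / 2) % w - w / 2
        d[:, 1] = (d[:, 1] + h / 2) % h - h / 2
    return d


def turning_resultant_length(traj: Trajectory, state: int = CORRELATED, wrap_geometry=None) -> float:
    """Mean resultant length of turning angles over steps in ``state`` —
    the empirical estimate of the wrapped-Cauchy concentration."""
    d = step_vectors(traj, wrap_geometry)
    moved = np.hypot(d[:, 0], d[:, 1]) > 0
    head = np.arctan2(d[:, 1], d[:, 0])
    turns = head[1:] - head[:-1]
    sel = (traj.states[1:] == state) & moved[1:] & moved[:-1]
    if not np.any(sel):
        return float("nan")
    return float(np.abs(np.exp(1j * turns[sel]).mean()))


def derive_seed(base_seed: int, index: int) -> int:
    """Reproducible per-realisation seed from a base seed (counter scheme)."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


def run_ensemble(
    entries,
    resistance_stack,
    params: MovementParams,
    n_realisations: int,
    base_seed: int = 0,
    engine: str = "numba",
    wrap: bool = False,
) -> list[Trajectory]:
    """Independent walker realisations with seeds fanned out from
    ``base_seed``.  ``entries`` is a mapping label → entry point (or a list
    of points); realisations cycle through the entries round-robin."""
    if n_realisations < 1:
        raise InvalidInputError("n_realisations must be >= 1")
    if isinstance(entries, dict):
        items = list(entries.items())
    else:
        items = [("custom", e) for e in entries]
    out: list[Trajectory] = []
    for i in range(n_realisations):
        label, entry = items[i % len(items)]
        out.append(
            simulate_walker(
                entry, resistance_stack, params,
                seed=derive_seed(base_seed, i),
                engine=engine, wrap=wrap, entry_label=label,
            )
        )
    return out
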