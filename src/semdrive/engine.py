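"""Samplers and event-driven simulation for stochastic Petri nets.

Three interchangeable integrators over one model representation:

* ``direct`` — Gillespie's direct method (exact CTMC sampling),
* ``tau``    — fixed-step tau-leaping with Poisson firing counts,
* ``ode``    — deterministic mean-field (RK4 on the expected flows).

All of them evaluate hazards either densely or with first-order
sparsity awareness: a transition whose first input place holds zero
tokens is assigned hazard zero *without evaluating its rate function*,
and a skip counter increments.  Because every hazard in this package is
multiplicative in its first input count, the two modes return
identical hazard vectors and — randomness being a function of the
hazard vector alone — bit-identical trajectories for the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError
from .spn import EMERGE, LARVAL, LINEAR, MATING, SimState, SPNModel

DENSE = "dense"
SPARSE = "sparse_first_order"


@dataclass
class HazardCounters:
    """Bookkeeping of hazard-function work."""

    evaluations: int = 0
    skips: int = 0


@dataclass(frozen=True)
class ReleaseEvent:
    """Timed addition of adults to the population.

    ``sex`` chooses the target place: males join the adult-male pool,
    females join the unmated-female pool (they mate in the model).
    """

    time: float
    sex: str
    genotype: str
    count: int

    def __post_init__(self):
        if self.time < 0:
            raise ConfigurationError("release time must be >= 0")
        if self.sex not in ("female", "male"):
            raise ConfigurationError(f"release sex must be 'female' or 'male', got {self.sex!r}")
        if not (isinstance(self.count, (int, np.integer)) and self.count > 0):
            raise ConfigurationError("release count must be a positive integer")


@dataclass(frozen=True)
class SprayWindow:
    """Half-open interval [start, end) of sustained small-molecule presence."""

    start: float
    end: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ConfigurationError("spray window start must precede end")


@dataclass
class Trajectory:
    """Recorded token counts on a fixed time grid for one run."""

    times: np.ndarray
    counts: np.ndarray  # (n_times, n_places)
    places: list
    sampler: str
    seed: int | None
    dt: float | None
    hazard_mode: str
    events: list = field(default_factory=list)
    molecule: np.ndarray | None = None
    counters: HazardCounters = field(default_factory=HazardCounters)

    def place_series(self, name: str, model: SPNModel) -> np.ndarray:
        return self.counts[:, model.place_index[name]]


# ---------------------------------------------------------------------------
# Hazards


def hazard_vector(
    model: SPNModel,
    x: np.ndarray,
    t: float = 0.0,
    molecule: bool = False,
    mode: str = SPARSE,
    counters: HazardCounters | None = None,
) -> np.ndarray:
    """Nonnegative transition rates at state ``x``.

    ``sparse_first_order`` skips the rate computation for every
    transition whose first input place is empty; ``dense`` evaluates
    all of them.  Both return the same vector (the SPN enabling rule
    forces zero either way).
    """
    if mode not in (DENSE, SPARSE, "sparse"):
        raise ConfigurationError(f"unknown hazard mode {mode!r}")
    coef = model.coef_on if molecule else model.coef_off
    first_tokens = x[model.first]
    T = model.n_transitions
    h = np.zeros(T)
    if mode == DENSE:
        sel = np.arange(T)
        if counters is not None:
            counters.evaluations += T
    else:
        sel = np.nonzero(first_tokens > 0)[0]
        if counters is not None:
            counters.evaluations += sel.size
            counters.skips += T - sel.size
    if sel.size == 0:
        return h
    vals = coef[sel] * first_tokens[sel]
    kinds = model.kind[sel]
    larval = kinds == LARVAL
    if larval.any():
        n_l = x[model.larval_places].sum()
        vals[larval] *= 1.0 + n_l / model.K
    mating = kinds == MATING
    if mating.any():
        m_tot = x[model.male_places].sum()
        if m_tot > 0:
            vals[mating] *= x[model.second[sel[mating]]] / m_tot
        else:
            vals[mating] = 0.0
    h[sel] = vals
    return h


# ---------------------------------------------------------------------------
# Stochastic steps


def _apply_sequential(model: SPNModel, x: np.ndarray, n: np.ndarray, n_fem: np.ndarray):
    """Fire transitions in fixed index order, capping removals at the
    available tokens per place.  Fallback path of the tau-leap when the
    simultaneous update would drive a count negative."""
    em_pos = {int(k): i for i, k in enumerate(model.em_idx)}
    for k in np.nonzero(n)[0]:
        allowed = int(n[k])
        for p, d in model.net_cols[k]:
            if d < 0:
                allowed = min(allowed, int(x[p] // -d))
        if allowed <= 0:
            continue
        for p, d in model.net_cols[k]:
            x[p] += d * allowed
        if int(model.kind[k]) == EMERGE:
            i = em_pos[int(k)]
            nf = int(n_fem[i])
            nm_drawn = int(n[k]) - nf
            # reconcile the pre-drawn sex split with the capped count
            f_used = max(min(nf, allowed), allowed - nm_drawn)
            m_used = allowed - f_used
            if model.em_female[i] >= 0:
                x[model.em_female[i]] += f_used
            if model.em_male[i] >= 0:
                x[model.em_male[i]] += m_used
    return x


def step_tau_leap(
    model: SPNModel,
    state: SimState,
    dt: float,
    rng: np.random.Generator,
    mode: str = SPARSE,
    counters: HazardCounters | None = None,
) -> SimState:
    """One tau-leap: each transition fires Poisson(hazard*dt) times.

    Firings are applied simultaneously through the net stoichiometry;
    if any count would go negative the step falls back to sequential
    processing in fixed transition order with per-place capping, so
    counts never go negative and the update is deterministic given the
    seed.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    h = hazard_vector(model, state.x, state.t, state.molecule, mode, counters)
    n = rng.poisson(h * dt)
    if model.em_idx.size:
        n_em = n[model.em_idx]
        n_fem = rng.binomial(n_em, model.em_pfem)
    else:
        n_fem = np.empty(0, dtype=np.int64)
    state.t += dt
    if not n.any():
        return state
    delta = model.S_net @ n
    for i, k in enumerate(model.em_idx):
        if n[k]:
            if model.em_female[i] >= 0:
                delta[model.em_female[i]] += n_fem[i]
            if model.em_male[i] >= 0:
                delta[model.em_male[i]] += n[k] - n_fem[i]
    x_new = state.x + delta
    if (x_new >= 0).all():
        state.x = x_new
    else:
        state.x = _apply_sequential(model, state.x, n, n_fem)
    return state


def step_direct(
    model: SPNModel,
    state: SimState,
    t_max: float,
    rng: np.random.Generator,
    mode: str = SPARSE,
    counters: HazardCounters | None = None,
) -> bool:
    """One firing of Gillespie's direct method, bounded by ``t_max``.

    Returns True if a transition fired, False if the clock advanced to
    ``t_max`` (zero total rate, or the exponential waiting time
    overshot the boundary — valid by memorylessness).
    """
    h = hazard_vector(model, state.x, state.t, state.molecule, mode, counters)
    total = h.sum()
    if total <= 0:
        state.t = t_max
        return False
    wait = rng.exponential(1.0 / total)
    if state.t + wait >= t_max:
        state.t = t_max
        return False
    state.t += wait
    u = rng.random() * total
    k = int(np.searchsorted(np.cumsum(h), u, side="right"))
    k = min(k, model.n_transitions - 1)
    for p, d in model.net_cols[k]:
        state.x[p] += d
        if state.x[p] < 0:
            raise RuntimeError(
                f"internal invariant violation: place {model.places[p].name} went negative"
            )
    if int(model.kind[k]) == EMERGE:
        i = int(np.searchsorted(model.em_idx, k))
        female = rng.random() < model.em_pfem[i]
        target = model.em_female[i] if female else model.em_male[i]
        if target >= 0:
            state.x[target] += 1
    return True


# ---------------------------------------------------------------------------
# Mean-field


def _mean_field_deriv(
    model: SPNModel, x: np.ndarray, t: float, molecule: bool, counters=None
) -> np.ndarray:
    xc = np.maximum(x, 0.0)
    h = hazard_vector(model, xc, t, molecule, DENSE, counters)
    dx = model.S_net @ h
    for i, k in enumerate(model.em_idx):
        rate = h[k]
        if model.em_female[i] >= 0:
            dx[model.em_female[i]] += rate * model.em_pfem[i]
        if model.em_male[i] >= 0:
            dx[model.em_male[i]] += rate * (1.0 - model.em_pfem[i])
    return dx


def step_mean_field(
    model: SPNModel, state: SimState, dt: float, counters: HazardCounters | None = None
) -> SimState:
    """Classical RK4 step on the expected-flow ODE (real-valued states)."""
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    x, t, mol = state.x, state.t, state.molecule
    k1 = _mean_field_deriv(model, x, t, mol, counters)
    k2 = _mean_field_deriv(model, x + 0.5 * dt * k1, t + 0.5 * dt, mol, counters)
    k3 = _mean_field_deriv(model, x + 0.5 * dt * k2, t + 0.5 * dt, mol, counters)
    k4 = _mean_field_deriv(model, x + dt * k3, t + dt, mol, counters)
    state.x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    np.clip(state.x, 0.0, None, out=state.x)
    state.t += dt
    return state


# ---------------------------------------------------------------------------
# Event-driven simulation


def _resolve_release_place(model: SPNModel, ev: ReleaseEvent) -> int:
    prefix = "M_" if ev.sex == "male" else "U_"
    name = prefix + ev.genotype
    if name not in model.place_index:
        valid = sorted(
            p.genotype for p in model.places if p.kind == ("M" if ev.sex == "male" else "U")
        )
        raise DomainError(
            f"release genotype {ev.genotype!r} ({ev.sex}) not in model; valid: {valid}"
        )
    return model.place_index[name]


def _validate_sprays(sprays) -> list[SprayWindow]:
    sprays = sorted(sprays, key=lambda s: s.start)
    for a, b in zip(sprays, sprays[1:]):
        if b.start < a.end:
            raise ConfigurationError(
                f"spray windows overlap: [{a.start}, {a.end}) and [{b.start}, {b.end})"
            )
    return sprays


def _molecule_at(sprays: list[SprayWindow], t: float) -> bool:
    return any(s.start <= t < s.end for s in sprays)


def simulate(
    model: SPNModel,
    initial_state: SimState,
    sampler: str = "tau",
    t_end: float = 100.0,
    record_dt: float = 1.0,
    releases: tuple[ReleaseEvent, ...] = (),
    sprays: tuple[SprayWindow, ...] = (),
    seed: int | None = 0,
    dt: float = 0.1,
    hazard_mode: str = SPARSE,
) -> Trajectory:
    """Integrate the model to ``t_end`` with releases and spray windows.

    Token counts are recorded on the fixed grid ``0, record_dt, ...``;
    releases add tokens exactly at their times; the molecule state
    toggles at spray boundaries (the on-cube rates apply within
    ``[start, end)``).  Identical (seed, sampler, dt, hazard mode)
    yields a bit-identical trajectory, and sparse vs dense hazard modes
    agree exactly for any seed.
    """
    if sampler not in ("tau", "direct", "ode"):
        raise ConfigurationError(f"unknown sampler {sampler!r}")
    sprays = _validate_sprays(sprays)
    releases = sorted(releases, key=lambda r: r.time)
    release_places = [_resolve_release_place(model, r) for r in releases]

    record_times = np.round(np.arange(0.0, t_end + 0.5 * record_dt, record_dt), 9)
    breakpoints = set(record_times.tolist()) | {t_end}
    breakpoints |= {r.time for r in releases if r.time <= t_end}
    for s in sprays:
        if s.start <= t_end:
            breakpoints.add(s.start)
        if s.end <= t_end:
            breakpoints.add(s.end)
    breakpoints = sorted(breakpoints)

    state = initial_state.copy()
    if sampler in ("tau", "direct"):
        state.x = np.rint(state.x)
    state.molecule = _molecule_at(sprays, 0.0)
    rng = np.random.default_rng(seed)
    counters = HazardCounters()
    events_log = []

    rec_idx = 0
    rec_counts = np.zeros((len(record_times), model.n_places))
    rec_mol = np.zeros(len(record_times), dtype=bool)

    def record_if_due(t):
        nonlocal rec_idx
        while rec_idx < len(record_times) and record_times[rec_idx] <= t + 1e-9:
            rec_counts[rec_idx] = state.x
            rec_mol[rec_idx] = state.molecule
            rec_idx += 1

    # releases grouped by time for application at breakpoints
    rel_by_time: dict[float, list[int]] = {}
    for ridx, r in enumerate(releases):
        rel_by_time.setdefault(r.time, []).append(ridx)

    if breakpoints[0] == 0.0:
        for ridx in rel_by_time.get(0.0, []):
            state.x[release_places[ridx]] += releases[ridx].count
            events_log.append(("release", 0.0, releases[ridx]))
        record_if_due(0.0)
        breakpoints = breakpoints[1:]

    for b in breakpoints:
        span = b - state.t
        if span > 1e-12:
            if sampler == "tau":
                n_steps = max(1, int(round(span / dt)))
                h = span / n_steps
                for _ in range(n_steps):
                    step_tau_leap(model, state, h, rng, hazard_mode, counters)
            elif sampler == "ode":
                n_steps = max(1, int(round(span / dt)))
                h = span / n_steps
                for _ in range(n_steps):
                    step_mean_field(model, state, h, counters)
            else:
                while state.t < b:
                    step_direct(model, state, b, rng, hazard_mode, counters)
        state.t = b
        new_mol = _molecule_at(sprays, b)
        if new_mol != state.molecule:
            events_log.append(("spray_toggle", b, new_mol))
            state.molecule = new_mol
        for ridx in rel_by_time.get(b, []):
            state.x[release_places[ridx]] += releases[ridx].count
            events_log.append(("release", b, releases[ridx]))
        record_if_due(b)

    return Trajectory(
        times=record_times,
        counts=rec_counts,
        places=model.places,
        sampler=sampler,
        seed=seed,
        dt=dt if sampler in ("tau", "ode") else None,
        hazard_mode=hazard_mode,
        events=events_log,
        molecule=rec_mol,
        counters=counters,
    )


def write_trajectory(traj: Trajectory, path) -> None:
    """Long-format CSV (``time,place,count``) for one repetition."""
    import csv
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "place", "count"])
        for i, t in enumerate(traj.times):
            for j, p in enumerate(traj.places):
                writer.writerow([repr(float(t)), p.name, repr(float(traj.counts[i, j]))])


def read_trajectory(path, model: SPNModel) -> Trajectory:
    """Rebuild a trajectory written by :func:`write_trajectory`."""
    import pandas as pd

    frame = pd.read_csv(path)
    wide = frame.pivot(index="time", columns="place", values="count").sort_index()
    counts = np.zeros((len(wide), model.n_places))
    for name, col in wide.items():
        counts[:, model.place_index[name]] = col.to_numpy()
    return Trajectory(
        times=wide.index.to_numpy(dtype=float),
        counts=counts,
        places=model.places,
        sampler="loaded",
        seed=None,
        dt=None,
        hazard_mode=SPARSE,
    )


def simulate_ensemble(
    model: SPNModel,
    initial_state: SimState,
    reps: int,
    seed: int = 0,
    **kwargs,
) -> list[Trajectory]:
    """Independent repetitions seeded ``seed + rep`` (rep = 0..reps-1)."""
    return [
        simulate(model, initial_state, seed=seed + rep, **kwargs) for rep in range(reps)
    ]
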