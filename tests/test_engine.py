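"""Samplers, sparsity-aware hazards and event handling."""

import numpy as np
import pytest
from scipy import stats

import semdrive as sd
from semdrive.errors import ConfigurationError
from semdrive.spn import LINEAR, Place, SimState, build_model

from _oracles import harmonic_extinction_mean


def _death_chain(n0=10, mu=1.0):
    model = build_model(
        [Place("A", "X")],
        [{"name": "death", "kind": LINEAR, "first": 0, "coef": mu, "net": [(0, -1)]}],
    )
    return model, SimState(x=np.array([float(n0)]))


def _birth_model(lam=5.0):
    """Constant-rate birth: catalytic in a permanently occupied source."""
    places = [Place("src", "X"), Place("out", "X")]
    transitions = [
        {"name": "birth", "kind": LINEAR, "first": 0, "coef": lam, "net": [(1, +1)]}
    ]
    return build_model(places, transitions)


# ---------------------------------------------------------------------------
# hazards


def test_sparse_skips_empty_first_input_and_matches_dense(rng):
    model, state = sd.make_fixture_spn(50, 0.2, seed=11)
    for _ in range(200):
        x = np.where(rng.random(model.n_places) < 0.3, rng.integers(0, 20, model.n_places), 0).astype(float)
        c_sparse, c_dense = sd.HazardCounters(), sd.HazardCounters()
        h_s = sd.hazard_vector(model, x, mode=sd.SPARSE, counters=c_sparse)
        h_d = sd.hazard_vector(model, x, mode=sd.DENSE, counters=c_dense)
        assert np.array_equal(h_s, h_d)
        empty_first = int(np.sum(x[model.first] == 0))
        assert c_sparse.skips == empty_first
        assert c_sparse.evaluations == model.n_transitions - empty_first
        assert c_dense.evaluations == model.n_transitions


def test_linear_hazard_value():
    model, _ = _death_chain(n0=10, mu=0.123)
    h = sd.hazard_vector(model, np.array([10.0]), mode=sd.DENSE)
    assert h[0] == pytest.approx(1.23)
    h0 = sd.hazard_vector(model, np.array([0.0]), mode=sd.SPARSE, counters=(c := sd.HazardCounters()))
    assert h0[0] == 0.0 and c.skips == 1 and c.evaluations == 0


# ---------------------------------------------------------------------------
# direct method


def test_direct_method_death_chain_mean_extinction():
    """Linear pure-death chain: E[T] is the harmonic sum over initial counts."""
    model, _ = _death_chain(n0=10, mu=1.0)
    times = []
    for rep in range(4000):
        state = SimState(x=np.array([10.0]))
        rng = np.random.default_rng(500 + rep)
        while state.x[0] > 0:
            sd.step_direct(model, state, 1e12, rng)
        times.append(state.t)
    expect = harmonic_extinction_mean(10)
    se = np.std(times) / np.sqrt(len(times))
    assert abs(np.mean(times) - expect) < 3 * se


def test_direct_waiting_times_exponential():
    """Single linear transition with constant-rate source: inter-event
    times must pass a KS test against the exponential law."""
    model = _birth_model(lam=2.0)
    state = SimState(x=np.array([1.0, 0.0]))
    rng = np.random.default_rng(77)
    times = []
    last = 0.0
    for _ in range(3000):
        sd.step_direct(model, state, 1e12, rng)
        times.append(state.t - last)
        last = state.t
    res = stats.kstest(times, "expon", args=(0, 1 / 2.0))
    assert res.pvalue > 0.01


def test_direct_zero_rate_jumps_to_horizon():
    model, state = _death_chain(n0=0)
    fired = sd.step_direct(model, state, 42.0, np.random.default_rng(0))
    assert not fired and state.t == 42.0 and state.x[0] == 0


# ---------------------------------------------------------------------------
# tau-leaping


def test_tau_leap_poisson_moments():
    model = _birth_model(lam=5.0)
    rng = np.random.default_rng(12)
    incs = []
    for _ in range(10_000):
        state = SimState(x=np.array([1.0, 0.0]))
        sd.step_tau_leap(model, state, 1.0, rng)
        incs.append(state.x[1])
    incs = np.asarray(incs)
    se_mean = np.sqrt(5.0 / len(incs))
    assert abs(incs.mean() - 5.0) < 3 * se_mean
    # variance of a Poisson(5): SE of sample variance ~ sqrt((mu+2mu^2)/n)
    se_var = np.sqrt((5 + 2 * 25) / len(incs))
    assert abs(incs.var() - 5.0) < 3 * se_var


def test_tau_leap_small_dt_matches_euler():
    model, _ = _death_chain(n0=1000, mu=0.5)
    rng = np.random.default_rng(9)
    dt = 1e-3
    changes = []
    for _ in range(20_000):
        state = SimState(x=np.array([1000.0]))
        sd.step_tau_leap(model, state, dt, rng)
        changes.append(1000.0 - state.x[0])
    expected = 0.5 * 1000 * dt
    assert np.mean(changes) == pytest.approx(expected, rel=0.05)


def test_tau_leap_empty_state_unchanged():
    model, state = _death_chain(n0=0)
    sd.step_tau_leap(model, state, 1.0, np.random.default_rng(1))
    assert state.x[0] == 0 and state.t == 1.0


def test_tau_leap_capping_never_goes_negative():
    # huge rate forces the sequential capped fallback
    model, _ = _death_chain(n0=5, mu=50.0)
    rng = np.random.default_rng(4)
    for _ in range(100):
        state = SimState(x=np.array([5.0]))
        sd.step_tau_leap(model, state, 1.0, rng)
        assert state.x[0] >= 0


def test_token_conservation_without_births_and_deaths():
    # pure transfer ring: total tokens constant under every sampler
    places = [Place(f"X{i}", "X") for i in range(4)]
    transitions = [
        {"name": f"move{i}", "kind": LINEAR, "first": i, "coef": 1.0,
         "net": [(i, -1), ((i + 1) % 4, +1)]}
        for i in range(4)
    ]
    model = build_model(places, transitions)
    x0 = np.array([40.0, 10.0, 0.0, 5.0])
    for sampler in ("tau", "direct", "ode"):
        traj = sd.simulate(model, SimState(x=x0.copy()), sampler=sampler,
                           t_end=20, record_dt=1, dt=0.05, seed=3)
        totals = traj.counts.sum(axis=1)
        assert np.allclose(totals, x0.sum(), atol=1e-9)


# ---------------------------------------------------------------------------
# mean field


def test_mean_field_exponential_decay():
    model, _ = _death_chain(n0=1, mu=0.7)
    state = SimState(x=np.array([1.0]))
    for _ in range(int(round(3.0 / 0.01))):
        sd.step_mean_field(model, state, 0.01)
    assert state.x[0] == pytest.approx(np.exp(-0.7 * 3.0), rel=1e-8)


def test_mean_field_equilibrium_derivative(sem_release_build):
    from semdrive.engine import _mean_field_deriv

    model, state0 = sem_release_build["model"], sem_release_build["state0"]
    d = _mean_field_deriv(model, state0.x, 0.0, False)
    occ = state0.x > 0
    assert np.max(np.abs(d[occ]) / state0.x[occ]) < 1e-6


# ---------------------------------------------------------------------------
# simulate: events, determinism, sparse/dense equivalence


def test_release_bookkeeping_exact_increment(sem_release_build):
    model, state0 = sem_release_build["model"], sem_release_build["state0"]
    rel = sd.ReleaseEvent(time=5.0, sex="male", genotype="GG", count=100)
    traj = sd.simulate(model, state0, sampler="ode", t_end=6, record_dt=1,
                       dt=0.25, releases=(rel,))
    before = traj.counts[4].sum()
    # run a twin without the release to isolate the jump
    traj0 = sd.simulate(model, state0, sampler="ode", t_end=6, record_dt=1, dt=0.25)
    assert traj.counts[5].sum() - traj0.counts[5].sum() == pytest.approx(100.0, abs=1e-6)
    gg = model.place_index["M_GG"]
    assert traj.counts[5, gg] >= 100.0 - 1e-9
    assert traj0.counts[5, gg] == 0.0


def test_spray_gating_no_excision_without_spray(sem_release_build):
    model, state0 = sem_release_build["model"], sem_release_build["state0"]
    cfg = sem_release_build["config"]
    traj = sd.simulate(model, state0, sampler="tau", t_end=200, record_dt=1,
                       dt=0.1, releases=cfg.releases, sprays=(), seed=21)
    v_places = [i for i, p in enumerate(model.places) if p.genotype and "V" in p.genotype]
    assert np.all(traj.counts[:, v_places] == 0)


def test_same_seed_bit_identical_and_sparse_dense_agree(sem_release_build):
    model, state0 = sem_release_build["model"], sem_release_build["state0"]
    cfg = sem_release_build["config"]
    kw = dict(sampler="tau", t_end=150, record_dt=1, dt=0.1,
              releases=cfg.releases, sprays=cfg.sprays, seed=13)
    a = sd.simulate(model, state0, hazard_mode=sd.SPARSE, **kw)
    b = sd.simulate(model, state0, hazard_mode=sd.SPARSE, **kw)
    c = sd.simulate(model, state0, hazard_mode=sd.DENSE, **kw)
    assert np.array_equal(a.counts, b.counts)
    assert np.array_equal(a.counts, c.counts)
    assert a.counters.skips > 0 and c.counters.skips == 0
    assert a.counters.evaluations < c.counters.evaluations


def test_overlapping_spray_windows_rejected(sem_release_build):
    model, state0 = sem_release_build["model"], sem_release_build["state0"]
    with pytest.raises(ConfigurationError, match="overlap"):
        sd.simulate(model, state0, sampler="ode", t_end=10, record_dt=1,
                    sprays=(sd.SprayWindow(0, 5), sd.SprayWindow(3, 8)))


def test_unknown_release_genotype_rejected(sem_release_build):
    model, state0 = sem_release_build["model"], sem_release_build["state0"]
    with pytest.raises(sd.errors.DomainError, match="ZZ"):
        sd.simulate(model, state0, sampler="ode", t_end=10, record_dt=1,
                    releases=(sd.ReleaseEvent(time=1.0, sex="male", genotype="ZZ", count=5),))


def test_trajectory_round_trips_through_csv(tmp_path, sem_release_build):
    model, state0 = sem_release_build["model"], sem_release_build["state0"]
    traj = sd.simulate(model, state0, sampler="tau", t_end=5, record_dt=1, dt=0.1, seed=2)
    sd.engine.write_trajectory(traj, tmp_path / "run.csv")
    loaded = sd.engine.read_trajectory(tmp_path / "run.csv", model)
    assert np.array_equal(loaded.times, traj.times)
    assert np.array_equal(loaded.counts, traj.counts)
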