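"""Single-node mosquito lifecycle as a stochastic Petri net.

Stage structure: eggs, larvae and pupae with Erlang-distributed dwell
times (n sub-stages each), then adults.  Emerging adults become
unmated females or males; unmated females mate once (mate genotype
drawn proportional to adult male counts), store the mate's genotype,
and lay eggs at rate ``beta`` with offspring genotypes drawn from the
active inheritance cube thinned by viability.  Larval mortality is
density dependent, ``mu_L * (1 + N_L / K)`` with ``N_L`` the total
larval count.  Unmated females are a short-lived transient (mating is
near-instant at the default ``nu``) and carry no death transition;
adult mortality acts on males and mated females.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import spn
from .errors import ConfigurationError, ParameterError
from .genetics import FEMALE, MALE, InheritanceCube, wild_genotype
from .spn import EMERGE, LARVAL, LINEAR, MATING, Place, SimState, SPNModel, build_model


@dataclass(frozen=True)
class LifecycleParams:
    """Lifecycle rates and durations (days, per-day rates).

    Defaults are typical warm-climate Anopheles/Aedes-scale values:
    32 eggs/female/day, egg and pupal stages of ~1 day each with no
    baseline mortality, a 14-day larval stage absorbing all density
    dependence, and an adult expected lifespan of ~8 days (mu=0.123).
    ``K`` is the larval density parameter; leave None and solve it from
    a target adult population with :func:`solve_carrying_capacity`.
    """

    beta: float = 32.0
    mu_E: float = 0.0
    mu_L: float = 0.1
    mu_P: float = 0.0
    mu_M: float = 0.123
    mu_F: float = 0.123
    t_E: float = 1.0
    t_L: float = 14.0
    t_P: float = 1.0
    n_E: int = 2
    n_L: int = 2
    n_P: int = 2
    K: float | None = None
    nu: float = 1.0
    phi: float = 0.5

    def __post_init__(self):
        for name in ("beta", "t_E", "t_L", "t_P", "nu"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("mu_E", "mu_L", "mu_P", "mu_M", "mu_F"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.mu_M <= 0 or self.mu_F <= 0:
            raise ConfigurationError("adult mortality rates must be positive")
        for name in ("n_E", "n_L", "n_P"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ConfigurationError(f"{name} must be an integer >= 1")
        if not 0.0 <= self.phi <= 1.0:
            raise ConfigurationError("phi must lie in [0, 1]")
        if self.K is not None and self.K <= 0:
            raise ConfigurationError("K must be positive")


def _stage_rates(lp: LifecycleParams):
    return lp.n_E / lp.t_E, lp.n_L / lp.t_L, lp.n_P / lp.t_P


def build_lifecycle_spn(
    lp: LifecycleParams, cube: InheritanceCube, cube_on: InheritanceCube
) -> SPNModel:
    """Build the lifecycle SPN driven by a molecule-off and a molecule-on cube.

    The two cubes must share genotype ordering; oviposition transitions
    carry one rate constant per molecule state so the active cube
    switches instantaneously at spray-window boundaries.
    """
    if (
        cube.female_genotypes != cube_on.female_genotypes
        or cube.male_genotypes != cube_on.male_genotypes
        or cube.offspring_genotypes != cube_on.offspring_genotypes
    ):
        raise ConfigurationError("molecule-off and molecule-on cubes must share alphabets")
    if lp.K is None:
        raise ConfigurationError(
            "LifecycleParams.K is unset; call solve_carrying_capacity first"
        )
    if not np.array_equal(cube.viability, cube_on.viability):
        raise ConfigurationError("cubes disagree on offspring viability")

    r_E, r_L, r_P = _stage_rates(lp)

    # Recruitable (viable) offspring classes define the aquatic places.
    recruit = [
        (o, lab, cube.offspring_sex[o])
        for o, lab in enumerate(cube.offspring_genotypes)
        if cube.viability[o] > 0
    ]

    places: list[Place] = []

    def add_place(p: Place) -> int:
        places.append(p)
        return len(places) - 1

    aqua: dict[str, dict[str, list[int]]] = {}
    for _, lab, sex in recruit:
        aqua[lab] = {
            "E": [
                add_place(Place(f"E{i + 1}_{lab}", "E", i + 1, lab, sex=None))
                for i in range(lp.n_E)
            ],
            "L": [
                add_place(Place(f"L{i + 1}_{lab}", "L", i + 1, lab, sex=None))
                for i in range(lp.n_L)
            ],
            "P": [
                add_place(Place(f"P{i + 1}_{lab}", "P", i + 1, lab, sex=None))
                for i in range(lp.n_P)
            ],
        }
    u_place = {
        lab: add_place(Place(f"U_{lab}", "U", genotype=lab, sex=FEMALE))
        for lab in cube.female_genotypes
    }
    m_place = {
        lab: add_place(Place(f"M_{lab}", "M", genotype=lab, sex=MALE))
        for lab in cube.male_genotypes
    }
    f_place = {
        (f, m): add_place(Place(f"F_{f}_{m}", "F", genotype=f, mate=m, sex=FEMALE))
        for f in cube.female_genotypes
        for m in cube.male_genotypes
    }

    transitions: list[dict] = []

    # Aquatic advances, deaths and emergence, per recruitable genotype.
    for _, lab, sex in recruit:
        chain = aqua[lab]
        seq = [("E", r_E, lp.mu_E), ("L", r_L, lp.mu_L), ("P", r_P, lp.mu_P)]
        for s, (stage, rate, mu) in enumerate(seq):
            subs = chain[stage]
            for i, pl in enumerate(subs):
                last_sub = i == len(subs) - 1
                last_stage = stage == "P" and last_sub
                if not last_stage:
                    nxt = subs[i + 1] if not last_sub else chain[seq[s + 1][0]][0]
                    transitions.append(
                        {
                            "name": f"adv_{places[pl].name}",
                            "kind": LINEAR,
                            "first": pl,
                            "coef": rate,
                            "net": [(pl, -1), (nxt, +1)],
                        }
                    )
                death_kind = LARVAL if stage == "L" else LINEAR
                transitions.append(
                    {
                        "name": f"death_{places[pl].name}",
                        "kind": death_kind,
                        "first": pl,
                        "coef": mu,
                        "net": [(pl, -1)],
                    }
                )
        # Emergence: single transition with a probabilistic sex split for
        # autosomal designs, forced sex where the genotype decides it.
        p_last = chain["P"][-1]
        if sex == "either":
            em_f, em_m, pfem = u_place[lab], m_place[lab], lp.phi
        elif sex == FEMALE:
            em_f, em_m, pfem = u_place[lab], -1, 1.0
        else:
            em_f, em_m, pfem = -1, m_place[lab], 0.0
        transitions.append(
            {
                "name": f"emerge_{lab}",
                "kind": EMERGE,
                "first": p_last,
                "coef": r_P,
                "net": [(p_last, -1)],
                "em_female": em_f,
                "em_male": em_m,
                "em_pfem": pfem,
            }
        )

    # Mating: unmated female picks a mate proportional to male counts.
    for f in cube.female_genotypes:
        for m in cube.male_genotypes:
            transitions.append(
                {
                    "name": f"mate_{f}_x_{m}",
                    "kind": MATING,
                    "first": u_place[f],
                    "second": m_place[m],
                    "coef": lp.nu,
                    "net": [(u_place[f], -1), (f_place[(f, m)], +1)],
                }
            )

    # Oviposition: one transition per (pair, viable offspring genotype),
    # catalytic in the mated female.  Rates carry cube row x viability.
    fi = {lab: i for i, lab in enumerate(cube.female_genotypes)}
    mi = {lab: i for i, lab in enumerate(cube.male_genotypes)}
    for (f, m), pl in f_place.items():
        row_off = cube.tensor[fi[f], mi[m]] * cube.viability
        row_on = cube_on.tensor[fi[f], mi[m]] * cube_on.viability
        for o, lab, _ in recruit:
            w_off, w_on = row_off[o], row_on[o]
            if w_off == 0.0 and w_on == 0.0:
                continue
            transitions.append(
                {
                    "name": f"ovi_{f}_x_{m}_to_{lab}",
                    "kind": LINEAR,
                    "first": pl,
                    "coef_off": lp.beta * w_off,
                    "coef_on": lp.beta * w_on,
                    "net": [(aqua[lab]["E"][0], +1)],
                }
            )

    # Adult deaths: males and mated females.
    for lab, pl in m_place.items():
        transitions.append(
            {"name": f"death_M_{lab}", "kind": LINEAR, "first": pl, "coef": lp.mu_M, "net": [(pl, -1)]}
        )
    for (f, m), pl in f_place.items():
        transitions.append(
            {"name": f"death_F_{f}_{m}", "kind": LINEAR, "first": pl, "coef": lp.mu_F, "net": [(pl, -1)]}
        )

    larval = [pl for chain in aqua.values() for pl in chain["L"]]
    model = build_model(
        places,
        transitions,
        larval_places=sorted(larval),
        male_places=sorted(m_place.values()),
        K=lp.K,
        metadata={
            "lifecycle": lp,
            "recruit_classes": [(lab, sex) for _, lab, sex in recruit],
            "n_places": len(places),
            "n_transitions": len(transitions),
        },
    )
    return model


# ---------------------------------------------------------------------------
# Equilibrium


def _survival(rate: float, mu: float, n: int) -> float:
    return (rate / (rate + mu)) ** n


def _equilibrium_scalars(lp: LifecycleParams, frac_female: float) -> dict:
    """Per-unit-K equilibrium of the stage-structured mean-field model.

    At demographic equilibrium the per-generation replacement condition
    pins the larval per-capita death rate d*; every compartment is then
    linear in K, so carrying capacity solves in closed form.
    """
    r_E, r_L, r_P = _stage_rates(lp)
    s_E = _survival(r_E, lp.mu_E, lp.n_E)
    s_P = _survival(r_P, lp.mu_P, lp.n_P)
    s_L_req = lp.mu_F / (frac_female * lp.beta * s_E * s_P)
    s_L_max = _survival(r_L, lp.mu_L, lp.n_L)
    R0 = frac_female * lp.beta * s_E * s_L_max * s_P / lp.mu_F
    if R0 <= 1.0:
        raise ParameterError(
            f"no positive equilibrium: net reproductive number R0={R0:.4g} <= 1 "
            "(fecundity/survival below adult replacement)"
        )
    d = r_L * (s_L_req ** (-1.0 / lp.n_L) - 1.0)
    # Larval sub-stage chain per unit egg-to-larva inflow.
    ratio = r_L / (r_L + d)
    chain = np.array([ratio**i / (r_L + d) for i in range(lp.n_L)])
    N_L_per_K = d / lp.mu_L - 1.0
    lam_E = N_L_per_K / chain.sum()  # larval inflow per unit K
    lam = lam_E / s_E  # egg-laying rate per unit K
    emerge = lam_E * s_L_req * s_P  # adult emergence rate per unit K
    F = lam / lp.beta
    R_F = frac_female * emerge
    U = R_F / lp.nu
    M = (1.0 - frac_female) * emerge / lp.mu_M
    return {
        "d": d,
        "lam": lam,
        "lam_E": lam_E,
        "emerge": emerge,
        "U": U,
        "F": F,
        "M": M,
        "adults_per_K": U + F + M,
        "s_E": s_E,
        "s_P": s_P,
        "s_L": s_L_req,
        "N_L_per_K": N_L_per_K,
    }


def solve_carrying_capacity(
    lp: LifecycleParams, N_adult_eq: float, frac_female: float | None = None
) -> float:
    """Larval density parameter K holding ``N_adult_eq`` total adults.

    Total adults (unmated + mated females + males) at the mean-field
    equilibrium are exactly linear in K, so this is closed-form.  For
    X-linked designs the emergence sex ratio is genetic (1/2); pass
    ``frac_female`` explicitly if it differs from ``lp.phi``.
    """
    if N_adult_eq <= 0:
        raise ParameterError("target adult population must be positive")
    ff = lp.phi if frac_female is None else frac_female
    eq = _equilibrium_scalars(lp, ff)
    return float(N_adult_eq / eq["adults_per_K"])


def equilibrium_state(
    model: SPNModel, lp: LifecycleParams, cube: InheritanceCube
) -> SimState:
    """Mean-field equilibrium state, all mass on the wild-type genotype.

    Returns real-valued token counts (round with ``np.rint`` before
    stochastic simulation); time 0, molecule off.
    """
    spec = cube.spec
    wf = wild_genotype(spec, FEMALE).label
    wm = wild_genotype(spec, MALE).label
    row = cube.row(wf, wm) * cube.viability
    recruit = model.metadata["recruit_classes"]
    labels = [lab for lab, _ in recruit]
    # Offspring distribution of the wild cross over recruit classes.
    pis = {}
    for o, lab in enumerate(cube.offspring_genotypes):
        if row[o] > 0:
            if lab not in labels:
                raise ConfigurationError(f"wild-cross offspring {lab!r} missing from model")
            pis[lab] = pis.get(lab, 0.0) + row[o]
    # Emergence female fraction implied by the wild cross.
    sex_of = dict(recruit)
    ff = sum(
        pi * (lp.phi if sex_of[lab] == "either" else (1.0 if sex_of[lab] == FEMALE else 0.0))
        for lab, pi in pis.items()
    )
    eq = _equilibrium_scalars(lp, ff)
    K = lp.K if lp.K is not None else model.K
    r_E, r_L, r_P = _stage_rates(lp)

    def chain_values(inflow, rate, mu, n):
        vals = []
        v = inflow
        for _ in range(n):
            v_stage = v / (rate + mu)
            vals.append(v_stage)
            v = v_stage * rate
        return vals, v  # sub-stage counts, outflow

    lam = eq["lam"] * K
    x = np.zeros(model.n_places)
    e_vals, e_out = chain_values(lam, r_E, lp.mu_E, lp.n_E)
    l_vals, l_out = chain_values(e_out, r_L, eq["d"], lp.n_L)
    p_vals, _ = chain_values(l_out, r_P, lp.mu_P, lp.n_P)
    for lab, pi in pis.items():
        for i, v in enumerate(e_vals):
            x[model.place_index[f"E{i + 1}_{lab}"]] = pi * v
        for i, v in enumerate(l_vals):
            x[model.place_index[f"L{i + 1}_{lab}"]] = pi * v
        for i, v in enumerate(p_vals):
            x[model.place_index[f"P{i + 1}_{lab}"]] = pi * v
    x[model.place_index[f"U_{wf}"]] = eq["U"] * K
    x[model.place_index[f"F_{wf}_{wm}"]] = eq["F"] * K
    x[model.place_index[f"M_{wm}"]] = eq["M"] * K
    return SimState(x=x, t=0.0, molecule=False)


def total_adults(model: SPNModel, x: np.ndarray):
    """Total adult count (unmated + mated females + males).

    Accepts a state vector or a (time, place) trajectory matrix; sums
    over the trailing place axis.
    """
    idx = [i for i, p in enumerate(model.places) if p.kind in ("U", "M", "F")]
    total = np.asarray(x)[..., idx].sum(axis=-1)
    return float(total) if total.ndim == 0 else total
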