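"""Stochastic Petri net containers.

A model is a fixed set of places (token counts) and transitions.  Every
transition is a competing Poisson process whose hazard is a rate
constant times the token count of its *first input place*, optionally
times a state factor (larval crowding, mate availability).  Because all
hazards carry that multiplicative first-input factor, a transition with
an empty first input place is disabled with hazard exactly zero — which
is what makes first-order sparsity-aware evaluation exact.

Hazard kinds
------------
LINEAR   c * x[first]                       (advances, deaths, oviposition)
LARVAL   c * x[first] * (1 + N_L / K)      (density-dependent larval death)
MATING   c * x[first] * x[second] / M_tot  (mate drawn proportional to males)
EMERGE   c * x[first], with a probabilistic female/male output split

Oviposition transitions carry two rate constants, one per inducer
molecule state, because the active inheritance cube changes during
spray windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

LINEAR = 0
LARVAL = 1
MATING = 2
EMERGE = 3

KIND_NAMES = {LINEAR: "linear", LARVAL: "larval_density", MATING: "mating", EMERGE: "emergence"}


@dataclass(frozen=True)
class Place:
    """One token bucket: a lifecycle stage × genotype combination."""

    name: str
    kind: str  # "E", "L", "P", "U", "M", "F", or "X" for abstract fixtures
    substage: int | None = None
    genotype: str | None = None
    mate: str | None = None  # mated females store the mate's genotype
    sex: str | None = None  # "female" | "male" | None (aquatic, unsexed)


@dataclass
class SimState:
    """Token counts plus simulation clock and global molecule state."""

    x: np.ndarray
    t: float = 0.0
    molecule: bool = False

    def copy(self) -> "SimState":
        return SimState(x=self.x.copy(), t=self.t, molecule=self.molecule)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)


@dataclass
class SPNModel:
    places: list[Place]
    place_index: dict[str, int]
    transition_names: list[str]
    kind: np.ndarray  # (T,) hazard kind codes
    first: np.ndarray  # (T,) first input place per transition
    second: np.ndarray  # (T,) second hazard place (mating), else -1
    coef_off: np.ndarray  # (T,) rate constants, molecule absent
    coef_on: np.ndarray  # (T,) rate constants, molecule present
    S_net: sparse.csr_matrix  # (P, T) net stoichiometry (EMERGE: consumption only)
    net_cols: list[list[tuple[int, int]]]  # per transition [(place, delta)]
    em_idx: np.ndarray  # indices of EMERGE transitions
    em_female: np.ndarray  # female output place per EMERGE transition (-1 if none)
    em_male: np.ndarray  # male output place (-1 if none)
    em_pfem: np.ndarray  # probability an emergence is female
    larval_places: np.ndarray
    male_places: np.ndarray
    K: float = np.inf
    metadata: dict = field(default_factory=dict)

    @property
    def n_places(self) -> int:
        return len(self.places)

    @property
    def n_transitions(self) -> int:
        return len(self.transition_names)

    def summary_dict(self) -> dict:
        """JSON-able audit summary of places, transitions and arcs."""
        transitions = []
        for k in range(self.n_transitions):
            consumed = [(self.places[p].name, -d) for p, d in self.net_cols[k] if d < 0]
            produced = [(self.places[p].name, d) for p, d in self.net_cols[k] if d > 0]
            entry = {
                "name": self.transition_names[k],
                "hazard": KIND_NAMES[int(self.kind[k])],
                "first_input": self.places[int(self.first[k])].name,
                "rate_off": float(self.coef_off[k]),
                "rate_on": float(self.coef_on[k]),
                "consumes": consumed,
                "produces": produced,
            }
            if int(self.kind[k]) == EMERGE:
                pos = int(np.searchsorted(self.em_idx, k))
                outs = {}
                if self.em_female[pos] >= 0:
                    outs["female"] = [self.places[int(self.em_female[pos])].name, float(self.em_pfem[pos])]
                if self.em_male[pos] >= 0:
                    outs["male"] = [self.places[int(self.em_male[pos])].name, float(1 - self.em_pfem[pos])]
                entry["emergence_outputs"] = outs
            transitions.append(entry)
        return {
            "n_places": self.n_places,
            "n_transitions": self.n_transitions,
            "places": [p.name for p in self.places],
            "carrying_capacity": None if np.isinf(self.K) else float(self.K),
            "transitions": transitions,
        }


def build_model(
    places: list[Place],
    transitions: list[dict],
    *,
    larval_places=(),
    male_places=(),
    K: float = np.inf,
    metadata: dict | None = None,
) -> SPNModel:
    """Assemble an :class:`SPNModel` from transition dictionaries.

    Each transition dict carries: ``name``, ``kind``, ``first``,
    ``net`` (list of (place, delta)), optional ``second``, ``coef`` or
    (``coef_off``, ``coef_on``), and for EMERGE transitions
    ``em_female``/``em_male`` places and ``em_pfem``.
    """
    place_index = {p.name: i for i, p in enumerate(places)}
    T = len(transitions)
    kind = np.zeros(T, dtype=np.int64)
    first = np.zeros(T, dtype=np.int64)
    second = np.full(T, -1, dtype=np.int64)
    coef_off = np.zeros(T)
    coef_on = np.zeros(T)
    net_cols: list[list[tuple[int, int]]] = []
    names = []
    rows, cols, vals = [], [], []
    em_rows = []
    for k, tr in enumerate(transitions):
        names.append(tr["name"])
        kind[k] = tr["kind"]
        first[k] = tr["first"]
        second[k] = tr.get("second", -1)
        c_off = tr.get("coef_off", tr.get("coef", 0.0))
        c_on = tr.get("coef_on", c_off)
        coef_off[k] = c_off
        coef_on[k] = c_on
        net = [(int(p), int(d)) for p, d in tr.get("net", []) if d != 0]
        net_cols.append(net)
        for p, d in net:
            rows.append(p)
            cols.append(k)
            vals.append(float(d))
        if tr["kind"] == EMERGE:
            em_rows.append(
                (k, tr.get("em_female", -1), tr.get("em_male", -1), tr.get("em_pfem", 1.0))
            )
    S_net = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(places), T), dtype=float
    )
    if em_rows:
        em_idx = np.array([r[0] for r in em_rows], dtype=np.int64)
        em_female = np.array([r[1] for r in em_rows], dtype=np.int64)
        em_male = np.array([r[2] for r in em_rows], dtype=np.int64)
        em_pfem = np.array([r[3] for r in em_rows], dtype=float)
    else:
        em_idx = np.empty(0, dtype=np.int64)
        em_female = np.empty(0, dtype=np.int64)
        em_male = np.empty(0, dtype=np.int64)
        em_pfem = np.empty(0, dtype=float)
    return SPNModel(
        places=places,
        place_index=place_index,
        transition_names=names,
        kind=kind,
        first=first,
        second=second,
        coef_off=coef_off,
        coef_on=coef_on,
        S_net=S_net,
        net_cols=net_cols,
        em_idx=em_idx,
        em_female=em_female,
        em_male=em_male,
        em_pfem=em_pfem,
        larval_places=np.asarray(larval_places, dtype=np.int64),
        male_places=np.asarray(male_places, dtype=np.int64),
        K=K,
        metadata=metadata or {},
    )
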