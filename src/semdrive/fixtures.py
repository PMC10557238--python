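"""Randomized linear-hazard SPN fixtures.

Small abstract models used to exercise the samplers independently of
the mosquito lifecycle: every transition has a linear hazard in its
first input place, so sparse and dense hazard evaluation must agree
exactly, and the expected number of skipped evaluations follows
directly from which places start empty.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .spn import LINEAR, Place, SimState, SPNModel, build_model


def make_fixture_spn(
    places: int, density: float, seed: int, transfers_per_place: int = 2
) -> tuple[SPNModel, SimState]:
    """Random linear SPN plus an initial marking.

    ``places`` token buckets; each gets one death transition and
    ``transfers_per_place`` random transfer transitions (consume one
    token at the source, produce one at a random other place).  A
    fraction ``density`` of places starts occupied (1..40 tokens).
    Identical seeds yield identical fixtures.
    """
    if places < 1:
        raise ConfigurationError("places must be >= 1")
    if not 0.0 < density <= 1.0:
        raise ConfigurationError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    place_objs = [Place(name=f"X{i}", kind="X") for i in range(places)]
    transitions = []
    for i in range(places):
        transitions.append(
            {
                "name": f"death_X{i}",
                "kind": LINEAR,
                "first": i,
                "coef": float(rng.uniform(0.05, 0.5)),
                "net": [(i, -1)],
            }
        )
    if places > 1:
        for i in range(places):
            for j in range(transfers_per_place):
                dst = int(rng.integers(0, places - 1))
                if dst >= i:
                    dst += 1
                transitions.append(
                    {
                        "name": f"move_X{i}_to_X{dst}_{j}",
                        "kind": LINEAR,
                        "first": i,
                        "coef": float(rng.uniform(0.05, 0.5)),
                        "net": [(i, -1), (dst, +1)],
                    }
                )
    model = build_model(place_objs, transitions)
    n_occupied = max(1, int(round(density * places)))
    occupied = rng.choice(places, size=n_occupied, replace=False)
    x = np.zeros(places)
    x[occupied] = rng.integers(1, 41, size=n_occupied)
    return model, SimState(x=x, t=0.0, molecule=False)
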