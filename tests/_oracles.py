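"""Independent oracles used by the test suite.

The Monte-Carlo gamete sampler re-implements the gametogenesis
branching tree by direct simulation of individual gametes — cleavage,
repair-pathway choice, meiotic segregation and excision are all drawn
as individual Bernoulli events — without touching the package's
analytic distribution code, so it can serve as an independent check.
"""

from __future__ import annotations

import numpy as np

from semdrive.genetics import (
    ACTIVE_DRIVE_ALLELES,
    BROKEN,
    DRIVE,
    EXCISED,
    Flavor,
    RES_FUNCTIONAL,
    SEM_ACTIVE,
    SEM_ELEMENT,
    SEM_RESISTANT,
    WILD,
)


def _transform_allele_mc(allele, partner, dp, spec, p_eff, n, rng):
    """Post-homing identity of one parental allele, per gamete draw."""
    out = np.full(n, allele, dtype="<U1")
    if allele != WILD or partner not in ACTIVE_DRIVE_ALLELES or p_eff == 0.0:
        return out
    cleaved = rng.random(n) < p_eff
    hr = cleaved & (rng.random(n) < dp.q)
    out[hr] = DRIVE
    nhej = cleaved & ~hr
    if spec.flavor is Flavor.COMPLETE:
        inframe = rng.random(n) < dp.rho
        out[nhej & inframe] = RES_FUNCTIONAL
        out[nhej & ~inframe] = BROKEN
    elif spec.flavor is Flavor.REDUCED:
        out[nhej] = RES_FUNCTIONAL
    else:
        out[nhej] = BROKEN
    return out


def mc_gamete_counts(g, dp, sp, spec, molecule_present, n, rng):
    """Sample ``n`` gametes from a parent; returns {gamete tuple: count}."""
    p_eff = 0.0 if (spec.inducible_drive and not molecule_present) else dp.p
    picked = []
    for locus, pair in enumerate(g.loci):
        if locus == spec.DRIVE_LOCUS:
            a1 = _transform_allele_mc(pair[0], pair[1], dp, spec, p_eff, n, rng)
            a2 = _transform_allele_mc(pair[1], pair[0], dp, spec, p_eff, n, rng)
        else:
            a1 = np.full(n, pair[0], dtype="<U1")
            a2 = np.full(n, pair[1], dtype="<U1")
        choose_first = rng.random(n) < 0.5
        picked.append(np.where(choose_first, a1, a2))

    sem_active = not (spec.inducible_sem and not molecule_present)
    if spec.is_trans and SEM_ELEMENT not in g.loci[spec.SEM_LOCUS]:
        sem_active = False
    if sem_active:
        alleles = picked[spec.DRIVE_LOCUS]
        was_g = alleles == DRIVE
        was_h = alleles == SEM_ACTIVE
        # resolution of parental H alleles
        ssa = rng.random(n) < sp.b
        resistant = rng.random(n) < sp.c
        alleles[was_h & ssa & resistant] = EXCISED
        alleles[was_h & ssa & ~resistant] = WILD
        nhej_target = SEM_RESISTANT if spec.sem_resistance else SEM_ACTIVE
        alleles[was_h & ~ssa] = nhej_target
        # activation of G gametes (after resolution: new H must not resolve)
        alleles[was_g & (rng.random(n) < sp.a)] = SEM_ACTIVE

    combined = picked[0]
    for extra in picked[1:]:
        combined = np.char.add(combined, extra)
    labels, counts = np.unique(combined, return_counts=True)
    return {tuple(lab): int(c) for lab, c in zip(labels, counts)}


def harmonic_extinction_mean(n0: int) -> float:
    """Mean absorption time of a linear pure-death chain with unit rate."""
    return sum(1.0 / k for k in range(1, n0 + 1))
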