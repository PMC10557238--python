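"""Genotypes, gamete distributions and inheritance cubes for
self-eliminating CRISPR homing gene drives.

The constructs modelled here couple an autonomous homing drive to a
secondary, small-molecule-inducible endonuclease that excises the
transgene between engineered direct repeats (single-strand annealing,
SSA), leaving behind a cut-resistant wild-type allele.  Allele symbols:

======  ==============================================================
``W``   susceptible wild-type (cleavable by the drive)
``G``   intact drive construct: homing-active, excision-capable
``H``   construct whose excision endonuclease has been activated;
        still homing-active, resolves to V/W/S in the next round of
        gametogenesis while the inducer molecule is present
``V``   excised, cut-resistant wild-type (immune to homing and SEM)
``S``   construct whose excision target site was disrupted by NHEJ;
        homing-active but excision-immune (optional, ``sem_resistance``)
``R``   in-frame functional drive-resistant allele (COMPLETE/REDUCED)
``B``   out-of-frame broken allele.  In the COMPLETE flavor it is an
        ordinary (default-neutral) allele; in the SIMPLIFIED flavor it
        is the lethal bookkeeping token for NHEJ at the drive locus —
        any genotype carrying it has viability zero.
``E``/``w``  presence/absence of the trans-acting excision element at
        its own (Mendelian) locus, trans designs only
``Y``   placeholder for the Y chromosome at X-linked loci in males
======  ==============================================================

Five designs are supported: cis-acting autosomal, cis-acting X-linked,
and three trans-acting arrangements (autosome targeting autosome,
autosome targeting an X-linked drive, X-linked element targeting an
autosomal drive).  Each comes in three flavors differing in how NHEJ at
the drive locus is resolved: COMPLETE (R and B), REDUCED (R only) and
SIMPLIFIED (lethal B, no resistant alleles).
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import sparse

from .errors import ConfigurationError, DomainError

# Allele symbols
WILD = "W"
DRIVE = "G"
SEM_ACTIVE = "H"
EXCISED = "V"
SEM_RESISTANT = "S"
RES_FUNCTIONAL = "R"
BROKEN = "B"
Y_TOKEN = "Y"
SEM_ELEMENT = "E"
SEM_WILD = "w"

#: Alleles that carry an active homing cassette (can cleave a paired W).
ACTIVE_DRIVE_ALLELES = frozenset({DRIVE, SEM_ACTIVE, SEM_RESISTANT})

FEMALE = "female"
MALE = "male"

ROW_MASS_TOL = 1e-10
GAMETE_MASS_TOL = 1e-12


class Design(str, Enum):
    """Chromosomal arrangement of the drive and the excision element."""

    CIS_AUTO = "CIS_AUTO"
    CIS_X = "CIS_X"
    TRANS_AUTO_AUTO = "TRANS_AUTO_AUTO"
    TRANS_AUTO_X = "TRANS_AUTO_X"
    TRANS_X_AUTO = "TRANS_X_AUTO"


class Flavor(str, Enum):
    """Resolution of NHEJ repair at the drive locus."""

    COMPLETE = "COMPLETE"
    REDUCED = "REDUCED"
    SIMPLIFIED = "SIMPLIFIED"


def _coerce_enum(value, enum_cls, field_name):
    try:
        return enum_cls(value)
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise ConfigurationError(
            f"unknown {field_name} {value!r}; expected one of: {valid}"
        ) from None


@dataclass(frozen=True)
class DesignSpec:
    """Which construct arrangement and model flavor to build.

    ``inducible_drive`` gates homing on the small molecule;
    ``inducible_sem`` gates excision on the small molecule.  Both False
    is an always-on construct (allowed; see :attr:`always_on`).
    """

    design: Design
    flavor: Flavor
    sem_resistance: bool = False
    inducible_drive: bool = False
    inducible_sem: bool = True

    def __post_init__(self):
        object.__setattr__(self, "design", _coerce_enum(self.design, Design, "design_id"))
        object.__setattr__(self, "flavor", _coerce_enum(self.flavor, Flavor, "flavor"))

    # -- structure ---------------------------------------------------------
    @property
    def always_on(self) -> bool:
        return not (self.inducible_drive or self.inducible_sem)

    @property
    def is_trans(self) -> bool:
        return self.design in (
            Design.TRANS_AUTO_AUTO,
            Design.TRANS_AUTO_X,
            Design.TRANS_X_AUTO,
        )

    @property
    def n_loci(self) -> int:
        return 2 if self.is_trans else 1

    DRIVE_LOCUS = 0
    SEM_LOCUS = 1

    @property
    def x_locus(self):
        """Index of the X-linked locus, or None for fully autosomal designs."""
        if self.design in (Design.CIS_X, Design.TRANS_AUTO_X):
            return self.DRIVE_LOCUS
        if self.design is Design.TRANS_X_AUTO:
            return self.SEM_LOCUS
        return None

    # -- alphabets ---------------------------------------------------------
    def drive_alleles(self, extended: bool = False) -> tuple[str, ...]:
        """Drive-locus alphabet.

        ``extended`` adds the lethal B token in the SIMPLIFIED flavor
        (needed on a cube's offspring axis; never a viable parent).
        """
        alleles = {WILD, DRIVE, SEM_ACTIVE, EXCISED}
        if self.flavor in (Flavor.REDUCED, Flavor.COMPLETE):
            alleles.add(RES_FUNCTIONAL)
        if self.flavor is Flavor.COMPLETE:
            alleles.add(BROKEN)
        if self.sem_resistance:
            alleles.add(SEM_RESISTANT)
        if extended and self.flavor is Flavor.SIMPLIFIED:
            alleles.add(BROKEN)
        return tuple(sorted(alleles))

    def locus_alphabets(self, extended: bool = False) -> tuple[tuple[str, ...], ...]:
        if self.is_trans:
            return (self.drive_alleles(extended), (SEM_ELEMENT, SEM_WILD))
        return (self.drive_alleles(extended),)


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class DriveParams:
    """Homing parameters.

    p    probability a paired wild-type allele is cleaved during
         gametogenesis in a drive-carrier heterozygote
    q    probability a cleaved allele is repaired by homologous
         recombination (copied into a drive allele)
    rho  in-frame fraction of NHEJ repairs (COMPLETE flavor only);
         defaults to 1/3 — one reading frame in three restores function
    """

    p: float
    q: float
    rho: float = 1.0 / 3.0

    def __post_init__(self):
        for name in ("p", "q", "rho"):
            object.__setattr__(self, name, _check_prob(name, getattr(self, name)))


@dataclass(frozen=True)
class SemParams:
    """Self-elimination parameters.

    a  probability an excision-capable drive allele is cut per
       gametogenesis while the molecule is present
    b  probability a cut construct resolves by single-strand annealing
       (otherwise NHEJ)
    c  probability SSA yields the cut-resistant wild-type V
       (otherwise susceptible W)
    """

    a: float
    b: float
    c: float

    def __post_init__(self):
        for name in ("a", "b", "c"):
            object.__setattr__(self, name, _check_prob(name, getattr(self, name)))


# ---------------------------------------------------------------------------
# Genotypes


@dataclass(frozen=True)
class Genotype:
    """A per-locus allele multiset plus sex.

    Alleles are canonically sorted within each locus on construction,
    so canonicalization is idempotent by construction.  Autosomal loci
    hold two alleles; X-linked loci hold two in females and one allele
    plus a ``Y`` token in males.
    """

    loci: tuple[tuple[str, str], ...]
    sex: str

    def __post_init__(self):
        object.__setattr__(
            self, "loci", tuple(tuple(sorted(locus)) for locus in self.loci)
        )
        if self.sex not in (FEMALE, MALE):
            raise ConfigurationError(f"sex must be 'female' or 'male', got {self.sex!r}")

    @property
    def label(self) -> str:
        return "".join("".join(locus) for locus in self.loci)

    def allele_counts(self, include_y: bool = False) -> Counter:
        counts = Counter(a for locus in self.loci for a in locus)
        if not include_y:
            counts.pop(Y_TOKEN, None)
        return counts


def canon(g: Genotype) -> Genotype:
    """Canonical form of a genotype (idempotent)."""
    return Genotype(g.loci, g.sex)


def enumerate_genotypes(spec: DesignSpec, sex: str, extended: bool = False) -> list[Genotype]:
    """Complete, duplicate-free, canonically ordered genotype list.

    Enumeration order is the lexicographic product of per-locus allele
    pairs (combinations with replacement over the sorted alphabet) and
    is stable across calls.
    """
    if sex not in (FEMALE, MALE):
        raise ConfigurationError(f"sex must be 'female' or 'male', got {sex!r}")
    per_locus = []
    for locus, alphabet in enumerate(spec.locus_alphabets(extended)):
        if spec.x_locus == locus and sex == MALE:
            options = [(a, Y_TOKEN) for a in alphabet]
        else:
            options = list(itertools.combinations_with_replacement(alphabet, 2))
        per_locus.append(options)
    return [Genotype(loci, sex) for loci in itertools.product(*per_locus)]


def wild_genotype(spec: DesignSpec, sex: str) -> Genotype:
    """The all-wild-type genotype for a design."""
    loci = []
    for locus in range(spec.n_loci):
        a = WILD if locus == spec.DRIVE_LOCUS else SEM_WILD
        if spec.x_locus == locus and sex == MALE:
            loci.append((a, Y_TOKEN))
        else:
            loci.append((a, a))
    return Genotype(tuple(loci), sex)


def _check_genotype(g: Genotype, spec: DesignSpec) -> None:
    if len(g.loci) != spec.n_loci:
        raise DomainError(
            f"genotype {g.label!r} has {len(g.loci)} loci; design "
            f"{spec.design.value} expects {spec.n_loci}"
        )
    for locus, alphabet in enumerate(spec.locus_alphabets(extended=False)):
        allowed = set(alphabet)
        if spec.x_locus == locus and g.sex == MALE:
            allowed.add(Y_TOKEN)
        for a in g.loci[locus]:
            if a not in allowed:
                raise DomainError(
                    f"allele {a!r} at locus {locus} of genotype {g.label!r} is not in "
                    f"the {spec.design.value}/{spec.flavor.value} alphabet {sorted(allowed)}"
                )


# ---------------------------------------------------------------------------
# Gamete distributions

#: GameteDist: mapping gamete tuple (one allele per locus) -> probability.


def _nhej_products(dp: DriveParams, flavor: Flavor) -> dict[str, float]:
    """Allele distribution of the NHEJ branch after cleavage (mass 1)."""
    if flavor is Flavor.COMPLETE:
        out = {}
        if dp.rho > 0:
            out[RES_FUNCTIONAL] = dp.rho
        if dp.rho < 1:
            out[BROKEN] = 1.0 - dp.rho
        return out
    if flavor is Flavor.REDUCED:
        return {RES_FUNCTIONAL: 1.0}
    return {BROKEN: 1.0}  # SIMPLIFIED: lethal token


def _homing_allele_dist(
    allele: str, partner: str, dp: DriveParams, spec: DesignSpec, p_eff: float
) -> dict[str, float]:
    """Fate of one drive-locus allele during gametogenesis.

    Only a W allele paired with an active drive allele (G, H or S) is
    cleavable; V, R, S and the lethal token are never cleaved.
    """
    if allele != WILD or partner not in ACTIVE_DRIVE_ALLELES or p_eff == 0.0:
        return {allele: 1.0}
    out = {}
    if p_eff < 1.0:
        out[WILD] = 1.0 - p_eff
    if dp.q > 0:
        out[DRIVE] = out.get(DRIVE, 0.0) + p_eff * dp.q
    nhej = p_eff * (1.0 - dp.q)
    if nhej > 0:
        for a, w in _nhej_products(dp, spec.flavor).items():
            out[a] = out.get(a, 0.0) + nhej * w
    return out


def drive_gamete_dist(
    g: Genotype, dp: DriveParams, spec: DesignSpec, molecule_present: bool = False
) -> dict[tuple[str, ...], float]:
    """Gamete distribution after homing, before any self-excision.

    Each cleavable W allele is independently cleaved with probability p
    (suppressed to 0 when the drive is inducible and the molecule is
    absent) and repaired by HR with probability q, else by NHEJ with
    flavor-specific products.  Meiosis then draws one allele per locus
    uniformly; loci assort independently, so the per-locus marginal is
    the average of the two transformed allele distributions.
    """
    _check_genotype(g, spec)
    p_eff = 0.0 if (spec.inducible_drive and not molecule_present) else dp.p

    locus_dists: list[dict[str, float]] = []
    for locus, pair in enumerate(g.loci):
        if locus == spec.DRIVE_LOCUS:
            a1, a2 = pair
            d1 = _homing_allele_dist(a1, a2, dp, spec, p_eff)
            d2 = _homing_allele_dist(a2, a1, dp, spec, p_eff)
            merged: dict[str, float] = {}
            for d in (d1, d2):
                for a, w in d.items():
                    merged[a] = merged.get(a, 0.0) + 0.5 * w
            locus_dists.append(merged)
        else:
            merged = {}
            for a in pair:
                merged[a] = merged.get(a, 0.0) + 0.5
            locus_dists.append(merged)

    out: dict[tuple[str, ...], float] = {}
    for combo in itertools.product(*(d.items() for d in locus_dists)):
        gamete = tuple(a for a, _ in combo)
        prob = 1.0
        for _, w in combo:
            prob *= w
        if prob > 0.0:
            out[gamete] = out.get(gamete, 0.0) + prob
    return out


def sem_transform(
    d: dict[tuple[str, ...], float],
    g: Genotype,
    sp: SemParams,
    spec: DesignSpec,
    molecule_present: bool = False,
) -> dict[tuple[str, ...], float]:
    """Apply self-excision to a gamete distribution.

    Two-step state machine: each G allele in the gametes is activated
    to H with probability a; each H allele (necessarily inherited from
    the parent, since activation has not yet produced new ones in this
    pass) resolves to V with probability b*c, W with b*(1-c), and with
    probability 1-b the NHEJ branch yields S (if ``sem_resistance``) or
    leaves the allele as H to be re-resolved next generation.

    The whole transform is the identity when the SEM is inducible and
    the molecule is absent, and — for trans designs — when the parent
    carries no copy of the excision element E.
    """
    _check_genotype(g, spec)
    if spec.inducible_sem and not molecule_present:
        return dict(d)
    if spec.is_trans and SEM_ELEMENT not in g.loci[spec.SEM_LOCUS]:
        return dict(d)

    a, b, c = sp.a, sp.b, sp.c
    table: dict[str, dict[str, float]] = {}
    activation = {}
    if a < 1.0:
        activation[DRIVE] = 1.0 - a
    if a > 0.0:
        activation[SEM_ACTIVE] = activation.get(SEM_ACTIVE, 0.0) + a
    table[DRIVE] = activation

    nhej_target = SEM_RESISTANT if spec.sem_resistance else SEM_ACTIVE
    resolution: dict[str, float] = {}
    for allele, w in ((EXCISED, b * c), (WILD, b * (1.0 - c)), (nhej_target, 1.0 - b)):
        if w > 0.0:
            resolution[allele] = resolution.get(allele, 0.0) + w
    table[SEM_ACTIVE] = resolution

    out: dict[tuple[str, ...], float] = {}
    drive_locus = spec.DRIVE_LOCUS
    for gamete, prob in d.items():
        allele = gamete[drive_locus]
        dist = table.get(allele)
        if dist is None:
            out[gamete] = out.get(gamete, 0.0) + prob
            continue
        for new_allele, w in dist.items():
            new_gamete = gamete[:drive_locus] + (new_allele,) + gamete[drive_locus + 1 :]
            out[new_gamete] = out.get(new_gamete, 0.0) + prob * w
    return out


def gamete_distribution(
    g: Genotype,
    dp: DriveParams,
    sp: SemParams,
    spec: DesignSpec,
    molecule_present: bool = False,
) -> dict[tuple[str, ...], float]:
    """Full gamete distribution: homing, then self-excision."""
    return sem_transform(
        drive_gamete_dist(g, dp, spec, molecule_present), g, sp, spec, molecule_present
    )


# ---------------------------------------------------------------------------
# Inheritance cubes


@lru_cache(maxsize=None)
def _gamete_space(spec: DesignSpec) -> tuple[tuple[str, ...], ...]:
    """All gamete tuples realizable under a design (extended alphabet)."""
    per_locus = []
    for locus, alphabet in enumerate(spec.locus_alphabets(extended=True)):
        opts = list(alphabet)
        if spec.x_locus == locus:
            opts.append(Y_TOKEN)
        per_locus.append(opts)
    return tuple(itertools.product(*per_locus))


@lru_cache(maxsize=None)
def _offspring_axis(spec: DesignSpec):
    """Offspring genotype labels, sexes, and lethal viability mask."""
    if spec.x_locus is None:
        genos = enumerate_genotypes(spec, FEMALE, extended=True)
        labels = [g.label for g in genos]
        sexes = ["either"] * len(genos)
    else:
        females = enumerate_genotypes(spec, FEMALE, extended=True)
        males = enumerate_genotypes(spec, MALE, extended=True)
        genos = females + males
        labels = [g.label for g in genos]
        sexes = [FEMALE] * len(females) + [MALE] * len(males)
    if spec.flavor is Flavor.SIMPLIFIED:
        viability = np.array([0.0 if BROKEN in lab else 1.0 for lab in labels])
    else:
        viability = np.ones(len(labels))
    return tuple(labels), tuple(sexes), viability


@lru_cache(maxsize=None)
def _pair_to_offspring(spec: DesignSpec):
    """Sparse one-hot map from (maternal gamete, paternal gamete) pairs to
    offspring genotype indices.  Pairs that cannot occur (maternal Y) map
    to a trailing sink bin that must receive zero mass."""
    gametes = _gamete_space(spec)
    labels, _, _ = _offspring_axis(spec)
    index = {lab: i for i, lab in enumerate(labels)}
    n_gam = len(gametes)
    n_off = len(labels)
    flat = np.empty(n_gam * n_gam, dtype=np.int64)
    for i, gi in enumerate(gametes):
        maternal_invalid = Y_TOKEN in gi
        for j, gj in enumerate(gametes):
            if maternal_invalid:
                flat[i * n_gam + j] = n_off
                continue
            label = "".join("".join(sorted((gi[l], gj[l]))) for l in range(len(gi)))
            flat[i * n_gam + j] = index.get(label, n_off)
    mat = sparse.csr_matrix(
        (np.ones(n_gam * n_gam), (np.arange(n_gam * n_gam), flat)),
        shape=(n_gam * n_gam, n_off + 1),
    )
    return mat


@dataclass
class InheritanceCube:
    """Offspring-genotype probability tensor indexed (female, male, offspring).

    ``offspring_sex`` is ``'female'``/``'male'`` where the sex-linked
    locus forces it and ``'either'`` for fully autosomal designs (the
    lifecycle assigns sex at adult emergence in that case).
    """

    spec: DesignSpec | None
    drive_params: DriveParams | None
    sem_params: SemParams | None
    molecule_present: bool
    female_genotypes: list[str]
    male_genotypes: list[str]
    offspring_genotypes: list[str]
    tensor: np.ndarray
    viability: np.ndarray
    offspring_sex: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def female_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.female_genotypes)}

    @property
    def male_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.male_genotypes)}

    @property
    def offspring_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.offspring_genotypes)}

    def row(self, female_label: str, male_label: str) -> np.ndarray:
        return self.tensor[self.female_index[female_label], self.male_index[male_label]]

    @property
    def allele_alphabet(self) -> tuple[str, ...]:
        alleles = sorted({a for lab in self.offspring_genotypes for a in lab} - {Y_TOKEN})
        return tuple(alleles)


def _cube_from_gametes(spec, female_dists, male_dists, dp, sp, molecule_present, metadata):
    gametes = _gamete_space(spec)
    gamete_index = {g: i for i, g in enumerate(gametes)}
    labels, sexes, viability = _offspring_axis(spec)
    pair_map = _pair_to_offspring(spec)
    n_gam = len(gametes)

    def to_matrix(dists):
        mat = np.zeros((len(dists), n_gam))
        for r, d in enumerate(dists):
            for gamete, prob in d.items():
                mat[r, gamete_index[gamete]] = prob
        return mat

    gf = to_matrix(female_dists)
    gm = to_matrix(male_dists)
    outer = np.einsum("fi,mj->fmij", gf, gm).reshape(len(gf) * len(gm), n_gam * n_gam)
    tensor_flat = pair_map.T.dot(outer.T).T
    sink = tensor_flat[:, -1]
    if sink.max(initial=0.0) > GAMETE_MASS_TOL:
        raise DomainError("gamete pair produced an unmapped offspring genotype")
    tensor = np.ascontiguousarray(
        tensor_flat[:, :-1].reshape(len(gf), len(gm), len(labels))
    )
    return InheritanceCube(
        spec=spec,
        drive_params=dp,
        sem_params=sp,
        molecule_present=molecule_present,
        female_genotypes=[g.label for g in metadata["females"]],
        male_genotypes=[g.label for g in metadata["males"]],
        offspring_genotypes=list(labels),
        tensor=tensor,
        viability=viability.copy(),
        offspring_sex=list(sexes),
        metadata={k: v for k, v in metadata.items() if k not in ("females", "males")},
    )


def build_cube(
    spec: DesignSpec,
    dp: DriveParams,
    sp: SemParams,
    molecule_present: bool = False,
) -> InheritanceCube:
    """Construct the full inheritance cube for a design.

    Offspring distributions are the outer product of the parents' final
    gamete distributions (homing then self-excision), marginalized onto
    canonical offspring genotypes.  Every row sums to 1 — lethal NHEJ
    products in the SIMPLIFIED flavor keep their mass but carry
    viability 0 (zygote-level death).
    """
    females = enumerate_genotypes(spec, FEMALE)
    males = enumerate_genotypes(spec, MALE)
    fdists = [gamete_distribution(g, dp, sp, spec, molecule_present) for g in females]
    mdists = [gamete_distribution(g, dp, sp, spec, molecule_present) for g in males]
    return _cube_from_gametes(
        spec,
        fdists,
        mdists,
        dp,
        sp,
        molecule_present,
        {"females": females, "males": males, "kind": "sem_drive"},
    )


def mendelian_cube(spec: DesignSpec) -> InheritanceCube:
    """Pure Mendelian cube on the same alphabet (meiosis only).

    Built without touching the homing or excision code paths; serves as
    the inert-construct reference.
    """

    def meiosis_only(g: Genotype) -> dict[tuple[str, ...], float]:
        locus_dists = []
        for pair in g.loci:
            merged: dict[str, float] = {}
            for a in pair:
                merged[a] = merged.get(a, 0.0) + 0.5
            locus_dists.append(merged)
        out: dict[tuple[str, ...], float] = {}
        for combo in itertools.product(*(d.items() for d in locus_dists)):
            gamete = tuple(a for a, _ in combo)
            prob = 1.0
            for _, w in combo:
                prob *= w
            out[gamete] = out.get(gamete, 0.0) + prob
        return out

    females = enumerate_genotypes(spec, FEMALE)
    males = enumerate_genotypes(spec, MALE)
    return _cube_from_gametes(
        spec,
        [meiosis_only(g) for g in females],
        [meiosis_only(g) for g in males],
        None,
        None,
        False,
        {"females": females, "males": males, "kind": "mendelian"},
    )


# ---------------------------------------------------------------------------
# Validation and bookkeeping


@dataclass
class CubeValidation:
    passed: bool
    max_row_deviation: float
    failing_rows: list[tuple[str, str, float]]
    n_negative_entries: int
    n_out_of_range_viability: int
    sex_violations: list[str]

    def __bool__(self) -> bool:
        return self.passed


def validate_cube(c: InheritanceCube, tol: float = ROW_MASS_TOL) -> CubeValidation:
    """Check row mass conservation, entry ranges and sex consistency."""
    row_sums = c.tensor.sum(axis=2)
    dev = np.abs(row_sums - 1.0)
    failing = [
        (c.female_genotypes[i], c.male_genotypes[j], float(dev[i, j]))
        for i, j in zip(*np.nonzero(dev > tol))
    ]
    n_negative = int(np.sum((c.tensor < 0) | (c.tensor > 1)))
    n_bad_viab = int(np.sum((c.viability < 0) | (c.viability > 1)))
    sex_violations = []
    for lab, sex in zip(c.offspring_genotypes, c.offspring_sex):
        has_y = Y_TOKEN in lab
        if has_y and sex != MALE:
            sex_violations.append(f"{lab}: carries Y but sex={sex}")
        if not has_y and sex == MALE:
            sex_violations.append(f"{lab}: sex=male without a Y token")
    passed = not failing and n_negative == 0 and n_bad_viab == 0 and not sex_violations
    return CubeValidation(
        passed=passed,
        max_row_deviation=float(dev.max()) if dev.size else 0.0,
        failing_rows=failing,
        n_negative_entries=n_negative,
        n_out_of_range_viability=n_bad_viab,
        sex_violations=sex_violations,
    )


def allele_counts_from_label(label: str, include_y: bool = False) -> dict[str, int]:
    counts = Counter(label)
    if not include_y:
        counts.pop(Y_TOKEN, None)
    return dict(counts)


def allele_count_map(c: InheritanceCube, include_y: bool = False) -> dict[str, dict[str, int]]:
    """Integer allele counts per offspring genotype (Y tokens excluded)."""
    return {lab: allele_counts_from_label(lab, include_y) for lab in c.offspring_genotypes}


# ---------------------------------------------------------------------------
# Plain-text export / import


def write_cube(c: InheritanceCube, directory) -> Path:
    """Export a cube as one TSV per female genotype plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "design": None
        if c.spec is None
        else {
            "design_id": c.spec.design.value,
            "flavor": c.spec.flavor.value,
            "sem_resistance": c.spec.sem_resistance,
            "inducible_drive": c.spec.inducible_drive,
            "inducible_sem": c.spec.inducible_sem,
        },
        "drive_params": None
        if c.drive_params is None
        else {"p": c.drive_params.p, "q": c.drive_params.q, "rho": c.drive_params.rho},
        "sem_params": None
        if c.sem_params is None
        else {"a": c.sem_params.a, "b": c.sem_params.b, "c": c.sem_params.c},
        "molecule_present": c.molecule_present,
        "female_genotypes": c.female_genotypes,
        "male_genotypes": c.male_genotypes,
        "offspring_genotypes": c.offspring_genotypes,
        "offspring_sex": c.offspring_sex,
        "viability": [float(v) for v in c.viability],
        "allele_alphabet": list(c.allele_alphabet),
        "metadata": c.metadata,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    for i, flab in enumerate(c.female_genotypes):
        lines = ["male\t" + "\t".join(c.offspring_genotypes)]
        for j, mlab in enumerate(c.male_genotypes):
            probs = "\t".join(f"{v:.17g}" for v in c.tensor[i, j])
            lines.append(f"{mlab}\t{probs}")
        (directory / f"cube_{flab}.tsv").write_text("\n".join(lines) + "\n")
    return directory


def read_cube(directory) -> InheritanceCube:
    """Load a cube written by :func:`write_cube`."""
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    spec = None
    if meta["design"] is not None:
        d = meta["design"]
        spec = DesignSpec(
            design=d["design_id"],
            flavor=d["flavor"],
            sem_resistance=d["sem_resistance"],
            inducible_drive=d["inducible_drive"],
            inducible_sem=d["inducible_sem"],
        )
    dp = None if meta["drive_params"] is None else DriveParams(**meta["drive_params"])
    sp = None if meta["sem_params"] is None else SemParams(**meta["sem_params"])
    n_f = len(meta["female_genotypes"])
    n_m = len(meta["male_genotypes"])
    n_o = len(meta["offspring_genotypes"])
    tensor = np.zeros((n_f, n_m, n_o))
    for i, flab in enumerate(meta["female_genotypes"]):
        lines = (directory / f"cube_{flab}.tsv").read_text().strip().split("\n")
        header = lines[0].split("\t")[1:]
        if header != meta["offspring_genotypes"]:
            raise ConfigurationError(f"cube_{flab}.tsv column order disagrees with sidecar")
        for line in lines[1:]:
            parts = line.split("\t")
            j = meta["male_genotypes"].index(parts[0])
            tensor[i, j] = [float(x) for x in parts[1:]]
    return InheritanceCube(
        spec=spec,
        drive_params=dp,
        sem_params=sp,
        molecule_present=meta["molecule_present"],
        female_genotypes=meta["female_genotypes"],
        male_genotypes=meta["male_genotypes"],
        offspring_genotypes=meta["offspring_genotypes"],
        tensor=tensor,
        viability=np.asarray(meta["viability"], dtype=float),
        offspring_sex=meta["offspring_sex"],
        metadata=meta.get("metadata", {}),
    )
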