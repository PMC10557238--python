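"""Scenario configuration, presets and the end-to-end runner.

A scenario bundles everything needed to reproduce a run: the construct
design and its probabilities, lifecycle rates, the target equilibrium
adult population, release and spray schedules, and sampler settings.
Scenarios serialize losslessly to a single JSON document.

The canonical preset is an inducible cis-acting autosomal
self-eliminating drive released into a closed population of 2000
adults: cleavage 50%, homologous repair 100%, excision cleavage 50%,
SSA repair 100% with no resistance alleles; four weekly releases of
100 drive-homozygous males starting at day 91, and a sustained
small-molecule window from day 365 to day 547, simulated to day 730.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import analysis, engine, genetics, lifecycle
from .engine import ReleaseEvent, SprayWindow
from .errors import ConfigurationError, ConfigValidationError
from .genetics import Design, DesignSpec, DriveParams, Flavor, SemParams
from .lifecycle import LifecycleParams
from .spn import SimState, SPNModel


@dataclass(frozen=True)
class SamplerSettings:
    kind: str = "tau"
    dt: float = 0.1
    record_dt: float = 1.0
    hazard_mode: str = engine.SPARSE

    def __post_init__(self):
        if self.kind not in ("tau", "direct", "ode"):
            raise ConfigurationError(f"sampler.kind must be tau/direct/ode, got {self.kind!r}")
        if self.dt <= 0 or self.record_dt <= 0:
            raise ConfigurationError("sampler.dt and sampler.record_dt must be positive")
        if self.hazard_mode not in (engine.DENSE, engine.SPARSE, "sparse"):
            raise ConfigurationError(f"unknown hazard mode {self.hazard_mode!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    design: DesignSpec
    drive: DriveParams
    sem: SemParams
    lifecycle: LifecycleParams = field(default_factory=LifecycleParams)
    target_adults: int = 2000
    releases: tuple[ReleaseEvent, ...] = ()
    sprays: tuple[SprayWindow, ...] = ()
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    t_end: float = 730.0
    reps: int = 100
    seed: int = 1

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "design": {
                "design_id": self.design.design.value,
                "flavor": self.design.flavor.value,
                "sem_resistance": self.design.sem_resistance,
                "inducible_drive": self.design.inducible_drive,
                "inducible_sem": self.design.inducible_sem,
            },
            "drive": dataclasses.asdict(self.drive),
            "sem": dataclasses.asdict(self.sem),
            "lifecycle": dataclasses.asdict(self.lifecycle),
            "target_adults": self.target_adults,
            "releases": [dataclasses.asdict(r) for r in self.releases],
            "sprays": [[s.start, s.end] for s in self.sprays],
            "sampler": dataclasses.asdict(self.sampler),
            "t_end": self.t_end,
            "reps": self.reps,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        errors = []

        def build(key, fn):
            try:
                return fn()
            except (ConfigurationError, TypeError, KeyError) as exc:
                errors.append(f"{key}: {exc}")
                return None

        dd = d.get("design", {})
        design = build(
            "design",
            lambda: DesignSpec(
                design=dd.get("design_id"),
                flavor=dd.get("flavor"),
                sem_resistance=bool(dd.get("sem_resistance", False)),
                inducible_drive=bool(dd.get("inducible_drive", False)),
                inducible_sem=bool(dd.get("inducible_sem", True)),
            ),
        )
        drive = build("drive", lambda: DriveParams(**d.get("drive", {})))
        sem = build("sem", lambda: SemParams(**d.get("sem", {})))
        lp = build("lifecycle", lambda: LifecycleParams(**d.get("lifecycle", {})))
        releases = []
        for i, r in enumerate(d.get("releases", [])):
            ev = build(f"releases[{i}]", lambda r=r: ReleaseEvent(**r))
            if ev is not None:
                releases.append(ev)
        sprays = []
        for i, s in enumerate(d.get("sprays", [])):
            sw = build(f"sprays[{i}]", lambda s=s: SprayWindow(start=s[0], end=s[1]))
            if sw is not None:
                sprays.append(sw)
        sampler = build("sampler", lambda: SamplerSettings(**d.get("sampler", {})))
        if errors:
            # collect as much semantic validation as the parsed pieces allow
            if design is not None:
                partial = ScenarioConfig(
                    design=design,
                    drive=drive or DriveParams(p=0.0, q=0.0),
                    sem=sem or SemParams(a=0.0, b=0.0, c=0.0),
                    lifecycle=lp or LifecycleParams(),
                    releases=tuple(releases),
                    sprays=tuple(sprays),
                    sampler=sampler or SamplerSettings(),
                )
                errors.extend(validate_config(partial))
            raise ConfigValidationError(errors)
        cfg = cls(
            design=design,
            drive=drive,
            sem=sem,
            lifecycle=lp,
            target_adults=int(d.get("target_adults", 2000)),
            releases=tuple(releases),
            sprays=tuple(sprays),
            sampler=sampler,
            t_end=float(d.get("t_end", 730.0)),
            reps=int(d.get("reps", 100)),
            seed=int(d.get("seed", 1)),
        )
        problems = validate_config(cfg)
        if problems:
            raise ConfigValidationError(problems)
        return cfg


def validate_config(cfg: ScenarioConfig) -> list[str]:
    """All invariant violations, each tagged with its key path."""
    problems = []
    if cfg.target_adults <= 0:
        problems.append("target_adults: must be positive")
    if cfg.t_end <= 0:
        problems.append("t_end: must be positive")
    if cfg.reps < 1:
        problems.append("reps: must be >= 1")
    male_labels = {g.label for g in genetics.enumerate_genotypes(cfg.design, genetics.MALE)}
    female_labels = {g.label for g in genetics.enumerate_genotypes(cfg.design, genetics.FEMALE)}
    for i, r in enumerate(cfg.releases):
        valid = male_labels if r.sex == "male" else female_labels
        if r.genotype not in valid:
            problems.append(
                f"releases[{i}].genotype: {r.genotype!r} not a valid {r.sex} genotype "
                f"for {cfg.design.design.value}/{cfg.design.flavor.value}"
            )
    ordered = sorted(cfg.sprays, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            problems.append(
                f"sprays: windows [{a.start},{a.end}) and [{b.start},{b.end}) overlap"
            )
    return problems


def save_config(cfg: ScenarioConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
    return path


def load_config(path) -> ScenarioConfig:
    """Parse and validate a scenario JSON; reports all violations at once."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigValidationError([f"JSON parse error: {exc}"]) from exc
    return ScenarioConfig.from_dict(raw)


def preset_sem_release() -> ScenarioConfig:
    """The canonical inducible cis-acting SEM release scenario.

    Cis-acting autosomal construct, simplified flavor (no resistance
    alleles), excision inducible by the small molecule; p=0.5, q=1.0,
    a=0.5, b=1.0, c=1.0; 2000-adult equilibrium; 4 weekly releases of
    100 drive-homozygous (GG) males at days 91/98/105/112; molecule
    window [365, 547); horizon 730 days; tau-leaping, 100 repetitions.
    """
    return ScenarioConfig(
        design=DesignSpec(
            design=Design.CIS_AUTO,
            flavor=Flavor.SIMPLIFIED,
            sem_resistance=False,
            inducible_drive=False,
            inducible_sem=True,
        ),
        drive=DriveParams(p=0.5, q=1.0),
        sem=SemParams(a=0.5, b=1.0, c=1.0),
        lifecycle=LifecycleParams(),
        target_adults=2000,
        releases=tuple(
            ReleaseEvent(time=float(day), sex="male", genotype="GG", count=100)
            for day in (91, 98, 105, 112)
        ),
        sprays=(SprayWindow(start=365.0, end=547.0),),
        sampler=SamplerSettings(kind="tau", dt=0.1, record_dt=1.0),
        t_end=730.0,
        reps=100,
        seed=1,
    )


# ---------------------------------------------------------------------------
# End-to-end runner


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    cube_off: genetics.InheritanceCube
    cube_on: genetics.InheritanceCube
    model: SPNModel
    initial_state: SimState
    K: float
    trajectories: list[engine.Trajectory]


def build_scenario(cfg: ScenarioConfig):
    """Cubes, lifecycle model and equilibrium initial state for a scenario."""
    problems = validate_config(cfg)
    if problems:
        raise ConfigValidationError(problems)
    cube_off = genetics.build_cube(cfg.design, cfg.drive, cfg.sem, molecule_present=False)
    cube_on = genetics.build_cube(cfg.design, cfg.drive, cfg.sem, molecule_present=True)
    frac_female = 0.5 if cfg.design.x_locus is not None else None
    K = lifecycle.solve_carrying_capacity(cfg.lifecycle, cfg.target_adults, frac_female)
    lp = dataclasses.replace(cfg.lifecycle, K=K)
    model = lifecycle.build_lifecycle_spn(lp, cube_off, cube_on)
    state0 = lifecycle.equilibrium_state(model, lp, cube_off)
    return cube_off, cube_on, model, state0, K


def run_scenario(
    cfg: ScenarioConfig, reps: int | None = None, seed: int | None = None
) -> ScenarioResult:
    """Build a scenario and run its stochastic (or ode) ensemble."""
    cube_off, cube_on, model, state0, K = build_scenario(cfg)
    reps = cfg.reps if reps is None else reps
    seed = cfg.seed if seed is None else seed
    common = dict(
        sampler=cfg.sampler.kind,
        t_end=cfg.t_end,
        record_dt=cfg.sampler.record_dt,
        releases=cfg.releases,
        sprays=cfg.sprays,
        dt=cfg.sampler.dt,
        hazard_mode=cfg.sampler.hazard_mode,
    )
    if cfg.sampler.kind == "ode":
        trajs = [engine.simulate(model, state0, seed=seed, **common)]
    else:
        trajs = engine.simulate_ensemble(model, state0, reps=reps, seed=seed, **common)
    return ScenarioResult(
        config=cfg,
        cube_off=cube_off,
        cube_on=cube_on,
        model=model,
        initial_state=state0,
        K=K,
        trajectories=trajs,
    )


def summarize_scenario(
    result: ScenarioResult, spec: analysis.SummarySpec
) -> "analysis.pd.DataFrame":
    """Ensemble summary table of a finished scenario run."""
    count_map = genetics.allele_count_map(result.cube_off)
    frames = [analysis.allele_series(t, count_map, spec) for t in result.trajectories]
    return analysis.summarize_ensemble(frames, spec)
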