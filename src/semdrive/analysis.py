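"""Allele/genotype time series and ensemble summaries.

Converts genotype-resolved trajectories into the quantities a field
survey of adults would report: allele counts or proportions over time,
optionally sex-specific, summarized across an ensemble of repetitions
with elemental statistics (max, min, mean, median and the central 95%
empirical quantile band) in a long-format, plotting-friendly table
with columns ``time,sex,feature,stat,value``.

By default only living adults are counted, each contributing the
allele content of its own somatic genotype; the mate genotype stored
in a mated female and all aquatic stages are excluded (both
toggleable).  Y placeholder tokens are never counted as alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Trajectory
from .errors import AlignmentError, ConfigurationError
from .genetics import allele_counts_from_label

STATISTICS = ("max", "min", "mean", "median", "q2.5", "q97.5")

_STAT_FUNCS = {
    "max": lambda a: a.max(axis=0),
    "min": lambda a: a.min(axis=0),
    "mean": lambda a: a.mean(axis=0),
    "median": lambda a: np.median(a, axis=0),
    "q2.5": lambda a: np.quantile(a, 0.025, axis=0, method="linear"),
    "q97.5": lambda a: np.quantile(a, 0.975, axis=0, method="linear"),
}


@dataclass(frozen=True)
class SummarySpec:
    """What to extract and how to aggregate it.

    ``features`` may mix allele symbols and genotype labels; allele
    features are normalized by total counted alleles, genotype features
    by total counted individuals.
    """

    features: tuple[str, ...]
    sex: str = "both"
    statistics: tuple[str, ...] = STATISTICS
    normalization: str = "proportions"

    def __post_init__(self):
        if not self.features:
            raise ConfigurationError("features must be nonempty")
        if self.sex not in ("female", "male", "both"):
            raise ConfigurationError(f"sex filter must be female/male/both, got {self.sex!r}")
        bad = [s for s in self.statistics if s not in STATISTICS]
        if bad:
            raise ConfigurationError(f"unknown statistics {bad}; valid: {list(STATISTICS)}")
        if self.normalization not in ("counts", "proportions"):
            raise ConfigurationError("normalization must be 'counts' or 'proportions'")


def _adult_place_mask(places, sex: str, include_aquatic: bool):
    keep = []
    for p in places:
        if p.kind in ("U", "M", "F"):
            if sex == "both" or p.sex == sex:
                keep.append(True)
            else:
                keep.append(False)
        elif include_aquatic and p.kind in ("E", "L", "P"):
            # aquatic stages are unsexed; included only under 'both'
            keep.append(sex == "both")
        else:
            keep.append(False)
    return np.asarray(keep)


def allele_series(
    traj: Trajectory,
    count_map: dict[str, dict[str, int]],
    spec: SummarySpec,
    include_mates: bool = False,
    include_aquatic: bool = False,
) -> pd.DataFrame:
    """Per-time feature values for one trajectory (wide frame).

    Returns a DataFrame indexed by time with one column per feature.
    Proportions divide allele features by the total number of counted
    alleles (full alphabet, Y excluded) and genotype features by the
    total number of counted individuals, over the selected sex set.
    """
    alphabet = sorted({a for counts in count_map.values() for a in counts})
    genotype_labels = set(count_map)
    for f in spec.features:
        if f not in alphabet and f not in genotype_labels:
            raise ConfigurationError(
                f"unknown feature {f!r}; valid alleles: {alphabet}; "
                f"valid genotypes: {sorted(genotype_labels)}"
            )

    mask = _adult_place_mask(traj.places, spec.sex, include_aquatic)
    idx = np.nonzero(mask)[0]
    places = [traj.places[i] for i in idx]
    counts = traj.counts[:, idx]

    # weight vectors: one entry per selected place
    n_alleles_per_place = np.zeros(len(places))
    allele_w = {a: np.zeros(len(places)) for a in alphabet}
    geno_w = {}
    for j, p in enumerate(places):
        sources = [p.genotype]
        if include_mates and p.kind == "F" and p.mate is not None:
            sources.append(p.mate)
        for g in sources:
            cm = count_map.get(g) or allele_counts_from_label(g)
            for a, c in cm.items():
                allele_w[a][j] += c
                n_alleles_per_place[j] += c
            geno_w.setdefault(g, np.zeros(len(places)))[j] += 1.0

    total_alleles = counts @ n_alleles_per_place
    if include_mates:
        # a mated-female place then contributes two genotypes
        per_place_ind = np.array([2.0 if p.kind == "F" else 1.0 for p in places])
        total_individuals = counts @ per_place_ind
    else:
        total_individuals = counts.sum(axis=1)

    data = {}
    for f in spec.features:
        if f in alphabet:
            vals = counts @ allele_w[f]
            denom = total_alleles
        else:
            vals = counts @ geno_w.get(f, np.zeros(len(places)))
            denom = total_individuals
        if spec.normalization == "proportions":
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(denom > 0, vals / np.where(denom > 0, denom, 1.0), 0.0)
        data[f] = vals
    frame = pd.DataFrame(data, index=pd.Index(traj.times, name="time"))
    frame.attrs["sex"] = spec.sex
    frame.attrs["normalization"] = spec.normalization
    return frame


def summarize_ensemble(series_list: list[pd.DataFrame], spec: SummarySpec) -> pd.DataFrame:
    """Long-format ensemble summary over repetitions.

    One row per (time, sex, feature, statistic).  The 95% band is the
    central empirical interval: 2.5%/97.5% order statistics with
    linear interpolation.
    """
    if not series_list:
        raise AlignmentError("need at least one repetition")
    base = series_list[0]
    for s in series_list[1:]:
        if len(s.index) != len(base.index) or not np.allclose(s.index, base.index):
            raise AlignmentError("ensemble members have mismatched time grids")
        if list(s.columns) != list(base.columns):
            raise AlignmentError("ensemble members have mismatched features")
    sex = base.attrs.get("sex", spec.sex)
    stack = np.stack([s.to_numpy() for s in series_list])  # (reps, times, features)
    records = []
    for stat in spec.statistics:
        vals = _STAT_FUNCS[stat](stack)  # (times, features)
        for j, feature in enumerate(base.columns):
            records.append(
                pd.DataFrame(
                    {
                        "time": base.index.to_numpy(),
                        "sex": sex,
                        "feature": feature,
                        "stat": stat,
                        "value": vals[:, j],
                    }
                )
            )
    out = pd.concat(records, ignore_index=True)
    return out.sort_values(["time", "sex", "feature", "stat"], ignore_index=True)


LONG_COLUMNS = ["time", "sex", "feature", "stat", "value"]


def write_long_table(table: pd.DataFrame, path) -> Path:
    """UTF-8 CSV with header ``time,sex,feature,stat,value``, full precision."""
    path = Path(path)
    if list(table.columns) != LONG_COLUMNS:
        table = table[LONG_COLUMNS]
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, encoding="utf-8")
    return path


def read_long_table(path) -> pd.DataFrame:
    """Companion reader; round-trips :func:`write_long_table` losslessly."""
    return pd.read_csv(
        path,
        dtype={"time": float, "sex": str, "feature": str, "stat": str, "value": float},
    )
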