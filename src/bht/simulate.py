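"""Seedable synthetic three-group cohort generator.

The default configuration is calibrated to the published group summaries:
per-group sizes, truncated-normal ages (lower bound 50 years), Bernoulli
risk-factor prevalences, and clipped-and-rounded normal cognitive item
scores.  Only group means/SDs are published for the items, so the discrete
item distributions are a normal approximation, which shifts totals slightly
relative to the published totals.

An optional ``coupling`` coefficient in [0, 1] introduces a per-subject
latent severity shared across cognitive items (and MMSE) while preserving
each item's marginal mean/SD; the dependence structure of the real cohort is
unpublished, so it is a free parameter rather than a calibrated one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import stats

from .cohort import FACTOR_COLUMNS, CohortRecord
from .instrument import CognitiveRaw, RiskProfile, Sex

__all__ = [
    "GroupParams",
    "SimulationConfig",
    "default_config",
    "simulate_cohort",
    "load_config",
]

#: (low, high) clipping range per cognitive item after rounding.
_ITEM_RANGES = {
    "orientation_time": (0, 4),
    "immediate_recall": (0, 5),
    "fluency_count": (0, 30),
    "delayed_recall": (0, 5),
}
_MMSE_RANGE = (0, 30)


@dataclass(frozen=True)
class GroupParams:
    """Sampling parameters for one diagnostic group."""

    n: int
    age_mean: float
    age_sd: float
    female_frac: float
    factor_prev: dict[str, float]
    item_params: dict[str, tuple[float, float]]  # item -> (mean, sd)
    mmse_mean: Optional[float] = None
    mmse_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group size must be >= 1, got {self.n}")
        if self.age_sd <= 0:
            raise ValueError("age SD must be > 0")
        if not 0 <= self.female_frac <= 1:
            raise ValueError(f"female_frac {self.female_frac} outside [0, 1]")
        unknown = set(self.factor_prev) - set(FACTOR_COLUMNS)
        if unknown:
            raise ValueError(f"unknown factor(s): {sorted(unknown)}")
        for name, p in self.factor_prev.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {name} = {p} outside [0, 1]")
        missing = set(_ITEM_RANGES) - set(self.item_params)
        if missing:
            raise ValueError(f"missing item parameters: {sorted(missing)}")
        for item, (_, sd) in self.item_params.items():
            if sd <= 0:
                raise ValueError(f"{item} SD must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full cohort recipe: one :class:`GroupParams` per diagnostic group plus
    the latent-severity coupling coefficient."""

    groups: dict[str, GroupParams]
    coupling: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if not 0 <= self.coupling <= 1:
            raise ValueError(f"coupling {self.coupling} outside [0, 1]")

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups.values())


def default_config(coupling: float = 0.0, seed: Optional[int] = None) -> SimulationConfig:
    """Configuration calibrated to the published validation cohort
    (166 healthy / 225 MCI / 422 dementia).

    Prevalences are the published per-group counts divided by group size;
    item and age parameters are the published means/SDs.
    """
    from .cohort import reference_summary

    ref = reference_summary()
    groups: dict[str, GroupParams] = {}
    for group, n in ref.group_sizes.items():
        counts = ref.factor_counts[group]
        stats_ = ref.item_stats[group]
        groups[group] = GroupParams(
            n=n,
            age_mean=stats_["age"][0],
            age_sd=stats_["age"][1],
            female_frac=counts["female"] / n,
            factor_prev={f: counts[f] / n for f in FACTOR_COLUMNS},
            item_params={item: stats_[item] for item in _ITEM_RANGES},
            mmse_mean=stats_["mmse"][0],
            mmse_sd=stats_["mmse"][1],
        )
    return SimulationConfig(groups=groups, coupling=coupling, seed=seed)


def _sample_truncated_age(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    a = (50.0 - mean) / sd  # ages below 50 are outside the screened population
    draw = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    return np.maximum(np.rint(draw).astype(int), 50)


def _sample_item(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: int,
    hi: int,
    latent: np.ndarray,
    coupling: float,
) -> np.ndarray:
    noise = rng.standard_normal(latent.shape[0])
    z = coupling * latent + math.sqrt(1.0 - coupling * coupling) * noise
    values = np.rint(mean + sd * z).astype(int)
    return np.clip(values, lo, hi)


def simulate_cohort(
    config: SimulationConfig, seed: Optional[int] = None
) -> list[CohortRecord]:
    """Draw a synthetic cohort; identical (config, seed) gives identical output.

    ``seed`` overrides ``config.seed`` when given.  With ``coupling = 0``
    every field of every record is drawn independently.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    counter = 0
    for group, params in config.groups.items():
        ages = _sample_truncated_age(rng, params.age_mean, params.age_sd, params.n)
        female = rng.random(params.n) < params.female_frac
        flags = {
            f: rng.random(params.n) < params.factor_prev.get(f, 0.0)
            for f in FACTOR_COLUMNS
        }
        latent = rng.standard_normal(params.n)
        items = {
            item: _sample_item(
                rng, mean, sd, *_ITEM_RANGES[item], latent, config.coupling
            )
            for item, (mean, sd) in params.item_params.items()
        }
        if params.mmse_mean is not None:
            mmse = _sample_item(
                rng,
                params.mmse_mean,
                params.mmse_sd or 1.0,
                *_MMSE_RANGE,
                latent,
                config.coupling,
            )
        else:
            mmse = None
        for i in range(params.n):
            counter += 1
            profile = RiskProfile(
                age=int(ages[i]),
                sex=Sex.FEMALE if female[i] else Sex.MALE,
                **{f: bool(flags[f][i]) for f in FACTOR_COLUMNS},
            )
            cognitive = CognitiveRaw(**{k: int(v[i]) for k, v in items.items()})
            records.append(
                CohortRecord(
                    subject_id=f"S{counter:05d}",
                    group=group,
                    profile=profile,
                    cognitive=cognitive,
                    mmse=None if mmse is None else int(mmse[i]),
                )
            )
    return records


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    groups = {
        name: GroupParams(
            n=int(g["n"]),
            age_mean=float(g["age_mean"]),
            age_sd=float(g["age_sd"]),
            female_frac=float(g["female_frac"]),
            factor_prev={k: float(v) for k, v in g.get("factor_prev", {}).items()},
            item_params={
                k: (float(v[0]), float(v[1])) for k, v in g["item_params"].items()
            },
            mmse_mean=g.get("mmse_mean"),
            mmse_sd=g.get("mmse_sd"),
        )
        for name, g in data["groups"].items()
    }
    return SimulationConfig(
        groups=groups,
        coupling=float(data.get("coupling", 0.0)),
        seed=data.get("seed"),
    )
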