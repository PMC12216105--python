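"""Two-population demographic models: isolation with migration (IM) and
secondary contact with varying population sizes (SC).

Both models describe an ancestral population of diploid effective size
``n_ancestral`` that splits ``split_time`` generations ago into two
descendant populations.  Under IM the descendants have constant sizes
``n_current_1`` / ``n_current_2`` and exchange migrants at a constant,
symmetric per-generation rate from the split to the present.  Under SC each
descendant additionally changes size exponentially (per-generation rate
``growth_rate_i``, positive = forward-time growth) and migration is
restricted to the most recent fraction ``migration_duration`` of the
post-split period: the window ``[0, migration_duration * split_time]``
generations before present.

Sizes follow the standard coalescent (backward-time) convention
``N_i(t) = n_current_i * exp(-growth_rate_i * t)`` for ``t`` generations
before present, up to the split.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import msprime
import numpy as np

__all__ = [
    "PriorSpec",
    "IMParams",
    "SCParams",
    "SampleDesign",
    "MigrationWindow",
    "PopulationEpoch",
    "DemographyEvents",
    "default_priors",
    "sample_parameters",
    "to_demography_events",
    "to_msprime_demography",
    "IM_PARAM_NAMES",
    "SC_PARAM_NAMES",
]

IM_PARAM_NAMES = (
    "split_time",
    "migration_rate",
    "n_ancestral",
    "n_current_1",
    "n_current_2",
)
SC_PARAM_NAMES = IM_PARAM_NAMES + (
    "growth_rate_1",
    "growth_rate_2",
    "migration_duration",
)


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior bounds for one demographic parameter."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError(f"prior bounds for {self.name!r} must be finite")
        if self.low > self.high:
            raise ValueError(
                f"prior for {self.name!r}: low={self.low} > high={self.high}"
            )

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


@dataclass(frozen=True)
class IMParams:
    """One parameter draw of the isolation-with-migration model.

    Times are in generations, sizes are diploid effective sizes and the
    migration rate is the proportion of a population replaced by migrants
    per generation.
    """

    split_time: float
    migration_rate: float
    n_ancestral: float
    n_current_1: float
    n_current_2: float

    model = "IM"

    def __post_init__(self) -> None:
        if self.split_time <= 0:
            raise ValueError("split_time must be positive")
        if self.migration_rate < 0:
            raise ValueError("migration_rate must be non-negative")
        for name in ("n_ancestral", "n_current_1", "n_current_2"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 diploid")

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SCParams:
    """One parameter draw of the secondary-contact model.

    Extends :class:`IMParams` with per-generation exponential growth rates
    (possibly negative) for the two descendant populations and the
    migration-duration ratio in [0, 1]: the fraction of the post-split
    period, anchored at the present, during which migration is active.
    """

    split_time: float
    migration_rate: float
    n_ancestral: float
    n_current_1: float
    n_current_2: float
    growth_rate_1: float
    growth_rate_2: float
    migration_duration: float

    model = "SC"

    def __post_init__(self) -> None:
        if self.split_time <= 0:
            raise ValueError("split_time must be positive")
        if self.migration_rate < 0:
            raise ValueError("migration_rate must be non-negative")
        if not 0.0 <= self.migration_duration <= 1.0:
            raise ValueError("migration_duration must be in [0, 1]")
        for name in ("n_ancestral", "n_current_1", "n_current_2"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 diploid")

    def size_at(self, pop: int, t: float) -> float:
        """Backward-time size of population ``pop`` (1 or 2), ``t`` generations ago."""
        n0 = self.n_current_1 if pop == 1 else self.n_current_2
        g = self.growth_rate_1 if pop == 1 else self.growth_rate_2
        return n0 * math.exp(-g * t)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SampleDesign:
    """Sampling and sequence design shared by all simulations of a run."""

    n_diploid_per_pop: int = 10
    n_loci: int = 20
    locus_length: float = 2_000_000
    recombination_rate: float = 1.0e-8
    mutation_rate: float = 1.25e-8

    def __post_init__(self) -> None:
        if self.n_diploid_per_pop < 1:
            raise ValueError("n_diploid_per_pop must be >= 1")
        for name in ("n_loci", "locus_length", "recombination_rate", "mutation_rate"):
            if getattr(self, name) <= 0 and name in ("n_loci", "locus_length"):
                raise ValueError(f"{name} must be positive")
        if self.recombination_rate < 0 or self.mutation_rate < 0:
            raise ValueError("rates must be non-negative")

    @property
    def n_hap_per_pop(self) -> int:
        return 2 * self.n_diploid_per_pop

    @property
    def n_hap_total(self) -> int:
        return 4 * self.n_diploid_per_pop


@dataclass(frozen=True)
class MigrationWindow:
    """Symmetric migration active on ``[start, end]`` generations before present."""

    start: float
    end: float
    rate: float


@dataclass(frozen=True)
class PopulationEpoch:
    """One population's size trajectory from the present back to the split.

    ``size_at(t) = initial_size * exp(-growth_rate * t)`` for t in
    [0, end_time] generations before present.
    """

    initial_size: float
    growth_rate: float
    end_time: float

    def size_at(self, t: float) -> float:
        return self.initial_size * math.exp(-self.growth_rate * t)


@dataclass(frozen=True)
class DemographyEvents:
    """Canonical intermediate representation of a two-population history.

    A coalescent backend consumes this: two descendant populations with
    (possibly exponential) size trajectories on [0, split_time], symmetric
    migration windows, and a merge into the ancestral population of
    constant size at ``split_time``.
    """

    pop1: PopulationEpoch
    pop2: PopulationEpoch
    ancestral_size: float
    split_time: float
    migration_windows: tuple[MigrationWindow, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.split_time <= 0:
            raise ValueError("split_time must be positive")
        if self.ancestral_size < 1:
            raise ValueError("ancestral size must be >= 1 diploid")
        for w in self.migration_windows:
            if not (0 <= w.start <= w.end <= self.split_time + 1e-9):
                raise ValueError("migration window outside [0, split_time]")


def default_priors(model: str) -> dict[str, PriorSpec]:
    """Uniform priors of the study design for ``model`` in {"IM", "SC"}.

    IM: split_time U[1, 5000] generations, sizes U[100, 10000] diploids,
    migration_rate U[0, 0.001] per generation.  SC: split_time U[100, 5000],
    sizes U[1000, 5000], migration_rate U[0, 0.005], growth rates
    U[-0.001, 0.002] per generation, migration_duration U[0, 1].
    """
    if model == "IM":
        specs = [
            PriorSpec("split_time", 1, 5000),
            PriorSpec("migration_rate", 0.0, 0.001),
            PriorSpec("n_ancestral", 100, 10000),
            PriorSpec("n_current_1", 100, 10000),
            PriorSpec("n_current_2", 100, 10000),
        ]
    elif model == "SC":
        specs = [
            PriorSpec("split_time", 100, 5000),
            PriorSpec("migration_rate", 0.0, 0.005),
            PriorSpec("n_ancestral", 1000, 5000),
            PriorSpec("n_current_1", 1000, 5000),
            PriorSpec("n_current_2", 1000, 5000),
            PriorSpec("growth_rate_1", -0.001, 0.002),
            PriorSpec("growth_rate_2", -0.001, 0.002),
            PriorSpec("migration_duration", 0.0, 1.0),
        ]
    else:
        raise ValueError(f"unknown demographic model {model!r}; expected 'IM' or 'SC'")
    return {s.name: s for s in specs}


def _params_class(priors: Mapping[str, PriorSpec]):
    names = set(priors)
    if names == set(IM_PARAM_NAMES):
        return IMParams, IM_PARAM_NAMES
    if names == set(SC_PARAM_NAMES):
        return SCParams, SC_PARAM_NAMES
    raise ValueError(
        "prior map matches neither the IM nor the SC parameter set: "
        f"{sorted(names)}"
    )


def _sc_draw_valid(p: SCParams) -> bool:
    # backward-time decline is monotone, so the minimum over [0, split_time]
    # is attained at an endpoint
    return (
        min(p.size_at(1, 0.0), p.size_at(1, p.split_time)) >= 1.0
        and min(p.size_at(2, 0.0), p.size_at(2, p.split_time)) >= 1.0
    )


def sample_parameters(
    priors: Mapping[str, PriorSpec],
    n: int,
    seed: int,
    max_rejects: int = 1_000_000,
):
    """Draw ``n`` independent parameter sets, each field uniform on its prior.

    SC draws whose exponential trajectory would put either population below
    one diploid anywhere on [0, split_time] are rejected and redrawn.

    Returns
    -------
    params : list of IMParams or SCParams
    n_rejected : int
        Count of invalid SC draws discarded (always 0 for IM).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cls, names = _params_class(priors)
    rng = np.random.default_rng(seed)
    out = []
    n_rejected = 0
    while len(out) < n:
        draw = {name: rng.uniform(priors[name].low, priors[name].high) for name in names}
        p = cls(**draw)
        if cls is SCParams and not _sc_draw_valid(p):
            n_rejected += 1
            if n_rejected > max_rejects:
                raise RuntimeError("SC prior rejection rate implausibly high")
            continue
        out.append(p)
    return out, n_rejected


def to_demography_events(params: IMParams | SCParams) -> DemographyEvents:
    """Translate a parameter draw into the epoch/migration-window form."""
    if isinstance(params, SCParams):
        for pop in (1, 2):
            if min(params.size_at(pop, 0.0), params.size_at(pop, params.split_time)) < 1.0:
                raise ValueError(
                    f"SC draw drives population {pop} below 1 diploid before the "
                    f"split: {params.as_dict()}"
                )
        windows = ()
        m_end = params.migration_duration * params.split_time
        if params.migration_rate > 0 and m_end > 0:
            windows = (MigrationWindow(0.0, m_end, params.migration_rate),)
        return DemographyEvents(
            pop1=PopulationEpoch(params.n_current_1, params.growth_rate_1, params.split_time),
            pop2=PopulationEpoch(params.n_current_2, params.growth_rate_2, params.split_time),
            ancestral_size=params.n_ancestral,
            split_time=params.split_time,
            migration_windows=windows,
        )
    if isinstance(params, IMParams):
        windows = ()
        if params.migration_rate > 0:
            windows = (MigrationWindow(0.0, params.split_time, params.migration_rate),)
        return DemographyEvents(
            pop1=PopulationEpoch(params.n_current_1, 0.0, params.split_time),
            pop2=PopulationEpoch(params.n_current_2, 0.0, params.split_time),
            ancestral_size=params.n_ancestral,
            split_time=params.split_time,
            migration_windows=windows,
        )
    raise TypeError(f"unsupported parameter type {type(params)!r}")


def to_msprime_demography(events: DemographyEvents) -> msprime.Demography:
    """Build the msprime demography for a two-population event list.

    Population labels: ``pop1``, ``pop2`` (sampled), ``anc`` (ancestral).
    Migration is symmetric within each window and zero elsewhere.
    """
    dem = msprime.Demography()
    dem.add_population(
        name="pop1",
        initial_size=events.pop1.initial_size,
        growth_rate=events.pop1.growth_rate,
    )
    dem.add_population(
        name="pop2",
        initial_size=events.pop2.initial_size,
        growth_rate=events.pop2.growth_rate,
    )
    dem.add_population(name="anc", initial_size=events.ancestral_size)

    changes = []  # (time, rate) migration switch points, forward-looking back in time
    for w in events.migration_windows:
        if w.rate <= 0:
            continue
        changes.append((w.start, w.rate))
        changes.append((w.end, 0.0))
    changes.sort(key=lambda c: c[0])

    initial_rate = 0.0
    for t, rate in changes:
        if t == 0.0:
            initial_rate = rate
    if initial_rate > 0:
        dem.set_symmetric_migration_rate(["pop1", "pop2"], initial_rate)
    for t, rate in changes:
        if t == 0.0:
            continue
        if t >= events.split_time:
            continue  # no-op once populations have merged
        dem.add_symmetric_migration_rate_change(
            time=t, populations=["pop1", "pop2"], rate=rate
        )
    dem.add_population_split(
        time=events.split_time, derived=["pop1", "pop2"], ancestral="anc"
    )
    dem.sort_events()
    return dem
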