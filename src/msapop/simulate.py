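"""Forward simulation of MSAP/TMD band data with planted population structure.

The generator emulates a multi-population common-garden survey of CCGG
methylation: several populations of selfing accessions, hundreds of band
sites, population-specific per-site methylation-state distributions, a
fraction of purely genetic (AFLP-like) presence/absence polymorphisms, and
per-lane band-call error.  Latent truth is recorded so every pipeline stage
can be checked against what was planted.

Model
-----
For each methylation site and population, a state distribution over
{UNMETHYLATED, CG_INTERNAL, CHG_HEMI, FULLY_METHYLATED} is drawn from a
Dirichlet centred on a shared base distribution with concentration
``1/divergence`` — ``divergence = 0`` makes all populations identical
(exchangeable null), large values plant strong structure.  Each sample
draws its state independently per site from its population's distribution
and emits lanes by the assay semantics: UNMETHYLATED -> (1,1),
CG_INTERNAL -> (0,1), CHG_HEMI -> (1,0), FULLY_METHYLATED -> (0,0) (full
methylation blocks both enzymes, so it is indistinguishable from fragment
absence).  Genetic sites carry a presence allele at a population frequency
(Balding-Nichols-style Beta resampling of a shared base frequency) copied
to both lanes.  Finally each lane call is flipped independently with
probability ``band_error``.

A second generation can be transmitted: each methylation state is retained
with probability ``inheritance_fidelity``, otherwise redrawn from the
population distribution; genetic alleles are inherited unchanged (selfed
lines).

Default parameters mirror the study design the generator stands in for:
5 populations x 10 accessions x 447 sites, scoreable-methylated fraction
0.65 with CHG:CG odds 62:38, 10% fully methylated mass, 10% genetic sites,
2% band-call error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import BandMatrix, SampleMetadata
from .errors import ConfigError

#: Lane emission per latent state (UNMETH, CG, CHG, FULL).
_H_OF_STATE = np.array([1, 0, 1, 0], dtype=np.int8)
_M_OF_STATE = np.array([1, 1, 0, 0], dtype=np.int8)

_DEFAULT_POPULATIONS = ("Hermon", "Amiad", "Tabgha", "Jaba", "Amasa")

#: Base state distribution: 65% of scoreable (non-FULL) sites methylated,
#: CHG:CG = 62:38 among the methylated, 10% fully-methylated mass.
DEFAULT_STATE_PROBS = (0.315, 0.2223, 0.3627, 0.1)


@dataclass(frozen=True)
class SimulationConfig:
    n_populations: int = 5
    n_per_population: int = 10
    n_sites: int = 447
    state_probs: tuple[float, float, float, float] = DEFAULT_STATE_PROBS
    divergence: float = 0.15
    genetic_site_fraction: float = 0.10
    band_error: float = 0.02
    inheritance_fidelity: float = 0.9
    seed: int = 0
    assay: str = "MSAP"
    te_family: str | None = None
    population_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.n_per_population < 1:
            raise ConfigError("need >=1 population with >=1 sample")
        if self.n_sites < 1:
            raise ConfigError("need >=1 site")
        probs = np.asarray(self.state_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or not np.isclose(
            probs.sum(), 1.0
        ):
            raise ConfigError("state_probs must be 4 non-negative values summing to 1")
        for name in ("divergence",):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("genetic_site_fraction", "band_error",
                     "inheritance_fidelity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.population_names is not None and (
            len(self.population_names) != self.n_populations
        ):
            raise ConfigError("population_names length != n_populations")

    def resolved_population_names(self) -> list[str]:
        if self.population_names is not None:
            return list(self.population_names)
        base = list(_DEFAULT_POPULATIONS)
        if self.n_populations <= len(base):
            return base[: self.n_populations]
        extra = [f"pop{k}" for k in range(len(base) + 1,
                                          self.n_populations + 1)]
        return base + extra


@dataclass
class TruthRecord:
    """Latent state of one generated dataset.

    ``states`` holds, for methylation sites, the latent state code
    (0=UNMETH, 1=CG, 2=CHG, 3=FULL) and, for genetic sites, the presence
    allele (0/1); ``is_genetic`` says which is which.
    """

    config: SimulationConfig
    band_ids: list[str]
    sample_ids: list[str]
    populations: list[str]
    is_genetic: np.ndarray
    states: np.ndarray
    pop_state_probs: np.ndarray
    genetic_freqs: np.ndarray
    generation: int = 1

    def partition(self) -> dict[str, str]:
        """Planted population assignment, sample -> population."""
        return dict(zip(self.sample_ids, self.populations))

    def planted_methylated_fraction(
        self, include_uninformative: bool = False
    ) -> np.ndarray:
        """Per-sample fraction of methylated latent states, with the same
        denominator convention as the scoring module (FULL excluded unless
        ``include_uninformative``)."""
        s = self.states[~self.is_genetic]
        meth = ((s == 1) | (s == 2)).sum(axis=0)
        denom = (s != 3).sum(axis=0) if not include_uninformative \
            else np.full(s.shape[1], s.shape[0])
        return meth / denom


def _emit_bands(
    truth: TruthRecord, band_error: float, rng: np.random.Generator
) -> BandMatrix:
    """Map latent states to H/M lane calls and apply band-call error."""
    states = truth.states
    h = np.where(truth.is_genetic[:, None], states,
                 _H_OF_STATE[np.minimum(states, 3)])
    m = np.where(truth.is_genetic[:, None], states,
                 _M_OF_STATE[np.minimum(states, 3)])
    if band_error > 0:
        h = np.where(rng.random(h.shape) < band_error, 1 - h, h)
        m = np.where(rng.random(m.shape) < band_error, 1 - m, m)
    return BandMatrix(
        band_ids=list(truth.band_ids),
        sample_ids=list(truth.sample_ids),
        h=h.astype(np.int8),
        m=m.astype(np.int8),
        assay=truth.config.assay,
        te_family=truth.config.te_family,
    )


def _draw_states(
    probs: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw categorical states; ``probs`` is (n_sites, 4) -> (n_sites, n)."""
    cum = probs.cumsum(axis=1)
    cum[:, -1] = 1.0
    u = rng.random((probs.shape[0], n_draws))
    return (u[:, :, None] >= cum[:, None, :]).sum(axis=2).astype(np.int8)


def generate(
    config: SimulationConfig,
) -> tuple[BandMatrix, SampleMetadata, TruthRecord]:
    """Generate one first-generation dataset.

    All randomness descends from ``config.seed`` through named substreams
    (population probabilities / states / genetic alleles / band errors), so
    a fixed seed gives byte-identical output.
    """
    ss = np.random.SeedSequence(config.seed)
    probs_rng, states_rng, genetic_rng, error_rng = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    n_sites = config.n_sites
    n_genetic = int(round(config.genetic_site_fraction * n_sites))
    n_meth = n_sites - n_genetic
    is_genetic = np.zeros(n_sites, dtype=bool)
    if n_genetic:
        is_genetic[genetic_rng.choice(n_sites, size=n_genetic,
                                      replace=False)] = True
    pops = config.resolved_population_names()
    sample_ids = [
        f"{pop}_{i + 1:02d}" for pop in pops
        for i in range(config.n_per_population)
    ]
    populations = [pop for pop in pops
                   for _ in range(config.n_per_population)]
    base = np.asarray(config.state_probs, dtype=float)

    if config.divergence > 0:
        pop_probs = probs_rng.dirichlet(
            base / config.divergence, size=(len(pops), n_meth)
        )
    else:
        pop_probs = np.broadcast_to(base, (len(pops), n_meth, 4)).copy()

    base_freq = genetic_rng.uniform(0.2, 0.8, size=n_genetic)
    if config.divergence > 0 and n_genetic:
        genetic_freqs = genetic_rng.beta(
            base_freq / config.divergence,
            (1.0 - base_freq) / config.divergence,
            size=(len(pops), n_genetic),
        )
    else:
        genetic_freqs = np.broadcast_to(
            base_freq, (len(pops), n_genetic)
        ).copy()

    states = np.zeros((n_sites, len(sample_ids)), dtype=np.int8)
    meth_idx = np.flatnonzero(~is_genetic)
    gen_idx = np.flatnonzero(is_genetic)
    for p in range(len(pops)):
        cols = slice(p * config.n_per_population,
                     (p + 1) * config.n_per_population)
        states[meth_idx, cols] = _draw_states(
            pop_probs[p], config.n_per_population, states_rng
        )
        if n_genetic:
            draws = states_rng.random((n_genetic, config.n_per_population))
            states[gen_idx, cols] = (
                draws < genetic_freqs[p][:, None]
            ).astype(np.int8)

    truth = TruthRecord(
        config=config,
        band_ids=[f"site{i + 1:04d}" for i in range(n_sites)],
        sample_ids=sample_ids,
        populations=populations,
        is_genetic=is_genetic,
        states=states,
        pop_state_probs=pop_probs,
        genetic_freqs=genetic_freqs,
        generation=1,
    )
    bands = _emit_bands(truth, config.band_error, error_rng)
    meta = SampleMetadata.from_records(sample_ids, populations, generation=1)
    return bands, meta, truth


def transmit_generation(
    truth: TruthRecord,
    inheritance_fidelity: float | None = None,
    seed: int = 1,
) -> tuple[BandMatrix, SampleMetadata, TruthRecord]:
    """Transmit the planted states one generation forward.

    Each methylation state is kept with probability
    ``inheritance_fidelity`` (default: the generating config's value) and
    otherwise redrawn from its population's site distribution; genetic
    presence alleles pass unchanged.  Bands are re-emitted with the
    config's band-call error under a fresh seeded stream.
    """
    config = truth.config
    fidelity = (config.inheritance_fidelity
                if inheritance_fidelity is None else inheritance_fidelity)
    if not 0.0 <= fidelity <= 1.0:
        raise ConfigError("inheritance_fidelity must be in [0, 1]")
    ss = np.random.SeedSequence(seed)
    keep_rng, redraw_rng, error_rng = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )
    pops = config.resolved_population_names()
    states = truth.states.copy()
    meth_idx = np.flatnonzero(~truth.is_genetic)
    n_meth = len(meth_idx)
    for p, pop in enumerate(pops):
        cols = np.flatnonzero(np.asarray(truth.populations) == pop)
        keep = keep_rng.random((n_meth, len(cols))) < fidelity
        fresh = _draw_states(truth.pop_state_probs[p], len(cols), redraw_rng)
        block = states[np.ix_(meth_idx, cols)]
        states[np.ix_(meth_idx, cols)] = np.where(keep, block, fresh)
    truth2 = replace_generation(truth, states, 2)
    bands = _emit_bands(truth2, config.band_error, error_rng)
    meta = SampleMetadata.from_records(
        truth.sample_ids, truth.populations, generation=2
    )
    return bands, meta, truth2


def replace_generation(
    truth: TruthRecord, states: np.ndarray, generation: int
) -> TruthRecord:
    return TruthRecord(
        config=truth.config,
        band_ids=list(truth.band_ids),
        sample_ids=list(truth.sample_ids),
        populations=list(truth.populations),
        is_genetic=truth.is_genetic.copy(),
        states=states,
        pop_state_probs=truth.pop_state_probs,
        genetic_freqs=truth.genetic_freqs,
        generation=generation,
    )
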