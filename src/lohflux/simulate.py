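"""Forward simulation of fluctuation cultures with class-specific LOH events.

Clonal growth is modelled as synchronous doublings from an inoculum of
``n0`` cells until the population reaches at least ``n_final``.  During each
round of division, every wild-type (URA3-heterozygous) division independently
yields one LOH daughter of class *k* with probability ``mu_k`` (events per
cell division).  A clone founded at generation *g* doubles for the remaining
generations — early events therefore produce "jackpot" cultures, giving the
resistant-count distribution the heavy Luria–Delbrück tail that
method-of-the-median estimation assumes.  Clones are neutral (no death, no
fitness cost) unless a relative-fitness knob is set, and secondary events on
already-mutant lineages are ignored.

Selective plating is modelled as binomial thinning of the final resistant
counts by ``dilution × plating_efficiency``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .markers import (
    HOMOLOG_A,
    HOMOLOG_B,
    Allele,
    ColonyPhenotype,
    ComplexSubclass,
    DiploidGenotype,
    LOHClass,
    MarkerMap,
    apply_event,
    default_marker_map,
    phenotype_of,
    starting_genotype,
)

__all__ = [
    "EventRates",
    "CultureConfig",
    "CultureResult",
    "EventOrigin",
    "POINT_MUTATION",
    "simulate_culture",
    "simulate_assay",
    "simulate_independent_colonies",
]

# 5FOA-resistance point mutation in URA3: phenotypically indistinguishable
# from gene conversion (all flanking markers retained) but URA3-heterozygous
# by PCR because both alleles are still physically present.
POINT_MUTATION = "POINT_MUTATION"

# Relative frequency of complex-event resolutions used by default:
# heterozygous telomeric locus 17/27, half-crossover NAT–TYR1 3/27,
# half-crossover TYR1–URA3 7/27 (the spectrum observed in cohesin mutants).
_DEFAULT_SUBCLASS_PROBS: dict[ComplexSubclass, float] = {
    ComplexSubclass.HET_TELOMERIC: 17 / 27,
    ComplexSubclass.HALF_CO_NAT_TYR1: 3 / 27,
    ComplexSubclass.HALF_CO_TYR1_URA3: 7 / 27,
}

_MAX_TOTAL_RATE = 0.1  # per division; above this the rare-event model breaks


@dataclass(frozen=True)
class EventRates:
    """Per-class LOH event rates, in events per cell division."""

    chromosome_loss: float = 0.0
    gene_conversion: float = 0.0
    segmental: float = 0.0
    complex_event: float = 0.0
    point_mutation: float = 0.0
    complex_subclass_probs: dict[ComplexSubclass, float] = field(
        default_factory=lambda: dict(_DEFAULT_SUBCLASS_PROBS)
    )

    def __post_init__(self) -> None:
        for label, rate in self.as_dict().items():
            if rate < 0:
                raise ValueError(f"rate for {label} must be >= 0, got {rate}")
        if self.complex_subclass_probs:
            total = sum(self.complex_subclass_probs.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise ValueError("complex subclass probabilities must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {
            LOHClass.CHROMOSOME_LOSS.value: self.chromosome_loss,
            LOHClass.GENE_CONVERSION.value: self.gene_conversion,
            LOHClass.SEGMENTAL.value: self.segmental,
            LOHClass.COMPLEX.value: self.complex_event,
            POINT_MUTATION: self.point_mutation,
        }

    @property
    def total(self) -> float:
        return sum(self.as_dict().values())


@dataclass(frozen=True)
class CultureConfig:
    """Growth and plating design of one fluctuation culture."""

    n0: int = 1000
    n_final: int = 1_000_000
    dilution: float = 1.0
    plating_efficiency: float = 1.0
    relative_fitness: float = 1.0  # growth of LOH clones relative to wild type
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (1 <= self.n0 <= self.n_final):
            raise ValueError("need n_final >= n0 >= 1")
        if not (0.0 < self.dilution <= 1.0):
            raise ValueError("dilution must be in (0, 1]")
        if not (0.0 < self.plating_efficiency <= 1.0):
            raise ValueError("plating efficiency must be in (0, 1]")
        if not (0.0 < self.relative_fitness <= 1.0):
            raise ValueError("relative fitness must be in (0, 1]")

    @property
    def generations(self) -> int:
        return max(1, math.ceil(math.log2(self.n_final / self.n0)))


@dataclass(frozen=True)
class EventOrigin:
    """One founding LOH event: class label, generation, number of events."""

    class_label: str
    generation: int
    n_events: int


@dataclass(frozen=True)
class CultureResult:
    """Outcome of a single simulated culture."""

    n0: int
    n_final: int  # realised final population (>= requested)
    generations: int
    resistant_by_class: dict[str, int]  # plated (post-thinning) counts
    resistant_pre_dilution: dict[str, int]
    event_log: tuple[EventOrigin, ...]
    dilution: float = 1.0
    plating_efficiency: float = 1.0

    @property
    def total_resistant(self) -> int:
        return sum(self.resistant_by_class.values())

    @property
    def total_resistant_pre_dilution(self) -> int:
        return sum(self.resistant_pre_dilution.values())

    @property
    def divisions(self) -> int:
        return self.n_final - self.n0


def _check_rates(rates: EventRates) -> None:
    if rates.total >= _MAX_TOTAL_RATE:
        raise ValueError(
            f"total event rate {rates.total:g} per division is too high for the "
            f"rare-event growth model (must be < {_MAX_TOTAL_RATE})"
        )


def simulate_culture(
    rates: EventRates,
    config: CultureConfig,
    rng: Optional[np.random.Generator] = None,
) -> CultureResult:
    """Grow one culture and return per-class resistant counts after plating.

    Deterministic given an explicit ``rng`` or ``config.seed``.
    """
    _check_rates(rates)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    labels = list(rates.as_dict())
    mu = np.array([rates.as_dict()[k] for k in labels])
    generations = config.generations
    mutants = np.zeros(len(labels), dtype=np.int64)
    population = config.n0
    log: list[EventOrigin] = []

    for g in range(1, generations + 1):
        wild_type = population - int(mutants.sum())
        # existing clones double (optionally slower than wild type)
        if config.relative_fitness >= 1.0:
            mutants = mutants * 2
        else:
            mutants = mutants + rng.binomial(mutants, config.relative_fitness)
        new_events = rng.binomial(wild_type, mu) if wild_type > 0 else np.zeros_like(mutants)
        mutants = mutants + new_events
        for idx, n_events in enumerate(new_events):
            if n_events > 0:
                log.append(EventOrigin(labels[idx], g, int(n_events)))
        population *= 2

    pre = {label: int(count) for label, count in zip(labels, mutants)}
    keep = config.dilution * config.plating_efficiency
    if keep >= 1.0:
        plated = dict(pre)
    else:
        plated = {
            label: int(rng.binomial(count, keep)) for label, count in pre.items()
        }
    return CultureResult(
        n0=config.n0,
        n_final=population,
        generations=generations,
        resistant_by_class=plated,
        resistant_pre_dilution=pre,
        event_log=tuple(log),
        dilution=config.dilution,
        plating_efficiency=config.plating_efficiency,
    )


def _spawn_rngs(seed: Optional[int], n: int) -> list[np.random.Generator]:
    """Master-seed splitting rule: SeedSequence(seed).spawn(n), one per culture."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(child) for child in children]


def simulate_assay(
    rates: EventRates,
    config: CultureConfig,
    n_cultures: int,
    seed: Optional[int] = None,
) -> list[CultureResult]:
    """Simulate ``n_cultures`` independent parallel cultures.

    Per-culture streams are spawned from the master seed, so results are
    reproducible and independent of evaluation order.
    """
    if n_cultures < 2:
        raise ValueError("a fluctuation assay needs at least 2 parallel cultures")
    return [
        simulate_culture(rates, config, rng=rng)
        for rng in _spawn_rngs(seed, n_cultures)
    ]


def _point_mutation_genotype(
    genotype: DiploidGenotype, marker_map: MarkerMap
) -> DiploidGenotype:
    """Inactivate the functional URA3 allele in place (allele still PCR-visible)."""
    old = genotype.alleles[HOMOLOG_A]["URA3"]
    new_a = dict(genotype.alleles[HOMOLOG_A])
    new_a["URA3"] = Allele(label=old.label, functional=False)
    return replace(
        genotype,
        alleles={HOMOLOG_A: new_a, HOMOLOG_B: dict(genotype.alleles[HOMOLOG_B])},
    )


_LABEL_TO_EVENT = {
    LOHClass.CHROMOSOME_LOSS.value: LOHClass.CHROMOSOME_LOSS,
    LOHClass.GENE_CONVERSION.value: LOHClass.GENE_CONVERSION,
    LOHClass.SEGMENTAL.value: LOHClass.SEGMENTAL,
    LOHClass.COMPLEX.value: LOHClass.COMPLEX,
}


def simulate_independent_colonies(
    rates: EventRates,
    config: CultureConfig,
    n_colonies: int,
    seed: Optional[int] = None,
    marker_map: Optional[MarkerMap] = None,
    max_retries_per_colony: int = 1000,
    with_zygosity: bool = True,
) -> list[ColonyPhenotype]:
    """Emulate the one-resistant-colony-per-mini-culture sampling design.

    Each colony comes from its own mini-culture: the culture is grown, one
    resistant cell is drawn with probability proportional to the culture's
    per-class resistant counts (so jackpot cultures weight their class, as in
    the real design), and its colony phenotype is computed through the
    genotype model.  Mini-cultures with no resistant cells are redrawn;
    exceeding the retry budget raises with the zero-culture tally.
    """
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    _check_rates(rates)
    if marker_map is None:
        marker_map = default_marker_map()
    g0 = starting_genotype(marker_map)

    phenotypes: list[ColonyPhenotype] = []
    rngs = _spawn_rngs(seed, n_colonies)
    for rng in rngs:
        for _attempt in range(max_retries_per_colony):
            culture = simulate_culture(rates, config, rng=rng)
            counts = culture.resistant_by_class
            total = sum(counts.values())
            if total > 0:
                break
        else:
            raise RuntimeError(
                f"no resistant cells in {max_retries_per_colony} mini-cultures; "
                "event rates are too low for this culture size"
            )
        labels = list(counts)
        probs = np.array([counts[k] for k in labels], dtype=float) / total
        label = labels[rng.choice(len(labels), p=probs)]
        if label == POINT_MUTATION:
            genotype = _point_mutation_genotype(g0, marker_map)
        else:
            event: LOHClass | ComplexSubclass = _LABEL_TO_EVENT[label]
            if event is LOHClass.COMPLEX and rates.complex_subclass_probs:
                subs = list(rates.complex_subclass_probs)
                sub_p = np.array([rates.complex_subclass_probs[s] for s in subs])
                event = subs[rng.choice(len(subs), p=sub_p / sub_p.sum())]
            genotype = apply_event(g0, event, marker_map)
        pheno = phenotype_of(genotype, marker_map)
        if not with_zygosity:
            pheno = replace(
                pheno,
                nat_zygosity=pheno.nat_zygosity.__class__.UNTESTED,
                trp1_zygosity=pheno.trp1_zygosity.__class__.UNTESTED,
                tyr1_alleles=None,
            )
        phenotypes.append(pheno)
    return phenotypes
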