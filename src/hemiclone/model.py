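"""Domain types for co-dominant marker datasets from hybridogenetic systems.

The data model mirrors a microsatellite study design: individuals carry a
diploid genotype (one or two integer allele states per locus, missing
allowed), every allele state can be classified by parental-species
specificity through an :class:`AlleleRegistry`, and individuals belong to
populations of a known system type (mixed hybrid/sexual composition).

Allele states are integers (fragment lengths).  The missing sentinel is
``0``; a cell may be half missing — ``(a, 0)`` — which is how loci that
amplify in only one parental genome are scored in hybrids.  A cell with a
single allele is therefore *not* auto-doubled into a homozygote; doubling a
haploid subgenome is an explicit, separate operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

#: Reserved missing-allele sentinel (never a legal allele state).
MISSING = 0

#: Reserved allele state used when blanks are recoded as null homozygotes.
NULL_ALLELE = -1

GENOMES = ("L", "R")
SPECIFICITIES = ("L", "R", "shared", "nonspecific")
TAXA = ("LL", "RR", "RL", "KK", "unknown")
SEXES = ("f", "m", "juv", "unknown")


class FormatError(ValueError):
    """A file did not conform to the expected dialect."""


class ValidationError(ValueError):
    """Input data violated a model invariant."""


def canonical_cell(a1: int, a2: int) -> tuple[int, int]:
    """Canonical unordered diploid cell: missing slots first, then ascending."""
    pair = sorted((int(a1), int(a2)), key=lambda a: (a != MISSING, a))
    return (pair[0], pair[1])


@dataclass(frozen=True)
class LocusDef:
    """A marker locus and the parental genome(s) it amplifies in."""

    name: str
    amplifies_in: frozenset = frozenset(GENOMES)
    motif_step: int | None = None

    def __post_init__(self):
        amp = frozenset(self.amplifies_in)
        if not amp or not amp <= set(GENOMES):
            raise ValidationError(
                f"locus {self.name!r}: amplifies_in must be a nonempty subset of "
                f"{set(GENOMES)}, got {set(self.amplifies_in)}"
            )
        object.__setattr__(self, "amplifies_in", amp)


class AlleleRegistry:
    """Per-locus mapping of allele states to parental-species specificity.

    Every allele is classifiable as exactly one of ``L``, ``R``, ``shared``,
    ``nonspecific`` or (if absent from the registry) ``unregistered``.
    Conflicting registrations — the same (locus, allele) entered with two
    different specificities — are rejected: an allele seen in both parental
    genomes must be entered once as ``nonspecific`` (or ``shared``), never
    twice.
    """

    def __init__(self, loci: Iterable[LocusDef] = ()):
        self._loci: dict[str, LocusDef] = {}
        self.specificity: dict[tuple[str, int], str] = {}
        for locus in loci:
            self.add_locus(locus)

    # -- construction -------------------------------------------------
    def add_locus(self, locus: LocusDef) -> None:
        if locus.name in self._loci:
            raise ValidationError(f"duplicate locus {locus.name!r}")
        self._loci[locus.name] = locus

    def add_allele(self, locus: str, allele: int, specificity: str) -> None:
        if specificity not in SPECIFICITIES:
            raise ValidationError(f"unknown specificity {specificity!r}")
        if locus not in self._loci:
            raise ValidationError(f"unknown locus {locus!r}")
        if allele == MISSING:
            raise ValidationError("the missing sentinel cannot be registered")
        key = (locus, int(allele))
        existing = self.specificity.get(key)
        if existing is not None and existing != specificity:
            raise ValidationError(
                f"conflicting specificity for allele {allele} at {locus}: "
                f"{existing!r} vs {specificity!r} (an allele amplifying in both "
                f"genomes must be registered once as 'nonspecific')"
            )
        self.specificity[key] = specificity

    # -- queries ------------------------------------------------------
    @property
    def loci(self) -> list[LocusDef]:
        return list(self._loci.values())

    def locus_names(self) -> list[str]:
        return list(self._loci)

    def __contains__(self, name: str) -> bool:
        return name in self._loci

    def locus(self, name: str) -> LocusDef:
        return self._loci[name]

    def classify(self, locus: str, allele: int) -> str:
        """Specificity of an allele, or ``"unregistered"`` if unknown."""
        if allele == NULL_ALLELE:
            return "nonspecific"
        return self.specificity.get((locus, int(allele)), "unregistered")

    def alleles(self, locus: str, genome: str | None = None) -> list[int]:
        """Registered allele states at a locus, optionally restricted to the
        states a given parental genome can carry (its specific alleles plus
        shared/nonspecific ones)."""
        out = []
        for (loc, allele), spec in self.specificity.items():
            if loc != locus:
                continue
            if genome is None or spec == genome or spec in ("shared", "nonspecific"):
                out.append(allele)
        return sorted(out)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AlleleRegistry)
            and self._loci == other._loci
            and self.specificity == other.specificity
        )


@dataclass
class IndividualRecord:
    """One sampled individual: metadata plus its multilocus genotype.

    ``genotype`` maps locus name to a canonical unordered allele pair;
    either slot may carry the missing sentinel.
    """

    id: str
    population: str
    taxon_label: str = "unknown"
    sex: str = "unknown"
    genotype: dict[str, tuple[int, int]] = field(default_factory=dict)
    ploidy: int = 2

    def __post_init__(self):
        if self.taxon_label not in TAXA:
            raise ValidationError(f"{self.id}: unknown taxon {self.taxon_label!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"{self.id}: unknown sex {self.sex!r}")
        if self.ploidy < 1:
            raise ValidationError(f"{self.id}: ploidy must be >= 1")
        self.genotype = {
            locus: canonical_cell(*cell) for locus, cell in self.genotype.items()
        }

    def cell(self, locus: str) -> tuple[int, int]:
        return self.genotype.get(locus, (MISSING, MISSING))

    def scored(self, locus: str) -> bool:
        """True if at least one allele slot is scored at this locus."""
        return self.cell(locus) != (MISSING, MISSING)

    def fully_scored(self, locus: str) -> bool:
        a1, a2 = self.cell(locus)
        return a1 != MISSING and a2 != MISSING

    def alleles_at(self, locus: str) -> list[int]:
        """Scored (non-missing) allele copies at a locus."""
        return [a for a in self.cell(locus) if a != MISSING]


@dataclass
class GenotypeDataset:
    """A genotype table plus its allele registry and population metadata."""

    individuals: list[IndividualRecord]
    registry: AlleleRegistry
    populations: dict[str, str] = field(default_factory=dict)
    #: (locus, population) pairs already null-corrected; guards idempotency.
    corrected_loci: set = field(default_factory=set)

    def __post_init__(self):
        known = set(self.registry.locus_names())
        for ind in self.individuals:
            extra = set(ind.genotype) - known
            if extra:
                raise ValidationError(
                    f"{ind.id}: loci not in registry: {sorted(extra)}"
                )
            self.populations.setdefault(ind.population, "other")

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[IndividualRecord]:
        return iter(self.individuals)

    def by_population(self, population: str) -> list[IndividualRecord]:
        return [i for i in self.individuals if i.population == population]

    def by_taxon(self, taxon: str) -> list[IndividualRecord]:
        return [i for i in self.individuals if i.taxon_label == taxon]

    def locus_names(self) -> list[str]:
        return self.registry.locus_names()

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeDataset)
            and self.individuals == other.individuals
            and self.registry == other.registry
            and self.populations == other.populations
        )


def allele_class(registry: AlleleRegistry, dataset_or_records, locus: str,
                 allele: int) -> str:
    """Convenience wrapper kept for symmetry with :meth:`AlleleRegistry.classify`."""
    return registry.classify(locus, allele)
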