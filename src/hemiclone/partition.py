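"""Splitting hybrid diploid genotypes into parental haploid subgenomes.

A hybrid carries one haploid chromosome set from each parental species.
With species-diagnostic markers most alleles route themselves: an
L-specific allele belongs to the L subgenome, an R-specific allele to the
R subgenome.  Shared or nonspecific alleles are resolved by the sympatric
pool rule — the sexually inherited allele must occur in the gene pool of
the sympatric sexual population of that species — and loci that still
cannot be resolved are surfaced as unresolved rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .model import (
    MISSING,
    AlleleRegistry,
    IndividualRecord,
    ValidationError,
)


@dataclass
class SubgenomeHaplotype:
    """One parental haploid allele vector extracted from a hybrid."""

    individual: str
    genome: str  # "L" or "R"
    population: str = ""
    alleles: dict = field(default_factory=dict)  # locus -> allele or MISSING
    resolution: dict = field(default_factory=dict)  # locus -> how it was routed

    def allele(self, locus: str) -> int:
        return self.alleles.get(locus, MISSING)


@dataclass
class PartitionReport:
    individual: str
    n_specific: int = 0
    n_pool_resolved: int = 0
    n_unresolved: int = 0
    violations: list = field(default_factory=list)

    @property
    def n_loci_scored(self) -> int:
        return self.n_specific + self.n_pool_resolved + self.n_unresolved


def sympatric_pools(records: Sequence[IndividualRecord],
                    loci: Sequence[str]) -> dict:
    """Observed allele sets per (genome, locus) from sexual individuals.

    LL individuals define the L pool, RR individuals the R pool.
    """
    pools: dict[tuple[str, str], set] = {("L", l): set() for l in loci}
    pools.update({("R", l): set() for l in loci})
    genome_of = {"LL": "L", "RR": "R"}
    for rec in records:
        genome = genome_of.get(rec.taxon_label)
        if genome is None:
            continue
        for locus in loci:
            pools[(genome, locus)].update(rec.alleles_at(locus))
    return pools


def partition_hybrid(
    ind: IndividualRecord,
    registry: AlleleRegistry,
    sympatric_pool: Mapping,
    clonal_genome: str = "L",
) -> tuple[SubgenomeHaplotype, SubgenomeHaplotype, PartitionReport]:
    """Split one hybrid's genotype into its L and R haploid subgenomes.

    Per locus: species-classified alleles are routed to their genome; a
    shared/nonspecific partner allele is routed to the remaining genome
    only if it occurs in that species' sympatric sexual pool (resolution
    ``pool-resolved``), otherwise the locus is unresolved in both
    subgenomes and logged.  Loci amplifying in a single genome yield one
    allele with a missing partner.  Two alleles classified to the same
    genome at one locus are a partition conflict (logged, unresolved).

    ``clonal_genome`` only labels the outputs; routing never assumes
    clonality.
    """
    if ind.taxon_label != "RL":
        raise ValidationError(f"{ind.id}: partition requires a hybrid (RL)")
    if clonal_genome not in ("L", "R"):
        raise ValidationError("clonal_genome must be 'L' or 'R'")
    haps = {
        g: SubgenomeHaplotype(ind.id, g, population=ind.population)
        for g in ("L", "R")
    }
    report = PartitionReport(ind.id)

    for locus in ind.genotype:
        locus_def = registry.locus(locus)
        cell = ind.cell(locus)
        scored = [a for a in cell if a != MISSING]
        if not scored:
            for g in "LR":
                haps[g].alleles[locus] = MISSING
                haps[g].resolution[locus] = "missing"
            continue
        classes = {a: registry.classify(locus, a) for a in scored}
        routed: dict[str, int] = {}
        unresolved = False

        specific = {a: c for a, c in classes.items() if c in ("L", "R")}
        rest = [a for a in scored if a not in specific]
        targets = list(specific.values())
        if len(targets) == 2 and targets[0] == targets[1] and \
                len(set(specific)) == 2:
            report.violations.append(
                (ind.id, locus, "two alleles specific to the same genome")
            )
            unresolved = True
        else:
            for a, c in specific.items():
                routed[c] = a
            if len(locus_def.amplifies_in) == 1:
                # single-genome locus: any remaining allele belongs there too
                (only,) = locus_def.amplifies_in
                for a in rest:
                    if only in routed and routed[only] != a:
                        report.violations.append(
                            (ind.id, locus, "two alleles at a single-genome locus")
                        )
                        unresolved = True
                    else:
                        routed[only] = a
            elif rest:
                remaining = [g for g in "LR" if g not in routed]
                if len(rest) == 1 and len(remaining) == 1:
                    a = rest[0]
                    pool = sympatric_pool.get((remaining[0], locus), set())
                    if a in pool:
                        routed[remaining[0]] = a
                        haps[remaining[0]].resolution[locus] = "pool-resolved"
                    else:
                        report.violations.append(
                            (ind.id, locus,
                             f"allele {a} absent from sympatric {remaining[0]} pool")
                        )
                        unresolved = True
                elif len(rest) == 2 and not routed:
                    # both alleles unclassified: resolvable only if each fits
                    # exactly one arrangement of the two pools
                    a, b = rest
                    fits = []
                    for la, ra in ((a, b), (b, a)):
                        if la in sympatric_pool.get(("L", locus), set()) and \
                                ra in sympatric_pool.get(("R", locus), set()):
                            fits.append((la, ra))
                    fits = list(dict.fromkeys(fits))
                    if len(fits) == 1:
                        routed["L"], routed["R"] = fits[0]
                        haps["L"].resolution[locus] = "pool-resolved"
                        haps["R"].resolution[locus] = "pool-resolved"
                    else:
                        unresolved = True
                else:
                    unresolved = True

        if unresolved:
            for g in "LR":
                haps[g].alleles[locus] = MISSING
                haps[g].resolution[locus] = "unresolved"
            report.n_unresolved += 1
            continue
        pool_resolved = any(
            haps[g].resolution.get(locus) == "pool-resolved" for g in "LR"
        )
        for g in "LR":
            haps[g].alleles[locus] = routed.get(g, MISSING)
            haps[g].resolution.setdefault(
                locus, "pool-resolved" if pool_resolved else "specific"
            )
        if pool_resolved:
            report.n_pool_resolved += 1
        else:
            report.n_specific += 1

    return haps["L"], haps["R"], report


def double_haploid(h: SubgenomeHaplotype,
                   mode: str = "self-double") -> IndividualRecord:
    """Diploidize a haploid subgenome.

    ``self-double`` writes (a, a) per locus — the coding under which
    diploid clonality statistics reduce to their haploid forms.
    ``missing-partner`` writes (a, missing) — the coding for match and
    summary tools that must not see artificial homozygosity.
    """
    if mode not in ("self-double", "missing-partner"):
        raise ValidationError(f"unknown doubling mode {mode!r}")
    genotype = {}
    for locus, allele in h.alleles.items():
        if allele == MISSING:
            genotype[locus] = (MISSING, MISSING)
        elif mode == "self-double":
            genotype[locus] = (allele, allele)
        else:
            genotype[locus] = (MISSING, allele)
    return IndividualRecord(
        id=f"{h.individual}:{h.genome}",
        population=h.population or "unknown-pop",
        taxon_label="unknown",
        sex="unknown",
        genotype=genotype,
        ploidy=2,
    )
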