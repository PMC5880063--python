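"""Shared fixtures: small registries, toy records, simulated systems."""

from __future__ import annotations

import pytest

from hemiclone import (
    AlleleRegistry,
    GenotypeDataset,
    IndividualRecord,
    LocusDef,
    PopulationSpec,
    SimConfig,
)


def make_record(id, population="pop1", taxon="RR", sex="unknown", **cells):
    """Record from keyword cells: loc1=(110, 112)."""
    return IndividualRecord(
        id=id, population=population, taxon_label=taxon, sex=sex,
        genotype=dict(cells),
    )


@pytest.fixture
def diagnostic_registry() -> AlleleRegistry:
    """Six both-genome loci with disjoint L (100s) and R (200s) alleles,
    one L-only and one R-only locus."""
    reg = AlleleRegistry()
    for i in range(1, 7):
        name = f"both{i}"
        reg.add_locus(LocusDef(name, frozenset("LR"), motif_step=2))
        for a in (100, 102, 104, 106):
            reg.add_allele(name, a, "L")
        for a in (200, 202, 204, 206):
            reg.add_allele(name, a, "R")
    reg.add_locus(LocusDef("lonly1", frozenset("L"), motif_step=2))
    for a in (110, 112, 114):
        reg.add_allele("lonly1", a, "L")
    reg.add_locus(LocusDef("ronly1", frozenset("R"), motif_step=2))
    for a in (210, 212, 214):
        reg.add_allele("ronly1", a, "R")
    return reg


@pytest.fixture
def small_system_config() -> SimConfig:
    """Compact hybridogenetic system: 2 populations, 8 both-genome loci."""
    return SimConfig(
        seed=11,
        n_loci=10,
        n_l_only=1,
        n_r_only=1,
        alleles_per_locus=(5, 8),
        populations=[
            PopulationSpec("A", "R-E-male", n_RR=10, n_hybrid_males=6),
            PopulationSpec("B", "R-E-male", n_RR=8, n_hybrid_males=4),
        ],
        missing_rate=0.0,
    )


def recovery_config(seed: int) -> SimConfig:
    """The end-to-end recovery study conditions: 5 populations, 20 hybrid
    males and 40 RR in total, 10 both-genome loci, 5% missing cells."""
    return SimConfig(
        seed=seed,
        n_loci=10,
        n_l_only=0,
        n_r_only=0,
        alleles_per_locus=(6, 10),
        populations=[
            PopulationSpec(f"P{i}", "R-E-male", n_RR=8, n_hybrid_males=4)
            for i in range(1, 6)
        ],
        n_clones=1,
        missing_rate=0.05,
    )
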