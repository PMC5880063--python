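"""Synthetic hybridogenetic population systems with known ground truth.

The generator emulates the observable genetic structure of mixed water-frog
populations in which diploid hybrids reproduce hemiclonally: one parental
subgenome is frozen (transmitted clonally, identical across all hybrids of
a clone up to stepwise mutation) while the other is a fresh recombinant
gamete drawn each generation from the sympatric sexual species.

Two system types are supported by the same engine:

``R-E-male``
    Populations of sexual *ridibundus*-like (RR) frogs plus hybrid males;
    the hybrids carry a clonal L haplotype and a sexual R haplotype.
``L-E``
    Populations of sexual LL frogs plus hybrids transmitting the R genome
    clonally (genome roles switched).

Marker loci come in three classes, as in real diagnostic microsatellite
panels: loci amplifying only in the L genome, only in the R genome, or in
both, with disjoint allele-size bands per species so every allele is
species-classifiable.  Artifacts (random dropout and null alleles) are
injected in a separate, replayable step.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    MISSING,
    AlleleRegistry,
    GenotypeDataset,
    IndividualRecord,
    LocusDef,
    ValidationError,
    canonical_cell,
)


@dataclass
class PopulationSpec:
    """Composition of one simulated population."""

    name: str
    system_type: str  # "R-E-male", "L-E" or "other"
    n_RR: int = 0
    n_LL: int = 0
    n_hybrid_males: int = 0
    n_hybrid_females: int = 0

    def __post_init__(self):
        if min(self.n_RR, self.n_LL, self.n_hybrid_males, self.n_hybrid_females) < 0:
            raise ValidationError(f"population {self.name}: negative counts")
        if self.system_type == "R-E-male":
            if self.n_LL > 0:
                raise ValidationError(
                    f"population {self.name}: an R-E male system excludes LL "
                    f"individuals"
                )
            if self.n_hybrid_females > 0:
                raise ValidationError(
                    f"population {self.name}: an R-E male system has no hybrid "
                    f"females"
                )


def _default_populations() -> list[PopulationSpec]:
    # Five R-E male populations matching the field composition of the
    # upper-Oder study system (RR counts 17/1/8/6/9; hybrid males 12/2/4/4/5).
    comp = [(17, 12), (1, 2), (8, 4), (6, 4), (9, 5)]
    return [
        PopulationSpec(f"P{i + 1}", "R-E-male", n_RR=rr, n_hybrid_males=hy)
        for i, (rr, hy) in enumerate(comp)
    ]


@dataclass
class SimConfig:
    """Configuration of one simulated study.

    Defaults mirror the structure of a 17-locus diagnostic panel on an
    all-male hybrid system: three L-only loci, three R-only loci, the rest
    amplifying in both genomes; a single hemiclone; sexual pools at
    Hardy-Weinberg equilibrium (``fis_sexual = 0``); sporadic missing data.
    """

    seed: int = 0
    n_loci: int = 17
    n_l_only: int = 3
    n_r_only: int = 3
    alleles_per_locus: tuple[int, int] = (6, 17)
    L_size_band: tuple[int, int] = (100, 198)
    R_size_band: tuple[int, int] = (200, 298)
    motif_step: int = 2
    populations: list[PopulationSpec] = field(default_factory=_default_populations)
    n_clones: int = 1
    generations: int = 10
    mutation_rate: float = 0.0
    missing_rate: float = 0.03
    null_allele_rate: float = 0.0
    null_allele_freq: float = 0.2
    nonspecific_rate: float = 0.0
    fis_sexual: float = 0.0

    def __post_init__(self):
        for name in ("mutation_rate", "missing_rate", "null_allele_rate",
                     "null_allele_freq", "nonspecific_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.fis_sexual <= 1.0:
            raise ValidationError("fis_sexual must be in [-1, 1]")
        if self.n_l_only + self.n_r_only > self.n_loci:
            raise ValidationError("single-genome locus counts exceed n_loci")
        lo, hi = self.L_size_band
        rlo, rhi = self.R_size_band
        if not (hi < rlo or rhi < lo):
            raise ValidationError("L and R allele size bands must be disjoint")
        self.populations = [
            p if isinstance(p, PopulationSpec) else PopulationSpec(**p)
            for p in self.populations
        ]


@dataclass
class TruthLog:
    """Ground truth of a simulated system, replayable given the seed."""

    seed: int = 0
    clone_haplotypes: dict = field(default_factory=dict)  # clone-id -> {locus: allele}
    membership: dict = field(default_factory=dict)  # individual -> clone-id | "sexual"
    events: list = field(default_factory=list)
    substreams: dict = field(default_factory=dict)  # population -> spawn key

    def log(self, kind: str, **info) -> None:
        self.events.append({"kind": kind, **info})

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def build_registry(cfg: SimConfig, rng: np.random.Generator | None = None) -> AlleleRegistry:
    """Registry with L-only, R-only and both-genome loci in the configured
    proportions, allele states on a motif-step grid inside disjoint bands."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    registry = AlleleRegistry()
    classes = (
        ["L"] * cfg.n_l_only
        + ["R"] * cfg.n_r_only
        + ["LR"] * (cfg.n_loci - cfg.n_l_only - cfg.n_r_only)
    )
    counters = {"L": 0, "R": 0, "LR": 0}
    for cls in classes:
        counters[cls] += 1
        prefix = {"L": "Lonly", "R": "Ronly", "LR": "Both"}[cls]
        name = f"{prefix}{counters[cls]:02d}"
        registry.add_locus(LocusDef(name, frozenset(cls), motif_step=cfg.motif_step))
        for genome in cls:
            band = cfg.L_size_band if genome == "L" else cfg.R_size_band
            grid = np.arange(band[0], band[1] + 1, cfg.motif_step)
            k = int(rng.integers(cfg.alleles_per_locus[0],
                                 cfg.alleles_per_locus[1] + 1))
            k = min(k, grid.size)
            states = np.sort(rng.choice(grid, size=k, replace=False))
            for allele in states:
                registry.add_allele(name, int(allele), genome)
        if cls == "LR" and rng.random() < cfg.nonspecific_rate:
            # one allele amplifying in both genomes, registered once
            grid = np.arange(cfg.L_size_band[0], cfg.L_size_band[1] + 1,
                             cfg.motif_step)
            candidates = [a for a in grid
                          if registry.classify(name, int(a)) == "unregistered"]
            if candidates:
                allele = int(rng.choice(candidates))
                registry.add_allele(name, allele, "nonspecific")
    return registry


def _species_frequencies(cfg: SimConfig, registry: AlleleRegistry,
                         rng: np.random.Generator) -> dict:
    """Flat-Dirichlet species-wide allele frequencies per (genome, locus)."""
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    for locus in registry.loci:
        for genome in sorted(locus.amplifies_in):
            alleles = registry.alleles(locus.name, genome)
            probs = rng.dirichlet(np.ones(len(alleles)))
            freqs[(genome, locus.name)] = dict(zip(alleles, probs.tolist()))
    return freqs


def _draw_genotype(freq: dict[int, float], fis: float,
                   rng: np.random.Generator) -> tuple[int, int]:
    alleles = list(freq)
    probs = np.asarray([freq[a] for a in alleles])
    probs = probs / probs.sum()
    if rng.random() < fis:
        a = alleles[rng.choice(len(alleles), p=probs)]
        return (a, a)
    i, j = rng.choice(len(alleles), size=2, p=probs)
    return canonical_cell(alleles[i], alleles[j])


def simulate_sexual_population(
    cfg: SimConfig,
    species: str,
    n: int,
    rng: np.random.Generator,
    registry: AlleleRegistry | None = None,
    freqs: dict | None = None,
    population: str = "sim",
    start_index: int = 0,
) -> list[IndividualRecord]:
    """Draw ``n`` sexual diploids of one parental species.

    Genotypes follow the inbreeding-adjusted Hardy-Weinberg proportions
    P(hom a) = p_a^2 + F p_a (1-p_a), P(het ab) = 2 p_a p_b (1-F) with
    F = ``cfg.fis_sexual``.  Loci not amplifying in the species are blank.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    if species not in ("L", "R"):
        raise ValidationError(f"species must be 'L' or 'R', got {species!r}")
    registry = registry or build_registry(cfg)
    freqs = freqs or _species_frequencies(cfg, registry, rng)
    taxon = "LL" if species == "L" else "RR"
    out = []
    for k in range(n):
        genotype = {}
        for locus in registry.loci:
            if species not in locus.amplifies_in:
                genotype[locus.name] = (MISSING, MISSING)
            else:
                genotype[locus.name] = _draw_genotype(
                    freqs[(species, locus.name)], cfg.fis_sexual, rng
                )
        out.append(
            IndividualRecord(
                id=f"{population}_{taxon}{start_index + k:03d}",
                population=population,
                taxon_label=taxon,
                sex="f" if (start_index + k) % 2 == 0 else "m",
                genotype=genotype,
            )
        )
    return out


def _make_clone_haplotypes(cfg: SimConfig, registry: AlleleRegistry,
                           genome: str, freqs: dict,
                           rng: np.random.Generator) -> dict:
    """Sample ``n_clones`` founder haplotypes for the clonally transmitted
    genome from the species allele frequencies (generation 0)."""
    clones = {}
    for c in range(cfg.n_clones):
        hap = {}
        for locus in registry.loci:
            if genome in locus.amplifies_in:
                f = freqs[(genome, locus.name)]
                alleles = list(f)
                probs = np.asarray([f[a] for a in alleles])
                hap[locus.name] = int(alleles[rng.choice(len(alleles),
                                                         p=probs / probs.sum())])
        clones[f"{genome}clone{c + 1}"] = hap
    return clones


def _mutate_haplotype(hap: dict, registry: AlleleRegistry, cfg: SimConfig,
                      rng: np.random.Generator, truth: TruthLog,
                      individual: str) -> dict:
    """Apply stepwise mutations accumulated over ``generations`` clonal
    transmissions: per locus the number of events is Binomial(g, mu), each
    shifting the allele by +-motif_step with equal probability."""
    if cfg.mutation_rate == 0.0 or cfg.generations == 0:
        return dict(hap)
    out = {}
    for locus, allele in hap.items():
        k = int(rng.binomial(cfg.generations, cfg.mutation_rate))
        new = allele
        if k:
            step = registry.locus(locus).motif_step or cfg.motif_step
            shift = int((rng.integers(0, 2, size=k) * 2 - 1).sum()) * step
            new = allele + shift
            truth.log("mutation", individual=individual, locus=locus,
                      from_allele=allele, to_allele=new, n_events=k)
        out[locus] = new
    return out


def simulate_re_system(cfg: SimConfig) -> tuple[GenotypeDataset, TruthLog]:
    """Simulate a full multi-population hybridogenetic system.

    Each hybrid carries a frozen clonal haplotype (one founder per clone,
    optionally mutated along the generations) in the transmitted genome and
    a fresh recombinant gamete from the sympatric sexual pool in the other;
    sexual individuals mate randomly (up to ``fis_sexual``).  Same seed,
    same output, bit for bit.
    """
    root = np.random.SeedSequence(cfg.seed)
    reg_ss, freq_ss, clone_ss, pop_root = root.spawn(4)
    registry = build_registry(cfg, np.random.default_rng(reg_ss))
    freqs = _species_frequencies(cfg, registry, np.random.default_rng(freq_ss))
    truth = TruthLog(seed=cfg.seed)

    clone_rng = np.random.default_rng(clone_ss)
    need_l_clones = any(p.system_type == "R-E-male" for p in cfg.populations)
    need_r_clones = any(p.system_type == "L-E" for p in cfg.populations)
    clones: dict[str, dict] = {}
    if need_l_clones:
        clones.update(_make_clone_haplotypes(cfg, registry, "L", freqs, clone_rng))
    if need_r_clones:
        clones.update(_make_clone_haplotypes(cfg, registry, "R", freqs, clone_rng))
    truth.clone_haplotypes = {cid: dict(hap) for cid, hap in clones.items()}

    individuals: list[IndividualRecord] = []
    populations: dict[str, str] = {}
    pop_streams = pop_root.spawn(len(cfg.populations))
    hybrid_counter = 0
    for spec, ss in zip(cfg.populations, pop_streams):
        rng = np.random.default_rng(ss)
        truth.substreams[spec.name] = repr(ss.spawn_key)
        populations[spec.name] = spec.system_type
        for species, count in (("R", spec.n_RR), ("L", spec.n_LL)):
            for ind in simulate_sexual_population(
                cfg, species, count, rng, registry, freqs, spec.name
            ):
                individuals.append(ind)
                truth.membership[ind.id] = "sexual"
        clonal_genome = "L" if spec.system_type == "R-E-male" else "R"
        sexual_genome = "R" if clonal_genome == "L" else "L"
        clone_ids = [c for c in clones if c.startswith(clonal_genome)]
        n_hyb = spec.n_hybrid_males + spec.n_hybrid_females
        for k in range(n_hyb):
            sex = "m" if k < spec.n_hybrid_males else "f"
            ind_id = f"{spec.name}_RL{k:03d}"
            clone_id = clone_ids[hybrid_counter % len(clone_ids)] if clone_ids else None
            hybrid_counter += 1
            if clone_id is None:
                raise ValidationError(
                    f"population {spec.name}: hybrids requested but n_clones=0"
                )
            clonal_hap = _mutate_haplotype(
                clones[clone_id], registry, cfg, rng, truth, ind_id
            )
            genotype = {}
            for locus in registry.loci:
                amp = locus.amplifies_in
                c_allele = clonal_hap.get(locus.name, MISSING)
                if sexual_genome in amp:
                    f = freqs[(sexual_genome, locus.name)]
                    alleles = list(f)
                    probs = np.asarray([f[a] for a in alleles])
                    s_allele = int(
                        alleles[rng.choice(len(alleles), p=probs / probs.sum())]
                    )
                else:
                    s_allele = MISSING
                genotype[locus.name] = canonical_cell(
                    c_allele if clonal_genome in amp else MISSING, s_allele
                )
            individuals.append(
                IndividualRecord(
                    id=ind_id,
                    population=spec.name,
                    taxon_label="RL",
                    sex=sex,
                    genotype=genotype,
                )
            )
            truth.membership[ind_id] = clone_id
    ds = GenotypeDataset(individuals, registry, populations)
    return ds, truth


def inject_artifacts(
    ds: GenotypeDataset,
    cfg: SimConfig,
    rng: np.random.Generator,
    truth: TruthLog | None = None,
) -> GenotypeDataset:
    """Overlay dropout and null alleles on a simulated dataset.

    Whole cells are blanked with probability ``missing_rate``.  Each locus
    independently carries a segregating null allele with probability
    ``null_allele_rate``; at a null locus every scored allele copy turns
    null with probability ``null_allele_freq``, so null homozygotes become
    blanks and null heterozygotes become apparent homozygotes for the
    visible allele — the classic genotyping artifact the downstream
    screening step has to detect.
    """
    loci = ds.locus_names()
    null_loci = [locus for locus in loci if rng.random() < cfg.null_allele_rate]
    if truth is not None and null_loci:
        truth.log("null_loci", loci=null_loci, freq=cfg.null_allele_freq)
    new_individuals = []
    for ind in ds.individuals:
        genotype = {}
        for locus in loci:
            cell = ind.cell(locus)
            if cell != (MISSING, MISSING) and locus in null_loci:
                visible = [
                    a for a in cell
                    if a == MISSING or rng.random() >= cfg.null_allele_freq
                ]
                dropped = len([a for a in cell if a != MISSING]) - len(
                    [a for a in visible if a != MISSING]
                )
                if dropped:
                    scored = [a for a in visible if a != MISSING]
                    if not scored:
                        cell = (MISSING, MISSING)
                    else:
                        # one null copy: scored as an apparent homozygote
                        cell = (scored[0], scored[0])
                    if truth is not None:
                        truth.log("null_dropout", individual=ind.id,
                                  locus=locus, n_copies=dropped)
            if cell != (MISSING, MISSING) and rng.random() < cfg.missing_rate:
                if truth is not None:
                    truth.log("missing", individual=ind.id, locus=locus)
                cell = (MISSING, MISSING)
            genotype[locus] = cell
        new_individuals.append(
            IndividualRecord(ind.id, ind.population, ind.taxon_label, ind.sex,
                             genotype, ind.ploidy)
        )
    return GenotypeDataset(new_individuals, ds.registry, dict(ds.populations))
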