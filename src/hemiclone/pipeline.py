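"""Full-pipeline orchestration: simulate/load -> quality -> assign ->
partition -> clones -> relatedness, with a machine-readable run manifest.

The stage order follows the analysis logic: genotyping-artifact screening
first (HWE + null alleles), then taxon assignment, then subgenome
partitioning of hybrids, then clonality statistics on the combined
diploidized set, and finally between-group relatedness (Nei DA / UPGMA /
PCA).  Every stage is toggleable and every random choice derives from the
single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .assign import AdmixtureEstimator, assign_taxon
from .clones import CloneDetector
from .io import (
    load_allele_registry,
    load_genotype_table,
    validate_dataset,
    write_allele_registry,
    write_genotype_table,
)
from .model import GenotypeDataset, ValidationError
from .partition import double_haploid, partition_hybrid, sympatric_pools
from .quality import (
    apply_null_correction,
    estimate_null_allele_freq,
    flag_null_loci,
    hwe_test,
)
from .relatedness import bootstrap_support, nei_da_matrix, pca_mlg
from .simulate import SimConfig, inject_artifacts, simulate_re_system

_SEXUAL_TAXON = {"R-E-male": "RR", "L-E": "LL"}


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable pipeline configuration."""

    seed: int = 0
    simulate: bool = False
    genotypes: str = ""
    registry: str = ""
    clonal_genome: str = "L"
    alpha: float = 0.05
    min_copies: int = 3
    min_shared_loci: int = 5
    null_r_threshold: float = 0.05
    null_p_threshold: float = 0.05
    hwe_reps: int = 2000
    bootstrap_reps: int = 7000
    min_support: float = 0.75
    pool_scope: str = "population"  # or "system"
    do_quality: bool = True
    do_assign: bool = True
    do_partition: bool = True
    do_clones: bool = True
    do_tree: bool = True
    do_pca: bool = True

    def __post_init__(self):
        for name, lo, hi in (("alpha", 0, 1), ("null_r_threshold", 0, 1),
                             ("null_p_threshold", 0, 1), ("min_support", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValidationError(f"{name} must be in [{lo}, {hi}]")
        if self.pool_scope not in ("population", "system"):
            raise ValidationError("pool_scope must be population or system")
        if self.clonal_genome not in ("L", "R"):
            raise ValidationError("clonal_genome must be L or R")

    # -- flat key=value round-trip -----------------------------------
    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        values = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                key, sep, value = line.partition("=")
                key = key.strip()
                if not sep or key not in fields:
                    raise ValidationError(
                        f"config line {lineno}: unknown or malformed entry "
                        f"{line!r}"
                    )
                ftype = fields[key].type
                value = value.strip()
                if ftype in ("bool", bool):
                    values[key] = value.lower() in ("1", "true", "yes", "on")
                elif ftype in ("int", int):
                    values[key] = int(value)
                elif ftype in ("float", float):
                    values[key] = float(value)
                else:
                    values[key] = value
        return cls(**values)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")


def _clone_row(rep) -> dict:
    return {
        "clone_id": rep.clone_id,
        "n_members": rep.count_total,
        "count_per_population": dict(sorted(rep.count_per_population.items())),
        "p_gen": rep.p_gen,
        "p_sex_min": rep.p_sex_min,
        "p_sex_global": rep.p_sex_global,
        "verdict": rep.verdict,
        "members": rep.members,
    }


def analyze_dataset(ds: GenotypeDataset, cfg: PipelineConfig) -> dict:
    """Run the analysis stages on a loaded dataset; returns the manifest
    fragment plus rich result objects under the ``objects`` key."""
    manifest: dict = {"stages": [], "decisions": []}
    objects: dict = {}
    loci = ds.locus_names()
    both_genome_loci = [
        l for l in loci if ds.registry.locus(l).amplifies_in == {"L", "R"}
    ]

    report = validate_dataset(ds)
    manifest["validation"] = {
        "n_individuals": len(ds),
        "n_loci": len(loci),
        "n_atypical_alleles": len(report.atypical_alleles),
        "n_wrong_genome_scores": len(report.wrong_genome_loci),
        "max_missingness": max(report.missingness.values(), default=0.0),
    }
    objects["validation"] = report

    # ---- quality ----------------------------------------------------
    if cfg.do_quality:
        manifest["stages"].append("quality")
        hwe_results = []
        estimates = []
        for pop, system in sorted(ds.populations.items()):
            taxon = _SEXUAL_TAXON.get(system)
            candidates = [t for t in ("LL", "RR")] if taxon is None else [taxon]
            for tax in candidates:
                records = [
                    r for r in ds.by_population(pop) if r.taxon_label == tax
                ]
                if len(records) < 5:
                    continue
                for locus in loci:
                    scored = [r for r in records if r.fully_scored(locus)]
                    if len(scored) < 5:
                        continue
                    try:
                        hwe_results.append(
                            hwe_test(records, locus, pop, cfg.hwe_reps,
                                     seed=cfg.seed)
                        )
                        estimates.append(
                            estimate_null_allele_freq(records, locus, pop)
                        )
                    except ValidationError:
                        continue
        flagged = flag_null_loci(estimates, hwe_results,
                                 cfg.null_r_threshold, cfg.null_p_threshold)
        if flagged:
            ds = apply_null_correction(ds, flagged,
                                       threshold=cfg.null_r_threshold,
                                       seed=cfg.seed)
            manifest["decisions"].append(
                "null correction applied (blanks recoded as null homozygotes; "
                "apparent homozygotes stochastically recoded by posterior)"
            )
        manifest["quality"] = {
            "n_tests": len(hwe_results),
            "flagged_loci": sorted({(e.locus, e.population) for e in flagged}),
        }
        objects["hwe"] = hwe_results
        objects["null_estimates"] = estimates
        objects["flagged"] = flagged

    # ---- assignment -------------------------------------------------
    if cfg.do_assign:
        manifest["stages"].append("assign")
        calls = [assign_taxon(r, ds.registry, cfg.min_support) for r in ds]
        objects["taxon_calls"] = calls
        call_counts: dict[str, int] = {}
        for c in calls:
            call_counts[c.call] = call_counts.get(c.call, 0) + 1
        manifest["assign"] = {"calls": dict(sorted(call_counts.items()))}
        ll = ds.by_taxon("LL")
        rr = ds.by_taxon("RR")
        if ll and rr:
            est = AdmixtureEstimator(registry=ds.registry).fit(ll + rr)
            q = est.predict_result(list(ds))
            objects["admixture"] = q
            hybrids_q = [
                res.q for res, rec in zip(q, ds) if rec.taxon_label == "RL"
            ]
            manifest["assign"]["hybrid_q_range"] = (
                [min(hybrids_q), max(hybrids_q)] if hybrids_q else None
            )

    # ---- partition --------------------------------------------------
    haps_L, haps_R, part_reports = [], [], []
    if cfg.do_partition:
        manifest["stages"].append("partition")
        system_pool = sympatric_pools(list(ds), loci)
        for rec in ds.by_taxon("RL"):
            if cfg.pool_scope == "population":
                pool = sympatric_pools(ds.by_population(rec.population), loci)
                # fall back to the system-wide pool where the local one is empty
                pool = {
                    k: (v if v else system_pool[k]) for k, v in pool.items()
                }
            else:
                pool = system_pool
            system = ds.populations.get(rec.population, "other")
            clonal = "L" if system == "R-E-male" else (
                "R" if system == "L-E" else cfg.clonal_genome
            )
            hl, hr, rep = partition_hybrid(rec, ds.registry, pool, clonal)
            haps_L.append(hl)
            haps_R.append(hr)
            part_reports.append(rep)
        manifest["partition"] = {
            "n_hybrids": len(part_reports),
            "n_unresolved_loci": sum(r.n_unresolved for r in part_reports),
            "n_pool_resolved_loci": sum(r.n_pool_resolved for r in part_reports),
            "n_violations": sum(len(r.violations) for r in part_reports),
        }
        objects["haplotypes_L"] = haps_L
        objects["haplotypes_R"] = haps_R
        objects["partition_reports"] = part_reports

    # ---- clonality --------------------------------------------------
    if cfg.do_clones:
        if not cfg.do_partition:
            raise ValidationError("clones stage requires the partition stage")
        manifest["stages"].append("clones")
        sexual = [r for r in ds if r.taxon_label in ("LL", "RR")]
        doubled = [double_haploid(h, "self-double") for h in haps_L + haps_R]
        analysis_loci = both_genome_loci if both_genome_loci else loci
        detector = CloneDetector(
            loci=analysis_loci,
            alpha=cfg.alpha,
            min_copies=cfg.min_copies,
            min_shared_loci=min(cfg.min_shared_loci, max(1, len(analysis_loci) - 1)),
        ).fit(sexual + doubled)
        objects["clone_detector"] = detector
        clone_rows = [_clone_row(rep) for rep in detector.reports_]
        clonal = [row for row in clone_rows if row["verdict"] == "clonal"]
        manifest["clones"] = {
            "analysis_loci": analysis_loci,
            "n_records": len(sexual) + len(doubled),
            "n_exact_mlgs": detector.n_mlgs_,
            "n_merged_mlgs": len(detector.reports_),
            "n_clonal": len(clonal),
            "clonal": clonal,
        }

    # ---- relatedness ------------------------------------------------
    if cfg.do_tree or cfg.do_pca:
        groups = {}
        rr = ds.by_taxon("RR")
        ll = ds.by_taxon("LL")
        if rr:
            groups["RR"] = rr
        if ll:
            groups["LL"] = ll
        if haps_L:
            groups["hybrid-L"] = [
                double_haploid(h, "missing-partner") for h in haps_L
            ]
        if haps_R:
            groups["hybrid-R"] = [
                double_haploid(h, "missing-partner") for h in haps_R
            ]
        if cfg.do_tree and len(groups) >= 2 and len(both_genome_loci) >= 2:
            manifest["stages"].append("tree")
            tree = bootstrap_support(groups, both_genome_loci,
                                     cfg.bootstrap_reps, seed=cfg.seed)
            objects["tree"] = tree
            objects["distance_matrix"] = nei_da_matrix(groups, both_genome_loci)
            manifest["tree"] = {
                "newick": tree.to_newick(),
                "groups": sorted(groups),
                "bootstrap_reps": cfg.bootstrap_reps,
            }
        if cfg.do_pca and len(groups) >= 1:
            manifest["stages"].append("pca")
            entities = [r for recs in groups.values() for r in recs]
            if len(entities) >= 2:
                pca = pca_mlg(entities, loci)
                objects["pca"] = pca
                manifest["pca"] = {
                    "explained_pct_axis1": float(pca.explained_pct[0])
                    if pca.explained_pct.size else 0.0,
                    "n_entities": len(entities),
                }

    manifest["objects"] = objects
    return manifest


def _write_partition_outputs(objects: dict, ds: GenotypeDataset, outdir: Path) -> None:
    for genome in ("L", "R"):
        haps = objects.get(f"haplotypes_{genome}", [])
        if not haps:
            continue
        records = [double_haploid(h, "missing-partner") for h in haps]
        sub = GenotypeDataset(records, ds.registry, dict(ds.populations))
        write_genotype_table(sub, outdir / f"genome-{genome}.csv")
    reports = objects.get("partition_reports", [])
    if reports:
        with open(outdir / "partition_report.tsv", "w", encoding="utf-8") as fh:
            fh.write("individual\tn_specific\tn_pool_resolved\tn_unresolved\t"
                     "violations\n")
            for rep in reports:
                viols = ";".join(f"{l}:{msg}" for _, l, msg in rep.violations)
                fh.write(
                    f"{rep.individual}\t{rep.n_specific}\t"
                    f"{rep.n_pool_resolved}\t{rep.n_unresolved}\t{viols}\n"
                )


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute the configured pipeline and write artifacts to ``outdir``.

    Returns the manifest (also written as ``manifest.json``, without the
    in-memory result objects).  Identical config + inputs give identical
    manifests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.simulate:
        sim_cfg = SimConfig(seed=cfg.seed)
        ds, truth = simulate_re_system(sim_cfg)
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 0xA27]).generate_state(1)[0]
        )
        ds = inject_artifacts(ds, sim_cfg, rng, truth)
        write_genotype_table(ds, outdir / "genotypes.csv")
        write_allele_registry(ds.registry, outdir / "registry.tsv")
        truth.to_json(outdir / "truth.json")
    else:
        if not cfg.genotypes or not cfg.registry:
            raise ValidationError(
                "either enable simulate or provide genotypes and registry paths"
            )
        registry = load_allele_registry(cfg.registry)
        ds = load_genotype_table(cfg.genotypes, registry)

    manifest = analyze_dataset(ds, cfg)
    manifest["version"] = __version__
    manifest["seed"] = cfg.seed
    manifest["config"] = {
        f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)
    }
    objects = manifest.pop("objects")

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)

    # stage artifact files
    if "tree" in manifest:
        (outdir / "tree.nwk").write_text(manifest["tree"]["newick"] + "\n")
    if "hwe" in objects:
        flagged_keys = {
            (e.locus, e.population) for e in objects.get("flagged", [])
        }
        est_by_key = {
            (e.locus, e.population): e for e in objects.get("null_estimates", [])
        }
        with open(outdir / "quality.tsv", "w", encoding="utf-8") as fh:
            fh.write("locus\tpopulation\tp_value\thet_deficit\tr_hat\tflagged\n")
            for h in objects["hwe"]:
                est = est_by_key.get((h.locus, h.population))
                r_hat = f"{est.r_hat:.4f}" if est else "NA"
                flag = int((h.locus, h.population) in flagged_keys)
                fh.write(
                    f"{h.locus}\t{h.population}\t{h.p_value:.5f}\t"
                    f"{h.het_deficit:.4f}\t{r_hat}\t{flag}\n"
                )
    _write_partition_outputs(objects, ds, outdir)
    if "pca" in objects:
        pca = objects["pca"]
        with open(outdir / "pca_coordinates.tsv", "w", encoding="utf-8") as fh:
            axes = range(pca.coordinates.shape[1])
            fh.write("id\t" + "\t".join(f"axis{i + 1}" for i in axes) + "\n")
            for eid, row in zip(pca.entity_ids, pca.coordinates):
                fh.write(eid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    if "clone_detector" in objects:
        det = objects["clone_detector"]
        with open(outdir / "clones.tsv", "w", encoding="utf-8") as fh:
            fh.write("clone_id\tn_members\tp_gen\tp_sex_min\tp_sex_global\t"
                     "verdict\tmembers\n")
            for rep in det.reports_:
                fh.write(
                    f"{rep.clone_id}\t{rep.count_total}\t{rep.p_gen:.6g}\t"
                    f"{rep.p_sex_min:.6g}\t{rep.p_sex_global:.6g}\t"
                    f"{rep.verdict}\t{','.join(rep.members)}\n"
                )
    manifest["objects"] = objects
    return manifest
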