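"""Readers, writers and validation for genotype tables and allele registries.

File dialects
-------------
Genotype CSV
    Header ``id,population,taxon,sex`` followed by one column per locus.
    A cell is ``a1/a2``, ``a1/0`` (half missing) or ``0/0`` (blank); ``0``
    is the reserved missing sentinel.  Comment lines start with ``#``;
    population system types round-trip through ``# system: NAME=TYPE``
    comments.

Registry TSV
    Four tab-separated columns ``locus  allele_or_range  specificity
    amplifies_in``.  ``allele_or_range`` is a single integer or an
    inclusive ``lo-hi[:step]`` interval, expanded to explicit entries at
    load.  ``specificity`` is one of ``L R shared nonspecific``;
    ``amplifies_in`` is ``L``, ``R`` or ``LR``.  An optional fifth column
    carries the locus motif step.

Both formats are UTF-8 and comment lines begin with ``#``.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

from .model import (
    MISSING,
    AlleleRegistry,
    FormatError,
    GenotypeDataset,
    IndividualRecord,
    LocusDef,
    ValidationError,
    canonical_cell,
)

_META_COLUMNS = ("id", "population", "taxon", "sex")


def _expand_allele_field(text: str, lineno: int) -> list[int]:
    text = text.strip()
    try:
        if "-" in text[1:]:
            span, _, step_s = text.partition(":")
            lo_s, _, hi_s = span[1:].partition("-")
            lo, hi = int(span[0] + lo_s), int(hi_s)
            step = int(step_s) if step_s else 1
            if step <= 0 or hi < lo:
                raise ValueError
            return list(range(lo, hi + 1, step))
        return [int(text)]
    except ValueError:
        raise FormatError(f"line {lineno}: bad allele or range {text!r}") from None


def load_allele_registry(path) -> AlleleRegistry:
    """Read a registry TSV; interval rows are expanded to explicit alleles.

    Duplicate (locus, allele) rows with conflicting specificity raise
    :class:`ValidationError`; malformed rows raise :class:`FormatError`
    with the offending line number.
    """
    registry = AlleleRegistry()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (4, 5):
                raise FormatError(
                    f"line {lineno}: expected 4 or 5 tab-separated fields, "
                    f"got {len(parts)}"
                )
            locus, allele_field, spec, amp = (p.strip() for p in parts[:4])
            motif = None
            if len(parts) == 5 and parts[4].strip():
                try:
                    motif = int(parts[4])
                except ValueError:
                    raise FormatError(f"line {lineno}: bad motif step {parts[4]!r}")
            if not amp or set(amp) - {"L", "R"}:
                raise FormatError(f"line {lineno}: bad amplifies_in {amp!r}")
            if locus not in registry:
                registry.add_locus(
                    LocusDef(locus, frozenset(amp), motif_step=motif)
                )
            elif registry.locus(locus).amplifies_in != frozenset(amp):
                raise ValidationError(
                    f"line {lineno}: locus {locus!r} re-declared with different "
                    f"amplifies_in"
                )
            for allele in _expand_allele_field(allele_field, lineno):
                try:
                    registry.add_allele(locus, allele, spec)
                except ValidationError as exc:
                    raise ValidationError(f"line {lineno}: {exc}") from None
    return registry


def write_allele_registry(registry: AlleleRegistry, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# locus\tallele\tspecificity\tamplifies_in\tmotif_step\n")
        for locus in registry.loci:
            amp = "".join(sorted(locus.amplifies_in))
            motif = "" if locus.motif_step is None else str(locus.motif_step)
            for allele in registry.alleles(locus.name):
                spec = registry.classify(locus.name, allele)
                fh.write(f"{locus.name}\t{allele}\t{spec}\t{amp}\t{motif}\n")


def _parse_cell(text: str, lineno: int, locus: str) -> tuple[int, int]:
    parts = [p.strip() for p in text.strip().split("/") if p.strip() != ""]
    if text.strip() == "":
        return (MISSING, MISSING)
    if len(parts) > 2:
        raise FormatError(
            f"line {lineno}, locus {locus}: {len(parts)} alleles in a diploid "
            f"cell ({text!r})"
        )
    try:
        alleles = [int(p) for p in parts]
    except ValueError:
        raise FormatError(
            f"line {lineno}, locus {locus}: non-integer allele in {text!r}"
        ) from None
    if len(alleles) == 1:
        alleles.append(MISSING)
    return canonical_cell(*alleles)


def load_genotype_table(path, registry: AlleleRegistry) -> GenotypeDataset:
    """Read a genotype CSV against a loaded registry.

    Unregistered alleles are collected onto the returned dataset as
    ``dataset.unregistered`` — reported, never silently dropped.
    """
    populations: dict[str, str] = {}
    individuals: list[IndividualRecord] = []
    unregistered: list[tuple[str, str, int]] = []
    with open(path, encoding="utf-8") as fh:
        header = None
        loci = []
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                meta = line[1:].strip()
                if meta.startswith("system:"):
                    name, _, kind = meta[len("system:"):].strip().partition("=")
                    populations[name.strip()] = kind.strip() or "other"
                continue
            if not line.strip():
                continue
            row = next(csv.reader(_io.StringIO(line)))
            if header is None:
                header = [c.strip() for c in row]
                if tuple(header[:4]) != _META_COLUMNS:
                    raise FormatError(
                        f"line {lineno}: header must start with "
                        f"{','.join(_META_COLUMNS)}"
                    )
                loci = header[4:]
                unknown = [c for c in loci if c not in registry]
                if unknown:
                    raise FormatError(
                        f"line {lineno}: unknown locus column(s) {unknown}"
                    )
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            ind_id, population, taxon, sex = (c.strip() for c in row[:4])
            genotype = {}
            for locus, cell_text in zip(loci, row[4:]):
                cell = _parse_cell(cell_text, lineno, locus)
                genotype[locus] = cell
                for allele in cell:
                    if allele not in (MISSING,) and registry.classify(
                        locus, allele
                    ) == "unregistered":
                        unregistered.append((ind_id, locus, allele))
            individuals.append(
                IndividualRecord(
                    id=ind_id,
                    population=population,
                    taxon_label=taxon or "unknown",
                    sex=sex or "unknown",
                    genotype=genotype,
                )
            )
    if header is None:
        raise FormatError("empty genotype file (no header)")
    ds = GenotypeDataset(individuals, registry, populations)
    ds.unregistered = unregistered
    return ds


def write_genotype_table(ds: GenotypeDataset, path) -> None:
    """Write a dataset back to the genotype CSV dialect (round-trip safe)."""
    loci = ds.locus_names()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for name in sorted(ds.populations):
            fh.write(f"# system: {name}={ds.populations[name]}\n")
        writer = csv.writer(fh)
        writer.writerow(list(_META_COLUMNS) + loci)
        for ind in ds.individuals:
            cells = ["/".join(str(a) for a in ind.cell(locus)) for locus in loci]
            writer.writerow(
                [ind.id, ind.population, ind.taxon_label, ind.sex] + cells
            )


@dataclass
class ValidationReport:
    """Report-only dataset screening; never mutates the dataset.

    ``atypical_alleles`` lists alleles whose species specificity conflicts
    with the bearer's taxon (e.g. an LL individual carrying an R-specific
    allele).  ``wrong_genome_loci`` lists scores at loci that should not
    amplify in the bearer's genomes at all.  ``missingness`` is the
    fraction of fully missing cells per locus.
    """

    atypical_alleles: list = field(default_factory=list)
    wrong_genome_loci: list = field(default_factory=list)
    missingness: dict = field(default_factory=dict)
    unregistered: list = field(default_factory=list)

    @property
    def anomalies(self) -> list:
        return self.atypical_alleles + self.wrong_genome_loci


_TAXON_GENOMES = {"LL": {"L"}, "RR": {"R"}, "RL": {"L", "R"}, "KK": {"R"}}


def validate_dataset(ds: GenotypeDataset) -> ValidationReport:
    report = ValidationReport(unregistered=list(getattr(ds, "unregistered", [])))
    loci = ds.locus_names()
    missing_counts = {locus: 0 for locus in loci}
    for ind in ds.individuals:
        genomes = _TAXON_GENOMES.get(ind.taxon_label)
        for locus in loci:
            cell = ind.cell(locus)
            if cell == (MISSING, MISSING):
                missing_counts[locus] += 1
                continue
            locus_def = ds.registry.locus(locus)
            if genomes is not None and not (locus_def.amplifies_in & genomes):
                report.wrong_genome_loci.append((ind.id, locus))
            for allele in ind.alleles_at(locus):
                spec = ds.registry.classify(locus, allele)
                if genomes is not None and spec in ("L", "R") and spec not in genomes:
                    report.atypical_alleles.append((ind.id, locus, allele, spec))
    n = len(ds.individuals)
    report.missingness = {
        locus: (missing_counts[locus] / n if n else 0.0) for locus in loci
    }
    return report
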