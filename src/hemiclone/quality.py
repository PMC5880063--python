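"""Per-locus screening: Hardy-Weinberg departure and null alleles.

Null alleles (non-amplifying variants) produce apparent homozygotes and
blank cells, inflating homozygosity and corrupting downstream clonality
statistics.  The screening chain mirrors the classic Micro-Checker
workflow: a Monte-Carlo exact HWE test per (locus, population), a
maximum-likelihood null-allele frequency estimate that treats blanks as
data (null homozygotes), and a correction that recodes the data so the
null segregates as an ordinary visible allele.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln

from .model import (
    MISSING,
    NULL_ALLELE,
    GenotypeDataset,
    IndividualRecord,
    ValidationError,
)


@dataclass
class HweResult:
    locus: str
    population: str
    p_value: float
    n_reps: int
    het_deficit: float  # H_EXP - H_OBS (positive = heterozygote deficit)
    n: int


@dataclass
class NullAlleleEstimate:
    locus: str
    population: str
    r_hat: float
    blanks_observed: int
    n: int
    method: str = "three-class-ML"
    visible_frequencies: dict | None = None


def _population_cells(ds_or_records, locus: str, population: str | None):
    records = ds_or_records.individuals if isinstance(
        ds_or_records, GenotypeDataset) else list(ds_or_records)
    if population is not None:
        records = [r for r in records if r.population == population]
    return records


def _genotype_log_prob(pair_codes: np.ndarray, log_hw: np.ndarray,
                       n_states: int) -> float:
    """Log multinomial probability of a genotype configuration under the
    Hardy-Weinberg genotype model (allele frequencies from the pooled
    copies; the multinomial coefficient depends on the genotype counts and
    therefore matters when comparing permuted configurations)."""
    counts = np.bincount(pair_codes, minlength=n_states * n_states)
    nz = counts.nonzero()[0]
    n = counts.sum()
    return float(
        gammaln(n + 1)
        - gammaln(counts[nz] + 1).sum()
        + (counts[nz] * log_hw[nz]).sum()
    )


def hwe_test(ds_or_records, locus: str, population: str | None = None,
             n_reps: int = 10000, seed: int = 0) -> HweResult:
    """Monte-Carlo exact test for Hardy-Weinberg departure at one locus.

    Allele copies are permuted among individuals ``n_reps`` times; the
    p-value is ``(1 + #{permutations with configuration probability <=
    observed}) / (n_reps + 1)``.  Monomorphic loci return p = 1 by
    convention.
    """
    records = _population_cells(ds_or_records, locus, population)
    cells = [r.cell(locus) for r in records if r.fully_scored(locus)]
    if len(cells) < 2:
        raise ValidationError(
            f"hwe_test needs >= 2 fully scored diploids at {locus}"
        )
    pool = np.asarray([a for cell in cells for a in cell])
    states, codes = np.unique(pool, return_inverse=True)
    k = len(states)
    pop_label = population if population is not None else "all"
    freqs = np.bincount(codes, minlength=k) / codes.size
    # Observed heterozygosity bookkeeping (reported alongside the test).
    h_obs = float(np.mean([a != b for a, b in cells]))
    h_exp = float(1.0 - np.sum(freqs ** 2))
    if k < 2:
        return HweResult(locus, pop_label, 1.0, 0, h_exp - h_obs, len(cells))

    # Genotype code = ordered pair index (i <= j) mapped into a k*k table.
    log_hw = np.full(k * k, -np.inf)
    for i in range(k):
        for j in range(i, k):
            p = freqs[i] ** 2 if i == j else 2 * freqs[i] * freqs[j]
            if p > 0:
                log_hw[i * k + j] = np.log(p)

    def pair_codes(flat: np.ndarray) -> np.ndarray:
        a = flat.reshape(-1, 2)
        lo = a.min(axis=1)
        hi = a.max(axis=1)
        return lo * k + hi

    observed = _genotype_log_prob(pair_codes(codes), log_hw, k)
    rng = np.random.default_rng(seed)
    hits = 0
    work = codes.copy()
    for _ in range(n_reps):
        rng.shuffle(work)
        if _genotype_log_prob(pair_codes(work), log_hw, k) <= observed + 1e-9:
            hits += 1
    p_value = (1 + hits) / (n_reps + 1)
    return HweResult(locus, pop_label, p_value, n_reps, h_exp - h_obs,
                     len(cells))


def estimate_null_allele_freq(ds_or_records, locus: str,
                              population: str | None = None,
                              tol: float = 1e-6,
                              max_iter: int = 10000) -> NullAlleleEstimate:
    """ML estimate of the null-allele frequency from the three observable
    classes at a locus: visible heterozygotes (2 p_i p_j), visible
    homozygotes (p_i^2 + 2 p_i r) and blanks (r^2), with the visible
    frequencies and r summing to one.  Solved by EM; blanks are counted as
    data (null homozygotes), never discarded.

    Invariant to allele relabeling; returns r = 0 outright when there is
    neither a heterozygote deficit nor a blank, and r = 1 when every cell
    is blank.
    """
    records = _population_cells(ds_or_records, locus, population)
    pop_label = population if population is not None else "all"
    scored = [r for r in records if r.scored(locus)]
    blanks = sum(
        1 for r in records
        if locus in r.genotype and r.cell(locus) == (MISSING, MISSING)
    )
    full = [r.cell(locus) for r in records if r.fully_scored(locus)]
    n = len(full) + blanks
    if n == 0 or (not full and blanks):
        r = 1.0 if blanks else 0.0
        return NullAlleleEstimate(locus, pop_label, r, blanks, n,
                                  visible_frequencies={})

    het = [c for c in full if c[0] != c[1]]
    hom = [c[0] for c in full if c[0] == c[1]]
    alleles = sorted({a for c in full for a in c})
    if blanks == 0:
        # no blank signal: short-circuit when homozygosity is not in excess
        copies = np.asarray([a for c in full for a in c])
        vals, counts = np.unique(copies, return_counts=True)
        p = counts / counts.sum()
        h_exp = 1.0 - float(np.sum(p * p))
        h_obs = len(het) / len(full)
        if h_obs >= h_exp:
            return NullAlleleEstimate(
                locus, pop_label, 0.0, 0, n,
                visible_frequencies=dict(zip(vals.tolist(), p.tolist())),
            )

    idx = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    het_counts = np.zeros(k)
    for a, b in het:
        het_counts[idx[a]] += 1
        het_counts[idx[b]] += 1
    hom_counts = np.zeros(k)
    for a in hom:
        hom_counts[idx[a]] += 1

    # EM over latent true genotypes of visible homozygotes and blanks.
    p = np.full(k, (1.0 - 0.1) / k)
    r = 0.1
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            w_null = np.where(p + 2 * r > 0, 2 * r / (p + 2 * r), 0.0)
        copies = het_counts + hom_counts * (2 * (1 - w_null) + w_null)
        null_copies = float(hom_counts @ w_null) + 2.0 * blanks
        total = copies.sum() + null_copies
        p_new = copies / total
        r_new = null_copies / total
        if abs(r_new - r) < tol and np.abs(p_new - p).max() < tol:
            p, r = p_new, r_new
            break
        p, r = p_new, r_new
    r = float(np.clip(r, 0.0, 1.0))
    if r < 1e-6:
        r = 0.0
    return NullAlleleEstimate(
        locus, pop_label, r, blanks, n,
        visible_frequencies={a: float(p[idx[a]]) for a in alleles},
    )


def flag_null_loci(estimates, hwe_results, r_threshold: float = 0.05,
                   p_threshold: float = 0.05) -> list:
    """Loci flagged as null-carrying: r_hat >= r_threshold AND a significant
    HWE departure in the heterozygote-deficit direction."""
    hwe_by_key = {(h.locus, h.population): h for h in hwe_results}
    flagged = []
    for est in estimates:
        h = hwe_by_key.get((est.locus, est.population))
        if est.r_hat >= r_threshold and h is not None \
                and h.p_value < p_threshold and h.het_deficit > 0:
            flagged.append(est)
    return flagged


def apply_null_correction(ds: GenotypeDataset, estimates,
                          threshold: float = 0.05,
                          seed: int = 0) -> GenotypeDataset:
    """Recode null-carrying loci so the null segregates as a visible allele.

    At each (locus, population) with ``r_hat >= threshold``: blanks become
    null homozygotes ``(null, null)``, and each visible homozygote (a, a)
    is recoded to the heterozygote (a, null) with the posterior
    probability 2r/(p_a + 2r) that it truly carries one null copy.  The
    corrected pairs are marked on the dataset, making the operation
    idempotent: re-applying any estimate to an already corrected pair is a
    no-op.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must be in [0, 1]")
    rng = np.random.default_rng(seed)
    todo = {}
    for est in estimates:
        key = (est.locus, est.population)
        if est.r_hat >= threshold and key not in ds.corrected_loci:
            todo[key] = est
    if not todo:
        out = GenotypeDataset(
            [replace(i, genotype=dict(i.genotype)) for i in ds.individuals],
            ds.registry, dict(ds.populations), set(ds.corrected_loci),
        )
        return out

    new_individuals = []
    for ind in ds.individuals:
        genotype = dict(ind.genotype)
        for (locus, pop), est in todo.items():
            if pop not in ("all", ind.population) or locus not in genotype:
                continue
            cell = genotype[locus]
            if cell == (MISSING, MISSING):
                genotype[locus] = (NULL_ALLELE, NULL_ALLELE)
            elif cell[0] == cell[1] and cell[0] != MISSING:
                a = cell[0]
                p_a = (est.visible_frequencies or {}).get(a, 0.0)
                denom = p_a + 2 * est.r_hat
                w = 2 * est.r_hat / denom if denom > 0 else 0.0
                if rng.random() < w:
                    genotype[locus] = (NULL_ALLELE, a)
        new_individuals.append(replace(ind, genotype=genotype))
    corrected = set(ds.corrected_loci) | set(todo)
    return GenotypeDataset(new_individuals, ds.registry, dict(ds.populations),
                           corrected)
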