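"""Multilocus-genotype clonality inference.

The core question: when the same multilocus genotype (MLG) recurs in a
sample, is that repetition compatible with independent sexual reproduction
or does it indicate clonal transmission?  The chain implemented here:

1. exact MLG indexing (:func:`index_mlgs`);
2. missing-data-aware merging of partial MLGs that differ only through
   unscored loci (:func:`merge_mlgs`);
3. round-robin allele frequencies and per-locus F_IS, so repeated clonal
   copies do not inflate their own allele frequencies
   (:func:`round_robin_frequencies`, :func:`estimate_fis`);
4. P_GEN — the probability that one sexual reproductive event produces a
   given MLG under inbreeding-adjusted Hardy-Weinberg genotype
   proportions (:func:`p_gen`);
5. P_SEX — the binomial tail probability that the n_obs observed copies
   of the MLG arose from that many independent sexual events
   (:func:`p_sex`);
6. the clone verdict, combining a minimum copy count with the P_SEX
   significance threshold (:func:`call_clones`).

Records may be ordinary diploids or self-doubled haploid subgenomes; for
the latter the statistics reduce exactly to their haploid counterparts
(round-robin F_IS = 1 and P_GEN = product of allele frequencies), which is
what justifies analysing clonal subgenomes with diploid machinery.

:class:`CloneDetector` packages the chain as a scikit-learn style
estimator (``fit`` -> ``reports_``, ``labels_``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .model import MISSING, IndividualRecord, ValidationError

_BLANK = (MISSING, MISSING)


@dataclass(frozen=True)
class MLGKey:
    """Canonical multilocus genotype: ordered loci, sorted allele pairs."""

    loci: tuple
    states: tuple  # one (a1, a2) pair per locus; (0, 0) = missing

    def scored_loci(self) -> tuple:
        return tuple(l for l, s in zip(self.loci, self.states) if s != _BLANK)

    def state(self, locus: str) -> tuple[int, int]:
        return self.states[self.loci.index(locus)]

    def __lt__(self, other: "MLGKey") -> bool:
        return self.states < other.states


def mlg_key(record: IndividualRecord, loci: Sequence[str]) -> MLGKey:
    return MLGKey(tuple(loci), tuple(record.cell(l) for l in loci))


@dataclass
class CloneReport:
    """One (possibly merged) MLG with its clonality statistics."""

    clone_id: str
    member_mlgs: list
    members: list  # individual ids
    consensus: MLGKey
    count_total: int
    count_per_population: dict
    member_records: list = field(default_factory=list)
    p_gen: float | None = None
    p_sex_per_population: dict = field(default_factory=dict)
    p_sex_global: float | None = None
    verdict: str | None = None
    notes: list = field(default_factory=list)

    @property
    def p_sex_min(self) -> float | None:
        values = list(self.p_sex_per_population.values())
        if self.p_sex_global is not None:
            values.append(self.p_sex_global)
        return min(values) if values else None


@dataclass
class FisEntry:
    fis: float
    frequencies: dict
    n: int


FisTable = dict  # locus -> FisEntry


# ---------------------------------------------------------------------------
# MLG indexing and merging
# ---------------------------------------------------------------------------

def index_mlgs(records: Sequence[IndividualRecord],
               loci: Sequence[str] | None = None) -> dict:
    """Group records by exact MLG.

    Records differing only at loci where either is missing are *not*
    grouped here — missing-aware grouping is :func:`merge_mlgs`.  Output
    ordering is deterministic (sorted by key states).
    """
    if loci is None:
        locus_sets = {tuple(sorted(r.genotype)) for r in records}
        if len(locus_sets) > 1:
            raise ValidationError("records do not share a locus set; pass loci=")
        loci = sorted(records[0].genotype) if records else []
    groups: dict[MLGKey, list] = {}
    for rec in records:
        groups.setdefault(mlg_key(rec, loci), []).append(rec)
    return dict(sorted(groups.items(), key=lambda kv: kv[0].states))


def _compatible(a: MLGKey, b: MLGKey, min_shared_loci: int) -> bool:
    shared = 0
    for sa, sb in zip(a.states, b.states):
        if sa == _BLANK or sb == _BLANK:
            continue
        if sa != sb:
            return False
        shared += 1
    return shared >= min_shared_loci


def _consensus(keys: Sequence[MLGKey]) -> MLGKey:
    loci = keys[0].loci
    states = []
    for i in range(len(loci)):
        scored = {k.states[i] for k in keys if k.states[i] != _BLANK}
        if len(scored) > 1:
            raise ValidationError("conflicting states in merge candidate")
        states.append(scored.pop() if scored else _BLANK)
    return MLGKey(loci, tuple(states))


def merge_mlgs(groups: Mapping, min_shared_loci: int = 5) -> list[CloneReport]:
    """Merge exact MLGs whose differences are explainable by missing data.

    Two MLGs are compatible iff they conflict at no co-scored locus and
    share at least ``min_shared_loci`` co-scored loci.  A connected
    component of the compatibility graph is merged only when it is a
    clique (pairwise compatibility guarantees a single conflict-free
    consensus); otherwise it is split into maximal cliques, assigned
    greedily — largest total membership first, ties by lexicographic
    consensus — and the split is noted on the resulting reports.
    """
    keys = list(groups)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(keys)))
    for i, j in itertools.combinations(range(len(keys)), 2):
        if _compatible(keys[i], keys[j], min_shared_loci):
            graph.add_edge(i, j)

    reports: list[CloneReport] = []
    for component in nx.connected_components(graph):
        comp = sorted(component)
        n = len(comp)
        is_clique = all(
            graph.has_edge(i, j) for i, j in itertools.combinations(comp, 2)
        )
        if is_clique:
            parts = [comp]
            notes = []
        else:
            cliques = [sorted(c) for c in nx.find_cliques(graph.subgraph(comp))]
            def _priority(clique):
                size = sum(len(groups[keys[i]]) for i in clique)
                return (-size, _consensus([keys[i] for i in clique]).states)
            cliques.sort(key=_priority)
            assigned: set[int] = set()
            parts = []
            for clique in cliques:
                rest = [i for i in clique if i not in assigned]
                if rest:
                    parts.append(rest)
                    assigned.update(rest)
            notes = [
                f"component of {n} MLGs was not a clique; split into "
                f"{len(parts)} maximal-clique groups (largest membership "
                f"first, then lexicographic consensus)"
            ]
        for part in parts:
            part_keys = [keys[i] for i in part]
            members = [rec for k in part_keys for rec in groups[k]]
            members.sort(key=lambda r: r.id)
            counts: dict[str, int] = {}
            for rec in members:
                counts[rec.population] = counts.get(rec.population, 0) + 1
            reports.append(
                CloneReport(
                    clone_id="",  # assigned after sorting
                    member_mlgs=part_keys,
                    members=[r.id for r in members],
                    member_records=members,
                    consensus=_consensus(part_keys),
                    count_total=len(members),
                    count_per_population=counts,
                    notes=list(notes),
                )
            )
    reports.sort(key=lambda r: (-r.count_total, r.consensus.states))
    for i, rep in enumerate(reports, start=1):
        rep.clone_id = f"MLG{i:03d}"
    return reports


# ---------------------------------------------------------------------------
# Round-robin frequencies and F_IS
# ---------------------------------------------------------------------------

def _round_robin_representatives(records: Sequence[IndividualRecord],
                                 locus: str,
                                 loci: Sequence[str]) -> list[IndividualRecord]:
    others = [l for l in loci if l != locus]
    if not others:
        raise ValidationError(
            "round-robin frequencies are undefined on a single-locus dataset"
        )
    seen: dict[tuple, IndividualRecord] = {}
    for rec in sorted(records, key=lambda r: r.id):
        sub = tuple(rec.cell(l) for l in others)
        if sub not in seen:
            seen[sub] = rec
    return list(seen.values())


def round_robin_frequencies(records: Sequence[IndividualRecord], locus: str,
                            loci: Sequence[str] | None = None) -> dict:
    """Allele frequencies at ``locus`` from one representative per distinct
    sub-MLG defined over the remaining loci.

    Collapsing repeated sub-MLGs removes the pseudo-replication a clone
    would otherwise introduce into its own allele frequencies.
    """
    if loci is None:
        loci = sorted({l for r in records for l in r.genotype})
    reps = _round_robin_representatives(records, locus, loci)
    counts: dict[int, int] = {}
    for rec in reps:
        for allele in rec.alleles_at(locus):
            counts[allele] = counts.get(allele, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {a: c / total for a, c in sorted(counts.items())}


def estimate_fis(records: Sequence[IndividualRecord],
                 loci: Sequence[str] | None = None,
                 frequencies: Mapping | None = None) -> FisTable:
    """Per-locus F_IS = 1 - H_OBS / H_EXP from round-robin subsamples.

    H_EXP = 1 - sum(p^2) with p the round-robin frequencies; H_OBS is the
    heterozygote fraction among fully scored round-robin representatives.
    Monomorphic loci (H_EXP = 0) give F_IS = 0 by convention.
    """
    if loci is None:
        loci = sorted({l for r in records for l in r.genotype})
    table: FisTable = {}
    for locus in loci:
        freqs = (frequencies or {}).get(locus)
        if freqs is None:
            freqs = round_robin_frequencies(records, locus, loci)
        reps = _round_robin_representatives(records, locus, loci)
        full = [r for r in reps if r.fully_scored(locus)]
        h_exp = 1.0 - sum(p * p for p in freqs.values())
        if h_exp <= 0.0 or not full:
            fis = 0.0
        else:
            h_obs = sum(
                1 for r in full if r.cell(locus)[0] != r.cell(locus)[1]
            ) / len(full)
            fis = float(np.clip(1.0 - h_obs / h_exp, -1.0, 1.0))
        table[locus] = FisEntry(fis=fis, frequencies=dict(freqs), n=len(reps))
    return table


# ---------------------------------------------------------------------------
# P_GEN / P_SEX
# ---------------------------------------------------------------------------

def p_gen(mlg: MLGKey, frequencies: Mapping, fis: FisTable | None = None) -> float:
    """Probability that a single sexual event generates this MLG.

    Product over scored loci of the inbreeding-adjusted genotype
    probability: ``p_a^2 + p_a (1 - p_a) F`` for homozygotes and
    ``2 p_a p_b (1 - F)`` for heterozygotes, each factor clamped to
    [0, 1].  A half-scored locus ``(a, -)`` contributes the single-copy
    factor ``p_a``; missing loci are skipped.  Alleles absent from the
    frequency table are an error — pseudo-counted tables must be used.
    """
    out = 1.0
    for locus, state in zip(mlg.loci, mlg.states):
        if state == _BLANK:
            continue
        freqs = frequencies.get(locus)
        if freqs is None:
            raise ValidationError(f"no frequency table for locus {locus}")
        f = fis[locus].fis if fis is not None and locus in fis else 0.0
        a1, a2 = state
        scored = [a for a in state if a != MISSING]
        for a in scored:
            if a not in freqs:
                raise ValidationError(
                    f"allele {a} at {locus} absent from frequency table; "
                    f"use pseudo-counted tables"
                )
        if len(scored) == 1:
            factor = freqs[scored[0]]
        elif a1 == a2:
            p = freqs[a1]
            factor = p * p + p * (1.0 - p) * f
        else:
            factor = 2.0 * freqs[a1] * freqs[a2] * (1.0 - f)
        out *= float(np.clip(factor, 0.0, 1.0))
    return out


def p_sex(p_gen_value: float, n_obs: int, n_sample: int,
          tail_from_n_obs: bool = True) -> float:
    """Binomial tail probability that an MLG seen ``n_obs`` times in
    ``n_sample`` genomes arose from that many independent sexual events.

    Computed as P[X >= n_obs] for X ~ Binomial(n_sample, P_GEN) via the
    log-safe survival function.  ``tail_from_n_obs=False`` switches to the
    alternative P[X >= n_obs - 1] convention.
    """
    if not 0.0 <= p_gen_value <= 1.0:
        raise ValidationError("p_gen_value must be in [0, 1]")
    if not 1 <= n_obs <= n_sample:
        raise ValidationError("need 1 <= n_obs <= n_sample")
    k = n_obs if tail_from_n_obs else max(n_obs - 1, 1)
    return float(stats.binom.sf(k - 1, n_sample, p_gen_value))


def call_clones(reports: Sequence[CloneReport], alpha: float = 0.05,
                min_copies: int = 3) -> list[CloneReport]:
    """Fill clone verdicts.

    ``clonal``  : count >= min_copies and min P_SEX <= alpha — repeated
    beyond the minimum copy rule *and* beyond sexual expectation.
    ``putative``: repeated (count >= 2) with either signal but not both.
    ``sexual``  : everything else.
    """
    for rep in reports:
        ps = rep.p_sex_min
        significant = ps is not None and ps <= alpha
        if rep.count_total >= min_copies and significant:
            rep.verdict = "clonal"
        elif rep.count_total >= 2 and (significant or rep.count_total >= min_copies):
            rep.verdict = "putative"
        else:
            rep.verdict = "sexual"
    return list(reports)


# ---------------------------------------------------------------------------
# Diversity summaries
# ---------------------------------------------------------------------------

@dataclass
class LocusSummary:
    locus: str
    an: int
    h_obs: float
    h_exp: float
    n: int


def locus_summaries(records: Sequence[IndividualRecord],
                    loci: Sequence[str] | None = None) -> dict:
    """AN, H_OBS and unbiased H_EXP per locus.

    AN counts distinct scored alleles; H_OBS is the heterozygote fraction
    among fully scored individuals; H_EXP is Nei's unbiased estimate
    (n_c/(n_c-1)) (1 - sum p^2) over the n_c scored allele copies.
    """
    if loci is None:
        loci = sorted({l for r in records for l in r.genotype})
    out = {}
    for locus in loci:
        copies = [a for r in records for a in r.alleles_at(locus)]
        full = [r for r in records if r.fully_scored(locus)]
        if not copies:
            out[locus] = LocusSummary(locus, 0, 0.0, 0.0, 0)
            continue
        values, counts = np.unique(copies, return_counts=True)
        p = counts / counts.sum()
        n_c = len(copies)
        h_exp = (n_c / (n_c - 1)) * (1.0 - float(np.sum(p * p))) if n_c > 1 else 0.0
        h_obs = (
            sum(1 for r in full if r.cell(locus)[0] != r.cell(locus)[1]) / len(full)
            if full else 0.0
        )
        out[locus] = LocusSummary(locus, int(len(values)), h_obs, h_exp,
                                  len(full))
    return out


def genotypic_richness(n_mlgs: int, n_records: int) -> float:
    """Scaled clonal diversity (G - 1) / (N - 1)."""
    if n_records < 2:
        return 0.0
    return (n_mlgs - 1) / (n_records - 1)


# ---------------------------------------------------------------------------
# The full chain as an estimator
# ---------------------------------------------------------------------------

def _pseudo_counted(frequencies: dict, records: Sequence[IndividualRecord],
                    loci: Sequence[str], eps_scale: float = 0.5) -> dict:
    """Ensure every allele observed in ``records`` has a positive frequency
    by adding a pseudo-count eps = eps_scale / (2N) before renormalizing."""
    n = max(len(records), 1)
    eps = eps_scale / (2 * n)
    out = {}
    for locus in loci:
        freqs = dict(frequencies.get(locus, {}))
        observed = {a for r in records for a in r.alleles_at(locus)}
        for a in observed:
            freqs[a] = freqs.get(a, 0.0) + eps
        total = sum(freqs.values())
        out[locus] = {a: v / total for a, v in freqs.items()} if total else {}
    return out


class CloneDetector(BaseEstimator):
    """Scikit-learn style front end for the clonality chain.

    Parameters
    ----------
    loci : sequence of str, optional
        Locus set to analyse; defaults to the loci shared by the records.
    alpha : float
        P_SEX significance threshold for the clone verdict.
    min_copies : int
        Minimum number of identical copies before an MLG can be ``clonal``.
    min_shared_loci : int
        Minimum co-scored loci for missing-data-aware MLG merging.
    tail_from_n_obs : bool
        P_SEX tail convention (see :func:`p_sex`).
    pseudo_count : float
        Scale of the pseudo-count added so every observed allele has a
        positive round-robin frequency.

    Attributes (after ``fit``)
    --------------------------
    reports_ : list of CloneReport, labels_ : ndarray of clone indices per
    record, frequencies_ : pseudo-counted round-robin tables,
    fis_ : FisTable, n_mlgs_ : exact MLG count before merging.
    """

    def __init__(self, loci=None, alpha=0.05, min_copies=3, min_shared_loci=5,
                 tail_from_n_obs=True, pseudo_count=0.5):
        self.loci = loci
        self.alpha = alpha
        self.min_copies = min_copies
        self.min_shared_loci = min_shared_loci
        self.tail_from_n_obs = tail_from_n_obs
        self.pseudo_count = pseudo_count

    def fit(self, X: Sequence[IndividualRecord], y=None):
        records = list(X)
        if not records:
            raise ValidationError("no records to analyse")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must be in [0, 1]")
        loci = list(self.loci) if self.loci is not None else sorted(
            set.intersection(*(set(r.genotype) for r in records))
        )
        if len(loci) < 2:
            raise ValidationError("need at least 2 loci")
        groups = index_mlgs(records, loci)
        self.n_mlgs_ = len(groups)
        reports = merge_mlgs(groups, min_shared_loci=self.min_shared_loci)

        raw_freqs = {l: round_robin_frequencies(records, l, loci) for l in loci}
        self.frequencies_ = _pseudo_counted(raw_freqs, records, loci,
                                            self.pseudo_count)
        self.fis_ = estimate_fis(records, loci, frequencies=self.frequencies_)

        pop_sizes: dict[str, int] = {}
        for rec in records:
            pop_sizes[rec.population] = pop_sizes.get(rec.population, 0) + 1
        n_total = len(records)
        for rep in reports:
            rep.p_gen = p_gen(rep.consensus, self.frequencies_, self.fis_)
            rep.p_sex_global = p_sex(rep.p_gen, rep.count_total, n_total,
                                     self.tail_from_n_obs)
            rep.p_sex_per_population = {
                pop: p_sex(rep.p_gen, count, pop_sizes[pop],
                           self.tail_from_n_obs)
                for pop, count in rep.count_per_population.items()
            }
        self.reports_ = call_clones(reports, alpha=self.alpha,
                                    min_copies=self.min_copies)
        label_of = {}
        for idx, rep in enumerate(self.reports_):
            for member in rep.members:
                label_of[member] = idx
        self.labels_ = np.asarray([label_of[r.id] for r in records])
        self.loci_ = loci
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
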