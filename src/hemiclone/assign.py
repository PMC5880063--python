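"""Taxon assignment and a supervised hybrid-index (admixture) estimator.

Taxon calls use diagnostic loci directly: per locus the allele composition
is classified as LL, RR or LR from allele species specificity, and the
majority class across informative loci is the call, with discordant loci
listed rather than reinterpreted.

The hybrid index q is estimated by a supervised two-source likelihood:
given parental allele-frequency panels f_L and f_R (from reference LL and
RR individuals), each scored allele copy a contributes
log(q f_R(a) + (1-q) f_L(a)) and q-hat maximizes the sum over copies on
[0, 1].  Sexual individuals sit near 0 or 1, hybrids near 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .model import (
    MISSING,
    AlleleRegistry,
    IndividualRecord,
    ValidationError,
)


@dataclass
class TaxonCall:
    individual: str
    call: str  # "LL", "RR", "RL" or "ambiguous"
    discordant_loci: list = field(default_factory=list)
    support: float = 0.0
    n_informative: int = 0


@dataclass
class AdmixtureResult:
    individual: str
    q: float
    loglik: float
    n_alleles_used: int
    flat_likelihood: bool = False


def _locus_class(alleles, registry: AlleleRegistry, locus: str) -> str | None:
    """Classify one locus' allele composition; None if uninformative."""
    specs = {registry.classify(locus, a) for a in alleles}
    has_l = "L" in specs
    has_r = "R" in specs
    if has_l and has_r:
        return "RL"
    if has_l:
        return "LL"
    if has_r:
        return "RR"
    return None


def assign_taxon(ind: IndividualRecord, registry: AlleleRegistry,
                 min_support: float = 0.75) -> TaxonCall:
    """Majority taxon call over informative (species-classified) loci.

    Loci amplifying in a single parental genome are skipped: they cannot
    discriminate a hybrid from the pure species whose genome they amplify
    in.  ``support`` is the fraction of informative loci agreeing with the
    majority class; the call is ``ambiguous`` when support falls below
    ``min_support`` or no locus is informative.
    """
    votes: dict[str, list] = {"LL": [], "RR": [], "RL": []}
    for locus in ind.genotype:
        alleles = ind.alleles_at(locus)
        if not alleles:
            continue
        if locus in registry and len(registry.locus(locus).amplifies_in) < 2:
            continue
        cls = _locus_class(alleles, registry, locus)
        if cls is not None:
            votes[cls].append(locus)
    n_informative = sum(len(v) for v in votes.values())
    if n_informative == 0:
        return TaxonCall(ind.id, "ambiguous", [], 0.0, 0)
    best = max(votes, key=lambda c: (len(votes[c]), c))
    support = len(votes[best]) / n_informative
    discordant = sorted(
        locus for cls, loci in votes.items() if cls != best for locus in loci
    )
    call = best if support >= min_support else "ambiguous"
    return TaxonCall(ind.id, call, discordant, support, n_informative)


def reference_frequencies(records: Sequence[IndividualRecord],
                          registry: AlleleRegistry,
                          eps_scale: float = 0.5) -> dict:
    """Allele-frequency table from a reference panel with a pseudo-count
    eps = eps_scale / (2N) on every registered allele, so no scored allele
    ever has zero likelihood."""
    if not records:
        raise ValidationError("empty reference panel")
    loci = sorted({l for r in records for l in r.genotype})
    n = len(records)
    eps = eps_scale / (2 * n)
    out = {}
    for locus in loci:
        counts: dict[int, float] = {
            a: eps for a in registry.alleles(locus)
        }
        for rec in records:
            for a in rec.alleles_at(locus):
                counts[a] = counts.get(a, eps) + 1.0
        total = sum(counts.values())
        out[locus] = {a: c / total for a, c in counts.items()} if total else {}
    return out


def estimate_admixture(ind: IndividualRecord, freqs_L: Mapping,
                       freqs_R: Mapping, tol: float = 1e-6) -> AdmixtureResult:
    """Maximum-likelihood hybrid index on [0, 1] (R-genepool ancestry).

    The per-copy likelihood q f_R + (1-q) f_L is linear in q, so the total
    log-likelihood is concave; a bounded 1-D optimization to ``tol``
    suffices.  Copies with f_R = f_L carry no information; if no copy is
    informative the likelihood is flat and flagged as such.
    """
    if not freqs_L or not freqs_R:
        raise ValidationError("empty parental frequency tables")
    fr = []
    fl = []
    for locus in ind.genotype:
        if locus not in freqs_L or locus not in freqs_R:
            continue
        for a in ind.alleles_at(locus):
            l = freqs_L[locus].get(a, 0.0)
            r = freqs_R[locus].get(a, 0.0)
            if l > 0.0 or r > 0.0:
                fl.append(l)
                fr.append(r)
    n_used = len(fr)
    if n_used == 0:
        return AdmixtureResult(ind.id, 0.5, float("nan"), 0, True)
    fl_arr = np.asarray(fl)
    fr_arr = np.asarray(fr)

    def nll(q: float) -> float:
        mix = q * fr_arr + (1.0 - q) * fl_arr
        if np.any(mix <= 0.0):
            return np.inf
        return -float(np.sum(np.log(mix)))

    flat = bool(np.allclose(fl_arr, fr_arr))
    if flat:
        q_hat = 0.5
    else:
        res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": tol})
        q_hat = float(res.x)
        # boundary polish: the optimum may sit exactly at 0 or 1
        for cand in (0.0, 1.0):
            if nll(cand) <= nll(q_hat):
                q_hat = cand
    return AdmixtureResult(ind.id, q_hat, -nll(q_hat), n_used, flat)


class AdmixtureEstimator(BaseEstimator):
    """Supervised two-source admixture model, scikit-learn style.

    ``fit`` takes reference records and taxon labels (only ``LL`` and
    ``RR`` rows train the parental panels); ``predict`` returns q-hat per
    record; ``predict_result`` returns full :class:`AdmixtureResult`
    objects.
    """

    def __init__(self, registry: AlleleRegistry | None = None,
                 eps_scale: float = 0.5, tol: float = 1e-6):
        self.registry = registry
        self.eps_scale = eps_scale
        self.tol = tol

    def fit(self, X: Sequence[IndividualRecord], y: Sequence[str] | None = None):
        labels = list(y) if y is not None else [r.taxon_label for r in X]
        if self.registry is None:
            raise ValidationError("AdmixtureEstimator requires a registry")
        ll = [r for r, lab in zip(X, labels) if lab == "LL"]
        rr = [r for r, lab in zip(X, labels) if lab == "RR"]
        if not ll or not rr:
            raise ValidationError("need both LL and RR reference individuals")
        self.freqs_L_ = reference_frequencies(ll, self.registry, self.eps_scale)
        self.freqs_R_ = reference_frequencies(rr, self.registry, self.eps_scale)
        return self

    def predict_result(self, X: Sequence[IndividualRecord]) -> list:
        return [
            estimate_admixture(r, self.freqs_L_, self.freqs_R_, self.tol)
            for r in X
        ]

    def predict(self, X: Sequence[IndividualRecord]) -> np.ndarray:
        return np.asarray([res.q for res in self.predict_result(X)])
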