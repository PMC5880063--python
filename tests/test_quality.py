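"""HWE screening, null-allele estimation and correction."""

import itertools

import numpy as np
import pytest
from scipy import stats

import hemiclone as hc
from hemiclone.model import NULL_ALLELE

from conftest import make_record


def _records_from_cells(cells, locus="l1"):
    return [make_record(f"i{k}", **{locus: c}) for k, c in enumerate(cells)]


def _hwe_sample(rng, n, freqs=(0.4, 0.3, 0.2, 0.1)):
    alleles = 100 + 2 * np.arange(len(freqs))
    draws = rng.choice(alleles, size=(n, 2), p=freqs)
    return [tuple(sorted(pair)) for pair in draws]


def enumerate_hwe_p(cells):
    """Exact permutation-test oracle for tiny samples: enumerate every
    perfect matching of the pooled (distinguishable) allele copies into
    individuals — the same distribution as random pairing."""
    pool = [a for c in cells for a in c]
    n = len(cells)
    k_states = sorted(set(pool))
    idx = {a: i for i, a in enumerate(k_states)}
    freqs = np.bincount([idx[a] for a in pool], minlength=len(k_states))
    freqs = freqs / freqs.sum()

    def config_prob(pairs):
        from scipy.special import gammaln
        counts = {}
        for a, b in pairs:
            g = tuple(sorted((a, b)))
            counts[g] = counts.get(g, 0) + 1
        logp = gammaln(n + 1)
        for g, c in counts.items():
            p = freqs[idx[g[0]]] ** 2 if g[0] == g[1] else \
                2 * freqs[idx[g[0]]] * freqs[idx[g[1]]]
            logp += c * np.log(p) - gammaln(c + 1)
        return logp

    def matchings(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for i in range(len(rest)):
            partner = rest[i]
            remainder = rest[:i] + rest[i + 1:]
            for m in matchings(remainder):
                yield [(first, partner)] + m

    observed = config_prob(cells)
    total = 0
    hits = 0
    for pairs in matchings(pool):
        total += 1
        if config_prob(pairs) <= observed + 1e-9:
            hits += 1
    return hits / total


class TestHweTest:
    def test_monomorphic_locus_p_one(self):
        records = _records_from_cells([(100, 100)] * 10)
        assert hc.hwe_test(records, "l1", n_reps=100).p_value == 1.0

    def test_all_homozygote_sample_strongly_rejected(self):
        # p = q = 0.5 but zero heterozygotes among 50 diploids
        cells = [(100, 100)] * 25 + [(102, 102)] * 25
        res = hc.hwe_test(_records_from_cells(cells), "l1", n_reps=5000,
                          seed=1)
        assert res.p_value < 0.001
        assert res.het_deficit > 0.4

    def test_matches_enumeration_oracle_small_samples(self):
        rng = np.random.default_rng(3)
        for trial in range(4):
            cells = _hwe_sample(rng, 5, freqs=(0.5, 0.5))
            exact = enumerate_hwe_p(cells)
            mc = hc.hwe_test(_records_from_cells(cells), "l1",
                             n_reps=20000, seed=trial).p_value
            assert mc == pytest.approx(exact, abs=0.02)

    def test_p_uniform_under_null(self):
        # under HWE the Monte-Carlo p-value is approximately uniform
        rng = np.random.default_rng(5)
        pvals = [
            hc.hwe_test(
                _records_from_cells(_hwe_sample(rng, 100)), "l1",
                n_reps=200, seed=int(rng.integers(2 ** 31)),
            ).p_value
            for _ in range(200)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(7)
        records = _records_from_cells(_hwe_sample(rng, 30))
        a = hc.hwe_test(records, "l1", n_reps=500, seed=42)
        b = hc.hwe_test(records, "l1", n_reps=500, seed=42)
        assert a.p_value == b.p_value


def _null_sample(rng, n, r, freqs=(0.5, 0.3, 0.2)):
    """HWE sample with a null allele at frequency r: null homozygotes are
    blank, null heterozygotes apparent homozygotes."""
    visible = 100 + 2 * np.arange(len(freqs))
    p = np.asarray(list(freqs)) * (1 - r)
    states = np.concatenate([visible, [0]])
    probs = np.concatenate([p, [r]])
    draws = states[rng.choice(len(states), size=(n, 2), p=probs)]
    cells = []
    for a, b in draws:
        scored = [x for x in (a, b) if x != 0]
        if not scored:
            cells.append((0, 0))
        elif len(scored) == 1:
            cells.append((scored[0], scored[0]))  # apparent homozygote
        else:
            cells.append(tuple(sorted(scored)))
    return cells


class TestNullAlleleEstimate:
    def test_no_deficit_no_blanks_gives_zero(self):
        cells = [(100, 102)] * 10 + [(100, 100)] * 5 + [(102, 102)] * 5
        est = hc.estimate_null_allele_freq(_records_from_cells(cells), "l1")
        assert est.r_hat == 0.0

    def test_all_blank_gives_one(self):
        est = hc.estimate_null_allele_freq(
            _records_from_cells([(0, 0)] * 12), "l1"
        )
        assert est.r_hat == 1.0

    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        cells = _null_sample(rng, 2000, r=0.2)
        est = hc.estimate_null_allele_freq(_records_from_cells(cells), "l1")
        assert est.r_hat == pytest.approx(0.2, abs=0.03)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(13)
        cells = _null_sample(rng, 300, r=0.15)
        relabel = {100: 500, 102: 300, 104: 700, 0: 0}
        swapped = [tuple(sorted((relabel[a], relabel[b]))) for a, b in cells]
        e1 = hc.estimate_null_allele_freq(_records_from_cells(cells), "l1")
        e2 = hc.estimate_null_allele_freq(_records_from_cells(swapped), "l1")
        assert e1.r_hat == pytest.approx(e2.r_hat, abs=1e-6)

    def test_single_visible_allele_matches_moment_estimator(self):
        # with one visible allele the heterozygote classes are empty and
        # the ML estimate collapses to sqrt(blank fraction)
        cells = [(100, 100)] * 84 + [(0, 0)] * 16
        est = hc.estimate_null_allele_freq(_records_from_cells(cells), "l1")
        assert est.r_hat == pytest.approx(np.sqrt(0.16), abs=1e-3)


class TestNullCorrection:
    def _flagged(self, records, locus="l1"):
        return [hc.estimate_null_allele_freq(records, locus)]

    def test_below_threshold_unchanged(self, diagnostic_registry):
        records = [make_record(f"i{k}", both1=(200, 202)) for k in range(10)]
        ds = hc.GenotypeDataset(records, diagnostic_registry)
        est = hc.NullAlleleEstimate("both1", "all", 0.01, 0, 10)
        out = hc.apply_null_correction(ds, [est], threshold=0.05)
        assert out == ds

    def test_blanks_become_null_homozygotes(self, diagnostic_registry):
        records = [make_record("a", both1=(0, 0)),
                   make_record("b", both1=(200, 202))]
        ds = hc.GenotypeDataset(records, diagnostic_registry)
        est = hc.NullAlleleEstimate("both1", "all", 0.3, 1, 2,
                                    visible_frequencies={200: 0.4, 202: 0.3})
        out = hc.apply_null_correction(ds, [est], threshold=0.05)
        assert out.individuals[0].cell("both1") == (NULL_ALLELE, NULL_ALLELE)

    def test_idempotent(self, diagnostic_registry):
        records = [make_record(f"i{k}",
                               both1=((0, 0) if k % 3 == 0 else (200, 200)))
                   for k in range(12)]
        ds = hc.GenotypeDataset(records, diagnostic_registry)
        est = hc.NullAlleleEstimate("both1", "all", 0.3, 4, 12,
                                    visible_frequencies={200: 0.7})
        once = hc.apply_null_correction(ds, [est], threshold=0.05, seed=2)
        twice = hc.apply_null_correction(once, [est], threshold=0.05, seed=3)
        assert once == twice

    def test_corrected_data_rescreen_clean(self, diagnostic_registry):
        # simulated null locus r = 0.2: after correction the HWE p-value
        # distribution is uniform again
        rng = np.random.default_rng(19)
        pvals = []
        for k in range(60):
            cells = _null_sample(rng, 150, r=0.2)
            records = [make_record(f"i{j}", both1=c)
                       for j, c in enumerate(cells)]
            ds = hc.GenotypeDataset(records, diagnostic_registry)
            est = hc.estimate_null_allele_freq(records, "both1")
            est = hc.NullAlleleEstimate("both1", "all", est.r_hat,
                                        est.blanks_observed, est.n,
                                        visible_frequencies=est.visible_frequencies)
            out = hc.apply_null_correction(ds, [est], threshold=0.05,
                                           seed=int(rng.integers(2 ** 31)))
            pvals.append(
                hc.hwe_test(out.individuals, "both1", n_reps=200,
                            seed=int(rng.integers(2 ** 31))).p_value
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        # and the null estimator no longer reports a null allele
        assert np.median([
            hc.estimate_null_allele_freq(
                hc.apply_null_correction(
                    hc.GenotypeDataset(
                        [make_record(f"i{j}", both1=c)
                         for j, c in enumerate(_null_sample(rng, 300, 0.2))],
                        diagnostic_registry),
                    [hc.NullAlleleEstimate("both1", "all", 0.2, 0, 300,
                                           visible_frequencies={100: 0.4,
                                                                102: 0.24,
                                                                104: 0.16})],
                    seed=j).individuals, "both1").r_hat
            for j in range(10)
        ]) < 0.05
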