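"""Site dosage likelihoods, parental posteriors and Mendelian MAP correction."""

import itertools
import math

import numpy as np
import pytest

from famphase.genotypes import (
    map_population_genotypes,
    parental_genotype_posterior,
    site_dosage_likelihood,
)
from famphase.popdata import MISSING
from famphase.transmission import offspring_dosage_pmf


def brute_likelihood(evidence, k, g):
    """Oracle: average over explicit homolog assignments of every call."""
    hap = [1] * g + [0] * (k - g)
    total = 1.0
    for call, err in evidence:
        p = 0.0
        for h in hap:  # the call's read came from homolog h uniformly
            p += (1 - err) if call == h else err
        total *= p / k
    return total


def test_likelihood_examples():
    assert site_dosage_likelihood([(0, 1e-9)] * 5, 4, 0) == pytest.approx(1.0)
    assert site_dosage_likelihood([(1, 0.0)], 4, 2) == pytest.approx(0.5)
    want = (0.25 * 0.99 + 0.75 * 0.01) * (0.75 * 0.99 + 0.25 * 0.01)
    assert site_dosage_likelihood([(1, 0.01), (0, 0.01)], 4, 1) == pytest.approx(want)


@pytest.mark.parametrize("k", [2, 4])
def test_likelihood_matches_homolog_enumeration(k):
    rng = np.random.default_rng(0)
    for _ in range(20):
        evidence = [
            (int(rng.integers(0, 2)), float(rng.uniform(0.001, 0.4)))
            for _ in range(rng.integers(1, 6))
        ]
        for g in range(k + 1):
            assert site_dosage_likelihood(evidence, k, g) == pytest.approx(
                brute_likelihood(evidence, k, g)
            )


def test_parental_posterior_uniform_without_reads():
    post = parental_genotype_posterior([], [], 4, 4)
    assert post.shape == (5, 5)
    assert np.allclose(post, 1 / 25)


def test_parental_posterior_normalized_and_peaked():
    rng = np.random.default_rng(1)
    ev_m = [(1, 0.001)] * 50 + [(0, 0.001)] * 50
    ev_f = [(int(rng.integers(0, 2)), 0.05) for _ in range(20)]
    post = parental_genotype_posterior(ev_m, ev_f, 4, 4)
    assert post.sum() == pytest.approx(1.0)
    # 50/50 alt/ref at low error pins the mother at duplex
    assert post.sum(axis=1).argmax() == 2
    brute = np.array(
        [site_dosage_likelihood(ev_m, 4, g) for g in range(5)]
    )
    assert np.allclose(post.sum(axis=1), brute / brute.sum())


def _strong(call, n=30, err=0.001):
    return [(call, err)] * n


def test_map_corrects_transmission_impossible_offspring_dosage():
    """Parents nulliplex, a single weak alt read cannot make the child dosage 1."""
    evidence = {
        "m": _strong(0),
        "f": _strong(0),
        "c1": [(1, 0.2)],
    }
    ploidies = {"m": 4, "f": 4, "c1": 4}
    got = map_population_genotypes(
        evidence, ploidies, "m", "f", ["c1"], called={"m": 0, "f": 0, "c1": 1}
    )
    assert got == {"m": 0, "f": 0, "c1": 0}


def test_map_imputes_missing_offspring_from_transmission_argmax():
    evidence = {"m": _strong(1) + _strong(0), "f": _strong(1) + _strong(0)}
    ploidies = {"m": 4, "f": 4, "c1": 4}
    got = map_population_genotypes(evidence, ploidies, "m", "f", ["c1"])
    assert got["m"] == 2 and got["f"] == 2
    assert got["c1"] == 2  # convolution PMF peaks at 2 with mass 0.5


def test_map_keeps_consistent_called_dosages():
    evidence = {
        "m": _strong(1, 60) + _strong(0, 60),  # duplex
        "f": _strong(0, 90) + _strong(1, 30),  # simplex
        "c1": _strong(0, 45) + _strong(1, 15),  # simplex child
    }
    ploidies = {"m": 4, "f": 4, "c1": 4}
    called = {"m": 2, "f": 1, "c1": 1}
    assert map_population_genotypes(
        evidence, ploidies, "m", "f", ["c1"], called
    ) == called


def test_map_results_always_mendelian_consistent():
    rng = np.random.default_rng(9)
    ploidies = {"m": 4, "f": 4, "c1": 4, "c2": 4}
    for _ in range(30):
        evidence = {
            ind: [
                (int(rng.integers(0, 2)), float(rng.uniform(0.001, 0.3)))
                for _ in range(rng.integers(0, 8))
            ]
            for ind in ploidies
        }
        got = map_population_genotypes(evidence, ploidies, "m", "f", ["c1", "c2"])
        pmf = offspring_dosage_pmf(4, got["m"], 4, got["f"])
        for child in ("c1", "c2"):
            assert got[child] in pmf


def test_map_agrees_with_exhaustive_enumeration():
    """Factorised MAP equals brute force over all (k+1)^(n+2) genotype vectors."""
    rng = np.random.default_rng(4)
    k = 4
    ploidies = {"m": k, "f": k, "c1": k, "c2": k, "c3": k}
    offspring = ["c1", "c2", "c3"]
    for trial in range(5):
        evidence = {
            ind: [
                (int(rng.integers(0, 2)), float(rng.uniform(0.01, 0.3)))
                for _ in range(rng.integers(1, 5))
            ]
            for ind in ploidies
        }
        got = map_population_genotypes(evidence, ploidies, "m", "f", offspring)

        def joint(gm, gf, gcs):
            p = site_dosage_likelihood(evidence["m"], k, gm)
            p *= site_dosage_likelihood(evidence["f"], k, gf)
            pmf = offspring_dosage_pmf(k, gm, k, gf)
            for child, gc in zip(offspring, gcs):
                p *= pmf.get(gc, 0.0) * site_dosage_likelihood(evidence[child], k, gc)
            return p

        best = max(
            (
                joint(gm, gf, gcs)
                for gm in range(k + 1)
                for gf in range(k + 1)
                for gcs in itertools.product(range(k + 1), repeat=3)
            ),
        )
        assert joint(got["m"], got["f"], [got[c] for c in offspring]) == pytest.approx(
            best
        )


def test_dosage_recovery_improves_with_depth_and_population():
    """Accuracy of the MAP dosages rises with read depth and offspring count."""
    rng = np.random.default_rng(12)
    k = 4

    def run(depth, n_off, trials=150):
        correct = total = 0
        for _ in range(trials):
            gm, gf = int(rng.integers(0, 5)), int(rng.integers(0, 5))
            pmf = offspring_dosage_pmf(k, gm, k, gf)
            gs = list(pmf)
            ps = np.array([pmf[g] for g in gs])
            truth = {"m": gm, "f": gf}
            offspring = [f"c{i}" for i in range(n_off)]
            for c in offspring:
                truth[c] = int(rng.choice(gs, p=ps))
            evidence = {}
            for ind, g in truth.items():
                calls = []
                for _ in range(depth):
                    allele = int(rng.random() < g / k)
                    if rng.random() < 0.02:
                        allele = 1 - allele
                    calls.append((allele, 0.02))
                evidence[ind] = calls
            got = map_population_genotypes(
                evidence, {i: k for i in truth}, "m", "f", offspring
            )
            for ind in truth:
                correct += got[ind] == truth[ind]
                total += 1
        return correct / total

    shallow = run(4, 2)
    deep = run(24, 2)
    assert deep >= shallow - 0.02
    small = run(6, 1)
    large = run(6, 6)
    assert large >= small - 0.02
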