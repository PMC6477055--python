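"""Site-wise genotype likelihoods and Mendelian dosage correction.

The base-call model: a read base at a site comes from a uniformly random
homolog of the individual, so for dosage g out of ploidy k an alt call has
probability (g/k)(1-e) + (1-g/k)e and a ref call the complement.  Parental
genotype pairs get a flat prior; offspring dosages are conditionally
independent given the parents, each weighted by the balanced-meiosis
transmission PMF.  Maximising the resulting factorised joint corrects
erroneous dosages and imputes missing ones with guaranteed Mendelian
consistency.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from .popdata import MISSING, FragmentMatrix
from .transmission import gamete_dosage_pmf

logger = logging.getLogger(__name__)

#: SiteEvidence for one individual: sequence of (allele call in {0,1}, error prob).
SiteEvidence = Sequence[tuple[int, float]]


def site_evidence(matrix: FragmentMatrix, site: int) -> list[tuple[int, float]]:
    """Collect (call, error) pairs for one individual at one SNP."""
    out = []
    for frag in matrix.fragments:
        if site in frag.alleles:
            out.append((frag.alleles[site], frag.errors[site]))
    return out


def site_dosage_likelihood(evidence: SiteEvidence, ploidy: int, dosage: int) -> float:
    """P(calls | dosage) under the uniform-homolog base-sampling model."""
    if not 0 <= dosage <= ploidy:
        raise ValueError(f"dosage {dosage} out of range 0..{ploidy}")
    p_alt = dosage / ploidy
    lik = 1.0
    for call, err in evidence:
        p = p_alt * (1.0 - err) + (1.0 - p_alt) * err
        lik *= p if call == 1 else 1.0 - p
    return lik


def _dosage_likelihood_vector(evidence: SiteEvidence, ploidy: int) -> np.ndarray:
    return np.array(
        [site_dosage_likelihood(evidence, ploidy, g) for g in range(ploidy + 1)]
    )


def parental_genotype_posterior(
    evidence_m: SiteEvidence,
    evidence_f: SiteEvidence,
    k_m: int,
    k_f: int,
) -> np.ndarray:
    """Posterior over (g_m, g_f) with a flat prior; shape (k_m+1, k_f+1)."""
    lik_m = _dosage_likelihood_vector(evidence_m, k_m)
    lik_f = _dosage_likelihood_vector(evidence_f, k_f)
    table = np.outer(lik_m, lik_f)
    total = table.sum()
    if total <= 0.0:
        logger.warning("all-zero parental genotype likelihoods; returning uniform")
        return np.full_like(table, 1.0 / table.size)
    return table / total


def _transmission_matrix(k_m: int, k_f: int) -> np.ndarray:
    """T[g_m, g_f, g_c] = P(offspring dosage g_c | parental dosages)."""
    half_m, half_f = k_m // 2, k_f // 2
    k_c = half_m + half_f
    out = np.zeros((k_m + 1, k_f + 1, k_c + 1))
    for g_m in range(k_m + 1):
        pmf_m = np.zeros(half_m + 1)
        for t, p in gamete_dosage_pmf(k_m, g_m).items():
            pmf_m[t] = p
        for g_f in range(k_f + 1):
            pmf_f = np.zeros(half_f + 1)
            for t, p in gamete_dosage_pmf(k_f, g_f).items():
                pmf_f[t] = p
            out[g_m, g_f] = np.convolve(pmf_m, pmf_f)
    return out


def map_population_genotypes(
    evidence: Mapping[str, SiteEvidence],
    ploidies: Mapping[str, int],
    mother: str,
    father: str,
    offspring: Sequence[str],
    called: Mapping[str, int] | None = None,
) -> dict[str, int]:
    """Joint MAP dosages for the whole population at one SNP.

    Maximises P(g_m, g_f | reads) * prod_i max contribution of offspring i,
    where each offspring factor is transmission PMF x read likelihood; an
    offspring with no reads gets the transmission-PMF argmax.  Ties are
    broken toward the originally called dosage (when supplied), then toward
    the smaller dosage.  Every returned offspring dosage has nonzero
    transmission probability given the returned parental pair.
    """
    k_m, k_f = ploidies[mother], ploidies[father]
    k_c = k_m // 2 + k_f // 2
    parent_post = parental_genotype_posterior(
        evidence.get(mother, ()), evidence.get(father, ()), k_m, k_f
    )
    trans = _transmission_matrix(k_m, k_f)

    child_lik = {
        c: _dosage_likelihood_vector(evidence.get(c, ()), ploidies[c])
        for c in offspring
    }

    def tie_key(ind: str, g: int) -> tuple[int, int]:
        # smaller is better: prefer the called dosage, then smaller g
        if called is not None and called.get(ind, MISSING) == g:
            return (0, g)
        return (1, g)

    best_score, best_assign = -1.0, None
    for g_m in range(k_m + 1):
        for g_f in range(k_f + 1):
            score = parent_post[g_m, g_f]
            if score <= 0.0:
                continue
            assign = {mother: g_m, father: g_f}
            for c in offspring:
                weights = trans[g_m, g_f] * child_lik[c]
                if weights.sum() <= 0.0:
                    weights = trans[g_m, g_f]
                g_best = min(
                    (g for g in range(k_c + 1) if weights[g] == weights.max()),
                    key=lambda g: tie_key(c, g),
                )
                score *= weights[g_best]
                assign[c] = g_best
            better = score > best_score
            if not better and score == best_score and best_assign is not None:
                # deterministic tie-break over the parental pair
                cand = [tie_key(mother, g_m), tie_key(father, g_f)]
                cur = [
                    tie_key(mother, best_assign[mother]),
                    tie_key(father, best_assign[father]),
                ]
                better = cand < cur
            if better:
                best_score, best_assign = score, assign
    assert best_assign is not None
    return best_assign
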