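"""Mendelian transmission machinery for even-ploidy balanced meiosis.

The gamete model is random polysomic segregation: a gamete receives a
uniformly random half of the parent's homologs, with no double reduction,
no preferential pairing and no recombination.  The alternative-allele count
of a gamete at one site is therefore hypergeometric, and an offspring dosage
is the convolution of the two parental gamete distributions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .popdata import Phasing, SNPSite


def _check_even(k: int) -> None:
    if k < 2 or k % 2 != 0:
        raise ValueError(f"ploidy must be an even integer >= 2, got {k}")


def gamete_dosage_pmf(ploidy: int, parent_dosage: int) -> dict[int, float]:
    """P(gamete carries t alt alleles) for a parent with dosage g.

    Hypergeometric: choosing k/2 of the k homologs, t of which are among the
    g alt-carrying ones: P(t) = C(g,t) C(k-g, k/2-t) / C(k, k/2).
    """
    _check_even(ploidy)
    if not 0 <= parent_dosage <= ploidy:
        raise ValueError(f"dosage {parent_dosage} out of range 0..{ploidy}")
    half = ploidy // 2
    ts = np.arange(half + 1)
    probs = hypergeom.pmf(ts, ploidy, parent_dosage, half)
    return {int(t): float(p) for t, p in zip(ts, probs) if p > 0.0}


def offspring_dosage_pmf(
    k_m: int, g_m: int, k_f: int, g_f: int
) -> dict[int, float]:
    """Offspring dosage distribution: convolution of the two gamete PMFs."""
    pmf_m = gamete_dosage_pmf(k_m, g_m)
    pmf_f = gamete_dosage_pmf(k_f, g_f)
    vec_m = np.zeros(k_m // 2 + 1)
    vec_f = np.zeros(k_f // 2 + 1)
    for t, p in pmf_m.items():
        vec_m[t] = p
    for t, p in pmf_f.items():
        vec_f[t] = p
    conv = np.convolve(vec_m, vec_f)
    return {int(g): float(p) for g, p in enumerate(conv) if p > 0.0}


@dataclass(frozen=True)
class Transmission:
    """Which half of each parent's homologs an offspring inherited."""

    maternal_subset: tuple[int, ...]
    paternal_subset: tuple[int, ...]

    def induced_phasing(self, h_m: Phasing, h_f: Phasing) -> Phasing:
        rows = np.vstack(
            [h_m.alleles[list(self.maternal_subset)], h_f.alleles[list(self.paternal_subset)]]
        )
        return Phasing(rows, h_m.snp_indices)


def enumerate_transmissions(
    h_m: Phasing, h_f: Phasing
) -> list[tuple[Transmission, Phasing]]:
    """All C(k_m, k_m/2) * C(k_f, k_f/2) candidate offspring phasings.

    Distinct homolog subsets that induce identical phasings (duplicated
    parental haplotypes) are retained here; deduplicate with
    :func:`distinct_transmission_classes` for probability bookkeeping.
    """
    _check_even(h_m.ploidy)
    _check_even(h_f.ploidy)
    if not np.array_equal(h_m.snp_indices, h_f.snp_indices):
        raise ValueError("parental phasings must span the same SNPs")
    out = []
    for sub_m in itertools.combinations(range(h_m.ploidy), h_m.ploidy // 2):
        for sub_f in itertools.combinations(range(h_f.ploidy), h_f.ploidy // 2):
            trans = Transmission(sub_m, sub_f)
            out.append((trans, trans.induced_phasing(h_m, h_f)))
    return out


def distinct_transmission_classes(
    h_m: Phasing, h_f: Phasing
) -> list[list[tuple[Transmission, Phasing]]]:
    """Group transmissions whose induced offspring phasings coincide.

    Returns the equivalence classes in canonical-phasing order; each class is
    a list of (transmission, phasing) with identical induced haplotype sets.
    """
    groups: dict[bytes, list[tuple[Transmission, Phasing]]] = {}
    for trans, ph in enumerate_transmissions(h_m, h_f):
        groups.setdefault(ph.canonical_key(), []).append((trans, ph))
    return [groups[key] for key in sorted(groups)]


@dataclass
class HtSNPResult:
    """Greedy haplotype-tagging SNP selection outcome.

    ``snps`` is the ordered selected subset; ``classes`` the distinct
    transmission classes being separated; ``unresolved`` lists groups of
    class indices whose dosage vectors coincide over ALL available SNPs and
    hence can never be told apart by dosages.
    """

    snps: list[int]
    classes: list[list[tuple[Transmission, Phasing]]]
    dosage_vectors: np.ndarray  # (n_classes, n_snps)
    unresolved: list[list[int]]

    @property
    def fully_resolved(self) -> bool:
        return not self.unresolved


def select_htsnps(h_m: Phasing, h_f: Phasing, redundancy: int = 0) -> HtSNPResult:
    """Select SNPs whose joint dosages pin down the parental transmission.

    Greedy set cover over pairs of distinct transmission classes: at each
    step pick the SNP separating the most still-unseparated class pairs,
    until every separable pair is separated; ``redundancy`` extra SNPs are
    then appended by the same rule (restarted pair coverage).  Classes with
    identical dosage vectors over all SNPs are reported, not raised.
    """
    classes = distinct_transmission_classes(h_m, h_f)
    dosage_vectors = np.array([cls[0][1].dosages() for cls in classes])
    n_cls, n_snps = dosage_vectors.shape

    pairs = list(itertools.combinations(range(n_cls), 2))
    separable = [
        (a, b) for a, b in pairs if not np.array_equal(dosage_vectors[a], dosage_vectors[b])
    ]
    # pairs never separable: union-find them into unresolved groups
    inseparable = [p for p in pairs if p not in separable]
    unresolved = _merge_pairs(inseparable)

    def greedy(target_pairs: list[tuple[int, int]], banned: set[int]) -> list[int]:
        chosen: list[int] = []
        remaining = set(target_pairs)
        while remaining:
            best_snp, best_hits = -1, -1
            for s in range(n_snps):
                if s in banned or s in chosen:
                    continue
                hits = sum(
                    1 for a, b in remaining if dosage_vectors[a, s] != dosage_vectors[b, s]
                )
                if hits > best_hits:
                    best_snp, best_hits = s, hits
            if best_hits <= 0:
                break
            chosen.append(best_snp)
            remaining = {
                (a, b)
                for a, b in remaining
                if dosage_vectors[a, best_snp] == dosage_vectors[b, best_snp]
            }
        return chosen

    selected = greedy(separable, banned=set())
    for _ in range(redundancy):
        extra = greedy(separable, banned=set(selected))
        if not extra:
            break
        selected.append(extra[0])
    return HtSNPResult(selected, classes, dosage_vectors, unresolved)


def _merge_pairs(pairs: list[tuple[int, int]]) -> list[list[int]]:
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        parent[find(a)] = find(b)
    groups: dict[int, list[int]] = {}
    for x in parent:
        groups.setdefault(find(x), []).append(x)
    return [sorted(g) for g in groups.values() if len(g) > 1]


def htsnp_table(
    result: HtSNPResult, sites: Sequence[SNPSite], h_m: Phasing, h_f: Phasing
) -> pd.DataFrame:
    """TSV-ready report of the selected tagging SNPs."""
    rows = []
    pos_of = {int(s): j for j, s in enumerate(h_m.snp_indices)}
    for s in result.snps:
        j = pos_of[int(h_m.snp_indices[s])] if s in pos_of else s
        site = sites[int(h_m.snp_indices[s])]
        rows.append(
            {
                "snp": int(h_m.snp_indices[s]),
                "pos": site.pos,
                "maternal_column": "".join(map(str, h_m.alleles[:, j])),
                "paternal_column": "".join(map(str, h_f.alleles[:, j])),
            }
        )
    return pd.DataFrame(rows, columns=["snp", "pos", "maternal_column", "paternal_column"])
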