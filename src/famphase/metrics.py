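"""Evaluation metrics for phasing estimates against simulated truth.

All metrics are invariant to homolog-row permutations of both truth and
estimate:

* RR (reconstruction rate): 1 - minimal total Hamming distance over row
  assignments, normalised by k * l, per estimated block; blocks are
  aggregated by SNP-weighted mean.
* PAR (pairwise phasing accuracy): fraction of SNP pairs co-phased within
  one estimated block whose two-column haplotype multiset matches the truth.
* SMR (SNP missing rate): fraction of true segregating SNPs absent from the
  estimate's phasing.
* IDR (incorrect dosage rate): fraction of phased SNPs whose estimated
  column dosage differs from the true dosage.
* NGPS: (number of blocks - 1) / l, computed in :mod:`famphase.blocks`.
* nucleotide diversity: mean pairwise per-site Hamming distance between
  haplotypes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .popdata import Phasing


def _hamming_cost(truth_rows: np.ndarray, est_rows: np.ndarray) -> np.ndarray:
    return (truth_rows[:, None, :] != est_rows[None, :, :]).sum(axis=2)


def min_assignment_distance(truth_rows: np.ndarray, est_rows: np.ndarray) -> int:
    """Minimal total Hamming distance over row-to-row assignments."""
    cost = _hamming_cost(truth_rows, est_rows)
    r, c = linear_sum_assignment(cost)
    return int(cost[r, c].sum())


def reconstruction_rate(truth: Phasing, estimate: Phasing) -> float:
    """RR over the SNPs phased in both, for one estimated block."""
    shared = [int(s) for s in estimate.snp_indices if s in set(map(int, truth.snp_indices))]
    if not shared:
        return math.nan
    t = truth.restrict(shared)
    e = estimate.restrict(shared)
    dist = min_assignment_distance(t.alleles, e.alleles)
    return 1.0 - dist / (t.ploidy * len(shared))


def pairwise_accuracy(truth: Phasing, estimate: Phasing) -> float:
    """PAR over SNP pairs co-phased within this estimated block."""
    truth_set = set(map(int, truth.snp_indices))
    shared = [int(s) for s in estimate.snp_indices if s in truth_set]
    if len(shared) < 2:
        return math.nan
    t = truth.restrict(shared)
    e = estimate.restrict(shared)
    correct = total = 0
    for a, b in itertools.combinations(range(len(shared)), 2):
        t_pairs = sorted(zip(t.alleles[:, a], t.alleles[:, b]))
        e_pairs = sorted(zip(e.alleles[:, a], e.alleles[:, b]))
        correct += t_pairs == e_pairs
        total += 1
    return correct / total


def missing_and_dosage_rates(
    truth_dosages: Sequence[int], estimates: Sequence[Phasing]
) -> tuple[float, float]:
    """(SMR, IDR) for one individual given all their estimated block phasings."""
    n_true = len(truth_dosages)
    phased: dict[int, int] = {}
    for ph in estimates:
        for j, s in enumerate(ph.snp_indices):
            phased[int(s)] = int(ph.alleles[:, j].sum())
    smr = (n_true - len(phased)) / n_true
    if phased:
        wrong = sum(1 for s, d in phased.items() if d != truth_dosages[s])
        idr = wrong / len(phased)
    else:
        idr = math.nan
    return smr, idr


def nucleotide_diversity(haplotypes: np.ndarray) -> float:
    """Mean per-site pairwise difference between the k haplotype rows."""
    haplotypes = np.asarray(haplotypes)
    k, length = haplotypes.shape
    if k < 2:
        raise ValueError("need at least two haplotypes")
    total = 0
    for a, b in itertools.combinations(range(k), 2):
        total += int((haplotypes[a] != haplotypes[b]).sum())
    return total / (math.comb(k, 2) * length)


@dataclass
class IndividualEval:
    individual: str
    rr: float
    par: float
    smr: float
    idr: float
    ngps: float


def evaluate_individual(
    individual: str,
    truth: Phasing,
    truth_dosages: Sequence[int],
    estimates: Sequence[Phasing],
    ngps_value: float,
) -> IndividualEval:
    """All metrics for one individual; RR/PAR are SNP/pair-weighted over blocks."""
    rr_num = rr_den = 0.0
    par_num = par_den = 0.0
    for ph in estimates:
        if ph.n_sites < 2:
            continue
        rr = reconstruction_rate(truth, ph)
        if not math.isnan(rr):
            rr_num += rr * ph.n_sites
            rr_den += ph.n_sites
        par = pairwise_accuracy(truth, ph)
        n_pairs = math.comb(ph.n_sites, 2)
        if not math.isnan(par):
            par_num += par * n_pairs
            par_den += n_pairs
    smr, idr = missing_and_dosage_rates(truth_dosages, estimates)
    return IndividualEval(
        individual,
        rr_num / rr_den if rr_den else math.nan,
        par_num / par_den if par_den else math.nan,
        smr,
        idr,
        ngps_value,
    )


def report_frame(evals: Sequence[IndividualEval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual": e.individual,
                "rr": e.rr,
                "par": e.par,
                "smr": e.smr,
                "idr": e.idr,
                "ngps": e.ngps,
            }
            for e in evals
        ]
    )
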