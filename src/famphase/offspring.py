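"""Offspring phasing by transmission enumeration and MEC selection.

Given an estimated parental pair over a block, every offspring phasing must
be one of the C(k_m, k_m/2) * C(k_f, k_f/2) transmissions of parental
homologs (36 in a tetraploid x tetraploid cross).  Each offspring gets the
transmission with the smallest minimum-error-correction score against its
own reads; ties are resolved by the read mixture likelihood of the induced
phasing, then by canonical order so runs are reproducible.

Sites whose called offspring dosage cannot be produced by any transmission
compatible with that offspring's dosages at the preceding sites are excluded
from the block's phasing, for the whole population, before scoring: without
recombination no haplotype set could explain them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .popdata import MISSING, FragmentMatrix, GenotypeTable, Phasing
from .phaser import BlockResult, pair_read_likelihood
from .transmission import Transmission, enumerate_transmissions

logger = logging.getLogger(__name__)


@dataclass
class MECResult:
    """Chosen transmission with its MEC score and per-fragment row assignment."""

    transmission: Transmission
    phasing: Phasing
    mec: int
    fragment_rows: list[int]


def mec_score(
    phasing: Phasing, fragments: FragmentMatrix
) -> tuple[int, list[int]]:
    """Minimum error correction: sum over fragments of the best-row mismatch count.

    Sites of a fragment outside the phasing are ignored; fragments with no
    phased site contribute zero (best row reported as 0).
    """
    col_of = {int(s): j for j, s in enumerate(phasing.snp_indices)}
    total = 0
    best_rows = []
    for frag in fragments.fragments:
        cols = [(col_of[s], frag.alleles[s]) for s in frag.indices if s in col_of]
        if not cols:
            best_rows.append(0)
            continue
        js = [j for j, _ in cols]
        obs = np.array([a for _, a in cols])
        mism = (phasing.alleles[:, js] != obs[None, :]).sum(axis=1)
        best = int(mism.argmin())
        best_rows.append(best)
        total += int(mism[best])
    return total, best_rows


def transmission_incompatible_sites(
    h_m: Phasing,
    h_f: Phasing,
    offspring_dosages: Mapping[int, int],
) -> list[int]:
    """Sites no transmission can reconcile with this offspring's dosages.

    Finds the transmission whose induced dosage vector disagrees with the
    offspring's called dosages at the fewest sites (ties broken toward the
    transmission that stays consistent over the longest site prefix, i.e.
    whose first disagreement comes latest) and reports those disagreement
    sites: they cannot be explained by any inheritance of the parental
    haplotypes without recombination.  Missing dosages constrain nothing.
    """
    cands = enumerate_transmissions(h_m, h_f)
    dosage_rows = np.array([ph.dosages() for _, ph in cands])  # (n_trans, l)
    sites = [int(s) for s in h_m.snp_indices]
    called_cols = [
        j for j, s in enumerate(sites) if offspring_dosages.get(s, MISSING) != MISSING
    ]
    if not called_cols:
        return []
    g = np.array([offspring_dosages[sites[j]] for j in called_cols])
    mismatch = dosage_rows[:, called_cols] != g[None, :]  # (n_trans, n_called)
    counts = mismatch.sum(axis=1)
    best_count = int(counts.min())
    if best_count == 0:
        return []

    def first_mismatch(t: int) -> int:
        return int(np.argmax(mismatch[t]))

    tied = np.flatnonzero(counts == best_count)
    best = max(tied, key=first_mismatch)
    return [sites[called_cols[j]] for j in np.flatnonzero(mismatch[best])]


def select_offspring_phasing(
    h_m: Phasing,
    h_f: Phasing,
    fragments: FragmentMatrix,
    offspring_dosages: Mapping[int, int] | None = None,
) -> MECResult:
    """Evaluate every transmission and return the MEC minimizer.

    Ties are broken by the higher read mixture likelihood of the induced
    phasing (errors already reflected in the fragment error probabilities),
    then by canonical phasing order.
    """
    cands = enumerate_transmissions(h_m, h_f)
    scored = []
    for trans, ph in cands:
        mec, rows = mec_score(ph, fragments)
        scored.append((trans, ph, mec, rows))
    best_mec = min(s[2] for s in scored)
    tied = [s for s in scored if s[2] == best_mec]
    if len(tied) > 1:
        def loglik(entry):
            _, ph, _, _ = entry
            ll = 0.0
            col_of = set(int(s) for s in ph.snp_indices)
            for frag in fragments.fragments:
                if any(s in col_of for s in frag.indices):
                    rows = ph.alleles
                    per_row = np.ones(rows.shape[0])
                    jmap = {int(s): j for j, s in enumerate(ph.snp_indices)}
                    for s in frag.indices:
                        if s in jmap:
                            e = frag.errors[s]
                            match = rows[:, jmap[s]] == frag.alleles[s]
                            per_row *= np.where(match, 1.0 - e, e)
                    ll += float(np.log(per_row.mean()))
            return ll
        tied.sort(key=lambda s: (-loglik(s), s[1].canonical_key()))
    trans, ph, mec, rows = tied[0]
    return MECResult(trans, ph, mec, rows)


@dataclass
class SolutionSet:
    """One parental candidate pair with all deduced offspring phasings."""

    h_m: Phasing
    h_f: Phasing
    parental_posterior: float
    offspring: dict[str, MECResult]

    @property
    def mec_sum(self) -> int:
        return sum(r.mec for r in self.offspring.values())

    def rank_key(self) -> tuple:
        return (-self.parental_posterior, self.mec_sum, self.h_m.canonical_key())


def rank_solution_sets(sets: Sequence[SolutionSet]) -> list[SolutionSet]:
    """Descending parental posterior, then ascending offspring MEC sum."""
    if not sets:
        raise ValueError("at least one surviving parental pair required")
    return sorted(sets, key=lambda s: s.rank_key())


def resolve_block(
    result: BlockResult,
    matrices: Mapping[str, FragmentMatrix],
    genotype_table: GenotypeTable,
    offspring: Sequence[str],
    top_sets: int = 1,
    exclude_population_wide: bool = True,
) -> tuple[list[SolutionSet], list[int]]:
    """Offspring selection for one phased block.

    Returns the ranked solution sets (restricted to ``top_sets``) and the
    sites excluded as transmission-incompatible.  Exclusion is applied for
    the whole population by default; the per-offspring alternative keeps the
    site for unaffected individuals.
    """
    if not result.is_phased:
        return [], []
    # Exclusion is judged against the top parental pair.
    h_m_top, h_f_top = result.top_pair()
    excluded: set[int] = set()
    per_child_bad: dict[str, set[int]] = {}
    for child in offspring:
        dosages = {
            int(s): genotype_table.get(child, int(s)) for s in h_m_top.snp_indices
        }
        bad = transmission_incompatible_sites(h_m_top, h_f_top, dosages)
        per_child_bad[child] = set(bad)
        excluded.update(bad)

    sets = []
    for h_m, h_f, post in result.ranked_pairs():
        if exclude_population_wide:
            keep = [int(s) for s in h_m.snp_indices if int(s) not in excluded]
        else:
            keep = [int(s) for s in h_m.snp_indices]
        if len(keep) < 1:
            continue
        h_m_r, h_f_r = h_m.restrict(keep), h_f.restrict(keep)
        selections = {}
        for child in offspring:
            if not exclude_population_wide and per_child_bad[child]:
                keep_c = [s for s in keep if s not in per_child_bad[child]]
                selections[child] = select_offspring_phasing(
                    h_m_r.restrict(keep_c), h_f_r.restrict(keep_c), matrices[child]
                )
            else:
                selections[child] = select_offspring_phasing(
                    h_m_r, h_f_r, matrices[child]
                )
        sets.append(SolutionSet(h_m_r, h_f_r, post, selections))
    if not sets:
        return [], sorted(excluded)
    ranked = rank_solution_sets(sets)[:top_sets]
    return ranked, sorted(excluded)
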