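"""Greedy Bayesian SNP-by-SNP extension of parental phasing pairs.

Within each haplotype block the two parental phasings are grown one SNP at a
time.  At every step all allele placements consistent with the parental
dosages are enumerated as candidate extensions; each extension's posterior
combines a uniform prior over dosage-consistent placements with the
likelihood of the population reads that link the new SNP to the already
phased ones.  Mother and father reads are uniform mixtures over that
parent's homologs; offspring reads, which under the no-recombination
assumption must originate from some parental homolog, are uniform mixtures
over the union of both parents' rows.  Surviving candidates are limited by a
hard posterior threshold (branching, rho) and a soft threshold relative to
the best candidate (pruning, kappa * P_max); the argmax always survives.

Per-fragment per-row running products are cached so each step touches only
the fragments covering the new SNP (incremental update).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .popdata import MISSING, FragmentMatrix, GenotypeTable, Phasing
from .transmission import offspring_dosage_pmf

logger = logging.getLogger(__name__)


@dataclass
class PhaserConfig:
    """Branch/prune thresholds: hard rho in (0,1], soft kappa in [0,1]."""

    rho: float = 0.2
    kappa: float = 0.94
    max_candidates: int = 256

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must be in [0, 1]")


class ZeroExtensionError(Exception):
    """All extensions at a site have zero posterior probability."""

    def __init__(self, site: int):
        super().__init__(f"zero-probability extensions at site {site}")
        self.site = site


def pair_read_likelihood(
    fragment,
    role: str,
    h_m: Phasing,
    h_f: Phasing,
    up_to: int | None = None,
) -> float:
    """Mixture likelihood of one fragment given a parental phasing pair.

    ``role`` selects the mixture components: the mother's rows, the
    father's, or (for offspring) the union of both.  Sites not phased, or
    beyond ``up_to`` (a region SNP index), contribute nothing; a fragment
    with no eligible site has likelihood 1.
    """
    if role == "mother":
        rows = h_m.alleles
        indices = h_m.snp_indices
    elif role == "father":
        rows = h_f.alleles
        indices = h_f.snp_indices
    elif role == "offspring":
        if not np.array_equal(h_m.snp_indices, h_f.snp_indices):
            raise ValueError("parental phasings must span the same SNPs")
        rows = np.vstack([h_m.alleles, h_f.alleles])
        indices = h_m.snp_indices
    else:
        raise ValueError(f"unknown role {role!r}")

    col_of = {int(s): j for j, s in enumerate(indices)}
    per_row = np.ones(rows.shape[0])
    used = False
    for s in fragment.indices:
        if s not in col_of or (up_to is not None and s > up_to):
            continue
        used = True
        e = fragment.errors[s]
        match = rows[:, col_of[s]] == fragment.alleles[s]
        per_row *= np.where(match, 1.0 - e, e)
    if not used:
        return 1.0
    return float(per_row.mean())


# ---------------------------------------------------------------------------
# vectorized per-block fragment arrays

class _RoleData:
    """Dense allele/error arrays for the fragments of one mixture role."""

    def __init__(self, matrices: Sequence[FragmentMatrix], block: Sequence[int]):
        col_of = {int(s): j for j, s in enumerate(block)}
        rows = []
        for mat in matrices:
            for frag in mat.fragments:
                covered = [s for s in frag.indices if s in col_of]
                if len(covered) >= 2:  # single-SNP fragments carry no linkage
                    rows.append(frag)
        self.n = len(rows)
        L = len(block)
        self.alleles = np.full((self.n, L), -1, dtype=np.int8)
        self.errors = np.ones((self.n, L))
        for i, frag in enumerate(rows):
            for s in frag.indices:
                j = col_of.get(s)
                if j is not None:
                    self.alleles[i, j] = frag.alleles[s]
                    self.errors[i, j] = frag.errors[s]
        self.at_col = [np.flatnonzero(self.alleles[:, j] >= 0) for j in range(L)]


@dataclass
class _Proto:
    """A candidate extension before materialization of its cached products."""

    parent: "CandidatePair | None"
    col_m: np.ndarray
    col_f: np.ndarray
    log_weight: float
    key: tuple[bytes, bytes]
    touched: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # role -> (idx, prod, mix)
    posterior: float = 0.0
    log_lik: float = 0.0


class CandidatePair:
    """A surviving pair of parental phasings over the block prefix."""

    def __init__(self, k_m: int, k_f: int, data: dict[str, _RoleData]):
        self.cols_m: list[np.ndarray] = []
        self.cols_f: list[np.ndarray] = []
        self.posterior = 1.0
        self.log_lik = 0.0
        self.prod = {
            role: np.ones((rd.n, k_m if role == "mother" else k_f if role == "father" else k_m + k_f))
            for role, rd in data.items()
        }
        self.mix = {role: np.ones(rd.n) for role, rd in data.items()}

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.column_stack(self.cols_m).astype(np.int8),
            np.column_stack(self.cols_f).astype(np.int8),
        )

    def phasings(self, snp_indices: Sequence[int]) -> tuple[Phasing, Phasing]:
        m, f = self.matrices()
        return Phasing(m, snp_indices), Phasing(f, snp_indices)

    def spawn(self, proto: _Proto) -> "CandidatePair":
        child = CandidatePair.__new__(CandidatePair)
        child.cols_m = self.cols_m + [proto.col_m]
        child.cols_f = self.cols_f + [proto.col_f]
        child.posterior = proto.posterior
        child.log_lik = proto.log_lik
        child.prod = {}
        child.mix = {}
        for role in self.prod:
            prod = self.prod[role].copy()
            mix = self.mix[role].copy()
            if role in proto.touched:
                idx, new_prod, new_mix = proto.touched[role]
                prod[idx] = new_prod
                mix[idx] = new_mix
            child.prod[role] = prod
            child.mix[role] = mix
        return child


def _canonical_key(cols: list[np.ndarray], new_col: np.ndarray) -> bytes:
    mat = np.column_stack(cols + [new_col]) if cols else new_col[:, None]
    order = np.lexsort(mat.T[::-1])
    return mat[order].astype(np.int8).tobytes()


def _placements(k: int, g: int) -> list[np.ndarray]:
    out = []
    for ones in itertools.combinations(range(k), g):
        col = np.zeros(k, dtype=np.int8)
        col[list(ones)] = 1
        out.append(col)
    return out


def prune_indices(
    posteriors: np.ndarray,
    keys: Sequence,
    rho: float,
    kappa: float,
    max_candidates: int,
) -> list[int]:
    """Indices surviving branching (>= rho) and pruning (>= kappa * P_max).

    The argmax always survives; survivors are returned in stable order
    (descending posterior, then key) and capped at ``max_candidates``.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    order = sorted(range(len(posteriors)), key=lambda i: (-posteriors[i], keys[i]))
    p_max = posteriors[order[0]]
    keep = [
        i
        for i in order
        if posteriors[i] >= rho and posteriors[i] >= kappa * p_max
    ]
    if not keep:
        keep = [order[0]]
    return keep[:max_candidates]


class BlockPhaser:
    """Extension engine for one haplotype block."""

    def __init__(
        self,
        block: Sequence[int],
        matrices: Mapping[str, FragmentMatrix],
        mother: str,
        father: str,
        offspring: Sequence[str],
        k_m: int,
        k_f: int,
        config: PhaserConfig,
    ):
        self.block = list(block)
        self.k_m, self.k_f = k_m, k_f
        self.config = config
        self.mother, self.father, self.offspring = mother, father, list(offspring)
        self.data = {
            "mother": _RoleData([matrices[mother]], block),
            "father": _RoleData([matrices[father]], block),
            "offspring": _RoleData(
                [matrices[c] for c in offspring if c in matrices], block
            ),
        }
        self.stats = {"extensions_evaluated": 0, "fragment_row_ops": 0}
        self.eta_trace: list[int] = []

    # -- likelihood factor of one placement pair at one column ---------------

    def _touch(
        self,
        cand: CandidatePair,
        role: str,
        col_local: int,
        column: np.ndarray,
    ) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray] | None, float]:
        rd = self.data[role]
        idx = rd.at_col[col_local]
        if idx.size == 0:
            return None, 0.0
        o = rd.alleles[idx, col_local][:, None]
        e = rd.errors[idx, col_local][:, None]
        factors = np.where(column[None, :] == o, 1.0 - e, e)
        new_prod = cand.prod[role][idx] * factors
        new_mix = new_prod.mean(axis=1)
        old_mix = cand.mix[role][idx]
        delta = float(np.log(new_mix).sum() - np.log(old_mix).sum())
        self.stats["fragment_row_ops"] += factors.size
        return (idx, new_prod, new_mix), delta

    def _check_compat(self, g_m: int, g_f: int, child_dosages: Sequence[int]) -> bool:
        pmf = offspring_dosage_pmf(self.k_m, g_m, self.k_f, g_f)
        return all(g == MISSING or g in pmf for g in child_dosages)

    def extend(
        self,
        candidates: list[CandidatePair],
        col_local: int,
        g_m: int,
        g_f: int,
        child_dosages: Sequence[int],
    ) -> list[_Proto]:
        """All distinct dosage-consistent extensions of every candidate.

        The prior over a candidate's extensions is uniform; extensions are
        zero (and the whole step fails) when some called offspring dosage
        has no transmission probability under (g_m, g_f).
        """
        if not self._check_compat(g_m, g_f, child_dosages):
            raise ZeroExtensionError(self.block[col_local])
        placements_m = _placements(self.k_m, g_m)
        placements_f = _placements(self.k_f, g_f)
        protos: dict[tuple[bytes, bytes], _Proto] = {}
        for cand in candidates:
            # deduplicate extensions equal up to row permutation of the full prefix
            local: dict[tuple[bytes, bytes], tuple[np.ndarray, np.ndarray]] = {}
            for pm in placements_m:
                key_m = _canonical_key(cand.cols_m, pm)
                for pf in placements_f:
                    key = (key_m, _canonical_key(cand.cols_f, pf))
                    local.setdefault(key, (pm, pf))
            log_prior = -np.log(len(local))
            for key, (pm, pf) in local.items():
                self.stats["extensions_evaluated"] += 1
                touched = {}
                delta = 0.0
                for role, column in (
                    ("mother", pm),
                    ("father", pf),
                    ("offspring", np.concatenate([pm, pf])),
                ):
                    t, d = self._touch(cand, role, col_local, column)
                    if t is not None:
                        touched[role] = t
                    delta += d
                log_w = np.log(cand.posterior) + log_prior + delta
                if key in protos:  # identical phasing reached from another base
                    protos[key].log_weight = float(
                        np.logaddexp(protos[key].log_weight, log_w)
                    )
                else:
                    protos[key] = _Proto(
                        cand, pm, pf, float(log_w), key, touched,
                        log_lik=cand.log_lik + delta,
                    )
        return list(protos.values())

    def branch_prune(self, protos: list[_Proto]) -> list[CandidatePair]:
        """Hard threshold rho, then soft threshold kappa * P_max; keep argmax."""
        if not protos:
            raise ValueError("no extensions to prune")
        logs = np.array([p.log_weight for p in protos])
        total = logsumexp(logs)
        if not np.isfinite(total):
            raise ZeroExtensionError(-1)
        posts = np.exp(logs - total)
        keep = prune_indices(
            posts,
            [p.key for p in protos],
            self.config.rho,
            self.config.kappa,
            self.config.max_candidates,
        )
        if len(keep) == self.config.max_candidates:
            logger.debug("candidate cap (%d) hit", self.config.max_candidates)
        norm = posts[keep].sum()
        out = []
        for i in keep:
            proto = protos[i]
            proto.posterior = float(posts[i] / norm)
            out.append(proto.parent.spawn(proto))
        return out


@dataclass
class BlockResult:
    """Phasing outcome for one haplotype block."""

    block: list[int]
    phased_sites: list[int]
    candidates: list[CandidatePair]
    excluded_sites: list[int]
    eta_trace: list[int]
    stats: dict[str, int] = field(default_factory=dict)

    @property
    def is_phased(self) -> bool:
        return len(self.phased_sites) >= 2 and bool(self.candidates)

    def top_pair(self) -> tuple[Phasing, Phasing]:
        best = max(self.candidates, key=lambda c: c.posterior)
        return best.phasings(self.phased_sites)

    def ranked_pairs(self) -> list[tuple[Phasing, Phasing, float]]:
        out = []
        for cand in sorted(self.candidates, key=lambda c: -c.posterior):
            h_m, h_f = cand.phasings(self.phased_sites)
            out.append((h_m, h_f, cand.posterior))
        return out


def phase_parents(
    matrices: Mapping[str, FragmentMatrix],
    genotype_table: GenotypeTable,
    blocks: Sequence[Sequence[int]],
    mother: str,
    father: str,
    offspring: Sequence[str],
    config: PhaserConfig | None = None,
    reestimate: Callable[[int], None] | None = None,
) -> list[BlockResult]:
    """Run the extension engine over every block.

    ``reestimate`` is called with a region SNP index when either parent's
    dosage is missing there or when every extension at the site has zero
    posterior; it is expected to update ``genotype_table`` in place.  A site
    that remains unusable after re-estimation is excluded from phasing.
    Blocks with fewer than two phased SNPs are returned without candidates
    (dosage-only).
    """
    config = config or PhaserConfig()
    k_m = genotype_table.ploidies[mother]
    k_f = genotype_table.ploidies[father]
    results = []

    def dosages_at(site: int) -> tuple[int, int, list[int]]:
        return (
            genotype_table.get(mother, site),
            genotype_table.get(father, site),
            [genotype_table.get(c, site) for c in offspring],
        )

    for block in blocks:
        block = list(block)
        if len(block) < 2:
            results.append(BlockResult(block, [], [], [], []))
            continue
        engine = BlockPhaser(
            block, matrices, mother, father, offspring, k_m, k_f, config
        )
        candidates: list[CandidatePair] = []
        phased: list[int] = []
        excluded: list[int] = []
        for j, site in enumerate(block):
            g_m, g_f, g_cs = dosages_at(site)
            needs = g_m == MISSING or g_f == MISSING
            if needs and reestimate is not None:
                reestimate(site)
                g_m, g_f, g_cs = dosages_at(site)
            if g_m == MISSING or g_f == MISSING:
                excluded.append(site)
                continue
            if not candidates:
                # base phasing: a single canonical placement of the dosage column
                if not engine._check_compat(g_m, g_f, g_cs) and reestimate is not None:
                    reestimate(site)
                    g_m, g_f, g_cs = dosages_at(site)
                if not engine._check_compat(g_m, g_f, g_cs):
                    excluded.append(site)
                    continue
                base = CandidatePair(k_m, k_f, engine.data)
                col_m = np.array([0] * (k_m - g_m) + [1] * g_m, dtype=np.int8)
                col_f = np.array([0] * (k_f - g_f) + [1] * g_f, dtype=np.int8)
                base.cols_m.append(col_m)
                base.cols_f.append(col_f)
                for role, column in (
                    ("mother", col_m),
                    ("father", col_f),
                    ("offspring", np.concatenate([col_m, col_f])),
                ):
                    t, d = engine._touch(base, role, j, column)
                    if t is not None:
                        idx, new_prod, new_mix = t
                        base.prod[role][idx] = new_prod
                        base.mix[role][idx] = new_mix
                    base.log_lik += d
                candidates = [base]
                phased.append(site)
                engine.eta_trace.append(1)
                continue
            try:
                protos = engine.extend(candidates, j, g_m, g_f, g_cs)
                candidates = engine.branch_prune(protos)
            except ZeroExtensionError:
                if reestimate is not None:
                    reestimate(site)
                    g_m, g_f, g_cs = dosages_at(site)
                    try:
                        protos = engine.extend(candidates, j, g_m, g_f, g_cs)
                        candidates = engine.branch_prune(protos)
                    except ZeroExtensionError:
                        excluded.append(site)
                        continue
                else:
                    excluded.append(site)
                    continue
            phased.append(site)
            engine.eta_trace.append(len(candidates))
        results.append(
            BlockResult(
                block, phased, candidates, excluded, engine.eta_trace, engine.stats
            )
        )
    return results
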