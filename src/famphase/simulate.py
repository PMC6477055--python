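"""Synthetic tetraploid F1 populations with paired-end short-read fragments.

The generator emulates an outcrossing cross of two autotetraploid parents
over short genomic regions (default 1 kb):

* random reference sequence; SNP positions from cumulative lognormal
  inter-site gaps with mean 50 bp and SD 90 bp (moment-matched parameters);
* per-site parental alt dosages from a configurable categorical distribution
  skewed toward low dosages, resampled until the site segregates (the two
  parents are not both homozygous for the same allele); alt alleles placed
  on uniformly random homologs;
* offspring by balanced meiosis without recombination: a uniform random
  half of each parent's homologs;
* paired-end fragments (2 x 125 bp reads, ~350 bp insert) from uniformly
  random homologs and start positions, with each covered SNP allele flipped
  independently with the base error rate.

Everything is reproducible from a single ``numpy`` Generator; the draw order
is fixed (parents, then offspring, then fragments per individual in pedigree
order).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .popdata import (
    Fragment,
    FragmentMatrix,
    GenotypeTable,
    Phasing,
    SNPSite,
    error_to_phred,
)
from .transmission import Transmission

#: Default per-parent alt-dosage distribution for a tetraploid (g = 0..4).
#: A stand-in skewed toward low alt dosages, as in resequencing panels of
#: tetraploid cultivars; fully configurable.
DEFAULT_DOSAGE_PROBS = (0.40, 0.30, 0.15, 0.10, 0.05)


@dataclass
class SimConfig:
    """Simulation parameters; depths are per HOMOLOG (total depth = k * d)."""

    region_length: int = 1000
    ploidy: int = 4
    n_offspring: int = 10
    snp_gap_mean: float = 50.0
    snp_gap_sd: float = 90.0
    dosage_probs: tuple[float, ...] = DEFAULT_DOSAGE_PROBS
    read_length: int = 125
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    depth_mother: float = 5.0
    depth_father: float = 5.0
    depth_offspring: float = 2.0
    base_error: float = 0.001
    chrom: str = "region1"

    def __post_init__(self) -> None:
        if self.ploidy % 2 != 0 or self.ploidy < 2:
            raise ValueError("ploidy must be even and >= 2")
        for name in (
            "region_length",
            "n_offspring",
            "snp_gap_mean",
            "snp_gap_sd",
            "read_length",
            "insert_mean",
            "insert_sd",
            "depth_mother",
            "depth_father",
            "depth_offspring",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.base_error < 0.5:
            raise ValueError("base_error must be in [0, 0.5)")


@dataclass
class F1Truth:
    """Ground truth of a simulated region, for metric evaluation."""

    sites: list[SNPSite]
    reference: str
    h_m: Phasing
    h_f: Phasing
    offspring: dict[str, Phasing]
    transmissions: dict[str, Transmission]
    config: SimConfig

    @property
    def n_snps(self) -> int:
        return len(self.sites)

    def true_dosages(self) -> dict[str, np.ndarray]:
        out = {"mother": self.h_m.dosages(), "father": self.h_f.dosages()}
        for name, ph in self.offspring.items():
            out[name] = ph.dosages()
        return out

    def genotype_table(self) -> GenotypeTable:
        k = self.config.ploidy
        ploidies = {ind: k for ind in ["mother", "father", *self.offspring]}
        return GenotypeTable.from_arrays(
            ploidies, {ind: d.tolist() for ind, d in self.true_dosages().items()}
        )


def lognormal_gap_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with the given mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


_BASES = np.array(list("ACGT"))


def simulate_parents(
    config: SimConfig, rng: np.random.Generator, min_snps: int = 2, max_tries: int = 100
) -> tuple[str, list[SNPSite], Phasing, Phasing]:
    """Reference sequence, segregating SNP sites and the two parental phasings."""
    mu, sigma = lognormal_gap_params(config.snp_gap_mean, config.snp_gap_sd)
    for _ in range(max_tries):
        reference = "".join(rng.choice(_BASES, size=config.region_length))
        positions: list[int] = []
        cursor = 0.0
        while True:
            cursor += rng.lognormal(mu, sigma)
            pos = int(round(cursor))
            if pos >= config.region_length:
                break
            if not positions or pos > positions[-1]:
                positions.append(pos)
        if len(positions) >= min_snps:
            break
    else:
        raise RuntimeError(
            f"could not place {min_snps} SNPs in {config.region_length} bp"
        )

    k = config.ploidy
    probs = np.asarray(config.dosage_probs, dtype=float)
    probs = probs / probs.sum()
    if len(probs) != k + 1:
        raise ValueError("dosage_probs must have ploidy + 1 entries")

    sites = []
    cols_m, cols_f = [], []
    for idx, pos in enumerate(positions):
        ref = reference[pos]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        sites.append(SNPSite(idx, config.chrom, pos + 1, ref, alt))
        while True:
            g_m = int(rng.choice(k + 1, p=probs))
            g_f = int(rng.choice(k + 1, p=probs))
            if not (g_m == g_f == 0 or g_m == g_f == k):
                break  # segregating: parents not both homozygous same allele
        col_m = np.zeros(k, dtype=np.int8)
        col_m[rng.choice(k, size=g_m, replace=False)] = 1
        col_f = np.zeros(k, dtype=np.int8)
        col_f[rng.choice(k, size=g_f, replace=False)] = 1
        cols_m.append(col_m)
        cols_f.append(col_f)

    indices = list(range(len(sites)))
    h_m = Phasing(np.column_stack(cols_m), indices)
    h_f = Phasing(np.column_stack(cols_f), indices)
    return reference, sites, h_m, h_f


def simulate_offspring(
    h_m: Phasing, h_f: Phasing, n: int, rng: np.random.Generator
) -> list[tuple[Transmission, Phasing]]:
    """Balanced meiosis without recombination: random half of each parent."""
    out = []
    for _ in range(n):
        sub_m = tuple(sorted(int(x) for x in rng.choice(h_m.ploidy, size=h_m.ploidy // 2, replace=False)))
        sub_f = tuple(sorted(int(x) for x in rng.choice(h_f.ploidy, size=h_f.ploidy // 2, replace=False)))
        trans = Transmission(sub_m, sub_f)
        out.append((trans, trans.induced_phasing(h_m, h_f)))
    return out


def simulate_fragments(
    phasing: Phasing,
    sites: Sequence[SNPSite],
    config: SimConfig,
    depth_per_homolog: float,
    rng: np.random.Generator,
    individual_id: str,
) -> FragmentMatrix:
    """Paired-end fragments over one individual's haplotypes.

    Each template picks a uniform homolog and start; the insert length is
    Gaussian truncated at twice the read length; the two mate reads cover
    the first and last ``read_length`` bases of the insert.  SNP alleles in
    covered positions are copied from the source homolog and flipped with
    probability ``base_error``.
    """
    k = phasing.ploidy
    length = config.region_length
    n_templates = int(
        round(depth_per_homolog * k * length / (2.0 * config.read_length))
    )
    snp_pos = np.array([s.pos - 1 for s in sites])  # 0-based
    fragments = []
    for t in range(n_templates):
        homolog = int(rng.integers(k))
        insert = max(2 * config.read_length, int(round(rng.normal(config.insert_mean, config.insert_sd))))
        insert = min(insert, length)
        start = int(rng.integers(0, max(1, length - insert + 1)))
        end = start + insert
        in_r1 = (snp_pos >= start) & (snp_pos < start + config.read_length)
        in_r2 = (snp_pos >= end - config.read_length) & (snp_pos < end)
        covered = np.flatnonzero(in_r1 | in_r2)
        alleles, errors = {}, {}
        for idx in covered:
            true_allele = int(phasing.alleles[homolog, idx])
            if config.base_error > 0.0 and rng.random() < config.base_error:
                true_allele = 1 - true_allele
            alleles[int(idx)] = true_allele
            errors[int(idx)] = max(config.base_error, 1e-6)
        if alleles:
            fragments.append(
                Fragment(individual_id, alleles, errors, name=f"{individual_id}_t{t}")
            )
    return FragmentMatrix(individual_id, fragments, len(sites))


def simulate_population(
    config: SimConfig, rng: np.random.Generator | int | None = None
) -> tuple[F1Truth, dict[str, FragmentMatrix]]:
    """Full region: truth plus per-individual fragment matrices."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    reference, sites, h_m, h_f = simulate_parents(config, rng)
    kids = simulate_offspring(h_m, h_f, config.n_offspring, rng)
    offspring = {f"offspring{i + 1}": ph for i, (_, ph) in enumerate(kids)}
    transmissions = {f"offspring{i + 1}": tr for i, (tr, _) in enumerate(kids)}
    truth = F1Truth(sites, reference, h_m, h_f, offspring, transmissions, config)

    matrices = {
        "mother": simulate_fragments(h_m, sites, config, config.depth_mother, rng, "mother"),
        "father": simulate_fragments(h_f, sites, config, config.depth_father, rng, "father"),
    }
    for name, ph in offspring.items():
        matrices[name] = simulate_fragments(
            ph, sites, config, config.depth_offspring, rng, name
        )
    return truth, matrices


# ---------------------------------------------------------------------------
# optional file emission

def write_reference_fasta(path: str | Path, truth: F1Truth) -> None:
    with open(path, "w") as fh:
        fh.write(f">{truth.config.chrom}\n")
        seq = truth.reference
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_truth_json(path: str | Path, truth: F1Truth) -> None:
    payload = {
        "chrom": truth.config.chrom,
        "positions": [s.pos for s in truth.sites],
        "ref_alleles": [s.ref_allele for s in truth.sites],
        "alt_alleles": [s.alt_allele for s in truth.sites],
        "mother": truth.h_m.alleles.tolist(),
        "father": truth.h_f.alleles.tolist(),
        "offspring": {n: p.alleles.tolist() for n, p in truth.offspring.items()},
        "transmissions": {
            n: [list(t.maternal_subset), list(t.paternal_subset)]
            for n, t in truth.transmissions.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth_json(path: str | Path) -> F1Truth:
    with open(path) as fh:
        payload = json.load(fh)
    sites = [
        SNPSite(i, payload["chrom"], pos, r, a)
        for i, (pos, r, a) in enumerate(
            zip(payload["positions"], payload["ref_alleles"], payload["alt_alleles"])
        )
    ]
    indices = list(range(len(sites)))
    h_m = Phasing(np.array(payload["mother"]), indices)
    offspring = {
        n: Phasing(np.array(rows), indices) for n, rows in payload["offspring"].items()
    }
    transmissions = {
        n: Transmission(tuple(t[0]), tuple(t[1]))
        for n, t in payload["transmissions"].items()
    }
    config = SimConfig(ploidy=h_m.ploidy, chrom=payload["chrom"])
    return F1Truth(
        sites,
        "",
        h_m,
        Phasing(np.array(payload["father"]), indices),
        offspring,
        transmissions,
        config,
    )


def fragments_to_sam(
    path: str | Path,
    matrices: dict[str, FragmentMatrix],
    truth: F1Truth,
) -> None:
    """Emit simulated fragments as minimal SAM records.

    One record per fragment, aligned with an N-skip CIGAR so that exactly the
    covered SNP positions carry bases (the allele base, with the matching
    base quality).  Intended for integration tests of the alignment reader;
    real pipelines would align real reads instead.
    """
    config = truth.config
    length = config.region_length
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{config.chrom}\tLN:{length}\n")
        records = []
        for ind, mat in matrices.items():
            for frag in mat.fragments:
                idx = frag.indices
                positions = [truth.sites[s].pos - 1 for s in idx]
                start = positions[0]
                cigar = []
                for prev, cur in zip(positions, positions[1:]):
                    cigar.append("1M")
                    gap = cur - prev - 1
                    if gap > 0:
                        cigar.append(f"{gap}N")
                cigar.append("1M")
                seq = "".join(
                    truth.sites[s].alt_allele if frag.alleles[s] else truth.sites[s].ref_allele
                    for s in idx
                )
                quals = "".join(
                    chr(min(40, error_to_phred(frag.errors[s])) + 33) for s in idx
                )
                records.append(
                    (
                        start,
                        f"{ind}:{frag.name}\t0\t{config.chrom}\t{start + 1}\t60\t"
                        f"{''.join(cigar)}\t*\t0\t0\t{seq}\t{quals}",
                    )
                )
        for _, rec in sorted(records, key=lambda r: r[0]):
            fh.write(rec + "\n")
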