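"""Domain types and I/O for family-based polyploid phasing.

Internally every SNP is addressed by a dense 0-based index within a region
(the rank of its reference coordinate); VCF coordinates stay 1-based and the
conversion is confined to this module.  Fragments are sparse read->allele
maps over those indices, with a per-call error probability derived from base
quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for an uncalled dosage.
MISSING = -1

#: Error probabilities are clamped into this closed interval.
ERROR_FLOOR = 1e-6
ERROR_CEIL = 0.5


@dataclass(frozen=True)
class SNPSite:
    """A bi-allelic SNP: dense index within the region plus VCF coordinates."""

    index: int
    chrom: str
    pos: int  # 1-based reference coordinate
    ref_allele: str
    alt_allele: str


@dataclass
class Fragment:
    """Alleles called by one sequencing template at the SNPs it covers.

    ``alleles`` maps SNP index -> 0 (ref) / 1 (alt); ``errors`` maps the same
    indices to the base-calling error probability in (0, 0.5].
    """

    individual_id: str
    alleles: dict[int, int]
    errors: dict[int, float]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError("fragment must cover at least one SNP")
        if set(self.alleles) != set(self.errors):
            raise ValueError("alleles and errors must cover the same SNP indices")

    @property
    def indices(self) -> list[int]:
        return sorted(self.alleles)


@dataclass
class FragmentMatrix:
    """All fragments of one individual over a region with ``n_snps`` sites."""

    individual_id: str
    fragments: list[Fragment]
    n_snps: int

    def __post_init__(self) -> None:
        for frag in self.fragments:
            if max(frag.alleles) >= self.n_snps:
                raise ValueError("fragment index exceeds n_snps")


class Phasing:
    """``k`` haplotypes over a subset of SNPs, as a k x l' {0,1} matrix.

    Rows are homologs and carry no identity: two phasings equal up to a row
    permutation represent the same haplotype set.  ``snp_indices`` names the
    phased columns in region coordinates.
    """

    def __init__(self, alleles: np.ndarray, snp_indices: Sequence[int]):
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        k = alleles.shape[0]
        if k < 2 or k % 2 != 0:
            raise ValueError(f"ploidy must be an even integer >= 2, got {k}")
        if alleles.shape[1] != len(snp_indices):
            raise ValueError("snp_indices length must match number of columns")
        if not np.isin(alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1")
        self.alleles = alleles
        self.snp_indices = np.asarray(snp_indices, dtype=np.int64)

    @property
    def ploidy(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def dosages(self) -> np.ndarray:
        """Column sums: the alternative-allele dosage at each phased site."""
        return self.alleles.sum(axis=0)

    def canonical(self) -> "Phasing":
        """Rows sorted lexicographically; the representative of the row-permutation class."""
        order = np.lexsort(self.alleles.T[::-1])
        return Phasing(self.alleles[order], self.snp_indices)

    def canonical_key(self) -> bytes:
        order = np.lexsort(self.alleles.T[::-1])
        return self.alleles[order].tobytes()

    def restrict(self, indices: Sequence[int]) -> "Phasing":
        """Sub-phasing over the given region SNP indices (must all be phased here)."""
        pos = {int(s): j for j, s in enumerate(self.snp_indices)}
        cols = [pos[int(i)] for i in indices]
        return Phasing(self.alleles[:, cols], list(indices))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Phasing):
            return NotImplemented
        return (
            np.array_equal(self.snp_indices, other.snp_indices)
            and self.canonical_key() == other.canonical_key()
        )

    def __repr__(self) -> str:
        return f"Phasing(k={self.ploidy}, sites={self.snp_indices.tolist()})"


class GenotypeTable:
    """Per-individual, per-site alternative-allele dosages (or MISSING)."""

    def __init__(self, ploidies: Mapping[str, int], n_snps: int):
        self.ploidies = dict(ploidies)
        self.n_snps = n_snps
        self._dosages = {
            ind: np.full(n_snps, MISSING, dtype=np.int16) for ind in self.ploidies
        }

    @classmethod
    def from_arrays(
        cls, ploidies: Mapping[str, int], dosages: Mapping[str, Sequence[int]]
    ) -> "GenotypeTable":
        n_snps = len(next(iter(dosages.values())))
        table = cls(ploidies, n_snps)
        for ind, arr in dosages.items():
            for s, g in enumerate(arr):
                table.set(ind, s, int(g))
        return table

    def get(self, individual: str, site: int) -> int:
        return int(self._dosages[individual][site])

    def set(self, individual: str, site: int, dosage: int) -> None:
        if dosage != MISSING and not 0 <= dosage <= self.ploidies[individual]:
            raise ValueError(
                f"dosage {dosage} out of range for ploidy {self.ploidies[individual]}"
            )
        self._dosages[individual][site] = dosage

    def row(self, individual: str) -> np.ndarray:
        return self._dosages[individual].copy()

    @property
    def individuals(self) -> list[str]:
        return list(self.ploidies)

    def copy(self) -> "GenotypeTable":
        new = GenotypeTable(self.ploidies, self.n_snps)
        for ind in self.ploidies:
            new._dosages[ind] = self._dosages[ind].copy()
        return new


def phred_to_error(q: float) -> float:
    """Convert a phred quality to a clamped error probability."""
    return float(min(max(10.0 ** (-q / 10.0), ERROR_FLOOR), ERROR_CEIL))


def error_to_phred(e: float) -> int:
    return int(round(-10.0 * np.log10(max(e, ERROR_FLOOR))))


def read_fragments(
    alignment_file: str | Path,
    variant_sites: Sequence[SNPSite],
    individual_id: str,
    min_base_quality: int = 13,
    min_mapping_quality: int = 20,
) -> FragmentMatrix:
    """Extract a fragment matrix from an alignment file at the given SNPs.

    Mates of one template are merged into a single fragment; a contradictory
    overlap between mates at a SNP drops that site from the fragment.  Bases
    matching neither the ref nor the alt allele, or with quality below the
    thresholds (Q=0 always excluded), leave the site uncovered.  Fragments
    covering no SNP are dropped.
    """
    import pysam

    sites_by_pos = {(s.chrom, s.pos - 1): s for s in variant_sites}
    # template name -> (alleles, errors)
    templates: dict[str, tuple[dict[int, int], dict[int, float]]] = {}
    conflicts: dict[str, set[int]] = {}

    mode = "rb" if str(alignment_file).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignment_file), mode, check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapping_quality:
                continue
            quals = read.query_qualities
            seq = read.query_sequence
            if seq is None:
                continue
            alleles, errors = templates.setdefault(read.query_name, ({}, {}))
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                site = sites_by_pos.get((read.reference_name, rpos))
                if site is None:
                    continue
                q = quals[qpos] if quals is not None else 30
                if q < min_base_quality or q == 0:
                    continue
                base = seq[qpos].upper()
                if base == site.ref_allele:
                    call = 0
                elif base == site.alt_allele:
                    call = 1
                else:
                    continue  # third nucleotide: leave uncovered
                err = phred_to_error(q)
                if site.index in alleles and alleles[site.index] != call:
                    conflicts.setdefault(read.query_name, set()).add(site.index)
                    continue
                if site.index not in alleles or errors[site.index] > err:
                    alleles[site.index] = call
                    errors[site.index] = err

    fragments = []
    n_snps = len(variant_sites)
    for name, (alleles, errors) in templates.items():
        for idx in conflicts.get(name, ()):  # mate disagreement: drop the site
            alleles.pop(idx, None)
            errors.pop(idx, None)
        if alleles:
            fragments.append(Fragment(individual_id, alleles, errors, name=name))
    return FragmentMatrix(individual_id, fragments, n_snps)


# ---------------------------------------------------------------------------
# fragment text files (HapCUT-style, one fragment per line)

def write_fragment_file(path: str | Path, matrices: Iterable[FragmentMatrix]) -> None:
    """One fragment per line: name individual (index allele phred)*."""
    with open(path, "w") as fh:
        for mat in matrices:
            for i, frag in enumerate(mat.fragments):
                name = frag.name or f"{mat.individual_id}_frag{i}"
                cells = []
                for idx in frag.indices:
                    cells.append(
                        f"{idx} {frag.alleles[idx]} {error_to_phred(frag.errors[idx])}"
                    )
                fh.write(f"{name}\t{mat.individual_id}\t" + " ".join(cells) + "\n")


def read_fragment_file(
    path: str | Path, n_snps: int
) -> dict[str, FragmentMatrix]:
    mats: dict[str, list[Fragment]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, ind, rest = line.split("\t")
            tokens = rest.split()
            alleles, errors = {}, {}
            for j in range(0, len(tokens), 3):
                idx, allele, q = int(tokens[j]), int(tokens[j + 1]), float(tokens[j + 2])
                alleles[idx] = allele
                errors[idx] = phred_to_error(q)
            mats.setdefault(ind, []).append(Fragment(ind, alleles, errors, name=name))
    return {
        ind: FragmentMatrix(ind, frags, n_snps) for ind, frags in mats.items()
    }


def read_input_vcf(
    path: str | Path, ploidies: Mapping[str, int]
) -> tuple[list[SNPSite], GenotypeTable]:
    """Read called bi-allelic SNPs and dosages from a VCF.

    Multi-allelic or non-SNP records are skipped with a warning.  Dosage is
    the number of alternative alleles in the GT field; uncalled GTs map to
    MISSING.  Samples without an entry in ``ploidies`` are ignored.
    """
    import pysam

    sites: list[SNPSite] = []
    dosages: dict[str, list[int]] = {}
    with pysam.VariantFile(str(path)) as vf:
        individuals = [s for s in vf.header.samples if s in ploidies]
        for ind in individuals:
            dosages[ind] = []
        for rec in vf:
            if (
                rec.alts is None
                or len(rec.alts) != 1
                or len(rec.ref) != 1
                or len(rec.alts[0]) != 1
            ):
                logger.warning(
                    "skipping non-bi-allelic-SNP record at %s:%d", rec.chrom, rec.pos
                )
                continue
            idx = len(sites)
            sites.append(SNPSite(idx, rec.chrom, rec.pos, rec.ref, rec.alts[0]))
            for ind in individuals:
                gt = rec.samples[ind]["GT"]
                if gt is None or any(a is None for a in gt):
                    dosages[ind].append(MISSING)
                else:
                    dosages[ind].append(int(sum(gt)))
    table = GenotypeTable.from_arrays(
        {ind: ploidies[ind] for ind in individuals}, dosages
    )
    return sites, table


# ---------------------------------------------------------------------------
# phased VCF output / input

def write_phased_vcf(
    path: str | Path,
    sites: Sequence[SNPSite],
    genotype_table: GenotypeTable,
    phasings: Mapping[str, Sequence[Phasing]],
    blocks: Sequence[Sequence[int]],
    original_dosages: Mapping[str, Sequence[int]] | None = None,
) -> None:
    """Write a VCF 4.2 with phased GTs and per-block phase sets.

    ``phasings[ind]`` is a list of per-block phasings for that individual;
    sites absent from every phasing of an individual are written unphased.
    A corrected dosage is recorded next to the original in the per-sample
    ``OD`` field.  Phase-set IDs (``PS``) are the 1-based position of the
    first SNP of the block, the usual convention.
    """
    individuals = genotype_table.individuals
    # site index -> (individual -> (column tuple, phase set id))
    phased_cols: dict[int, dict[str, tuple[tuple[int, ...], int]]] = {}
    block_of_site = {}
    for block in blocks:
        ps_id = sites[min(block)].pos
        for s in block:
            block_of_site[s] = ps_id
    for ind, plist in phasings.items():
        for ph in plist:
            for j, s in enumerate(ph.snp_indices):
                s = int(s)
                col = tuple(int(a) for a in ph.alleles[:, j])
                g = genotype_table.get(ind, s)
                if g != MISSING and sum(col) != g:
                    raise ValueError(
                        f"phasing/dosage mismatch for {ind} at site {s}: "
                        f"column {col} vs dosage {g}"
                    )
                phased_cols.setdefault(s, {})[ind] = (col, block_of_site.get(s, sites[s].pos))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write(
            '##FORMAT=<ID=OD,Number=1,Type=Integer,'
            'Description="Original input dosage where corrected">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(individuals)
            + "\n"
        )
        for site in sites:
            cells = []
            for ind in individuals:
                k = genotype_table.ploidies[ind]
                g = genotype_table.get(ind, site.index)
                entry = phased_cols.get(site.index, {}).get(ind)
                if entry is not None:
                    col, ps = entry
                    gt = "|".join(str(a) for a in col)
                    cell = f"{gt}:{ps}"
                elif g == MISSING:
                    cell = "/".join("." * k) + ":."
                else:
                    gt = "/".join(["0"] * (k - g) + ["1"] * g)
                    cell = f"{gt}:."
                od = "."
                if original_dosages is not None:
                    orig = int(original_dosages[ind][site.index])
                    if orig != genotype_table.get(ind, site.index):
                        od = str(orig)
                cells.append(f"{cell}:{od}")
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref_allele}\t{site.alt_allele}"
                f"\t.\tPASS\t.\tGT:PS:OD\t" + "\t".join(cells) + "\n"
            )


def read_phased_vcf(
    path: str | Path, ploidies: Mapping[str, int]
) -> tuple[list[SNPSite], GenotypeTable, dict[str, list[Phasing]], list[list[int]]]:
    """Read back a phased VCF written by :func:`write_phased_vcf`."""
    import pysam

    sites: list[SNPSite] = []
    columns: dict[str, list[tuple[int, tuple[int, ...], int] ]] = {}
    dosages: dict[str, list[int]] = {}
    with pysam.VariantFile(str(path)) as vf:
        individuals = list(vf.header.samples)
        for ind in individuals:
            columns[ind] = []
            dosages[ind] = []
        for idx, rec in enumerate(vf):
            sites.append(
                SNPSite(idx, rec.chrom, rec.pos, rec.ref, rec.alts[0])
            )
            for ind in individuals:
                sample = rec.samples[ind]
                gt = sample["GT"]
                if gt is None or gt[0] is None:
                    dosages[ind].append(MISSING)
                    continue
                dosages[ind].append(int(sum(gt)))
                if sample.phased:
                    ps = sample["PS"]
                    columns[ind].append((idx, tuple(int(a) for a in gt), int(ps)))

    table = GenotypeTable.from_arrays(
        {ind: ploidies[ind] for ind in individuals}, dosages
    )
    phasings: dict[str, list[Phasing]] = {ind: [] for ind in individuals}
    block_sets: dict[int, set[int]] = {}
    for ind in individuals:
        by_ps: dict[int, list[tuple[int, tuple[int, ...]]]] = {}
        for idx, col, ps in columns[ind]:
            by_ps.setdefault(ps, []).append((idx, col))
            block_sets.setdefault(ps, set()).add(idx)
        for ps in sorted(by_ps):
            entries = sorted(by_ps[ps])
            mat = np.array([col for _, col in entries], dtype=np.int8).T
            phasings[ind].append(Phasing(mat, [idx for idx, _ in entries]))
    blocks = [sorted(block_sets[ps]) for ps in sorted(block_sets)]
    return sites, table, phasings, blocks
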