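"""End-to-end orchestration: blocks -> genotype correction -> parental
phasing -> offspring selection, plus the simulation benchmark driver."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import blocks as blocks_mod
from . import genotypes, metrics, offspring as offspring_mod
from .phaser import BlockResult, PhaserConfig, phase_parents
from .popdata import MISSING, FragmentMatrix, GenotypeTable, Phasing
from .simulate import F1Truth, SimConfig, simulate_population

logger = logging.getLogger(__name__)


@dataclass
class PopulationPhasing:
    """Rank-1 phasing of a whole population plus bookkeeping."""

    blocks: list[list[int]]
    block_results: list[BlockResult]
    solution_sets: list[list[offspring_mod.SolutionSet]]  # ranked, per block
    phasings: dict[str, list[Phasing]]  # rank-1, per individual
    genotype_table: GenotypeTable  # corrected dosages
    excluded_sites: list[int]
    corrections: list[tuple[str, int, int, int]]  # individual, site, old, new
    n_snps: int

    @property
    def ngps(self) -> float:
        return blocks_mod.ngps(self.blocks, self.n_snps)


def phase_population(
    matrices: Mapping[str, FragmentMatrix],
    genotype_table: GenotypeTable,
    mother: str,
    father: str,
    offspring: Sequence[str],
    config: PhaserConfig | None = None,
    top_sets: int = 1,
) -> PopulationPhasing:
    """Run the full family-based phasing pipeline on one region.

    Input dosages are used as given; a site's genotypes are re-estimated by
    the Mendelian MAP model only when a parental dosage is missing or every
    phasing extension there has zero posterior.  The corrected table,
    including dosages implied by the selected offspring transmissions, is
    returned alongside the phasings.
    """
    config = config or PhaserConfig()
    table = genotype_table.copy()
    original = genotype_table
    n_snps = table.n_snps
    partition = blocks_mod.find_blocks(matrices.values(), n_snps)
    corrections: list[tuple[str, int, int, int]] = []

    individuals = [mother, father, *offspring]

    def reestimate(site: int) -> None:
        evidence = {
            ind: genotypes.site_evidence(matrices[ind], site)
            for ind in individuals
            if ind in matrices
        }
        called = {ind: table.get(ind, site) for ind in individuals}
        assign = genotypes.map_population_genotypes(
            evidence, table.ploidies, mother, father, list(offspring), called
        )
        for ind, g in assign.items():
            old = table.get(ind, site)
            if old != g:
                corrections.append((ind, site, old, g))
                table.set(ind, site, g)

    results = phase_parents(
        matrices, table, partition, mother, father, offspring, config, reestimate
    )

    phasings: dict[str, list[Phasing]] = {ind: [] for ind in individuals}
    solution_sets: list[list[offspring_mod.SolutionSet]] = []
    excluded: list[int] = []
    for result in results:
        excluded.extend(result.excluded_sites)
        if not result.is_phased:
            solution_sets.append([])
            continue
        ranked, bad_sites = offspring_mod.resolve_block(
            result, matrices, table, offspring, top_sets=top_sets
        )
        excluded.extend(bad_sites)
        solution_sets.append(ranked)
        if not ranked:
            continue
        best = ranked[0]
        phasings[mother].append(best.h_m)
        phasings[father].append(best.h_f)
        for child in offspring:
            phasings[child].append(best.offspring[child].phasing)

    # reconcile table dosages with the dosages implied by the phasings
    for ind in individuals:
        for ph in phasings[ind]:
            implied = ph.dosages()
            for j, s in enumerate(map(int, ph.snp_indices)):
                old = table.get(ind, s)
                if old != int(implied[j]):
                    corrections.append((ind, s, old, int(implied[j])))
                    table.set(ind, s, int(implied[j]))

    return PopulationPhasing(
        partition,
        results,
        solution_sets,
        phasings,
        table,
        sorted(set(excluded)),
        corrections,
        n_snps,
    )


# ---------------------------------------------------------------------------
# evaluation against simulated truth


def evaluate_against_truth(
    truth: F1Truth, outcome: PopulationPhasing
) -> pd.DataFrame:
    """Per-individual RR/PAR/SMR/IDR/NGPS of a pipeline outcome."""
    ngps_value = outcome.ngps
    evals = []
    roles = {"mother": "parent", "father": "parent"}
    truth_ph = {"mother": truth.h_m, "father": truth.h_f}
    truth_dos = truth.true_dosages()
    for name, ph in truth.offspring.items():
        roles[name] = "offspring"
        truth_ph[name] = ph
    for name in roles:
        ev = metrics.evaluate_individual(
            name,
            truth_ph[name],
            truth_dos[name].tolist(),
            outcome.phasings.get(name, []),
            ngps_value,
        )
        evals.append(ev)
    frame = metrics.report_frame(evals)
    frame["role"] = [roles[n] for n in frame["individual"]]
    return frame


def run_region(
    sim_config: SimConfig,
    phaser_config: PhaserConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[F1Truth, PopulationPhasing, pd.DataFrame]:
    """Simulate one region, phase it, evaluate it."""
    truth, matrices = simulate_population(sim_config, rng)
    outcome = phase_population(
        matrices,
        truth.genotype_table(),
        "mother",
        "father",
        list(truth.offspring),
        phaser_config,
    )
    frame = evaluate_against_truth(truth, outcome)
    return truth, outcome, frame


def benchmark_grid(
    n_offspring_values: Sequence[int],
    n_regions: int,
    seed: int,
    sim_config: SimConfig | None = None,
    phaser_config: PhaserConfig | None = None,
) -> pd.DataFrame:
    """Simulate/phase/evaluate a grid of population sizes.

    Returns one row per (scenario, region, individual).  Each region draws
    its generator from a seed sequence spawned deterministically from
    ``seed``, so results are reproducible and independent of grid order.
    """
    base = sim_config or SimConfig()
    frames = []
    for n in n_offspring_values:
        for region in range(n_regions):
            cfg = SimConfig(
                **{
                    **base.__dict__,
                    "n_offspring": int(n),
                    "chrom": f"region_n{n}_r{region}",
                }
            )
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), int(n), int(region)])
            )
            _, _, frame = run_region(cfg, phaser_config, rng)
            frame.insert(0, "n_offspring", int(n))
            frame.insert(1, "region", region)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Scenario means and 2.5/97.5 empirical percentiles per metric."""
    rows = []
    for n, group in results.groupby("n_offspring"):
        for metric in ("par", "rr", "smr", "idr", "ngps"):
            vals = group[metric].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            rows.append(
                {
                    "n_offspring": n,
                    "metric": metric,
                    "mean": vals.mean() if vals.size else np.nan,
                    "lo95": np.percentile(vals, 2.5) if vals.size else np.nan,
                    "hi95": np.percentile(vals, 97.5) if vals.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def grid_averages(results: pd.DataFrame) -> dict[str, float]:
    """Scenario-balanced averages of the five metrics, plus role-restricted RR.

    Each scenario (offspring count) contributes its individual-level mean;
    scenarios are then averaged with equal weight, mirroring a summary over
    population sizes.
    """
    per_scenario = []
    for n, group in results.groupby("n_offspring"):
        entry = {"n_offspring": n}
        for metric in ("par", "rr", "smr", "idr", "ngps"):
            entry[metric] = float(np.nanmean(group[metric].to_numpy(dtype=float)))
        entry["rr_offspring"] = float(
            np.nanmean(group.loc[group.role == "offspring", "rr"].to_numpy(dtype=float))
        )
        entry["rr_parents"] = float(
            np.nanmean(group.loc[group.role == "parent", "rr"].to_numpy(dtype=float))
        )
        entry["idr_all"] = entry["idr"]
        per_scenario.append(entry)
    frame = pd.DataFrame(per_scenario)
    out = {}
    for col in ("par", "rr", "smr", "idr", "ngps", "rr_offspring", "rr_parents"):
        out[col] = float(frame[col].mean())
    return out
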