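# Methods

## Setting and assumptions

`famphase` phases bi-allelic SNPs in an outcrossing F1 family: two parents
of even ploidies k_m, k_f and n offspring, each sequenced with short reads
aligned to a common reference, with per-individual allele dosages called at
every SNP. Three assumptions carry the whole method:

1. **No recombination within a block.** Haplotype blocks obtained from
   short reads span at most a few kb. At typical genetic-to-physical ratios
   of a few cM/Mb, crossovers inside such a window are vanishingly rare for
   family sizes up to a few hundred, so every offspring haplotype is taken
   to be an exact copy of a parental haplotype.
2. **Balanced polysomic meiosis.** A gamete receives a uniformly random
   half of the parent's homologs: no double reduction, no preferential
   pairing, even ploidies only. The alt-allele count of a gamete at one SNP
   is then hypergeometric, and an offspring dosage distribution is the
   convolution of the two parental gamete distributions.
3. **Independent uniform-homolog base sampling.** A read base at a SNP
   originates from a uniformly random homolog of its individual and is
   miscalled with the probability encoded in its base quality (clamped to
   [1e-6, 0.5]; Q=0 bases are discarded).

Input dosages are trusted as called; re-estimation is an exception path,
not the default (see below).

## Pipeline

**Blocks.** Fragments (mate pairs merged per template) from *all*
individuals are pooled; two SNPs are connected when one fragment covers
both, and blocks are the connected components. Pooling is what gives the
family-based method its continuity advantage: a gap in one individual's
coverage is bridged by any other family member. Singleton blocks are
reported dosage-only.

**Parental extension.** Within a block the parental pair is grown SNP by
SNP. The base phasing at the first usable SNP is the canonical placement of
its dosage column (all placements are equivalent up to homolog relabeling).
At each further SNP s, all C(k_m, g_m)·C(k_f, g_f) allele placements are
enumerated per surviving candidate, deduplicated up to row permutation of
the extended prefix, and given a uniform prior; the likelihood factor is the
product over fragments covering s of the fragment's homolog-mixture
likelihood (mother and father fragments mix over their own rows, offspring
fragments over the union of both parents' rows). Posteriors are normalised
over all extensions of all candidates, then thresholded: extensions below
rho are dropped (branching), survivors below kappa times the best posterior
are dropped (pruning), the argmax is always kept.

Only fragments covering at least two SNPs of the block participate:
single-SNP fragments multiply every same-dosage extension by the same
constant and cancel in the normalisation. Likelihoods are accumulated
incrementally — per-fragment, per-row running products are cached per
candidate, and a step touches only fragments covering the new SNP — which
keeps the work per step proportional to coverage at that SNP times the
number of enumerated extensions (linear overall in block length and family
size at a fixed number of surviving candidates; the test suite checks this
operationally via the engine's operation counters).

**Genotype re-estimation.** Two triggers: a missing parental dosage at the
extension SNP, or all extensions there having zero posterior (which, since
read likelihoods are strictly positive, means some called offspring dosage
has zero transmission probability under the called parental pair). The
population genotypes at the SNP are then re-estimated by joint MAP under
flat parental prior × parental read likelihoods × per-offspring
(transmission pmf × read likelihood), maximised exactly thanks to the
conditional independence of offspring given parents. Ties break toward the
originally called dosage, then toward the smaller dosage. Offspring with no
reads receive the transmission argmax — this is how uncalled genotypes are
imputed. If the site remains unusable it is excluded from phasing.

**Offspring selection.** For each surviving parental pair all
C(k_m, k_m/2)·C(k_f, k_f/2) transmissions are materialised (36 for 4×4).
First, per offspring, the transmission with the fewest disagreements
between its induced dosages and the offspring's called dosages is found;
with ties, the transmission whose first disagreement comes latest in block
order wins, so the site excluded in a two-site conflict is the downstream
one, matching the extension-order semantics. Any remaining disagreement
sites are unexplainable without recombination and are excluded from the
block's phasing — population-wide by default (a flag keeps the site for
unaffected individuals). Each offspring then receives the MEC-minimising
transmission over the retained sites; MEC ties break by the read-mixture
log-likelihood of the induced phasing, then canonical order. Offspring
inherit phased alleles at every retained parental SNP, including sites
their own reads never cover.

**Ranking and output.** Population solutions are ranked by parental
posterior, then ascending summed offspring MEC. The rank-1 solution is
written as a VCF 4.2 with ordered (|-separated) genotypes, a per-block
phase-set tag, and the pre-correction dosage in a per-sample `OD` field
wherever the pipeline changed it.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| rho | 0.2 | hard posterior floor per extension; keeps the candidate set from exploding while tolerating a 4-way ambiguity |
| kappa | 0.94 | soft floor relative to the best extension; discards candidates clearly dominated by the leader |
| max_candidates | 256 | safety cap on survivors beyond rho/kappa; logged when hit |
| min_base_quality | Q13 | ≈5% error ceiling per used base (configurable; alignment input only) |
| min_mapping_quality | 20 | standard short-read mapping floor (configurable) |

## The simulator

The generator emulates the validation conditions: 1 kb regions, SNP
inter-site gaps lognormal with mean 50 bp and SD 90 bp (moment-matched
μ = ln 50 − σ²/2, σ² = ln(1 + (90/50)²)), per-parent alt dosages from a
categorical distribution skewed toward low dosages
(0.40/0.30/0.15/0.10/0.05 for g = 0..4 — a stand-in for panel-derived
dosage frequencies in tetraploid cultivars, fully configurable), resampled
until the site segregates; offspring by balanced meiosis without
recombination; paired-end templates of 2×125 bp with Gaussian inserts
(mean 350 bp, SD 35 bp — the SD is this package's choice), uniform start
and homolog, per-homolog depths 5-5-2× (mother-father-offspring), and a
uniform per-base flip rate ε = 0.001 recorded as the matching quality.

What it deliberately does **not** emulate: indels and structural variants,
alignment and mapping bias, a variant-calling stage (input dosages are the
simulated truth), quality-score profiles of real instruments, and real
reference sequence content (haplotyping accuracy depends on the SNPs, not
the bases between them). Consequences for interpreting green tests: dosage
errors enter only through the pipeline's own decisions, so the incorrect
dosage rate measures phasing-induced errors, not caller noise, and the SNP
missing rate reflects exclusions and connectivity only, not uncalled
variants. On real data all of these would be higher.

A known sensitivity: the number of phasing gaps per SNP is governed by the
tail of the inter-SNP gap distribution relative to the maximal template
span (~insert mean + a few SDs). Under the defaults roughly one region in
ten contains a gap no template can bridge, so simulated NGPS is small but
not negligible; a simulator with a longer-insert tail or denser SNPs would
drive it toward zero. The lognormal parametrisation and insert SD are the
two knobs involved; both are documented above and left at their stated
defaults.

## Numerical and design choices

* All extension weights are handled in log space; posteriors are
  renormalised after every step (asserted in tests).
* Homolog rows carry no identity: canonical form is rows sorted
  lexicographically, used for deduplication, reproducible tie-breaking and
  equality.
* Identical extended phasings reached from different candidates are merged,
  summing their posteriors.
* The reconstruction-rate row matching is solved exactly with a linear
  assignment solver (brute-force permutation oracle in the tests).
* Degenerate inputs: blocks of one SNP are dosage-only; fragments covering
  zero SNPs are dropped; contradictory mate overlaps drop the site from the
  template; an all-zero genotype likelihood falls back to a flat posterior
  with a warning; an empty candidate set after thresholding keeps the
  argmax.
* Offspring read likelihood during parental extension mixes uniformly over
  the union of parental rows rather than weighting rows by transmission;
  transmission information enters through the dosage conditioning and the
  later MEC selection. This keeps the extension posterior a function of the
  parental pair alone.
* The benchmark grid (20 regions per scenario, 2/6/10/30 offspring) is the
  package's chosen problem size: large enough for stable means of
  region-level metrics, small enough to run routinely on one CPU.

## Limitations

Even ploidies only; no recombination within blocks (long regions or very
large families violate this); bi-allelic SNPs only (multi-allelic records
are skipped); no variant calling or alignment — the tool starts from called
dosages and aligned reads; population-wide site exclusion can discard a
site a single aberrant offspring could not explain; accuracy with a single
offspring is limited because some parental haplotypes may simply not be
transmitted.
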