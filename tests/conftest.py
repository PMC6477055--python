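import numpy as np
import pytest

from famphase.popdata import Fragment, FragmentMatrix, Phasing
from famphase.simulate import SimConfig, simulate_population


def make_phasing(rows, indices=None) -> Phasing:
    rows = np.asarray(rows, dtype=np.int8)
    if indices is None:
        indices = list(range(rows.shape[1]))
    return Phasing(rows, indices)


def make_fragment(alleles: dict[int, int], err: float = 0.001, ind="x", name="f"):
    return Fragment(ind, dict(alleles), {i: err for i in alleles}, name=name)


def fragments_from_rows(phasing: Phasing, spans, err=1e-6, ind="x"):
    """Noise-free fragments copying the given homolog rows over index spans.

    ``spans`` is a list of (row, [snp indices]).
    """
    frags = []
    for i, (row, idx) in enumerate(spans):
        alleles = {int(s): int(phasing.alleles[row, list(phasing.snp_indices).index(s)]) for s in idx}
        frags.append(Fragment(ind, alleles, {int(s): err for s in idx}, name=f"{ind}{i}"))
    return FragmentMatrix(ind, frags, int(max(phasing.snp_indices)) + 1)


@pytest.fixture(scope="session")
def small_family():
    """A deeply covered 6-offspring tetraploid region (fixed seed)."""
    cfg = SimConfig(n_offspring=6, region_length=600)
    truth, mats = simulate_population(cfg, np.random.default_rng(20260930))
    return truth, mats
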