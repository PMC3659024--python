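import numpy as np
import pytest

from culturekin import (
    GeneticPedigree,
    Individual,
)


@pytest.fixture
def trio() -> GeneticPedigree:
    """Two unrelated founders and their offspring."""
    return GeneticPedigree([
        Individual("s"), Individual("d"), Individual("o", "s", "d"),
    ])


@pytest.fixture
def full_sib_mating() -> GeneticPedigree:
    """Full sibs a, b from unrelated founders; x is their offspring."""
    return GeneticPedigree([
        Individual("s"), Individual("d"),
        Individual("a", "s", "d"), Individual("b", "s", "d"),
        Individual("x", "a", "b"),
    ])


def gene_drop_kinship(ped: GeneticPedigree, i: str, j: str,
                      n_drops: int = 1_000_000, seed: int = 0
                      ) -> tuple[float, float]:
    """Monte-Carlo coancestry oracle by gene dropping.

    Founders receive unique allele pairs; every offspring inherits one
    random allele from each parent (unknown parents contribute fresh
    unique alleles).  theta_ij is estimated as the probability that an
    allele picked at random from i equals one picked at random from j.
    Returns (estimate, standard error).  Fully vectorized over drops.
    """
    rng = np.random.default_rng(seed)
    sire, dam = ped.parent_arrays()
    n = len(ped)
    # allele ids: 2k / 2k+1 for the founder-contributed copies of slot k
    mat = np.empty((n, n_drops), dtype=np.int64)
    pat = np.empty((n, n_drops), dtype=np.int64)
    for k in range(n):
        for alleles, parent in ((pat, sire[k]), (mat, dam[k])):
            if parent < 0:
                alleles[k] = 2 * k + (0 if alleles is pat else 1)
            else:
                pick = rng.integers(0, 2, size=n_drops, dtype=np.int64)
                alleles[k] = np.where(pick == 0, pat[parent], mat[parent])
    idx = {name: k for k, name in enumerate(ped.ids)}
    a, b = idx[i], idx[j]
    pick_i = rng.integers(0, 2, size=n_drops)
    pick_j = rng.integers(0, 2, size=n_drops)
    allele_i = np.where(pick_i == 0, pat[a], mat[a])
    allele_j = np.where(pick_j == 0, pat[b], mat[b])
    hits = (allele_i == allele_j).astype(float)
    est = float(hits.mean())
    se = float(hits.std(ddof=1) / np.sqrt(n_drops))
    return est, se
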