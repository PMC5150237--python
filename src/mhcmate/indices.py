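"""The five MHC genetic parameters.

Three couple-level dissimilarity indices and two male-level diversity
indices, all computed on pooled allele sets and an amino-acid Hamming
distance matrix:

* ``MALDis`` — male allele dissimilarity: number of alleles the male
  carries that the female does not (alleles "unknown" to her immune
  repertoire).
* ``CALDis`` — couple allele dissimilarity: size of the symmetric
  difference of the two allele sets.
* ``muAADis`` — mean amino-acid distance among the couple's non-shared
  alleles. The phrase "among the non-shared alleles" admits two readings,
  selected by ``mode``: pairs *within* the symmetric difference (default)
  or *cross* pairs female-only x male-only. Undefined (no pairs) is
  reported with ``defined=False``.
* ``MALDiv`` — number of distinct alleles of the male.
* ``MAADiv`` — sum of pairwise amino-acid distances among the male's
  alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np

from .types import Allele

__all__ = [
    "INDEX_NAMES",
    "DISSIMILARITY_INDICES",
    "DIVERSITY_INDICES",
    "AADistanceMatrix",
    "IndexValue",
    "aa_distance_matrix",
    "maldis",
    "caldis",
    "mu_aadis",
    "maldiv",
    "maadiv",
    "compute_index",
]

DISSIMILARITY_INDICES = ("MALDis", "CALDis", "muAADis")
DIVERSITY_INDICES = ("MALDiv", "MAADiv")
INDEX_NAMES = DISSIMILARITY_INDICES + DIVERSITY_INDICES


@dataclass(frozen=True)
class IndexValue:
    value: float
    defined: bool = True


class AADistanceMatrix:
    """Pairwise amino-acid Hamming distances for one gene's allele catalog."""

    def __init__(self, gene: str, allele_ids: list[str], d: np.ndarray):
        d = np.asarray(d)
        if d.shape != (len(allele_ids), len(allele_ids)):
            raise ValueError("distance matrix shape mismatch")
        if (d < 0).any() or not np.array_equal(d, d.T) or np.diag(d).any():
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
        self.gene = gene
        self.allele_ids = list(allele_ids)
        self.d = d
        self._idx = {a: i for i, a in enumerate(allele_ids)}

    def index_of(self, allele_id: str) -> int:
        try:
            return self._idx[allele_id]
        except KeyError:
            raise KeyError(f"allele {allele_id!r} not in {self.gene} distance matrix")

    def dist(self, a: str, b: str) -> int:
        return int(self.d[self.index_of(a), self.index_of(b)])


def aa_distance_matrix(alleles: Iterable[Allele]) -> AADistanceMatrix:
    """Hamming distances between translations; no alignment is attempted."""
    alleles = list(alleles)
    if not alleles:
        raise ValueError("empty allele list")
    genes = {a.gene for a in alleles}
    if len(genes) != 1:
        raise ValueError(f"alleles from multiple genes: {sorted(genes)}")
    lengths = {len(a.aa) for a in alleles}
    if len(lengths) != 1:
        raise ValueError(f"unequal amino-acid lengths: {sorted(lengths)}")
    # byte matrix -> pairwise mismatch counts
    arr = np.frombuffer("".join(a.aa for a in alleles).encode(), dtype=np.uint8).reshape(
        len(alleles), -1
    )
    d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(np.int64)
    return AADistanceMatrix(genes.pop(), [a.allele_id for a in alleles], d)


def maldis(female: frozenset[str] | set[str], male: frozenset[str] | set[str]) -> int:
    """Number of male alleles not shared by the female."""
    _check_sets(female, male)
    return len(set(male) - set(female))


def caldis(female: frozenset[str] | set[str], male: frozenset[str] | set[str]) -> int:
    """Total non-shared alleles in the couple (symmetric difference size)."""
    _check_sets(female, male)
    return len(set(male) ^ set(female))


def mu_aadis(
    female: frozenset[str] | set[str],
    male: frozenset[str] | set[str],
    D: AADistanceMatrix,
    mode: str = "within_symdiff",
) -> IndexValue:
    """Mean amino-acid distance among the couple's non-shared alleles."""
    _check_sets(female, male)
    female, male = set(female), set(male)
    for a in female | male:
        D.index_of(a)
    if mode == "within_symdiff":
        pool = sorted(female ^ male)
        pairs = list(combinations(pool, 2))
    elif mode == "cross":
        f_only = sorted(female - male)
        m_only = sorted(male - female)
        pairs = [(a, b) for a in f_only for b in m_only]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not pairs:
        return IndexValue(0.0, defined=False)
    return IndexValue(float(np.mean([D.dist(a, b) for a, b in pairs])), True)


def maldiv(male: frozenset[str] | set[str]) -> int:
    """Number of distinct alleles of the male."""
    if not male:
        raise ValueError("empty genotype set")
    return len(set(male))


def maadiv(male: frozenset[str] | set[str], D: AADistanceMatrix) -> float:
    """Sum of pairwise amino-acid distances among the male's alleles."""
    if not male:
        raise ValueError("empty genotype set")
    for a in male:
        D.index_of(a)
    return float(sum(D.dist(a, b) for a, b in combinations(sorted(male), 2)))


def compute_index(
    index_name: str,
    female: frozenset[str] | None,
    male: frozenset[str],
    D: AADistanceMatrix | None = None,
    mu_mode: str = "within_symdiff",
) -> IndexValue:
    """Uniform entry point; ``female`` may be None for diversity indices."""
    if index_name in DISSIMILARITY_INDICES and female is None:
        raise ValueError(f"{index_name} requires the female genotype")
    if index_name == "MALDis":
        return IndexValue(float(maldis(female, male)))
    if index_name == "CALDis":
        return IndexValue(float(caldis(female, male)))
    if index_name == "muAADis":
        return mu_aadis(female, male, _require_d(index_name, D), mode=mu_mode)
    if index_name == "MALDiv":
        return IndexValue(float(maldiv(male)))
    if index_name == "MAADiv":
        return IndexValue(maadiv(male, _require_d(index_name, D)))
    raise ValueError(f"unknown index {index_name!r}")


def _require_d(name: str, D: AADistanceMatrix | None) -> AADistanceMatrix:
    if D is None:
        raise ValueError(f"{name} requires an amino-acid distance matrix")
    return D


def _check_sets(female, male) -> None:
    if not female or not male:
        raise ValueError("genotype sets must be non-empty")
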