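"""Domain types shared across the package.

Genotypes are *pooled* allele sets: for gene families whose member loci
cannot be resolved (the usual situation for MHC amplicons in non-model
species) an individual's genotype is the unordered set of allele IDs
amplified from all loci of that family, treated as one super-locus.
Diploid candidate genes (TAARs) and microsatellites are stored the same
way, as sets of 1-2 distinct alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "CODING_GENES",
    "Allele",
    "Individual",
    "ChoiceEvent",
    "CandidatePool",
    "GenotypeTable",
]

#: Gene families with in-frame coding amplicons (translated for distance work).
CODING_GENES = ("MHC1", "MHC2", "TAAR2", "TAAR3", "TAAR8")


@dataclass(frozen=True)
class Allele:
    """A named in-frame coding (or neutral) DNA sequence of one gene."""

    allele_id: str
    gene: str
    dna: str
    aa: str = ""

    def __post_init__(self) -> None:
        if self.aa and len(self.dna) != 3 * len(self.aa):
            raise ValueError(
                f"{self.allele_id}: dna length {len(self.dna)} does not match "
                f"aa length {len(self.aa)}"
            )


@dataclass
class Individual:
    id: str
    sex: str  # "F" | "M"
    colony: str
    birth_year: int
    genotypes: dict[str, frozenset[str]] = field(default_factory=dict)


@dataclass(frozen=True)
class ChoiceEvent:
    """One offspring, modelled as the outcome of one maternal choice."""

    offspring_id: str
    mother_id: str
    father_id: str
    candidate_ids: tuple[str, ...]
    colony: str
    conception_year: int

    def __post_init__(self) -> None:
        if self.father_id not in self.candidate_ids:
            raise ValueError(
                f"event {self.offspring_id}: father {self.father_id} not in candidates"
            )
        if len(self.candidate_ids) < 2:
            raise ValueError(f"event {self.offspring_id}: fewer than 2 candidates")
        if self.mother_id in self.candidate_ids:
            raise ValueError(f"event {self.offspring_id}: mother among candidates")


@dataclass(frozen=True)
class CandidatePool:
    """Males available to females of one colony in one conception season."""

    colony: str
    year: int
    male_ids: tuple[str, ...]


class GenotypeTable:
    """Mapping (individual_id, gene) -> frozenset of allele IDs."""

    def __init__(self, data: Mapping[tuple[str, str], Iterable[str]] | None = None):
        self._data: dict[tuple[str, str], frozenset[str]] = {}
        if data:
            for (ind, gene), alleles in data.items():
                self.set(ind, gene, alleles)

    def set(self, individual_id: str, gene: str, alleles: Iterable[str]) -> None:
        fs = frozenset(alleles)
        if not fs:
            raise ValueError(f"empty genotype for {individual_id}/{gene}")
        self._data[(individual_id, gene)] = fs

    def get(self, individual_id: str, gene: str) -> frozenset[str] | None:
        return self._data.get((individual_id, gene))

    def drop(self, individual_id: str, gene: str) -> None:
        self._data.pop((individual_id, gene), None)

    def genes(self) -> list[str]:
        return sorted({g for _, g in self._data})

    def individuals(self, gene: str | None = None) -> list[str]:
        if gene is None:
            return sorted({i for i, _ in self._data})
        return sorted(i for i, g in self._data if g == gene)

    def items(self) -> Iterator[tuple[tuple[str, str], frozenset[str]]]:
        return iter(sorted(self._data.items()))

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._data

    def copy(self) -> "GenotypeTable":
        out = GenotypeTable()
        out._data = dict(self._data)
        return out

    @classmethod
    def from_individuals(cls, individuals: Iterable[Individual]) -> "GenotypeTable":
        out = cls()
        for ind in individuals:
            for gene, alleles in ind.genotypes.items():
                out.set(ind.id, gene, alleles)
        return out
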