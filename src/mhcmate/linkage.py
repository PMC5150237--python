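"""Permutation test of linkage disequilibrium from unphased genotypes.

Each individual's genotype at a locus is reduced to a category: the
unordered allele pair for diploid loci, the whole allele-set profile for
pooled multi-locus genes (single-locus genotypes are unrecoverable there).
The observed statistic is the probability of the genotype x genotype
contingency table under independence with fixed margins,

    P(T) = (prod_i r_i! * prod_j c_j!) / (N! * prod_ij n_ij!),

and the null is generated by permuting one locus's genotype labels across
individuals; the p-value is the fraction of permuted tables with
probability at most that of the observed table (Fisher's exact test
ordering, extended to arbitrary table sizes). On 2x2 tables this ranking
coincides with the two-sided Fisher exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._seeds import substream
from .types import GenotypeTable

__all__ = ["LdResult", "ld_mc_test", "taar_mhc_screen", "table_log_probability"]


@dataclass
class LdResult:
    locus_pair: tuple[str, str]
    observed_statistic: float  # log table probability
    n_steps: int
    n_dememorization: int  # no analogue in the permutation scheme; always 0
    p_value: float


def _codes(genotypes: Sequence[frozenset | tuple | str]) -> np.ndarray:
    cats = {}
    out = np.empty(len(genotypes), dtype=np.int64)
    for i, g in enumerate(genotypes):
        key = tuple(sorted(g)) if not isinstance(g, str) else g
        out[i] = cats.setdefault(key, len(cats))
    return out


def table_log_probability(table: np.ndarray) -> float:
    """Log probability of an r x c contingency table under independence
    with both margins fixed."""
    table = np.asarray(table, dtype=np.int64)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def ld_mc_test(
    genotypes_a: Sequence[frozenset],
    genotypes_b: Sequence[frozenset],
    n_perm: int = 100_000,
    seed: int = 0,
    locus_pair: tuple[str, str] = ("A", "B"),
) -> LdResult:
    """Monte Carlo LD test between two loci typed in the same individuals."""
    if len(genotypes_a) != len(genotypes_b):
        raise ValueError("loci must be typed in the same individuals")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ca, cb = _codes(genotypes_a), _codes(genotypes_b)
    na, nb = ca.max() + 1, cb.max() + 1
    if na < 2 or nb < 2:
        warnings.warn(
            f"{locus_pair}: fewer than 2 distinct genotypes at a locus; p = 1"
        )
        return LdResult(locus_pair, 0.0, n_perm, 0, 1.0)
    rng = substream(seed, f"ld:{locus_pair[0]}:{locus_pair[1]}")
    obs_tab = np.bincount(ca * nb + cb, minlength=na * nb).reshape(na, nb)
    obs = table_log_probability(obs_tab)

    # Both margins are invariant under permutation, so the ranking reduces
    # to the cell term sum gammaln(n_ij + 1); cells with n_ij <= 1
    # contribute zero, which keeps sparse profile x profile tables cheap.
    def cell_term(pair_codes: np.ndarray) -> float:
        counts = np.bincount(pair_codes, minlength=1)
        big = counts[counts > 1]
        return float(gammaln(big + 1).sum()) if len(big) else 0.0

    s_obs = cell_term(ca * nb + cb)
    hits = 0
    cb_perm = cb.copy()
    for _ in range(n_perm):
        rng.shuffle(cb_perm)
        if cell_term(ca * nb + cb_perm) >= s_obs - 1e-9:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return LdResult(locus_pair, obs, n_perm, 0, float(p))


def taar_mhc_screen(
    genotypes: GenotypeTable,
    gene_pairs: list[tuple[str, str]] | None = None,
    genes: list[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise LD screen; no multiplicity correction is applied."""
    if gene_pairs is None:
        genes = genes if genes is not None else genotypes.genes()
        gene_pairs = list(combinations(genes, 2))
    if not gene_pairs:
        warnings.warn("no gene pairs to test")
        return pd.DataFrame(columns=["gene_a", "gene_b", "n", "log_prob", "p_value"])
    rows = []
    for ga, gb in gene_pairs:
        shared = sorted(
            set(genotypes.individuals(ga)) & set(genotypes.individuals(gb))
        )
        gen_a = [genotypes.get(i, ga) for i in shared]
        gen_b = [genotypes.get(i, gb) for i in shared]
        res = ld_mc_test(gen_a, gen_b, n_perm=n_perm, seed=seed, locus_pair=(ga, gb))
        rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "n": len(shared),
                "log_prob": res.observed_statistic,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
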