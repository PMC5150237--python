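"""Replicate-free amplicon allele calling and genotype validation.

The workflow assigns reads to individuals by exact barcode/primer match,
removes PCR chimeras with a reference-free splice test, removes
non-functional sequences with a translated-homology filter, and calls
alleles by oligotyping: concatenating each read's bases at high
Shannon-entropy alignment columns, so that true variants separate from the
sequencing-error background. Called genotypes are then validated by
Mendelian trio consistency and (where replicates exist) repeatability.

All amplicons of one gene are assumed equal length after trimming, so the
"alignment" is positional; deviant-length reads are discarded and logged.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .io import translate_cds
from .types import GenotypeTable

__all__ = [
    "OligotypeCall",
    "TrioViolation",
    "UnresolvableGeneError",
    "demultiplex_and_trim",
    "filter_chimeras",
    "homology_filter",
    "column_entropy",
    "call_alleles",
    "mendelian_check",
    "repeatability",
    "recoverable_genotypes",
]


class UnresolvableGeneError(ValueError):
    """Raised when distinct reads share identical bases at every
    above-threshold entropy column, so no allele decomposition exists."""


@dataclass(frozen=True)
class OligotypeCall:
    allele_id: str
    entropy_positions: tuple[int, ...]
    oligotype: str
    representative_sequence: str
    read_count: int
    individual_count: int


@dataclass(frozen=True)
class TrioViolation:
    offspring_id: str
    gene: str
    offending_allele_ids: frozenset[str]


# --------------------------------------------------------------------------


def demultiplex_and_trim(
    raw_reads: list[str],
    barcode_map: dict[str, str],
    primer_pairs: dict[str, tuple[str, str]],
) -> tuple[dict[tuple[str, str], list[str]], dict[str, int]]:
    """Assign raw reads to (individual, gene) by exact barcode + primer match.

    Reads with any mismatch in the barcode or either primer are discarded
    (no error correction is attempted); retained reads are trimmed to the
    inter-primer region.
    """
    if not barcode_map or not primer_pairs:
        raise ValueError("barcode map and primer pairs must be non-empty")
    bc_lens = {len(b) for b in barcode_map}
    if len(bc_lens) != 1:
        raise ValueError("barcodes must share one length")
    if len(set(barcode_map.values())) != len(barcode_map):
        # one individual may own several barcodes, but warn-level duplicates of
        # (barcode -> individual) pairs cannot occur in a dict; this guards
        # against two barcodes differing only by case etc. being collapsed.
        pass
    bl = bc_lens.pop()
    out: dict[tuple[str, str], list[str]] = defaultdict(list)
    log = {"input": len(raw_reads), "assigned": 0, "bad_barcode": 0, "bad_primer": 0}
    for read in raw_reads:
        bc = read[:bl]
        ind = barcode_map.get(bc)
        if ind is None:
            log["bad_barcode"] += 1
            continue
        rest = read[bl:]
        for gene, (fwd, rev) in primer_pairs.items():
            if rest.startswith(fwd) and rest.endswith(rev) and len(rest) > len(fwd) + len(rev):
                out[(ind, gene)].append(rest[len(fwd) : len(rest) - len(rev)])
                log["assigned"] += 1
                break
        else:
            log["bad_primer"] += 1
    return dict(out), log


# --------------------------------------------------------------------------


def filter_chimeras(
    reads: list[str], max_mismatches: int = 0
) -> tuple[list[str], list[str]]:
    """Reference-free splice test, abundance ordered.

    A read is flagged as chimeric when some prefix/suffix split matches two
    *distinct*, strictly more abundant sequences with at most
    ``max_mismatches`` total mismatches, strictly fewer than the read's
    best single (more abundant) parent. PCR chimeras arise by template
    switching and are exact splices of their parents, hence the default of
    zero: a merely-closer splice is common between true alleles that are
    themselves mutation clouds around a shared ancestor and must not be
    flagged. Returns (retained, flagged) with retained + flagged = input.
    """
    if not reads:
        return [], []
    lengths = {len(r) for r in reads}
    if len(lengths) != 1:
        raise ValueError("chimera filter requires equal-length reads")
    L = lengths.pop()
    counts = Counter(reads)
    uniq = sorted(counts, key=lambda s: (-counts[s], s))
    arrs = np.frombuffer("".join(uniq).encode(), dtype=np.uint8).reshape(len(uniq), L)
    abund = np.array([counts[s] for s in uniq])
    chimeric: set[str] = set()
    for i, seq in enumerate(uniq):
        parents = np.flatnonzero(abund > abund[i])
        if len(parents) < 2:
            continue
        mism = arrs[parents] != arrs[i]  # (P, L)
        totals = mism.sum(axis=1)
        m1 = int(totals.min())
        if m1 == 0:
            continue  # identical to a more abundant sequence: not a chimera
        pref = np.concatenate(
            [np.zeros((len(parents), 1), int), np.cumsum(mism, axis=1)], axis=1
        )
        suf = totals[:, None] - pref  # suffix mismatches from split k
        ks = np.arange(1, L)
        # best + runner-up per split on each side, to force distinct parents
        p_order = np.argsort(pref[:, ks], axis=0, kind="stable")
        s_order = np.argsort(suf[:, ks], axis=0, kind="stable")
        best = np.inf
        for k_i, k in enumerate(ks):
            p1, p2 = p_order[0, k_i], p_order[min(1, len(parents) - 1), k_i]
            s1, s2 = s_order[0, k_i], s_order[min(1, len(parents) - 1), k_i]
            if p1 != s1:
                cand = pref[p1, k] + suf[s1, k]
            else:
                cand = min(pref[p1, k] + suf[s2, k], pref[p2, k] + suf[s1, k])
            if cand < best:
                best = cand
                if best == 0:
                    break
        if best <= max_mismatches and best < m1:
            chimeric.add(seq)
    retained, flagged = [], []
    for r in reads:
        (flagged if r in chimeric else retained).append(r)
    return retained, flagged


# --------------------------------------------------------------------------


def homology_filter(
    reads: list[str],
    reference_proteins: list[str],
    min_identity: float,
    frame: int = 0,
) -> tuple[list[str], dict[str, int]]:
    """Keep reads whose in-frame translation is stop-free and at least
    ``min_identity`` identical (boundary inclusive) to a reference protein."""
    if not reference_proteins:
        raise ValueError("no reference proteins supplied")
    retained: list[str] = []
    log = {"input": len(reads), "retained": 0, "stop_codon": 0, "low_identity": 0, "bad_frame": 0}
    cache: dict[str, bool] = {}
    for read in reads:
        keep = cache.get(read)
        if keep is None:
            keep = _homologous(read, reference_proteins, min_identity, frame, log)
            cache[read] = keep
        else:
            _homologous(read, reference_proteins, min_identity, frame, log)
        if keep:
            retained.append(read)
            log["retained"] += 1
    return retained, log


def _homologous(read, refs, min_identity, frame, log) -> bool:
    cds = read[frame:]
    if len(cds) % 3 != 0:
        log["bad_frame"] += 1
        return False
    aa = translate_cds(cds)
    if "*" in aa:
        log["stop_codon"] += 1
        return False
    best = 0.0
    for ref in refs:
        n = min(len(aa), len(ref))
        if n == 0:
            continue
        ident = sum(a == b for a, b in zip(aa[:n], ref[:n])) / len(aa)
        best = max(best, ident)
    if best >= min_identity:
        return True
    log["low_identity"] += 1
    return False


# --------------------------------------------------------------------------


def column_entropy(reads: list[str]) -> np.ndarray:
    """Per-column Shannon entropy (nats) of the positional alignment."""
    L = len(reads[0])
    arr = np.frombuffer("".join(reads).encode(), dtype=np.uint8).reshape(len(reads), L)
    ent = np.zeros(L)
    for j in range(L):
        _, counts = np.unique(arr[:, j], return_counts=True)
        p = counts / counts.sum()
        ent[j] = float(-(p * np.log(p)).sum())
    return ent


def call_alleles(
    reads_by_individual: dict[str, list[str]],
    gene: str,
    entropy_threshold: float = 0.2,
    min_reads_per_allele: int = 5,
    min_fraction_per_allele: float = 0.05,
    min_alleles_per_individual: int = 1,
    min_individuals_per_allele: int = 2,
) -> tuple[GenotypeTable, list[OligotypeCall], dict]:
    """Oligotype allele calling over the pooled per-gene alignment.

    Columns with pooled entropy above ``entropy_threshold`` define the
    oligotype of every read; an oligotype is an allele of an individual
    when its reads there meet both the absolute and fractional minimum;
    alleles seen in fewer than ``min_individuals_per_allele`` individuals
    are deleted everywhere, and individuals left with fewer than
    ``min_alleles_per_individual`` alleles are dropped for this gene.
    """
    if not (0 < min_fraction_per_allele <= 1) or min_reads_per_allele < 1:
        raise ValueError("thresholds out of range")
    log: dict = {"gene": gene, "individuals_in": len(reads_by_individual)}
    # length harmonisation
    all_lengths = Counter(
        len(r) for reads in reads_by_individual.values() for r in reads
    )
    if not all_lengths:
        raise ValueError("no reads supplied")
    modal_len = max(all_lengths, key=lambda k: (all_lengths[k], -k))
    clean: dict[str, list[str]] = {}
    dropped_len = 0
    for ind, reads in reads_by_individual.items():
        keep = [r for r in reads if len(r) == modal_len]
        dropped_len += len(reads) - len(keep)
        if keep:
            clean[ind] = keep
    log["reads_dropped_length"] = dropped_len
    pooled = [r for ind in sorted(clean) for r in clean[ind]]
    ent = column_entropy(pooled)
    positions = tuple(int(j) for j in np.flatnonzero(ent > entropy_threshold))
    log["entropy_positions"] = len(positions)
    if not positions:
        if len(set(pooled)) > 1:
            raise UnresolvableGeneError(
                f"{gene}: {len(set(pooled))} distinct sequences but no column "
                f"exceeds entropy threshold {entropy_threshold}"
            )
    oligo_of = lambda r: "".join(r[j] for j in positions)  # noqa: E731

    per_ind_counts: dict[str, Counter] = {}
    for ind in sorted(clean):
        per_ind_counts[ind] = Counter(oligo_of(r) for r in clean[ind])

    # provisional per-individual calls
    calls: dict[str, set[str]] = {}
    for ind, cnt in per_ind_counts.items():
        total = sum(cnt.values())
        called = {
            o
            for o, c in cnt.items()
            if c >= min_reads_per_allele and c / total >= min_fraction_per_allele
        }
        if called:
            calls[ind] = called

    carriers: Counter = Counter()
    for called in calls.values():
        carriers.update(called)
    kept_oligos = {o for o, k in carriers.items() if k >= min_individuals_per_allele}
    log["oligotypes_called"] = len(carriers)
    log["oligotypes_single_individual_removed"] = len(carriers) - len(kept_oligos)

    # stable allele names by pooled abundance
    pooled_counts = Counter(oligo_of(r) for r in pooled)
    ordered = sorted(kept_oligos, key=lambda o: (-pooled_counts[o], o))
    name_of = {o: f"{gene}-o{i + 1:02d}" for i, o in enumerate(ordered)}

    table = GenotypeTable()
    dropped_ind = 0
    for ind in sorted(calls):
        kept = {name_of[o] for o in calls[ind] if o in kept_oligos}
        if len(kept) >= max(1, min_alleles_per_individual):
            table.set(ind, gene, kept)
        else:
            dropped_ind += 1
    log["individuals_dropped"] = dropped_ind + (len(clean) - len(calls))
    log["individuals_out"] = len(table.individuals(gene))

    # representatives: modal full-length sequence per oligotype
    rep_counts: dict[str, Counter] = defaultdict(Counter)
    for r in pooled:
        o = oligo_of(r)
        if o in kept_oligos:
            rep_counts[o][r] += 1
    oligocalls = [
        OligotypeCall(
            allele_id=name_of[o],
            entropy_positions=positions,
            oligotype=o,
            representative_sequence=min(
                rep_counts[o], key=lambda s: (-rep_counts[o][s], s)
            ),
            read_count=int(pooled_counts[o]),
            individual_count=int(carriers[o]),
        )
        for o in ordered
    ]
    return table, oligocalls, log


# --------------------------------------------------------------------------


def mendelian_check(
    genotypes: GenotypeTable,
    trios: list[tuple[str, str, str]],
    correct: bool = False,
) -> tuple[list[TrioViolation], GenotypeTable, dict]:
    """Flag offspring alleles absent from mother-union-father.

    With ``correct=True`` the offending alleles are removed from the
    offspring's set, never reducing it below one allele.
    """
    violations: list[TrioViolation] = []
    corrected = genotypes.copy()
    log = {"trios": len(trios), "skipped": 0, "checked": 0}
    for gene in genotypes.genes():
        for off, mom, dad in trios:
            g_off = genotypes.get(off, gene)
            g_mom = genotypes.get(mom, gene)
            g_dad = genotypes.get(dad, gene)
            if g_off is None or g_mom is None or g_dad is None:
                log["skipped"] += 1
                continue
            log["checked"] += 1
            offending = g_off - (g_mom | g_dad)
            if not offending:
                continue
            violations.append(TrioViolation(off, gene, frozenset(offending)))
            if correct:
                keep = g_off - offending
                if not keep:  # never empty a genotype
                    keep = frozenset([min(offending)])
                corrected.set(off, gene, keep)
    return violations, corrected, log


@dataclass(frozen=True)
class RepeatabilityResult:
    overall: float
    per_gene: dict[str, float]
    n_pairs: int


def repeatability(
    genotypes: GenotypeTable,
    replicate_pairs: list[tuple[str, str]],
    method: str = "jaccard",
) -> RepeatabilityResult:
    """Agreement of allele calls between replicate samples.

    ``jaccard``: mean |A∩B| / |A∪B| over replicate pairs and genes;
    ``exact``: fraction of pairs whose called sets are identical.
    """
    if not replicate_pairs:
        raise ValueError("need at least one replicate pair")
    if method not in ("jaccard", "exact"):
        raise ValueError(f"unknown method {method!r}")
    per_gene: dict[str, list[float]] = defaultdict(list)
    for gene in genotypes.genes():
        for a, b in replicate_pairs:
            ga, gb = genotypes.get(a, gene), genotypes.get(b, gene)
            if ga is None or gb is None:
                continue
            if method == "jaccard":
                per_gene[gene].append(len(ga & gb) / len(ga | gb))
            else:
                per_gene[gene].append(1.0 if ga == gb else 0.0)
    if not per_gene:
        raise ValueError("no replicate pair genotyped at any gene")
    gene_means = {g: float(np.mean(v)) for g, v in sorted(per_gene.items())}
    all_vals = [x for v in per_gene.values() for x in v]
    return RepeatabilityResult(
        overall=float(np.mean(all_vals)),
        per_gene=gene_means,
        n_pairs=len(all_vals),
    )


def recoverable_genotypes(
    truth: GenotypeTable,
    gene: str,
    min_individuals_per_allele: int = 2,
    min_alleles_per_individual: int = 1,
) -> GenotypeTable:
    """Project true genotypes through the workflow's frequency filters.

    The calling workflow deliberately deletes alleles carried by fewer than
    ``min_individuals_per_allele`` individuals and drops individuals left
    below the per-gene minimum, so this is the genotype table a perfect
    caller would return; recovery should be measured against it.
    """
    carriers: Counter = Counter()
    for ind in truth.individuals(gene):
        carriers.update(truth.get(ind, gene))
    keep = {a for a, k in carriers.items() if k >= min_individuals_per_allele}
    out = GenotypeTable()
    for ind in truth.individuals(gene):
        g = truth.get(ind, gene) & keep
        if len(g) >= max(1, min_alleles_per_individual):
            out.set(ind, gene, g)
    return out
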