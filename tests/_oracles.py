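"""Independent naive implementations used as test oracles.

Deliberately written with explicit loops over sets and pairs, sharing no
code with the package's implementations.
"""


def naive_maldis(female, male):
    n = 0
    for a in male:
        if a not in female:
            n += 1
    return n


def naive_caldis(female, male):
    n = 0
    for a in male:
        if a not in female:
            n += 1
    for a in female:
        if a not in male:
            n += 1
    return n


def naive_mu_aadis_within(female, male, dist):
    pool = sorted(set(female) ^ set(male))
    total = 0
    count = 0
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            total += dist[pool[i]][pool[j]]
            count += 1
    return (total / count, True) if count else (0.0, False)


def naive_mu_aadis_cross(female, male, dist):
    f_only = sorted(set(female) - set(male))
    m_only = sorted(set(male) - set(female))
    total = 0
    count = 0
    for a in f_only:
        for b in m_only:
            total += dist[a][b]
            count += 1
    return (total / count, True) if count else (0.0, False)


def naive_maldiv(male):
    seen = []
    for a in male:
        if a not in seen:
            seen.append(a)
    return len(seen)


def naive_maadiv(male, dist):
    alleles = sorted(male)
    total = 0
    for i in range(len(alleles)):
        for j in range(i + 1, len(alleles)):
            total += dist[alleles[i]][alleles[j]]
    return total


def dist_lookup(D):
    """Nested-dict distance lookup from an AADistanceMatrix."""
    out = {}
    for i, a in enumerate(D.allele_ids):
        out[a] = {}
        for j, b in enumerate(D.allele_ids):
            out[a][b] = int(D.d[i, j])
    return out
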