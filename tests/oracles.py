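"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by the most literal method available
(per-base pileups, explicit enumeration, quadratic DP) and stays
independent of the library code paths it checks.
"""

from itertools import combinations_with_replacement, product

import numpy as np


def pileup_bin_counts(records, bins, mapq_min):
    """Per-bin read-base counts via an explicit per-base pileup."""
    depth = {}
    for rec in records:
        if rec.mapq < mapq_min:
            continue
        ref = rec.pos
        for op, n in rec.ops:
            if op in ("M", "=", "X"):
                for p in range(ref, ref + n):
                    depth[(rec.chrom, p)] = depth.get((rec.chrom, p), 0) + 1
                ref += n
            elif op in ("D", "N"):
                ref += n
    return [
        sum(depth.get((b.chrom, p), 0) for p in range(b.start, b.end)) for b in bins
    ]


def cigar_reference_span(pos, ops):
    """Reference end of an alignment by walking the CIGAR one op at a time."""
    ref = pos
    for op, n in ops:
        if op in ("M", "=", "X", "D", "N"):
            ref += n
    return ref


def cigar_deletion_intervals(pos, ops, min_len):
    """(start, end) of every D/N op >= min_len, by a literal cigar walk."""
    out = []
    ref = pos
    for op, n in ops:
        if op in ("M", "=", "X"):
            ref += n
        elif op in ("D", "N"):
            if n >= min_len:
                out.append((ref, ref + n))
            ref += n
    return out


def lcs_dp(a, b):
    """Longest common substring by quadratic dynamic programming."""
    best, best_a, best_b = 0, 0, 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
                    best_a, best_b = i - best, j - best
        prev = cur
    return best, best_a, best_b


def itim_positions(protein):
    """1-based ITIM hexamer starts by explicit window enumeration."""
    hits = []
    for i in range(len(protein) - 5):
        w = protein[i : i + 6]
        if w[0] in "SIVL" and w[2] == "Y" and w[5] in "IVL":
            hits.append(i + 1)
    return hits


def pcr_products_bruteforce(template, fwd, rev_rc):
    """Product lengths by scanning all exact primer-site pairs.

    `fwd` and `rev_rc` must be the template-strand binding sequences
    (forward primer core, reverse-complemented reverse primer core).
    """
    f_sites = [i for i in range(len(template)) if template.startswith(fwd, i)]
    r_sites = [i for i in range(len(template)) if template.startswith(rev_rc, i)]
    return sorted(
        (r + len(rev_rc)) - f
        for f in f_sites
        for r in r_sites
        if r >= f
    )


def mahalanobis_nearest(x, genotypes, variances):
    """Nearest lattice genotype in (diagonal) Mahalanobis distance."""
    means = np.column_stack(
        [genotypes[:, 0], genotypes[:, 1], genotypes[:, 0] + genotypes[:, 1]]
    ).astype(float)
    d2 = (((np.asarray(x) - means) ** 2) / variances).sum(axis=1)
    return tuple(genotypes[int(np.argmin(d2))])


def trio_configs_bruteforce(gf, gm, space):
    """All parental configurations by raw nested enumeration."""
    out = []
    for f1, f2 in combinations_with_replacement(sorted(space), 2):
        if (f1.h_b3 + f2.h_b3, f1.h_a6 + f2.h_a6) != gf:
            continue
        for m1, m2 in combinations_with_replacement(sorted(space), 2):
            if (m1.h_b3 + m2.h_b3, m1.h_a6 + m2.h_a6) != gm:
                continue
            for tf in {f1, f2}:
                for tm in {m1, m2}:
                    out.append(((f1, f2), (m1, m2), tf, tm))
    return out


def trio_best_bruteforce(gf, gm, gc, space, freqs):
    """MAP trio configuration by exhaustive scoring (indicator likelihoods)."""
    best, best_score = None, -1.0
    for (f1, f2), (m1, m2), tf, tm in trio_configs_bruteforce(gf, gm, space):
        if (tf.h_b3 + tm.h_b3, tf.h_a6 + tm.h_a6) != gc:
            continue
        score = freqs[f1] * freqs[f2] * freqs[m1] * freqs[m2] * 0.25
        if score > best_score:
            best, best_score = ((f1, f2), (m1, m2), tf, tm), score
    return best, best_score


def hw_loglik(genotypes, freqs, space):
    """Cohort log-likelihood under Hardy-Weinberg for a frequency table."""
    ll = 0.0
    for g in genotypes:
        p = 0.0
        for h1, h2 in product(space, repeat=2):
            if (h1.h_b3 + h2.h_b3, h1.h_a6 + h2.h_a6) == tuple(g):
                p += freqs[h1] * freqs[h2]
        ll += np.log(max(p, 1e-300))
    return ll
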