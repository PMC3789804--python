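"""Independent oracle implementations used only by the tests.

Everything here is written from the definitions, deliberately avoiding the
package's own code paths: exhaustive hidden-path enumeration for the
haplotype-copying HMM, sum-based Pearson correlation, loop-based concordance
counting, and pair-by-pair minor-allele classification.
"""

from itertools import product

import numpy as np


def brute_force_alt_posteriors(target, ref, typed_idx, switch_rate, miscopy_rate):
    """Alt-allele posterior at every site by summing over all K^L hidden paths.

    The chain runs over every site with per-interval switch probability
    ``switch_rate`` (stay with 1-s, else jump to a uniformly chosen reference
    haplotype, which may be the same one); emissions apply at typed sites only
    with miscopy probability ``miscopy_rate``.
    """
    ref = np.asarray(ref, dtype=float)
    K, L = ref.shape
    s, mu = switch_rate, miscopy_rate
    tmap = dict(zip((int(t) for t in typed_idx), target))
    post = np.zeros(L)
    total = 0.0
    for path in product(range(K), repeat=L):
        pr = 1.0 / K
        for i in range(1, L):
            pr *= (1 - s) * (path[i] == path[i - 1]) + s / K
        for t, a in tmap.items():
            h = ref[path[t], t]
            pr *= (1 - mu) if h == a else mu
        total += pr
        for site in range(L):
            h = ref[path[site], site]
            post[site] += pr * ((1 - mu) * h + mu * (1 - h))
    return post / total


def pearson_r2_by_sums(x, y):
    """Squared Pearson correlation from raw definitional sums."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((v - mx) ** 2 for v in x)
    syy = sum((v - my) ** 2 for v in y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    if sxx == 0 or syy == 0:
        return 0.0
    return sxy * sxy / (sxx * syy)


def concordance_by_loop(obs, bg):
    return sum(1 for a, b in zip(obs, bg) if a == b) / len(obs)


def ma_concordance_by_pairs(obs, bg, minor_is_alt):
    """Classify every sample pair-of-genotypes; keep those carrying the minor allele."""
    kept = []
    for a, b in zip(obs, bg):
        if minor_is_alt:
            carries = a > 0 or b > 0
        else:
            carries = a < 2 or b < 2
        if carries:
            kept.append(a == b)
    if not kept:
        return 1.0
    return sum(kept) / len(kept)


def minor_allele_by_count(genotypes, two_n):
    """(minor_is_alt, maf, mac) by direct allele counting; ties go to alt."""
    alt = int(sum(genotypes))
    ref = two_n - alt
    if alt <= ref:
        return True, alt / two_n, alt
    return False, ref / two_n, ref
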