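"""Independent brute-force oracles used by the tests.

These are written straight from the textbook formulas with plain Python
loops and share no code with the package implementation.
"""

from __future__ import annotations

import math

MISSING = -1


def wc_theta_single_locus(dosage_by_group: list[list[int]]):
    """Weir & Cockerham (1984) theta for one locus, looped from scratch.

    ``dosage_by_group``: one list of dosages (0/1/2, MISSING dropped) per
    group. Returns (a, b, c, theta) with theta None when a+b+c == 0 or
    fewer than two groups have called samples.
    """
    groups = [[d for d in grp if d != MISSING] for grp in dosage_by_group]
    groups = [grp for grp in groups if len(grp) > 0]
    r = len(groups)
    if r < 2:
        return None
    n_i = [len(grp) for grp in groups]
    p_i = [sum(grp) / (2.0 * n) for grp, n in zip(groups, n_i)]
    h_i = [sum(1 for d in grp if d == 1) / n for grp, n in zip(groups, n_i)]

    n_sum = sum(n_i)
    nbar = n_sum / r
    nc = (n_sum - sum(n * n for n in n_i) / n_sum) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / n_sum
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / n_sum

    if nbar <= 1 or nc == 0:
        return None
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                             - hbar / 4.0) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    denom = a + b + c
    if denom == 0:
        return (a, b, c, None)
    return (a, b, c, a / denom)


def naive_assignment_loglik(dosages, group_freq_counts):
    """Product-of-genotype-probabilities likelihood, looped from scratch.

    ``group_freq_counts``: per group, a list of (alt_count, called_allele
    count) per locus. Smoothing (x + 0.5)/(n + 1) applied per locus.
    Returns a list of log-likelihoods, one per group, skipping missing
    calls.
    """
    out = []
    for freqs in group_freq_counts:
        ll = 0.0
        for d, (x, n) in zip(dosages, freqs):
            if d == MISSING:
                continue
            q = (x + 0.5) / (n + 1.0)
            if d == 0:
                ll += math.log((1 - q) ** 2)
            elif d == 1:
                ll += math.log(2 * q * (1 - q))
            elif d == 2:
                ll += math.log(q ** 2)
            else:
                raise ValueError(d)
        out.append(ll)
    return out
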