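"""Independent oracles shared between unit tests and the acceptance suite.

These deliberately re-derive quantities with different code paths (plain
Python loops, direct combinatorics, constructive tree building) so they stay
independent of the implementations they check.
"""

import numpy as np
import pandas as pd
from scipy.special import comb

from knotpop.io_core import MISSING


def wc_theta_oracle(g, rows_a, rows_b):
    """Loop-based Weir-Cockerham two-population variance-components theta."""
    num = den = 0.0
    r = 2
    for j in range(g.n_variants):
        ga = [g.calls[i, j] for i in rows_a if g.calls[i, j] != MISSING]
        gb = [g.calls[i, j] for i in rows_b if g.calls[i, j] != MISSING]
        na, nb = len(ga), len(gb)
        if na < 2 or nb < 2:
            continue
        pa = sum(ga) / (2 * na)
        pb = sum(gb) / (2 * nb)
        ha = sum(1 for x in ga if x == 1) / na
        hb = sum(1 for x in gb if x == 1) / nb
        nbar = (na + nb) / r
        pbar = (na * pa + nb * pb) / (r * nbar)
        if pbar in (0.0, 1.0):
            continue
        nc = (r * nbar - (na**2 + nb**2) / (r * nbar)) / (r - 1)
        s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (na * ha + nb * hb) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact HWE test by direct binomial-coefficient enumeration."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    probs = {}
    for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
        a_hom = (na - h) // 2
        b_hom = n - h - a_hom
        if a_hom < 0 or b_hom < 0:
            continue
        probs[h] = (
            comb(n, h, exact=True)
            * comb(n - h, a_hom, exact=True)
            * 2**h
            / comb(2 * n, na, exact=True)
        )
    z = sum(probs.values())
    p_obs = probs[n_ab] / z
    return sum(v / z for v in probs.values() if v / z <= p_obs * (1 + 1e-12))


def random_additive_matrix(rng, labels):
    """Patristic distances of a randomly built tree with positive branches."""
    paths = {(a, b): 0.0 for a in labels for b in labels}
    clades = [[lab] for lab in labels]
    depth = {lab: 0.0 for lab in labels}
    while len(clades) > 1:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        bi, bj = rng.uniform(0.5, 2.0), rng.uniform(0.5, 2.0)
        for a in clades[i]:
            depth[a] += bi
        for b in clades[j]:
            depth[b] += bj
        for a in clades[i]:
            for b in clades[j]:
                paths[(a, b)] = paths[(b, a)] = depth[a] + depth[b]
        clades[i] = clades[i] + clades[j]
        del clades[j]
    return pd.DataFrame(
        [[paths[(a, b)] for b in labels] for a in labels], index=labels, columns=labels
    )


def population_pool(rng, n_samples, n_snps):
    """Unrelated diploids drawn from one allele-frequency pool; returns
    (frequencies, dosage matrix, first haplotype per sample)."""
    p = rng.uniform(0.1, 0.9, n_snps)
    a1 = rng.binomial(1, p, (n_samples, n_snps))
    a2 = rng.binomial(1, p, (n_samples, n_snps))
    return p, (a1 + a2).astype(np.int8), a1
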