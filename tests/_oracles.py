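"""Brute-force reference implementations used only by tests.

These enumerate every hidden configuration explicitly and share no code
with the package's forward-backward or peeling machinery.
"""

import itertools

import numpy as np

# ordered genotype states: (paternal allele, maternal allele)
STATES = [(0, 0), (0, 1), (1, 0), (1, 1)]


def hmm_enumeration(evidence, r):
    """Exact two-state chain quantities by summing over all 2^L paths.

    Returns (marginals (L, 2), switch expectation per interval (L-1,)).
    Uniform initial distribution; transition probability r_j per interval.
    """
    evidence = np.asarray(evidence, dtype=float)
    L = evidence.shape[0]
    marg = np.zeros((L, 2))
    switch = np.zeros(L - 1)
    total = 0.0
    for path in itertools.product((0, 1), repeat=L):
        w = 0.5 * evidence[0, path[0]]
        for j in range(1, L):
            rj = r[j - 1]
            w *= (rj if path[j] != path[j - 1] else 1 - rj) * evidence[j, path[j]]
        total += w
        for j, s in enumerate(path):
            marg[j, s] += w
        for j in range(L - 1):
            if path[j] != path[j + 1]:
                switch[j] += w
    return marg / total, switch / total


def _penetrance(call, eps):
    if call == 9:
        return np.ones(4)
    consistent = np.array([0, 1, 1, 2]) == call
    return np.where(consistent, 1.0 - eps, eps / (~consistent).sum())


def trio_enumeration(calls_father, calls_mother, calls_child, r_pat, r_mat, eps):
    """Exact child marginals in a trio by joint enumeration.

    Enumerates both segregation chains of the child jointly ((2^L)^2
    paths); founder parents have independent uniform priors over the 4
    ordered states per locus, so their genotypes are marginalised exactly
    per locus given each (s_pat, s_mat) pair.

    Returns (child genotype marginals (L, 4), paternal segregation
    marginals (L, 2), paternal switch expectations (L-1,)).
    """
    L = len(calls_child)
    pen_f = np.array([_penetrance(c, eps) for c in calls_father])
    pen_m = np.array([_penetrance(c, eps) for c in calls_mother])
    pen_c = np.array([_penetrance(c, eps) for c in calls_child])

    # N[j, sp, sm, g] = sum over parent genotypes of prior x penetrances x
    # indicator that the transmitted alleles form child state g
    N = np.zeros((L, 2, 2, 4))
    for j in range(L):
        for gf, (f0, f1) in enumerate(STATES):
            for gm, (m0, m1) in enumerate(STATES):
                w = (1 / 16) * pen_f[j, gf] * pen_m[j, gm]
                for sp, a_pat in enumerate((f0, f1)):
                    for sm, a_mat in enumerate((m0, m1)):
                        g = 2 * a_pat + a_mat
                        N[j, sp, sm, g] += w * pen_c[j, g]
    M = N.sum(axis=3)  # p(child data_j | sp, sm)

    geno = np.zeros((L, 4))
    seg_pat = np.zeros((L, 2))
    switch_pat = np.zeros(L - 1)
    total = 0.0
    for sp in itertools.product((0, 1), repeat=L):
        w_sp = 0.5
        for j in range(1, L):
            w_sp *= r_pat[j - 1] if sp[j] != sp[j - 1] else 1 - r_pat[j - 1]
        for sm in itertools.product((0, 1), repeat=L):
            w = w_sp * 0.5
            for j in range(1, L):
                w *= r_mat[j - 1] if sm[j] != sm[j - 1] else 1 - r_mat[j - 1]
            for j in range(L):
                w *= M[j, sp[j], sm[j]]
            if w == 0.0:
                continue
            total += w
            for j in range(L):
                seg_pat[j, sp[j]] += w
                geno[j] += w * N[j, sp[j], sm[j]] / M[j, sp[j], sm[j]]
            for j in range(L - 1):
                if sp[j] != sp[j + 1]:
                    switch_pat[j] += w
    return geno / total, seg_pat / total, switch_pat / total
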