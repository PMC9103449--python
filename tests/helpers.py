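"""Shared independent oracles for the test suite."""

import itertools

import numpy as np


def permutation_shapley(predict, background, x):
    """Shapley values by brute force: average marginal contribution over all
    d! feature orderings with the interventional value function. Independent
    of the coalition-enumeration implementation it checks."""
    d = x.shape[0]

    def v(S):
        Z = background.copy()
        for j in S:
            Z[:, j] = x[j]
        return float(np.mean(predict(Z)))

    phi = np.zeros(d)
    perms = list(itertools.permutations(range(d)))
    for perm in perms:
        S = []
        for j in perm:
            before = v(S)
            S.append(j)
            phi[j] += v(S) - before
    return phi / len(perms)
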