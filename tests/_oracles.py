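"""Independent test oracles (kept apart from the implementation)."""

import numpy as np

from sprucegs.pedigree import Pedigree


def kinship_oracle(pedigree: Pedigree):
    """Independent path-coefficient oracle for the A matrix.

    Recursive coefficient-of-kinship computation (memoized), distinct
    from the tabular method: phi(i,i) = (1 + phi(s,d))/2 and, taking j
    as not younger than i, phi(i,j) = (phi(s,j) + phi(d,j))/2.
    A = 2 * phi off-diagonal convention folded in via a_ij = 2 phi(i,j).
    """
    order = {iid: k for k, iid in enumerate(pedigree.ids)}
    rank = {iid: r for r, iid in
            enumerate(pedigree.ids[i] for i in pedigree.topological_order)}
    cache = {}

    def phi(i, j):
        if i is None or j is None:
            return 0.0
        key = (min(i, j), max(i, j))
        if key in cache:
            return cache[key]
        if i == j:
            s, d = pedigree.parents_of(i)
            val = 0.5 * (1.0 + phi(s, d))
        else:
            # recurse on the individual later in topological order
            if rank[i] < rank[j]:
                i, j = j, i
            s, d = pedigree.parents_of(i)
            val = 0.5 * (phi(s, j) + phi(d, j))
        cache[key] = val
        return val

    n = len(pedigree.ids)
    A = np.zeros((n, n))
    for ii in pedigree.ids:
        for jj in pedigree.ids:
            # a_ij = 2 phi(i,j); on the diagonal 2 phi(i,i) = 1 + F_i
            A[order[ii], order[jj]] = 2 * phi(ii, jj)
    return A
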