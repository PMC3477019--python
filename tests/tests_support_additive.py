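"""Shared test helper: additive distance matrices from random binary trees."""

import numpy as np


def random_additive_matrix(n, rng):
    """Path-length matrix of a random binary tree with branch lengths in
    [0.5, 3.0]; additive by construction, the oracle for NJ recovery."""
    lengths: dict = {}
    parent_of: dict = {}
    items = list(range(n))
    counter = n
    while len(items) > 1:
        i = items.pop(int(rng.integers(len(items))))
        j = items.pop(int(rng.integers(len(items))))
        for c in (i, j):
            parent_of[c] = counter
            lengths[c] = float(rng.uniform(0.5, 3.0))
        items.append(counter)
        counter += 1

    def path_to_root(x):
        out = []
        while x in parent_of:
            out.append(x)
            x = parent_of[x]
        return out

    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = path_to_root(i), path_to_root(j)
            shared = set(pi) & set(pj)
            dist = sum(lengths[x] for x in pi if x not in shared)
            dist += sum(lengths[x] for x in pj if x not in shared)
            d[i, j] = d[j, i] = dist
    return d
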