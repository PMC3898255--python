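"""Independent naive agglomerative-clustering oracle for Ward linkage tests."""

import numpy as np


def naive_ward_steps(X):
    """O(n^3) Lance-Williams minimum-variance agglomeration.

    Starts from Euclidean distances between rows and at each step merges the
    globally closest pair, updating distances with the Ward (minimum variance)
    recurrence. Returns the merge sequence as (frozenset_of_leaf_indices,
    merge_height) tuples.
    """
    n = len(X)
    active = list(range(n))
    members = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {}
    for ii, i in enumerate(active):
        for j in active[ii + 1:]:
            dist[frozenset((i, j))] = float(np.linalg.norm(X[i] - X[j]))
    steps = []
    nxt = n
    while len(active) > 1:
        a, b = min(
            ((i, j) for ii, i in enumerate(active) for j in active[ii + 1:]),
            key=lambda ij: dist[frozenset(ij)],
        )
        h = dist[frozenset((a, b))]
        merged = members[a] | members[b]
        steps.append((merged, h))
        sa, sb = sizes[a], sizes[b]
        for c in active:
            if c in (a, b):
                continue
            sc = sizes[c]
            dac = dist[frozenset((a, c))]
            dbc = dist[frozenset((b, c))]
            new = np.sqrt(
                ((sa + sc) * dac**2 + (sb + sc) * dbc**2 - sc * h**2)
                / (sa + sb + sc)
            )
            dist[frozenset((nxt, c))] = float(new)
        active = [c for c in active if c not in (a, b)] + [nxt]
        members[nxt] = merged
        sizes[nxt] = sa + sb
        nxt += 1
    return steps


def merge_steps_from_linkage(Z, n):
    """Convert a scipy linkage matrix into the same merge-step representation."""
    members = {i: frozenset([i]) for i in range(n)}
    steps = []
    for i, (a, b, h, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        steps.append((merged, float(h)))
    return steps
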