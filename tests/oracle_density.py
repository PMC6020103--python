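"""Brute-force density-connectivity oracle, independent of the clustering
implementation under test.

Semantics of density clustering with (eps, min_samples):
* a point is *core* when at least min_samples points (itself included) lie
  within eps of it;
* core points within eps of each other are density-connected; clusters are
  the connected components of the core graph, numbered by their smallest
  core-point index;
* a non-core point joins the earliest-numbered cluster owning a core point
  within eps of it (border point); otherwise it is noise.
"""

import numpy as np


def density_cluster_oracle(X: np.ndarray, eps: float, min_samples: int
                           ) -> np.ndarray:
    n = len(X)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    adj = d2 <= eps * eps
    core = adj.sum(axis=1) >= min_samples
    # connected components of the core-core graph, in core-index order
    comp = np.full(n, -1, dtype=int)
    next_label = 0
    for i in range(n):
        if not core[i] or comp[i] != -1:
            continue
        stack = [i]
        comp[i] = next_label
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(adj[j] & core):
                if comp[k] == -1:
                    comp[k] = next_label
                    stack.append(k)
        next_label += 1
    labels[core] = comp[core]
    # border points: earliest cluster with a core neighbour
    for i in np.flatnonzero(~core):
        neigh = comp[adj[i] & core]
        if neigh.size:
            labels[i] = neigh.min()
    return labels
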