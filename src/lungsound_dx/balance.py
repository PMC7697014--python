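"""ADASYN adaptive synthetic oversampling in feature space.

COPD recordings outnumber pneumonia and healthy ones in the focused data,
so the minority classes are grown by interpolation: each minority point
receives a generation weight proportional to the fraction of its k nearest
neighbors (searched over the whole data set) that belong to *other* classes
— points near class boundaries spawn more synthetic neighbors.  A synthetic
row is x_new = x_i + lambda * (x_z - x_i) with lambda ~ U(0, 1) and x_z a
random same-class neighbor of x_i, so every synthetic point stays inside
its class's convex hull (and hence its bounding box).

Features are z-scored (fit on the original rows) before the Euclidean
neighbor searches and mapped back afterwards: the 116 descriptor dimensions
carry wildly different units.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .audio_io import FeatureTable

__all__ = ["adasyn"]


def adasyn(
    table: FeatureTable,
    k_neighbors: int = 5,
    balance_ratio: float = 1.0,
    seed: int = 0,
) -> FeatureTable:
    """Balance minority classes against the majority by adaptive synthesis.

    For each class c with n_c < n_majority, G = round((n_majority - n_c) *
    balance_ratio) synthetic rows are appended with provenance "synthetic".
    When every minority point sits deep inside its class (all density
    weights zero) the weights fall back to uniform.  Deterministic under a
    fixed seed.  A table that is already balanced is returned unchanged.
    """
    labels = table.labels
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("ADASYN requires at least 2 classes")
    majority_count = int(counts.max())

    for cls, cnt in zip(classes, counts):
        if cnt < majority_count and cnt <= k_neighbors:
            raise ValueError(
                f"minority class {cls!r} has {cnt} members; "
                f"needs more than k_neighbors={k_neighbors}"
            )

    rng = np.random.default_rng(seed)
    x = table.matrix
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd

    nn_all = NearestNeighbors(n_neighbors=min(k_neighbors + 1, len(z))).fit(z)

    new_rows: list[np.ndarray] = []
    new_labels: list[object] = []
    for cls, cnt in zip(classes, counts):
        g = int(round((majority_count - cnt) * balance_ratio))
        if g <= 0:
            continue
        members = np.nonzero(labels == cls)[0]
        z_cls = z[members]

        # density weights: fraction of whole-data kNN in *other* classes
        _, nbr_idx = nn_all.kneighbors(z_cls)
        nbr_idx = nbr_idx[:, 1:]  # drop self
        other = (labels[nbr_idx] != cls).mean(axis=1)
        weights = other / other.sum() if other.sum() > 0 else np.full(len(members), 1.0 / len(members))

        # same-class neighbor pool for interpolation
        nn_cls = NearestNeighbors(n_neighbors=min(k_neighbors + 1, len(members))).fit(z_cls)
        _, cls_nbrs = nn_cls.kneighbors(z_cls)
        cls_nbrs = cls_nbrs[:, 1:]

        seeds = rng.choice(len(members), size=g, p=weights)
        for i in seeds:
            j = cls_nbrs[i][rng.integers(cls_nbrs.shape[1])]
            lam = rng.uniform()
            z_new = z_cls[i] + lam * (z_cls[j] - z_cls[i])
            new_rows.append(z_new * sd + mu)
            new_labels.append(cls)

    if not new_rows:
        return table
    matrix = np.vstack([x, np.vstack(new_rows)])
    out_labels = np.concatenate([labels, np.array(new_labels, dtype=object)])
    provenance = np.concatenate(
        [table.provenance, np.array(["synthetic"] * len(new_rows), dtype=object)]
    )
    return FeatureTable(matrix, out_labels, table.feature_names, provenance)
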