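"""Minority oversampling for the binary task: SMOTE and ADASYN, from scratch.

Both algorithms add synthetic minority rows by interpolating between a
minority sample and one of its k nearest minority neighbours:

    x_new = x + u * (x_neighbour - x),   u ~ Uniform(0, 1).

SMOTE spreads the synthetics uniformly over the minority class (round-robin
over a shuffled ordering).  ADASYN first measures, for each minority point
x_i, the fraction r_i = Δ_i / k of *majority* points among its k nearest
neighbours in the full dataset, and allocates synthetics proportionally to
the normalized r̂_i — so points near the class boundary receive more.

Only the nearest-neighbour search is delegated (scikit-learn); the sampling
logic itself is implemented here.  Originals are preserved unchanged;
synthetics are appended after them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass
class OversampleConfig:
    """k_neighbors: neighbourhood size; target_ratio: minority:majority
    after balancing (1.0 = fully balanced); seed: RNG seed."""

    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must lie in (0, 1]")


def _split_classes(s):
    if s.label_scheme != "binary":
        raise ValueError("oversampling expects a binary SegmentSet")
    counts = s.class_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present")
    minority = min(counts, key=counts.get)
    majority = 1 - minority
    return minority, majority, counts


def _n_needed(counts, minority, majority, ratio) -> int:
    return max(0, int(round(ratio * counts[majority])) - counts[minority])


def _interpolate(rng, x, neighbours, seeds, picks):
    """Emit one synthetic per (seed index, neighbour pick)."""
    u = rng.uniform(0.0, 1.0, size=len(seeds))
    base = x[seeds]
    nb = x[neighbours[seeds, picks]]
    return base + u[:, None] * (nb - base)


def smote(s, cfg: OversampleConfig = OversampleConfig()):
    """Uniform SMOTE oversampling of the minority class."""
    minority, majority, counts = _split_classes(s)
    if counts[minority] <= cfg.k_neighbors:
        raise ValueError(
            f"minority count {counts[minority]} must exceed k_neighbors "
            f"{cfg.k_neighbors}; use a smaller k"
        )
    g = _n_needed(counts, minority, majority, cfg.target_ratio)
    if g == 0:
        return dataclasses.replace(s, signals=s.signals.copy(),
                                   labels=s.labels.copy())
    rng = np.random.default_rng(cfg.seed)
    min_idx = np.flatnonzero(s.labels == minority)
    xm = s.signals[min_idx]
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(xm)
    neighbours = nn.kneighbors(xm, return_distance=False)[:, 1:]  # drop self

    order = rng.permutation(len(min_idx))
    seeds = np.resize(order, g)  # round-robin over the shuffled minority
    picks = rng.integers(0, cfg.k_neighbors, size=g)
    synth = _interpolate(rng, xm, neighbours, seeds, picks)
    signals = np.vstack([s.signals, synth])
    labels = np.concatenate([s.labels, np.full(g, minority, dtype=int)])
    return dataclasses.replace(s, signals=signals, labels=labels)


def adasyn(s, cfg: OversampleConfig = OversampleConfig()):
    """Density-adaptive oversampling: more synthetics near the boundary.

    Allocation g_i = round(r̂_i * G) per minority seed; the rounding residue
    is settled one synthetic at a time on the highest-r̂ seeds.  When no
    minority point sees any majority neighbour (Σ r_j = 0) the allocation
    falls back to uniform, reducing to SMOTE-like counts.
    """
    minority, majority, counts = _split_classes(s)
    if counts[minority] <= cfg.k_neighbors:
        raise ValueError(
            f"minority count {counts[minority]} must exceed k_neighbors "
            f"{cfg.k_neighbors}; use a smaller k"
        )
    g_total = _n_needed(counts, minority, majority, cfg.target_ratio)
    if g_total == 0:
        return dataclasses.replace(s, signals=s.signals.copy(),
                                   labels=s.labels.copy())
    rng = np.random.default_rng(cfg.seed)
    min_idx = np.flatnonzero(s.labels == minority)
    xm = s.signals[min_idx]

    # r_i: majority fraction among each minority point's k NN in the full set
    nn_all = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(s.signals)
    neigh_all = nn_all.kneighbors(xm, return_distance=False)[:, 1:]
    is_majority = (s.labels == majority)
    r = is_majority[neigh_all].sum(axis=1) / cfg.k_neighbors
    if r.sum() == 0:
        r_hat = np.full(len(min_idx), 1.0 / len(min_idx))
    else:
        r_hat = r / r.sum()

    g = np.round(r_hat * g_total).astype(int)
    residue = g_total - g.sum()
    order_by_density = np.argsort(-r_hat, kind="stable")
    i = 0
    while residue != 0:
        j = order_by_density[i % len(g)]
        if residue > 0:
            g[j] += 1
            residue -= 1
        elif g[j] > 0:
            g[j] -= 1
            residue += 1
        i += 1

    # interpolate toward minority neighbours, as in SMOTE
    nn_min = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(xm)
    neigh_min = nn_min.kneighbors(xm, return_distance=False)[:, 1:]
    seeds = np.repeat(np.arange(len(min_idx)), g)
    picks = rng.integers(0, cfg.k_neighbors, size=len(seeds))
    synth = _interpolate(rng, xm, neigh_min, seeds, picks)
    signals = np.vstack([s.signals, synth])
    labels = np.concatenate([s.labels, np.full(len(seeds), minority, dtype=int)])
    return dataclasses.replace(s, signals=signals, labels=labels)
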