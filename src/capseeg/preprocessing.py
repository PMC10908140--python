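"""Dataset conditioning: identity, standardization, PCA(40), and their chain.

Four named conditions are supported, mirroring the comparison protocol the
models are evaluated under:

- ``any``          no preprocessing;
- ``scaling``      per-feature standardization (population variance);
- ``pca``          projection onto the top 40 principal components;
- ``scaling_pca``  standardization followed by PCA(40).

All parameters are fit on the training partition only and then applied to
the remaining partitions; params serialize to JSON for reuse across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .data import SegmentSet

CONDITIONS = ("any", "scaling", "pca", "scaling_pca")
DEFAULT_N_COMPONENTS = 40
SCALER_EPS = 1e-12


@dataclass
class ScalerParams:
    """Per-feature mean/sd of the training signals (population sd, ddof=0)."""

    mean: np.ndarray
    sd: np.ndarray
    epsilon: float = SCALER_EPS

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean.tolist(), "sd": self.sd.tolist(),
                           "epsilon": self.epsilon})

    @classmethod
    def from_json(cls, s: str) -> "ScalerParams":
        d = json.loads(s)
        return cls(mean=np.asarray(d["mean"]), sd=np.asarray(d["sd"]),
                   epsilon=d["epsilon"])


@dataclass
class PCAParams:
    """Principal directions of the centered training matrix.

    ``components`` has orthonormal rows ordered by descending explained
    variance; each row's sign is fixed so its largest-magnitude loading is
    positive, making fits reproducible.
    """

    components: np.ndarray
    center: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_json(self) -> str:
        return json.dumps({"components": self.components.tolist(),
                           "center": self.center.tolist(),
                           "explained_variance": self.explained_variance.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "PCAParams":
        d = json.loads(s)
        return cls(components=np.asarray(d["components"]),
                   center=np.asarray(d["center"]),
                   explained_variance=np.asarray(d["explained_variance"]))


def fit_scaler(train: SegmentSet) -> ScalerParams:
    if train.n_segments < 2:
        raise ValueError("need at least 2 segments to fit a scaler")
    x = train.signals
    return ScalerParams(mean=x.mean(axis=0), sd=x.std(axis=0, ddof=0))


def apply_scaler(p: ScalerParams, s: SegmentSet) -> SegmentSet:
    if s.segment_len != p.mean.shape[0]:
        raise ValueError(
            f"segment_len {s.segment_len} does not match scaler width "
            f"{p.mean.shape[0]}"
        )
    z = (s.signals - p.mean) / (p.sd + p.epsilon)
    return dataclasses.replace(s, signals=z, labels=s.labels.copy())


def fit_pca(train: SegmentSet, n_components: int = DEFAULT_N_COMPONENTS) -> PCAParams:
    x = train.signals
    max_rank = min(x.shape)
    if n_components > max_rank:
        raise ValueError(
            f"n_components {n_components} exceeds min(n_segments, segment_len) "
            f"= {max_rank}"
        )
    sk = _SkPCA(n_components=n_components, svd_solver="full")
    sk.fit(x)
    comps = sk.components_.copy()
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCAParams(components=comps, center=sk.mean_.copy(),
                     explained_variance=sk.explained_variance_.copy())


def apply_pca(p: PCAParams, s: SegmentSet) -> SegmentSet:
    if s.segment_len != p.center.shape[0]:
        raise ValueError(
            f"segment_len {s.segment_len} does not match PCA input width "
            f"{p.center.shape[0]}"
        )
    z = (s.signals - p.center) @ p.components.T
    return dataclasses.replace(s, signals=z, labels=s.labels.copy())


def condition_pipeline(name: str, train: SegmentSet, *others: SegmentSet,
                       n_components: int = DEFAULT_N_COMPONENTS):
    """Fit the named condition on `train` and apply it to all sets.

    Returns ``(transformed_sets, params)`` where ``transformed_sets`` is a
    tuple beginning with the transformed training set and ``params`` is a
    dict of the fitted parameter objects (empty for ``any``).
    """
    if name not in CONDITIONS:
        raise ValueError(
            f"unknown condition {name!r}; valid conditions: {', '.join(CONDITIONS)}"
        )
    sets = (train,) + others
    params: dict = {}
    if name == "any":
        return sets, params
    if name in ("scaling", "scaling_pca"):
        sc = fit_scaler(train)
        params["scaler"] = sc
        sets = tuple(apply_scaler(sc, s) for s in sets)
    if name in ("pca", "scaling_pca"):
        pca = fit_pca(sets[0], n_components=n_components)
        params["pca"] = pca
        sets = tuple(apply_pca(pca, s) for s in sets)
    return sets, params
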