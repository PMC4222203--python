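"""Simple presence-only envelope algorithms for multi-model consensus.

Bioclim (percentile envelope), Envelope Score (fraction of variables inside
the presence min-max box), and Environmental Distance to the presence mean
under four metrics (euclidean, mahalanobis, manhattan_gower, chebyshev),
normalized by the maximum training-background distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .occurrences import SampleMatrix

KINDS = ("bioclim", "envelope_score", "env_distance")
METRICS = ("euclidean", "mahalanobis", "manhattan_gower", "chebyshev")

_RIDGE = 1e-8


@dataclass
class EnvelopeModel:
    kind: str
    variables: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    p5: np.ndarray
    p95: np.ndarray
    mean: np.ndarray
    metric: str | None = None
    cov_inv: np.ndarray | None = None
    ranges: np.ndarray | None = None  # per-variable scaling for gower
    d_max: float | None = None
    meta: dict = field(default_factory=dict)

    def _distance(self, X: np.ndarray) -> np.ndarray:
        d = X - self.mean
        if self.metric == "euclidean":
            return np.sqrt((d ** 2).sum(axis=1))
        if self.metric == "mahalanobis":
            return np.sqrt(np.einsum("ij,jk,ik->i", d, self.cov_inv, d))
        if self.metric == "manhattan_gower":
            return (np.abs(d) / self.ranges).sum(axis=1) / d.shape[1]
        if self.metric == "chebyshev":
            return np.abs(d).max(axis=1)
        raise InputError(f"unknown metric {self.metric!r}")

    def score(self, X: np.ndarray) -> np.ndarray:
        """Suitability in [0,1] per row (bioclim is three-valued)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.variables):
            raise InputError("row width does not match model variables")
        if self.kind == "bioclim":
            in_core = np.all((X >= self.p5) & (X <= self.p95), axis=1)
            in_box = np.all((X >= self.mins) & (X <= self.maxs), axis=1)
            return np.where(in_core, 1.0, np.where(in_box, 0.5, 0.0))
        if self.kind == "envelope_score":
            inside = (X >= self.mins) & (X <= self.maxs)
            return inside.mean(axis=1)
        if self.kind == "env_distance":
            d = self._distance(X)
            return np.clip(1.0 - d / self.d_max, 0.0, 1.0)
        raise InputError(f"unknown kind {self.kind!r}")

    def to_json(self) -> str:
        doc = {
            "kind": self.kind,
            "metric": self.metric,
            "variables": list(self.variables),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "p5": self.p5.tolist(),
            "p95": self.p95.tolist(),
            "mean": self.mean.tolist(),
            "cov_inv": None if self.cov_inv is None else self.cov_inv.tolist(),
            "ranges": None if self.ranges is None else self.ranges.tolist(),
            "d_max": self.d_max,
            "meta": self.meta,
        }
        return json.dumps(doc, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EnvelopeModel":
        doc = json.loads(text)
        if doc.get("kind") not in KINDS:
            raise InputError("not an envelope model document")
        arr = lambda x: None if x is None else np.asarray(x, dtype=float)
        return cls(
            kind=doc["kind"],
            metric=doc.get("metric"),
            variables=tuple(doc["variables"]),
            mins=arr(doc["mins"]), maxs=arr(doc["maxs"]),
            p5=arr(doc["p5"]), p95=arr(doc["p95"]), mean=arr(doc["mean"]),
            cov_inv=arr(doc["cov_inv"]), ranges=arr(doc["ranges"]),
            d_max=doc["d_max"], meta=doc.get("meta", {}),
        )


def fit_envelope(
    presence: SampleMatrix,
    kind: str,
    metric: str | None = None,
    background: SampleMatrix | None = None,
) -> EnvelopeModel:
    """Fit an envelope model on presence rows.

    ``env_distance`` additionally needs the training background to set the
    normalizing distance d_max (the maximum background distance from the
    presence mean) and, for gower scaling, the combined variable ranges.
    """
    if kind not in KINDS:
        raise InputError(f"unknown envelope kind {kind!r}")
    X = presence.X
    m, p = X.shape
    if m < 2:
        raise InputError("need at least 2 presence rows")
    model = EnvelopeModel(
        kind=kind,
        variables=presence.variables,
        mins=X.min(axis=0),
        maxs=X.max(axis=0),
        p5=np.percentile(X, 5, axis=0),
        p95=np.percentile(X, 95, axis=0),
        mean=X.mean(axis=0),
        metric=metric,
        meta={"n_presence": int(m)},
    )
    if kind != "env_distance":
        return model
    if metric not in METRICS:
        raise InputError(f"env_distance needs a metric from {METRICS}")
    if background is None:
        raise InputError("env_distance needs the training background for d_max")
    if metric == "mahalanobis":
        if m < p + 1:
            raise InputError("mahalanobis needs more presences than variables")
        cov = np.cov(X, rowvar=False)
        cov = np.atleast_2d(cov)
        # ridge keeps near-singular presence clouds invertible
        cov = cov + _RIDGE * np.trace(cov) / p * np.eye(p)
        model.cov_inv = np.linalg.inv(cov)
    if metric == "manhattan_gower":
        combined = np.vstack([X, background.X])
        rng = combined.max(axis=0) - combined.min(axis=0)
        model.ranges = np.where(rng > 0, rng, 1.0)
    d_bg = model._distance(background.X)
    d_max = float(d_bg.max())
    if d_max <= 0:
        raise InputError("degenerate background: zero maximum distance")
    model.d_max = d_max
    return model
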