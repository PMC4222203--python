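"""Presence-only maximum-entropy model with hinge features and L1 penalty.

The model places a probability distribution over background cells that
maximizes entropy subject to (soft) feature-mean constraints. Fitting
minimizes the equivalent penalized log-loss

    J(lambda) = -mean_presence eta(x) + log sum_background exp(eta(x))
                + sum_j beta_j |lambda_j|

with eta(x) = sum_j lambda_j f_j(x), by deterministic cyclic coordinate
descent with an exact soft-thresholded line search per coordinate. Only
hinge features are used; the per-feature penalty is the hinge-class default
0.5 * sd_j(presences) / sqrt(m), scaled by a global beta multiplier.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .errors import InputError, StateError
from .occurrences import SampleMatrix

log = logging.getLogger(__name__)

#: Hard bound on any single weight; reached only when a feature perfectly
#: separates presences from background at negligible penalty.
LAMBDA_BOUND = 50.0

#: Relative floor on the per-feature presence SD entering the penalty.
BETA_SD_FLOOR = 1e-3


@dataclass(frozen=True)
class HingeFeature:
    """A forward or reverse hinge ramp, scaled to [0, 1] on training data."""

    variable: str
    knot: float
    direction: str  # "forward" | "reverse"
    lo: float
    hi: float

    def value(self, v: np.ndarray) -> np.ndarray:
        v = np.clip(v, self.lo, self.hi)
        if self.direction == "forward":
            return np.clip((v - self.knot) / (self.hi - self.knot), 0.0, 1.0)
        return np.clip((self.knot - v) / (self.knot - self.lo), 0.0, 1.0)


def build_features(
    presence: SampleMatrix,
    background: SampleMatrix,
    knots_per_variable: int = 30,
) -> list[HingeFeature]:
    """Hinge features with knots at evenly spaced quantiles of the data.

    For each variable, lo/hi are the min/max over presences plus background;
    each interior knot yields a forward and a reverse hinge (degenerate
    zero-width ramps are skipped). Constant variables contribute nothing.
    """
    if presence.variables != background.variables:
        raise InputError("presence and background matrices have different variables")
    if knots_per_variable < 1:
        raise InputError("knots_per_variable must be >= 1")
    feats: list[HingeFeature] = []
    for k, var in enumerate(presence.variables):
        combined = np.concatenate([presence.X[:, k], background.X[:, k]])
        if not np.all(np.isfinite(combined)):
            raise InputError(f"non-finite covariate values for {var!r}")
        lo, hi = float(combined.min()), float(combined.max())
        if hi - lo <= 1e-12:
            log.warning("variable %r is constant over training data; skipped", var)
            continue
        qs = np.linspace(0.0, 1.0, knots_per_variable)
        knots = np.unique(np.quantile(combined, qs))
        for knot in knots:
            knot = float(knot)
            if hi - knot > 1e-12:
                feats.append(HingeFeature(var, knot, "forward", lo, hi))
            if knot - lo > 1e-12:
                feats.append(HingeFeature(var, knot, "reverse", lo, hi))
    return feats


def feature_matrix(
    features: Sequence[HingeFeature],
    X: np.ndarray,
    variables: Sequence[str],
) -> np.ndarray:
    """Evaluate features on raw covariate rows -> (n, n_features) in [0,1]."""
    col = {v: i for i, v in enumerate(variables)}
    out = np.empty((X.shape[0], len(features)))
    for j, f in enumerate(features):
        if f.variable not in col:
            raise InputError(f"rows lack variable {f.variable!r}")
        out[:, j] = f.value(X[:, col[f.variable]])
    return out


def penalized_objective(
    lam: np.ndarray, Fp: np.ndarray, Fb: np.ndarray, betas: np.ndarray
) -> float:
    """The L1-penalized log-loss J(lambda); the quantity the fitter minimizes."""
    eta_p = Fp @ lam
    eta_b = Fb @ lam
    return float(-eta_p.mean() + logsumexp(eta_b) + betas @ np.abs(lam))


def _phi_prime(delta: float, eta_b: np.ndarray, f: np.ndarray, pbar_j: float) -> float:
    """d/d delta of the smooth part along one coordinate."""
    z = eta_b + delta * f
    z -= z.max()
    w = np.exp(z)
    return float((w @ f) / w.sum() - pbar_j)


def _coordinate_solve(
    lam_j: float, eta_b: np.ndarray, f: np.ndarray, pbar_j: float, beta_j: float
) -> float:
    """Exact minimizer of the 1-D penalized objective along coordinate j.

    Returns the new weight value. Uses the soft-threshold optimality split:
    the origin is optimal iff |phi'(-lam_j)| <= beta; otherwise the solution
    solves phi'(delta) = -sign * beta on the appropriate side.
    """
    g0 = _phi_prime(-lam_j, eta_b, f, pbar_j)  # smooth slope at x = 0
    if abs(g0) <= beta_j:
        return 0.0
    if g0 < -beta_j:  # minimizer at x > 0 where phi'(delta) = -beta
        sign, target = 1.0, -beta_j
    else:  # minimizer at x < 0 where phi'(delta) = +beta
        sign, target = -1.0, beta_j

    def psi(delta: float) -> float:
        return _phi_prime(delta, eta_b, f, pbar_j) - target

    lo = -lam_j  # x = 0
    hi = lo + sign
    # expand until bracketed or the weight bound is hit
    for _ in range(60):
        x = lam_j + hi
        if psi(hi) * psi(lo) <= 0:
            break
        if abs(x) >= LAMBDA_BOUND:
            return sign * LAMBDA_BOUND
        lo_, hi = hi, hi + sign * 2.0 * abs(hi - lo)
        lo = lo_
    else:  # pragma: no cover - expansion loop always terminates
        return sign * LAMBDA_BOUND
    if psi(lo) * psi(hi) > 0:
        return float(np.clip(lam_j + hi, -LAMBDA_BOUND, LAMBDA_BOUND))
    delta = brentq(psi, min(lo, hi), max(lo, hi), xtol=1e-12, rtol=8.9e-16, maxiter=200)
    return float(np.clip(lam_j + delta, -LAMBDA_BOUND, LAMBDA_BOUND))


def fit_feature_weights(
    Fp: np.ndarray,
    Fb: np.ndarray,
    betas: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 3000,
    kkt_tol: float = 5e-5,
) -> tuple[np.ndarray, list[tuple[int, float]], bool, int]:
    """Cyclic coordinate descent on J(lambda) over given feature matrices.

    Returns (weights, gain trace [(feature, objective decrease)], converged
    flag, sweeps used). Deterministic: coordinates are visited in feature
    order, updates are exact 1-D minimizations.
    """
    m, J = Fp.shape
    if m < 1 or Fb.shape[0] < 2:
        raise InputError("need >=1 presence and >=2 background rows")
    pbar = Fp.mean(axis=0)
    lam = np.zeros(J)
    eta_b = np.zeros(Fb.shape[0])
    obj = penalized_objective(lam, Fp, Fb, betas)
    trace: list[tuple[int, float]] = []
    converged = False
    sweeps = 0

    def _sweep(indices) -> None:
        nonlocal eta_b, obj
        for j in indices:
            f = Fb[:, j]
            if lam[j] == 0.0:
                # cheap KKT screen: stay at zero if the box condition holds
                g = _phi_prime(0.0, eta_b, f, pbar[j])
                if abs(g) <= betas[j]:
                    continue
            new = _coordinate_solve(lam[j], eta_b, f, pbar[j], betas[j])
            if new == lam[j]:
                continue
            eta_b = eta_b + (new - lam[j]) * f
            lam[j] = new
            new_obj = penalized_objective(lam, Fp, Fb, betas)
            gain = obj - new_obj
            if abs(gain) > 0:
                trace.append((j, gain))
            obj = new_obj

    while sweeps < max_iter:
        obj_start = obj
        sweeps += 1
        _sweep(range(J))
        # active-set refinement: iterate the nonzero weights to convergence
        while sweeps < max_iter:
            active = np.nonzero(lam)[0]
            if active.size == 0:
                break
            inner_start = obj
            sweeps += 1
            _sweep(active)
            if inner_start - obj < tol:
                break
        # sweep-level stopping: objective stall + KKT box condition
        z = eta_b - eta_b.max()
        w = np.exp(z)
        p = w / w.sum()
        grad = Fb.T @ p - pbar
        viol = np.where(
            lam == 0.0,
            np.maximum(0.0, np.abs(grad) - betas),
            np.abs(grad + betas * np.sign(lam)),
        )
        # weights pinned at the bound legitimately exceed the box condition
        viol[np.abs(lam) >= LAMBDA_BOUND] = 0.0
        if obj_start - obj < tol and viol.max() <= kkt_tol:
            converged = True
            break
    return lam, trace, converged, sweeps


@dataclass
class MaxentModel:
    """Fitted maximum-entropy model.

    ``logZ`` and ``entropy`` are computed over the training background and
    fix the logistic link: suitability = c q / (1 + c q) with
    q = exp(eta - logZ) and c = exp(entropy) (tau = 0.5 convention).
    """

    features: list[HingeFeature]
    lam: np.ndarray
    betas: np.ndarray
    beta_multiplier: float
    variables: tuple[str, ...]
    logZ: float
    entropy: float
    tau: float = 0.5
    trace: list[tuple[int, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    # -- prediction -------------------------------------------------------

    def eta(self, X: np.ndarray) -> np.ndarray:
        F = feature_matrix(self.features, X, self.variables)
        return F @ self.lam

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Normalized maxent distribution over the provided rows (sums to 1)."""
        e = self.eta(X)
        e -= e.max()
        w = np.exp(e)
        return w / w.sum()

    def predict_logistic(self, X: np.ndarray) -> np.ndarray:
        """Logistic suitability in [0,1]; covariates are clamped per feature."""
        if self.lam is None:
            raise StateError("model not fitted")
        loq = self.eta(X) - self.logZ + self.entropy  # log(c q)
        return 1.0 / (1.0 + np.exp(-loq))

    @property
    def gain(self) -> float:
        """Unpenalized training gain relative to the uniform distribution."""
        return self.meta["gain"]

    # -- reporting --------------------------------------------------------

    def variable_contributions(self) -> dict[str, float]:
        """Percent contribution per variable from positive gain increments."""
        totals = {v: 0.0 for v in self.variables}
        for j, inc in self.trace:
            if inc > 0:
                totals[self.features[j].variable] += inc
        s = sum(totals.values())
        if s <= 0:
            log.warning("empty gain trace: contributions undefined, returning zeros")
            return totals
        return {v: 100.0 * t / s for v, t in totals.items()}

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "kind": "maxent",
            "variables": list(self.variables),
            "features": [
                {"variable": f.variable, "knot": f.knot, "direction": f.direction,
                 "lo": f.lo, "hi": f.hi}
                for f in self.features
            ],
            "lambda": self.lam.tolist(),
            "beta": self.betas.tolist(),
            "beta_multiplier": self.beta_multiplier,
            "logZ": self.logZ,
            "entropy": self.entropy,
            "tau": self.tau,
            "trace": [[int(j), float(g)] for j, g in self.trace],
            "meta": self.meta,
        }
        return json.dumps(doc, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        doc = json.loads(text)
        if doc.get("kind") != "maxent":
            raise InputError("not a maxent model document")
        feats = [HingeFeature(**f) for f in doc["features"]]
        return cls(
            features=feats,
            lam=np.asarray(doc["lambda"], dtype=float),
            betas=np.asarray(doc["beta"], dtype=float),
            beta_multiplier=float(doc["beta_multiplier"]),
            variables=tuple(doc["variables"]),
            logZ=float(doc["logZ"]),
            entropy=float(doc["entropy"]),
            tau=float(doc["tau"]),
            trace=[(int(j), float(g)) for j, g in doc["trace"]],
            meta=doc["meta"],
        )


def compute_betas(
    Fp: np.ndarray, beta_multiplier: float = 1.0
) -> np.ndarray:
    """Per-feature L1 penalties: bm * 0.5 * sd_presence / sqrt(m), floored.

    Features live in [0,1]; the SD floor keeps every penalty positive.
    """
    m = Fp.shape[0]
    sd = Fp.std(axis=0)
    rng_j = Fp.max(axis=0) - Fp.min(axis=0)
    floor = BETA_SD_FLOOR * np.maximum(rng_j, 1.0)
    return beta_multiplier * 0.5 * np.maximum(sd, floor) / math.sqrt(m)


def fit(
    presence: SampleMatrix,
    background: SampleMatrix,
    beta_multiplier: float = 1.0,
    tol: float = 1e-5,
    max_iter: int = 3000,
    knots_per_variable: int = 30,
    features: Sequence[HingeFeature] | None = None,
) -> MaxentModel:
    """Fit the maxent model on presence vs background covariate rows."""
    if beta_multiplier <= 0:
        raise InputError("beta_multiplier must be positive")
    if not (np.all(np.isfinite(presence.X)) and np.all(np.isfinite(background.X))):
        raise InputError("non-finite covariates in training matrices")
    feats = list(features) if features is not None else build_features(
        presence, background, knots_per_variable
    )
    variables = presence.variables
    Fp = feature_matrix(feats, presence.X, variables)
    Fb = feature_matrix(feats, background.X, variables)
    if feats:
        betas = compute_betas(Fp, beta_multiplier)
        lam, trace, converged, sweeps = fit_feature_weights(
            Fp, Fb, betas, tol=tol, max_iter=max_iter
        )
    else:
        betas = np.zeros(0)
        lam, trace, converged, sweeps = np.zeros(0), [], True, 0
    if not converged:
        log.warning("maxent fit did not converge in %d sweeps", max_iter)
    eta_b = Fb @ lam
    logZ = float(logsumexp(eta_b))
    p = np.exp(eta_b - logZ)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = float(-plogp.sum())
    n_bg = Fb.shape[0]
    gain = float(Fp.mean(axis=0) @ lam - logZ + math.log(n_bg))
    model = MaxentModel(
        features=feats,
        lam=lam,
        betas=betas,
        beta_multiplier=beta_multiplier,
        variables=variables,
        logZ=logZ,
        entropy=entropy,
        trace=trace,
        meta={
            "converged": bool(converged),
            "sweeps": int(sweeps),
            "n_presence": int(Fp.shape[0]),
            "n_background": int(n_bg),
            "gain": gain,
            "background_means": background.X.mean(axis=0).tolist(),
            "knots_per_variable": int(knots_per_variable),
        },
    )
    return model
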