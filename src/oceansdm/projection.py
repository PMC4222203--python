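"""Model projection onto grids, consensus/ensemble maps, and evaluation.

Covers projection of fitted maxent/envelope models on environmental stacks,
thresholded and multi-model consensus maps, climate-ensemble mean/SD maps,
per-longitude range-boundary profiles, rank-based AUC, cross-validation,
jackknife variable importance, and response curves.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from . import maxent
from .envelopes import EnvelopeModel
from .errors import AlignmentError, InputError
from .grids import EnvGrid, EnvStack
from .maxent import MaxentModel
from .occurrences import SampleMatrix

log = logging.getLogger(__name__)


@dataclass
class SuitabilityMap:
    """Per-cell habitat suitability in [0,1] on an ocean grid."""

    grid: EnvGrid
    model_id: str = ""
    time_tag: str = "annual"
    scenario_tag: str = "present"
    gcm_tag: str | None = None

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


@dataclass
class ConsensusMap:
    grid: EnvGrid  # integer counts stored as float
    threshold: float
    n_models: int


@dataclass
class EnsembleMap:
    mean: EnvGrid
    sd: EnvGrid
    members: list[str]
    scenario: str
    time_tag: str


@dataclass
class EvaluationReport:
    auc: float
    cv_auc_mean: float | None = None
    cv_auc_sd: float | None = None
    cv_aucs: list[float] = field(default_factory=list)
    contributions: dict[str, float] = field(default_factory=dict)
    jackknife: dict[str, dict[str, float]] = field(default_factory=dict)
    response_curves: dict[str, dict[str, list[float]]] = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "auc": self.auc,
            "cv_auc_mean": self.cv_auc_mean,
            "cv_auc_sd": self.cv_auc_sd,
            "cv_aucs": self.cv_aucs,
            "contributions": self.contributions,
            "jackknife": self.jackknife,
            "response_curves": self.response_curves,
        }
        return json.dumps(doc, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# projection

def _model_scores(model, X: np.ndarray) -> np.ndarray:
    if isinstance(model, MaxentModel):
        return model.predict_logistic(X)
    if isinstance(model, EnvelopeModel):
        return model.score(X)
    raise InputError(f"cannot project model of type {type(model).__name__}")


def project(model, stack: EnvStack, model_id: str | None = None) -> SuitabilityMap:
    """Score every ocean cell of a stack with a fitted model."""
    for v in model.variables:
        if v not in stack.grids:
            raise InputError(f"stack lacks model variable {v!r}")
    X = stack.map_values(model.variables)
    scores = _model_scores(model, X)
    ref = stack.reference()
    values = np.full(ref.shape, np.nan)
    values[stack.mask] = scores
    grid = EnvGrid(
        variable="suitability", units="1",
        lat=ref.lat.copy(), lon=ref.lon.copy(),
        values=values, mask=stack.mask.copy(),
    )
    if model_id is None:
        model_id = getattr(model, "kind", type(model).__name__.lower())
    return SuitabilityMap(
        grid=grid, model_id=model_id, time_tag=stack.time_tag,
        scenario_tag=stack.scenario_tag, gcm_tag=stack.gcm_tag,
    )


def threshold_map(smap: SuitabilityMap | EnvGrid, t: float) -> EnvGrid:
    """Binary presence grid: cell true iff suitability >= t."""
    if not 0.0 < t < 1.0:
        raise InputError("threshold must lie in (0,1)")
    grid = smap.grid if isinstance(smap, SuitabilityMap) else smap
    binary = np.where(grid.mask, (grid.values >= t).astype(float), np.nan)
    return grid.with_values(binary, variable="presence", units="1")


def consensus(maps: Sequence[SuitabilityMap], t: float = 0.2) -> ConsensusMap:
    """Per-cell count of models whose suitability reaches the threshold."""
    if not maps:
        raise InputError("need at least one map for consensus")
    ref = maps[0].grid
    counts = np.zeros(ref.shape)
    for m in maps:
        if not m.grid.same_geometry(ref) or not np.array_equal(m.grid.mask, ref.mask):
            raise AlignmentError("consensus maps do not share geometry/mask")
        counts += np.where(ref.mask, (m.grid.values >= t), 0.0)
    grid = ref.with_values(np.where(ref.mask, counts, np.nan), variable="count", units="1")
    return ConsensusMap(grid=grid, threshold=t, n_models=len(maps))


def ensemble(model, stacks: Sequence[EnvStack]) -> EnsembleMap:
    """Mean and population SD of projections over GCM member stacks."""
    if not stacks:
        raise InputError("need at least one member stack")
    tags = {(s.time_tag, s.scenario_tag) for s in stacks}
    if len(tags) != 1:
        raise InputError(f"ensemble members disagree on time/scenario tags: {tags}")
    maps = [project(model, s) for s in stacks]
    arr = np.stack([m.grid.values for m in maps])
    ref = maps[0].grid
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    # exact zero where all members agree (guards float rounding in std)
    with np.errstate(invalid="ignore"):
        allsame = (arr.max(axis=0) - arr.min(axis=0)) == 0.0
    sd = np.where(allsame, 0.0, sd)
    return EnsembleMap(
        mean=ref.with_values(mean, variable="suitability"),
        sd=ref.with_values(sd, variable="suitability"),
        members=[s.gcm_tag or f"member{i}" for i, s in enumerate(stacks)],
        scenario=stacks[0].scenario_tag,
        time_tag=stacks[0].time_tag,
    )


def boundary_latitude(
    source: SuitabilityMap | EnvGrid,
    t: float | None = None,
    pole: str = "south",
    contiguous: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-longitude equatorward boundary of the above-threshold range.

    For each longitude column, finds the contiguous above-threshold run that
    touches the polar side (land cells do not break a run) and reports the
    latitude of its most equatorward cell; NaN for empty columns. With
    ``contiguous=False`` the most equatorward above-threshold cell is
    reported regardless of contiguity.
    """
    grid = source.grid if isinstance(source, SuitabilityMap) else source
    if t is not None:
        if not 0.0 < t < 1.0:
            raise InputError("threshold must lie in (0,1)")
        above = grid.mask & (np.nan_to_num(grid.values, nan=-1.0) >= t)
    else:
        above = grid.mask & (np.nan_to_num(grid.values, nan=0.0) > 0)
    if pole not in ("south", "north"):
        raise InputError("pole must be 'south' or 'north'")
    nlat, nlon = grid.shape
    out = np.full(nlon, np.nan)
    # iterate rows polar side -> equator
    order = range(nlat) if pole == "south" else range(nlat - 1, -1, -1)
    order = list(order)
    for j in range(nlon):
        col_above = above[:, j]
        if not col_above.any():
            continue
        if not contiguous:
            idx = np.nonzero(col_above)[0]
            out[j] = grid.lat[idx[-1] if pole == "south" else idx[0]]
            continue
        started = False
        last = None
        for i in order:
            if col_above[i]:
                started = True
                last = i
            elif started and grid.mask[i, j]:
                break  # ocean gap ends the polar run
        if last is not None:
            out[j] = grid.lat[last]
    return grid.lon.copy(), out


# ---------------------------------------------------------------------------
# evaluation statistics

def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney U / (n_p * n_b)); ties count one half."""
    ps = np.asarray(presence_scores, dtype=float).ravel()
    bs = np.asarray(background_scores, dtype=float).ravel()
    if ps.size == 0 or bs.size == 0:
        raise InputError("auc needs non-empty score sets")
    ranks = rankdata(np.concatenate([ps, bs]))
    u = ranks[: ps.size].sum() - ps.size * (ps.size + 1) / 2.0
    return float(u / (ps.size * bs.size))


def cross_validate(
    presence: SampleMatrix,
    background: SampleMatrix,
    k: int = 5,
    seed: int = 0,
    beta_multiplier: float = 1.0,
    knots_per_variable: int = 30,
    tol: float = 1e-5,
    max_iter: int = 3000,
) -> dict:
    """K-fold CV over presences with a shared background.

    Presences are split into k folds by a seeded permutation; each fold is
    held out, the model refit on the rest, and AUC computed for the held-out
    presences against the full background.
    """
    m = len(presence)
    if k < 2:
        raise InputError("k must be >= 2")
    if k > m:
        raise InputError(f"k={k} exceeds number of presences ({m})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    folds = np.array_split(perm, k)
    aucs, models = [], []
    for fold in folds:
        train_idx = np.setdiff1d(perm, fold)
        model = maxent.fit(
            presence.subset(train_idx), background,
            beta_multiplier=beta_multiplier,
            knots_per_variable=knots_per_variable,
            tol=tol, max_iter=max_iter,
        )
        held = presence.subset(fold)
        aucs.append(auc(model.predict_logistic(held.X), model.predict_logistic(background.X)))
        models.append(model)
    aucs_arr = np.asarray(aucs)
    return {
        "cv_auc_mean": float(aucs_arr.mean()),
        "cv_auc_sd": float(aucs_arr.std(ddof=1)) if k > 1 else 0.0,
        "aucs": [float(a) for a in aucs],
        "models": models,
    }


def jackknife_variables(
    presence: SampleMatrix,
    background: SampleMatrix,
    beta_multiplier: float = 1.0,
    knots_per_variable: int = 30,
    tol: float = 1e-5,
    max_iter: int = 3000,
) -> dict[str, dict[str, float]]:
    """Training gain with each variable alone and with each omitted."""
    variables = presence.variables
    if len(variables) < 2:
        raise InputError("jackknife needs >=2 variables")

    def _gain(vars_: Sequence[str]) -> float:
        model = maxent.fit(
            presence.select_variables(vars_),
            background.select_variables(vars_),
            beta_multiplier=beta_multiplier,
            knots_per_variable=knots_per_variable,
            tol=tol, max_iter=max_iter,
        )
        return model.gain

    gain_full = _gain(variables)
    out: dict[str, dict[str, float]] = {}
    for v in variables:
        others = [w for w in variables if w != v]
        out[v] = {
            "gain_only": _gain([v]),
            "gain_without": _gain(others),
            "gain_full": gain_full,
        }
    return out


def response_curve(
    model: MaxentModel,
    variable: str,
    n_points: int = 100,
    background_means: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal response: vary one variable over its training range.

    Other variables are held at their background means (taken from the
    model's training metadata unless supplied).
    """
    if variable not in model.variables:
        raise InputError(f"model has no variable {variable!r}")
    spans = [(f.lo, f.hi) for f in model.features if f.variable == variable]
    if spans:
        lo = min(s[0] for s in spans)
        hi = max(s[1] for s in spans)
    else:
        lo, hi = 0.0, 1.0
    if background_means is None:
        background_means = np.asarray(model.meta["background_means"], dtype=float)
    values = np.linspace(lo, hi, n_points)
    X = np.tile(background_means, (n_points, 1))
    X[:, model.variables.index(variable)] = values
    return values, model.predict_logistic(X)


def evaluate(
    model: MaxentModel,
    presence: SampleMatrix,
    background: SampleMatrix,
    cv_folds: int | None = 5,
    seed: int = 0,
    jackknife: bool = True,
    n_curve_points: int = 50,
    knots_per_variable: int | None = None,
    max_iter: int = 3000,
) -> EvaluationReport:
    """Full evaluation report: AUC, CV, contributions, jackknife, curves."""
    knots = knots_per_variable or model.meta.get("knots_per_variable", 30)
    report = EvaluationReport(
        auc=auc(model.predict_logistic(presence.X), model.predict_logistic(background.X)),
        contributions=model.variable_contributions(),
    )
    if cv_folds and cv_folds >= 2 and len(presence) >= cv_folds:
        cv = cross_validate(
            presence, background, k=cv_folds, seed=seed,
            beta_multiplier=model.beta_multiplier,
            knots_per_variable=knots, max_iter=max_iter,
        )
        report.cv_auc_mean = cv["cv_auc_mean"]
        report.cv_auc_sd = cv["cv_auc_sd"]
        report.cv_aucs = cv["aucs"]
    if jackknife and len(model.variables) >= 2:
        report.jackknife = jackknife_variables(
            presence, background,
            beta_multiplier=model.beta_multiplier,
            knots_per_variable=knots, max_iter=max_iter,
        )
    for v in model.variables:
        xs, ys = response_curve(model, v, n_points=n_curve_points)
        report.response_curves[v] = {
            "values": [float(x) for x in xs],
            "suitability": [float(y) for y in ys],
        }
    return report
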