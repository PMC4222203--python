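"""End-to-end demo pipeline on the synthetic ocean.

simulate -> prepare (yearly + monthly) -> fit maxent + envelope models ->
project (annual + 12 months) -> future GCM ensembles -> multi-model
consensus -> evaluation reports. Every artifact is written under the run
directory and listed, with a content hash, in ``manifest.json``; reruns
with the same config and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Any

from . import envelopes, grids, maxent, occurrences, projection, synthetic
from .config import RunConfig
from .errors import InputError, OceanSDMError
from .grids import write_grid

log = logging.getLogger(__name__)

# fixed per-stage seed offsets derived from the one global seed
SEED_SAMPLING = 1000
SEED_BACKGROUND = 2000
SEED_CV = 3000
SEED_FUTURE = 4000

ENVELOPE_SPECS = [
    ("bioclim", None),
    ("envelope_score", None),
    ("env_distance", "euclidean"),
    ("env_distance", "mahalanobis"),
    ("env_distance", "manhattan_gower"),
    ("env_distance", "chebyshev"),
]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Artifacts:
    def __init__(self, root: str):
        self.root = root
        self.files: list[str] = []
        os.makedirs(root, exist_ok=True)

    def path(self, rel: str) -> str:
        p = os.path.join(self.root, rel)
        os.makedirs(os.path.dirname(p), exist_ok=True)
        self.files.append(rel)
        return p

    def write_text(self, rel: str, text: str) -> None:
        with open(self.path(rel), "w") as fh:
            fh.write(text)

    def write_grid(self, rel: str, grid) -> None:
        write_grid(grid, self.path(rel), format="ascii_grid")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except OceanSDMError as e:
                raise OceanSDMError(f"pipeline stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def run_pipeline(config: RunConfig, output_dir: str | None = None) -> dict[str, Any]:
    """Execute the full synthetic workflow; returns the manifest dict."""
    out = _Artifacts(output_dir or config.output_dir)
    seed = config.seed
    counts: dict[str, Any] = {}

    # --- simulate --------------------------------------------------------
    oc = dict(config["ocean"])
    oc["lat_range"] = tuple(oc.pop("lat_range"))
    oc["lon_range"] = tuple(oc.pop("lon_range"))
    oc["si_decouple_band"] = tuple(oc.pop("si_decouple_band"))
    params = synthetic.OceanParams(seed=seed, **oc)
    truth = synthetic.TruthParams(**config["truth"])
    layers = _stage("simulate")(synthetic.make_environment)(params)
    truths = [synthetic.true_suitability(s, truth) for s in layers.monthly]
    truth_annual = synthetic.true_suitability(layers.annual, truth)
    for v, g in layers.annual.grids.items():
        out.write_grid(f"env/annual_{v}.asc", g)
    out.write_grid("truth/annual_suitability.asc", truth_annual.grid)

    mw = config["sampling"]["month_weights"]
    occset = _stage("sample")(synthetic.sample_presences)(
        truths, n=config["sampling"]["n"], month_weights=mw, seed=seed + SEED_SAMPLING
    )
    occ_csv = "\n".join(
        ["lon,lat,month,source"]
        + [f"{r.lon:.6f},{r.lat:.6f},{r.month},{r.source}" for r in occset.records]
    ) + "\n"
    out.write_text("occurrences.csv", occ_csv)
    counts["presences_raw"] = len(occset)

    # --- prepare ---------------------------------------------------------
    geom = layers.annual.reference()
    prep = config["prepare"]
    bias = None
    if prep["use_bias"]:
        bias = occurrences.build_bias_grid(
            occset.records, geom, smooth_radius=prep["bias_smooth_radius"]
        )
        out.write_grid("bias.asc", bias)

    @_stage("prepare")
    def _prepare(mode: str):
        ded = occurrences.dedupe(occset.records, geom, mode=mode)
        if not ded.records:
            raise InputError(
                f"{mode} prepare produced no records"
                + (" (no dated records?)" if mode == "monthly" else "")
            )
        pres = occurrences.extract_covariates(ded, layers.annual, layers.monthly, mode=mode)
        if mode == "yearly":
            bg = occurrences.sample_background(
                layers.annual, n=prep["background"], bias=bias, seed=seed + SEED_BACKGROUND
            )
        else:
            bg = occurrences.sample_background_monthly(
                layers.monthly, n=prep["background"], bias=bias, seed=seed + SEED_BACKGROUND
            )
        return ded, pres, bg

    ded_y, pres_y, bg_y = _prepare("yearly")
    ded_m, pres_m, bg_m = _prepare("monthly")
    counts["presences_yearly"] = len(ded_y)
    counts["presences_monthly"] = len(ded_m)
    counts["dropped_no_month"] = ded_m.n_dropped_no_month
    counts["background"] = len(bg_y)
    log.info(
        "prepare: %d raw -> %d yearly / %d monthly records (%d without month dropped)",
        counts["presences_raw"], len(ded_y), len(ded_m), ded_m.n_dropped_no_month,
    )

    # --- fit -------------------------------------------------------------
    fitcfg = config["fit"]
    fit_kwargs = dict(
        beta_multiplier=fitcfg["beta_multiplier"],
        knots_per_variable=fitcfg["knots"],
        tol=fitcfg["tol"],
        max_iter=fitcfg["max_iter"],
    )
    model_y = _stage("fit")(maxent.fit)(pres_y, bg_y, **fit_kwargs)
    model_m = _stage("fit")(maxent.fit)(pres_m, bg_m, **fit_kwargs)
    out.write_text("models/maxent_yearly.json", model_y.to_json())
    out.write_text("models/maxent_monthly.json", model_m.to_json())

    env_models = []
    for kind, metric in ENVELOPE_SPECS:
        em = _stage("fit-envelope")(envelopes.fit_envelope)(
            pres_y, kind, metric=metric, background=bg_y
        )
        name = kind if metric is None else f"{kind}_{metric}"
        out.write_text(f"models/{name}.json", em.to_json())
        env_models.append((name, em))

    # --- project ---------------------------------------------------------
    proj = _stage("project")(projection.project)
    map_annual_y = proj(model_y, layers.annual, model_id="maxent_yearly")
    map_annual_m = proj(model_m, layers.annual, model_id="maxent_monthly")
    out.write_grid("maps/present_annual_yearly.asc", map_annual_y.grid)
    out.write_grid("maps/present_annual_monthly.asc", map_annual_m.grid)
    monthly_maps = []
    for stack in layers.monthly:
        m = proj(model_m, stack, model_id="maxent_monthly")
        monthly_maps.append(m)
        out.write_grid(f"maps/present_{stack.time_tag}.asc", m.grid)
    counts["present_maps"] = 2 + len(monthly_maps)

    # --- consensus -------------------------------------------------------
    consensus_maps = [map_annual_y, map_annual_m]
    consensus_maps += [proj(em, layers.annual, model_id=name) for name, em in env_models]
    cons = _stage("consensus")(projection.consensus)(
        consensus_maps, t=config["project"]["consensus_threshold"]
    )
    out.write_grid("maps/consensus_annual.asc", cons.grid)
    counts["consensus_models"] = cons.n_models

    # --- future ensemble -------------------------------------------------
    ens = config["ensemble"]
    futures = _stage("future")(synthetic.make_future)(
        layers.monthly,
        delta_sst=ens["delta_sst"],
        nitrate_scale=ens["nitrate_scale"],
        n_gcms=ens["n_gcms"],
        seed=seed + SEED_FUTURE,
        perturb=ens["perturb"],
        scenario=ens["scenario"],
    )
    n_ens = 0
    for month in ens["months"]:
        members = [gcm_stacks[month - 1] for gcm_stacks in futures]
        emap = _stage("ensemble")(projection.ensemble)(model_m, members)
        tag = f"{ens['scenario']}_{grids.month_tag(month)}"
        out.write_grid(f"maps/ensemble_{tag}_mean.asc", emap.mean)
        out.write_grid(f"maps/ensemble_{tag}_sd.asc", emap.sd)
        n_ens += 1
    counts["ensemble_maps"] = n_ens

    # --- evaluate --------------------------------------------------------
    ev = config["evaluate"]
    for label, model, pres, bg in (
        ("yearly", model_y, pres_y, bg_y),
        ("monthly", model_m, pres_m, bg_m),
    ):
        report = _stage("evaluate")(projection.evaluate)(
            model, pres, bg,
            cv_folds=ev["cv"] or None,
            seed=seed + SEED_CV,
            jackknife=ev["jackknife"],
            n_curve_points=ev["curve_points"],
            max_iter=fitcfg["max_iter"],
        )
        out.write_text(f"evaluation_{label}.json", report.to_json())

    # --- manifest --------------------------------------------------------
    config_text = json.dumps(config.data, sort_keys=True)
    manifest = {
        "config": config.data,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": seed,
        "stage_seeds": {
            "sampling": seed + SEED_SAMPLING,
            "background": seed + SEED_BACKGROUND,
            "cv": seed + SEED_CV,
            "future": seed + SEED_FUTURE,
        },
        "counts": counts,
        "files": {},
    }
    for rel in sorted(set(out.files)):
        manifest["files"][rel] = _sha256(os.path.join(out.root, rel))
    with open(os.path.join(out.root, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest
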