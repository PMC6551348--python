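"""End-to-end reproducible runs: simulate -> fit/predict -> NPM ->
overlap + GLM -> extremes -> associations, with a manifest.

One global seed is expanded into per-stage substreams
(``numpy.random.SeedSequence`` children), so any stage can be rerun in
isolation with the seed recorded in the manifest; identical configuration
yields bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ndio
from .associations import associate, confound_checks
from .config import RunConfig
from .deviations import npm_from_predictions
from .extremes import (fit_gumbel, score_subjects, scores_frame,
                       topk_membership_test)
from .group import glm_case_control, overlap_map
from .normative import evaluate_fit, run_normative
from .simulate import simulate_cohort

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "folds", "fit")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage substream seeds (< 2**31) from one seed."""
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES))
    return {name: int(s % (2 ** 31)) for name, s in zip(_STAGES, state)}


def build_covariates(cohort: pd.DataFrame, covariates=("age", "sex")
                     ) -> np.ndarray:
    """Assemble the numeric covariate matrix in the declared column order.

    ``sex`` becomes a male=1 dummy; ``site`` expands to site dummies
    (first level dropped); ``iq`` is mean-imputed with a missingness
    indicator appended; ``quality_surrogate`` passes through.
    """
    cols = []
    for cov in covariates:
        if cov == "age":
            cols.append(cohort["age"].to_numpy(float))
        elif cov == "sex":
            cols.append((cohort["sex"] == "male").to_numpy(float))
        elif cov == "iq":
            iq = cohort["iq"].to_numpy(float)
            missing = ~np.isfinite(iq)
            filled = np.where(missing, np.nanmean(iq), iq)
            cols.append(filled)
            cols.append(missing.astype(float))
        elif cov == "site":
            sites = sorted(cohort["site"].astype(str).unique())
            for s in sites[1:]:
                cols.append((cohort["site"].astype(str) == s)
                            .to_numpy(float))
        elif cov == "quality_surrogate":
            cols.append(cohort["quality_surrogate"].to_numpy(float))
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return np.column_stack(cols)


def run(config: RunConfig, out_dir=None) -> dict:
    """Execute the full pipeline; optionally write all artifacts to
    ``out_dir``. Returns an in-memory results dictionary."""
    config.validate()
    seeds = stage_seeds(config.seed)
    meta_base = {"seed": config.seed, "config": config.digest()}
    timers: dict[str, float] = {}
    results: dict = {"config": config, "seeds": seeds}
    current = {"stage": "init"}

    def _stage(name):
        logger.info("stage %s ...", name)
        current["stage"] = name
        timers[name] = time.perf_counter()

    def _done(name):
        timers[name] = round(time.perf_counter() - timers[name], 3)
        logger.info("stage %s done in %.1fs", name, timers[name])

    try:
        _stage("simulate")
        sim_cfg = dataclasses.replace(config.simulation,
                                      seed=seeds["simulate"])
        cohort, matrix, parcellation, truth = simulate_cohort(sim_cfg)
        results.update(cohort=cohort, matrix=matrix,
                       parcellation=parcellation, truth=truth)
        _done("simulate")

        _stage("normative")
        td = (cohort["group"] == "TD").to_numpy()
        asd = ~td
        X = build_covariates(cohort, config.covariates)
        td_pred, asd_pred, full_model = run_normative(
            X[td], matrix.values[td], asd_X=X[asd] if asd.any() else None,
            folds=config.folds, n_restarts=config.n_restarts,
            seed=seeds["fit"])
        results.update(td_pred=td_pred, asd_pred=asd_pred,
                       model=full_model)
        _done("normative")

        _stage("evaluate")
        fit_eval = evaluate_fit(td_pred, matrix.values[td], q=config.q_fit)
        results["fit_evaluation"] = fit_eval
        _done("evaluate")

        _stage("npm")
        npm_td = npm_from_predictions(matrix.values[td], td_pred,
                                      q=config.q_npm)
        results["npm_td"] = npm_td
        Z = np.zeros_like(matrix.values)
        mask = np.zeros(matrix.values.shape, dtype=np.int8)
        Z[td] = npm_td.Z
        mask[td] = npm_td.signed_mask
        if asd_pred is not None:
            npm_asd = npm_from_predictions(matrix.values[asd], asd_pred,
                                           q=config.q_npm)
            results["npm_asd"] = npm_asd
            Z[asd] = npm_asd.Z
            mask[asd] = npm_asd.signed_mask
        results["Z"] = Z
        results["mask"] = mask
        _done("npm")

        _stage("group")
        overlap = overlap_map(mask, cohort["group"].to_numpy(),
                              cohort["schedule"].to_numpy())
        glm = glm_case_control(
            matrix.values, asd.astype(float), cohort["age"].to_numpy(float),
            sex=(cohort["sex"] == "male").to_numpy(float),
            age_powers=config.glm_age_powers, q=config.q_glm)
        results.update(overlap=overlap, glm=glm)
        _done("group")

        _stage("extremes")
        scores = score_subjects(Z, parcellation,
                                fraction=config.extreme_fraction,
                                subject_ids=cohort["subject_id"].to_numpy())
        gumbel = {}
        for label, sel in (("TD", td), ("ASD", asd)):
            if sel.sum() >= 10 and np.std(scores.global_scores[sel]) > 0:
                gumbel[label] = fit_gumbel(scores.global_scores[sel])
        topk = topk_membership_test(
            scores.global_scores, cohort["group"].to_numpy(),
            k=min(config.top_k, len(cohort)), null=config.topk_null)
        results.update(scores=scores, gumbel=gumbel, topk=topk)
        _done("extremes")

        _stage("associate")
        assoc = associate(scores, cohort, q=config.q_assoc)
        confounds = confound_checks(scores, cohort)
        results.update(associations=assoc, confounds=confounds)
        _done("associate")
    except Exception as exc:
        record = {"stage": current["stage"], "error": type(exc).__name__,
                  "message": str(exc)}
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "error.json").write_text(json.dumps(record, indent=2))
        raise RuntimeError(f"pipeline failed at stage "
                           f"{record['stage']}: {exc}") from exc

    if out_dir is not None:
        _write_outputs(results, config, Path(out_dir), meta_base, timers)
    results["timers"] = timers
    return results


def _write_outputs(results: dict, config: RunConfig, out: Path,
                   meta: dict, timers: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cohort = results["cohort"]
    matrix = results["matrix"]
    ndio.write_cohort(cohort, out / "cohort.tsv", {**meta, "stage": "simulate"})
    ndio.write_measure_matrix(matrix, out / "thickness.tsv",
                              {**meta, "stage": "simulate"})
    ndio.write_parcellation(results["parcellation"], out / "parcellation.tsv",
                            {**meta, "stage": "simulate"})
    truth = results["truth"]
    ndio.write_matrix(truth.deviation_mask, out / "truth_mask.tsv",
                      matrix.vertex_ids, {**meta, "stage": "simulate"},
                      float_fmt="%d")
    td = (cohort["group"] == "TD").to_numpy()
    pred_rows = np.empty(len(cohort), dtype=object)
    pred_rows[td] = results["td_pred"].provenance
    if results["asd_pred"] is not None:
        pred_rows[~td] = results["asd_pred"].provenance
    yhat = np.zeros_like(matrix.values)
    yhat[td] = results["td_pred"].yhat
    if results["asd_pred"] is not None:
        yhat[~td] = results["asd_pred"].yhat
    ndio.write_matrix(yhat, out / "predicted.tsv", matrix.vertex_ids,
                      {**meta, "stage": "normative"})
    ndio.write_table(pd.DataFrame({
        "subject_id": cohort["subject_id"], "provenance": pred_rows}),
        out / "provenance.tsv", {**meta, "stage": "normative"})
    ndio.write_table(results["fit_evaluation"], out / "fit_evaluation.tsv",
                     {**meta, "stage": "evaluate"})
    ndio.write_matrix(results["Z"], out / "z.tsv", matrix.vertex_ids,
                      {**meta, "stage": "npm"})
    ndio.write_matrix(results["mask"], out / "npm_mask.tsv",
                      matrix.vertex_ids, {**meta, "stage": "npm"},
                      float_fmt="%d")
    ndio.write_table(results["overlap"].to_frame(), out / "overlap.tsv",
                     {**meta, "stage": "group"})
    ndio.write_table(results["glm"], out / "glm.tsv",
                     {**meta, "stage": "group"})
    ndio.write_table(scores_frame(results["scores"], cohort),
                     out / "extreme_scores.tsv",
                     {**meta, "stage": "extremes"})
    ndio.write_table(results["associations"], out / "associations.tsv",
                     {**meta, "stage": "associate"})
    ndio.write_table(results["confounds"], out / "confounds.tsv",
                     {**meta, "stage": "associate"})

    manifest = {
        "seed": config.seed,
        "stage_seeds": results["seeds"],
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "n_subjects": int(len(cohort)),
        "n_td": int(td.sum()),
        "n_asd": int((~td).sum()),
        "n_vertices": int(matrix.n_vertices),
        "n_failed_vertices": int(results["td_pred"].failed_vertices.size),
        "glm_significant_vertices": int(results["glm"]["significant"].sum()),
        "topk": {"k": results["topk"].k,
                 "n_cases_in_top": results["topk"].n_cases_in_top,
                 "p_value": results["topk"].p_value,
                 "null": results["topk"].null},
        "gumbel": {k: dataclasses.asdict(v)
                   for k, v in results["gumbel"].items()},
        "overlap_proportions": {
            f"{c}/{s}/{sign}": p
            for (c, s, sign), p in results["overlap"].proportions.items()},
        # stage timings go to the log, not the manifest, so identical
        # configurations produce byte-identical manifests
        "stages": list(timers),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
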