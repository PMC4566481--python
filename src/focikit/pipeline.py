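"""End-to-end orchestration of the analysis workflow.

``run_pipeline`` executes: generate (or load) a dataset suite, fit the
requested model variants, rank them, and optionally run the resampling
selection, cross-validation, likelihood profiles, Latin-hypercube
robustness and the ERR risk prediction.  Every artifact lands in the
output directory together with a provenance manifest (config hash, master
seed, package version).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .config import RunConfig
from .data import (default_design, default_ground_truth, generate_suite,
                   read_dataset, write_dataset)
from .fitting import FitProblem, fit_ensemble, study_bounds
from .optimize import OptimizerConfig
from .selection import build_selection_table, mc_model_selection
from .validation import (classify_identifiability, cross_validate,
                         lhs_robustness, profile_likelihood)
from .risk import err_band, err_predict
from .variants import get_variant

__all__ = ["run_pipeline"]

log = logging.getLogger("focikit")


def _optimizer_config(config: RunConfig) -> OptimizerConfig:
    opt = dict(config.optimizer)
    opt.setdefault("budget_scale", config.budget_scale)
    return OptimizerConfig(**opt)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns a dict of artifact paths.

    A stage failure aborts the run with the stage name; artifacts written
    before the failure are left in place.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "setup"
    try:
        manifest = {
            "config": config.to_dict(), "config_hash": config.hash,
            "seed": config.seed, "focikit_version": __version__,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        artifacts["manifest"] = str(outdir / "manifest.json")

        stage = "data"
        if config.dataset_path:
            log.info("loading dataset from %s", config.dataset_path)
            suite = read_dataset(config.dataset_path)
        else:
            variant_gt, params_gt = default_ground_truth()
            design = default_design(
                n_cells=int(config.design.get("n_cells", 50)))
            log.info("generating synthetic suite (seed %d)",
                     config.stage_seed("generate"))
            suite = generate_suite(variant_gt, params_gt, design,
                                   seed=config.stage_seed("generate"))
        write_dataset(suite, outdir / "dataset.csv")
        artifacts["dataset"] = str(outdir / "dataset.csv")

        stage = "fit"
        variants = [get_variant(v) for v in config.variants]
        opt_cfg = _optimizer_config(config)

        def variant_bounds(v):
            if config.bounds:
                return dict(config.bounds)
            return study_bounds(v) if config.use_study_bounds else None

        fits = []
        for v in variants:
            res = fit_ensemble(
                suite, [v], opt_cfg, seed=config.stage_seed("fit"),
                bounds=variant_bounds(v),
            )[0]
            fits.append(res)
            if res is not None:
                res.to_json(outdir / f"fit_variant{v.variant_id:02d}.json")
        ok = [f for f in fits if f is not None]
        if not ok:
            raise RuntimeError("every variant fit failed")
        log.info("fitted %d/%d variants", len(ok), len(variants))
        artifacts["fits"] = str(outdir)

        stage = "selection"
        cutoff = float(config.selection.get("cutoff", 0.125))
        table = build_selection_table(ok, cutoff=cutoff)
        table.to_csv(outdir / "selection_table.csv")
        table.to_json(outdir / "selection_table.json")
        artifacts["selection_table"] = str(outdir / "selection_table.csv")
        best = get_variant(table.best_variant_id)
        best_fit = next(f for f in ok
                        if f.variant.variant_id == best.variant_id)
        log.info("best variant: %d", best.variant_id)

        replicates = int(config.selection.get("replicates", 0))
        if replicates:
            stage = "resample-select"
            report = mc_model_selection(
                suite, variants, n_replicates=replicates,
                optimizer_config=opt_cfg,
                seed=config.stage_seed("resample"), cutoff=cutoff,
                bounds=variant_bounds(best),
            )
            report.to_csv(str(outdir / "resampling"))
            report.to_json(outdir / "resampling.json")
            artifacts["resampling"] = str(outdir / "resampling.json")

        if config.crossval.get("enabled"):
            stage = "crossval"
            cv_variant = get_variant(
                int(config.crossval.get("variant_id", best.variant_id)))
            cv = cross_validate(suite, cv_variant, opt_cfg,
                                seed=config.stage_seed("crossval"),
                                bounds=variant_bounds(cv_variant))
            cv.to_json(outdir / "crossval.json")
            artifacts["crossval"] = str(outdir / "crossval.json")

        profile_params = list(config.profile.get("parameters", []))
        profiles = {}
        if profile_params:
            stage = "profile"
            problem = FitProblem(suite, best, bounds=variant_bounds(best))
            for pname in profile_params:
                prof = profile_likelihood(
                    best_fit, problem, pname,
                    n_points=int(config.profile.get("n_points", 41)),
                    span_decades=float(
                        config.profile.get("span_decades", 2.0)),
                    optimizer_config=opt_cfg,
                    seed=config.stage_seed("profile", pname),
                )
                prof.to_csv(outdir / f"profile_{pname}.csv")
                profiles[pname] = prof
                log.info("profile %s: %s", pname,
                         classify_identifiability(prof))
            artifacts["profiles"] = str(outdir)

        if config.robustness.get("enabled"):
            stage = "robustness"
            rob = lhs_robustness(
                best_fit.params, best,
                doses=tuple(config.robustness.get("doses", (2.5, 10, 20))),
                rel_width=float(config.robustness.get("rel_width", 0.2)),
                n_samples=int(config.robustness.get("n_samples", 1000)),
                seed=config.stage_seed("robustness"),
            )
            rob.to_csv(outdir / "robustness.csv")
            rob.tau.to_csv(outdir / "robustness_tau.csv", index=False)
            artifacts["robustness"] = str(outdir / "robustness.csv")

        if config.err.get("enabled"):
            stage = "err"
            doses = list(config.err.get(
                "doses", [0.5 * i for i in range(1, 25)]))
            rule = config.err.get("rule", "cumulative")
            band = None
            if "kTAF" in profiles and "B" in profiles:
                band = err_band(
                    best_fit.params,
                    profiles["kTAF"].confidence_interval(),
                    profiles["B"].confidence_interval(),
                    doses, seed=config.stage_seed("err"), rule=rule,
                    dose_map=best.dose_map,
                )
            pred = err_predict(doses, best_fit.params, rule=rule,
                               dose_map=best.dose_map, band=band)
            pred.to_csv(outdir / "err_prediction.csv")
            artifacts["err"] = str(outdir / "err_prediction.csv")

        return artifacts
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {exc}"
        ) from exc
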