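"""End-to-end orchestration of the stratification analysis.

Stages: (optional) cohort simulation -> normative fit on the reference
group -> deviation maps for all subjects -> spectral clustering of the
clinical group (fixed k or model-order selection) -> leave-one-out
stability -> separability with permutation test and structure
coefficients -> global + regional atypicality indices -> Spearman
associations with block FDR -> clinical-measure cluster classifier ->
cluster demographics profile. Every stage writes its artifacts (TSV/JSON)
to the run directory; a provenance record ties outputs to the config and
input hashes. Reruns with the same config and seed are bit-identical for
all deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (annotate_fdr, cluster_demographics,
                          clinical_cluster_classifier, spearman_associations)
from .clustering import (cosine_affinity, loo_stability, select_model_order,
                         spectral_cluster)
from .config import PipelineConfig, derive_seeds
from .io import AlignedTables, file_hash, read_tables, write_json, write_tsv
from .metrics import regional_atypicality
from .normative import (DeviationMap, compute_deviations,
                        calibration_report, fit_normative)
from .separability import (cv_ova_decision_values,
                           permutation_test_separability,
                           structure_coefficients)
from .simulate import (CLASSIFIER_MEASURES, MEASURE_BLOCKS, generate_cohort,
                       make_parcellation)

logger = logging.getLogger(__name__)

STAGE_NAMES = ["inputs", "normative", "deviations", "clustering",
               "stability", "separability", "atypicality", "associations",
               "clinical_classifier", "demographics"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis graph; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed, len(STAGE_NAMES))
    stage_seed = dict(zip(STAGE_NAMES, seeds))
    provenance: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "input_hashes": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }

    def done(stage: str) -> None:
        provenance["stages"].append(stage)
        logger.info("stage complete: %s", stage)

    stage = "inputs"
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate,
                                      seed=stage_seed["inputs"]
                                      if config.simulate.seed == 0
                                      else config.simulate.seed)
            covariates, features, clinical, truth = generate_cohort(sim)
            parcels = make_parcellation(sim.n_features, sim.n_parcels,
                                        seed=stage_seed["inputs"])
            write_tsv(covariates, out / "covariates.tsv")
            write_tsv(features, out / "features.tsv")
            write_tsv(clinical, out / "clinical.tsv")
            write_tsv(pd.DataFrame({"feature_id":
                                    [c for c in features.columns
                                     if c != "subject_id"],
                                    "parcel": parcels}),
                      out / "parcels.tsv")
            write_tsv(pd.DataFrame({"subject_id": truth.subject_id,
                                    "true_subtype": truth.true_subtype,
                                    "severity": truth.severity}),
                      out / "subtype_truth.tsv")
            write_json({"pattern_matrix": truth.pattern_matrix},
                       out / "pattern_matrix.json")
            tables = AlignedTables(covariates=covariates, features=features,
                                   clinical=clinical, parcels=parcels)
        else:
            if config.covariates_path is None or config.features_path is None:
                raise FileNotFoundError(
                    "covariates_path and features_path are required when "
                    "the simulate stage is disabled")
            tables = read_tables(config.covariates_path, config.features_path,
                                 config.clinical_path, config.parcels_path)
            for key in ("covariates_path", "features_path", "clinical_path",
                        "parcels_path"):
                p = getattr(config, key)
                if p is not None:
                    provenance["input_hashes"][key] = file_hash(p)
            if tables.parcels is None:
                n_feat = tables.features.shape[1] - 1
                tables.parcels = make_parcellation(
                    n_feat, max(1, n_feat // 10), seed=stage_seed["inputs"])
        done(stage)

        covariates, features = tables.covariates, tables.features
        group = covariates["group"].to_numpy()
        clinical_mask = group == "clinical"

        stage = "normative"
        model = fit_normative(covariates, features, config.kernel)
        model.to_json(out / "normative_model.json")
        done(stage)

        stage = "deviations"
        deviations = compute_deviations(model, covariates, features)
        write_tsv(deviations.to_frame(), out / "deviations.tsv")
        calib = calibration_report(deviations, mask=~clinical_mask)
        write_tsv(calib, out / "calibration_reference.tsv")
        done(stage)

        z_clin = deviations.z[clinical_mask]
        clin_ids = deviations.subject_id[clinical_mask]

        stage = "clustering"
        model_order = None
        if config.k is None or config.run_model_order:
            model_order = select_model_order(
                z_clin, range(config.k_min, config.k_max + 1), config.cv,
                seed=stage_seed["clustering"], subject_id=clin_ids)
            write_json(model_order.to_dict(), out / "model_order.json")
        k = config.k if config.k is not None else model_order.selected_k
        solution = spectral_cluster(cosine_affinity(z_clin, clin_ids), k,
                                    seed=stage_seed["clustering"])
        write_tsv(pd.DataFrame({"subject_id": clin_ids,
                                "cluster": solution.labels}),
                  out / "clusters.tsv")
        done(stage)

        stage = "stability"
        if config.run_stability:
            stab = loo_stability(z_clin, k, seed=stage_seed["stability"])
            write_json({"mean_ari": stab["mean_ari"],
                        "sd_ari": stab["sd_ari"],
                        "n_failed_runs": stab["n_failed_runs"],
                        "assignment_consistency":
                            stab["assignment_consistency"]},
                       out / "stability.json")
        done(stage)

        stage = "separability"
        report = permutation_test_separability(
            z_clin, solution.labels, config.cv,
            n_permutations=config.n_permutations,
            seed=stage_seed["separability"])
        write_json(report.to_dict(), out / "separability.json")
        dv = cv_ova_decision_values(z_clin, solution.labels, config.cv,
                                    seed=stage_seed["separability"])
        coeffs = structure_coefficients(z_clin, dv)
        coeff_df = pd.DataFrame(
            coeffs.values.T,
            columns=[f"cluster_{c}" for c in coeffs.classes])
        coeff_df.insert(0, "feature_id", deviations.feature_ids)
        write_tsv(coeff_df, out / "structure_coefficients.tsv")
        done(stage)

        stage = "atypicality"
        clin_dev = DeviationMap(
            subject_id=clin_ids, feature_ids=deviations.feature_ids,
            z=z_clin, predictive_mean=deviations.predictive_mean[
                clinical_mask],
            predictive_sd=deviations.predictive_sd[clinical_mask])
        indices = regional_atypicality(clin_dev, tables.parcels,
                                       config.atypicality_fraction)
        write_tsv(indices, out / "atypicality.tsv")
        done(stage)

        stage = "associations"
        if config.run_associations and tables.clinical is not None:
            clin_tab = (tables.clinical.set_index("subject_id")
                        .loc[clin_ids].reset_index())
            assoc_g = spearman_associations(indices, clin_tab,
                                            solution.labels,
                                            blocks=MEASURE_BLOCKS,
                                            scope="global")
            assoc_r = spearman_associations(indices, clin_tab,
                                            solution.labels,
                                            blocks=MEASURE_BLOCKS,
                                            scope="regional")
            assoc = pd.concat([assoc_g,
                               assoc_r[assoc_r["region"] != "global"]],
                              ignore_index=True)
            assoc = annotate_fdr(assoc, q_level=config.q_level)
            write_tsv(assoc, out / "associations.tsv")
        done(stage)

        stage = "clinical_classifier"
        if config.run_clinical_classifier and tables.clinical is not None:
            clin_tab = (tables.clinical.set_index("subject_id")
                        .loc[clin_ids].reset_index())
            try:
                clf_report, info = clinical_cluster_classifier(
                    clin_tab, solution.labels, CLASSIFIER_MEASURES,
                    config.cv, seed=stage_seed["clinical_classifier"],
                    impute=config.impute,
                    n_permutations=config.n_permutations)
                payload = clf_report.to_dict()
                payload.update(info)
                write_json(payload, out / "clinical_classifier.json")
            except ValueError as exc:
                # e.g. a cluster too small for the fold count after deletion
                write_json({"skipped": str(exc)},
                           out / "clinical_classifier.json")
                logger.warning("clinical classifier skipped: %s", exc)
        done(stage)

        stage = "demographics"
        if config.run_demographics and tables.clinical is not None:
            clin_tab = (tables.clinical.set_index("subject_id")
                        .loc[clin_ids].reset_index())
            cov_clin = (covariates[clinical_mask]
                        .reset_index(drop=True))
            profile = cluster_demographics(cov_clin, clin_tab,
                                           solution.labels)
            write_tsv(profile, out / "demographics.tsv")
        done(stage)
    except Exception as exc:  # persist partial provenance, name the stage
        provenance["failed_stage"] = stage
        provenance["error"] = str(exc)
        write_json(provenance, out / "provenance.json")
        raise PipelineError(stage, exc) from exc

    write_json(provenance, out / "provenance.json")
    return out
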