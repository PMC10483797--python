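"""End-to-end orchestration: simulate/load -> normalize -> QC -> SNR -> DEP.

``run_full_qc`` turns a quantification matrix plus run metadata into a
QCReport whose every number is reproducible from (inputs, config, seed); the
provenance block records the configuration hash, seed and package version.
``run_benchmark_suite`` sweeps simulated scenarios (injection modes, noise,
degradation) and scores each against the planted truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .absolute_quant import CalibrationModel, fit_anchor_calibration
from .differential import (dep_reproducibility, detect_deps,
                           score_against_truth)
from .errors import DegenerateReplicatesError, ProteoQCError
from .matrix_io import QuantMatrix, RunMetadata, read_metadata, \
    read_quant_matrix, validate_pairing
from .normalization import assign_intensity_groups, ibaq_to_fot
from .qc_metrics import (FourDimSummary, StabilityResult, four_dim_summary,
                         occurrence_bins, stability_series)
from .snr import snr_by_intensity_group, snr_for_experiment
from .synthetic_data import SimulationConfig, simulate_experiment, with_seed

logger = logging.getLogger("proteoqc")


@dataclass
class QCReport:
    four_dim: pd.DataFrame
    snr: pd.DataFrame
    dep_frequency: pd.DataFrame
    occurrence: pd.DataFrame
    stability: StabilityResult | None
    calibration: CalibrationModel | None
    provenance: dict

    def tables(self) -> dict:
        out = {"four_dim": self.four_dim, "snr": self.snr,
               "dep_frequency": self.dep_frequency,
               "occurrence": self.occurrence}
        if self.stability is not None:
            out["stability"] = self.stability.reproducibility
        if self.calibration is not None:
            out["calibration"] = pd.DataFrame(
                [dataclasses.asdict(self.calibration)])
        return out

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t")
        with open(os.path.join(outdir, "provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)


def _provenance(config: dict, seed: int) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str)
    return {"config": config,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": seed, "tool_version": __version__}


def run_full_qc(matrix, metadata, *, fc_threshold: float = 2.0,
                seed: int = 0, anchors: pd.DataFrame | None = None,
                cells_per_sample: float = 1.0,
                reference_month: int = 1,
                per_intensity_snr: bool = False) -> QCReport:
    """Run the full QC battery over all experiments of a dataset.

    ``matrix``/``metadata`` may be objects or file paths. An iBAQ matrix is
    FOT-normalized first. ``anchors`` (optional) is a DataFrame with columns
    ``abq`` and ``ibaq`` for absolute-quantification calibration. Raises on
    the first validation failure; no partial outputs are produced.
    """
    if not isinstance(matrix, QuantMatrix):
        matrix = read_quant_matrix(matrix)
    if not isinstance(metadata, RunMetadata):
        metadata = read_metadata(metadata)
    validate_pairing(matrix, metadata)
    if matrix.unit_tag == "iBAQ":
        logger.info("normalizing iBAQ -> FOT (%d proteins, %d runs)",
                    matrix.n_proteins, matrix.n_runs)
        matrix = ibaq_to_fot(matrix)

    experiments = metadata.experiments()
    four_rows, snr_rows, all_records = [], [], []
    for exp in experiments:
        logger.info("experiment %s: four-dim summary, SNR, DEP detection", exp)
        fd = four_dim_summary(matrix, metadata, exp)
        four_rows.append(dataclasses.asdict(fd))
        row = {"experiment_id": exp}
        try:
            res = snr_for_experiment(matrix, metadata, exp)
            row.update(snr_db=res.snr_db, category=res.category,
                       signal=res.signal, noise=res.noise)
        except DegenerateReplicatesError:
            row.update(snr_db=float("inf"), category="degenerate",
                       signal=float("nan"), noise=0.0)
        if per_intensity_snr:
            for name, res_g in snr_by_intensity_group(matrix, metadata, exp).items():
                row[f"snr_db_{name}"] = res_g.snr_db
        snr_rows.append(row)
        all_records.extend(detect_deps(matrix, metadata, exp,
                                       fc_threshold=fc_threshold))

    dep_freq = dep_reproducibility(all_records, len(experiments))
    occurrence = occurrence_bins(matrix)

    stability = None
    if len(metadata.months()) > 1:
        stability = stability_series(matrix, metadata, reference_month)

    calibration = None
    if anchors is not None:
        calibration = fit_anchor_calibration(anchors["abq"], anchors["ibaq"],
                                             cells_per_sample)

    config = {"fc_threshold": fc_threshold,
              "reference_month": reference_month,
              "cells_per_sample": cells_per_sample,
              "n_experiments": len(experiments),
              "n_proteins": matrix.n_proteins, "n_runs": matrix.n_runs}
    return QCReport(four_dim=pd.DataFrame(four_rows),
                    snr=pd.DataFrame(snr_rows),
                    dep_frequency=dep_freq, occurrence=occurrence,
                    stability=stability, calibration=calibration,
                    provenance=_provenance(config, seed))


def run_benchmark_suite(base_config: SimulationConfig | None = None,
                        scenarios: list | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Score simulated scenarios: SNR, median CV, DEP recall/precision.

    Each scenario is a dict of SimulationConfig field overrides plus a
    ``name``. Failed scenarios report their error and the suite continues.
    """
    from .qc_metrics import median_cv_by_group
    if base_config is None:
        base_config = SimulationConfig(n_proteins=800, seed=seed)
    if scenarios is None:
        scenarios = [
            {"name": "RI_drift", "injection_mode": "RI",
             "drift_per_injection": 1.06},
            {"name": "CI1_drift", "injection_mode": "CI1",
             "drift_per_injection": 1.06},
            {"name": "CI2_drift", "injection_mode": "CI2",
             "drift_per_injection": 1.06},
            {"name": "no_drift", "injection_mode": "RI",
             "drift_per_injection": 1.0},
        ]
    rows = []
    for sc in scenarios:
        sc = dict(sc)
        name = sc.pop("name")
        row = {"scenario": name, "seed": seed}
        try:
            cfg = dataclasses.replace(with_seed(base_config, seed), **sc)
            mat, meta, truth = simulate_experiment(cfg)
            fot = ibaq_to_fot(mat)
            try:
                res = snr_for_experiment(fot, meta)
                row.update(snr_db=res.snr_db, snr_category=res.category)
            except DegenerateReplicatesError:
                row.update(snr_db=float("inf"), snr_category="degenerate")
            assignment = assign_intensity_groups(fot, meta)
            med = median_cv_by_group(fot, meta, assignment)
            row["median_cv"] = med["global"]
            records = detect_deps(fot, meta, fc_threshold=cfg.fc_threshold)
            exclude = [p for ids in truth.specific_proteins.values() for p in ids]
            scores = score_against_truth(records, truth.dep_flags,
                                         truth.protein_ids, exclude)
            row.update(dep_recall=scores["recall"],
                       dep_precision=scores["precision"],
                       null_false_call_rate=scores["null_false_call_rate"])
        except ProteoQCError as exc:  # scenario-level failure, suite continues
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
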