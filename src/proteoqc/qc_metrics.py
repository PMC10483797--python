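"""Reproducibility, variability, stability and flow statistics for QC.

"Present" throughout this module means non-missing AND not the 1e-5
sentinel: sentinel-filled entries count as absent for every
identification-based metric (identification frequency, occurrence bins,
overlap, stability), while quantitative comparisons (Pearson correlation)
may include them to compare global profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .matrix_io import QuantMatrix, RunMetadata
from .normalization import assign_intensity_groups
from .util import SENTINEL, present_mask

OCCURRENCE_BIN_LABELS = tuple(
    f"[{10 * i},{10 * (i + 1)}%)" for i in range(10)) + ("100%",)


def protein_cv(values) -> float:
    """Coefficient of variation in percent: 100 * sd / mean (sample SD).

    Returns NaN when fewer than two present values are supplied; callers
    skip (rather than fail on) such proteins.
    """
    vals = np.asarray([v for v in np.ravel(values) if np.isfinite(v)], dtype=float)
    if vals.size < 2:
        return float("nan")
    return float(100.0 * vals.std(ddof=1) / vals.mean())


def cv_per_protein(matrix: QuantMatrix, metadata: RunMetadata,
                   experiment_id: str | None = None) -> pd.DataFrame:
    """Per-protein, per-group CV over present replicate values.

    Returns a proteins x groups DataFrame; NaN where fewer than two present
    replicate measurements exist.
    """
    groups = metadata.groups(experiment_id)
    out = {}
    for g in groups:
        runs = metadata.runs_for(experiment_id, group=g)
        vals = matrix.values.loc[:, runs]
        present = vals.where(present_mask(vals))
        enough = present.notna().sum(axis=1) >= 2
        cv = 100.0 * present.std(axis=1, ddof=1) / present.mean(axis=1)
        out[g] = cv.where(enough)
    return pd.DataFrame(out)


def median_cv_by_group(matrix: QuantMatrix, metadata: RunMetadata,
                       assignment: pd.DataFrame,
                       experiment_id: str | None = None) -> pd.Series:
    """Median per-protein CV (percent) within each intensity group and globally.

    Each (protein, sample-group) CV with >= 2 present replicates is one
    observation; observations are pooled by the protein's intensity group.
    """
    cvs = cv_per_protein(matrix, metadata, experiment_id)
    long = cvs.stack().rename("cv").reset_index()
    long.columns = ["protein_id", "group_label", "cv"]
    long["intensity"] = long["protein_id"].map(assignment["group"])
    result = {}
    for name in ("low", "medium", "high"):
        sub = long.loc[long["intensity"] == name, "cv"]
        if sub.empty:
            warnings.warn(f"intensity group {name!r} has no CV observations")
            result[name] = float("nan")
        else:
            result[name] = float(sub.median())
    result["global"] = float(long["cv"].median()) if len(long) else float("nan")
    return pd.Series(result)


def identification_frequency(matrix: QuantMatrix, runs) -> pd.Series:
    """Number of the given runs in which each protein is present (IDF).

    Proteins absent from all of the runs are excluded.
    """
    runs = list(runs)
    if not runs:
        raise ValidationError("identification_frequency needs >= 1 run")
    mask = present_mask(matrix.values.loc[:, runs])
    idf = mask.sum(axis=1)
    return idf[idf > 0].astype(int)


def occurrence_bins(matrix: QuantMatrix) -> pd.DataFrame:
    """Occurrence frequency over all runs, binned into 11 confidence groups.

    Frequency = presence count / total runs. Bins are the ten decade-wide
    intervals [0,10%), ..., [90,100%) plus a distinct bin for proteins
    present in every run (100%). Proteins never observed are excluded.
    """
    total = matrix.n_runs
    if total < 1:
        raise ValidationError("occurrence_bins needs >= 1 run")
    count = present_mask(matrix.values).sum(axis=1)
    count = count[count > 0]
    freq = count / total
    idx = np.minimum((freq * 10).astype(int), 9)
    labels = np.where(freq == 1.0, OCCURRENCE_BIN_LABELS[10],
                      np.asarray(OCCURRENCE_BIN_LABELS)[idx])
    out = pd.DataFrame({"occurrence_frequency": freq, "bin": labels})
    out.index.name = "protein_id"
    return out


def pairwise_correlation(matrix: QuantMatrix, runs: list | None = None, *,
                         union: bool = True) -> pd.DataFrame:
    """Pearson correlation matrix between runs on log10 sentinel-filled values.

    For each pair, the proteins considered are those present in at least one
    of the two runs (``union=True``, the default, which compares global
    profiles including dropout structure) or present in both
    (``union=False``). Constant columns yield NaN with a warning.
    """
    if runs is None:
        runs = matrix.run_ids
    runs = list(runs)
    if len(runs) < 2:
        raise InsufficientDataError("pairwise correlation needs >= 2 runs")
    vals = matrix.values.loc[:, runs]
    present = present_mask(vals)
    logged = np.log10(vals.fillna(SENTINEL).clip(lower=SENTINEL))
    r = pd.DataFrame(np.eye(len(runs)), index=runs, columns=runs)
    for a, b in combinations(runs, 2):
        sel = (present[a] | present[b]) if union else (present[a] & present[b])
        x, y = logged.loc[sel, a], logged.loc[sel, b]
        if sel.sum() < 2 or x.std() == 0 or y.std() == 0:
            warnings.warn(f"correlation undefined for runs {a!r}/{b!r}")
            rv = float("nan")
        else:
            rv = float(np.corrcoef(x, y)[0, 1])
        r.loc[a, b] = r.loc[b, a] = rv
    return r


@dataclass
class OverlapResult:
    intersection: int
    union: int
    specific: dict
    fraction_of_reference: dict
    reference: str


def overlap_sets(sets: dict, reference: str) -> OverlapResult:
    """Set algebra over protein sets per condition, relative to a reference.

    ``fraction_of_reference[name]`` is |name ∩ reference| / |reference| as a
    percentage; ``specific[name]`` counts proteins found only in that set.
    """
    if len(sets) < 2:
        raise ValidationError("overlap_sets needs >= 2 sets")
    if reference not in sets:
        raise ValidationError(f"reference {reference!r} not among sets")
    ref = set(sets[reference])
    if not ref:
        raise ValidationError("reference set is empty")
    all_sets = {k: set(v) for k, v in sets.items()}
    inter = set.intersection(*all_sets.values())
    union = set.union(*all_sets.values())
    specific = {k: len(s - set.union(*(o for n, o in all_sets.items() if n != k)))
                for k, s in all_sets.items()}
    frac = {k: 100.0 * len(s & ref) / len(ref) for k, s in all_sets.items()}
    return OverlapResult(intersection=len(inter), union=len(union),
                         specific=specific, fraction_of_reference=frac,
                         reference=reference)


def intensity_flow(assignment_a: pd.DataFrame,
                   assignment_b: pd.DataFrame) -> pd.DataFrame:
    """Transition percentages of intensity groups between two experiments.

    Rows: source intensity group in A; columns: destination group in B plus
    ``not_detected`` for proteins absent from B's assignment. Each row sums
    to 100 (NaN row when the source group is empty). This is the tabular
    input of a Sankey flow diagram.
    """
    cols = ["low", "medium", "high", "not_detected"]
    rows = ["low", "medium", "high"]
    out = pd.DataFrame(np.nan, index=rows, columns=cols)
    dest = assignment_b["group"]
    for src in rows:
        ids = assignment_a.index[assignment_a["group"] == src]
        if len(ids) == 0:
            warnings.warn(f"source intensity group {src!r} is empty")
            continue
        landed = dest.reindex(ids).fillna("not_detected")
        counts = landed.value_counts()
        for c in cols:
            out.loc[src, c] = 100.0 * counts.get(c, 0) / len(ids)
    return out


@dataclass
class StabilityResult:
    """Longitudinal reproducibility relative to a reference month.

    ``reproducibility`` is months x (global, low, medium, high): the
    fraction of reference-month proteins (per intensity group) still
    identified in each month. ``trends`` holds per-protein monthly mean
    abundances for inspection of individual trajectories.
    """

    reproducibility: pd.DataFrame
    trends: pd.DataFrame
    reference_month: int


def stability_series(matrix: QuantMatrix, metadata: RunMetadata,
                     reference_month: int = 1,
                     assignment: pd.DataFrame | None = None) -> StabilityResult:
    """Monthly identification reproducibility against a reference month.

    reproducibility(month) = |identified(month) ∩ identified(ref)| /
    |identified(ref)|, computed globally and within the reference month's
    intensity groups. A protein is identified in a month when present in at
    least one of that month's runs.
    """
    months = metadata.months()
    if len(months) < 2:
        raise InsufficientDataError("stability needs >= 2 months")
    if reference_month not in months:
        raise ValidationError(f"reference month {reference_month} absent")
    ref_runs = metadata.runs_for(month=reference_month)
    if assignment is None:
        assignment = assign_intensity_groups(matrix, runs=ref_runs)
    identified = {}
    trend_cols = {}
    for m in months:
        runs = metadata.runs_for(month=m)
        vals = matrix.values.loc[:, runs]
        mask = present_mask(vals)
        identified[m] = set(vals.index[mask.any(axis=1)])
        trend_cols[m] = vals.where(mask).mean(axis=1)
    ref_set = identified[reference_month]
    group_sets = {"global": ref_set}
    for name in ("low", "medium", "high"):
        ids = set(assignment.index[assignment["group"] == name]) & ref_set
        group_sets[name] = ids
    rows = {}
    for m in months:
        row = {}
        for name, ids in group_sets.items():
            row[name] = (len(identified[m] & ids) / len(ids)) if ids else float("nan")
        rows[m] = row
    repro = pd.DataFrame.from_dict(rows, orient="index")
    repro.index.name = "month"
    trends = pd.DataFrame(trend_cols)
    trends.index.name = "protein_id"
    return StabilityResult(reproducibility=repro, trends=trends,
                           reference_month=reference_month)


@dataclass
class FourDimSummary:
    """The four QC dimensions of one experiment: identification depth,
    replicate reproducibility, replicate correlation, and quantitative CV."""

    experiment_id: str
    n_proteins_identified: float
    reproducibility: float
    mean_pearson_r: float
    median_cv: float


def four_dim_summary(matrix: QuantMatrix, metadata: RunMetadata,
                     experiment_id: str | None = None) -> FourDimSummary:
    """Summarize an experiment on the four QC dimensions.

    - n_proteins_identified: mean number of present proteins per run;
    - reproducibility: fraction of observed proteins identified in all n
      replicates of their sample group (averaged over groups);
    - mean_pearson_r: mean Pearson r between replicate pairs within groups;
    - median_cv: median per-(protein, group) CV in percent.
    """
    runs = metadata.runs_for(experiment_id)
    vals = matrix.values.loc[:, runs]
    mask = present_mask(vals)
    n_ident = float(mask.sum(axis=0).mean())
    groups = metadata.groups(experiment_id)
    repro_parts, r_values = [], []
    for g in groups:
        gruns = metadata.runs_for(experiment_id, group=g)
        idf = identification_frequency(matrix, gruns)
        if len(idf):
            repro_parts.append(float((idf == len(gruns)).mean()))
        if len(gruns) >= 2:
            r = pairwise_correlation(matrix, gruns)
            tri = r.to_numpy()[np.triu_indices(len(gruns), k=1)]
            r_values.extend(tri.tolist())
    cvs = cv_per_protein(matrix, metadata, experiment_id)
    med_cv = float(cvs.stack().median()) if cvs.stack().size else float("nan")
    return FourDimSummary(
        experiment_id=experiment_id if experiment_id is not None else "all",
        n_proteins_identified=n_ident,
        reproducibility=float(np.mean(repro_parts)) if repro_parts else float("nan"),
        mean_pearson_r=float(np.nanmean(r_values)) if r_values else float("nan"),
        median_cv=med_cv)
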