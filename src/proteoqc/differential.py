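"""Fold-change DEP detection and cross-experiment reproducibility frequency.

A protein is a DEP for an ordered group pair (test, reference) when the
ratio of replicate-mean sentinel-filled FOT values exceeds the threshold
(strictly) in either direction. Across E experiments the occurrence
frequency of each (protein, pair, direction) record is binned into
low/medium/high reproducibility; at E = 24 the bins are 1-9, 10-18, 19-24
(three, three and two eighths of the frequency axis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import ceil

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .matrix_io import QuantMatrix, RunMetadata
from .util import SENTINEL


@dataclass(frozen=True)
class DEPRecord:
    """One differential call: protein, ordered (test, reference) pair,
    direction, and fold change expressed as a magnitude > threshold."""

    protein_id: str
    group_pair: tuple
    direction: str  # "up" or "down"
    fold_change: float
    experiment_id: str


def detect_deps(matrix: QuantMatrix, metadata: RunMetadata,
                experiment_id: str | None = None,
                fc_threshold: float = 2.0,
                pairs: list | None = None) -> list[DEPRecord]:
    """Call DEPs for each group pair of an experiment by mean fold change.

    Fold change = mean FOT(test) / mean FOT(reference) with missing entries
    sentinel-filled at 1e-5, so a protein absent from one group yields a
    large but finite ratio. A record is emitted when the ratio strictly
    exceeds the threshold (up) or is strictly below its reciprocal (down);
    ``fold_change`` stores the magnitude max(ratio, 1/ratio). By default
    pairs are the sorted unordered group combinations, ordered
    (test, reference) = (earlier, later) label.
    """
    if fc_threshold <= 1:
        raise ConfigurationError("fc_threshold must exceed 1")
    groups = metadata.groups(experiment_id)
    if pairs is None:
        pairs = list(combinations(sorted(groups), 2))
    means = {}
    for g in {g for p in pairs for g in p}:
        if g not in groups:
            raise ValidationError(f"unknown group {g!r}")
        runs = metadata.runs_for(experiment_id, group=g)
        means[g] = matrix.values.loc[:, runs].fillna(SENTINEL).mean(axis=1)
    exp_id = experiment_id if experiment_id is not None else "all"
    records = []
    for test, ref in pairs:
        ratio = means[test] / means[ref]
        for pid, fc in ratio.items():
            if fc > fc_threshold:
                records.append(DEPRecord(pid, (test, ref), "up", float(fc), exp_id))
            elif fc < 1.0 / fc_threshold:
                records.append(DEPRecord(pid, (test, ref), "down",
                                         float(1.0 / fc), exp_id))
    return records


def canonical_record_key(protein_id, group_pair, direction) -> tuple:
    """Canonicalize so that up(A vs B) and down(B vs A) compare equal."""
    test, ref = group_pair
    if str(test) > str(ref):
        test, ref = ref, test
        direction = "down" if direction == "up" else "up"
    return (protein_id, (test, ref), direction)


def frequency_bins(n_experiments: int) -> dict:
    """Reproducibility-frequency bin edges for an E-experiment campaign.

    The frequency axis [1, E] is split in the ratio 3:3:2 (low gets the
    first three eighths, medium the next three, high the final two), which
    yields 1-9 / 10-18 / 19-24 at E = 24.
    """
    if n_experiments < 1:
        raise ConfigurationError("need >= 1 experiment")
    lo_hi = max(1, ceil(3 * n_experiments / 8))
    med_hi = max(lo_hi, ceil(6 * n_experiments / 8))
    return {"low": (1, lo_hi),
            "medium": (lo_hi + 1, med_hi),
            "high": (med_hi + 1, n_experiments)}


def dep_reproducibility(records: list[DEPRecord],
                        n_experiments: int) -> pd.DataFrame:
    """Occurrence frequency of each DEP record across experiments, binned.

    Frequency counts the experiments in which the canonicalized
    (protein, pair, direction) record appears; duplicate records within one
    experiment are deduplicated with a warning.
    """
    bins = frequency_bins(n_experiments)

    seen = {}
    dupes = 0
    for rec in records:
        key = canonical_record_key(rec.protein_id, rec.group_pair, rec.direction)
        exps = seen.setdefault(key, set())
        if rec.experiment_id in exps:
            dupes += 1
        exps.add(rec.experiment_id)
    if dupes:
        warnings.warn(f"{dupes} duplicate DEP records within an experiment "
                      "were deduplicated")

    def bin_of(freq: int) -> str:
        for name, (lo, hi) in bins.items():
            if lo <= freq <= hi:
                return name
        raise ValidationError(
            f"frequency {freq} outside [1, {n_experiments}]")

    rows = []
    for (pid, pair, direction), exps in seen.items():
        freq = len(exps)
        rows.append({"protein_id": pid, "group_pair": pair,
                     "direction": direction, "frequency": freq,
                     "bin": bin_of(freq)})
    out = pd.DataFrame(rows, columns=["protein_id", "group_pair", "direction",
                                      "frequency", "bin"])
    return out.sort_values(["protein_id", "group_pair", "direction"],
                           ignore_index=True)


def consistent_trend_deps(frequency_table: pd.DataFrame,
                          n_experiments: int) -> pd.DataFrame:
    """Records reproduced with the same direction in every experiment.

    A protein flagged in both directions for the same pair (in different
    experiments) is never returned.
    """
    full = frequency_table[frequency_table["frequency"] == n_experiments]
    both = (frequency_table.groupby(["protein_id", "group_pair"])["direction"]
            .nunique())
    conflicted = set(both[both > 1].index)
    keep = [i for i in full.index
            if (full.loc[i, "protein_id"], full.loc[i, "group_pair"])
            not in conflicted]
    return full.loc[keep].reset_index(drop=True)


def score_against_truth(records: list[DEPRecord], dep_flags: pd.DataFrame,
                        protein_ids, exclude_proteins=()) -> dict:
    """Recall / precision / null false-call rate against planted truth.

    ``dep_flags`` rows carry protein_id, test_group, ref_group, direction.
    Records for ``exclude_proteins`` (e.g. group-specific proteins, which
    are genuinely differential but not fold-change-planted) are ignored.
    Returns recall and precision over canonical (protein, pair, direction)
    triples and the fraction of non-planted proteins with any record.
    """
    truth = {canonical_record_key(r.protein_id, (r.test_group, r.ref_group),
                                  r.direction)
             for r in dep_flags.itertuples()}
    excluded = set(exclude_proteins)
    detected = {canonical_record_key(r.protein_id, r.group_pair, r.direction)
                for r in records if r.protein_id not in excluded}
    tp = len(truth & detected)
    recall = tp / len(truth) if truth else float("nan")
    precision = tp / len(detected) if detected else float("nan")
    flagged_proteins = {k[0] for k in truth}
    null_proteins = [p for p in protein_ids
                     if p not in flagged_proteins and p not in excluded]
    called = {k[0] for k in detected}
    false_rate = (sum(p in called for p in null_proteins) / len(null_proteins)
                  if null_proteins else float("nan"))
    return {"recall": recall, "precision": precision,
            "null_false_call_rate": false_rate}
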