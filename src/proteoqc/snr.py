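"""PCA-weighted signal-to-noise ratio for replicated multi-group designs.

For a balanced design of m sample groups with n technical replicates each,
runs are embedded in the first two principal components. The *signal* is the
average variance-weighted squared distance between replicates of different
groups; the *noise* is the average over pairs of replicates within a group:

    SNR(dB) = 10 * log10( [ S_inter / (C(m,2) * n^2) ]
                        / [ S_intra / (m * C(n,2)) ] )

where each squared distance is sum_p W_p (PC_p,i - PC_p,j)^2 over the two
retained components and W_p is the fraction of total variance explained by
component p. High SNR means the biological differences between groups
dominate technical variation; scores are binned into ineligible [0,2),
average [2,10), good [10,20) and excellent [20,inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import (DegenerateReplicatesError, DesignError,
                     InsufficientDataError, ValidationError)
from .matrix_io import QuantMatrix, RunMetadata
from .util import SENTINEL

SNR_CATEGORIES = ("ineligible", "average", "good", "excellent")

#: Left-closed category bin edges in dB.
SNR_BIN_EDGES = (2.0, 10.0, 20.0)


def pair_counts(m: int, n: int) -> tuple[int, int]:
    """Number of inter-group and intra-group replicate pairs.

    inter = C(m,2) * n^2 (every replicate of one group against every
    replicate of every other group); intra = m * C(n,2). For the quartet
    design (m=4, n=3) these are 54 and 12.
    """
    if m < 2 or n < 2:
        raise DesignError(
            f"SNR undefined for m={m}, n={n}: need >= 2 groups with >= 2 "
            "replicates each")
    return math.comb(m, 2) * n * n, m * math.comb(n, 2)


@dataclass
class SNREmbedding:
    """Run coordinates on the first two principal components.

    ``weights`` are the variance-explained fractions of the two components
    relative to the full decomposition (they need not sum to 1).
    """

    coordinates: np.ndarray  # (n_runs, 2)
    weights: np.ndarray      # (2,)
    group_labels: np.ndarray
    run_ids: list | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.group_labels = np.asarray(self.group_labels)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValidationError("coordinates must be (n_runs, 2)")
        if self.weights.shape != (2,) or (self.weights < 0).any():
            raise ValidationError("weights must be two non-negative values")
        if not np.isfinite(self.coordinates).all():
            raise ValidationError("coordinates must be finite")
        if len(self.group_labels) != len(self.coordinates):
            raise ValidationError("one group label per run required")


@dataclass
class SNRResult:
    snr_db: float
    signal: float
    noise: float
    m: int
    n: int
    category: str
    weights: np.ndarray = field(default=None, repr=False)


def embed_pca(matrix: QuantMatrix, metadata: RunMetadata,
              experiment_id: str | None = None, runs: list | None = None, *,
              sentinel_fill: bool = True, log_transform: bool = True,
              center: bool = True, scale: bool = True,
              renormalize_weights: bool = False) -> SNREmbedding:
    """Embed runs in the first two principal components.

    Preprocessing (each step switchable): fill missing with the 1e-5
    sentinel, log10-transform, then center and unit-scale each protein
    across runs. Proteins with zero variance across runs are dropped before
    scaling. PCA is computed over runs; weights are variance-explained
    fractions of the full decomposition unless ``renormalize_weights``.
    """
    if runs is None:
        runs = metadata.runs_for(experiment_id)
    if len(runs) < 3:
        raise InsufficientDataError(f"PCA embedding needs >= 3 runs, got {len(runs)}")
    vals = matrix.values.loc[:, list(runs)].to_numpy(dtype=float)
    if sentinel_fill:
        vals = np.where(np.isnan(vals), SENTINEL, vals)
    elif np.isnan(vals).any():
        raise ValidationError("missing values present and sentinel_fill=False")
    if log_transform:
        if (vals <= 0).any():
            raise ValidationError("log transform requires positive values")
        vals = np.log10(vals)
    keep = np.ptp(vals, axis=1) > 0  # ptp, not std: immune to mean rounding
    vals = vals[keep]
    if vals.shape[0] < 2:
        raise ValidationError(
            "fewer than 2 proteins with non-zero variance across runs")
    X = vals.T  # runs x proteins
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    weights = pca.explained_variance_ratio_.copy()
    if renormalize_weights:
        weights = weights / weights.sum()
    meta = metadata.table.set_index("run_id").loc[list(runs)]
    return SNREmbedding(coordinates=coords, weights=weights,
                        group_labels=meta["group_label"].to_numpy(),
                        run_ids=list(runs))


def compute_snr(embedding: SNREmbedding) -> SNRResult:
    """SNR in decibels from an embedding of a balanced replicated design.

    Averages the variance-weighted squared distances over all inter-group
    and intra-group replicate pairs; equals the closed-form prefactor
    m*C(n,2) / (C(m,2)*n*n) applied to the raw pair sums.
    """
    labels = embedding.group_labels
    groups = list(dict.fromkeys(labels))
    m = len(groups)
    sizes = {g: int((labels == g).sum()) for g in groups}
    ns = set(sizes.values())
    if len(ns) != 1:
        raise DesignError(f"unbalanced design: replicate counts {sizes}")
    n = ns.pop()
    inter_pairs, intra_pairs = pair_counts(m, n)
    w = embedding.weights
    coords = {g: embedding.coordinates[labels == g] for g in groups}

    def wsq(a: np.ndarray, b: np.ndarray) -> float:
        d = a[:, None, :] - b[None, :, :]
        return float((w * d * d).sum())

    inter_sum = sum(wsq(coords[gx], coords[gy])
                    for gx, gy in combinations(groups, 2))
    intra_sum = 0.0
    for g in groups:
        c = coords[g]
        # each unordered pair once
        intra_sum += 0.5 * (wsq(c, c))
    signal = inter_sum / inter_pairs
    noise = intra_sum / intra_pairs
    # noise below float-noise level relative to signal is numerically zero
    if noise == 0.0 or noise <= signal * 1e-12:
        raise DegenerateReplicatesError(
            "replicates coincide within every group: noise power is zero "
            "and SNR is infinite")
    if signal == 0.0:
        snr_db = -math.inf
        category = "ineligible"
    else:
        snr_db = 10.0 * math.log10(signal / noise)
        category = classify_snr(snr_db)
    return SNRResult(snr_db=snr_db, signal=signal, noise=noise, m=m, n=n,
                     category=category, weights=w)


def classify_snr(snr_db: float) -> str:
    """Category of an SNR score: left-closed bins [0,2), [2,10), [10,20),
    [20, inf); negative scores are ineligible."""
    if not math.isfinite(snr_db):
        raise ValidationError("SNR category undefined for non-finite score")
    if snr_db < SNR_BIN_EDGES[0]:
        return "ineligible"
    if snr_db < SNR_BIN_EDGES[1]:
        return "average"
    if snr_db < SNR_BIN_EDGES[2]:
        return "good"
    return "excellent"


def derive_snr_threshold(snr_values) -> float:
    """Mean minus sample standard deviation of a collection of SNR scores.

    Used to set a discriminating-power threshold from the empirical SNR
    distribution of a batch of experiments.
    """
    vals = np.asarray(list(snr_values), dtype=float)
    if vals.size < 2:
        raise InsufficientDataError("need >= 2 SNR values for a threshold")
    return float(vals.mean() - vals.std(ddof=1))


def snr_for_experiment(matrix: QuantMatrix, metadata: RunMetadata,
                       experiment_id: str | None = None,
                       **pca_options) -> SNRResult:
    """Convenience: embed an experiment's runs and compute its SNR."""
    emb = embed_pca(matrix, metadata, experiment_id, **pca_options)
    return compute_snr(emb)


def snr_by_intensity_group(matrix: QuantMatrix, metadata: RunMetadata,
                           experiment_id: str | None = None,
                           assignment: pd.DataFrame | None = None) -> dict:
    """SNR computed on the low/medium/high intensity sub-proteomes and globally."""
    from .normalization import assign_intensity_groups
    if assignment is None:
        assignment = assign_intensity_groups(matrix, metadata, experiment_id)
    runs = metadata.runs_for(experiment_id)
    out = {}
    for name in ("low", "medium", "high"):
        ids = assignment.index[assignment["group"] == name]
        sub = QuantMatrix(matrix.values.loc[ids, :], matrix.unit_tag)
        out[name] = compute_snr(embed_pca(sub, metadata, experiment_id, runs=runs))
    out["global"] = compute_snr(embed_pca(matrix, metadata, experiment_id, runs=runs))
    return out
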