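"""Ground-truthed simulator of quartet-style label-free quantification data.

The generator emulates the structure of a four-member family reference
design: m biological groups measured in n technical replicates per
experiment, lognormal base abundances spanning a configurable dynamic range
(~7 orders of magnitude by default), a fraction of group-specific proteins
absent from all other groups, planted fold-change DEPs, intensity-dependent
technical noise (high CV at low abundance), intensity-dependent stochastic
detection mimicking data-dependent acquisition, multiplicative
injection-order drift, and time-dependent degradation of a protein subset.

Every stochastic element is driven by a single integer seed, so identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, ValidationError
from .matrix_io import QuantMatrix, RunMetadata
from .util import lognormal_sigma

QUARTET_GROUPS = ("D5", "D6", "F7", "M8")

INJECTION_MODES = ("RI", "CI1", "CI2")

CV_STRATA = ("low", "medium", "high")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulator; ``seed`` fully determines the output.

    Defaults follow the quartet reference design: 4 groups x 3 technical
    replicates, ~7 decades of dynamic range, ~4% group-specific proteins,
    5% planted DEPs with fold change in [2.3, 8], technical CV rising from
    ~20% (high-intensity tertile) to ~80% (low tertile), and a logistic
    detection curve in log10 abundance.
    """

    n_proteins: int = 2000
    m_groups: int = 4
    n_replicates: int = 3
    dynamic_range_log10: float = 7.0
    abundance_center_log10: float = 2.5
    dep_fraction: float = 0.05
    specific_fraction: float = 0.04
    dep_fc_log2_range: tuple = (1.2, 3.0)
    fc_threshold: float = 2.0
    cv_profile: dict = field(default_factory=lambda: {
        "low": 0.8, "medium": 0.4, "high": 0.2})
    detection_midpoint_log10: float = 1.5
    detection_slope: float = 1.5
    injection_mode: str = "CI1"
    drift_per_injection: float = 1.0
    drift_heterogeneity: float = 0.3
    ri_time_spread: float = 10.0
    months: int = 1
    degradation_fraction: float = 0.0
    degradation_rate: float = 0.5
    degradation_onset_month: int = 12
    twin_similarity: float = 0.0
    group_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ConfigurationError("n_proteins must be >= 2")
        if self.m_groups < 2:
            raise ConfigurationError("m_groups must be >= 2")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        for name in ("dep_fraction", "specific_fraction",
                     "degradation_fraction", "twin_similarity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.dynamic_range_log10 <= 0:
            raise ConfigurationError("dynamic_range_log10 must be positive")
        if self.injection_mode not in INJECTION_MODES:
            raise ConfigurationError(
                f"injection_mode must be one of {INJECTION_MODES}")
        if self.fc_threshold <= 1:
            raise ConfigurationError("fc_threshold must exceed 1")
        if self.dep_fraction > 0 and \
                2.0 ** self.dep_fc_log2_range[0] <= self.fc_threshold:
            raise ConfigurationError(
                "planted fold changes must exceed fc_threshold")
        if set(self.cv_profile) != set(CV_STRATA):
            raise ConfigurationError(f"cv_profile needs keys {CV_STRATA}")
        if any(v < 0 for v in self.cv_profile.values()):
            raise ConfigurationError("CV targets must be non-negative")
        if self.months < 1:
            raise ConfigurationError("months must be >= 1")
        if self.drift_per_injection <= 0:
            raise ConfigurationError("drift_per_injection must be positive")
        if self.drift_heterogeneity < 0:
            raise ConfigurationError("drift_heterogeneity must be >= 0")
        if self.ri_time_spread < 1:
            raise ConfigurationError("ri_time_spread must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth behind a simulated dataset.

    ``base_abundance`` is proteins x groups with NaN where a protein does
    not belong to the group (group-specific absences); ``dep_flags`` lists
    every (protein, test_group, ref_group, direction, true_fc) implied by
    the planted modifications; ``cv_stratum`` maps proteins to the intensity
    stratum that sets their technical CV; ``degraded_proteins`` decay
    exponentially after the onset month.
    """

    protein_ids: list
    groups: list
    base_abundance: pd.DataFrame
    dep_flags: pd.DataFrame
    specific_proteins: dict
    cv_profile: dict
    cv_stratum: pd.Series
    drift_sensitivity: pd.Series
    detection_midpoint: float
    detection_slope: float
    degraded_proteins: tuple
    degradation_rate: float
    degradation_onset_month: int


def detection_probability(log10_abundance, midpoint: float, slope: float):
    """Logistic detection curve: p = expit(slope * (log10 a - midpoint)).

    Monotone nondecreasing in abundance for slope >= 0. ``midpoint`` of
    -inf forces detection (p = 1); +inf suppresses it (p = 0).
    """
    la = np.asarray(log10_abundance, dtype=float)
    if np.isneginf(midpoint):
        return np.where(np.isnan(la), np.nan, 1.0)
    if np.isposinf(midpoint):
        return np.where(np.isnan(la), np.nan, 0.0)
    return expit(slope * (la - midpoint))


def _group_names(m: int) -> list:
    if m <= len(QUARTET_GROUPS):
        return list(QUARTET_GROUPS[:m])
    return [f"G{i + 1:02d}" for i in range(m)]


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the planted truth: abundances, specific proteins, DEPs, strata.

    Base log10 abundances are drawn normal and affinely rescaled so the
    realized max/min span equals ``dynamic_range_log10`` exactly, centered
    at ``abundance_center_log10``. Group-specific proteins are disjoint
    subsets absent from all other groups. Each DEP protein has one group's
    abundance multiplied (up) or divided (down) by a fold change drawn
    log-uniform above the threshold, which flags it against every other
    group.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n, m = config.n_proteins, config.m_groups
    groups = _group_names(m)
    protein_ids = [f"P{i + 1:05d}" for i in range(n)]

    la = rng.standard_normal(n)
    span = la.max() - la.min()
    r = config.dynamic_range_log10
    la = (la - la.min()) / span * r + (config.abundance_center_log10 - r / 2.0)
    base = pd.DataFrame({g: 10.0 ** la for g in groups}, index=protein_ids)

    if config.group_effect_sd > 0:
        eff = rng.standard_normal((n, m)) * config.group_effect_sd
        if config.twin_similarity > 0 and m >= 2:
            ts = config.twin_similarity
            eff[:, 1] = ts * eff[:, 0] + np.sqrt(1 - ts * ts) * eff[:, 1]
        base = base * (10.0 ** eff)

    k = round(config.specific_fraction * n)
    if m * k > n:
        raise ConfigurationError("specific_fraction too large for n_proteins")
    perm = rng.permutation(n)
    specific = {}
    specific_all = []
    for gi, g in enumerate(groups):
        ids = [protein_ids[j] for j in perm[gi * k:(gi + 1) * k]]
        specific[g] = tuple(sorted(ids))
        specific_all.extend(ids)
        others = [h for h in groups if h != g]
        base.loc[ids, others] = np.nan

    eligible = [p for p in protein_ids if p not in set(specific_all)]
    d = round(config.dep_fraction * n)
    if d > len(eligible):
        raise ConfigurationError("dep_fraction too large given specific proteins")
    dep_ids = list(rng.choice(eligible, size=d, replace=False)) if d else []
    lo, hi = config.dep_fc_log2_range
    rows = []
    for pid in dep_ids:
        g = groups[rng.integers(m)]
        direction = "up" if rng.random() < 0.5 else "down"
        fc = float(2.0 ** rng.uniform(lo, hi))
        if direction == "up":
            base.loc[pid, g] *= fc
        else:
            base.loc[pid, g] /= fc
        for other in groups:
            if other != g:
                rows.append({"protein_id": pid, "test_group": g,
                             "ref_group": other, "direction": direction,
                             "true_fc": fc})
    dep_flags = pd.DataFrame(rows, columns=["protein_id", "test_group",
                                            "ref_group", "direction", "true_fc"])

    q1, q2 = np.percentile(la, [33.33, 66.67])
    stratum = np.where(la < q1, "low", np.where(la > q2, "high", "medium"))
    cv_stratum = pd.Series(stratum, index=protein_ids)

    sens = 1.0 + rng.standard_normal(n) * config.drift_heterogeneity
    drift_sensitivity = pd.Series(sens, index=protein_ids)

    n_deg = round(config.degradation_fraction * n)
    degraded = tuple(sorted(rng.choice(protein_ids, size=n_deg, replace=False))) \
        if n_deg else ()

    return GroundTruth(protein_ids=protein_ids, groups=groups,
                       base_abundance=base, dep_flags=dep_flags,
                       specific_proteins=specific,
                       cv_profile=dict(config.cv_profile),
                       cv_stratum=cv_stratum,
                       drift_sensitivity=drift_sensitivity,
                       detection_midpoint=config.detection_midpoint_log10,
                       detection_slope=config.detection_slope,
                       degraded_proteins=degraded,
                       degradation_rate=config.degradation_rate,
                       degradation_onset_month=config.degradation_onset_month)


def simulate_run(truth: GroundTruth, group: str, replicate: int,
                 injection_index: int, month: int,
                 config: SimulationConfig, seed, *,
                 injection_time: float | None = None) -> pd.Series:
    """Simulate one MS run: a protein abundance vector with missingness.

    observed = base * mean-one lognormal technical noise (stratum CV)
             * drift(injection)^sensitivity * degradation(month);
    the drift factor is drift_per_injection raised to
    (injection_time - 1) * drift_sensitivity_p, where ``injection_time``
    defaults to the injection index (continuous back-to-back injections)
    and the per-protein sensitivity makes the drift survive fraction-of-
    total normalization, as instrument drift does in practice. Each protein
    is then detected with logistic probability in the *deterministic*
    (noise-free, drift- and degradation-adjusted) log10 abundance.
    Undetected entries are NaN.
    """
    if group not in truth.groups:
        raise KeyError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    base = truth.base_abundance[group].to_numpy(dtype=float)
    n = base.size

    t = injection_index if injection_time is None else injection_time
    sens = truth.drift_sensitivity.to_numpy(dtype=float)
    factor = config.drift_per_injection ** ((t - 1) * sens)
    if truth.degraded_proteins and month > truth.degradation_onset_month:
        decay = np.exp(-truth.degradation_rate *
                       (month - truth.degradation_onset_month))
        idx = truth.base_abundance.index.get_indexer(truth.degraded_proteins)
        factor[idx] *= decay
    a_det = base * factor

    sigma = np.array([lognormal_sigma(truth.cv_profile[s])
                      for s in truth.cv_stratum.to_numpy()])
    noise = np.exp(rng.standard_normal(n) * sigma - 0.5 * sigma * sigma)
    observed = a_det * noise

    with np.errstate(invalid="ignore", divide="ignore"):
        la_det = np.log10(a_det)
    p = detection_probability(la_det, truth.detection_midpoint,
                              truth.detection_slope)
    u = rng.random(n)
    detected = ~np.isnan(base) & (u < p)
    out = np.where(detected, observed, np.nan)
    return pd.Series(out, index=truth.base_abundance.index, name=f"{group}_r{replicate}")


def _injection_order(groups, n_replicates, mode, rng) -> list:
    """Sequence of (group, replicate) by injection slot for each mode."""
    ci1 = [(g, r) for r in range(1, n_replicates + 1) for g in groups]
    if mode == "CI1":
        return ci1
    if mode == "CI2":
        return [(g, r) for g in groups for r in range(1, n_replicates + 1)]
    order = list(ci1)
    rng.shuffle(order)
    return order


def simulate_experiment(config: SimulationConfig, *,
                        experiment_seed: int | None = None,
                        experiment_id: str = "E1",
                        truth: GroundTruth | None = None
                        ) -> tuple[QuantMatrix, RunMetadata, GroundTruth]:
    """Simulate one experiment: m groups x n replicates at month 1.

    Injection slots 1..m*n are assigned by ``injection_mode``: RI draws a
    random permutation, CI1 interleaves the groups each cycle
    (D5 D6 F7 M8, D5 D6 F7 M8, ...), CI2 runs each group as a consecutive
    block (D5 D5 D5, D6 D6 D6, ...). Continuous modes run back-to-back
    (injection time = slot); RI runs are additionally scattered over a
    ``ri_time_spread``-fold longer time window, emulating random injection
    across idle instrument time, so drift acts over larger gaps.
    ``experiment_seed`` (default ``config.seed``) varies the run-level noise
    while the planted truth stays tied to ``config.seed``, so several
    experiments can share one ground truth.
    """
    if truth is None:
        truth = generate_ground_truth(config)
    eseed = config.seed if experiment_seed is None else experiment_seed
    order_rng = np.random.default_rng(np.random.SeedSequence([eseed, 1]))
    order = _injection_order(truth.groups, config.n_replicates,
                             config.injection_mode, order_rng)
    n_runs = len(order)
    if config.injection_mode == "RI":
        times = np.sort(order_rng.uniform(1.0, config.ri_time_spread * n_runs,
                                          size=n_runs))
    else:
        times = np.arange(1, n_runs + 1, dtype=float)
    seed_rng = np.random.default_rng(np.random.SeedSequence([eseed, 2]))
    run_seeds = seed_rng.integers(0, 2 ** 31 - 1, size=n_runs)

    slot_of = {gr: slot for slot, gr in enumerate(order)}
    columns, meta_rows = {}, []
    for g, r in sorted(slot_of, key=lambda gr: (truth.groups.index(gr[0]),
                                                gr[1])):
        slot = slot_of[(g, r)]
        vec = simulate_run(truth, g, r, slot + 1, 1, config,
                           int(run_seeds[slot]),
                           injection_time=float(times[slot]))
        run_id = f"{experiment_id}_{g}_r{r}"
        columns[run_id] = vec
        meta_rows.append({"run_id": run_id, "group_label": g,
                          "replicate_index": r, "experiment_id": experiment_id,
                          "site_id": "SIM", "instrument_id": "simulator",
                          "injection_index": slot + 1,
                          "injection_time": float(times[slot]), "month": 1,
                          "material_form": "peptide"})
    matrix = QuantMatrix(pd.DataFrame(columns), unit_tag="iBAQ")
    metadata = RunMetadata(pd.DataFrame(meta_rows))
    return matrix, metadata, truth


def simulate_longitudinal(config: SimulationConfig
                          ) -> tuple[QuantMatrix, RunMetadata, GroundTruth]:
    """Simulate ``config.months`` monthly experiments on one ground truth.

    Each month contributes m x n runs (experiment id ``M<month>``) with a
    fresh CI1 injection order; degradation acts on months past the onset.
    """
    if config.months < 2:
        raise ConfigurationError("simulate_longitudinal needs months >= 2")
    truth = generate_ground_truth(config)
    columns, meta_rows = {}, []
    for month in range(1, config.months + 1):
        seed_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 3, month]))
        order = [(g, r) for r in range(1, config.n_replicates + 1)
                 for g in truth.groups]
        run_seeds = seed_rng.integers(0, 2 ** 31 - 1, size=len(order))
        for slot, (g, r) in enumerate(order):
            vec = simulate_run(truth, g, r, slot + 1, month, config,
                               int(run_seeds[slot]))
            run_id = f"M{month:02d}_{g}_r{r}"
            columns[run_id] = vec
            meta_rows.append({"run_id": run_id, "group_label": g,
                              "replicate_index": r,
                              "experiment_id": f"M{month:02d}",
                              "site_id": "SIM", "instrument_id": "simulator",
                              "injection_index": slot + 1, "month": month,
                              "material_form": "protein"})
    matrix = QuantMatrix(pd.DataFrame(columns), unit_tag="iBAQ")
    metadata = RunMetadata(pd.DataFrame(meta_rows))
    return matrix, metadata, truth


def simulate_dilution_series(anchor_peptides, dilution_factors,
                             noise_cv: float = 0.0, seed: int = 0,
                             response_log10_range: tuple = (4.0, 6.0)
                             ) -> pd.DataFrame:
    """Simulate heavy-anchor dilution series signals.

    signal = dilution_factor * per-peptide response * mean-one lognormal
    noise. Needs at least three strictly positive, distinct dilution points.
    Returns a long DataFrame (peptide_id, dilution_factor, signal).
    """
    factors = np.asarray(list(dilution_factors), dtype=float)
    if factors.size < 3 or len(set(factors.tolist())) < 3:
        raise ConfigurationError("need >= 3 distinct dilution points")
    if (factors <= 0).any():
        raise ConfigurationError("dilution factors must be strictly positive")
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    sigma = lognormal_sigma(noise_cv)
    rows = []
    for pid in anchor_peptides:
        response = 10.0 ** rng.uniform(*response_log10_range)
        for f in factors:
            noise = np.exp(rng.standard_normal() * sigma - 0.5 * sigma * sigma) \
                if sigma > 0 else 1.0
            rows.append({"peptide_id": pid, "dilution_factor": float(f),
                         "signal": float(f * response * noise)})
    return pd.DataFrame(rows)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of a config with a different seed."""
    return replace(config, seed=seed)
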