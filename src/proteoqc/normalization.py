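"""Relative-quantification conventions: iBAQ -> FOT and intensity tertiles.

FOT ("fraction of total") is a protein's iBAQ divided by the summed iBAQ of
all identified proteins in the run, scaled by 1e5. Entries missing before
normalization are assigned the 1e-5 sentinel. Intensity grouping splits
proteins into low/medium/high at the 33.33rd and 66.67th percentiles of a
per-experiment summary intensity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import NormalizationError, ValidationError
from .matrix_io import QuantMatrix, RunMetadata
from .util import FOT_SCALE, SENTINEL, present_mask

INTENSITY_GROUPS = ("low", "medium", "high")

#: Percentile cut points for the intensity tertiles.
TERTILE_PERCENTILES = (33.33, 66.67)


def ibaq_to_fot(matrix: QuantMatrix) -> QuantMatrix:
    """Normalize an iBAQ matrix to FOT x 1e5 per run, sentinel-filling missing.

    Per run: FOT_i = iBAQ_i / sum(present iBAQ) * 1e5, so the values that
    were present in the input sum to 1e5 exactly. Entries missing in the
    input become the 1e-5 sentinel.
    """
    if matrix.unit_tag != "iBAQ":
        raise NormalizationError(
            f"ibaq_to_fot expects unit_tag 'iBAQ', got {matrix.unit_tag!r}")
    vals = matrix.values
    totals = vals.sum(axis=0, skipna=True)
    empty = vals.notna().sum(axis=0) == 0
    if empty.any():
        run = vals.columns[empty.to_numpy()][0]
        raise NormalizationError(f"run {run!r} has no present values")
    fot = vals.div(totals, axis=1) * FOT_SCALE
    fot = fot.fillna(SENTINEL)
    return QuantMatrix(fot, unit_tag="FOT")


def assign_intensity_groups(matrix: QuantMatrix,
                            metadata: RunMetadata | None = None,
                            experiment_id: str | None = None,
                            runs: list | None = None) -> pd.DataFrame:
    """Assign each detected protein of an experiment to an intensity tertile.

    The ranking basis is the mean of *present* values (sentinel and missing
    excluded) across the experiment's runs; only proteins detected at least
    once are assigned. Cuts fall at the 33.33rd / 66.67th percentiles of the
    basis values (linear interpolation): low < P33.33, high > P66.67,
    medium in between. If every basis value is equal the split is
    undefined and all proteins go to "medium" with a warning.

    Returns a DataFrame indexed by protein_id with columns
    ``group`` and ``basis_value``.
    """
    if runs is None:
        if metadata is not None:
            runs = metadata.runs_for(experiment_id)
        else:
            runs = matrix.run_ids
    if not runs:
        raise ValidationError("experiment has no runs")
    vals = matrix.values.loc[:, list(runs)]
    mask = present_mask(vals)
    basis = vals.where(mask).mean(axis=1, skipna=True)
    basis = basis[mask.any(axis=1)]
    if basis.empty:
        raise ValidationError("no protein detected in the experiment")
    lo, hi = np.percentile(basis.to_numpy(), TERTILE_PERCENTILES)
    if lo == hi and basis.nunique() == 1:
        warnings.warn("all basis intensities equal; assigning every protein "
                      "to 'medium'")
        group = pd.Series("medium", index=basis.index)
    else:
        group = pd.Series("medium", index=basis.index, dtype=object)
        group[basis < lo] = "low"
        group[basis > hi] = "high"
    out = pd.DataFrame({"group": group, "basis_value": basis})
    out.index.name = "protein_id"
    return out
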