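"""Shared constants and small helpers.

The two constants encode the relative-quantification conventions used
throughout the package: FOT (fraction of total) values are scaled by 1e5,
and entries that were missing before normalization carry the sentinel 1e-5.
A value equal to the sentinel is therefore treated as *absent* by every
identification-based metric.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Sentinel written into FOT matrices where the protein was not detected.
SENTINEL = 1e-5

#: FOT scale factor: fractions of total are multiplied by 1e5.
FOT_SCALE = 1e5


def present_mask(values: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Boolean mask of entries that represent a real detection.

    An entry is *present* when it is non-missing and not the 1e-5 sentinel.
    """
    return values.notna() & (values != SENTINEL)


def lognormal_sigma(cv: float) -> float:
    """Log-space sigma of a lognormal with the given coefficient of variation.

    sigma = sqrt(ln(1 + CV^2)); a mean-one lognormal with this sigma has
    exactly the requested CV.
    """
    if cv < 0:
        raise ValueError("CV must be non-negative")
    return float(np.sqrt(np.log1p(cv * cv)))
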