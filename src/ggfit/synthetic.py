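"""Synthetic hospital-stay fixtures.

The application data this package was designed around — lengths of stay of
male traumatic-brain-injury patients, in whole days, at three stages of
hospitalization — cannot be redistributed.  These generators draw from the
GG distribution at the published point estimates for those three samples
and round up to whole days, giving fixtures with the same size, scale and
tie structure as the real data (ceil rounding: a stay of 0.3 days is
recorded as 1, matching strictly positive integer day counts).

The presets are synthetic stand-ins, not the patient data:

=======  ======================  ===  ==========================
name     (phi, mu, alpha)          n  emulates
=======  ======================  ===  ==========================
D1-like  (0.410, 0.025, 3.040)   19  total days in hospital
D2-like  (0.268, 0.045, 4.658)   19  days in neurology inpatient
D3-like  (0.148, 0.053, 6.065)   16  days on mechanical ventilation
=======  ======================  ===  ==========================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import GGParams, LifetimeSample, gg_rng

__all__ = ["FixtureSpec", "FIXTURE_PRESETS", "make_fixture", "xls_to_csv"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic stay-duration sample."""

    name: str
    params: GGParams
    n: int
    rounding: str = "ceil-to-day"  # or "none"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.rounding not in ("none", "ceil-to-day"):
            raise ValueError("rounding must be 'none' or 'ceil-to-day'")


FIXTURE_PRESETS = {
    "D1-like": FixtureSpec("D1-like", GGParams(0.410, 0.025, 3.040), 19),
    "D2-like": FixtureSpec("D2-like", GGParams(0.268, 0.045, 4.658), 19),
    "D3-like": FixtureSpec("D3-like", GGParams(0.148, 0.053, 6.065), 16),
}


def make_fixture(spec, seed=None, csv_path=None) -> LifetimeSample:
    """Draw one fixture sample; optionally write it as a one-column CSV.

    ``spec`` is a :class:`FixtureSpec` or a preset name ("D1-like",
    "D2-like", "D3-like", or "custom" via an explicit spec).  ``seed``
    overrides the spec's seed.  The CSV has the single header ``days``.
    """
    if isinstance(spec, str):
        if spec not in FIXTURE_PRESETS:
            raise ValueError(
                f"unknown preset {spec!r}; choose from {sorted(FIXTURE_PRESETS)}"
            )
        spec = FIXTURE_PRESETS[spec]
    use_seed = seed if seed is not None else spec.seed
    sample = gg_rng(spec.n, spec.params, seed=use_seed)
    if spec.rounding == "ceil-to-day":
        sample = LifetimeSample(np.ceil(sample.values))
    if csv_path is not None:
        import pandas as pd

        pd.DataFrame({"days": sample.values}).to_csv(csv_path, index=False)
    return sample


def xls_to_csv(xls_path, out_dir, sheet=0, column=None):
    """Convert a spreadsheet of stay durations to the canonical CSV form.

    Helper for users who hold the original admissions spreadsheet; requires
    an Excel engine (openpyxl handles .xlsx; legacy .xls files must be
    re-saved as .xlsx or CSV first).  Returns the written path.
    """
    import pathlib

    import pandas as pd

    try:
        df = pd.read_excel(xls_path, sheet_name=sheet)
    except ImportError as exc:
        raise ImportError(
            "reading spreadsheets needs an Excel engine: install openpyxl "
            "and convert legacy .xls to .xlsx first"
        ) from exc
    col = df[column] if column is not None else df.iloc[:, 0]
    out = pathlib.Path(out_dir) / (pathlib.Path(xls_path).stem + ".csv")
    pd.DataFrame({"days": pd.to_numeric(col, errors="raise")}).to_csv(out, index=False)
    return out
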