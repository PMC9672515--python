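"""Relative qPCR quantification by the 2^-ddCt method.

dCt = Ct(target) - Ct(reference) within a condition; ddCt subtracts the
calibrator condition's dCt from the test condition's; relative expression
is 2^-ddCt.  Replicate Ct values are averaged arithmetically before the
differences are taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["CtMeasurement", "relative_expression", "ddct_table"]


@dataclass(frozen=True)
class CtMeasurement:
    """Mean Ct cycle numbers of target and reference genes in a test and a
    calibrator condition."""

    ct_target_test: float
    ct_ref_test: float
    ct_target_cal: float
    ct_ref_cal: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a finite positive cycle number, got {v!r}")

    @property
    def ddct(self) -> float:
        return (self.ct_target_test - self.ct_ref_test) - (
            self.ct_target_cal - self.ct_ref_cal
        )


def relative_expression(m: CtMeasurement) -> float:
    """2^-ddCt; 1.0 when test equals calibrator."""
    return 2.0 ** (-m.ddct)


def ddct_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Vectorized 2^-ddCt over a table with columns ct_target_test,
    ct_ref_test, ct_target_cal, ct_ref_cal (replicates pre-averaged or one
    row per assay)."""
    needed = ["ct_target_test", "ct_ref_test", "ct_target_cal", "ct_ref_cal"]
    missing = [c for c in needed if c not in ct.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing}")
    out = ct.copy()
    measurements = [
        CtMeasurement(*row) for row in ct[needed].itertuples(index=False, name=None)
    ]
    out["ddct"] = [m.ddct for m in measurements]
    out["relative_expression"] = [relative_expression(m) for m in measurements]
    return out
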