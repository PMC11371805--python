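"""Expression helpers: exon-level TPM and relative qPCR expression.

``exon_tpm`` normalises read counts for feature length and library size
(transcripts per million): TPM_i = (c_i / l_i) / sum_j(c_j / l_j) x 1e6,
the normalising sum running over all features of the library, so the
vector sums to one million.  Multimapping reads are assumed to have been
excluded upstream — this module consumes counts, it does not produce them.

``ddct_ratio`` implements the comparative-Ct (2^-ddCt) method: per sample,
dCt = Ct_target - Ct_reference (replicates averaged); ddCt subtracts the
calibrator sample's dCt, and the expression ratio is E^-ddCt with an
amplification efficiency E of exactly 2 unless measured otherwise.
Replicate scatter is propagated as s = sqrt(s_target^2 + s_reference^2) on
the Ct scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["exon_tpm", "tpm_table", "ddct_ratio", "QpcrResult"]


def exon_tpm(
    lengths: Sequence[float] | np.ndarray, counts: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Length- and library-size-normalised expression per feature.

    ``lengths`` in bp (> 0), ``counts`` raw reads (>= 0) over *all* features
    of the library.  All-zero counts yield an all-NaN vector with a warning.
    Invariant to uniform count scaling.
    """
    lengths = np.asarray(lengths, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if lengths.shape != counts.shape:
        raise ValidationError("lengths and counts must have the same shape")
    if np.any(lengths <= 0):
        raise ValidationError("feature lengths must be > 0")
    if np.any(counts < 0):
        raise ValidationError("counts must be >= 0")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        warnings.warn("all counts are zero; TPM undefined", stacklevel=2)
        return np.full_like(rate, np.nan)
    return rate / total * 1e6


def tpm_table(frame: pd.DataFrame, length_col: str = "length") -> pd.DataFrame:
    """Per-library TPM for a table with a length column and one column per library."""
    out = frame[[c for c in frame.columns if c == length_col]].copy()
    for col in frame.columns:
        if col == length_col or frame[col].dtype == object:
            out[col] = frame[col]
            continue
        out[col] = exon_tpm(frame[length_col], frame[col])
    return out


@dataclass(frozen=True)
class QpcrResult:
    """Relative expression by the comparative-Ct method."""

    ratio: float
    ddct: float
    ddct_sd: float
    efficiency: float

    @property
    def ratio_lower(self) -> float:
        return self.efficiency ** -(self.ddct + self.ddct_sd)

    @property
    def ratio_upper(self) -> float:
        return self.efficiency ** -(self.ddct - self.ddct_sd)


def _mean_sd_ct(run: pd.DataFrame, sample: str, target: str) -> tuple[float, float]:
    wells = run[(run["sample"] == sample) & (run["target"] == target)]["ct"]
    if wells.empty:
        raise ValidationError(f"no {target!r} wells for sample {sample!r}")
    if (wells <= 0).any():
        raise ValidationError(f"non-positive Ct for sample {sample!r}")
    return float(wells.mean()), float(wells.std(ddof=1)) if len(wells) > 1 else 0.0


def ddct_ratio(
    run: pd.DataFrame,
    sample: str,
    calibrator: str,
    target: str = "gene",
    reference: str = "reference",
    efficiency: float = 2.0,
) -> QpcrResult:
    """Expression of ``sample`` relative to ``calibrator`` (E^-ddCt).

    ``run`` holds one well per row with columns ``sample``, ``target`` and
    ``ct``; replicates (typically triplicates) are averaged.  The reference
    target normalises input amounts within each sample.
    """
    for col in ("sample", "target", "ct"):
        if col not in run.columns:
            raise ValidationError(f"qPCR run table lacks column {col!r}")
    mt, st = _mean_sd_ct(run, sample, target)
    mr, sr = _mean_sd_ct(run, sample, reference)
    ct_cal_t, sct = _mean_sd_ct(run, calibrator, target)
    ct_cal_r, scr = _mean_sd_ct(run, calibrator, reference)
    dct = mt - mr
    dct_cal = ct_cal_t - ct_cal_r
    ddct = dct - dct_cal
    sd = float(np.sqrt(st**2 + sr**2))
    return QpcrResult(
        ratio=float(efficiency**-ddct),
        ddct=float(ddct),
        ddct_sd=sd,
        efficiency=efficiency,
    )
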