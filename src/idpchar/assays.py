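"""Protection-assay arithmetic: LDH activity, residual activity, yeast
viability ratios and the accompanying two-sample significance test."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LDH_ACTIVITY_FACTOR", "ldh_activity", "residual_activity",
    "viability_ratio", "ViabilitySummary", "two_sample_t",
]

#: Conversion of the linear NADH-oxidation rate to enzyme activity:
#: dA340/min * 8095 = U/L.
LDH_ACTIVITY_FACTOR = 8095.0


def ldh_activity(dA340_per_min):
    """LDH activity (U/L) from the absorbance rate at 340 nm."""
    rate = np.asarray(dA340_per_min, dtype=float)
    if not np.all(np.isfinite(rate)):
        raise ValueError("absorbance rate must be finite")
    out = rate * LDH_ACTIVITY_FACTOR
    return float(out) if out.ndim == 0 else out


def residual_activity(stressed, baseline):
    """Residual activity (%) relative to the pre-stress baseline of the
    same sample series."""
    stressed = np.asarray(stressed, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline activity must be positive")
    out = 100.0 * stressed / baseline
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ViabilitySummary:
    strain: str
    viability_ratio: float  # percent
    fold_vs_reference: float | None = None


def viability_ratio(
    stressed_counts: Sequence[float],
    control_counts: Sequence[float],
    strain: str = "strain",
    reference_ratio: float | None = None,
) -> ViabilitySummary:
    """Viability (%) = 100 * mean(stressed colonies) / mean(control colonies).

    With ``reference_ratio`` (the empty-vector strain's ratio) the
    fold-change versus the reference is attached.
    """
    stressed = np.asarray(stressed_counts, dtype=float)
    control = np.asarray(control_counts, dtype=float)
    if np.any(stressed < 0) or np.any(control < 0):
        raise ValueError("colony counts must be non-negative")
    if control.mean() <= 0:
        raise ValueError("control plate mean must be positive")
    ratio = 100.0 * stressed.mean() / control.mean()
    fold = None
    if reference_ratio is not None:
        if reference_ratio <= 0:
            raise ValueError("reference ratio must be positive")
        fold = ratio / reference_ratio
    return ViabilitySummary(strain=strain, viability_ratio=float(ratio), fold_vs_reference=fold)


def two_sample_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = 0.05,
    welch: bool = False,
) -> tuple[float, float, bool]:
    """Two-sided two-sample t-test; classic pooled-variance Student by
    default, Welch behind a flag.  Returns ``(t, p, significant)``."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0, False
        raise ValueError("degenerate zero-variance groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p), bool(p < alpha)
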