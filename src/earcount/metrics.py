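"""Count-regression evaluation statistics.

For paired reference counts r_i and estimated counts e_i over N images:

    RMSE  = sqrt( (1/N) * sum (r_i - e_i)^2 )
    rRMSE = sqrt( (1/N) * sum ((r_i - e_i) / r_i)^2 )
    bias  = (1/N) * sum (r_i - e_i)

so a negative bias means the estimator systematically over-counts relative to
the reference. R^2 and the regression slope/offset come from an ordinary
least-squares line; by default the reference is the ordinate (r ~ a*e + b),
the orientation used when plotting automatic counts against manual ones. R^2
is the squared Pearson correlation and is orientation-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PairedCounts", "MetricsReport", "compare_counts"]


@dataclass
class PairedCounts:
    reference: np.ndarray
    estimated: np.ndarray

    def __post_init__(self):
        self.reference = np.asarray(self.reference, dtype=float)
        self.estimated = np.asarray(self.estimated, dtype=float)
        if self.reference.ndim != 1 or self.estimated.ndim != 1:
            raise ValueError("reference and estimated must be 1-D")
        if len(self.reference) != len(self.estimated):
            raise ValueError("reference and estimated must have equal length")
        if len(self.reference) < 1:
            raise ValueError("need at least one pair")
        if (self.estimated < 0).any():
            raise ValueError("estimated counts must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.reference)


@dataclass
class MetricsReport:
    rmse: float
    rrmse: float | None
    bias: float
    r2: float | None
    slope: float | None
    offset: float | None
    n: int

    @property
    def rrmse_percent(self) -> str:
        if self.rrmse is None:
            return "n/a"
        return f"{100.0 * self.rrmse:.1f}%"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "rmse": self.rmse,
            "rrmse": self.rrmse,
            "rrmse_percent": self.rrmse_percent,
            "bias": self.bias,
            "r2": self.r2,
            "slope": self.slope,
            "offset": self.offset,
        }

    def __str__(self) -> str:
        lines = [f"n      = {self.n}", f"RMSE   = {self.rmse:.4g}"]
        lines.append(f"rRMSE  = {self.rrmse_percent}")
        lines.append(f"bias   = {self.bias:.4g}")
        if self.r2 is not None:
            lines.append(f"R^2    = {self.r2:.4f}")
        if self.slope is not None:
            lines.append(f"slope  = {self.slope:.4g}")
            lines.append(f"offset = {self.offset:.4g}")
        return "\n".join(lines)


def compare_counts(
    pairs: PairedCounts,
    *,
    relative: bool = True,
    regress_reference_on_estimate: bool = True,
) -> MetricsReport:
    """Compute RMSE, rRMSE, bias, R^2 and the regression line for paired counts.

    ``relative=False`` skips rRMSE (required when some reference counts are
    zero, since the per-image relative error divides by r_i). With fewer than
    two pairs, or a degenerate (constant) regressor, R^2/slope/offset are None.
    """
    r, e = pairs.reference, pairs.estimated
    diff = r - e
    rmse = float(np.sqrt(np.mean(diff**2)))
    bias = float(np.mean(diff))
    rrmse = None
    if relative:
        if (r <= 0).any():
            raise ValueError("rRMSE requires strictly positive reference counts")
        rrmse = float(np.sqrt(np.mean((diff / r) ** 2)))
    r2 = slope = offset = None
    if pairs.n >= 2:
        x, y = (e, r) if regress_reference_on_estimate else (r, e)
        if np.ptp(x) > 0:
            a, b = np.polyfit(x, y, 1)
            slope, offset = float(a), float(b)
            # R^2 is undefined when either variable has zero variance
            if np.ptp(y) > 0:
                r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return MetricsReport(
        rmse=rmse, rrmse=rrmse, bias=bias, r2=r2, slope=slope, offset=offset, n=pairs.n
    )
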