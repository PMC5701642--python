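"""Turning scan maps into source localizations and error summaries."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateInputError


@dataclass
class LocalizationResult:
    """Peak of a scan map and its distance to the simulated source."""

    estimated_node: int
    estimated_position: np.ndarray
    criterion: str
    true_position: Optional[np.ndarray] = None
    error_mm: Optional[float] = None
    tie: bool = False


def localize(scan_outputs: Sequence, criterion: str,
             true_position=None) -> LocalizationResult:
    """Node with the maximal variance or kurtosis output.

    Degenerate nodes (ok=False / NaN outputs) are ignored.  Exact ties are
    resolved to the lowest node index and flagged on the result.
    """
    if criterion not in ("variance", "kurtosis"):
        raise ValueError("criterion must be 'variance' or 'kurtosis'")
    attr = "variance_output" if criterion == "variance" else "kurtosis_output"
    vals = np.array([getattr(s, attr) if s.ok else np.nan for s in scan_outputs])
    if vals.size == 0 or not np.any(np.isfinite(vals)):
        raise DegenerateInputError("scan contains no usable nodes")
    best = np.nanmax(vals)
    winners = np.flatnonzero(vals == best)
    k = int(winners[0])
    out = scan_outputs[k]
    res = LocalizationResult(estimated_node=out.node,
                             estimated_position=np.asarray(out.position, float),
                             criterion=criterion, tie=winners.size > 1)
    if true_position is not None:
        res.true_position = np.asarray(true_position, float)
        res.error_mm = localization_error(res.estimated_position, res.true_position)
    return res


def localization_error(estimated, truth) -> float:
    """Euclidean distance in mm (stored unrounded; summaries round to mm)."""
    return float(np.linalg.norm(np.asarray(estimated, float) - np.asarray(truth, float)))


@dataclass
class ErrorSummary:
    """Tukey-style boxplot statistics of localization errors (mm).

    The whisker rule measures the 1.5*IQR distance from the *median* (as the
    study reports it), not from the quartiles; ``whisker_anchor='quartile'``
    switches to the conventional rule.  ``cap`` only affects rendered values
    (:meth:`display`), never the stored statistics.
    """

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    n: int
    cap: float = 40.0
    whisker_anchor: str = "median"

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def display(self) -> dict:
        """Reporting view: values capped at ``cap`` mm and rounded to mm."""
        capped = lambda v: round(min(v, self.cap))
        return {
            "median": capped(self.median), "q1": capped(self.q1), "q3": capped(self.q3),
            "whisker_low": capped(self.whisker_low), "whisker_high": capped(self.whisker_high),
            "outliers": [capped(v) for v in self.outliers], "n": self.n,
        }


def tukey_summary(errors, cap: float = 40.0,
                  whisker_anchor: str = "median") -> ErrorSummary:
    """Median, quartiles, whiskers and outliers of an error sample.

    Quartiles use linear interpolation between order statistics.  Whiskers
    extend to the smallest/largest observation within 1.5*IQR of the anchor
    (median by default); everything beyond is an outlier.
    """
    x = np.asarray([e for e in np.ravel(errors)], float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("need at least one finite error value")
    if whisker_anchor not in ("median", "quartile"):
        raise ValueError("whisker_anchor must be 'median' or 'quartile'")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_anchor, hi_anchor = (med, med) if whisker_anchor == "median" else (q1, q3)
    lo_bound = lo_anchor - 1.5 * iqr
    hi_bound = hi_anchor + 1.5 * iqr
    inside = x[(x >= lo_bound) & (x <= hi_bound)]
    if inside.size == 0:
        wlo = whi = med
    else:
        wlo, whi = float(inside.min()), float(inside.max())
    outliers = np.sort(x[(x < wlo) | (x > whi)])
    return ErrorSummary(median=float(med), q1=float(q1), q3=float(q3),
                        whisker_low=wlo, whisker_high=whi, outliers=outliers,
                        n=int(x.size), cap=cap, whisker_anchor=whisker_anchor)
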