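"""Bliss-independence interaction scores for odor-mixture responses.

With f1 and f2 the dF/F0 responses (as decimals) to the two mixture
components and f3 the observed response to their 1:1 mixture (each component
at half concentration), the no-interaction expectation is the
inclusion-exclusion of the halved components,

    f_expected = f1/2 + f2/2 - (f1/2)(f2/2),

and the Bliss score is 100 * (f_observed - f_expected).  Positive scores mark
synergy, negative antagonism, near-zero additivity.  Negative (inhibitory)
responses are passed through unmodified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BlissTrace",
    "bliss_score",
    "bliss_traces",
    "synergistic_fraction",
]


def bliss_score(f1, f2, f3):
    """Bliss interaction score 100*(f3 - f_expected); symmetric in f1, f2."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    f3 = np.asarray(f3, dtype=float)
    if not (np.all(np.isfinite(f1)) and np.all(np.isfinite(f2))
            and np.all(np.isfinite(f3))):
        raise ValueError("non-finite responses")
    f_expected = (f1 / 2 + f2 / 2) - (f1 / 2) * (f2 / 2)
    out = 100.0 * (f3 - f_expected)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BlissTrace:
    """Frame-wise Bliss score of one unit plus its window summary."""

    unit: object
    f1: np.ndarray            # component 1 trace (Laa)
    f2: np.ndarray            # component 2 trace (Lct)
    f3: np.ndarray            # observed mixture trace (LaaLct)
    score: np.ndarray         # 100*(f3 - f_expected) per frame
    summary: float            # mean frame-wise score over the window
    pooled: bool = True       # False for units with identical motif triplets

    @property
    def f_expected(self) -> np.ndarray:
        return (self.f1 / 2 + self.f2 / 2) - (self.f1 / 2) * (self.f2 / 2)


def bliss_traces(unit_traces: dict, window: tuple, triplets=None) -> list[BlissTrace]:
    """Frame-wise Bliss scores for a set of units.

    ``unit_traces`` maps unit id -> (f_Laa, f_Lct, f_LaaLct) frame-aligned
    dF/F0 traces.  ``window`` is the (start, stop) frame range summarized by
    the mean score.  Units whose motif triplet (from ``triplets``, unit ->
    (m_Lct, m_Laa, m_LaaLct)) is identical across all three stimuli are still
    scored but flagged ``pooled=False`` and left out of population summaries.
    """
    out = []
    lo, hi = window
    for unit, (f1, f2, f3) in unit_traces.items():
        f1 = np.asarray(f1, float)
        f2 = np.asarray(f2, float)
        f3 = np.asarray(f3, float)
        if not (f1.shape == f2.shape == f3.shape):
            raise ValueError(f"misaligned frame counts for unit {unit!r}")
        score = bliss_score(f1, f2, f3)
        pooled = True
        if triplets is not None and unit in triplets:
            trip = tuple(triplets[unit])
            pooled = len(set(trip)) > 1
        out.append(BlissTrace(unit, f1, f2, f3, score,
                              float(score[lo:hi].mean()), pooled))
    return out


def synergistic_fraction(scores) -> dict:
    """Fraction of strongly synergistic units.

    The threshold is one standard deviation of the pooled window-summary
    score distribution; a unit counts when its score is strictly greater.
    Returns ``{"fraction", "threshold", "n"}``; a zero-variance distribution
    yields fraction 0 (flagged via warning).
    """
    s = np.asarray(scores, dtype=float).ravel()
    if s.size < 2:
        raise ValueError("need at least 2 units")
    sd = float(s.std(ddof=1))
    if sd == 0:
        warnings.warn("zero-variance score distribution; fraction set to 0")
        return {"fraction": 0.0, "threshold": 0.0, "n": int(s.size)}
    return {"fraction": float((s > sd).mean()), "threshold": sd, "n": int(s.size)}
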