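"""LTR retrotransposon insertion-age estimation.

The two long terminal repeats of a retroelement are identical at
insertion, so the divergence K between the 5' and 3' LTRs of one element
dates the insertion: T = K / (2 mu), where mu is the substitution rate per
site per year and K is the Jukes–Cantor-corrected p-distance over the
alignable (ungapped, unambiguous) columns of the LTR alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .kaks import jukes_cantor

log = logging.getLogger("camgen")

jc69_distance = jukes_cantor  # same correction; re-exported under the LTR name


@dataclass
class LtrPair:
    """Aligned 5'/3' LTR sequences of one element, or a precomputed p."""

    element_id: str
    ltr5: str | None = None
    ltr3: str | None = None
    p_distance: float | None = None

    def __post_init__(self) -> None:
        if self.p_distance is None:
            if self.ltr5 is None or self.ltr3 is None:
                raise ValueError(f"{self.element_id}: need sequences or p")
            if len(self.ltr5) != len(self.ltr3):
                raise ValueError(f"{self.element_id}: unequal alignment lengths")
            self.p_distance = self._p_from_alignment()

    def _p_from_alignment(self) -> float | None:
        """p-distance over columns without gaps or ambiguous bases."""
        diffs = sites = 0
        for a, b in zip(self.ltr5.upper(), self.ltr3.upper()):
            if a not in "ACGT" or b not in "ACGT":
                continue
            sites += 1
            diffs += a != b
        if sites == 0:
            log.warning("%s: no alignable columns; age undefined",
                        self.element_id)
            return None
        return diffs / sites


def ltr_insertion_age(pair: LtrPair, mu: float) -> float:
    """Insertion age in years, T = K/(2 mu); NaN when saturated/undefined."""
    if mu <= 0:
        raise ValueError("substitution rate mu must be positive")
    if pair.p_distance is None or pair.p_distance >= 0.75:
        return float("nan")
    return jukes_cantor(pair.p_distance) / (2.0 * mu)


def age_summary(ages, bin_width: float = 1e4,
                bandwidth: float | None = None) -> dict:
    """Histogram, kernel-density modal age and 5/50/95% quantiles.

    NaN (saturated or undefined) ages are dropped; an all-undefined input
    yields an empty summary with a warning.
    """
    vals = np.asarray(list(ages), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        log.warning("no defined insertion ages; empty summary")
        return {"n": 0, "bin_edges": np.array([]), "counts": np.array([]),
                "mode": float("nan"), "quantiles": {}}
    hi = max(vals.max(), bin_width)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    if vals.size < 2 or np.ptp(vals) == 0:
        mode = float(vals[0])
    else:
        kde = _st.gaussian_kde(vals, bw_method=bandwidth)
        grid = np.linspace(0.0, vals.max(), 2048)
        mode = float(grid[np.argmax(kde(grid))])
    q5, q50, q95 = np.quantile(vals, [0.05, 0.5, 0.95])
    return {"n": int(vals.size), "bin_edges": edges, "counts": counts,
            "mode": mode,
            "quantiles": {"q5": float(q5), "q50": float(q50),
                          "q95": float(q95)}}
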