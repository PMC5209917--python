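"""Cutoff recommendation and locus-specific detection limits.

The prediction-index cutoff that keeps false positives at a tolerated rate
grows linearly with barcode depth; the fitted equations (intercept a, slope
b, one pair per tolerated false-positive rate in calls per megabase) are

    FPR  20 /Mb : y = 14 + 0.012  x
    FPR  50 /Mb : y = 15 + 0.0092 x
    FPR 100 /Mb : y = 13 + 0.0088 x

with the recommended integer cutoff being the ceiling of y.  No
interpolation is offered for other FPRs — only these three fits exist.

The detection limit f* at a locus is the smallest allele fraction whose
expected number of variant molecules clears the cutoff with stated
confidence: with k = ceil(cutoff / i_bar) variant barcodes needed (i_bar
being the typical per-barcode index of a well-supported molecule, ~3.5), f*
is the smallest f such that P(X >= k) >= confidence for X ~ Binomial(d, f),
d the locus barcode depth.

Two conventions are implemented for which depth feeds the cutoff and which
feeds the binomial (see ``detection_limit``); the default, "narrative",
derives the cutoff from the run-average depth D (the cutoff is a property of
the run) and samples molecules from the locus depth d (power is a property
of the locus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binom

__all__ = [
    "CUTOFF_COEFFICIENTS",
    "recommend_cutoff",
    "min_alt_barcodes",
    "DetectionLimitParams",
    "detection_limit",
    "DetectionLimitProfile",
    "detection_limit_track",
]

#: FPR (per Mb) -> (intercept, slope) of the linear cutoff fit.
CUTOFF_COEFFICIENTS: Dict[int, Tuple[float, float]] = {
    20: (14.0, 0.012),
    50: (15.0, 0.0092),
    100: (13.0, 0.0088),
}


def recommend_cutoff(fpr_per_mb: int, barcode_depth: float) -> int:
    """Recommended integer prediction-index cutoff, ``ceil(a + b * depth)``."""
    if fpr_per_mb not in CUTOFF_COEFFICIENTS:
        raise ValueError(
            f"unsupported FPR {fpr_per_mb}/Mb; supported: "
            f"{sorted(CUTOFF_COEFFICIENTS)}"
        )
    if barcode_depth <= 0:
        raise ValueError("barcode depth must be positive")
    a, b = CUTOFF_COEFFICIENTS[fpr_per_mb]
    return math.ceil(a + b * barcode_depth)


def min_alt_barcodes(cutoff: float, i_bar: float = 3.5) -> int:
    """Minimum variant barcodes needed to clear ``cutoff``: ``ceil(cutoff/i_bar)``."""
    if cutoff <= 0 or i_bar <= 0:
        raise ValueError("cutoff and i_bar must be positive")
    return math.ceil(cutoff / i_bar)


@dataclass(frozen=True)
class DetectionLimitParams:
    """Inputs of the detection-limit computation.

    ``d``: locus barcode depth; ``big_d``: run-average barcode depth;
    ``i_bar``: typical per-barcode index of a good variant barcode;
    ``confidence``: required detection probability; ``fpr_per_mb``: tolerated
    false-positive rate feeding the cutoff equation.
    """

    d: int
    big_d: float
    i_bar: float = 3.5
    confidence: float = 0.95
    fpr_per_mb: int = 20
    convention: str = "narrative"  # "narrative" | "literal"

    def __post_init__(self) -> None:
        if self.d < 0 or self.big_d <= 0 or self.i_bar <= 0:
            raise ValueError("require d >= 0, big_d > 0, i_bar > 0")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")
        if self.convention not in ("narrative", "literal"):
            raise ValueError("convention must be 'narrative' or 'literal'")


def _required_barcodes_and_n(params: DetectionLimitParams) -> Tuple[int, int]:
    a, b = CUTOFF_COEFFICIENTS[params.fpr_per_mb]
    if params.convention == "narrative":
        cutoff = recommend_cutoff(params.fpr_per_mb, params.big_d)
        n = params.d
    else:  # literal: cutoff from the locus depth, sampling from the run average
        cutoff = a + b * params.d
        n = int(round(params.big_d))
    return min_alt_barcodes(cutoff, params.i_bar), n


def detection_limit(params: DetectionLimitParams, tol: float = 1e-5) -> float:
    """Smallest allele fraction detectable with the stated confidence.

    Solved by bisection on f (P(X >= k) is increasing in f) to absolute
    tolerance ``tol``; returns 1.0 when even f = 1 cannot supply the required
    number of variant barcodes (undetectable at this depth).
    """
    if params.d == 0:
        return 1.0
    k, n = _required_barcodes_and_n(params)
    if k > n:
        return 1.0

    def tail(f: float) -> float:
        return float(binom.sf(k - 1, n, f))

    if tail(1.0) < params.confidence:
        return 1.0
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if tail(mid) >= params.confidence:
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class DetectionLimitProfile:
    """Per-locus minimal detectable allele fraction over a region.

    ``limits[i]`` is f* for 1-based position ``start + 1 + i``; NaN where the
    barcode depth is zero (undefined).
    """

    contig: str
    start: int  # 0-based start of the track
    depths: np.ndarray
    limits: np.ndarray

    def to_bedgraph(self, path: str, precision: int = 6) -> None:
        """bedGraph (0-based half-open), adjacent equal values merged,
        zero-depth bases omitted."""
        with open(path, "w") as fh:
            fh.write(
                f'track type=bedGraph name="detection_limit" '
                f'description="minimal detectable allele fraction"\n'
            )
            run_start: Optional[int] = None
            run_value: Optional[str] = None
            for i, value in enumerate(self.limits):
                text = None if np.isnan(value) else f"{value:.{precision}f}"
                if text != run_value:
                    if run_value is not None:
                        fh.write(
                            f"{self.contig}\t{self.start + run_start}\t"
                            f"{self.start + i}\t{run_value}\n"
                        )
                    run_start, run_value = i, text
            if run_value is not None:
                fh.write(
                    f"{self.contig}\t{self.start + run_start}\t"
                    f"{self.start + len(self.limits)}\t{run_value}\n"
                )


def detection_limit_track(
    depths: Sequence[int],
    contig: str,
    start: int,
    big_d: float,
    i_bar: float = 3.5,
    confidence: float = 0.95,
    fpr_per_mb: int = 20,
    convention: str = "narrative",
) -> DetectionLimitProfile:
    """Detection-limit profile over a per-base barcode-depth track.

    f* is computed once per distinct depth value (the map depth -> f* is
    deterministic) and broadcast over the track.
    """
    depths_arr = np.asarray(depths, dtype=int)
    limits = np.full(depths_arr.shape, np.nan)
    cache: Dict[int, float] = {}
    for i, d in enumerate(depths_arr):
        d = int(d)
        if d == 0:
            continue
        if d not in cache:
            cache[d] = detection_limit(
                DetectionLimitParams(
                    d=d,
                    big_d=big_d,
                    i_bar=i_bar,
                    confidence=confidence,
                    fpr_per_mb=fpr_per_mb,
                    convention=convention,
                )
            )
        limits[i] = cache[d]
    return DetectionLimitProfile(
        contig=contig, start=start, depths=depths_arr, limits=limits
    )
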