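"""Read-level pre-filters and candidate-level post-filters.

Pre-filters discard unusable alignments (low MAPQ, secondary/supplementary/
QC-fail records, optionally non-proper pairs) before barcode families are
formed; individual base observations below the base-quality floor are dropped
during pileup construction.

Post-filters annotate candidate variants that look like artifacts rather than
deleting them, mirroring VCF convention:

* StrongBarcode — a real variant should be carried by multiple molecules,
  each with decisive read evidence; candidates lacking ``m`` barcodes with
  per-barcode evidence weight >= ``tau`` are flagged.
* StrandBias — first-cycle polymerase errors and DNA damage arise on one
  strand; a Fisher exact test on the 2x2 (ref/alt x forward/reverse) table of
  *barcode* counts flags candidates whose alt support is both statistically
  and substantially one-sided while the reference is not.
* Homopolymer / LowComplexity / Repeat — sequence-context filters for the
  region classes where alignment artifacts concentrate.

All thresholds are reconstructed defaults, exposed on :class:`FilterConfig`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

from scipy.stats import fisher_exact

from .model import LocusCall

__all__ = [
    "FilterConfig",
    "prefilter_read",
    "strong_barcode_filter",
    "strand_bias_filter",
    "region_context_filters",
    "apply_filters",
]


@dataclass(frozen=True)
class FilterConfig:
    min_mapq: int = 17
    min_baseq: int = 20
    require_proper_pair: bool = True
    strong_barcode_min_count: int = 2          # m
    strong_barcode_min_evidence: float = 2.0   # tau, index units per barcode
    strand_bias_p_floor: float = 1e-5
    strand_bias_min_ratio: float = 5.0
    homopolymer_max_run: int = 8
    low_complexity_window: int = 50            # bp each side
    low_complexity_entropy_floor: float = 1.0  # bits, dinucleotide Shannon
    repeat_max_period: int = 6
    repeat_min_coverage: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "min_mapq", "min_baseq", "strong_barcode_min_count",
            "strong_barcode_min_evidence", "strand_bias_p_floor",
            "strand_bias_min_ratio", "homopolymer_max_run",
            "low_complexity_window", "low_complexity_entropy_floor",
        ):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and non-negative")


def prefilter_read(read, config: FilterConfig = FilterConfig()) -> Tuple[bool, Optional[str]]:
    """Accept or reject one aligned record before family formation."""
    if read.is_unmapped:
        return False, "unmapped"
    if read.is_secondary:
        return False, "secondary"
    if read.is_supplementary:
        return False, "supplementary"
    if read.is_qcfail:
        return False, "qcfail"
    if read.is_duplicate:
        return False, "duplicate"
    if read.mapping_quality < config.min_mapq:
        return False, "low_mapq"
    if config.require_proper_pair and read.is_paired and not read.is_proper_pair:
        return False, "not_proper_pair"
    return True, None


def strong_barcode_filter(
    call: LocusCall, allele: str, config: FilterConfig = FilterConfig()
) -> bool:
    """True iff at least ``m`` barcodes contribute evidence >= ``tau`` for allele."""
    weights = call.barcode_evidence.get(allele, [])
    strong = sum(1 for w in weights if w >= config.strong_barcode_min_evidence)
    return strong >= config.strong_barcode_min_count


def strand_bias_filter(
    ref_fwd: int,
    ref_rev: int,
    alt_fwd: int,
    alt_rev: int,
    config: FilterConfig = FilterConfig(),
) -> Tuple[bool, float]:
    """Fisher exact test on barcode strand counts; returns (pass, p_value).

    Fails only when the association is significant below the p-floor AND the
    alt forward:reverse ratio (0.5 continuity correction) is one-sided beyond
    ``strand_bias_min_ratio`` while the reference ratio in the same direction
    is not — a genuine variant sampled from both strands never trips this.
    """
    table = [[ref_fwd, ref_rev], [alt_fwd, alt_rev]]
    if ref_fwd + ref_rev + alt_fwd + alt_rev == 0:
        return True, 1.0  # nothing to test
    _, p = fisher_exact(table, alternative="two-sided")
    if p >= config.strand_bias_p_floor:
        return True, float(p)
    alt_ratio_f = (alt_fwd + 0.5) / (alt_rev + 0.5)
    ref_ratio_f = (ref_fwd + 0.5) / (ref_rev + 0.5)
    r = config.strand_bias_min_ratio
    biased = (alt_ratio_f >= r and ref_ratio_f < r) or (
        alt_ratio_f <= 1.0 / r and ref_ratio_f > 1.0 / r
    )
    return (not biased), float(p)


def _dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits) of overlapping dinucleotide frequencies."""
    pairs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    pairs = [p for p in pairs if all(c in "ACGT" for c in p)]
    if not pairs:
        return 0.0
    counts = Counter(pairs)
    total = sum(counts.values())
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def _homopolymer_hit(window: str, offset: int, max_run: int) -> bool:
    """Variant at ``offset`` inside or adjacent to a single-base run >= max_run."""
    i = 0
    n = len(window)
    while i < n:
        j = i
        while j < n and window[j] == window[i]:
            j += 1
        if j - i >= max_run and i - 1 <= offset <= j:
            return True
        i = j
    return False


def _repeat_coverage(seq: str, max_period: int) -> float:
    """Fraction of the window covered by tandem repeats of period 2..max_period.

    Exhaustive scan: for each period p, positions i with seq[i] == seq[i+p]
    form match runs; a run of length L >= p spans a repeat tract of L + p
    bases (at least two full periods), and those bases count as covered.
    """
    n = len(seq)
    if n == 0:
        return 0.0
    covered = [False] * n
    for p in range(2, max_period + 1):
        i = 0
        while i < n - p:
            if seq[i] == seq[i + p]:
                j = i
                while j < n - p and seq[j] == seq[j + p]:
                    j += 1
                # require a true tandem unit: homopolymer tracts (a single
                # distinct base) belong to the homopolymer filter instead
                if j - i >= p and len(set(seq[i : min(j + p, n)])) > 1:
                    for k in range(i, min(j + p, n)):
                        covered[k] = True
                i = j
            i += 1
    return sum(covered) / n


def region_context_filters(
    window: str,
    variant_offset: int,
    allele: str,
    config: FilterConfig = FilterConfig(),
) -> List[str]:
    """Sequence-context fail labels for a variant inside ``window``.

    ``window`` is the reference sequence around the locus (nominally
    +/- ``low_complexity_window`` bases; truncated windows at contig edges are
    evaluated as-is) and ``variant_offset`` the locus index within it.
    """
    window = window.upper()
    labels: List[str] = []
    if _homopolymer_hit(window, variant_offset, config.homopolymer_max_run):
        labels.append("Homopolymer")
    if _dinucleotide_entropy(window) < config.low_complexity_entropy_floor:
        labels.append("LowComplexity")
    if _repeat_coverage(window, config.repeat_max_period) >= config.repeat_min_coverage:
        labels.append("Repeat")
    return labels


def apply_filters(
    call: LocusCall,
    reference_window: Optional[str] = None,
    window_offset: Optional[int] = None,
    config: FilterConfig = FilterConfig(),
) -> LocusCall:
    """Annotate a candidate-bearing call with every failed post-filter label.

    FILTER is PASS (empty ``filters`` list) iff every post-filter passes for
    the best candidate allele; otherwise the sorted list of failed labels.
    Candidates are annotated, never deleted.
    """
    if not call.candidate_alleles:
        return call
    failed: set = set()
    best = call.best_candidate()
    ref = call.reference

    if not strong_barcode_filter(call, best, config):
        failed.add("StrongBarcode")

    ref_fwd, ref_rev = call.strand_counts.get(ref, (0, 0))
    alt_fwd, alt_rev = call.strand_counts.get(best, (0, 0))
    ok, _p = strand_bias_filter(ref_fwd, ref_rev, alt_fwd, alt_rev, config)
    if not ok:
        failed.add("StrandBias")

    if reference_window is not None:
        offset = window_offset if window_offset is not None else len(reference_window) // 2
        failed.update(region_context_filters(reference_window, offset, best, config))

    call.filters = sorted(failed)
    return call
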