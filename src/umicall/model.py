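"""Per-barcode Bayesian allele model and locus-level prediction index.

The evidence unit is the *barcode family*: all read pairs at one locus that
share a molecular barcode and therefore derive from a single original DNA
molecule.  For each family the likelihood of the observed base calls given a
true allele X is approximated as a weighted sum of two error channels:

* base-calling errors — every read disagreeing with X is an independent
  sequencing miscall with its Phred-derived probability, scaled by the
  probability ``c_p`` that a PCR error occurred at all;
* PCR errors — no base was miscalled, but a polymerase error during
  amplification produced the discordant reads; approximated heuristically by
  ``min over Y != X of 10**(-6*(0.5+n_Y)/sum_Z(0.5+n_Z))``.

Posteriors over the locus allele space (uniform prior) follow by Bayes rule,
and the locus-level *prediction index* of an allele is the sum over families
of ``-log10(1 - P(allele | family))`` — the log-scale probability that at
least one molecule truly carries the allele.  A non-reference allele whose
index exceeds a preselected threshold is a candidate variant.

All likelihood arithmetic is done in log space; the complement
``1 - P(allele|family)`` is computed directly from the log-likelihoods of the
competing alleles so that strong families do not lose precision to
cancellation.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "NUCLEOTIDES",
    "AlleleSpace",
    "ReadObservation",
    "BarcodeFamily",
    "ModelParams",
    "LocusCall",
    "phred_to_error",
    "likelihood_family_given_allele",
    "posterior_family",
    "barcode_evidence",
    "family_evidence_weights",
    "prediction_index",
    "call_locus",
]

NUCLEOTIDES = ("A", "C", "G", "T")

_LN10 = math.log(10.0)


def _allele_sort_key(allele: str) -> Tuple[int, str]:
    # A < C < G < T < indel tokens (by string), deterministic everywhere.
    if allele in NUCLEOTIDES:
        return (0, allele)
    return (1, allele)


@dataclass(frozen=True)
class AlleleSpace:
    """The ordered allele space Theta at one locus.

    Contains the nucleotides observed at the locus, every distinct observed
    indel allele, and always the reference allele.  The prior over Theta is
    uniform, ``1/|Theta|``.
    """

    alleles: Tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.alleles:
            raise ValueError(
                f"reference allele {self.reference!r} not in allele space"
            )
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError("duplicate alleles in allele space")

    @classmethod
    def from_observed(cls, reference: str, observed: Iterable[str]) -> "AlleleSpace":
        alleles = set(observed)
        alleles.add(reference)
        return cls(tuple(sorted(alleles, key=_allele_sort_key)), reference)

    @classmethod
    def full_snv(cls, reference: str) -> "AlleleSpace":
        """All four nucleotides; reference must be a nucleotide."""
        return cls(NUCLEOTIDES, reference)

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, allele: str) -> bool:
        return allele in self.alleles

    @property
    def prior(self) -> float:
        return 1.0 / len(self.alleles)

    @property
    def non_reference(self) -> Tuple[str, ...]:
        return tuple(a for a in self.alleles if a != self.reference)


@dataclass(frozen=True)
class ReadObservation:
    """One consolidated base/indel call of a read pair at a locus."""

    allele: str
    phred_q: int
    strand: str = "+"
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.phred_q < 0:
            raise ValueError(f"negative Phred quality: {self.phred_q}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def error_prob(self) -> float:
        return 10.0 ** (-self.phred_q / 10.0)


@dataclass
class BarcodeFamily:
    """All observations at one locus sharing one molecular barcode."""

    barcode: str
    observations: List[ReadObservation] = field(default_factory=list)

    @property
    def allele_counts(self) -> Counter:
        return Counter(obs.allele for obs in self.observations)

    def __len__(self) -> int:
        return len(self.observations)

    def composition_key(self) -> Tuple[Tuple[str, int], ...]:
        """Canonical (allele, phred) multiset — posteriors depend on nothing else."""
        return tuple(sorted((o.allele, o.phred_q) for o in self.observations))


@dataclass(frozen=True)
class ModelParams:
    """Tunable parameters of the barcode evidence model.

    ``alpha`` weighs the base-calling-error channel against the PCR-error
    channel (the posterior is invariant to alpha=0.5 vs an unweighted sum);
    ``c_p`` is the probability of a PCR error over the whole amplification,
    constructed as ``pcr_cycles * pcr_per_cycle_error``; ``posterior_clamp``
    floors ``1 - posterior`` so a single family can contribute at most
    ``-log10(clamp)`` (6 by default) index units.
    """

    alpha: float = 0.5
    c_p: float = 3e-5
    pcr_cycles: int = 30
    pcr_per_cycle_error: float = 1e-6
    pseudo_count: float = 0.5
    posterior_clamp: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 < self.posterior_clamp < 1.0:
            raise ValueError("posterior_clamp must lie in (0, 1)")


@dataclass
class LocusCall:
    """Per-allele evidence at one locus, ready for filtering and VCF output."""

    contig: str
    pos: int  # 1-based
    allele_space: AlleleSpace
    prediction_index: Dict[str, float]
    barcode_evidence: Dict[str, List[float]]
    n_barcodes: int
    candidate_alleles: List[str]
    filters: List[str] = field(default_factory=list)
    # bookkeeping for post-filters / VCF INFO
    read_depth: int = 0
    consensus_counts: Dict[str, int] = field(default_factory=dict)
    strand_counts: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    @property
    def reference(self) -> str:
        return self.allele_space.reference

    @property
    def rpb(self) -> float:
        return self.read_depth / self.n_barcodes if self.n_barcodes else 0.0

    def best_candidate(self) -> Optional[str]:
        if not self.candidate_alleles:
            return None
        return max(
            self.candidate_alleles,
            key=lambda a: (self.prediction_index[a], a),
        )


def phred_to_error(q: int) -> float:
    """Phred quality to base-calling error probability, ``10**(-q/10)``."""
    if q < 0:
        raise ValueError(f"Phred quality must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def _log_or_ninf(x: float) -> float:
    return math.log(x) if x > 0.0 else -math.inf


def _log_likelihood(
    family: BarcodeFamily,
    x: str,
    space: AlleleSpace,
    params: ModelParams,
    alpha: Optional[float] = None,
) -> float:
    """Natural-log likelihood of the family's observations given true allele x."""
    if alpha is None:
        alpha = params.alpha

    # base-calling-error channel
    log_a = -math.inf
    if alpha > 0.0:
        log_a = math.log(alpha) + math.log(params.c_p)
        for obs in family.observations:
            e = obs.error_prob
            log_a += _log_or_ninf(1.0 - e) if obs.allele == x else _log_or_ninf(e)

    # PCR-error channel
    log_b = -math.inf
    if alpha < 1.0:
        log_b = math.log(1.0 - alpha)
        for obs in family.observations:
            log_b += _log_or_ninf(1.0 - obs.error_prob)
        counts = family.allele_counts
        others = [a for a in space.alleles if a != x]
        if others:
            denom = params.pseudo_count * len(space) + len(family)
            n_max = max(counts.get(a, 0) for a in others)
            log_b += _LN10 * (-6.0 * (params.pseudo_count + n_max) / denom)
        # |Theta| == 1: no competing allele to attribute errors to; the PCR
        # term degenerates to the no-base-calling-error product alone.

    return np.logaddexp(log_a, log_b)


def likelihood_family_given_allele(
    family: BarcodeFamily,
    x: str,
    space: AlleleSpace,
    params: ModelParams = ModelParams(),
) -> float:
    """Likelihood P(family | true allele x): weighted sum of the two channels."""
    if x not in space:
        raise ValueError(f"allele {x!r} not in allele space {space.alleles}")
    if len(family) == 0:
        raise ValueError("cannot evaluate the likelihood of an empty family")
    return float(math.exp(_log_likelihood(family, x, space, params)))


def _log_likelihood_vector(
    family: BarcodeFamily, space: AlleleSpace, params: ModelParams
) -> np.ndarray:
    ll = np.array(
        [_log_likelihood(family, x, space, params) for x in space.alleles]
    )
    if np.all(np.isneginf(ll)):
        # Degenerate input (e.g. every allele contradicted by a Q0 read):
        # fall back to the uniform prior rather than returning NaN.
        return np.zeros(len(space.alleles))
    return ll


def posterior_family(
    family: BarcodeFamily,
    space: AlleleSpace,
    params: ModelParams = ModelParams(),
) -> Dict[str, float]:
    """Posterior P(X | family) over the allele space, uniform prior."""
    if len(family) == 0:
        raise ValueError("cannot evaluate posteriors of an empty family")
    ll = _log_likelihood_vector(family, space, params)
    m = ll.max()
    w = np.exp(ll - m)
    w /= w.sum()
    return dict(zip(space.alleles, w.tolist()))


def barcode_evidence(posterior: float, params: ModelParams = ModelParams()) -> float:
    """Evidence weight of one family: ``-log10(max(1 - posterior, clamp))``."""
    if not 0.0 <= posterior <= 1.0:
        raise ValueError(f"posterior must lie in [0, 1], got {posterior}")
    return -math.log10(max(1.0 - posterior, params.posterior_clamp))


def family_evidence_weights(
    family: BarcodeFamily,
    space: AlleleSpace,
    params: ModelParams = ModelParams(),
) -> Dict[str, float]:
    """Per-allele evidence weights of one family.

    Equivalent to ``barcode_evidence(posterior_family(...)[a])`` for every a,
    but computes ``1 - P(a | family)`` from the log-likelihoods of the
    competing alleles, which stays exact for families whose posterior is
    within double-precision epsilon of 1.
    """
    ll = _log_likelihood_vector(family, space, params)
    m = ll.max()
    w = np.exp(ll - m)
    total = w.sum()
    log10_clamp = math.log10(params.posterior_clamp)
    out: Dict[str, float] = {}
    for i, allele in enumerate(space.alleles):
        complement = total - w[i]
        if complement <= 0.0:
            log10_comp = -math.inf
        else:
            log10_comp = math.log10(complement / total)
        out[allele] = -max(log10_comp, log10_clamp)
    return out


def prediction_index(
    families: Sequence[BarcodeFamily],
    allele: str,
    space: AlleleSpace,
    params: ModelParams = ModelParams(),
) -> float:
    """Locus-level index I(allele) = sum over families of the evidence weights."""
    total = 0.0
    for fam in families:
        total += family_evidence_weights(fam, space, params)[allele]
    return total


def _consensus_allele(family: BarcodeFamily, reference: str) -> str:
    """Plurality allele of a family; ties resolved toward the reference,
    then by the deterministic allele order."""
    counts = family.allele_counts
    best = max(counts.values())
    top = sorted((a for a, c in counts.items() if c == best), key=_allele_sort_key)
    return reference if reference in top else top[0]


def call_locus(
    pileup,
    threshold: float,
    params: ModelParams = ModelParams(),
) -> LocusCall:
    """Score one locus pileup and nominate candidate variant alleles.

    ``pileup`` is a ``umicall.pileup.LocusPileup`` (duck-typed: needs
    ``contig``, ``pos``, ``ref`` and ``families``).  Candidates are the
    non-reference alleles whose prediction index reaches ``threshold``.
    Identical family compositions are scored once and cached.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    families = [f for f in pileup.families if len(f) > 0]
    observed = [o.allele for fam in families for o in fam.observations]
    space = AlleleSpace.from_observed(pileup.ref, observed)

    if not families:
        return LocusCall(
            contig=pileup.contig,
            pos=pileup.pos,
            allele_space=space,
            prediction_index={a: 0.0 for a in space.alleles},
            barcode_evidence={a: [] for a in space.alleles},
            n_barcodes=0,
            candidate_alleles=[],
            filters=["no-coverage"],
        )

    cache: Dict[Tuple, Dict[str, float]] = {}
    evidence: Dict[str, List[float]] = {a: [] for a in space.alleles}
    consensus_counts: Dict[str, int] = {a: 0 for a in space.alleles}
    strand_counts: Dict[str, List[int]] = {a: [0, 0] for a in space.alleles}
    read_depth = 0
    for fam in families:
        key = fam.composition_key()
        weights = cache.get(key)
        if weights is None:
            weights = family_evidence_weights(fam, space, params)
            cache[key] = weights
        for a, w in weights.items():
            evidence[a].append(w)
        cons = _consensus_allele(fam, space.reference)
        consensus_counts[cons] += 1
        fwd = sum(1 for o in fam.observations if o.strand == "+")
        strand_counts[cons][0 if 2 * fwd >= len(fam) else 1] += 1
        read_depth += len(fam)

    index = {a: float(sum(ws)) for a, ws in evidence.items()}
    candidates = sorted(
        (a for a in space.non_reference if index[a] >= threshold),
        key=_allele_sort_key,
    )
    return LocusCall(
        contig=pileup.contig,
        pos=pileup.pos,
        allele_space=space,
        prediction_index=index,
        barcode_evidence=evidence,
        n_barcodes=len(families),
        candidate_alleles=candidates,
        read_depth=read_depth,
        consensus_counts=consensus_counts,
        strand_counts={a: (c[0], c[1]) for a, c in strand_counts.items()},
    )
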