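"""Synthetic barcoded deep-sequencing data and caller evaluation.

Emulates the generative process of a single-primer barcoded amplicon run:

* per locus, the number of captured molecules (barcode families) is
  Poisson with the configured mean barcode depth D;
* each molecule carries the truth alternative allele with probability f
  (the allele fraction) — independently, a *first-cycle* polymerase error
  replaces its allele before barcoded amplification, so every read of the
  barcode inherits the error and consensus cannot correct it;
* each molecule yields a read-pair count drawn from the rpb distribution
  (``1 + Poisson(rpb - 1)`` by default, or constant);
* each read pair independently suffers a later-cycle PCR error
  (cycles x per-cycle rate) and a Phred-modelled base-calling error
  (``10**(-q/10)``), each replacing the base uniformly with one of the
  other three; strand is Bernoulli(0.5) per molecule.

Two sampling granularities produce the same distribution of barcode-family
compositions:

* :func:`simulate_pileups` — explicit read-level :class:`LocusPileup`
  objects, suitable for the full caller pipeline and fixture tables;
* :func:`simulate_locus_indices` — draws family *compositions* directly
  (pure-reference, single-error, multi-error, variant and first-cycle-error
  families) and scores them with evidence weights computed by the real
  Bayes model on explicitly constructed families, cached per composition.
  This makes megabase-scale wild-type false-positive scans run in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .filters import FilterConfig, strand_bias_filter
from .model import (
    AlleleSpace,
    BarcodeFamily,
    ModelParams,
    ReadObservation,
    family_evidence_weights,
    phred_to_error,
)
from .pileup import LocusPileup, _vcf_alleles

__all__ = [
    "SimConfig",
    "TruthVariant",
    "TruthSet",
    "random_reference",
    "simulate_truth",
    "simulate_pileups",
    "downsample_barcodes",
    "downsample_rpb",
    "evaluate_calls",
    "normalize_variant",
    "LocusScan",
    "simulate_locus_indices",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the simulator.

    Defaults follow the benchmarked cancer-panel run: mean barcode depth
    3612, mean read pairs per barcode 8.6, 30 PCR cycles at 1e-6 error per
    cycle per base, 1e-6 first-cycle (uncorrectable) error per base, constant
    Q30 base-calling quality, strands assigned Bernoulli(0.5) per molecule.
    """

    contig: str = "sim"
    region_length: int = 1000
    allele_fraction: float = 0.01
    mean_barcode_depth: float = 3612.0
    rpb_mean: float = 8.6
    rpb_distribution: str = "poisson"  # "poisson" (1 + Poisson(mean-1)) | "constant"
    first_cycle_error_rate: float = 1e-6
    later_cycle_error_rate: float = 1e-6
    pcr_cycles: int = 30
    phred_q: int = 30

    def __post_init__(self) -> None:
        for name in ("allele_fraction", "first_cycle_error_rate", "later_cycle_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_barcode_depth <= 0:
            raise ValueError("mean_barcode_depth must be positive")
        if self.rpb_mean < 1:
            raise ValueError("rpb_mean must be >= 1")
        if self.rpb_distribution not in ("poisson", "constant"):
            raise ValueError("rpb_distribution must be 'poisson' or 'constant'")

    @property
    def pcr_error_prob(self) -> float:
        """Per-read later-cycle PCR error probability."""
        return min(1.0, self.pcr_cycles * self.later_cycle_error_rate)

    @property
    def baseq_error_prob(self) -> float:
        return phred_to_error(self.phred_q)

    @property
    def read_error_prob(self) -> float:
        """Probability that a read shows a non-true allele.

        A read passes two error stages (PCR then base calling); a double
        error returns to the true base with probability 1/3.  Conditional on
        error, the shown allele is uniform over the other three bases by
        symmetry.
        """
        pcr, bq = self.pcr_error_prob, self.baseq_error_prob
        return 1.0 - ((1.0 - pcr) * (1.0 - bq) + pcr * bq / 3.0)


@dataclass(frozen=True)
class TruthVariant:
    pos: int  # 1-based
    ref: str  # reference base at the locus
    alt: str  # pileup-style token: base, +SEQ or -SEQ
    fraction: float


@dataclass
class TruthSet:
    """Ground-truth variants over a synthetic reference contig."""

    contig: str
    reference: str
    variants: List[TruthVariant] = field(default_factory=list)

    def by_pos(self) -> Dict[int, TruthVariant]:
        return {v.pos: v for v in self.variants}

    def to_vcf(self, path: str) -> None:
        import pysam

        header = pysam.VariantHeader()
        header.add_line("##fileformat=VCFv4.2")
        header.add_line("##source=umicall-simulate")
        header.add_meta("INFO", items=[("ID", "AF"), ("Number", "A"), ("Type", "Float"),
                                       ("Description", "Simulated allele fraction")])
        header.contigs.add(self.contig, length=len(self.reference))
        with pysam.VariantFile(path, "w", header=header) as out:
            for v in sorted(self.variants, key=lambda v: v.pos):
                ref, alt = _vcf_alleles(v.ref, v.alt)
                rec = out.new_record(
                    contig=self.contig, start=v.pos - 1, alleles=(ref, alt)
                )
                rec.info["AF"] = (v.fraction,)
                out.write(rec)


def random_reference(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _make_barcode(i: int, length: int = 12) -> str:
    """Deterministic unique barcode string over {A,C,G,T} (base-4 encoding)."""
    chars = []
    for _ in range(length):
        chars.append(_BASES[i % 4])
        i //= 4
    return "".join(chars)


def simulate_truth(
    config: SimConfig,
    n_snv: int,
    n_indel: int = 0,
    min_spacing: int = 50,
    max_indel_len: int = 10,
    seed: int = 0,
) -> TruthSet:
    """Place SNVs and short indels uniformly over the region at the
    configured allele fraction; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    reference = random_reference(config.region_length, rng)
    n_total = n_snv + n_indel
    if n_total == 0:
        return TruthSet(contig=config.contig, reference=reference)
    # leave room for deletion alleles at the right edge
    usable = config.region_length - max_indel_len - 1
    if usable < n_total * min_spacing:
        raise ValueError(
            f"region of {config.region_length} bp cannot hold {n_total} variants "
            f"at spacing {min_spacing}"
        )
    # one variant per spacing-sized slot keeps the spacing guarantee exact
    n_slots = usable // min_spacing
    slots = rng.choice(n_slots, size=n_total, replace=False)
    kinds = np.array(["snv"] * n_snv + ["indel"] * n_indel)
    rng.shuffle(kinds)
    variants: List[TruthVariant] = []
    for slot, kind in zip(sorted(slots), kinds):
        pos = int(slot) * min_spacing + 1  # 1-based
        ref_base = reference[pos - 1]
        if kind == "snv":
            alt = str(rng.choice([b for b in _BASES if b != ref_base]))
        else:
            ln = int(rng.integers(1, max_indel_len + 1))
            if rng.random() < 0.5:
                alt = "+" + "".join(rng.choice(list(_BASES), size=ln))
            else:
                alt = "-" + reference[pos : pos + ln]
        variants.append(
            TruthVariant(pos=pos, ref=ref_base, alt=alt, fraction=config.allele_fraction)
        )
    return TruthSet(contig=config.contig, reference=reference, variants=variants)


def _draw_rpb(config: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    if config.rpb_distribution == "constant":
        return np.full(size, max(1, round(config.rpb_mean)), dtype=np.int64)
    return 1 + rng.poisson(config.rpb_mean - 1.0, size=size)


def _read_allele(true_allele: str, config: SimConfig, rng: np.random.Generator) -> str:
    """Two-stage per-read error process (later-cycle PCR, then base calling).

    Substitution errors act on base alleles; indel alleles pass through
    unchanged (a substitution inside an indel read does not change the
    indel call at the locus).
    """
    allele = true_allele
    if allele in _BASES and rng.random() < config.pcr_error_prob:
        allele = str(rng.choice([b for b in _BASES if b != allele]))
    if allele in _BASES and rng.random() < config.baseq_error_prob:
        allele = str(rng.choice([b for b in _BASES if b != allele]))
    return allele


def _simulate_family(
    barcode: str,
    ref: str,
    alt: Optional[str],
    f: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> BarcodeFamily:
    true_allele = ref
    if alt is not None and rng.random() < f:
        true_allele = alt
    if true_allele in _BASES and rng.random() < config.first_cycle_error_rate:
        true_allele = str(rng.choice([b for b in _BASES if b != true_allele]))
    n_reads = int(_draw_rpb(config, rng, 1)[0])
    strand = "+" if rng.random() < 0.5 else "-"
    fam = BarcodeFamily(barcode=barcode)
    for r in range(n_reads):
        fam.observations.append(
            ReadObservation(
                allele=_read_allele(true_allele, config, rng),
                phred_q=config.phred_q,
                strand=strand,
                pair_id=f"{barcode}.{r}",
            )
        )
    return fam


def simulate_pileups(
    truth: TruthSet,
    config: SimConfig,
    positions: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> List[LocusPileup]:
    """Read-level pileups at the given 1-based positions (default: the whole
    region).  Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    truth_map = truth.by_pos()
    if positions is None:
        positions = range(1, config.region_length + 1)
    pileups: List[LocusPileup] = []
    bc_counter = 0
    for pos in positions:
        ref = truth.reference[pos - 1]
        variant = truth_map.get(pos)
        n_mol = int(rng.poisson(config.mean_barcode_depth))
        families = []
        for _ in range(n_mol):
            fam = _simulate_family(
                _make_barcode(bc_counter),
                ref,
                variant.alt if variant else None,
                variant.fraction if variant else 0.0,
                config,
                rng,
            )
            bc_counter += 1
            families.append(fam)
        pileups.append(
            LocusPileup(contig=truth.contig, pos=pos, ref=ref, families=families)
        )
    return pileups


def downsample_barcodes(
    pileups: Iterable[LocusPileup], fraction: float, seed: int = 0
) -> List[LocusPileup]:
    """Bernoulli thinning of whole families; families are never split."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for pu in pileups:
        kept = (
            list(pu.families)
            if fraction == 1.0
            else [f for f in pu.families if rng.random() < fraction]
        )
        out.append(LocusPileup(contig=pu.contig, pos=pu.pos, ref=pu.ref, families=kept))
    return out


def downsample_rpb(
    pileups: Sequence[LocusPileup], target_rpb: float, seed: int = 0
) -> List[LocusPileup]:
    """Subsample read pairs within families to a target mean rpb, floor 1.

    Each read pair is kept with probability p; an emptied family keeps one
    random read pair instead.  p solves
    ``mean_i [ n_i * p + (1 - p)^n_i ] = target`` on the observed family
    sizes, so the expected mean lands on the target despite the floor.
    """
    sizes = np.array([len(f) for pu in pileups for f in pu.families], dtype=float)
    if sizes.size == 0:
        return list(pileups)
    current = sizes.mean()
    if target_rpb < 1.0 or target_rpb > current + 1e-9:
        raise ValueError(
            f"target rpb {target_rpb} outside [1, current mean {current:.3f}]"
        )

    def expected_mean(p: float) -> float:
        return float(np.mean(sizes * p + (1.0 - p) ** sizes))

    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if expected_mean(mid) < target_rpb:
            lo = mid
        else:
            hi = mid
    p = (lo + hi) / 2.0

    rng = np.random.default_rng(seed)
    out = []
    for pu in pileups:
        new_fams = []
        for fam in pu.families:
            keep = [o for o in fam.observations if rng.random() < p]
            if not keep:
                keep = [fam.observations[int(rng.integers(len(fam.observations)))]]
            new_fams.append(BarcodeFamily(barcode=fam.barcode, observations=keep))
        out.append(
            LocusPileup(contig=pu.contig, pos=pu.pos, ref=pu.ref, families=new_fams)
        )
    return out


def normalize_variant(contig: str, pos: int, ref: str, alt: str) -> Tuple[str, int, str, str]:
    """Trim shared suffix then shared prefix (keeping one anchor base)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return contig, pos, ref, alt


def evaluate_calls(
    calls_vcf: str,
    truth_vcf: str,
    target_size: int,
    thresholds: Optional[Sequence[float]] = None,
    require_pass: bool = True,
) -> pd.DataFrame:
    """Sensitivity / FP-per-Mb / PPV of a call set against a truth set.

    Variants match on normalized (contig, pos, ref, alt).  One row per swept
    prediction-index threshold (calls with QUAL >= threshold count).
    """
    import pysam

    if target_size <= 0:
        raise ValueError("target_size must be positive")

    def load(path: str, with_qual: bool):
        out = []
        with pysam.VariantFile(path) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    key = normalize_variant(rec.contig, rec.pos, rec.ref, alt)
                    qual = rec.qual if rec.qual is not None else 0.0
                    filters = list(rec.filter.keys())
                    passing = not filters or filters == ["PASS"]
                    out.append((key, qual, passing))
        return out

    truth_keys = {key for key, _, _ in load(truth_vcf, False)}
    calls = load(calls_vcf, True)
    if require_pass:
        calls = [c for c in calls if c[2]]
    if thresholds is None:
        thresholds = [0.0]

    rows = []
    for t in thresholds:
        called = {key for key, qual, _ in calls if qual >= t}
        tp = len(called & truth_keys)
        fp = len(called - truth_keys)
        fn = len(truth_keys - called)
        rows.append(
            {
                "threshold": t,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
                "fp_per_mb": fp * 1e6 / target_size,
                "ppv": tp / (tp + fp) if tp + fp else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Composition-level fast path
# --------------------------------------------------------------------------

class _WeightTables:
    """Evidence weights for the recurring family compositions.

    Every weight is computed by the real model on an explicitly constructed
    family; tables are keyed by the locus allele-space size t (the reference
    plus the distinct non-reference alleles observed at the locus).

    ``w0[t][n]`` — weight of a non-reference allele given a family of n
    pure-reference reads; ``w1[t][n]`` — weight of allele a given a family
    of n-1 reference reads and one a read; ``wx[t][n]`` — weight of a
    *different* non-reference allele given that same family.
    """

    _LABELS = ("A", "C", "G")  # non-reference slots; reference is "T"

    def __init__(self, n_cap: int, q: int, params: ModelParams):
        self.n_cap = n_cap
        self.q = q
        self.params = params
        self.w0: Dict[int, np.ndarray] = {}
        self.w1: Dict[int, np.ndarray] = {}
        self.wx: Dict[int, np.ndarray] = {}
        self._comp_cache: Dict[Tuple, Dict[int, float]] = {}

    def _space(self, t: int) -> AlleleSpace:
        alleles = tuple(sorted(self._LABELS[: t - 1] + ("T",)))
        return AlleleSpace(alleles, "T")

    def _family(self, counts: Dict[str, int]) -> BarcodeFamily:
        fam = BarcodeFamily(barcode="BC")
        for allele, c in counts.items():
            for _ in range(c):
                fam.observations.append(ReadObservation(allele=allele, phred_q=self.q))
        return fam

    def ensure(self, t: int) -> None:
        if t in self.w0 or t < 2:
            return
        space = self._space(t)
        w0 = np.zeros(self.n_cap + 1)
        w1 = np.zeros(self.n_cap + 1)
        wx = np.zeros(self.n_cap + 1)
        for n in range(1, self.n_cap + 1):
            pure = family_evidence_weights(self._family({"T": n}), space, self.params)
            w0[n] = pure["A"]
            single = family_evidence_weights(
                self._family({"T": n - 1, "A": 1}), space, self.params
            )
            w1[n] = single["A"]
            wx[n] = single["C"] if t >= 3 else 0.0
        self.w0[t], self.w1[t], self.wx[t] = w0, w1, wx

    def family_weights(self, t: int, c_ref: int, nonref: Sequence[int]) -> Dict[int, float]:
        """Weights of the non-reference alleles of an arbitrary composition,
        keyed by each allele's read count (equal counts => equal weights).

        ``nonref`` lists the family's read counts of the locus's t-1
        non-reference alleles (zeros included).
        """
        key = (t, c_ref, tuple(sorted(nonref, reverse=True)))
        cached = self._comp_cache.get(key)
        if cached is None:
            space = self._space(t)
            counts: Dict[str, int] = {"T": c_ref}
            for label, c in zip(self._LABELS, key[2]):
                counts[label] = c
            weights = family_evidence_weights(self._family(counts), space, self.params)
            cached = {}
            for label, c in zip(self._LABELS, key[2]):
                cached[c] = weights[label]
            self._comp_cache[key] = cached
        return cached


@dataclass
class LocusScan:
    """Vectorized per-locus result of a composition-level simulation run.

    Allele slot 0 is the designated truth alternative (meaningful when the
    simulated allele fraction is positive); slots 1-2 are the other two
    non-reference bases.  ``index[l, a]`` is the prediction index, zero for
    alleles absent from the locus allele space.
    """

    index: np.ndarray          # (n_loci, 3)
    strong: np.ndarray         # (n_loci, 3) barcodes with weight >= tau
    cons_alt: np.ndarray       # (n_loci, 3) families whose consensus is the allele
    n_barcodes: np.ndarray     # (n_loci,)
    alt_families: np.ndarray   # (n_loci,) molecules truly carrying the alt
    config: SimConfig
    params: ModelParams
    strong_tau: float

    def candidates(self, threshold: float) -> np.ndarray:
        """Boolean (n_loci, 3): allele prediction index reaches threshold."""
        return self.index >= threshold

    def passing(
        self,
        threshold: float,
        filter_config: Optional[FilterConfig] = None,
        seed: int = 0,
    ) -> np.ndarray:
        """Candidates surviving the strong-barcode and strand-bias filters.

        Family strands are Bernoulli(0.5) per molecule; strand counts are
        drawn here only for candidate loci (the filters need them nowhere
        else).
        """
        cfg = filter_config or FilterConfig()
        if cfg.strong_barcode_min_evidence != self.strong_tau:
            raise ValueError(
                "strong-barcode tau of the scan and the filter config differ"
            )
        cand = self.candidates(threshold)
        out = np.zeros_like(cand)
        rng = np.random.default_rng(seed)
        for l, a in zip(*np.nonzero(cand)):
            if self.strong[l, a] < cfg.strong_barcode_min_count:
                continue
            n_alt = int(self.cons_alt[l, a])
            n_ref = max(int(self.n_barcodes[l]) - int(self.cons_alt[l].sum()), 0)
            alt_fwd = int(rng.binomial(n_alt, 0.5))
            ref_fwd = int(rng.binomial(n_ref, 0.5))
            ok, _ = strand_bias_filter(
                ref_fwd, n_ref - ref_fwd, alt_fwd, n_alt - alt_fwd, cfg
            )
            if ok:
                out[l, a] = True
        return out


def _rpb_pmf(config: SimConfig) -> Tuple[np.ndarray, int]:
    """Truncated, renormalized pmf of the family-size distribution (index =
    family size; entry 0 is zero)."""
    if config.rpb_distribution == "constant":
        n = max(1, round(config.rpb_mean))
        pmf = np.zeros(n + 1)
        pmf[n] = 1.0
        return pmf, n
    mu = config.rpb_mean - 1.0
    n_cap = int(poisson.ppf(1.0 - 1e-12, mu)) + 2 if mu > 0 else 1
    pmf = np.zeros(n_cap + 1)
    pmf[1:] = poisson.pmf(np.arange(0, n_cap), mu)
    pmf /= pmf.sum()
    return pmf, n_cap


def simulate_locus_indices(
    n_loci: int,
    config: SimConfig,
    params: ModelParams = ModelParams(),
    strong_tau: float = 2.0,
    seed: int = 0,
    batch_size: int = 100_000,
) -> LocusScan:
    """Simulate and score ``n_loci`` independent loci at the composition level.

    Every locus carries a (potential) variant at ``config.allele_fraction``
    on allele slot 0; set the fraction to 0 for wild-type loci.  The sampling
    distributions are identical to :func:`simulate_pileups`; only the
    granularity differs (family compositions instead of individual reads).
    """
    rng = np.random.default_rng(seed)
    pmf, n_cap = _rpb_pmf(config)
    q_err = config.read_error_prob
    tables = _WeightTables(n_cap=n_cap, q=config.phred_q, params=params)
    f = config.allele_fraction
    fc = config.first_cycle_error_rate

    index = np.zeros((n_loci, 3))
    strong = np.zeros((n_loci, 3), dtype=np.int64)
    cons_alt = np.zeros((n_loci, 3), dtype=np.int64)
    n_barcodes = np.zeros(n_loci, dtype=np.int64)
    alt_families = np.zeros(n_loci, dtype=np.int64)

    # probability of a multi-error family conditional on family size
    p_pure_n = pmf * (1.0 - q_err) ** np.arange(len(pmf))
    p_single_n = pmf * np.arange(len(pmf)) * q_err * (1.0 - q_err) ** np.maximum(
        np.arange(len(pmf)) - 1, 0
    )
    p_multi_total = max(1.0 - p_pure_n.sum() - p_single_n.sum(), 0.0)
    # conditional (n, j>=2) distribution for multi-error families
    multi_pairs: List[Tuple[int, int]] = []
    multi_probs: List[float] = []
    if p_multi_total > 0:
        from scipy.stats import binom as _binom

        for n in range(2, len(pmf)):
            if pmf[n] == 0:
                continue
            for j in range(2, n + 1):
                p = pmf[n] * float(_binom.pmf(j, n, q_err))
                if p > 0:
                    multi_pairs.append((n, j))
                    multi_probs.append(p)
        multi_probs_arr = np.array(multi_probs)
        multi_probs_arr /= multi_probs_arr.sum()

    for start in range(0, n_loci, batch_size):
        stop = min(start + batch_size, n_loci)
        B = stop - start
        N = rng.poisson(config.mean_barcode_depth, size=B)
        n_barcodes[start:stop] = N
        n_alt = rng.binomial(N, f) if f > 0 else np.zeros(B, dtype=np.int64)
        alt_families[start:stop] = n_alt
        n_fc = rng.binomial(N - n_alt, fc) if fc > 0 else np.zeros(B, dtype=np.int64)
        rem = N - n_alt - n_fc

        # distribute the remaining (pure-reference-molecule) families over
        # (pure, n) and (single, n) cells by a conditional-binomial chain
        pure_cnt = np.zeros((B, len(pmf)), dtype=np.int32)
        single_cnt = np.zeros((B, len(pmf), 3), dtype=np.int32)
        remaining = rem.copy()
        restmass = 1.0
        for n in range(1, len(pmf)):
            for p_cell, target in ((p_pure_n[n], "pure"), (p_single_n[n], "single")):
                if p_cell <= 0 or restmass <= 0:
                    continue
                frac = min(p_cell / restmass, 1.0)
                c = rng.binomial(remaining, frac)
                remaining -= c
                restmass -= p_cell
                if target == "pure":
                    pure_cnt[:, n] = c
                else:
                    s1 = rng.binomial(c, 1.0 / 3.0)
                    s2 = rng.binomial(c - s1, 0.5)
                    single_cnt[:, n, 0] = s1
                    single_cnt[:, n, 1] = s2
                    single_cnt[:, n, 2] = c - s1 - s2
        n_multi = remaining  # whatever is left is a multi-error family

        # explicit rare families: (locus, counts over [ref, a0, a1, a2])
        loop_fams: List[Tuple[int, np.ndarray]] = []

        def _two_stage_counts(n: int, true_slot: int) -> np.ndarray:
            """Counts over [ref, a0, a1, a2] for an n-read family whose
            molecule carries the allele in ``true_slot`` (0 = ref)."""
            c = np.zeros(4, dtype=np.int64)
            j = int(rng.binomial(n, q_err))
            c[true_slot] = n - j
            others = [s for s in range(4) if s != true_slot]
            if j:
                spread = rng.multinomial(j, [1 / 3] * 3)
                for s, k in zip(others, spread):
                    c[s] += k
            return c

        has_rare = np.nonzero(n_alt + n_fc + n_multi)[0]
        for l in has_rare:
            l = int(l)
            for _ in range(int(n_alt[l])):
                # truth molecule on slot 1 (allele 0 of the output arrays);
                # first-cycle errors on alt molecules are possible but
                # vanishingly rare — applied for fidelity
                slot = 1
                if fc > 0 and rng.random() < fc:
                    slot = int(rng.choice([s for s in range(4) if s != slot]))
                n = int(rng.choice(len(pmf), p=pmf))
                loop_fams.append((l, _two_stage_counts(n, slot)))
            for _ in range(int(n_fc[l])):
                slot = int(rng.integers(1, 4))
                n = int(rng.choice(len(pmf), p=pmf))
                loop_fams.append((l, _two_stage_counts(n, slot)))
            if p_multi_total > 0:
                for _ in range(int(n_multi[l])):
                    n, j = multi_pairs[int(rng.choice(len(multi_pairs), p=multi_probs_arr))]
                    c = np.zeros(4, dtype=np.int64)
                    c[0] = n - j
                    spread = rng.multinomial(j, [1 / 3] * 3)
                    c[1:] = spread
                    loop_fams.append((l, c))

        # which non-reference alleles exist at each locus
        present = single_cnt.sum(axis=1) > 0  # (B, 3)
        for l, c in loop_fams:
            present[l] |= c[1:] > 0
        t_arr = 1 + present.sum(axis=1)

        # vectorized contributions of pure and single-error families
        for t in np.unique(t_arr):
            t = int(t)
            if t < 2:
                continue
            tables.ensure(t)
            mask = t_arr == t
            pure_part = pure_cnt[mask] @ tables.w0[t]
            s = single_cnt[mask]
            s_tot = s.sum(axis=2)
            for a in range(3):
                own_a = s[:, :, a] @ tables.w1[t]
                cross_a = (s_tot - s[:, :, a]) @ tables.wx[t]
                contrib = pure_part + own_a + cross_a
                rows = np.nonzero(mask)[0] + start
                index[rows, a] += np.where(present[mask, a], contrib, 0.0)
                strong_n = tables.w1[t] >= strong_tau
                if strong_n.any():
                    strong[rows, a] += s[:, :, a] @ strong_n.astype(np.int64)
            # single-read families have their own allele as consensus
            for a in range(3):
                rows = np.nonzero(mask)[0] + start
                cons_alt[rows, a] += s[:, 1, a]

        # rare-family contributions through the composition cache
        for l, c in loop_fams:
            t = int(t_arr[l])
            if t < 2:
                continue
            tables.ensure(t)
            nonref_full = c[1:]
            present_l = present[l]
            counts_for_space = [int(nonref_full[a]) for a in range(3) if present_l[a]]
            weights_by_count = tables.family_weights(
                t, int(c[0]), counts_for_space
            )
            row = start + l
            for a in range(3):
                if not present_l[a]:
                    continue
                w = weights_by_count[int(nonref_full[a])]
                index[row, a] += w
                if w >= strong_tau:
                    strong[row, a] += 1
            # family consensus: plurality allele, ties toward the reference
            top = int(c.max())
            winners = [s for s in range(4) if c[s] == top]
            if len(winners) == 1 and winners[0] != 0:
                cons_alt[row, winners[0] - 1] += 1

    return LocusScan(
        index=index,
        strong=strong,
        cons_alt=cons_alt,
        n_barcodes=n_barcodes,
        alt_families=alt_families,
        config=config,
        params=params,
        strong_tau=strong_tau,
    )
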