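import numpy as np
import pytest

from umicall.model import AlleleSpace, BarcodeFamily, ModelParams, ReadObservation


@pytest.fixture
def snv_space():
    """All four nucleotides, reference T."""
    return AlleleSpace.full_snv("T")


@pytest.fixture
def params():
    return ModelParams()


def make_family(barcode="BC", **allele_reads):
    """make_family(A=[(30, 3)], T=[(30, 5)]) -> 3 A reads and 5 T reads at Q30."""
    obs = []
    i = 0
    for allele, specs in allele_reads.items():
        for q, n in specs:
            for _ in range(n):
                obs.append(
                    ReadObservation(allele=allele, phred_q=q, pair_id=f"p{i}")
                )
                i += 1
    return BarcodeFamily(barcode=barcode, observations=obs)


def naive_likelihood(observations, x, alleles, alpha=0.5, c_p=3e-5, pseudo=0.5):
    """Direct-product evaluation of the two-channel family likelihood.

    Independent of the package's log-space implementation: plain floating
    arithmetic straight from the formula.  ``observations`` is a list of
    (allele, phred_q) pairs.
    """
    e = lambda q: 10.0 ** (-q / 10.0)
    term_a = alpha * c_p
    for a, q in observations:
        term_a *= (1.0 - e(q)) if a == x else e(q)
    no_miscall = 1.0
    for _, q in observations:
        no_miscall *= 1.0 - e(q)
    counts = {al: 0 for al in alleles}
    for a, _ in observations:
        counts[a] += 1
    denom = pseudo * len(alleles) + len(observations)
    pcr = min(
        10.0 ** (-6.0 * (pseudo + counts[y]) / denom) for y in alleles if y != x
    )
    term_b = (1.0 - alpha) * no_miscall * pcr
    return term_a + term_b


def naive_posteriors(observations, alleles, **kw):
    like = {x: naive_likelihood(observations, x, alleles, **kw) for x in alleles}
    total = sum(like.values())
    return {x: v / total for x, v in like.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
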