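"""Forced genotyping: per-site genotype likelihoods at every panel position.

Forced genotyping evaluates P(reads | g) for g in {0, 1, 2} at a fixed,
pre-specified site list regardless of local evidence -- essential at 0.25x
where most sites have zero or one read.  The model is a symmetric
single-parameter error model: a read from a genotype-g individual shows the
alt allele with probability (g/2)(1-eps) + (1-g/2)eps.  Likelihood triples
are normalized per site; downstream use as HMM emission factors is
invariant to per-site scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cfdna import Pileups

GENOTYPE_ALT_PROB = np.array([0.0, 0.5, 1.0])  # P(read shows alt | g), before error


@dataclass
class LikelihoodMatrix:
    """Normalized per-site genotype likelihood triples plus read depth.

    ``lik`` has shape (n_sites, 3) with rows summing to 1; a zero-depth site
    carries the uninformative triple (1/3, 1/3, 1/3).
    """

    lik: np.ndarray
    depth: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.lik.shape[0]

    def validate(self, tol: float = 1e-12) -> None:
        if np.any(self.lik < 0):
            raise ValueError("likelihoods must be non-negative")
        if not np.allclose(self.lik.sum(axis=1), 1.0, atol=tol):
            raise ValueError("likelihood triples must sum to 1")


def genotype_likelihoods(pileups: Pileups, error_rate: float) -> LikelihoodMatrix:
    """Compute normalized genotype likelihoods at every forced position.

    With n alt reads and m ref reads at a site, L(g) = p_g^n (1-p_g)^m with
    p_g = (g/2)(1-eps) + (1-g/2)eps, then normalized.  Computed in log space
    so 30x sites do not underflow.
    """
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    depth = pileups.depth()
    n_alt = pileups.alt_counts()
    n_ref = depth - n_alt

    p = GENOTYPE_ALT_PROB * (1 - error_rate) + (1 - GENOTYPE_ALT_PROB) * error_rate
    with np.errstate(divide="ignore"):
        log_p, log_q = np.log(p), np.log1p(-p)
    # 0 * log(0) is a legal "no observation" term, not NaN
    alt_term = np.where(n_alt[:, None] > 0, n_alt[:, None] * log_p[None, :], 0.0)
    ref_term = np.where(n_ref[:, None] > 0, n_ref[:, None] * log_q[None, :], 0.0)
    loglik = alt_term + ref_term
    # eps=0 with both alleles observed gives -inf for the impossible homozygote
    loglik -= loglik.max(axis=1, keepdims=True)
    lik = np.exp(loglik)
    lik /= lik.sum(axis=1, keepdims=True)
    return LikelihoodMatrix(lik=lik, depth=depth)


def call_genotypes(
    lik: LikelihoodMatrix, min_depth: int = 4, uniform_tol: float = 1e-9
) -> np.ndarray:
    """Hard genotype calls (argmax likelihood) as float with NaN = missing.

    A site is missing when depth < ``min_depth`` or the triple is uniform
    (no information).  Used for the high-coverage, non-imputed arm.
    """
    calls = lik.lik.argmax(axis=1).astype(np.float64)
    uniform = np.ptp(lik.lik, axis=1) < uniform_tol
    calls[(lik.depth < min_depth) | uniform] = np.nan
    return calls
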