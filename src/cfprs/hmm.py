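"""Diploid Li-Stephens haplotype-copying imputation.

The maternal genome is modelled as an ordered pair of imperfect mosaics of
the reference panel: the hidden state at each site is a pair (h1, h2) of
panel haplotypes (K^2 states).  Between adjacent sites each copied
haplotype independently switches template with probability
r = 1 - exp(-n_eff * d_cM / K), landing uniformly on any of the K
haplotypes; at a site the copied allele miscopies with probability mu, and
the genotype implied by the pair is scored against the forced-genotyping
likelihood triple.  A single scaled forward-backward pass yields per-site
posterior genotype distributions; the dosage is their mean.

The model deliberately assumes a *pure* diploid maternal sample: fetal
reads in a cfDNA mixture are unmodelled, which is exactly the confounder
whose impact the experiments quantify.

The K^2 recursion is exact -- no state pruning and no pre-phasing.  By
default the panel is first collapsed to a copying subset of the 60
haplotypes sharing the most alleles with the observed reads, which keeps
the cost at roughly K_sub^2 * L * 2 emission updates; full-panel mode is
``panel_subset=None``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .genolik import LikelihoodMatrix
from .panel import HaplotypePanel


@dataclass
class HmmParams:
    """Copying-model parameters.

    ``n_eff`` scales the per-cM switch probability (dimensionless effective
    recombination intensity); ``copy_error`` is the allele miscopy
    probability mu; ``panel_subset`` the copying-subset size (None = full
    panel).
    """

    n_eff: float = 4.0
    copy_error: float = 1e-3
    panel_subset: int | None = 60
    min_posterior_floor: float = 1e-300

    def __post_init__(self) -> None:
        if not 0 < self.copy_error < 0.5:
            raise ValueError("copy_error must be in (0, 0.5)")
        if self.n_eff <= 0:
            raise ValueError("n_eff must be > 0")


@dataclass
class DosageVector:
    """Imputation output: expected alt-allele dosage and genotype posteriors."""

    dosage: np.ndarray          # E[g] in [0, 2] per site
    posterior: np.ndarray       # (L, 3) genotype posterior per site
    hard_genotype: np.ndarray   # argmax posterior, int8
    max_posterior: np.ndarray   # per-site max posterior probability

    @property
    def n_sites(self) -> int:
        return self.dosage.size


def genotype_given_pair(copy_error: float) -> np.ndarray:
    """P(g | a1, a2, mu) as an array [g, a1, a2].

    Each copied allele is its template's allele flipped independently with
    probability mu; g is the sum of the two copies.
    """
    mu = copy_error
    p = np.array([mu, 1 - mu])  # P(copied allele = 1 | template allele a)
    out = np.empty((3, 2, 2))
    for a1 in (0, 1):
        for a2 in (0, 1):
            p1, p2 = p[a1], p[a2]
            out[0, a1, a2] = (1 - p1) * (1 - p2)
            out[1, a1, a2] = p1 * (1 - p2) + (1 - p1) * p2
            out[2, a1, a2] = p1 * p2
    return out


def switch_probabilities(cm_positions: np.ndarray, n_eff: float, K: int) -> np.ndarray:
    """Per-interval template switch probability r = 1 - exp(-n_eff * dcM / K)."""
    d = np.diff(cm_positions)
    return 1.0 - np.exp(-n_eff * d / K)


def select_copying_subset(
    lik: LikelihoodMatrix, panel: HaplotypePanel, k_sub: int, n_windows: int = 10
) -> np.ndarray:
    """Indices of ``k_sub`` panel haplotypes sharing most alleles with the reads.

    Selection is windowed so that haplotypes matching the target only over a
    short segment are still captured: the genetic map is cut into
    ``n_windows`` equal windows, each informative site contributes its naive
    expected alt fraction e = (L1 + 2 L2) / 2, a haplotype's window score
    sums e where it carries alt and 1 - e where it carries ref, and the
    per-window top scorers are pooled.  The pool is trimmed (by total score)
    or topped up (by next-best total score) to exactly ``k_sub``; ties break
    by panel order.
    """
    K = panel.n_haplotypes
    if k_sub >= K:
        return np.arange(K)
    informative = lik.depth > 0
    e = lik.lik[:, 1] * 0.5 + lik.lik[:, 2]
    H = panel.haplotypes.astype(np.float64)
    cm = panel.cm_positions
    edges = np.linspace(cm[0], cm[-1] + 1e-9, n_windows + 1)
    window = np.clip(np.searchsorted(edges, cm, side="right") - 1, 0, n_windows - 1)
    per_window = max(1, int(np.ceil(k_sub / n_windows)))
    total_score = np.zeros(K)
    chosen = []
    for w in range(n_windows):
        m = (window == w) & informative
        if not m.any():
            continue
        score = H[:, m] @ e[m] + (1 - H[:, m]) @ (1 - e[m])
        total_score += score
        chosen.append(np.argsort(-score, kind="stable")[:per_window])
    sel = np.unique(np.concatenate(chosen)) if chosen else np.arange(k_sub)
    if sel.size > k_sub:
        sel = sel[np.argsort(-total_score[sel], kind="stable")[:k_sub]]
    elif sel.size < k_sub:
        remaining = np.setdiff1d(np.argsort(-total_score, kind="stable"), sel,
                                 assume_unique=False)
        order = np.argsort(-total_score[remaining], kind="stable")
        sel = np.concatenate([sel, remaining[order][: k_sub - sel.size]])
    return np.sort(sel)


@njit(cache=True, fastmath=True)
def _transition(M, r, K):
    """Apply A M A^T in place-free form, A = (1-r) I + (r/K) 11^T."""
    q = 1.0 - r
    out = np.empty_like(M)
    # left multiply: rows mix over first haplotype
    for j in range(K):
        col = 0.0
        for i in range(K):
            col += M[i, j]
        col *= r / K
        for i in range(K):
            out[i, j] = q * M[i, j] + col
    # right multiply: columns mix over second haplotype
    for i in range(K):
        row = 0.0
        for j in range(K):
            row += out[i, j]
        row *= r / K
        for j in range(K):
            out[i, j] = q * out[i, j] + row
    return out


@njit(cache=True, fastmath=True)
def _fb_pair_class_posteriors(H, e2, r):
    """Scaled forward-backward over the K^2 pair states.

    H: (K, L) uint8 panel alleles; e2: (L, 2, 2) emission by allele pair;
    r: (L-1,) switch probabilities.  Returns w: (L, 2, 2), the posterior
    probability mass on states whose template alleles at the site are
    (a1, a2).  Collapsing states to their allele pair is lossless for
    genotype posteriors because the emission depends on the state only
    through its allele pair.
    """
    K, L = H.shape
    alpha = np.empty((L, K, K))

    # forward
    cur = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            cur[i, j] = e2[0, H[i, 0], H[j, 0]]
    cur /= cur.sum()
    alpha[0] = cur
    for s in range(1, L):
        cur = _transition(alpha[s - 1], r[s - 1], K)
        for i in range(K):
            for j in range(K):
                cur[i, j] *= e2[s, H[i, s], H[j, s]]
        tot = cur.sum()
        if tot <= 0.0:
            # fully contradictory site under underflow; reset to uniform
            cur[:] = 1.0 / (K * K)
        else:
            cur /= tot
        alpha[s] = cur

    # backward, accumulating allele-pair class posteriors on the fly
    w = np.zeros((L, 2, 2))
    beta = np.full((K, K), 1.0 / (K * K))
    for i in range(K):
        for j in range(K):
            w[L - 1, H[i, L - 1], H[j, L - 1]] += alpha[L - 1, i, j]
    for s in range(L - 2, -1, -1):
        tmp = np.empty((K, K))
        for i in range(K):
            for j in range(K):
                tmp[i, j] = beta[i, j] * e2[s + 1, H[i, s + 1], H[j, s + 1]]
        beta = _transition(tmp, r[s], K)
        tot = beta.sum()
        if tot <= 0.0:
            beta[:] = 1.0 / (K * K)
        else:
            beta /= tot
        gnorm = 0.0
        for i in range(K):
            for j in range(K):
                gnorm += alpha[s, i, j] * beta[i, j]
        if gnorm <= 0.0:
            # degenerate overlap after an underflow reset; fall back to the
            # forward marginal, which is always normalized
            for i in range(K):
                for j in range(K):
                    w[s, H[i, s], H[j, s]] += alpha[s, i, j]
        else:
            for i in range(K):
                for j in range(K):
                    w[s, H[i, s], H[j, s]] += alpha[s, i, j] * beta[i, j] / gnorm
    return w


def impute(
    lik: LikelihoodMatrix, panel: HaplotypePanel, params: HmmParams | None = None
) -> DosageVector:
    """Impute maternal genotype dosages from sparse genotype likelihoods.

    Runs the exact diploid forward-backward over the (optionally subset)
    panel and converts pair-state posteriors into per-site genotype
    posteriors: P(g | data) = sum over allele-pair classes of
    class_posterior * lik(g) P(g | class) / sum_g' lik(g') P(g' | class).
    """
    if params is None:
        params = HmmParams()
    if lik.n_sites != panel.n_sites:
        raise ValueError(
            f"likelihood sites ({lik.n_sites}) do not align with panel sites ({panel.n_sites})"
        )
    if params.panel_subset is not None:
        idx = select_copying_subset(lik, panel, params.panel_subset)
        H = np.ascontiguousarray(panel.haplotypes[idx])
    else:
        H = np.ascontiguousarray(panel.haplotypes)
    K = H.shape[0]

    pg = genotype_given_pair(params.copy_error)          # (3, 2, 2)
    likm = np.asarray(lik.lik, dtype=np.float64)
    e2 = np.einsum("sg,gab->sab", likm, pg)              # (L, 2, 2)
    e2 = np.maximum(e2, params.min_posterior_floor)
    r = switch_probabilities(panel.cm_positions, params.n_eff, K)

    w = _fb_pair_class_posteriors(H, e2, r)              # (L, 2, 2)

    # genotype posterior: reweight each class posterior by lik(g) P(g|class)
    contrib = likm[:, :, None, None] * pg[None, :, :, :]  # (L, 3, 2, 2)
    post = np.einsum("sab,sgab->sg", w / e2, contrib)
    post = np.maximum(post, 0.0)
    post /= post.sum(axis=1, keepdims=True)

    dosage = post @ np.array([0.0, 1.0, 2.0])
    return DosageVector(
        dosage=dosage,
        posterior=post,
        hard_genotype=post.argmax(axis=1).astype(np.int8),
        max_posterior=post.max(axis=1),
    )


def posterior_r2(dosages: DosageVector | np.ndarray, truth: np.ndarray) -> float:
    """Squared Pearson correlation between dosages and truth genotypes.

    Returns NaN when either vector has zero variance (undefined).
    """
    d = dosages.dosage if isinstance(dosages, DosageVector) else np.asarray(dosages, float)
    t = np.asarray(truth, dtype=np.float64)
    if d.size != t.size:
        raise ValueError("dosage and truth vectors must have equal length")
    if np.std(d) == 0 or np.std(t) == 0:
        return float("nan")
    return float(np.corrcoef(d, t)[0, 1] ** 2)
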