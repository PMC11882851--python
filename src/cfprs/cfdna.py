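"""cfDNA pileup simulation: maternal/fetal read mixtures at low coverage.

Plasma cfDNA in pregnancy is a mixture of maternal and placental (fetal)
fragments.  Each simulated read carries an observed allele (after sequencing
error), a fragment length drawn from an origin-specific truncated-normal
distribution (maternal peak 166 bp, fetal peak 143 bp), and a hidden origin
tag that is simulation truth only -- inference never sees it.  Reads are
independent across sites: at ~0.25x coverage with panel sites kilobases
apart, one fragment essentially never spans two panel sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

MATERNAL = 0
FETAL = 1


@dataclass
class MixtureConfig:
    """Coverage, fetal fraction, error and fragment-length settings."""

    coverage: float = 0.25
    fetal_fraction: float = 0.0
    error_rate: float = 0.005
    maternal_length_mean: float = 166.0
    fetal_length_mean: float = 143.0
    length_sd: float = 15.0
    length_bounds: tuple[float, float] = (50.0, 400.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fetal_fraction <= 1:
            raise ValueError("fetal_fraction must be in [0, 1]")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        lo, hi = self.length_bounds
        if lo <= 0 or lo >= hi:
            raise ValueError("length_bounds must be positive with min < max")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")


@dataclass
class Pileups:
    """Per-site read observations, stored as flat parallel arrays.

    ``site_index[i]`` is the panel-site index of read i; ``allele`` the
    observed allele in {0, 1}; ``length`` the fragment length in bp;
    ``origin`` the true read origin (MATERNAL/FETAL), hidden from inference.
    """

    n_sites: int
    site_index: np.ndarray
    allele: np.ndarray
    length: np.ndarray
    origin: np.ndarray

    @property
    def n_reads(self) -> int:
        return self.site_index.size

    def depth(self) -> np.ndarray:
        """Read count per site (length ``n_sites``)."""
        return np.bincount(self.site_index, minlength=self.n_sites)

    def alt_counts(self) -> np.ndarray:
        """Alt-allele read count per site."""
        return np.bincount(self.site_index, weights=self.allele, minlength=self.n_sites).astype(
            np.int64
        )

    def _subset(self, mask: np.ndarray) -> "Pileups":
        return Pileups(
            n_sites=self.n_sites,
            site_index=self.site_index[mask],
            allele=self.allele[mask],
            length=self.length[mask],
            origin=self.origin[mask],
        )

    def to_frame(self, include_origin: bool = False) -> pd.DataFrame:
        """Tabular form for serialization; origin excluded by default so the
        written file carries no information inference must not see."""
        cols = {"site": self.site_index, "allele": self.allele, "length": self.length}
        if include_origin:
            cols["origin"] = self.origin
        return pd.DataFrame(cols)

    def to_tsv(self, path, include_origin: bool = False) -> None:
        self.to_frame(include_origin).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, n_sites: int) -> "Pileups":
        df = pd.read_csv(path, sep="\t")
        origin = df["origin"].to_numpy(np.int8) if "origin" in df else np.full(len(df), -1, np.int8)
        return cls(
            n_sites=n_sites,
            site_index=df["site"].to_numpy(np.int64),
            allele=df["allele"].to_numpy(np.int8),
            length=df["length"].to_numpy(np.float64),
            origin=origin,
        )


def _truncnorm_lengths(
    mean: float, sd: float, bounds: tuple[float, float], size: int, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = bounds
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_pileups(
    pair,
    mix: MixtureConfig,
    rng: np.random.Generator | None = None,
) -> Pileups:
    """Simulate a cfDNA pileup over all panel sites of a mother-fetus pair.

    Per-site depth is Poisson(coverage); each read is fetal with probability
    ``fetal_fraction``, copies one uniformly chosen haplotype of its origin
    individual, flips the observed allele with probability ``error_rate``,
    and draws a fragment length from its origin's length distribution.
    """
    if rng is None:
        rng = np.random.default_rng(mix.seed)
    L = pair.n_sites
    depth = rng.poisson(mix.coverage, size=L)
    site_index = np.repeat(np.arange(L, dtype=np.int64), depth)
    n = site_index.size

    origin = (rng.random(n) < mix.fetal_fraction).astype(np.int8)
    which_hap = rng.integers(0, 2, size=n)
    hap_stack = np.stack(
        [pair.mother_hap_a, pair.mother_hap_b, pair.fetus_hap_transmitted, pair.fetus_hap_paternal]
    )
    template = hap_stack[2 * origin + which_hap, site_index].astype(np.int8)
    errors = rng.random(n) < mix.error_rate
    allele = np.where(errors, 1 - template, template).astype(np.int8)

    length = np.empty(n, dtype=np.float64)
    for org, mean in ((MATERNAL, mix.maternal_length_mean), (FETAL, mix.fetal_length_mean)):
        sel = origin == org
        length[sel] = _truncnorm_lengths(
            mean, mix.length_sd, mix.length_bounds, int(sel.sum()), rng
        )
    return Pileups(n_sites=L, site_index=site_index, allele=allele, length=length, origin=origin)


def filter_by_length(pileups: Pileups, min_length: float) -> Pileups:
    """Keep only reads with fragment length >= ``min_length``.

    The site list is unchanged; sites may become empty.  This is the
    in-silico size-selection step intended to deplete the (shorter) fetal
    fragments before imputation.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    return pileups._subset(pileups.length >= min_length)


def downsample(
    pileups: Pileups, keep_fraction: float, rng: np.random.Generator | int | None = None
) -> Pileups:
    """Retain each read independently with probability ``keep_fraction``."""
    if not 0 <= keep_fraction <= 1:
        raise ValueError("keep_fraction must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return pileups._subset(rng.random(pileups.n_reads) < keep_fraction)
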