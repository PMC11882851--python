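"""Reference haplotype panel and mother-fetus genotype simulation.

The panel is built by a copying-mosaic process: a small set of founder
haplotypes is drawn site-wise from per-site founder allele frequencies, and
every subsequent haplotype copies segments from previously generated
haplotypes, switching template at a Poisson rate per centimorgan and
flipping the copied allele with a small mutation probability.  Template
switches are what create linkage disequilibrium that decays with genetic
distance, which is the property genotype imputation relies on.

The mother is generated by the same copying process *from* the panel, so she
is closely related to, but not a member of, the reference panel -- the
situation of a study subject drawn from the same population as the
imputation panel.  The fetus carries one recombined maternal haplotype and
one independent panel-mosaic paternal haplotype.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the panel / mother-fetus simulator.

    Rates are per centimorgan (switches) or per copied site (mutation).
    ``n_sites`` is the number of *candidate* sites before the MAF filter.
    """

    n_panel_haplotypes: int = 200
    n_sites: int = 5000
    n_founders: int = 20
    mosaic_switch_rate: float = 1.0      # template switches per cM (panel)
    mother_switch_rate: float = 0.01     # template switches per cM (mother/father)
    mutation_rate: float = 0.0001        # per-site allele flip while copying
    maf_floor: float = 0.05
    region_length_bp: int = 20_000_000
    map_cm_per_mb: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_panel_haplotypes < 4:
            raise ValueError("n_panel_haplotypes must be >= 4")
        if self.n_panel_haplotypes % 2:
            raise ValueError("n_panel_haplotypes must be even (written as diploid VCF samples)")
        if self.n_founders < 2 or self.n_founders > self.n_panel_haplotypes:
            raise ValueError("n_founders must be in [2, n_panel_haplotypes]")
        for name in ("mosaic_switch_rate", "mother_switch_rate", "mutation_rate",
                     "maf_floor", "map_cm_per_mb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class HaplotypePanel:
    """Phased reference haplotypes over biallelic sites on one pseudo-chromosome.

    ``haplotypes`` is a (K, L) uint8 matrix, 0=ref / 1=alt.  ``positions``
    are 1-based base-pair coordinates, strictly increasing; ``cm_positions``
    the genetic-map coordinates in centimorgans.
    """

    positions: np.ndarray
    cm_positions: np.ndarray
    haplotypes: np.ndarray
    ref_alleles: np.ndarray
    alt_alleles: np.ndarray
    chrom: str = "1"
    allele_freq: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.cm_positions = np.asarray(self.cm_positions, dtype=np.float64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.allele_freq = self.haplotypes.mean(axis=0)
        self.validate()

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def validate(self) -> None:
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        K, L = self.haplotypes.shape
        if self.positions.shape != (L,) or self.cm_positions.shape != (L,):
            raise ValueError("positions/cm_positions must match haplotype columns")
        if L and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if L and not np.all(np.diff(self.cm_positions) >= 0):
            raise ValueError("cm_positions must be non-decreasing")
        vals = np.unique(self.haplotypes)
        if vals.size and not np.isin(vals, [0, 1]).all():
            raise ValueError("haplotype entries must be 0/1")

    def site_table(self):
        """Site metadata as a DataFrame (CHROM/POS/REF/ALT/AF), VCF conventions."""
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.positions,
                "id": [f"site{i}" for i in range(self.n_sites)],
                "ref": self.ref_alleles,
                "alt": self.alt_alleles,
                "af": self.allele_freq,
            }
        )


@dataclass
class MotherFetusPair:
    """A mother's two haplotypes and her fetus's two haplotypes.

    The transmitted fetal haplotype is a recombinant of the mother's pair;
    the paternal haplotype is an independent panel mosaic.  Genotypes are
    alt-allele counts in {0, 1, 2}.
    """

    mother_hap_a: np.ndarray
    mother_hap_b: np.ndarray
    fetus_hap_transmitted: np.ndarray
    fetus_hap_paternal: np.ndarray

    @property
    def mother_genotype(self) -> np.ndarray:
        return (self.mother_hap_a + self.mother_hap_b).astype(np.uint8)

    @property
    def fetus_genotype(self) -> np.ndarray:
        return (self.fetus_hap_transmitted + self.fetus_hap_paternal).astype(np.uint8)

    @property
    def n_sites(self) -> int:
        return self.mother_hap_a.size

    def validate(self) -> None:
        ok = (self.fetus_hap_transmitted == self.mother_hap_a) | (
            self.fetus_hap_transmitted == self.mother_hap_b
        )
        if not ok.all():
            raise ValueError("transmitted haplotype violates Mendelian consistency")


class MafFilterError(ValueError):
    """Raised when the MAF floor leaves fewer than 2 usable sites."""


def _copy_mosaic(
    templates: np.ndarray,
    cm: np.ndarray,
    switch_rate: float,
    mutation_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One haplotype copied from ``templates`` with per-cM template switches.

    Switch points are a Poisson process on the genetic map; between switches
    the allele at each site is copied from the current template, flipped
    with probability ``mutation_rate``.
    """
    n_templates, L = templates.shape
    total_cm = cm[-1] - cm[0] if L else 0.0
    n_switch = rng.poisson(switch_rate * total_cm)
    # breakpoints in genetic-map space; a site belongs to the segment left of it
    breaks = np.sort(rng.uniform(cm[0], cm[-1], size=n_switch)) if n_switch else np.empty(0)
    seg_of_site = np.searchsorted(breaks, cm, side="right")
    seg_templates = rng.integers(0, n_templates, size=n_switch + 1)
    hap = templates[seg_templates[seg_of_site], np.arange(L)].astype(np.uint8)
    if mutation_rate > 0:
        flips = rng.random(L) < mutation_rate
        hap[flips] ^= 1
    return hap


def generate_panel(config: SimConfig, rng: np.random.Generator | None = None) -> HaplotypePanel:
    """Generate a reference haplotype panel by the copying-mosaic process.

    Candidate sites are placed uniformly on the region; founder haplotypes
    are drawn site-wise from U(0.05, 0.95) founder allele frequencies; each
    non-founder haplotype copies segments from all previously generated
    haplotypes.  Sites failing the MAF floor are dropped.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L0 = config.n_sites
    positions = np.sort(rng.choice(config.region_length_bp, size=L0, replace=False)) + 1
    cm = positions * (config.map_cm_per_mb / 1e6)

    founder_freq = rng.uniform(0.05, 0.95, size=L0)
    K = config.n_panel_haplotypes
    haps = np.empty((K, L0), dtype=np.uint8)
    F = config.n_founders
    haps[:F] = rng.random((F, L0)) < founder_freq
    for k in range(F, K):
        haps[k] = _copy_mosaic(
            haps[:k], cm, config.mosaic_switch_rate, config.mutation_rate, rng
        )

    af = haps.mean(axis=0)
    maf = np.minimum(af, 1 - af)
    keep = maf >= config.maf_floor
    if keep.sum() < 2:
        raise MafFilterError(
            f"MAF floor {config.maf_floor} leaves {int(keep.sum())} site(s); need >= 2"
        )

    ref_idx = rng.integers(0, 4, size=L0)
    alt_idx = (ref_idx + rng.integers(1, 4, size=L0)) % 4
    return HaplotypePanel(
        positions=positions[keep],
        cm_positions=cm[keep],
        haplotypes=haps[:, keep],
        ref_alleles=_BASES[ref_idx[keep]],
        alt_alleles=_BASES[alt_idx[keep]],
    )


def _recombine(
    hap_a: np.ndarray, hap_b: np.ndarray, cm: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Meiotic recombinant of a haplotype pair; crossovers ~ Poisson(map Morgans)."""
    total_morgans = (cm[-1] - cm[0]) / 100.0
    n_cross = rng.poisson(total_morgans)
    breaks = np.sort(rng.uniform(cm[0], cm[-1], size=n_cross)) if n_cross else np.empty(0)
    phase = (np.searchsorted(breaks, cm, side="right") + rng.integers(0, 2)) % 2
    return np.where(phase == 0, hap_a, hap_b).astype(np.uint8)


def sample_mother_fetus(
    panel: HaplotypePanel,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> MotherFetusPair:
    """Draw one mother-fetus pair related to (but absent from) the panel.

    The mother's haplotypes and the paternal haplotype are low-switch-rate
    mosaics of the panel; the transmitted haplotype recombines the mother's
    pair with a crossover count set by the genetic-map length.
    """
    if panel.n_sites == 0:
        raise ValueError("panel has no sites")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cm = panel.cm_positions
    mk = lambda: _copy_mosaic(
        panel.haplotypes, cm, config.mother_switch_rate, config.mutation_rate, rng
    )
    mother_a, mother_b, paternal = mk(), mk(), mk()
    transmitted = _recombine(mother_a, mother_b, cm, rng)
    pair = MotherFetusPair(
        mother_hap_a=mother_a,
        mother_hap_b=mother_b,
        fetus_hap_transmitted=transmitted,
        fetus_hap_paternal=paternal,
    )
    pair.validate()
    return pair
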