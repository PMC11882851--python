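"""Polygenic risk scores from genotype dosages.

A PRS for sample j is the weighted sum of effect-allele dosages over the
markers of a scoring panel, PRS_j = sum_i beta_i g_ij / M_j.  The
normalizer M_j is the matched non-missing marker count (per-marker
average); since any common affine rescaling of scores leaves cross-sample
correlations unchanged, the choice of M convention cannot affect
correlation-based comparisons.

Scoring panels are read and written in the PGS Catalog harmonized text
dialect: '#'-prefixed header lines, then a tab-separated table with at
least chr_name, chr_position, effect_allele, other_allele, effect_weight.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("chr_name", "chr_position", "effect_allele", "other_allele", "effect_weight")


@dataclass
class ScoringPanel:
    """A PRS marker panel: positions, allele pair, and effect weight per marker."""

    panel_id: str
    markers: pd.DataFrame  # columns: chr_name, chr_position, effect_allele, other_allele, effect_weight
    n_skipped_rows: int = 0

    def __post_init__(self) -> None:
        m = self.markers
        if len(m) < 1:
            raise ValueError("scoring panel must contain at least one marker")
        keys = m[["chr_name", "chr_position"]].astype(str).agg(":".join, axis=1)
        if keys.duplicated().any():
            raise ValueError("marker positions must be unique within a panel")
        if not np.isfinite(m["effect_weight"].to_numpy(float)).all():
            raise ValueError("effect weights must be finite")

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def load_scoring_file(path) -> ScoringPanel:
    """Parse a PGS Catalog harmonized scoring file.

    Header lines start with '#'; a ``#pgs_id=...`` line, if present, names
    the panel.  Unknown columns are ignored; rows with a non-numeric weight
    or missing position are counted and skipped with a logged tally.
    """
    panel_id = None
    with open(path) as fh:
        text = fh.read()
    header_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    for ln in header_lines:
        body = ln.lstrip("#").strip()
        if body.startswith("pgs_id"):
            panel_id = body.split("=", 1)[-1].strip()
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scoring file is missing required column(s): {', '.join(missing)}")

    weights = pd.to_numeric(df["effect_weight"], errors="coerce")
    positions = pd.to_numeric(df["chr_position"], errors="coerce")
    bad = weights.isna() | positions.isna() | df["effect_allele"].isna() | df["other_allele"].isna()
    n_skipped = int(bad.sum())
    if n_skipped:
        logger.warning("%s: skipped %d malformed scoring row(s)", path, n_skipped)
    markers = pd.DataFrame(
        {
            "chr_name": df.loc[~bad, "chr_name"].astype(str).to_numpy(),
            "chr_position": positions[~bad].astype(np.int64).to_numpy(),
            "effect_allele": df.loc[~bad, "effect_allele"].to_numpy(),
            "other_allele": df.loc[~bad, "other_allele"].to_numpy(),
            "effect_weight": weights[~bad].to_numpy(np.float64),
        }
    )
    return ScoringPanel(
        panel_id=panel_id or "unnamed", markers=markers, n_skipped_rows=n_skipped
    )


def write_scoring_file(panel: ScoringPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("### PGS CATALOG SCORING FILE\n")
        fh.write(f"#pgs_id={panel.panel_id}\n")
        panel.markers.to_csv(fh, sep="\t", index=False)


def make_random_scoring_panel(
    site_table: pd.DataFrame,
    n_markers: int,
    rng: np.random.Generator,
    weight_sd: float = 1.0,
    panel_id: str | None = None,
) -> ScoringPanel:
    """Synthetic scoring panel: random panel sites with Normal(0, sd^2) weights.

    The effect allele is the site's alt or ref with equal probability, so
    orientation handling is exercised throughout.
    """
    if n_markers > len(site_table):
        raise ValueError("n_markers exceeds available sites")
    idx = np.sort(rng.choice(len(site_table), size=n_markers, replace=False))
    sites = site_table.iloc[idx]
    flip = rng.random(n_markers) < 0.5
    markers = pd.DataFrame(
        {
            "chr_name": sites["chrom"].to_numpy(),
            "chr_position": sites["pos"].to_numpy(),
            "effect_allele": np.where(flip, sites["ref"], sites["alt"]),
            "other_allele": np.where(flip, sites["alt"], sites["ref"]),
            "effect_weight": rng.normal(0.0, weight_sd, size=n_markers),
        }
    )
    return ScoringPanel(panel_id=panel_id or f"synthetic_{n_markers}", markers=markers)


@dataclass
class MarkerMatch:
    """Marker-to-site mapping with effect-allele orientation.

    ``site_idx[i]`` is the panel-site row of matched marker i; ``flip[i]``
    is True when the effect allele is the site's *ref* allele, in which
    case the effect-allele dosage is 2 - d.
    """

    site_idx: np.ndarray
    weight: np.ndarray
    flip: np.ndarray
    n_matched: int
    n_unmatched: int


def match_markers(panel: ScoringPanel, site_table: pd.DataFrame) -> MarkerMatch:
    """Match markers to sites by position and unordered allele pair."""
    sites = site_table.reset_index(drop=True)
    key = {
        (str(c), int(p)): i
        for i, (c, p) in enumerate(zip(sites["chrom"], sites["pos"]))
    }
    site_idx, weight, flip = [], [], []
    n_unmatched = 0
    for row in panel.markers.itertuples(index=False):
        i = key.get((str(row.chr_name), int(row.chr_position)))
        if i is None:
            n_unmatched += 1
            continue
        ref, alt = sites.at[i, "ref"], sites.at[i, "alt"]
        if {row.effect_allele, row.other_allele} != {ref, alt}:
            n_unmatched += 1
            continue
        site_idx.append(i)
        weight.append(row.effect_weight)
        flip.append(row.effect_allele == ref)
    return MarkerMatch(
        site_idx=np.asarray(site_idx, dtype=np.int64),
        weight=np.asarray(weight, dtype=np.float64),
        flip=np.asarray(flip, dtype=bool),
        n_matched=len(site_idx),
        n_unmatched=n_unmatched,
    )


@dataclass
class PrsResult:
    """A sample's score with its normalizer and marker accounting."""

    score: float
    m: float
    n_matched: int
    n_skipped: int
    panel_id: str = ""


def compute_prs(
    dosages: np.ndarray,
    panel: ScoringPanel,
    match: MarkerMatch,
    missing_policy: str = "drop",
    allele_freq: np.ndarray | None = None,
) -> PrsResult:
    """Score one sample: PRS = sum(beta_i * effect-dosage_i) / M.

    ``dosages`` is the per-site dosage vector (NaN = missing).  M is the
    matched non-missing marker count.  Missing dosages are dropped from
    both the sum and M (default), or mean-imputed as 2 * panel allele
    frequency of the effect allele (``missing_policy='mean'``, requires
    ``allele_freq``).
    """
    if match.n_matched == 0:
        raise ValueError("no scoring-panel markers matched the site table")
    d = np.asarray(dosages, dtype=np.float64)[match.site_idx]
    if missing_policy == "mean":
        if allele_freq is None:
            raise ValueError("missing_policy='mean' requires allele_freq")
        d = np.where(np.isnan(d), 2.0 * np.asarray(allele_freq)[match.site_idx], d)
    elif missing_policy != "drop":
        raise ValueError("missing_policy must be 'drop' or 'mean'")
    eff = np.where(match.flip, 2.0 - d, d)
    ok = ~np.isnan(eff)
    m = float(ok.sum())
    if m == 0:
        raise ValueError("all matched markers have missing dosage")
    score = float(np.dot(match.weight[ok], eff[ok]) / m)
    return PrsResult(
        score=score,
        m=m,
        n_matched=match.n_matched,
        n_skipped=panel.n_markers - match.n_matched,
        panel_id=panel.panel_id,
    )


def score_matrix(
    dosage_matrix: np.ndarray, panel: ScoringPanel, match: MarkerMatch, **kw
) -> np.ndarray:
    """Scores for a (n_samples, n_sites) dosage matrix, one PRS per row."""
    return np.array(
        [compute_prs(row, panel, match, **kw).score for row in np.atleast_2d(dosage_matrix)]
    )
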