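"""End-to-end accuracy experiments for cfDNA-based maternal PRS.

Three studies, mirroring an in-silico evaluation design:

* coverage experiment -- pure maternal samples sequenced at 30x are
  down-sampled to 1.0x and 0.2x; the low-coverage arms are imputed, the
  30x arm is hard-called, and PRS from the three arms are correlated.
* mixture experiment -- cfDNA pileups at 0.25x for fetal fractions
  0/5/10/15%, seven replicates each; PRS from each mixture arm is
  correlated against the fetal-fraction-0 arm.
* cohort experiment -- a prospective-cohort analog: per-sample fetal
  fraction drawn from a plausible clinical range, a 0.25x cfDNA arm
  (imputed) against a 15x gDNA arm (hard-called), scored with panels of
  several sizes, with fetal-fraction stratification and top-5% high-risk
  misclassification.

Every experiment is fully determined by (config, seed); reports embed both.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cfdna, genolik, hmm, panel as panel_mod, prs

# ---------------------------------------------------------------------------
# statistics


def pearson(x, y) -> float:
    """Sample Pearson correlation; NaN when undefined (zero variance)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    """Spearman rank correlation (diagnostic companion to ``pearson``)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def high_risk_labels(scores: np.ndarray, q: float) -> np.ndarray:
    """Boolean labels flagging the top ceil(q*n) scores, stable tie-break."""
    scores = np.asarray(scores, dtype=np.float64)
    n = scores.size
    k = int(np.ceil(q * n))
    order = np.argsort(-scores, kind="stable")
    labels = np.zeros(n, dtype=bool)
    labels[order[:k]] = True
    return labels


def misclassification_rate(ref_scores, alt_scores, q: float = 0.05) -> float:
    """Fraction of samples whose top-q high-risk label differs between vectors.

    Each vector flags its own top ceil(q*n) samples (rank-based, ties by
    stable sample order); the rate is the fraction of discordant labels.
    """
    ref = np.asarray(ref_scores, dtype=np.float64)
    alt = np.asarray(alt_scores, dtype=np.float64)
    if ref.size != alt.size:
        raise ValueError("score vectors must have equal length")
    if not 0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    if ref.size * q < 1:
        raise ValueError(f"need n >= 1/q (n={ref.size}, q={q})")
    return float(np.mean(high_risk_labels(ref, q) != high_risk_labels(alt, q)))


# ---------------------------------------------------------------------------
# configs and report


@dataclass
class PipelineConfig:
    """Simulator and model settings shared by all experiments."""

    sim: panel_mod.SimConfig = field(default_factory=panel_mod.SimConfig)
    hmm: hmm.HmmParams = field(default_factory=hmm.HmmParams)
    error_rate: float = 0.005
    length_sd: float = 15.0


@dataclass
class CoverageExperimentConfig:
    n_subjects: int = 10
    n_replicate_cohorts: int = 20
    low_coverages: tuple[float, ...] = (0.2, 1.0)
    high_coverage: float = 30.0
    n_markers: int = 2000
    seed: int = 0
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)


@dataclass
class MixtureExperimentConfig:
    n_pairs: int = 40
    fetal_fractions: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15)
    n_replicates: int = 7
    coverage: float = 0.25
    n_markers: int = 2000
    fragment_filter_min: float | None = None
    seed: int = 0
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)


@dataclass
class CohortExperimentConfig:
    n_samples: int = 450
    cfdna_coverage: float = 0.25
    gdna_coverage: float = 15.0
    ff_range: tuple[float, float] = (0.03, 0.20)
    panel_sizes: tuple[int, ...] = (50, 500, 2000, 5000)
    n_panels_per_size: int = 2
    high_risk_q: float = 0.05
    seed: int = 0
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)


def _config_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return clean(d)


@dataclass
class ExperimentReport:
    """Replicate-level tables plus summary statistics of one experiment."""

    name: str
    correlations: dict
    conditions: pd.DataFrame
    summary: dict
    config: dict
    seed: int

    def to_json(self, path=None) -> str:
        payload = {
            "name": self.name,
            "seed": self.seed,
            "correlations": self.correlations,
            "summary": self.summary,
            "config": self.config,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_tsv(self, path) -> None:
        self.conditions.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline pieces


def _imputed_dosages(pileups, pipe: PipelineConfig, ref_panel) -> np.ndarray:
    lik = genolik.genotype_likelihoods(pileups, pipe.error_rate)
    return hmm.impute(lik, ref_panel, pipe.hmm).dosage


def _hard_call_dosages(pileups, pipe: PipelineConfig) -> np.ndarray:
    lik = genolik.genotype_likelihoods(pileups, pipe.error_rate)
    return genolik.call_genotypes(lik)


def _mix_config(pipe: PipelineConfig, coverage: float, ff: float, seed: int) -> cfdna.MixtureConfig:
    return cfdna.MixtureConfig(
        coverage=coverage,
        fetal_fraction=ff,
        error_rate=pipe.error_rate,
        length_sd=pipe.length_sd,
        seed=seed,
    )


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# experiments


def run_coverage_experiment(config: CoverageExperimentConfig | None = None) -> ExperimentReport:
    """Impact of coverage alone (fetal fraction 0) on PRS accuracy.

    Each subject's 30x pileup is down-sampled in silico to the low-coverage
    arms, so all arms observe the same underlying read pool.  Low arms are
    imputed; the 30x arm is hard-called.  Scores are pooled over replicate
    cohorts before correlating.
    """
    cfg = config or CoverageExperimentConfig()
    pipe = cfg.pipeline
    rng_panel, rng_score, rng_cohorts = _spawn(cfg.seed, 3)
    ref_panel = panel_mod.generate_panel(pipe.sim, rng_panel)
    scoring = prs.make_random_scoring_panel(ref_panel.site_table(), cfg.n_markers, rng_score)
    match = prs.match_markers(scoring, ref_panel.site_table())

    arms = list(cfg.low_coverages) + [cfg.high_coverage]
    scores: dict[float, list[float]] = {c: [] for c in arms}
    rows = []
    for cohort_i, rng in enumerate(_spawn(int(rng_cohorts.integers(2**31)), cfg.n_replicate_cohorts)):
        for subj in range(cfg.n_subjects):
            pair = panel_mod.sample_mother_fetus(ref_panel, pipe.sim, rng)
            deep = cfdna.simulate_pileups(
                pair, _mix_config(pipe, cfg.high_coverage, 0.0, 0), rng
            )
            dos = {cfg.high_coverage: _hard_call_dosages(deep, pipe)}
            for cov in cfg.low_coverages:
                down = cfdna.downsample(deep, cov / cfg.high_coverage, rng)
                dos[cov] = _imputed_dosages(down, pipe, ref_panel)
            for cov in arms:
                s = prs.compute_prs(dos[cov], scoring, match).score
                scores[cov].append(s)
                rows.append({"cohort": cohort_i, "subject": subj, "coverage": cov, "prs": s})

    correlations = {}
    for i, a in enumerate(arms):
        for b in arms[i + 1 :]:
            correlations[f"{a}x_vs_{b}x"] = pearson(scores[a], scores[b])
            correlations[f"{a}x_vs_{b}x_spearman"] = spearman(scores[a], scores[b])
    summary = {"n_scores_per_arm": cfg.n_subjects * cfg.n_replicate_cohorts}
    return ExperimentReport(
        name="coverage",
        correlations=correlations,
        conditions=pd.DataFrame(rows),
        summary=summary,
        config=_config_dict(cfg),
        seed=cfg.seed,
    )


def run_mixture_experiment(config: MixtureExperimentConfig | None = None) -> ExperimentReport:
    """Impact of fetal fraction on maternal PRS at fixed 0.25x coverage.

    For each fetal fraction and replicate, every pair gets a fresh mixture
    pileup; per-sample scores are averaged over replicates and each
    fetal-fraction arm is correlated against the fetal-fraction-0 arm.
    """
    cfg = config or MixtureExperimentConfig()
    pipe = cfg.pipeline
    rng_panel, rng_score, rng_pairs, rng_reps = _spawn(cfg.seed, 4)
    ref_panel = panel_mod.generate_panel(pipe.sim, rng_panel)
    scoring = prs.make_random_scoring_panel(ref_panel.site_table(), cfg.n_markers, rng_score)
    match = prs.match_markers(scoring, ref_panel.site_table())
    pairs = [
        panel_mod.sample_mother_fetus(ref_panel, pipe.sim, rng_pairs)
        for _ in range(cfg.n_pairs)
    ]

    # scores[ff][rep] is the cohort score vector of one replicate
    scores = {ff: np.empty((cfg.n_replicates, cfg.n_pairs)) for ff in cfg.fetal_fractions}
    rows = []
    for ff in cfg.fetal_fractions:
        for rep, rng in enumerate(_spawn(int(rng_reps.integers(2**31)), cfg.n_replicates)):
            for j, pair in enumerate(pairs):
                pl = cfdna.simulate_pileups(pair, _mix_config(pipe, cfg.coverage, ff, 0), rng)
                if cfg.fragment_filter_min is not None:
                    pl = cfdna.filter_by_length(pl, cfg.fragment_filter_min)
                s = prs.compute_prs(_imputed_dosages(pl, pipe, ref_panel), scoring, match).score
                scores[ff][rep, j] = s
                rows.append({"fetal_fraction": ff, "replicate": rep, "sample": j, "prs": s})

    base_ff = cfg.fetal_fractions[0]
    base_mean = scores[base_ff].mean(axis=0)
    correlations, summary = {}, {"per_sample_bias": {}, "per_sample_sd": {}}
    for ff in cfg.fetal_fractions:
        mean_scores = scores[ff].mean(axis=0)
        correlations[f"ff_{ff:g}_vs_ff_{base_ff:g}"] = pearson(mean_scores, base_mean)
        correlations[f"ff_{ff:g}_vs_ff_{base_ff:g}_spearman"] = spearman(mean_scores, base_mean)
        dev = mean_scores - base_mean
        summary["per_sample_bias"][f"{ff:g}"] = float(dev.mean())
        summary["per_sample_sd"][f"{ff:g}"] = float(dev.std(ddof=1))
    return ExperimentReport(
        name="mixture",
        correlations=correlations,
        conditions=pd.DataFrame(rows),
        summary=summary,
        config=_config_dict(cfg),
        seed=cfg.seed,
    )


def run_cohort_experiment(config: CohortExperimentConfig | None = None) -> ExperimentReport:
    """Prospective-cohort analog: 0.25x cfDNA arm vs 15x gDNA arm.

    Per-sample fetal fractions are drawn uniformly from ``ff_range``; the
    cfDNA arm is imputed, the gDNA arm hard-called.  Reports per-panel
    correlations, correlations stratified by scoring-panel size and by
    fetal fraction (median split), and top-q high-risk misclassification
    against the gDNA arm.
    """
    cfg = config or CohortExperimentConfig()
    pipe = cfg.pipeline
    rng_panel, rng_score, rng_pairs, rng_seq = _spawn(cfg.seed, 4)
    ref_panel = panel_mod.generate_panel(pipe.sim, rng_panel)
    site_table = ref_panel.site_table()
    # a nominal size above the post-MAF-filter site count means "all sites"
    panels = [
        prs.make_random_scoring_panel(
            site_table, min(size, len(site_table)), rng_score,
            panel_id=f"synthetic_{size}_{k}",
        )
        for size in cfg.panel_sizes
        for k in range(cfg.n_panels_per_size)
    ]
    nominal_sizes = [s for s in cfg.panel_sizes for _ in range(cfg.n_panels_per_size)]
    matches = [prs.match_markers(p, site_table) for p in panels]

    ff = rng_pairs.uniform(*cfg.ff_range, size=cfg.n_samples)
    n_sites = ref_panel.n_sites
    cf_dos = np.empty((cfg.n_samples, n_sites))
    gd_dos = np.empty((cfg.n_samples, n_sites))
    for j in range(cfg.n_samples):
        pair = panel_mod.sample_mother_fetus(ref_panel, pipe.sim, rng_pairs)
        cf_pl = cfdna.simulate_pileups(
            pair, _mix_config(pipe, cfg.cfdna_coverage, float(ff[j]), 0), rng_seq
        )
        cf_dos[j] = _imputed_dosages(cf_pl, pipe, ref_panel)
        gd_pl = cfdna.simulate_pileups(
            pair, _mix_config(pipe, cfg.gdna_coverage, 0.0, 0), rng_seq
        )
        gd_dos[j] = _hard_call_dosages(gd_pl, pipe)

    low = ff <= np.median(ff)
    rows, correlations = [], {}
    mis_rates = []
    by_size: dict[int, list[float]] = {s: [] for s in cfg.panel_sizes}
    low_corrs, high_corrs = [], []
    for size, p, match in zip(nominal_sizes, panels, matches):
        cf = prs.score_matrix(cf_dos, p, match)
        gd = prs.score_matrix(gd_dos, p, match)
        corr = pearson(cf, gd)
        mis = misclassification_rate(gd, cf, cfg.high_risk_q)
        # a degenerate FF distribution can empty a stratum; report NaN there
        strat = lambda m: pearson(cf[m], gd[m]) if m.sum() >= 3 else float("nan")
        c_low, c_high = strat(low), strat(~low)
        by_size[size].append(corr)
        mis_rates.append(mis)
        low_corrs.append(c_low)
        high_corrs.append(c_high)
        correlations[p.panel_id] = corr
        rows.append(
            {
                "panel_id": p.panel_id,
                "panel_size": size,
                "pearson": corr,
                "spearman": spearman(cf, gd),
                "pearson_low_ff": c_low,
                "pearson_high_ff": c_high,
                "misclassification": mis,
            }
        )
    summary = {
        "mean_correlation": float(np.mean(list(correlations.values()))),
        "correlation_by_panel_size": {str(s): float(np.mean(v)) for s, v in by_size.items()},
        "mean_correlation_low_ff": float(np.mean(low_corrs)),
        "mean_correlation_high_ff": float(np.mean(high_corrs)),
        "ff_median": float(np.median(ff)),
        "misclassification_mean": float(np.mean(mis_rates)),
        "misclassification_max": float(np.max(mis_rates)),
        "high_risk_q": cfg.high_risk_q,
    }
    return ExperimentReport(
        name="cohort",
        correlations=correlations,
        conditions=pd.DataFrame(rows),
        summary=summary,
        config=_config_dict(cfg),
        seed=cfg.seed,
    )
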