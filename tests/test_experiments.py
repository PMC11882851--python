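"""Experiment orchestration: statistics, determinism, degradation trends.

Statistical trend tests run at a reduced scale (small panel, few samples)
so the whole file stays in the minutes range; the trends themselves are
scale-free.
"""

import numpy as np
import pytest
from scipy import stats

from cfprs import experiments as E
from cfprs import hmm
from cfprs.panel import SimConfig

SMALL_SIM = SimConfig(
    n_panel_haplotypes=100, n_sites=800, n_founders=10,
    region_length_bp=8_000_000, seed=0,
)
SMALL_PIPE = E.PipelineConfig(sim=SMALL_SIM, hmm=hmm.HmmParams(panel_subset=40))


# ---------------------------------------------------------------------------
# pearson / misclassification


def test_pearson_reference_values():
    x = [1.0, 2.0, 3.0, 4.0]
    assert E.pearson(x, x) == pytest.approx(1.0)
    assert E.pearson(x, [-v for v in x]) == pytest.approx(-1.0)
    assert E.pearson(x, [1, 2, 3, 5]) == pytest.approx(0.9827, abs=5e-5)
    assert np.isnan(E.pearson([1.0, 1.0, 1.0], x[:3]))
    with pytest.raises(ValueError):
        E.pearson([1.0, 2.0], [1.0, 2.0])


def brute_force_misclassification(ref, alt, q):
    """Independent oracle: explicit sort-based top-q labelling per vector."""
    n = len(ref)
    k = int(np.ceil(q * n))

    def labels(scores):
        order = sorted(range(n), key=lambda i: (-scores[i], i))
        flagged = set(order[:k])
        return [i in flagged for i in range(n)]

    lr, la = labels(list(ref)), labels(list(alt))
    return sum(a != b for a, b in zip(lr, la)) / n


def test_misclassification_reference_cases(rng):
    ref = rng.normal(size=100)
    assert E.misclassification_rate(ref, ref.copy(), 0.05) == 0.0
    assert E.misclassification_rate(ref, 2.5 * ref + 1.0, 0.05) == 0.0  # rank invariance
    # reverse exactly the top-5 and bottom-5 samples: 10 flipped labels
    order = np.argsort(-ref)
    alt = ref.copy()
    alt[order[:5]], alt[order[-5:]] = ref[order[-5:]], ref[order[:5]]
    assert E.misclassification_rate(ref, alt, 0.05) == pytest.approx(0.10)


def test_misclassification_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for n in (20, 35, 50):
        for q in (0.05, 0.1, 0.25):
            if n * q < 1:
                continue
            ref = rng.normal(size=n)
            alt = ref + rng.normal(scale=0.5, size=n)
            assert E.misclassification_rate(ref, alt, q) == pytest.approx(
                brute_force_misclassification(ref, alt, q)
            )
    # ties broken by stable sample order in both implementations
    ref = np.array([1.0, 1.0, 1.0, 0.0, 0.0])
    alt = np.array([0.0, 1.0, 1.0, 1.0, 0.0])
    assert E.misclassification_rate(ref, alt, 0.25) == pytest.approx(
        brute_force_misclassification(ref, alt, 0.25)
    )


def test_misclassification_input_validation():
    with pytest.raises(ValueError, match="n >= 1/q"):
        E.misclassification_rate(np.arange(5), np.arange(5), 0.05)
    with pytest.raises(ValueError, match="q"):
        E.misclassification_rate(np.arange(100), np.arange(100), 0.7)


# ---------------------------------------------------------------------------
# coverage experiment


def test_noise_free_identical_arms_correlate_perfectly():
    cfg = E.CoverageExperimentConfig(
        n_subjects=8, n_replicate_cohorts=1, low_coverages=(30.0,),
        high_coverage=30.0, n_markers=200, seed=3,
        pipeline=E.PipelineConfig(
            sim=SMALL_SIM, hmm=hmm.HmmParams(panel_subset=40), error_rate=0.0
        ),
    )
    rep = E.run_coverage_experiment(cfg)
    assert rep.correlations["30.0x_vs_30.0x"] > 0.9999


def test_coverage_report_is_seed_deterministic():
    cfg = E.CoverageExperimentConfig(
        n_subjects=4, n_replicate_cohorts=2, n_markers=200, seed=7, pipeline=SMALL_PIPE
    )
    a, b = E.run_coverage_experiment(cfg), E.run_coverage_experiment(cfg)
    assert a.correlations == b.correlations
    assert a.conditions.equals(b.conditions)


def test_higher_coverage_correlates_better_with_deep_arm():
    cfg = E.CoverageExperimentConfig(
        n_subjects=8, n_replicate_cohorts=4, n_markers=400, seed=5, pipeline=SMALL_PIPE
    )
    rep = E.run_coverage_experiment(cfg)
    assert rep.correlations["1.0x_vs_30.0x"] > rep.correlations["0.2x_vs_30.0x"]


# ---------------------------------------------------------------------------
# mixture experiment


def test_mixture_baseline_self_correlation_is_one():
    cfg = E.MixtureExperimentConfig(
        n_pairs=6, fetal_fractions=(0.0, 0.1), n_replicates=2,
        n_markers=200, seed=2, pipeline=SMALL_PIPE,
    )
    rep = E.run_mixture_experiment(cfg)
    assert rep.correlations["ff_0_vs_ff_0"] == pytest.approx(1.0)
    # regenerating from the recorded seed reproduces the report
    rep2 = E.run_mixture_experiment(cfg)
    assert rep.correlations == rep2.correlations


def test_correlation_degrades_monotonically_with_fetal_fraction():
    # condition means over 10 seeded runs; Mann-Kendall direction check
    ffs = (0.0, 0.05, 0.10, 0.15)
    corr = {ff: [] for ff in ffs[1:]}
    for seed in range(10):
        cfg = E.MixtureExperimentConfig(
            n_pairs=12, fetal_fractions=ffs, n_replicates=2,
            n_markers=300, seed=seed, pipeline=SMALL_PIPE,
        )
        rep = E.run_mixture_experiment(cfg)
        for ff in corr:
            corr[ff].append(rep.correlations[f"ff_{ff:g}_vs_ff_0"])
    means = [np.mean(corr[ff]) for ff in ffs[1:]]
    assert means[0] > means[1] > means[2]
    tau = stats.kendalltau(ffs[1:], means).statistic
    assert tau < 0


def test_fragment_filter_recovers_accuracy_when_lengths_separate():
    # sd=0 makes the 166/143 bp distributions disjoint: a 150 bp floor
    # removes exactly the fetal reads, so the FF=0.15 arm improves
    def corr_at(filter_min, seed):
        pipe = E.PipelineConfig(
            sim=SMALL_SIM, hmm=hmm.HmmParams(panel_subset=40), length_sd=0.0
        )
        cfg = E.MixtureExperimentConfig(
            n_pairs=12, fetal_fractions=(0.0, 0.15), n_replicates=2, n_markers=300,
            fragment_filter_min=filter_min, seed=seed, pipeline=pipe,
        )
        return E.run_mixture_experiment(cfg).correlations["ff_0.15_vs_ff_0"]

    unfiltered = np.mean([corr_at(None, s) for s in range(4)])
    filtered = np.mean([corr_at(150.0, s) for s in range(4)])
    assert filtered > unfiltered


# ---------------------------------------------------------------------------
# cohort experiment


def test_cohort_pure_deep_arms_correlate_perfectly():
    cfg = E.CohortExperimentConfig(
        n_samples=25, cfdna_coverage=30.0, gdna_coverage=30.0, ff_range=(0.0, 0.0),
        panel_sizes=(100,), n_panels_per_size=1, seed=4,
        pipeline=E.PipelineConfig(
            sim=SMALL_SIM, hmm=hmm.HmmParams(panel_subset=40), error_rate=0.0
        ),
    )
    rep = E.run_cohort_experiment(cfg)
    for corr in rep.correlations.values():
        assert corr > 0.9999
    assert rep.summary["misclassification_max"] == 0.0


def test_low_fetal_fraction_stratum_correlates_better_on_average():
    lows, highs = [], []
    for seed in range(4):
        cfg = E.CohortExperimentConfig(
            n_samples=40, panel_sizes=(300,), n_panels_per_size=1, seed=seed,
            pipeline=SMALL_PIPE,
        )
        rep = E.run_cohort_experiment(cfg)
        lows.append(rep.summary["mean_correlation_low_ff"])
        highs.append(rep.summary["mean_correlation_high_ff"])
    assert np.mean(lows) > np.mean(highs)


def test_cohort_report_serializes_and_reproduces(tmp_path):
    cfg = E.CohortExperimentConfig(
        n_samples=25, panel_sizes=(100, 300), n_panels_per_size=1, seed=6,
        pipeline=SMALL_PIPE,
    )
    rep = E.run_cohort_experiment(cfg)
    # misclassification recomputed from the same report data is identical
    assert rep.summary["misclassification_mean"] == pytest.approx(
        float(np.mean(rep.conditions["misclassification"]))
    )
    path = tmp_path / "report.json"
    rep.to_json(path)
    rep.to_tsv(tmp_path / "conditions.tsv")
    import json

    data = json.loads(path.read_text())
    assert data["name"] == "cohort" and data["seed"] == 6
    assert data["config"]["n_samples"] == 25
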