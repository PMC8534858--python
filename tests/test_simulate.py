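import numpy as np
import pytest
import scipy.stats

from phenotree import (
    CohortConfig,
    ConfigurationError,
    build_matrix,
    build_vocabulary,
    generate_cohort,
    golden_fixture,
    rank_features,
)


def test_same_seed_byte_identical():
    cfg = CohortConfig(n_patients=100, prevalence=0.1, n_codes=50, seed=5)
    e1, l1 = generate_cohort(cfg)
    e2, l2 = generate_cohort(cfg)
    assert e1.frame.equals(e2.frame)
    assert l1.entries == l2.entries


def test_different_seed_differs():
    a, _ = generate_cohort(CohortConfig(100, 0.1, 50, seed=1))
    b, _ = generate_cohort(CohortConfig(100, 0.1, 50, seed=2))
    assert not a.frame.equals(b.frame)


def test_positive_count_within_binomial_interval():
    # central 99% binomial interval for n=2000, p=0.1 is [173, 229]
    lo, hi = scipy.stats.binom.ppf([0.005, 0.995], 2000, 0.1)
    _, labels = generate_cohort(CohortConfig(2000, 0.1, 100, seed=42))
    n_pos = sum(labels.entries.values())
    assert lo <= n_pos <= hi


def test_prevalence_law_of_large_numbers():
    # at n = 1e5 the empirical prevalence sits within 3 sigma of the target
    n, p = 100_000, 0.05
    cfg = CohortConfig(n, p, 10, mean_events=0.01, seed=8)
    _, labels = generate_cohort(cfg)
    n_pos = sum(labels.entries.values())
    sigma = (n * p * (1 - p)) ** 0.5
    assert abs(n_pos - n * p) <= 3 * sigma


def test_every_patient_labelled_even_without_events():
    cfg = CohortConfig(n_patients=200, prevalence=0.3, n_codes=20,
                       mean_events=0.5, seed=3)
    events, labels = generate_cohort(cfg)
    assert len(labels) == 200
    assert set(events.patient_ids) <= set(labels.entries)
    assert len(set(events.patient_ids)) < 200  # Poisson(0.5) leaves zero-event patients


def test_zipf_slope_recovered_in_loglog_regression():
    s = 1.2
    cfg = CohortConfig(n_patients=2000, prevalence=0.1, n_codes=1000,
                       zipf_exponent=s, mean_events=60.0, seed=17)
    events, _ = generate_cohort(cfg)
    counts = events.codes.value_counts().to_numpy()
    # regress over the well-sampled head of the distribution
    top = np.sort(counts)[::-1][:100]
    ranks = np.arange(1, len(top) + 1)
    slope = scipy.stats.linregress(np.log(ranks), np.log(top)).slope
    assert abs(-slope - s) / s <= 0.15


def test_null_cohort_passes_bonferroni_chi2_calibration():
    """With no planted codes, no code should clear the Bonferroni chi-square
    threshold in at least 95% of seeds (family-wise error control).

    The cohort is large enough (n=2000) that even the rarest Zipf-tail code
    appears in ~15 patients, keeping the asymptotic chi-square null valid.
    """
    clean = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = CohortConfig(n_patients=2000, prevalence=0.2, n_codes=150,
                           mean_events=20.0, seed=seed)
        events, labels = generate_cohort(cfg)
        matrix = build_matrix(events, labels, build_vocabulary(events))
        ranked = rank_features(matrix, method="chi2")
        max_chi2 = ranked.entries[0][1]
        threshold = scipy.stats.chi2.isf(0.05 / len(matrix.vocab), df=1)
        clean += max_chi2 <= threshold
    assert clean >= int(0.95 * n_seeds)


def test_planted_codes_enriched_in_positives():
    cfg = CohortConfig(n_patients=1500, prevalence=0.1, n_codes=200,
                       mean_events=30.0,
                       informative=((0, 4.0, 0.01), (5, 4.0, 0.01)),
                       seed=12)
    events, labels = generate_cohort(cfg)
    matrix = build_matrix(events, labels, build_vocabulary(events))
    names = sorted({c for c in events.codes})  # vocabulary order
    from phenotree.simulate import default_code_names

    planted = {default_code_names(200)[0], default_code_names(200)[5]}
    ranked = rank_features(matrix, method="chi2")
    assert planted <= set(ranked.top(5))


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_patients=0, prevalence=0.1, n_codes=10),
        dict(n_patients=10, prevalence=0.0, n_codes=10),
        dict(n_patients=10, prevalence=0.1, n_codes=10, zipf_exponent=0),
        dict(n_patients=10, prevalence=0.1, n_codes=10,
             informative=((0, 0.5, 0.01),)),
        dict(n_patients=10, prevalence=0.1, n_codes=10,
             informative=((0, 2.0, 0.6), (1, 2.0, 0.6))),
        dict(n_patients=10, prevalence=0.1, n_codes=10,
             informative=((0, 2.0, 0.1), (0, 3.0, 0.1))),
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        CohortConfig(**kwargs)


def test_golden_fixtures_deterministic_and_shaped():
    for name in ("tiny_separable", "tiny_imbalanced"):
        e1, l1 = golden_fixture(name)
        e2, l2 = golden_fixture(name)
        assert e1.frame.equals(e2.frame) and l1.entries == l2.entries
    e, l = golden_fixture("tiny_separable")
    assert len(l) == 12 and sum(l.entries.values()) == 6
    e, l = golden_fixture("tiny_imbalanced")
    assert len(l) == 50 and sum(l.entries.values()) == 2
    with pytest.raises(ConfigurationError):
        golden_fixture("nope")


def test_as_like_fixture_top2_codes_are_planted(as_like_matrix):
    _, labels = golden_fixture("as_like")
    assert len(labels) == 2000
    prevalence = sum(labels.entries.values()) / 2000
    assert 0.01 <= prevalence <= 0.035
    ranked = rank_features(as_like_matrix, method="chi2")
    assert set(ranked.top(2)) == {"N100.", "F440."}


def test_ra_like_fixture_prevalence():
    _, labels = golden_fixture("ra_like")
    prevalence = sum(labels.entries.values()) / len(labels)
    assert 0.10 <= prevalence <= 0.18
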