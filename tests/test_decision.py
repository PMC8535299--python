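"""Posterior fusion rules, threshold, and the decision layer."""

import numpy as np
import pytest

import diabfuse as df
from diabfuse.decision import (
    ClassPriors,
    FusionModel,
    average_density,
    classify,
    combine_rule,
    fusion_threshold,
    sweep_threshold,
)


class StubMember:
    """Member that returns a fixed posterior (or a per-row mapping)."""

    def __init__(self, value):
        self.value = value

    def posterior_target(self, x):
        return self.value if np.isscalar(self.value) else float(self.value(x))

    def posterior_target_batch(self, X):
        X = np.atleast_2d(X)
        if np.isscalar(self.value):
            return np.full(X.shape[0], self.value)
        return np.array([float(self.value(x)) for x in X])


def make_fm(posteriors, priors=(0.5, 0.5), **kw):
    return FusionModel(
        members=[StubMember(p) for p in posteriors],
        priors=ClassPriors(p_target=priors[0], p_outlier=priors[1]),
        **kw,
    )


@pytest.mark.parametrize(
    "posteriors, rule, expected",
    [
        ((0.8, 0.6), "mean", 0.7),
        ((0.5, 0.5), "mean", 0.5),
        ((0.5, 0.5), "min", 0.5),
        ((0.5, 0.5), "max", 0.5),
        ((0.5, 0.5), "product", 0.25),
        ((0.7,), "product", 0.7),  # single member: every rule is identity
        ((0.7,), "min", 0.7),
    ],
)
def test_combine_rule_values(posteriors, rule, expected):
    assert combine_rule(posteriors, rule) == pytest.approx(expected)


def test_combine_rule_rejects_empty_and_unknown():
    with pytest.raises(ValueError):
        combine_rule([], "mean")
    with pytest.raises(ValueError):
        combine_rule([0.5], "median")


def test_rule_ordering_product_min_mean_max():
    rng = np.random.default_rng(0)
    for _ in range(100):
        p = rng.random(rng.integers(1, 6))
        prod = combine_rule(p, "product")
        mn = combine_rule(p, "min")
        mean = combine_rule(p, "mean")
        mx = combine_rule(p, "max")
        assert prod <= mn + 1e-12
        assert mn <= mean + 1e-12
        assert mean <= mx + 1e-12
        # mean equals the brute-force average
        assert mean == pytest.approx(sum(p) / len(p))


@pytest.mark.parametrize(
    "priors, theta, expected",
    [
        ((0.5, 0.5), (1.0, 1.0), 1.0),
        ((0.335, 0.665), (1.0, 1.0), 0.665 / 0.335),
        ((0.5, 0.5), (2.0, 4.0), 3.0),
    ],
)
def test_fusion_threshold(priors, theta, expected):
    pr = ClassPriors(p_target=priors[0], p_outlier=priors[1])
    assert fusion_threshold(pr, theta) == pytest.approx(expected)


def test_fusion_threshold_rejects_bad_inputs():
    with pytest.raises(ValueError):
        ClassPriors(p_target=0.0, p_outlier=1.0)
    with pytest.raises(ValueError):
        fusion_threshold(ClassPriors(0.5, 0.5), (0.0,))


def test_member_posteriors_order_and_clipping():
    fm = make_fm([0.9, 0.0])  # exact 0 must be clipped away
    p = fm.member_posteriors(np.zeros(2))
    assert p[0] == pytest.approx(0.9)
    assert 0.0 < p[1] < 1e-11


def test_mu_complementarity_mean_rule():
    rng = np.random.default_rng(1)
    for _ in range(20):
        vals = rng.random(3)
        fm = make_fm(vals)
        d = classify(fm, np.zeros(2))
        assert d.mu_target + d.mu_outlier == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize(
    "posteriors, expected_label",
    [((0.9, 0.8), 1), ((0.2, 0.3), 0), ((0.5, 0.5), 1)],  # tie goes to target
)
def test_classify_mean_posterior_mode(posteriors, expected_label):
    fm = make_fm(posteriors)
    assert classify(fm, np.zeros(2)).label == expected_label


def test_classify_density_threshold_mode():
    # mean posterior 0.6, p_target 0.5 -> y_avg proxy 1.2
    fm = make_fm([0.6, 0.6], mode="density_threshold")
    d = classify(fm, np.zeros(2))
    assert d.y_avg == pytest.approx(1.2)
    assert d.label == 1  # 1.2 >= theta_bar = 1
    assert classify(fm, np.zeros(2), threshold=1.5).label == 0
    # equality at the boundary goes to the target class
    assert classify(fm, np.zeros(2), threshold=1.2).label == 1


def test_average_density_monotone_in_mean_posterior():
    vals = [0.1, 0.3, 0.5, 0.9]
    dens = [average_density(make_fm([v]), np.zeros(2)) for v in vals]
    assert np.all(np.diff(dens) > 0)
    # single member reduces to posterior / prior
    assert dens[0] == pytest.approx(0.1 / 0.5)


def test_classify_is_deterministic():
    fm = make_fm([0.42, 0.77])
    x = np.ones(3)
    assert classify(fm, x) == classify(fm, x)


def test_sweep_threshold_tradeoff(schema):
    rng = np.random.default_rng(3)
    n = 200
    labels = (rng.random(n) < 0.4).astype(int)
    values = rng.normal(size=(n, 8))
    ds = df.LabeledDataset(
        values=values, labels=labels,
        sources=np.array(["t"] * n, dtype=object), schema=schema,
    )
    # posterior correlated with the first standardized feature plus label signal
    score = 1.0 / (1.0 + np.exp(-(values[:, 0] + 2.0 * labels)))
    member = StubMember(lambda x: float(1.0 / (1.0 + np.exp(-(x[0] + 0.0)))))

    class RowMember:
        def posterior_target_batch(self, X):
            return score

        def posterior_target(self, x):
            raise NotImplementedError

    fm = FusionModel(members=[RowMember()], priors=ClassPriors(0.4, 0.6), mode="density_threshold")
    grid = np.linspace(0.0, 3.0, 10)
    table = sweep_threshold(fm, ds, grid)
    # theta 0 -> everything target -> FNR 0; huge theta -> everything outlier -> FPR 0
    assert table.iloc[0]["fnr"] == 0.0
    big = sweep_threshold(fm, ds, [score.max() / 0.4 + 1.0])
    assert big.iloc[0]["fpr"] == 0.0
    # FNR non-decreasing and FPR non-increasing as theta rises
    assert np.all(np.diff(table["fnr"]) >= -1e-12)
    assert np.all(np.diff(table["fpr"]) <= 1e-12)


def test_sweep_threshold_empty_grid(schema):
    fm = make_fm([0.5], mode="density_threshold")
    ds = df.LabeledDataset(
        values=np.zeros((2, 8)), labels=np.array([0, 1]),
        sources=np.array(["t", "t"], dtype=object), schema=schema,
    )
    with pytest.raises(ValueError):
        sweep_threshold(fm, ds, [])
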