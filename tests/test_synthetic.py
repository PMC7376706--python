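"""Generator: moment matching, truncation, determinism, parameter recovery."""

import dataclasses

import numpy as np
import pytest

from cytoroc import default_study_params, fit_lognormal_from_mean_median, generate_cohort
from cytoroc.cohort import MARKER_COLUMNS
from cytoroc.synthetic import MarkerParams, GroupParams, params_from_json, params_to_json


@pytest.mark.parametrize(
    "mean, median, mu, sigma",
    [
        (1157.62, 600.00, 6.3969, 1.1464),  # suboptimal CA-125 summary
        (237.52, 120.30, 4.7900, 1.1666),  # optimal CA-125 summary
    ],
)
def test_lognormal_fit_matches_closed_form(mean, median, mu, sigma):
    got_mu, got_sigma = fit_lognormal_from_mean_median(mean, median)
    assert got_mu == pytest.approx(mu, abs=5e-4)
    assert got_sigma == pytest.approx(sigma, abs=5e-4)
    # the fitted law reproduces the requested moments exactly
    assert np.exp(got_mu) == pytest.approx(median, rel=1e-12)
    assert np.exp(got_mu + got_sigma**2 / 2) == pytest.approx(mean, rel=1e-12)


def test_lognormal_fit_degenerate_and_errors():
    mu, sigma = fit_lognormal_from_mean_median(3.7, 3.7)
    assert sigma == 0.0 and np.exp(mu) == pytest.approx(3.7)
    with pytest.raises(ValueError):
        fit_lognormal_from_mean_median(100.0, 200.0)  # mean below median
    with pytest.raises(ValueError):
        fit_lognormal_from_mean_median(-1.0, 1.0)


def test_default_params_match_published_summaries():
    sub, opt = default_study_params()
    assert (sub.n, opt.n) == (56, 53)
    gls = sub.markers["gls"]
    assert (gls.mu, gls.sigma, gls.lo, gls.hi) == (25.19, 5.415, 14.27, 37.50)
    ca_opt = opt.markers["ca125"]
    assert (ca_opt.lo, ca_opt.hi) == (5.10, 1941.90)
    for gp in (sub, opt):
        assert abs(sum(gp.stage_probs.values()) - 1.0) < 1e-9
        assert abs(sum(gp.histology_probs.values()) - 1.0) < 1e-9


def test_generation_is_deterministic():
    a = generate_cohort(seed=42)
    b = generate_cohort(seed=42)
    assert a.data.equals(b.data)
    c = generate_cohort(seed=43)
    assert not a.data.equals(c.data)


def test_all_values_inside_truncation_bounds(study_cohort):
    sub, opt = default_study_params()
    for gp, label in ((sub, "suboptimal"), (opt, "optimal")):
        rows = study_cohort.data[study_cohort.data["group"] == label]
        for marker, col in MARKER_COLUMNS.items():
            p = gp.markers[marker]
            assert rows[col].between(p.lo, p.hi).all()


def _scaled(gp, n):
    return dataclasses.replace(gp, n=n)


def test_median_and_mean_recovery_at_large_n():
    sub, opt = default_study_params()
    big = generate_cohort((_scaled(sub, 10_000), _scaled(opt, 10_000)), seed=7,
                          with_covariates=False)
    df = big.data
    # lognormal markers: sample median within 10% of the target median
    for label, gp in (("suboptimal", sub), ("optimal", opt)):
        rows = df[df["group"] == label]
        for marker in ("ca125", "fasn"):
            target = np.exp(gp.markers[marker].mu)
            got = rows[MARKER_COLUMNS[marker]].median()
            assert got == pytest.approx(target, rel=0.10)
        # truncated normal: sample mean within 5% of the truncation-adjusted
        # expectation (Monte-Carlo oracle via an independent generator)
        p = gp.markers["gls"]
        rng = np.random.default_rng(12345)
        draws = rng.normal(p.mu, p.sigma, 400_000)
        oracle = draws[(draws >= p.lo) & (draws <= p.hi)].mean()
        assert rows[MARKER_COLUMNS["gls"]].mean() == pytest.approx(oracle, rel=0.05)


def test_lognormal_parameter_recovery_round_trip():
    # untruncated sample -> summary stats -> fitted (mu, sigma) near truth
    mu, sigma = 6.3969, 1.1464
    rng = np.random.default_rng(11)
    x = rng.lognormal(mu, sigma, 50_000)
    got_mu, got_sigma = fit_lognormal_from_mean_median(x.mean(), np.median(x))
    assert got_mu == pytest.approx(mu, rel=0.02)
    assert got_sigma == pytest.approx(sigma, rel=0.05)


def test_covariates_follow_group_proportions(study_cohort):
    opt_rows = study_cohort.data[study_cohort.data["group"] == "optimal"]
    assert not (opt_rows["stage"] == "IV").any()  # probability 0 in that group
    assert set(study_cohort.data["stage"]) <= {"II", "III", "IV"}


def test_inconsistent_bounds_raise():
    bad = MarkerParams("gls", "truncated-normal", mu=0.0, sigma=0.001,
                       lo=50.0, hi=51.0)
    gp = GroupParams("suboptimal", 10, {"ca125": bad, "fasn": bad, "gls": bad})
    sub, opt = default_study_params()
    with pytest.raises(ValueError, match="rejection"):
        generate_cohort((gp, opt), seed=0, with_covariates=False)


def test_params_json_round_trip(tmp_path):
    params = default_study_params()
    path = tmp_path / "params.json"
    params_to_json(params, path)
    back = params_from_json(path)
    assert back == params
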