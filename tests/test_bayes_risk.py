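import numpy as np
import pytest
from hypothesis import given, strategies as st

from hfrpam.bayes_risk import (
    ALL_CAUSE,
    LEVELS,
    DenominatorConfig,
    RiskBandScheme,
    assess_risk,
    classify_band,
    count_levels,
    is_risky,
    map_correlation_level,
    posterior_probability,
)
from hfrpam.factor_model import CorrelationAnchors


def brute_force_levels(column, anchors=CorrelationAnchors()):
    """Independent tally oracle: explicit loop, no shared code path."""
    out = {"low": 0, "medium": 0, "high": 0}
    for r in column:
        if r <= anchors.low_max:
            out["low"] += 1
        elif r == anchors.medium_value:
            out["medium"] += 1
        else:
            out["high"] += 1
    return out


class TestLevelMapping:
    @pytest.mark.parametrize(
        "rating,level",
        [(1, "low"), (2, "low"), (3, "medium"), (4, "high"), (5, "high")],
    )
    def test_default_anchors(self, rating, level):
        assert map_correlation_level(rating) == level

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            map_correlation_level(6)


class TestCountLevels:
    def test_all_fives(self, make_panel, hierarchy):
        counts = count_levels(make_panel(np.full((2, 8), 5)), hierarchy)
        for f in hierarchy.factors:
            assert counts.per_factor[f] == {"low": 0, "medium": 0, "high": 2}
        assert counts.pooled == {"low": 0, "medium": 0, "high": 16}

    def test_mixed_column(self, make_panel, hierarchy):
        ratings = np.full((3, 8), 5)
        ratings[:, 2] = [1, 3, 4]  # X3
        counts = count_levels(make_panel(ratings), hierarchy)
        assert counts.per_factor["X3"] == {"low": 1, "medium": 1, "high": 1}

    def test_group_cells(self, make_panel, hierarchy):
        counts = count_levels(make_panel(np.full((5, 8), 3)), hierarchy)
        assert counts.group_cells == {
            "core_stage": 20,
            "external_stage": 20,
            "secondary": 30,
            "all": 40,
        }

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_tally(self, random_panel, hierarchy, seed):
        panel = random_panel(10, seed=seed)
        counts = count_levels(panel, hierarchy)
        for f in hierarchy.factors:
            assert counts.per_factor[f] == brute_force_levels(panel.column(f))

    def test_counts_sum_to_n(self, random_panel, hierarchy):
        panel = random_panel(17, seed=42)
        counts = count_levels(panel, hierarchy)
        for f in hierarchy.factors:
            assert sum(counts.per_factor[f].values()) == 17


class TestPosteriorProbability:
    def test_hand_evaluation(self):
        pc = posterior_probability(0.5, 0.8)
        assert pc.inverse == pytest.approx(0.2)
        assert pc.marginal == pytest.approx(0.5)
        assert pc.posterior == pytest.approx(0.8)

    def test_prior_one(self):
        pc = posterior_probability(1.0, 0.3)
        assert pc.marginal == pytest.approx(0.3)
        assert pc.posterior == pytest.approx(1.0)

    def test_symmetric_likelihood_returns_prior(self):
        for prior in (0.1, 0.37, 0.9):
            assert posterior_probability(prior, 0.5).posterior == pytest.approx(prior)

    def test_marginal_zero_flagged(self):
        pc = posterior_probability(0.0, 1.0)
        assert pc.marginal == 0.0
        assert pc.undefined

    @pytest.mark.parametrize("prior,lik", [(-0.1, 0.5), (0.5, 1.5)])
    def test_inputs_outside_unit_interval(self, prior, lik):
        with pytest.raises(ValueError):
            posterior_probability(prior, lik)

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_posterior_in_unit_interval(self, prior, lik):
        pc = posterior_probability(prior, lik)
        if not pc.undefined:
            assert 0.0 <= pc.posterior <= 1.0

    def test_monotone_in_likelihood(self):
        # posterior p*l / (p*l + (1-p)(1-l)) is increasing in l on a grid
        for prior in (0.2, 0.5, 0.8):
            liks = np.linspace(0.01, 0.99, 50)
            posts = [posterior_probability(prior, l).posterior for l in liks]
            assert np.all(np.diff(posts) > 0)


class TestBanding:
    @pytest.mark.parametrize(
        "p,band",
        [
            (0.9838, "high"),
            (0.4803, "medium"),
            (0.4652, "medium"),
            (0.0545, "low"),
            (0.3243, "low"),
            (0.805, "high"),  # gap [0.80, 0.81) closed upward
            (0.4, "low"),
            (0.8, "high"),
            (0.0, "low"),
            (1.0, "high"),
        ],
    )
    def test_band_examples(self, p, band):
        assert classify_band(p) == band

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_bands_partition_unit_interval(self, p):
        assert classify_band(p) in ("low", "medium", "high")

    def test_risky_cut(self):
        assert not is_risky(0.4)
        assert is_risky(0.41)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_band(1.1)


class TestAssessRisk:
    def test_all_fives_all_cause_certainty(self, make_panel, hierarchy):
        ra = assess_risk(make_panel(np.full((4, 8), 5)), hierarchy)
        row = ra.lookup(ALL_CAUSE, "high")
        assert row["posterior"] == pytest.approx(1.0)
        assert row["band"] == "high"

    def test_all_fives_factor_level_under_default_denominators(
        self, make_panel, hierarchy
    ):
        # with prior = n/(4n) = 0.25 and likelihood = n/(6n) = 1/6 the
        # published combination rule gives 0.0625, not certainty
        ra = assess_risk(make_panel(np.full((4, 8), 5)), hierarchy)
        for f in hierarchy.factors:
            row = ra.lookup(f, "high")
            assert row["prior"] == pytest.approx(0.25)
            assert row["likelihood"] == pytest.approx(1 / 6)
            assert row["posterior"] == pytest.approx(0.0625)

    def test_all_fives_certainty_with_column_denominators(
        self, make_panel, hierarchy
    ):
        ra = assess_risk(
            make_panel(np.full((4, 8), 5)),
            hierarchy,
            denominators=DenominatorConfig(prior="column", likelihood="column"),
        )
        for scope in list(hierarchy.factors) + [ALL_CAUSE]:
            row = ra.lookup(scope, "high")
            assert row["posterior"] == pytest.approx(1.0)
            assert row["band"] == "high"

    def test_all_ones_no_high_risk(self, make_panel, hierarchy):
        ra = assess_risk(make_panel(np.full((4, 8), 1)), hierarchy)
        for scope in list(hierarchy.factors) + [ALL_CAUSE]:
            row = ra.lookup(scope, "high")
            assert row["prior"] == 0.0
            assert row["likelihood"] == 0.0
            assert row["posterior"] == pytest.approx(0.0)
            assert row["band"] == "low"
            assert not row["risky"]

    def test_counting_scheme_oracle(self, random_panel, hierarchy):
        # spreadsheet-style recomputation on a seeded 12x8 panel
        panel = random_panel(12, seed=99)
        ra = assess_risk(panel, hierarchy)
        n = 12
        for f in hierarchy.factors:
            tallies = brute_force_levels(panel.column(f))
            stage_cols = hierarchy.stage_group(f)
            stage_cells = len(stage_cols) * n
            secondary_cells = 6 * n
            for lv in LEVELS:
                prior = tallies[lv] / stage_cells
                lik = tallies[lv] / secondary_cells
                inverse = 1 - lik
                marginal = prior * lik + (1 - prior) * inverse
                row = ra.lookup(f, lv)
                assert row["prior"] == pytest.approx(prior)
                assert row["likelihood"] == pytest.approx(lik)
                assert row["marginal"] == pytest.approx(marginal)
                if marginal > 0:
                    assert row["posterior"] == pytest.approx(prior * lik / marginal)

    def test_all_cause_uses_pooled_counts(self, random_panel, hierarchy):
        panel = random_panel(9, seed=5)
        ra = assess_risk(panel, hierarchy)
        pooled = {"low": 0, "medium": 0, "high": 0}
        for f in hierarchy.factors:
            for lv, c in brute_force_levels(panel.column(f)).items():
                pooled[lv] += c
        cells = 8 * 9
        for lv in LEVELS:
            row = ra.lookup(ALL_CAUSE, lv)
            assert row["prior"] == pytest.approx(pooled[lv] / cells)
            assert row["likelihood"] == pytest.approx(pooled[lv] / cells)

    @pytest.mark.parametrize("seed", range(30))
    def test_posteriors_in_unit_interval(self, random_panel, hierarchy, seed):
        ra = assess_risk(random_panel(10, seed=seed), hierarchy)
        defined = ra.records[~ra.records["undefined"]]
        assert ((defined["posterior"] >= 0) & (defined["posterior"] <= 1)).all()

    def test_configurable_denominators(self, random_panel, hierarchy):
        panel = random_panel(10, seed=1)
        ra = assess_risk(
            panel, hierarchy, denominators=DenominatorConfig(prior="all",
                                                             likelihood="all")
        )
        tallies = brute_force_levels(panel.column("X2"))
        assert ra.lookup("X2", "high")["prior"] == pytest.approx(
            tallies["high"] / 80
        )

    def test_canonical_mode_normalizes_over_levels(self, random_panel, hierarchy):
        panel = random_panel(15, seed=3)
        ra = assess_risk(panel, hierarchy, canonical=True)
        for f in hierarchy.factors:
            rows = ra.records[ra.records["scope"] == f]
            total = (rows["prior"] * rows["likelihood"]).sum()
            if total > 0:
                assert rows["posterior"].sum() == pytest.approx(1.0)

    def test_band_scheme_override(self, make_panel, hierarchy):
        ra = assess_risk(
            make_panel(np.full((4, 8), 5)),
            hierarchy,
            scheme=RiskBandScheme(risky_cut=0.3, high_min=0.9),
        )
        assert ra.lookup(ALL_CAUSE, "high")["band"] == "high"
        # factor-level posterior 0.0625 is below the overridden risky cut
        assert ra.lookup("X1", "high")["band"] == "low"
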