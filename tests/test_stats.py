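"""Statistics layer: standardization, robust regression, rank-sum, reporting."""

import json

import numpy as np
import pandas as pd
import pytest

from moral_inference.stats import (
    phenotype_report,
    ranksum_test,
    render_report,
    reverse_uncertainty,
    robust_fit,
    standardize,
    wald_interaction_test,
)


class TestStandardize:
    def test_symmetric_triple(self):
        assert np.allclose(standardize([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        z = standardize(rng.normal(3.0, 2.0, 500))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=40)
        assert np.allclose(standardize(standardize(x)), standardize(x))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            standardize([2.0, 2.0, 2.0])


class TestReverseUncertainty:
    @pytest.mark.parametrize("c,u", [(1.0, 0.0), (0.0, 1.0), (0.25, 0.75)])
    def test_values(self, c, u):
        assert reverse_uncertainty(c) == pytest.approx(u)

    def test_order_reversing_and_range_check(self):
        x = np.array([0.1, 0.5, 0.9])
        assert np.all(np.diff(reverse_uncertainty(x)) < 0)
        with pytest.raises(ValueError):
            reverse_uncertainty(1.2)


def _cell_mean_table(cells, reps=4, noise=0.0, seed=0):
    """Long table with exact cell means per group x agent (optionally noisy)."""
    rng = np.random.default_rng(seed)
    rows = []
    for (group, agent), mean in cells.items():
        for r in range(reps):
            rows.append(
                {
                    "participant_id": f"{group}-{agent}-{r}",
                    "group": group,
                    "agent": agent,
                    "trial_index": r + 1,
                    "measure": "uncertainty",
                    "value": mean + (rng.normal(0, noise) if noise else 0.0),
                }
            )
    return pd.DataFrame(rows)


class TestRobustFit:
    CELLS = {
        ("BPD", "bad"): 0.30, ("BPD", "good"): 0.35,
        ("non-BPD", "bad"): 0.60, ("non-BPD", "good"): 0.20,
        ("DTC", "bad"): 0.55, ("DTC", "good"): 0.25,
    }

    def test_noise_free_cell_means_give_exact_contrasts(self):
        table = _cell_mean_table(self.CELLS)
        ct = robust_fit(table, "uncertainty", reference_group="BPD", include_trial=False)
        get = lambda frag: float(ct.loc[ct["term"].str.contains(frag, regex=False), "estimate"].iloc[0])
        base = self.CELLS[("BPD", "bad")] - self.CELLS[("BPD", "good")]
        assert get("Intercept") == pytest.approx(self.CELLS[("BPD", "good")], abs=1e-10)
        assert float(ct.loc[ct["term"] == "agent_bad", "estimate"].iloc[0]) == pytest.approx(base, abs=1e-10)
        for g in ("non-BPD", "DTC"):
            expect = (self.CELLS[(g, "bad")] - self.CELLS[(g, "good")]) - base
            assert get(f"agent_bad:C(group, Treatment(reference='BPD'))[T.{g}]") == pytest.approx(
                expect, abs=1e-10
            )

    def test_matches_ols_when_residuals_vanish(self):
        import statsmodels.api as sm
        from patsy import dmatrices

        table = _cell_mean_table(self.CELLS)
        table = table.assign(agent_bad=(table["agent"] == "bad").astype(float))
        y, x = dmatrices(
            "value ~ agent_bad * C(group, Treatment(reference='BPD'))",
            data=table, return_type="dataframe",
        )
        ols = sm.OLS(np.asarray(y).ravel(), x).fit()
        ct = robust_fit(table, "uncertainty", reference_group="BPD", include_trial=False)
        assert np.allclose(ct["estimate"].to_numpy(), ols.params.to_numpy(), atol=1e-6)

    def test_single_gross_outlier_hurts_ols_more(self):
        rng = np.random.default_rng(4)
        n = 60
        x = rng.uniform(-1, 1, n)
        slope = 2.0
        y = slope * x + rng.normal(0, 0.1, n)
        y[0] += 40.0  # gross outlier
        table = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(n)],
                "group": "BPD",
                "agent": np.where(x > 0, "bad", "good"),
                "trial_index": 1,
                "measure": "uncertainty",
                "value": y,
                "xcov": x,
            }
        )
        ct = robust_fit(
            table, "uncertainty", include_agent=False, include_group=False,
            include_trial=False, covariates=("xcov",),
        )
        robust_slope = float(ct.loc[ct["term"] == "xcov", "estimate"].iloc[0])
        import statsmodels.api as sm

        ols_slope = sm.OLS(y, sm.add_constant(x)).fit().params[1]
        assert abs(robust_slope - slope) < abs(ols_slope - slope)
        assert abs(robust_slope - slope) < 0.1

    def test_rank_deficient_design_names_terms(self):
        table = _cell_mean_table(self.CELLS)
        table["dup"] = (table["agent"] == "bad").astype(float)  # duplicates agent_bad
        with pytest.raises(ValueError, match="dup"):
            robust_fit(table, "uncertainty", include_trial=False, covariates=("dup",))

    def test_t_equals_estimate_over_se(self):
        table = _cell_mean_table(self.CELLS, reps=6, noise=0.05, seed=2)
        ct = robust_fit(table, "uncertainty", include_trial=False)
        assert np.allclose(ct["t"], ct["estimate"] / ct["se"], atol=1e-8)

    def test_wald_interaction_on_null_cells(self):
        cells = {(g, a): 0.4 + (0.1 if a == "bad" else 0.0) for g in ("BPD", "non-BPD", "DTC") for a in ("bad", "good")}
        table = _cell_mean_table(cells, reps=10, noise=0.05, seed=3)
        ct = robust_fit(table, "uncertainty", include_trial=False)
        stat, df, p = wald_interaction_test(ct)
        assert df == 2
        assert p > 0.05


class TestRankSum:
    def test_identical_samples(self):
        z, p = ranksum_test([1.0, 1.0, 1.0], [1.0, 1.0])
        assert z == 0.0 and p == 1.0

    def test_extreme_separation_small_n(self):
        z, p = ranksum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(2 / 20)  # exact enumeration over C(6,3)
        assert z < 0

    def test_antisymmetry(self):
        a, b = [1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 6.0]
        za, pa = ranksum_test(a, b)
        zb, pb = ranksum_test(b, a)
        assert za == pytest.approx(-zb)
        assert pa == pytest.approx(pb)

    @pytest.mark.parametrize(
        "a,b",
        [
            ([1, 2], [3, 4, 5]),
            ([1.5, 2.5, 2.5], [2.5, 3.5, 4.0]),  # ties across groups
            ([0, 0, 1], [0, 1, 1, 2]),  # heavy ties
            ([5], [1, 2, 3, 4]),
            ([1, 4, 2, 8], [3, 3, 9, 7, 5]),
        ],
    )
    def test_matches_exact_enumeration(self, exact_ranksum_p, a, b):
        _, p = ranksum_test(a, b)
        assert p == pytest.approx(exact_ranksum_p(a, b), abs=1e-12)

    def test_large_sample_matches_scipy_normal_approximation(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(9)
        a = rng.normal(0.0, 1.0, 25)
        b = rng.normal(0.4, 1.0, 30)
        _, p = ranksum_test(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref, abs=1e-10)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ranksum_test([], [1.0])


class TestPhenotypeReport:
    def _fits(self):
        table = _cell_mean_table(TestRobustFit.CELLS, reps=6, noise=0.03, seed=5)
        entry = {
            "omnibus": robust_fit(table, "uncertainty", include_trial=False),
            "simple": {
                agent: robust_fit(
                    table[table["agent"] == agent], "uncertainty",
                    include_agent=False, include_trial=False,
                )
                for agent in ("bad", "good")
            },
        }
        return {"uncertainty": entry}

    def test_report_structure_and_json_round_trip(self):
        report = phenotype_report(self._fits())
        assert "uncertainty" in report["measures"]
        entry = report["measures"]["uncertainty"]
        assert set(entry["interactions"]) == {"non-BPD", "DTC"}
        assert entry["agent_main"]["sign"] in (-1, 0, 1)
        back = json.loads(json.dumps(report))
        assert back == report

    def test_absent_measures_listed_not_fabricated(self):
        report = phenotype_report(self._fits())
        assert "learning_rate" in report["absent"]

    def test_render_mentions_each_interaction(self):
        text = render_report(phenotype_report(self._fits()))
        assert "non-BPD x agent interaction" in text
        assert "DTC x agent interaction" in text
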