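"""Recurrence filtering, stratum proportion tests, target-ledger overlaps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fgf21cohort.stats import AlphaPolicy
from fgf21cohort.targets import (
    TargetLedger,
    make_synthetic_ledger,
    overlap_percentage,
    proportion_compare,
    recurrence_filter,
    validate_targets,
)


def _calls_with_counts(n_up_calls, stratum_size=30, gene="TF1"):
    """Call matrix with exactly n_up_calls patients at +1 for one gene."""
    patients = [f"P{i}" for i in range(stratum_size)]
    row = [1] * n_up_calls + [0] * (stratum_size - n_up_calls)
    calls = pd.DataFrame([row], index=[gene], columns=patients)
    strata = pd.Series(["up"] * stratum_size, index=patients)
    return calls, strata


class TestRecurrenceFilter:
    @pytest.mark.parametrize("n, passes", [(10, True), (9, False), (11, True)])
    def test_ten_patient_boundary(self, n, passes):
        calls, strata = _calls_with_counts(n)
        record = recurrence_filter(calls, strata, ["TF1"])
        up_row = record[(record["gene_id"] == "TF1") & (record["stratum"] == "up")]
        assert bool(up_row["pass_up"].iloc[0]) is passes

    def test_pass_set_is_monotone_in_min_patients(self):
        rng = np.random.default_rng(0)
        patients = [f"P{i}" for i in range(40)]
        calls = pd.DataFrame(rng.choice([-1, 0, 1], size=(25, 40)),
                             index=[f"g{i}" for i in range(25)], columns=patients)
        strata = pd.Series(["up"] * 20 + ["down"] * 20, index=patients)
        prev = None
        for mp in (5, 10, 15):
            rec = recurrence_filter(calls, strata, list(calls.index),
                                    min_patients=mp)
            passing = set(
                rec.loc[rec["pass_up"] | rec["pass_down"], "gene_id"]
            )
            if prev is not None:
                assert passing.issubset(prev)
            prev = passing

    def test_empty_candidates_warn_and_return_empty(self, caplog):
        calls, strata = _calls_with_counts(5)
        with caplog.at_level("WARNING", logger="fgf21cohort"):
            record = recurrence_filter(calls, strata, [])
        assert record.empty

    def test_pooled_mode_merges_strata(self):
        patients = [f"P{i}" for i in range(20)]
        calls = pd.DataFrame([[1] * 6 + [0] * 4 + [1] * 6 + [0] * 4],
                             index=["TF1"], columns=patients)
        strata = pd.Series(["up"] * 10 + ["down"] * 10, index=patients)
        within = recurrence_filter(calls, strata, ["TF1"], min_patients=10)
        pooled = recurrence_filter(calls, strata, ["TF1"], min_patients=10,
                                   pooled=True)
        assert not (within["pass_up"]).any()          # 6 per stratum
        assert bool(pooled["pass_up"].iloc[0])        # 12 pooled

    def test_planted_regulators_are_recovered(self, strong_cohort):
        """With strong planted effects the pass set equals the planted
        program genes for the matching stratum and direction."""
        from fgf21cohort.stratify import control_reference, direction_calls, stratify

        config, expr, meta, truth = strong_cohort
        ref = control_reference(expr, meta)
        calls = direction_calls(expr, ref, meta)
        status = stratify(expr, meta, reference=ref).status
        up_programs = truth.gene_programs[
            (truth.gene_programs["stratum"] == "up")
            & (truth.gene_programs["direction"] == 1)
        ]["gene_id"]
        null_genes = [g for g in expr.index if g.startswith("G")][-30:]
        candidates = list(up_programs) + null_genes
        record = recurrence_filter(calls, status, candidates)
        up_pass = set(
            record.loc[(record["stratum"] == "up") & record["pass_up"], "gene_id"]
        )
        assert up_pass == set(up_programs)

    def test_null_pass_count_matches_binomial_tail(self):
        """On Bernoulli-null calls the expected number of passing genes is
        n_genes * P(Bin(n_patients, p) >= 10) (oracle check)."""
        rng = np.random.default_rng(7)
        n_genes, n_pat, p_call = 400, 60, 0.1
        patients = [f"P{i}" for i in range(n_pat)]
        up_calls = (rng.random((n_genes, n_pat)) < p_call).astype(int)
        calls = pd.DataFrame(up_calls, index=[f"g{i}" for i in range(n_genes)],
                             columns=patients)
        strata = pd.Series(["up"] * n_pat, index=patients)
        record = recurrence_filter(calls, strata, list(calls.index))
        observed = int(record.loc[record["stratum"] == "up", "pass_up"].sum())
        tail = sps.binom.sf(9, n_pat, p_call)
        expected = n_genes * tail
        sd = np.sqrt(n_genes * tail * (1 - tail))
        assert abs(observed - expected) <= 4 * sd


class TestProportionCompare:
    def _record(self, up_reg, n_up, down_reg, n_down):
        return pd.DataFrame(
            {
                "gene_id": ["TF1", "TF1"],
                "stratum": ["up", "down"],
                "n_stratum": [n_up, n_down],
                "n_up_calls": [up_reg, down_reg],
                "n_down_calls": [0, 0],
                "pass_up": [True, True],
                "pass_down": [False, False],
            }
        )

    def test_exactly_proportional_counts_are_not_significant(self):
        record = self._record(20, 100, 30, 150)
        comp = proportion_compare(record, "TF1")
        assert comp.result.p == pytest.approx(1.0)
        assert not comp.significant

    def test_flag_matches_direct_formula_oracle(self):
        """2x2 Williams-corrected G computed from first principles."""
        record = self._record(30, 117, 5, 159)
        comp = proportion_compare(record, "TF1")
        obs = np.array([[30.0, 5.0], [87.0, 154.0]])
        n = obs.sum()
        expected = np.outer(obs.sum(1), obs.sum(0)) / n
        g = 2 * np.sum(obs * np.log(obs / expected))
        q = 1 + ((n * np.sum(1 / obs.sum(1)) - 1)
                 * (n * np.sum(1 / obs.sum(0)) - 1)) / (6 * n)
        p = sps.chi2.sf(g / q, 1)
        assert comp.result.p == pytest.approx(p, rel=1e-12)
        assert comp.significant is bool(p < 0.025)
        assert comp.alpha == pytest.approx(0.025)

    def test_symmetric_under_stratum_swap(self):
        a = proportion_compare(self._record(30, 117, 5, 159), "TF1")
        b = proportion_compare(self._record(5, 159, 30, 117), "TF1")
        assert a.result.p == pytest.approx(b.result.p)

    def test_zero_stratum_size_is_an_error(self):
        with pytest.raises(ValueError):
            proportion_compare(self._record(0, 0, 5, 10), "TF1")


class TestTargetLedger:
    def test_published_counts_reproduce_printed_percentages(self):
        """87/188 shared with animal models = 46.3%; 146/188 regulated in
        patients = 77.7% (> 77%)."""
        report = validate_targets(make_synthetic_ledger()).set_index("evidence")
        assert report.loc["animal_models", "n_overlap"] == 87
        assert report.loc["animal_models", "pct_of_master"] == 46.3
        assert report.loc["patients_regulated", "n_overlap"] == 146
        assert report.loc["patients_regulated", "pct_of_master"] == 77.7
        assert report.loc["patients_regulated", "pct_of_master"] > 77

    def test_disjoint_sets_give_zero_percent(self):
        ledger = TargetLedger(master=["a", "b"], evidence={"e": {"x", "y"}})
        report = validate_targets(ledger).set_index("evidence")
        assert report.loc["e", "pct_of_master"] == 0.0

    def test_percentage_is_asymmetric_for_unequal_sets(self):
        big = [f"m{i}" for i in range(100)]
        small = big[:20] + ["zz"]
        _, pct_big = overlap_percentage(big, small)
        _, pct_small = overlap_percentage(small, big)
        assert pct_big == 20.0
        assert pct_small == pytest.approx(95.2)

    def test_master_list_is_deduplicated(self):
        ledger = TargetLedger(master=["a", "b", "a"], evidence={})
        assert ledger.master == ["a", "b"]

    def test_empty_master_is_an_error(self):
        with pytest.raises(ValueError):
            TargetLedger(master=[])

    def test_from_tables_builds_membership(self):
        master = pd.DataFrame({"gene_id": ["a", "b", "a"],
                               "source": ["knockout", "analog", "transgenic"]})
        ev = {"animal": pd.DataFrame({"gene_id": ["b", "c"],
                                      "source": ["x", "x"]})}
        ledger = TargetLedger.from_tables(master, ev)
        assert ledger.master == ["a", "b"]
        assert sorted(ledger.source_tags["a"]) == ["knockout", "transgenic"]
        assert ledger.evidence["animal"] == {"b", "c"}
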