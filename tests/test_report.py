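"""Engagement accounting, SUS scoring, and geriatric-assessment change flags."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from remowear import fixtures, prompts as pr, report
from remowear._util import round_half_up
from remowear.synth import generate_cohort


@pytest.fixture(scope="module")
def table():
    return report.tabulate_completeness(fixtures.table2_ledger())


class TestCompleteness:
    def test_totals_row(self, table):
        tot = table[table["participant_id"] == "Total"].iloc[0]
        assert (tot["srh_scheduled"], tot["srh_completed"]) == (126, 108)
        assert (tot["symptom_scheduled"], tot["symptom_completed"]) == (53, 46)
        assert (tot["scale_scheduled"], tot["scale_completed"]) == (100, 83)
        assert (tot["watch_scheduled"], tot["watch_completed"]) == (62, 40)
        assert tot["watch_incomplete_participant"] == 14
        assert tot["watch_incomplete_device"] == 8

    def test_aggregate_percentages_half_up(self, table):
        tot = table[table["participant_id"] == "Total"].iloc[0]
        assert tot["srh_pct"] == 86
        assert tot["symptom_pct"] == 87
        assert tot["scale_pct"] == 83
        assert tot["watch_pct"] == 65

    def test_every_fixture_cell(self, table):
        for pid, mods in fixtures.COMPLETION_TABLE.items():
            row = table[table["participant_id"] == pid].iloc[0]
            for mod, (sched, comp, inc_p, inc_d) in mods.items():
                assert row[f"{mod}_scheduled"] == sched, (pid, mod)
                assert row[f"{mod}_completed"] == comp, (pid, mod)
                assert row[f"{mod}_incomplete_participant"] == inc_p, (pid, mod)
                assert row[f"{mod}_incomplete_device"] == inc_d, (pid, mod)

    def test_empty_ledger_reports_na(self):
        t = report.tabulate_completeness(pr.PromptLedger())
        assert t["srh_pct"].isna().all()
        assert (t["srh_scheduled"] == 0).all()

    def test_simulated_ledger_matches_recount(self):
        led = pr.run_simulation(generate_cohort(6, seed=5), seed=5, horizon_days=56)
        t = report.tabulate_completeness(led)
        df = led.to_frame()
        for mod in pr.MODALITIES:
            tot = t[t["participant_id"] == "Total"].iloc[0]
            g = df[df["modality"] == mod]
            assert tot[f"{mod}_scheduled"] == len(g)
            assert tot[f"{mod}_completed"] == (g["status"] == "completed").sum()

    def test_conservation_violation_names_row(self):
        led = fixtures.table2_ledger()
        led.prompts[0].status = "pending"
        with pytest.raises(pr.IntegrityError, match=led.prompts[0].participant_id):
            report.tabulate_completeness(led)


class TestParticipantAttributable:
    def test_watch_40_of_54(self):
        led = fixtures.table2_ledger()
        frac = report.participant_attributable(led, "watch")
        assert frac == pytest.approx(40 / 54)
        assert round_half_up(100 * frac) == 74

    def test_no_device_failures_equals_end_to_end(self):
        led = fixtures.table2_ledger()
        frac = report.participant_attributable(led, "srh")
        assert frac == pytest.approx(108 / 126)

    def test_all_device_failed_is_nan(self):
        led = pr.PromptLedger(prompts=[
            pr.PromptInstance("a", "p", "watch", datetime(2026, 1, 5), status="device_failed")
        ])
        assert np.isnan(report.participant_attributable(led, "watch"))

    def test_geq_end_to_end_when_failures_exist(self):
        led = fixtures.table2_ledger()
        e2e = 40 / 62
        assert report.participant_attributable(led, "watch") >= e2e


class TestRounding:
    @pytest.mark.parametrize(
        "num,den,expected", [(108, 126, 86), (46, 53, 87), (40, 62, 65), (40, 54, 74)]
    )
    def test_printed_style_percentages(self, num, den, expected):
        assert round_half_up(100 * num / den) == expected


class TestBlockEngagement:
    def _ledger(self, statuses_by_block, pid="p1", start=datetime(2026, 1, 5)):
        led = pr.PromptLedger(deployments={pid: start})
        k = 0
        for b, statuses in enumerate(statuses_by_block):
            for i, s in enumerate(statuses):
                issued = start + timedelta(days=28 * b + (i % 27))
                led.prompts.append(
                    pr.PromptInstance(f"q{k}", pid, "srh", issued, status=s)
                )
                k += 1
        return led

    def test_half_completed_meets_inclusive(self):
        led = self._ledger([["completed"] * 5 + ["expired"] * 5])
        blocks, _ = report.block_engagement(led, min_participants=1)
        assert blocks.iloc[0]["met"]

    def test_4_of_10_does_not_meet(self):
        led = self._ledger([["completed"] * 4 + ["expired"] * 6])
        blocks, crit = report.block_engagement(led, min_participants=1)
        assert not blocks.iloc[0]["met"]
        assert not crit

    def test_device_failed_leaves_denominator(self):
        led = self._ledger([["completed"] * 2 + ["device_failed"] * 6 + ["expired"] * 2])
        blocks, _ = report.block_engagement(led, min_participants=1)
        assert blocks.iloc[0]["scheduled"] == 4  # 10 - 6 device-failed
        assert blocks.iloc[0]["met"]  # 2/4

    def test_criterion_needs_enough_participants_in_every_block(self):
        led = pr.PromptLedger()
        start = datetime(2026, 1, 5)
        for i in range(10):
            pid = f"p{i}"
            led.deployments[pid] = start
            ok = i != 0  # participant 0 fails block 1
            for b in range(3):
                for j in range(10):
                    status = "completed" if (ok or b != 1 or j < 4) else "expired"
                    led.prompts.append(pr.PromptInstance(
                        f"{pid}-{b}-{j}", pid, "scale",
                        start + timedelta(days=28 * b + j * 2), status=status,
                    ))
        blocks, crit = report.block_engagement(led)
        assert crit  # 9/10 meet every block
        per = blocks[blocks["participant_id"] == "p0"]
        assert not per[per["block"] == 1]["met"].iloc[0]

    def test_monotone_in_completions(self):
        led = self._ledger([["completed"] * 5 + ["expired"] * 5])
        led.prompts[5].status = "completed"  # one more completion
        blocks, _ = report.block_engagement(led, min_participants=1)
        assert blocks.iloc[0]["met"]


class TestSus:
    def test_maximum(self):
        assert report.sus_score([5, 1, 5, 1, 5, 1, 5, 1, 5, 1]) == 100.0

    def test_all_threes(self):
        assert report.sus_score([3] * 10) == 50.0

    def test_minimum(self):
        assert report.sus_score([1, 5, 1, 5, 1, 5, 1, 5, 1, 5]) == 0.0

    def test_wrong_length_or_range_rejected(self):
        with pytest.raises(ValueError):
            report.sus_score([3] * 9)
        with pytest.raises(ValueError):
            report.sus_score([3] * 9 + [6])


class TestGaFlags:
    def test_g8_decline(self):
        out = report.ga_change_flags({"g8": 14}, {"g8": 13})
        assert "g8_decline" in out.flags

    def test_factg_exactly_3_no_flag(self):
        out = report.ga_change_flags({"fact_g": 90}, {"fact_g": 87})
        assert "fact_g_decline" not in out.flags
        out2 = report.ga_change_flags({"fact_g": 90}, {"fact_g": 86.5})
        assert "fact_g_decline" in out2.flags

    def test_identical_timepoints_no_flags(self):
        base = {"g8": 14, "carg": 6, "cirsg": 4, "g8_srh": 2, "fact_g": 90}
        assert report.ga_change_flags(base, dict(base)).flags == set()

    def test_increase_flags_and_srh_downgrade(self):
        base = {"carg": 5, "cirsg": 3, "g8_srh": 2}
        wk12 = {"carg": 6, "cirsg": 4, "g8_srh": 1}
        out = report.ga_change_flags(base, wk12)
        assert {"carg_increase", "cirsg_increase", "g8_srh_downgrade"} <= out.flags

    def test_missing_instrument_unevaluable(self):
        out = report.ga_change_flags({"g8": 14}, {})
        assert "g8" in out.unevaluable
        assert out.flags == set()


class TestRecoverableIntervals:
    def test_two_per_initiated_session(self):
        assert report.max_recoverable_intervals(40) == 80
        assert report.max_recoverable_intervals({"a": 3, "b": 2}) == 10

    def test_fixture_total(self):
        assert sum(fixtures.FULL_DEPLOYMENT_INITIATIONS.values()) == 40
        assert report.max_recoverable_intervals(fixtures.FULL_DEPLOYMENT_INITIATIONS) == 80
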