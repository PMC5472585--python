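"""Parsing, deduplication, labeling and median-threshold rules."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from rxnaudit.reaction_io import (
    LabeledDataset,
    LabelSpec,
    ReactionRecord,
    RsmiParseError,
    Target,
    dedup_key,
    deduplicate,
    label,
    median_threshold,
    parse_rsmi,
    read_reactions_csv,
    write_labeled_csv,
    write_rejections,
)


def rec(rid, rsmi="CCO>>CC=O", y=None, t=None, **kw):
    return ReactionRecord(rid, rsmi, y, t, **kw)


class TestParseRsmi:
    def test_simple_reaction(self):
        p = parse_rsmi("CCO>>CC=O")
        assert (len(p.reactants), len(p.agents), len(p.products)) == (1, 0, 1)

    def test_agents_and_multi_component(self):
        p = parse_rsmi("CC(=O)O.CCO>[H+]>CC(=O)OCC.O")
        assert (len(p.reactants), len(p.agents), len(p.products)) == (2, 1, 2)

    def test_single_separator_rejected(self):
        with pytest.raises(RsmiParseError) as exc:
            parse_rsmi("CCO>CC=O")
        assert exc.value.reason == "malformed_rsmi"

    def test_bad_smiles_rejected_with_reason(self):
        with pytest.raises(RsmiParseError) as exc:
            parse_rsmi("C(C>>CCO")
        assert exc.value.reason == "unparseable_smiles"

    def test_empty_side_rejected(self):
        with pytest.raises(RsmiParseError):
            parse_rsmi(">>CCO")

    def test_canonical_key_is_spelling_invariant(self):
        assert dedup_key(rec("a", "OCC>>CC=O")) == dedup_key(rec("b", "CCO>>CC=O"))


class TestDeduplicate:
    def test_highest_yield_survives(self):
        out = deduplicate([rec("a", y=40.0), rec("b", y=80.0)], Target.YIELD)
        assert len(out) == 1 and out[0].yield_pct == 80.0

    def test_shortest_time_survives(self):
        out = deduplicate([rec("a", t=24.0), rec("b", t=2.0)], Target.TIME)
        assert len(out) == 1 and out[0].time_h == 2.0

    def test_distinct_products_both_retained(self):
        out = deduplicate(
            [rec("a", "CCO>>CC=O", y=10.0), rec("b", "CCO>>CC(=O)O", y=20.0)],
            Target.YIELD,
        )
        assert len(out) == 2

    def test_agent_insensitive_key(self):
        out = deduplicate(
            [rec("a", "CCO>[Pd]>CC=O", y=10.0), rec("b", "CCO>>CC=O", y=90.0)],
            Target.YIELD,
        )
        assert len(out) == 1 and out[0].yield_pct == 90.0

    def test_empty_input(self):
        assert deduplicate([], Target.YIELD) == []

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        yields=st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False), min_size=1,
            max_size=8,
        ),
        target=st.sampled_from([Target.YIELD, Target.TIME]),
    )
    def test_idempotent_and_extremal(self, yields, target):
        records = [
            rec(f"r{i}", y=v, t=v / 2 + 0.1) for i, v in enumerate(yields)
        ]
        once = deduplicate(records, target)
        assert deduplicate(once, target) == once
        assert len(once) <= len(records)
        # survivor carries the extremal value of its duplicate group
        surv = once[0]
        if target == Target.YIELD:
            assert surv.yield_pct == max(r.yield_pct for r in records)
        else:
            assert surv.time_h == min(r.time_h for r in records)


class TestLabel:
    def test_strict_threshold_yield(self):
        ds = label(
            [rec("a", y=90.0), rec("b", y=65.0), rec("c", y=10.0)],
            LabelSpec(Target.YIELD, 65.0),
        )
        assert ds.labels == [1, 0, 0]

    def test_time_positive_class_is_slow(self):
        ds = label(
            [rec("a", t=1.0), rec("b", t=12.0), rec("c", t=48.0)],
            LabelSpec(Target.TIME),
        )
        assert ds.labels == [0, 0, 1]
        assert ds.label_spec.resolved_positive_name() == "slow"

    def test_missing_target_excluded_and_counted(self):
        ds = label(
            [rec("a", y=90.0), rec("b", t=3.0), rec("c", y=10.0)],
            LabelSpec(Target.YIELD, 50.0),
        )
        assert len(ds.records) == 2 and ds.n_excluded == 1
        assert len(ds.records) + ds.n_excluded == 3  # partition

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="no labelable"):
            label([], LabelSpec(Target.YIELD))

    def test_default_thresholds(self):
        assert LabelSpec(Target.YIELD).resolved_threshold() == 65.0
        assert LabelSpec(Target.TIME).resolved_threshold() == 12.0


class TestMedianThreshold:
    @pytest.mark.parametrize(
        "values,expected",
        [([10, 65, 90], 65.0), ([10, 60, 70, 90], 60.0), ([50], 50.0)],
    )
    def test_lower_middle_convention(self, values, expected):
        records = [rec(f"r{i}", y=float(v)) for i, v in enumerate(values)]
        assert median_threshold(records, Target.YIELD) == expected

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=15))
    def test_matches_sort_and_index_oracle(self, values):
        records = [rec(f"r{i}", y=v) for i, v in enumerate(values)]
        oracle = sorted(values)[(len(values) - 1) // 2]
        assert median_threshold(records, Target.YIELD) == oracle

    def test_no_values_errors(self):
        with pytest.raises(ValueError):
            median_threshold([rec("a", t=1.0)], Target.YIELD)


class TestCsvIO:
    def test_roundtrip_and_rejection_log(self, tmp_path):
        raw = tmp_path / "raw.csv"
        raw.write_text(
            "reaction_id,rsmi,yield,time,solvent,temperature\n"
            "r1,CCO>>CC=O,80,2,water,25\n"
            "r2,CCO>CC=O,50,1,,\n"          # malformed
            "r3,CC(=O)O.CCO>>CC(=O)OCC.O,,,,\n"  # missing both outcomes
            "r4,CCO>>CC(=O)O,150,1,,\n"     # yield out of range
            "r5,CCCO>>CCC=O,30,,DMF,60\n"
        )
        records, rejections = read_reactions_csv(raw)
        assert [r.reaction_id for r in records] == ["r1", "r5"]
        reasons = {r["reaction_id"]: r["reason"] for r in rejections}
        assert reasons == {
            "r2": "malformed_rsmi",
            "r3": "missing_outcomes",
            "r4": "yield_out_of_range",
        }
        ds = label(records, LabelSpec(Target.YIELD, 50.0))
        out = tmp_path / "labeled.csv"
        write_labeled_csv(ds, out)
        again, rej2 = read_reactions_csv(out)
        assert [r.reaction_id for r in again] == ["r1", "r5"]
        assert rej2 == []
        rej_path = tmp_path / "rej.jsonl"
        write_rejections(rejections, rej_path)
        lines = [json.loads(l) for l in rej_path.read_text().splitlines()]
        assert {l["reason"] for l in lines} == set(reasons.values())

    def test_missing_header_errors(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="rsmi"):
            read_reactions_csv(p)


def test_labeled_dataset_alignment_enforced():
    with pytest.raises(ValueError):
        LabeledDataset([rec("a", y=1.0)], [0, 1], LabelSpec(Target.YIELD))
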