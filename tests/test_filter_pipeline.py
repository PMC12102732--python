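import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cimmerge.filter_pipeline import (
    FilterThresholds,
    MergedPeptide,
    apply_metric_filters,
    apply_replicate_and_rsd_filters,
    failed_rules,
    identify_best_trendline,
    merge_multisequence,
    merge_multitrendline,
    merge_replicates,
    rank_and_dedup,
    rt_rsd,
    run_tag_pipeline,
)

from conftest import make_pid


class TestRtRsd:
    def test_zero_spread(self):
        assert rt_rsd([10.0, 10.0, 10.0]) == 0.0

    def test_sample_sd_formula(self):
        # sample SD of (9.9, 10.0, 10.1) is 0.1; mean 10 -> 1.0%
        assert rt_rsd([9.9, 10.0, 10.1]) == pytest.approx(1.0)

    def test_singleton_convention(self):
        assert rt_rsd([12.5]) == 0.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            rt_rsd([10.0, -1.0])


class TestMergeReplicates:
    def test_replicate_count_across_three(self):
        tables = [[make_pid(replicate_id=f"rep{i}")] for i in range(1, 4)]
        (m,) = merge_replicates(tables)
        assert m.replicate_count == 3
        assert m.source_tags == frozenset({"11_13"})

    def test_rt_stats(self):
        tables = [
            [make_pid(replicate_id="r1", rt=9.9)],
            [make_pid(replicate_id="r2", rt=10.0)],
            [make_pid(replicate_id="r3", rt=10.1)],
        ]
        (m,) = merge_replicates(tables)
        assert m.rt_mean == pytest.approx(10.0)
        assert m.rt_rsd == pytest.approx(1.0)

    def test_within_replicate_duplicate_represented_by_top_score(self):
        tables = [[
            make_pid(replicate_id="r1", plgs_score=7.0, rt=9.0),
            make_pid(replicate_id="r1", plgs_score=8.0, rt=11.0),
        ]]
        (m,) = merge_replicates(tables)
        assert m.replicate_count == 1
        assert m.plgs_score == pytest.approx(8.0)
        assert m.rt_mean == pytest.approx(11.0)  # the 8.0 instance represents

    def test_metrics_averaged_and_ppm_absolute(self):
        tables = [
            [make_pid(replicate_id="r1", intensity=100.0, mh_ppm_error=-4.0)],
            [make_pid(replicate_id="r2", intensity=300.0, mh_ppm_error=2.0)],
        ]
        (m,) = merge_replicates(tables)
        assert m.intensity == pytest.approx(200.0)
        assert m.mh_ppm_error == pytest.approx(3.0)  # mean of |.-4|, |2|

    def test_empty_input(self):
        assert merge_replicates([]) == []

    def test_mixed_tags_rejected(self):
        tables = [[make_pid(trendline_tag="11_13")], [make_pid(trendline_tag="1_1")]]
        with pytest.raises(ValueError, match="single trendline tag"):
            merge_replicates(tables)

    def test_distinct_modifications_stay_separate(self):
        tables = [[make_pid(), make_pid(modification="Oxidation M")]]
        assert len(merge_replicates(tables)) == 2


def merged(seq="PEPTIDE", start=1, *, count=3, rsd=1.0, score=8.0, tags=("11_13",),
           length=None, **over):
    if length is not None:
        seq = "A" * length
    fields = dict(
        protein_id="PROT1", sequence=seq, modification="", start=start,
        end=start + len(seq) - 1, replicate_count=count, rt_mean=10.0,
        rt_rsd=rsd, plgs_score=score, intensity=1e5, products_per_aa=1.0,
        matched_products=8.0, consecutive_products=4.0,
        sum_product_intensity=5e4, mh_ppm_error=1.0,
        source_tags=frozenset(tags),
    )
    fields.update(over)
    return MergedPeptide(**fields)


class TestReplicateAndRsdFilters:
    def test_replicate_count_threshold(self):
        recs = [merged(f"PEP{c}", count=c) for c in (3, 1, 2)]
        th = FilterThresholds.no_op()
        th = dataclasses.replace(th, min_replicates=2)
        out = apply_replicate_and_rsd_filters(recs, th)
        assert [m.replicate_count for m in out] == [3, 2]

    def test_zero_rsd_always_passes(self):
        rec = merged(rsd=0.0, count=3)
        th = dataclasses.replace(FilterThresholds.no_op(), max_rt_rsd=0.0)
        assert apply_replicate_and_rsd_filters([rec], th) == [rec]

    def test_noop_thresholds_identity(self):
        recs = [merged(f"PEP{i}", count=1, rsd=50.0) for i in range(5)]
        assert apply_replicate_and_rsd_filters(recs, FilterThresholds.no_op()) == recs


class TestMetricFilters:
    def test_short_peptide_removed(self):
        th = dataclasses.replace(FilterThresholds.no_op(), min_length=5)
        assert apply_metric_filters([merged(length=4)], th) == []

    def test_noop_identity(self):
        recs = [merged(f"PEP{i}") for i in range(4)]
        assert apply_metric_filters(recs, FilterThresholds.no_op()) == recs

    @pytest.mark.parametrize(
        "rule,override",
        [
            ("min_products_per_aa", {"products_per_aa": 0.0}),
            ("min_intensity", {"intensity": 1.0}),
            ("min_length", {"length": 4}),
            ("max_length", {"length": 50}),
            ("min_matched_products", {"matched_products": 0.0}),
            ("min_consecutive_products", {"consecutive_products": 0.0}),
            ("min_sum_product_intensity", {"sum_product_intensity": 1.0}),
            ("min_plgs_score", {"score": 0.5}),
            ("max_abs_ppm_error", {"mh_ppm_error": 50.0}),
        ],
    )
    def test_single_rule_failure_is_named(self, rule, override):
        rec = merged(**override)
        th = FilterThresholds()
        assert failed_rules(rec, th) == [rule]
        assert apply_metric_filters([rec], th) == []

    def test_inclusive_comparisons(self):
        th = FilterThresholds()
        rec = merged(
            score=th.min_plgs_score,
            intensity=th.min_intensity,
            mh_ppm_error=th.max_abs_ppm_error,
            length=th.min_length,
        )
        assert failed_rules(rec, th) == []


class TestRankAndDedup:
    def test_top_score_survives(self):
        recs = [merged(score=7.3, tags=("1_1",)), merged(score=8.1, tags=("11_13",))]
        out = rank_and_dedup(recs)
        assert len(out) == 1
        assert out[0].plgs_score == pytest.approx(8.1)
        assert out[0].source_tags == frozenset({"1_1", "11_13"})

    def test_unique_list_unchanged_as_set(self):
        recs = [merged(f"PEP{i}", score=5 + i) for i in range(4)]
        out = rank_and_dedup(recs)
        assert {m.key for m in out} == {m.key for m in recs}

    def test_idempotent(self):
        recs = [merged(score=7.0), merged(score=9.0), merged("OTHERPEP", score=8.0)]
        once = rank_and_dedup(recs)
        assert rank_and_dedup(once) == once

    def test_order_invariance(self):
        recs = [merged(f"P{i}" * 3, score=5 + (i % 3), start=i + 1) for i in range(6)]
        a = rank_and_dedup(recs)
        b = rank_and_dedup(list(reversed(recs)))
        assert a == b

    def test_sorted_descending_by_score(self):
        recs = [merged(f"PEP{i}", score=s) for i, s in enumerate((3.0, 9.0, 6.0))]
        out = rank_and_dedup(recs)
        assert [m.plgs_score for m in out] == sorted(
            (m.plgs_score for m in out), reverse=True
        )


class TestMonotonicity:
    """Tightening any single threshold never enlarges the surviving set."""

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_tightening_shrinks_survivors(self, data):
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        recs = [
            merged(
                f"PEP{i}",
                count=int(rng.integers(1, 4)),
                rsd=float(rng.uniform(0, 10)),
                score=float(rng.uniform(0, 12)),
                intensity=float(rng.uniform(0, 2e4)),
                length=int(rng.integers(4, 45)),
                mh_ppm_error=float(rng.uniform(0, 20)),
            )
            for i in range(25)
        ]
        base = FilterThresholds.no_op()
        tighten = data.draw(
            st.sampled_from(
                [
                    ("min_replicates", 2),
                    ("max_rt_rsd", 5.0),
                    ("min_intensity", 1e4),
                    ("min_plgs_score", 6.0),
                    ("min_length", 10),
                    ("max_length", 20),
                    ("max_abs_ppm_error", 8.0),
                ]
            )
        )
        tight = dataclasses.replace(base, **{tighten[0]: tighten[1]})

        def survivors(th):
            out = apply_replicate_and_rsd_filters(recs, th)
            return {m.key for m in apply_metric_filters(out, th)}

        assert survivors(tight) <= survivors(base)


class TestBestTrendline:
    def _tables(self, tag, n_keys):
        return [
            [make_pid(f"PEPSEQ{k:02d}", start=k + 1, trendline_tag=tag,
                      replicate_id=f"r{r}")
             for k in range(n_keys)]
            for r in (1, 2, 3)
        ]

    def test_argmax_count(self):
        per_tag = {
            "5_8": self._tables("5_8", 5),
            "11_14": self._tables("11_14", 8),
            "81_84": self._tables("81_84", 4),
        }
        report = identify_best_trendline(per_tag, FilterThresholds.no_op())
        assert report.best_tag == "11_14"
        assert report.counts == {"5_8": 5, "11_14": 8, "81_84": 4}
        assert len(report.best_list) == 8

    def test_single_tag_is_best(self):
        per_tag = {"9_11": self._tables("9_11", 3)}
        assert identify_best_trendline(per_tag, FilterThresholds.no_op()).best_tag == "9_11"

    def test_tie_broken_by_smaller_fwhm_start(self):
        per_tag = {
            "11_13": self._tables("11_13", 6),
            "9_11": self._tables("9_11", 6),
        }
        report = identify_best_trendline(per_tag, FilterThresholds.no_op())
        assert report.best_tag == "9_11"


class TestMultiSequenceMerge:
    def test_disjoint_union_count(self):
        a = [merged(f"AAA{i}PEP", start=1, tags=("1_1",)) for i in range(10)]
        b = [merged(f"BBB{i}PEP", start=1, tags=("11_13",)) for i in range(7)]
        out = merge_multisequence(a, b, FilterThresholds.no_op())
        assert len(out) == 17

    def test_identical_inputs_idempotent(self):
        a = [merged(f"PEP{i}") for i in range(5)]
        out = merge_multisequence(a, list(a), FilterThresholds.no_op())
        assert {m.key for m in out} == {m.key for m in a}

    def test_higher_scoring_single_pass_survives_with_union_tags(self):
        sp = merged(score=9.0, tags=("1_1",))
        mp = merged(score=7.0, tags=("11_13",))
        (out,) = merge_multisequence([sp], [mp], FilterThresholds.no_op())
        assert out.plgs_score == pytest.approx(9.0)
        assert out.source_tags == frozenset({"1_1", "11_13"})


def _random_tag_tables(rng, tags=("1_1", "9_11", "21_23")):
    """Random per-tag replicate tables over a shared pool of keys."""
    pool = [f"PEPSEQ{i:02d}" for i in range(rng.integers(3, 10))]
    out = {}
    for tag in tags:
        n_rep = int(rng.integers(1, 4))
        tables = []
        for r in range(n_rep):
            rows = []
            for i, seq in enumerate(pool):
                if rng.random() < 0.6:
                    rows.append(
                        make_pid(
                            seq, start=i + 1, trendline_tag=tag,
                            replicate_id=f"r{r}",
                            plgs_score=float(rng.uniform(1, 10)),
                            rt=float(rng.uniform(5, 15)),
                        )
                    )
            tables.append(rows)
        out[tag] = tables
    return out


class TestMultiTrendlineMerge:
    def test_union_law_against_bruteforce_oracle(self):
        """Pooled unique keys equal the union of per-tag pipeline keys,
        checked on 200 random instances."""
        th = FilterThresholds(
            min_replicates=1, max_rt_rsd=50.0, min_intensity=0.0,
            min_products_per_aa=0.0, min_length=4, max_length=60,
            min_matched_products=0, min_consecutive_products=0,
            min_sum_product_intensity=0.0, min_plgs_score=5.0,
            max_abs_ppm_error=100.0,
        )
        rng = np.random.default_rng(1234)
        for _ in range(200):
            tag_tables = _random_tag_tables(rng)
            pooled = merge_multitrendline(tag_tables, th)
            oracle = set()
            for tag, tables in tag_tables.items():
                oracle |= {m.key for m in run_tag_pipeline(tables, th)}
            assert {m.key for m in pooled} == oracle

    def test_superset_of_best_single_trendline(self):
        rng = np.random.default_rng(7)
        tag_tables = _random_tag_tables(rng)
        th = FilterThresholds.no_op()
        pooled_keys = {m.key for m in merge_multitrendline(tag_tables, th)}
        report = identify_best_trendline(tag_tables, th)
        assert pooled_keys >= {m.key for m in report.best_list}

    def test_identical_tags_collapse(self):
        rows = [[make_pid(f"PEPSEQ{i}", start=i + 1, trendline_tag="1_1",
                          replicate_id="r1") for i in range(4)]]

        def retag(tag):
            return [[dataclasses.replace(r, trendline_tag=tag) for r in t] for t in rows]

        tag_tables = {"1_1": rows, "9_11": retag("9_11"), "21_23": retag("21_23")}
        th = FilterThresholds.no_op()
        pooled = merge_multitrendline(tag_tables, th)
        single = run_tag_pipeline(rows, th)
        assert {m.key for m in pooled} == {m.key for m in single}

    def test_pipeline_order_invariance_to_row_and_file_order(self):
        rng = np.random.default_rng(99)
        tag_tables = _random_tag_tables(rng)
        th = FilterThresholds(min_plgs_score=5.0)
        a = merge_multitrendline(tag_tables, th)
        shuffled = {
            tag: [list(reversed(t)) for t in reversed(tables)]
            for tag, tables in reversed(list(tag_tables.items()))
        }
        b = merge_multitrendline(shuffled, th)
        assert a == b


class TestThresholdsConfig:
    def test_yaml_roundtrip(self, tmp_path):
        th = FilterThresholds(min_plgs_score=7.2, min_replicates=3)
        path = th.to_file(tmp_path / "th.yaml")
        assert FilterThresholds.from_file(path) == th

    def test_partial_file_keeps_defaults(self, tmp_path):
        p = tmp_path / "th.yaml"
        p.write_text("min_plgs_score: 9.9\n")
        th = FilterThresholds.from_file(p)
        assert th.min_plgs_score == 9.9
        assert th.min_replicates == FilterThresholds().min_replicates

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "th.yaml"
        p.write_text("min_scor: 9.9\n")
        with pytest.raises(ValueError, match="min_scor"):
            FilterThresholds.from_file(p)

    def test_invalid_length_window_rejected(self):
        with pytest.raises(ValueError):
            FilterThresholds(min_length=10, max_length=5)
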