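"""Homozygosity mapping: informative markers, shared intervals, exclusion."""

import logging

import numpy as np
import pandas as pd
import pytest

from enumap.assays import MARKER_CALL_COLUMNS
from enumap.genome import Marker
from enumap.mapping import (CandidateInterval, exclude_by_normals,
                            interval_size_mbp, select_informative_markers,
                            shared_homozygosity_intervals)

GENOTYPES = ["B6B6", "HET", "FVBFVB", "MISSING"]


def make_calls(markers, genotype_by_individual):
    rows = []
    for ind, genotypes in genotype_by_individual.items():
        for marker, genotype in zip(markers, genotypes):
            rows.append((ind, marker.id, marker.chrom, marker.pos, genotype))
    return pd.DataFrame(rows, columns=MARKER_CALL_COLUMNS)


def brute_force_intervals(calls, markers):
    """O(n^2) enumeration of maximal all-B6B6-compatible marker runs."""
    genotypes = calls.pivot_table(index="marker_id", columns="individual_id",
                                  values="genotype", aggfunc="first")
    comp_cache = {}
    for marker_id, row in genotypes.iterrows():
        vals = row.dropna()
        comp_cache[marker_id] = bool(vals.isin(["B6B6", "MISSING"]).all())

    def compatible(marker):
        return comp_cache.get(marker.id, True)

    found = []
    by_chrom = {}
    for m in sorted(markers, key=lambda m: (m.chrom, m.pos)):
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom, ms in by_chrom.items():
        n = len(ms)
        for i in range(n):
            for j in range(i, n):
                run = ms[i:j + 1]
                if not all(compatible(m) for m in run):
                    continue
                if i > 0 and compatible(ms[i - 1]):
                    continue  # not maximal on the left
                if j < n - 1 and compatible(ms[j + 1]):
                    continue  # not maximal on the right
                left = (ms[i - 1].id, ms[i - 1].pos) if i > 0 else (None, 1)
                right = ((ms[j + 1].id, ms[j + 1].pos) if j < n - 1
                         else (None, ms[-1].pos + 1))
                found.append((chrom, left, right,
                              tuple(m.id for m in run)))
    return sorted(found, key=lambda t: (t[0], t[1][1], t[2][1]))


def as_tuples(intervals):
    return sorted(((iv.chrom, iv.left_flank, iv.right_flank,
                    tuple(iv.core_markers)) for iv in intervals),
                  key=lambda t: (t[0], t[1][1], t[2][1]))


class TestSelectInformativeMarkers:
    def test_three_criteria_applied(self):
        markers = (
            [Marker(f"x{i}", "chrX", 100 + i, "A", "G", autosomal=False)
             for i in range(2)]
            + [Marker(f"u{i}", "chr1", 200 + i, "A", "A") for i in range(2)]
            + [Marker("nh", "chr1", 300, "A", "G")]
            + [Marker(f"ok{i}", "chr1", 400 + i, "A", "G") for i in range(5)]
        )
        f1 = make_calls(markers, {"F1": ["HET"] * 5 + ["B6B6"]
                                  + ["HET"] * 4})
        # align: nh (index 4 in markers list) gets the non-HET call
        f1.loc[f1["marker_id"] == "nh", "genotype"] = "B6B6"
        f1.loc[f1["marker_id"] != "nh", "genotype"] = "HET"
        kept = select_informative_markers(markers, f1)
        assert [m.id for m in kept] == [f"ok{i}" for i in range(5)]

    def test_empty_panel(self):
        assert select_informative_markers([], pd.DataFrame(
            columns=MARKER_CALL_COLUMNS)) == []

    def test_all_pass_returns_position_order(self):
        markers = [Marker("b", "chr1", 500, "A", "G"),
                   Marker("a", "chr1", 100, "A", "G")]
        f1 = make_calls(markers, {"F1": ["HET", "HET"]})
        kept = select_informative_markers(markers, f1)
        assert [m.id for m in kept] == ["a", "b"]

    def test_marker_without_f1_call_warned_and_excluded(self, caplog):
        markers = [Marker("a", "chr1", 100, "A", "G"),
                   Marker("b", "chr1", 200, "A", "G")]
        f1 = make_calls(markers[:1], {"F1": ["HET"]})
        with caplog.at_level(logging.WARNING):
            kept = select_informative_markers(markers, f1)
        assert [m.id for m in kept] == ["a"]
        assert "no F1 call" in caplog.text


class TestSharedHomozygosityIntervals:
    def test_published_flank_geometry_spans_33_58_mbp(self):
        from enumap.fixtures import make_worked_example
        ex = make_worked_example()
        informative = select_informative_markers(ex.markers, ex.f1_calls)
        intervals = shared_homozygosity_intervals(ex.affected_calls,
                                                  informative)
        assert len(intervals) == 1
        iv = intervals[0]
        assert iv.left_flank == ("gnf02.126.027", 127_800_747)
        assert iv.right_flank == ("rs3664408", 161_380_222)
        assert interval_size_mbp(iv) == 33.58

    def test_all_het_yields_no_interval(self):
        markers = [Marker(f"m{i}", "chr1", 100 * (i + 1), "A", "G")
                   for i in range(5)]
        calls = make_calls(markers, {"a": ["HET"] * 5, "b": ["HET"] * 5})
        assert shared_homozygosity_intervals(calls, markers) == []

    def test_no_affected_individuals_is_an_error(self):
        with pytest.raises(ValueError):
            shared_homozygosity_intervals(
                pd.DataFrame(columns=MARKER_CALL_COLUMNS), [])

    def test_missing_is_compatible_but_never_a_flank(self):
        markers = [Marker(f"m{i}", "chr1", 100 * (i + 1), "A", "G")
                   for i in range(5)]
        calls = make_calls(markers, {
            "a": ["HET", "B6B6", "MISSING", "B6B6", "HET"],
            "b": ["HET", "B6B6", "B6B6", "MISSING", "HET"],
        })
        intervals = shared_homozygosity_intervals(calls, markers)
        assert len(intervals) == 1
        assert intervals[0].core_markers == ["m1", "m2", "m3"]
        assert intervals[0].left_flank == ("m0", 100)
        assert intervals[0].right_flank == ("m4", 500)

    def test_chromosome_terminal_runs_flagged_open(self):
        markers = [Marker(f"m{i}", "chr1", 100 * (i + 1), "A", "G")
                   for i in range(4)]
        calls = make_calls(markers, {"a": ["B6B6", "HET", "B6B6", "B6B6"]})
        intervals = shared_homozygosity_intervals(calls, markers,
                                                  {"chr1": 1000})
        assert len(intervals) == 2
        left, right = intervals
        assert left.open_left and left.left_flank == (None, 1)
        assert right.open_right and right.right_flank == (None, 1000)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(777)
        for _ in range(200):
            n_markers = int(rng.integers(1, 31))
            n_mice = int(rng.integers(1, 5))
            markers = [Marker(f"m{i}", "chr1", 10 * (i + 1), "A", "G")
                       for i in range(n_markers)]
            calls = make_calls(markers, {
                f"ind{k}": rng.choice(GENOTYPES, size=n_markers,
                                      p=[0.5, 0.25, 0.15, 0.1]).tolist()
                for k in range(n_mice)})
            got = shared_homozygosity_intervals(calls, markers)
            assert as_tuples(got) == brute_force_intervals(calls, markers)

    def test_adding_an_affected_mouse_never_widens_intervals(self):
        rng = np.random.default_rng(31)
        markers = [Marker(f"m{i}", "chr1", 10 * (i + 1), "A", "G")
                   for i in range(20)]
        base = {f"ind{k}": rng.choice(GENOTYPES, size=20).tolist()
                for k in range(3)}
        more = dict(base, extra=rng.choice(GENOTYPES, size=20).tolist())
        before = shared_homozygosity_intervals(make_calls(markers, base),
                                               markers)
        after = shared_homozygosity_intervals(make_calls(markers, more),
                                              markers)
        spans_before = {(iv.left_pos, iv.right_pos) for iv in before}
        for iv in after:
            assert any(lo <= iv.left_pos and iv.right_pos <= hi
                       for lo, hi in spans_before)


class TestExcludeByNormals:
    def _interval(self):
        return CandidateInterval("chr1", ("m0", 100), ("m4", 500),
                                 ["m1", "m2", "m3"])

    def test_interval_homozygous_in_a_normal_is_dropped(self):
        markers = [Marker(f"m{i}", "chr1", 100 * (i + 1), "A", "G")
                   for i in range(5)]
        normal = make_calls(markers, {"n": ["HET", "B6B6", "B6B6", "B6B6",
                                            "HET"]})
        assert exclude_by_normals([self._interval()], normal) == []

    def test_no_normals_leaves_intervals_unchanged(self):
        intervals = [self._interval()]
        out = exclude_by_normals(intervals,
                                 pd.DataFrame(columns=MARKER_CALL_COLUMNS))
        assert out == intervals

    def test_missing_calls_in_normals_do_not_exclude(self):
        markers = [Marker(f"m{i}", "chr1", 100 * (i + 1), "A", "G")
                   for i in range(5)]
        normal = make_calls(markers, {"n": ["HET", "B6B6", "MISSING", "B6B6",
                                            "HET"]})
        assert len(exclude_by_normals([self._interval()], normal)) == 1

    def test_adding_a_normal_never_adds_an_interval(self):
        rng = np.random.default_rng(41)
        markers = [Marker(f"m{i}", "chr1", 10 * (i + 1), "A", "G")
                   for i in range(15)]
        affected = make_calls(markers, {
            f"a{k}": rng.choice(GENOTYPES, size=15,
                                p=[0.6, 0.2, 0.1, 0.1]).tolist()
            for k in range(3)})
        intervals = shared_homozygosity_intervals(affected, markers)
        normals = {}
        kept = intervals
        for k in range(4):
            normals[f"n{k}"] = rng.choice(GENOTYPES, size=15).tolist()
            new = exclude_by_normals(intervals, make_calls(markers, normals))
            assert len(new) <= len(kept)
            assert {id(iv) for iv in new} <= {id(iv) for iv in intervals}
            kept = new


class TestIntervalSize:
    @pytest.mark.parametrize("left,right,size", [
        (127_800_747, 161_380_222, 33.58),
        (143_947_738, 161_380_222, 17.43),
        (5_000_000, 6_000_000, 1.00),
    ])
    def test_flank_to_flank_mbp(self, left, right, size):
        iv = CandidateInterval("chr2", ("l", left), ("r", right), [])
        assert interval_size_mbp(iv) == size

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            CandidateInterval("chr2", ("l", 10), ("r", 10), [])
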