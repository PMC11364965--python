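"""Peak-table ingestion, tolerance matching, ranking and deduplication."""

import numpy as np
import pytest

from hormonomics.compounds import Compound
from hormonomics.query import (
    Annotation,
    Feature,
    FeatureTable,
    PeakTableError,
    Tolerance,
    dedup_compounds,
    match_features,
    match_rate,
    rank_annotations,
    read_peak_table,
    rt_match_percent,
    screen,
    tolerance_in_da,
)
from hormonomics.shifts import MassShiftRule, ShiftedEntry, parse_shift

IDENTITY = parse_shift("M")


def entry(mz, name="X", rt=None, rule: MassShiftRule = IDENTITY):
    return ShiftedEntry(
        compound=Compound(name, "test", mz if mz > 0 else 1.0),
        rule=rule,
        theoretical_mz=mz,
        predicted_rt=rt,
    )


def feature(mz, rt=5.0, row=0):
    return Feature(mz=mz, rt=rt, row_index=row)


class TestReadPeakTable:
    def test_standard_layout(self, write_csv):
        p = write_csv(
            "mz,rt,s1,s2\n100.1,1.5,10,20\n200.2,2.5,30,40\n300.3,3.5,50,60\n"
        )
        table = read_peak_table(p)
        assert len(table) == 3
        assert table.sample_names == ["s1", "s2"]
        assert table.features[1].mz == 200.2
        assert table.features[2].intensities == (50.0, 60.0)
        assert [f.row_index for f in table] == [0, 1, 2]

    def test_size_limit(self, write_csv):
        p = write_csv("mz,rt\n" + "100.0,1.0\n" * 100)
        with pytest.raises(PeakTableError, match="exceeds"):
            read_peak_table(p, max_bytes=64)
        assert len(read_peak_table(p, max_bytes=10**7)) == 100

    def test_header_only_warns_and_returns_empty(self, write_csv):
        p = write_csv("mz,rt,s1\n")
        with pytest.warns(UserWarning, match="0 features"):
            table = read_peak_table(p)
        assert len(table) == 0 and table.sample_names == ["s1"]

    def test_too_few_columns(self, write_csv):
        p = write_csv("mz\n100.0\n")
        with pytest.raises(PeakTableError, match="at least"):
            read_peak_table(p)

    def test_non_numeric_mz_reports_row(self, write_csv):
        p = write_csv("mz,rt\n100.0,1.0\nbroken,2.0\n")
        with pytest.raises(PeakTableError, match="row 1"):
            read_peak_table(p)


class TestTolerance:
    def test_da_window_is_constant(self):
        assert tolerance_in_da(Tolerance(0.02, "Da"), 123.4) == 0.02

    @pytest.mark.parametrize(
        ("ppm", "at_mz", "expected"),
        [(10, 500.0, 0.005), (5, 200.0, 0.001)],
    )
    def test_ppm_window_scales_with_mz(self, ppm, at_mz, expected):
        assert tolerance_in_da(Tolerance(ppm, "ppm"), at_mz) == pytest.approx(
            expected, abs=1e-12
        )

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            Tolerance(0.0, "Da")
        with pytest.raises(ValueError):
            Tolerance(1.0, "mDa")


class TestRTMatchPercent:
    def test_exact_match_scores_100(self):
        assert rt_match_percent(4.20, 4.20) == 100.0

    def test_partial_match(self):
        assert round(rt_match_percent(3.94, 4.20), 2) == 93.81

    def test_clipped_at_zero(self):
        assert rt_match_percent(20.0, 4.0) == 0.0

    def test_undefined_for_nonpositive_prediction(self):
        with pytest.raises(ValueError):
            rt_match_percent(5.0, 0.0)


class TestMatchFeatures:
    def test_inclusive_window_match(self):
        annots = match_features(
            [feature(262.1596)], [entry(262.1569)], Tolerance(0.02, "Da")
        )
        assert len(annots) == 1
        assert annots[0].delta_mz == pytest.approx(0.0027, abs=1e-10)
        assert annots[0].msi_level == 3

    def test_outside_window_no_match(self):
        assert match_features(
            [feature(262.20)], [entry(262.1569)], Tolerance(0.02, "Da")
        ) == []

    def test_boundary_is_inclusive(self):
        annots = match_features(
            [feature(100.02)], [entry(100.00)], Tolerance(0.02, "Da")
        )
        assert len(annots) == 1

    def test_isobars_all_returned(self):
        entries = [entry(100.000, "A"), entry(100.010, "B")]
        annots = match_features([feature(100.005)], entries, Tolerance(0.02, "Da"))
        assert {a.entry.compound.name for a in annots} == {"A", "B"}

    def test_equivalent_to_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for trial in range(200):
            n = int(rng.integers(1, 101))
            m = int(rng.integers(1, 101))
            feats = [
                feature(float(mz), row=i)
                for i, mz in enumerate(rng.uniform(100, 500, n))
            ]
            entries = [
                entry(float(mz), f"c{j}")
                for j, mz in enumerate(rng.uniform(100, 500, m))
            ]
            unit = "Da" if trial % 2 == 0 else "ppm"
            tol = Tolerance(
                float(rng.uniform(0.001, 0.5)) if unit == "Da"
                else float(rng.uniform(1, 500)),
                unit,
            )
            got = {
                (a.feature.row_index, a.entry.compound.name)
                for a in match_features(feats, entries, tol)
            }
            expected = {
                (f.row_index, e.compound.name)
                for f in feats
                for e in entries
                if abs(f.mz - e.theoretical_mz)
                <= tolerance_in_da(tol, e.theoretical_mz)
            }
            assert got == expected

    def test_tolerance_monotonicity(self):
        rng = np.random.default_rng(5)
        feats = [feature(float(mz), row=i)
                 for i, mz in enumerate(rng.uniform(100, 500, 60))]
        entries = [entry(float(mz), f"c{j}")
                   for j, mz in enumerate(rng.uniform(100, 500, 60))]
        sets = []
        for tol in (0.01, 0.05, 0.2, 1.0):
            sets.append({
                (a.feature.row_index, a.entry.compound.name)
                for a in match_features(feats, entries, Tolerance(tol, "Da"))
            })
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger

    def test_ppm_da_consistency_at_one_theoretical_mz(self):
        mu = 400.0
        ppm = 25.0
        da = mu * ppm / 1e6
        entries = [entry(mu)]
        for obs in (mu - da, mu - da / 2, mu, mu + da / 2, mu + da,
                    mu + da * 1.001):
            via_ppm = match_features([feature(obs)], entries, Tolerance(ppm, "ppm"))
            via_da = match_features([feature(obs)], entries, Tolerance(da, "Da"))
            assert len(via_ppm) == len(via_da)


class TestRanking:
    def test_higher_rt_match_first(self):
        f = feature(100.0, rt=4.0)
        a_hi = Annotation(f, entry(100.0, "hi", rt=4.1), 0.0, 95.0)
        a_lo = Annotation(f, entry(100.0, "lo", rt=7.0), 0.0, 60.0)
        assert rank_annotations([a_lo, a_hi]) == [a_hi, a_lo]

    def test_tie_broken_by_smaller_delta_mz(self):
        f = feature(100.0)
        near = Annotation(f, entry(100.001, "near", rt=4.0), -0.001, 80.0)
        far = Annotation(f, entry(100.01, "far", rt=4.0), -0.01, 80.0)
        assert rank_annotations([far, near]) == [near, far]

    def test_missing_rt_match_sorts_last(self):
        f = feature(100.0)
        scored = Annotation(f, entry(100.0, "scored", rt=4.0), 0.0, 10.0)
        unscored = Annotation(f, entry(100.0, "unscored"), 0.0, None)
        assert rank_annotations([unscored, scored]) == [scored, unscored]

    def test_groups_by_feature_row(self):
        a0 = Annotation(feature(100.0, row=0), entry(100.0, "x"), 0.0, None)
        a1 = Annotation(feature(200.0, row=1), entry(200.0, "y", rt=4.0), 0.0, 99.0)
        assert rank_annotations([a1, a0]) == [a0, a1]

    def test_is_a_permutation(self):
        rng = np.random.default_rng(3)
        annots = [
            Annotation(
                feature(float(mz), row=int(rng.integers(5))),
                entry(float(mz), f"c{i}", rt=float(rng.uniform(1, 10))),
                float(rng.normal(0, 0.01)),
                float(rng.uniform(0, 100)),
            )
            for i, mz in enumerate(rng.uniform(100, 500, 30))
        ]
        ranked = rank_annotations(annots)
        assert len(ranked) == 30 and set(map(id, ranked)) == set(map(id, annots))

    def test_empty_input(self):
        assert rank_annotations([]) == []


class TestDedup:
    def test_same_compound_and_rule_collapses(self):
        e = entry(100.0, "A", rt=4.0)
        annots = [
            Annotation(feature(100.0, rt=4.0, row=i), e, 0.0, pct)
            for i, pct in enumerate([90.0, 70.0, 50.0])
        ]
        deduped = dedup_compounds(annots)
        assert len(deduped) == 1 and deduped[0].rt_match_pct == 90.0

    def test_different_rules_kept_separate(self):
        f = feature(100.0)
        a = Annotation(f, entry(100.0, "A", rule=parse_shift("M+CH3")), 0.0, None)
        b = Annotation(f, entry(100.0, "A", rule=parse_shift("M+OH")), 0.0, None)
        assert len(dedup_compounds([a, b])) == 2

    def test_all_unique_unchanged_and_idempotent(self):
        annots = [
            Annotation(feature(100.0 + i, row=i), entry(100.0 + i, f"c{i}"), 0.0, None)
            for i in range(5)
        ]
        once = dedup_compounds(annots)
        assert once == annots
        assert dedup_compounds(once) == once


class TestMatchRate:
    def test_one_annotation_per_reference(self):
        refs = [Compound(f"r{i}", "x", 100.0 + i) for i in range(5)]
        annots = [
            Annotation(feature(100.0 + i, row=i), entry(100.0 + i, f"r{i}"), 0.0, None)
            for i in range(5)
        ]
        assert match_rate(annots, refs, Tolerance(0.02, "Da")) == 100.0

    def test_isobaric_extras_exceed_100(self):
        refs = [Compound(f"r{i}", "x", 100.0 + i) for i in range(20)]
        annots = [
            Annotation(feature(100.0 + i % 20, row=i % 20),
                       entry(100.0 + i % 20, f"c{i}"), 0.0, None)
            for i in range(22)
        ]
        assert match_rate(annots, refs, Tolerance(0.02, "Da")) == 110.0

    def test_no_overlap_scores_zero(self):
        refs = [Compound("r", "x", 900.0)]
        annots = [Annotation(feature(100.0), entry(100.0), 0.0, None)]
        assert match_rate(annots, refs, Tolerance(0.02, "Da")) == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            match_rate([], [], Tolerance(0.02, "Da"))


class TestScreen:
    def test_spiked_table_fully_annotated(self, fixture_db):
        from hormonomics.simulate import SpikePlan, generate_peak_table

        plans = [
            SpikePlan(name, "M+CH3")
            for name in ("Melatonin", "Serotonin", "Zeatin", "Kinetin")
        ]
        table, _ = generate_peak_table(fixture_db, plans, n_decoys=0, seed=1)
        frame = screen(table, fixture_db, "biotransformations",
                       Tolerance(0.02, "Da"))
        hits = set(zip(frame["Compound name"], frame["Biotransformation"]))
        assert {(p.compound_name, "M+CH3") for p in plans} <= hits

    def test_empty_peak_table_yields_empty_frame(self, fixture_db, write_csv):
        p = write_csv("mz,rt,s1\n")
        with pytest.warns(UserWarning):
            frame = screen(p, fixture_db, "mh", Tolerance(0.02, "Da"))
        assert frame.empty

    def test_published_experimental_mz_recovers_pairs(self, fixture_db, write_csv):
        # experimental m/z values from the reference cranberry screen
        observed = [
            (262.1596, "Abscisic acid", "M-OH+CH3"),
            (234.1195, "Melatonin", "M-CH3+OH"),
            (369.1448, "Feruloyl serotonin", "M+OH"),
            (266.0744, "2-methylthio-cis-zeatin", "M-NH2+OH"),
            (279.1603, "Abscisic acid", "M-H+NH2"),
        ]
        rows = "".join(f"{mz},2.0,1.0\n" for mz, _, _ in observed)
        p = write_csv("mz,rt,s1\n" + rows)
        frame = screen(p, fixture_db, "biotransformations", Tolerance(0.02, "Da"))
        hits = set(zip(frame["Compound name"], frame["Biotransformation"]))
        for _, name, rule in observed:
            assert (name, rule) in hits
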