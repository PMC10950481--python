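import numpy as np
import pytest

from corescan import (
    MotifModelError,
    PlantSpec,
    background_from_gc,
    call_composites,
    compare_datasets,
    export_distribution_table,
    generate,
    position_distribution,
    qc_summary,
    read_distribution_table,
    scan,
    spacing_distribution,
    to_scoring_matrix,
)
from corescan.scanner import MotifHit

UNIFORM = background_from_gc(0.5)


def hit(element, start, score=1.0, seq_id="s", strand="+"):
    return MotifHit(
        seq_id=seq_id, element=element, strand=strand,
        start_tss_rel=start, anchor_tss_rel=start, score=score, length=6,
    )


class TestPositionDistribution:
    def test_degenerate_single_position(self):
        hits = [hit("dInr", -2, score=s) for s in range(1, 11)]
        dist = position_distribution(hits, "dInr", axis="start")
        assert dist.total_hits == 10
        assert len(dist.table) == 1
        row = dist.table.iloc[0]
        assert row["position"] == -2
        assert row["fraction_pct"] == pytest.approx(100.0)
        assert row["mean_score"] == pytest.approx(5.5)
        assert row["median_score"] == pytest.approx(5.5)

    def test_three_to_one_split(self):
        hits = [hit("e", -2), hit("e", -2), hit("e", -2), hit("e", -1)]
        dist = position_distribution(hits, "e")
        fr = dict(zip(dist.table["position"], dist.table["fraction_pct"]))
        assert fr == {-2: pytest.approx(75.0), -1: pytest.approx(25.0)}

    def test_fractions_sum_to_100(self):
        rng = np.random.default_rng(41)
        hits = [hit("e", int(p)) for p in rng.integers(-50, 50, size=500) if p != 0]
        dist = position_distribution(hits, "e")
        assert dist.table["fraction_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        assert dist.table["n"].sum() == dist.total_hits

    def test_order_invariance(self):
        rng = np.random.default_rng(42)
        hits = [hit("e", int(p), score=float(s)) for p, s in
                zip(rng.integers(1, 20, size=200), rng.normal(size=200))]
        d1 = position_distribution(hits, "e")
        shuffled = list(hits)
        rng.shuffle(shuffled)
        d2 = position_distribution(shuffled, "e")
        assert d1.table.equals(d2.table)

    def test_empty_distribution_not_an_error(self):
        dist = position_distribution([], "ghost")
        assert dist.total_hits == 0 and len(dist.table) == 0

    def test_unknown_axis_rejected(self):
        with pytest.raises(MotifModelError, match="axis"):
            position_distribution([], "e", axis="sideways")

    def test_planted_motif_recovery_with_sampled_instances(self, default_library):
        # dInr planted at -2 in 60% of sequences, instances drawn from the
        # PWM, over random background: the modal start must still be -2
        pwms = {el.name: el.pwm for el in default_library}
        recs, truth = generate(
            n=300, width=201, tss_index=101, gc=0.5,
            plants=[PlantSpec("dInr", -2, probability=0.6, sample_from_pwm=True)],
            pwms=pwms, seed=1234,
        )
        sm = to_scoring_matrix(default_library["dInr"].pwm, UNIFORM)
        hits = scan(recs, [sm], strands="both")
        dist = position_distribution(hits, "dInr", axis="start")
        (summary,) = qc_summary([dist])
        assert summary.modal_position == -2


class TestQcSummary:
    def test_single_position_concentration_100(self):
        dist = position_distribution([hit("e", 5), hit("e", 5)], "e")
        (s,) = qc_summary([dist])
        assert s.modal_position == 5
        assert s.concentration_pct == pytest.approx(100.0)

    def test_uniform_20_positions_concentration_25(self):
        hits = [hit("e", p) for p in range(1, 21) for _ in range(3)]
        dist = position_distribution(hits, "e")
        (s,) = qc_summary([dist])
        assert s.concentration_pct == pytest.approx(25.0)

    def test_mode_window_does_not_gain_a_position_across_the_missing_zero(self):
        # positions -2..+3 are 5 consecutive bases around a -1 mode: all
        # within +/-2 except +3
        hits = [hit("e", -1)] * 5 + [hit("e", p) for p in (-3, -2, 1, 2, 3)]
        (s,) = qc_summary([position_distribution(hits, "e")])
        assert s.modal_position == -1
        assert s.concentration_pct == pytest.approx(100.0 * 9 / 10)

    def test_empty_distribution_summary(self):
        (s,) = qc_summary([position_distribution([], "e")])
        assert s.modal_position is None and s.total_hits == 0

    def test_jitter_free_dataset_wins_concentration(self, default_library):
        # two synthetic datasets differing only in positional jitter: the
        # jitter-free one must rank first for every planted element
        # instances are PWM-sampled: motif variability is part of what the
        # concentration statistic must be robust to
        pwms = {el.name: el.pwm for el in default_library}
        plants = lambda sd: [
            PlantSpec("TATA", -30, jitter_sd=sd, sample_from_pwm=True),
            PlantSpec("dInr", -2, jitter_sd=sd, sample_from_pwm=True),
            PlantSpec("PB", 26, jitter_sd=sd, sample_from_pwm=True),
        ]
        lib = default_library.subset(["TATA", "dInr", "PB"])
        mats = [to_scoring_matrix(el.pwm, UNIFORM) for el in lib]
        datasets = {}
        for name, sd, seed in [("sharp", 0.0, 7), ("jittered", 3.0, 8)]:
            recs, _ = generate(201, 201, 101, 0.5, plants(sd), pwms, seed=seed)
            hits = scan(recs, mats, strands="both")
            datasets[name] = [position_distribution(hits, el, "start") for el in lib.names]
        table = compare_datasets(datasets)
        assert set(table["element"]) == {"TATA", "dInr", "PB"}
        assert (table["winner"] == "sharp").all()

    def test_mode_recovery_under_unit_jitter(self):
        # planted position +10 with integer jitter of sd 1: the recovered
        # mode stays within one base in at least 95% of seeded replicates
        ok = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            positions = 10 + np.rint(rng.normal(0.0, 1.0, size=300)).astype(int)
            hits = [hit("e", int(p)) for p in positions]
            (s,) = qc_summary([position_distribution(hits, "e")])
            if abs(s.modal_position - 10) <= 1:
                ok += 1
        assert ok >= 95


class TestSpacingAxis:
    def test_spacing_distribution_matches_annotated_hits(self, default_library):
        pwms = {el.name: el.pwm for el in default_library}
        recs, _ = generate(
            n=80, width=201, tss_index=101, gc=0.5,
            plants=[PlantSpec("dInr", -2), PlantSpec("DPE", 28, anchor="dInr")],
            pwms=pwms, seed=9,
        )
        lib = default_library.subset(["dInr", "DPE"])
        mats = [to_scoring_matrix(el.pwm, UNIFORM) for el in lib]
        hits = scan(recs, mats, strands="both")
        calls, annotated = call_composites(hits, lib.rules)
        from_calls = spacing_distribution(calls, "DPE")
        from_hits = position_distribution(annotated, "DPE", axis="spacing")
        assert from_calls.table.equals(from_hits.table)
        (s,) = qc_summary([from_calls])
        assert s.modal_position == 28


class TestExportRoundTrip:
    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "dist.tsv"
        export_distribution_table([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t")[0] == "element"

    def test_single_row_fixture(self, tmp_path):
        hits = [hit("dInr", -2, score=s) for s in range(1, 11)]
        dist = position_distribution(hits, "dInr")
        path = tmp_path / "dist.tsv"
        export_distribution_table([dist], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 2
        assert "100.000000" in lines[1]

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(43)
        dists = [
            position_distribution(
                [hit(el, int(p), score=float(s)) for p, s in
                 zip(rng.integers(1, 30, size=100), rng.normal(5, 2, size=100))],
                el,
            )
            for el in ("a", "b")
        ]
        path = tmp_path / "dist.tsv"
        export_distribution_table(dists, path)
        back = read_distribution_table(path)
        assert [d.element for d in back] == ["a", "b"]
        for orig, rt in zip(dists, back):
            assert rt.total_hits == orig.total_hits
            assert list(rt.table["position"]) == list(orig.table["position"])
            np.testing.assert_allclose(
                rt.table["fraction_pct"], orig.table["fraction_pct"], atol=1e-6
            )
            np.testing.assert_allclose(
                rt.table["mean_score"], orig.table["mean_score"], atol=1e-6
            )
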