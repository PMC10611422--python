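"""Pile-up evidence, conversion QC, index calling and categorical codings."""

import itertools

import numpy as np
import pytest

from methindex.amplicon import bisulfite_convert
from methindex.caller import (
    CallerConfig,
    QCError,
    Read,
    ReadSet,
    call_index,
    call_sample,
    categorize,
    pile_up,
    qc_controls,
    read_reads,
    write_reads,
)
from methindex.synthetic_data import ReadSimConfig, pattern_with_index, simulate_reads


def _readset(sequences, sample_id="s"):
    reads = tuple(
        Read(f"{sample_id}|F|{i}", "forward", 1 + i % 2, s)
        for i, s in enumerate(sequences)
    )
    return ReadSet(sample_id, reads)


class TestPileUp:
    def test_uniform_t_at_control(self, toy_template):
        sm = toy_template.site_map
        conv = bisulfite_convert(toy_template, [False] * sm.n_cpg, sm)
        ev = pile_up(_readset([conv] * 4), sm)
        by_pos = {e.position: e for e in ev}
        for p in sm.control_positions:
            assert by_pos[p].c_fraction == 0.0
            assert by_pos[p].coverage == 4

    def test_half_methylated_cpg(self, toy_template):
        sm = toy_template.site_map
        on = bisulfite_convert(toy_template, [True] * sm.n_cpg, sm)
        off = bisulfite_convert(toy_template, [False] * sm.n_cpg, sm)
        ev = pile_up(_readset([on, on, off, off]), sm)
        for p in sm.cpg_positions:
            e = next(x for x in ev if x.position == p)
            assert e.c_fraction == 0.5

    def test_all_n_site_has_undefined_fraction(self, toy_template):
        sm = toy_template.site_map
        conv = bisulfite_convert(toy_template, [False] * sm.n_cpg, sm)
        pos = sm.cpg_positions[0]
        masked = conv[:pos] + "N" + conv[pos + 1 :]
        ev = pile_up(_readset([masked] * 4), sm)
        e = next(x for x in ev if x.position == pos)
        assert e.c_fraction is None and e.coverage == 0

    def test_length_mismatch_rejected(self, toy_template):
        sm = toy_template.site_map
        conv = bisulfite_convert(toy_template, [False] * sm.n_cpg, sm)
        with pytest.raises(ValueError, match="length"):
            pile_up(_readset([conv, conv[:-1] ]), sm)

    def test_reverse_reads_normalized(self, template, site_map, rng):
        rs, truth = simulate_reads(
            template,
            site_map,
            ReadSimConfig(allele_fractions=(1.0,) * 17),
            rng=rng,
        )
        assert {r.orientation for r in rs.reads} == {"forward", "reverse"}
        ev = pile_up(rs, site_map)
        for p in site_map.cpg_positions:
            assert next(e for e in ev if e.position == p).c_fraction == 1.0


class TestQCControls:
    def test_fully_converted_passes(self, toy_template):
        sm = toy_template.site_map
        conv = bisulfite_convert(toy_template, [False] * sm.n_cpg, sm)
        ok, failed = qc_controls(pile_up(_readset([conv] * 4), sm), sm)
        assert ok and failed == ()

    def test_simulated_conversion_failure_is_caught(self, template, site_map, rng):
        rs, _ = simulate_reads(
            template,
            site_map,
            ReadSimConfig(allele_fractions=(0.0,) * 17, conversion_failure_rate=0.5),
            rng=rng,
        )
        ev = pile_up(rs, site_map)
        ok, failed = qc_controls(ev, site_map)
        # oracle: recount directly from the piled evidence
        expected = tuple(
            e.position
            for e in ev
            if e.kind == "control"
            and (e.c_fraction is None or e.c_fraction >= 0.10 or e.coverage < 2)
        )
        assert not ok
        assert failed == expected

    def test_single_read_coverage_fails_gate(self, toy_template):
        sm = toy_template.site_map
        conv = bisulfite_convert(toy_template, [False] * sm.n_cpg, sm)
        ok, failed = qc_controls(pile_up(_readset([conv]), sm), sm)
        assert not ok and set(failed) == set(sm.control_positions)


class TestCallIndex:
    def test_fully_methylated_scores_17(self, template, site_map):
        conv = bisulfite_convert(template, [True] * 17, site_map)
        call = call_index(pile_up(_readset([conv] * 4), site_map), site_map)
        assert call.index == 17 and call.binary == "methylated"

    def test_fully_converted_scores_0_unmethylated(self, template, site_map):
        conv = bisulfite_convert(template, [False] * 17, site_map)
        call = call_index(pile_up(_readset([conv] * 4), site_map), site_map)
        assert call.index == 0
        assert call.binary == call.tertile == call.quintile == "unmethylated"

    def test_error_free_simulation_recovers_median_methylated_index(
        self, template, site_map, rng
    ):
        fractions = tuple([1.0] * 8 + [0.0] * 9)
        rs, truth = simulate_reads(
            template, site_map, ReadSimConfig(allele_fractions=fractions), rng=rng
        )
        call = call_sample(rs, site_map)
        assert call.qc_pass
        assert call.index == int(sum(truth.fractions)) == 8

    def test_qc_failed_sample_raises_on_direct_call(self, template, site_map, rng):
        rs, _ = simulate_reads(
            template,
            site_map,
            ReadSimConfig(allele_fractions=(0.0,) * 17, conversion_failure_rate=1.0),
            rng=rng,
        )
        with pytest.raises(QCError):
            call_index(pile_up(rs, site_map), site_map)


class TestCategorize:
    @pytest.mark.parametrize(
        "index,expected",
        [
            (0, ("unmethylated", "unmethylated", "unmethylated")),
            (1, ("methylated", "1-6", "1-3")),
            (3, ("methylated", "1-6", "1-3")),
            (4, ("methylated", "1-6", "4-6")),
            (6, ("methylated", "1-6", "4-6")),
            (7, ("methylated", "7-12", "7-9")),
            (9, ("methylated", "7-12", "7-9")),
            (10, ("methylated", "7-12", "10-13")),
            (12, ("methylated", "7-12", "10-13")),
            (13, ("methylated", "13-17", "10-13")),  # deliberate asymmetry
            (14, ("methylated", "13-17", "14-17")),
            (17, ("methylated", "13-17", "14-17")),
        ],
    )
    def test_boundary_map(self, index, expected):
        assert categorize(index) == expected

    @pytest.mark.parametrize("bad", [-1, 18, 3.5, "7"])
    def test_out_of_range_or_type(self, bad):
        with pytest.raises((ValueError, TypeError)):
            categorize(bad)


class TestExactRecovery:
    def test_exhaustive_patterns_on_toy_template(self, toy_template):
        """Every one of the 2^5 binary patterns is recovered exactly."""
        sm = toy_template.site_map
        for bits in itertools.product([0, 1], repeat=sm.n_cpg):
            conv = bisulfite_convert(toy_template, bits, sm)
            call = call_sample(_readset([conv] * 4), sm)
            assert call.qc_pass
            assert call.per_cpg_methylated == tuple(bool(b) for b in bits)
            assert call.index == sum(bits)

    def test_sampled_patterns_on_default_template(self, template, site_map, rng):
        for _ in range(150):
            k = int(rng.integers(0, 18))
            pattern = pattern_with_index(site_map, k, rng)
            rs, _ = simulate_reads(
                template,
                site_map,
                ReadSimConfig(allele_fractions=pattern.fractions),
                rng=rng,
            )
            call = call_sample(rs, site_map)
            assert call.qc_pass and call.index == k

    def test_raising_threshold_never_raises_index(self, template, site_map, rng):
        rs, _ = simulate_reads(
            template,
            site_map,
            ReadSimConfig(allele_fractions=tuple(rng.random(17)), seq_error_rate=0.02),
            rng=rng,
        )
        ev = pile_up(rs, site_map)
        last = None
        for thr in (0.05, 0.10, 0.26, 0.51, 0.76):
            ok, _ = qc_controls(ev, site_map, CallerConfig(detection_threshold=thr))
            if not ok:
                continue
            idx = call_index(
                ev, site_map, CallerConfig(detection_threshold=thr)
            ).index
            if last is not None:
                assert idx <= last
            last = idx

    def test_unconverted_control_always_blocks_index(self, template, site_map, rng):
        """QC dominance: one unconverted control, no index, ever."""
        for _ in range(20):
            rs, _ = simulate_reads(
                template,
                site_map,
                ReadSimConfig(
                    allele_fractions=tuple(rng.random(17)),
                    conversion_failure_rate=1.0,
                ),
                rng=rng,
            )
            call = call_sample(rs, site_map)
            assert not call.qc_pass and call.index is None


def test_reads_fasta_round_trip(template, site_map, rng, tmp_path):
    sets = []
    for i in range(3):
        rs, _ = simulate_reads(
            template,
            site_map,
            ReadSimConfig(allele_fractions=tuple(rng.random(17))),
            rng=rng,
            sample_id=f"S{i}",
        )
        sets.append(rs)
    path = tmp_path / "reads.fa"
    write_reads(sets, path)
    back = read_reads(path)
    assert [rs.sample_id for rs in back] == [rs.sample_id for rs in sets]
    for a, b in zip(back, sets):
        assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]
        assert [r.orientation for r in a.reads] == [r.orientation for r in b.reads]
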