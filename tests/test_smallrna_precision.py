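"""Read classification, strand counting and precision profiling."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amirnakit.design_engine import EngineeredScaffold, ValidationReport
from amirnakit.scaffold_core import Interval, ScaffoldError
from amirnakit.smallrna_precision import (
    Classification,
    ReadRecord,
    ReferenceWindow,
    StrandCounts,
    build_reference_windows,
    classify_read,
    count_strands,
    guide_passenger_ratio,
    precision_profile,
    quantify,
    read_windows_fasta,
    write_windows_fasta,
)


# ---------------------------------------------------------------------------
# Reference windows
# ---------------------------------------------------------------------------

def test_default_flanks_give_42_base_window(grafted_scaffold):
    windows = build_reference_windows(grafted_scaffold)
    assert len(windows["guide"]) == 42
    assert len(windows["guide"].core) == 22
    assert windows["guide"].expected_start == 10


def test_zero_flank_window_equals_core(grafted_scaffold):
    w = build_reference_windows(grafted_scaffold, flank_len=0)["guide"]
    assert w.window == w.core


def _tiny_scaffold(arm5p_start: int) -> EngineeredScaffold:
    seq = "ACGU" * 30
    a5 = Interval(arm5p_start, arm5p_start + 21)
    a3 = Interval(80, 101)
    return EngineeredScaffold(
        parent_id="tiny",
        sequence=seq,
        structure="." * len(seq),
        applied_mods=("base",),
        guide=seq[a5.start : a5.end + 1],
        passenger=seq[a3.start : a3.end + 1],
        guide_arm="5p",
        arm5p=a5,
        arm3p=a3,
        loop_interval=Interval(60, 70),
        anchor=a5.start,
        validation=ValidationReport({}),
    )


def test_insufficient_scaffold_flank_names_the_side():
    with pytest.raises(ScaffoldError, match="5' side"):
        build_reference_windows(_tiny_scaffold(arm5p_start=8), flank_len=10)


def test_windows_fasta_round_trip(tmp_path, grafted_scaffold):
    windows = build_reference_windows(grafted_scaffold)
    path = tmp_path / "windows.fasta"
    write_windows_fasta(windows, path)
    back = read_windows_fasta(path)
    for role in windows:
        assert back[role].id == windows[role].id
        assert back[role].core == windows[role].core.replace("U", "T")
        assert len(back[role]) == len(windows[role])


# ---------------------------------------------------------------------------
# Read classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "cigar,flag,accepted,reason",
    [
        ("22M", 0, True, None),
        ("18M", 0, True, None),
        ("24M", 0, True, None),
        ("17M", 0, False, "too_short"),
        ("25M", 0, False, "too_long"),
        ("10M1I11M", 0, False, "indel"),
        ("10M1D12M", 0, False, "indel"),
        ("2S20M", 0, False, "clipped"),
        ("20M2H", 0, False, "clipped"),
        ("11M11M", 0, False, "multi_segment"),
        ("10=2X10=", 0, False, "mismatch"),
        ("22M", 0x10, False, "antisense"),
        ("22M", 0x100, False, "secondary"),
        ("22M", 0x800, False, "supplementary"),
        ("*", 0x4, False, "unmapped"),
    ],
)
def test_classify_read_filter(cigar, flag, accepted, reason):
    r = ReadRecord("r", "A" * 22, cigar, 0, flag, "w|guide")
    cls = classify_read(r)
    assert cls.accepted is accepted
    assert cls.reason == reason


def test_malformed_cigar_raises():
    with pytest.raises(ValueError):
        classify_read(ReadRecord("r", "A", "M22", 0, 0, "w"))


def test_strict_mode_requires_exact_match():
    r = ReadRecord("r", "A" * 22, "22M", 0, 0, "w", nm=1)
    assert classify_read(r, strict=True).accepted is False
    r0 = ReadRecord("r", "A" * 22, "22M", 0, 0, "w", nm=0)
    assert classify_read(r0, strict=True).accepted is True


def _brute_force_classify(cigar, flag, min_len=18, max_len=24):
    """Independent re-implementation of the acceptance criteria."""
    for bit, reason in ((0x4, "unmapped"), (0x100, "secondary"),
                        (0x800, "supplementary"), (0x10, "antisense")):
        if flag & bit:
            return (False, reason)
    if cigar == "*":
        return (False, "unmapped")
    ops = re.findall(r"(\d+)([A-Z=])", cigar)
    if any(op in "ID" or op in "NP" for _, op in ops):
        return (False, "indel")
    if any(op in "SH" for _, op in ops):
        return (False, "clipped")
    if any(op == "X" for _, op in ops):
        return (False, "mismatch")
    if len(ops) != 1:
        return (False, "multi_segment")
    n = int(ops[0][0])
    if n < min_len:
        return (False, "too_short")
    if n > max_len:
        return (False, "too_long")
    return (True, None)


@given(st.data())
@settings(derandomize=True, max_examples=1000)
def test_classify_matches_brute_force_oracle(data):
    ops = data.draw(
        st.lists(
            st.tuples(st.integers(1, 30), st.sampled_from("MIDNSHP=X")),
            min_size=1,
            max_size=4,
        )
    )
    cigar = "".join(f"{n}{op}" for n, op in ops)
    flag = data.draw(st.sampled_from([0, 0x4, 0x10, 0x100, 0x800, 0x10 | 0x100]))
    r = ReadRecord("r", "A" * 22, cigar, 0, flag, "w")
    cls = classify_read(r)
    assert (cls.accepted, cls.reason) == _brute_force_classify(cigar, flag)


# ---------------------------------------------------------------------------
# Counting and ratios
# ---------------------------------------------------------------------------

def _windows():
    g = ReferenceWindow("s", "guide", "G" * 22, "A" * 10, "C" * 10)
    p = ReferenceWindow("s", "passenger", "C" * 22, "A" * 10, "C" * 10)
    return {"guide": g, "passenger": p}


def _read(window, start=10, length=22, name="r"):
    return ReadRecord(name, "A" * length, f"{length}M", start, 0, window.id)


def test_count_strands_partitions_reads():
    w = _windows()
    reads = [_read(w["guide"], name=f"g{i}") for i in range(10)]
    c = count_strands(reads, w)
    assert (c.guide_count, c.passenger_count) == (10, 0)
    assert c.normalized_guide == pytest.approx(1e6)


def test_count_strands_empty_input():
    c = count_strands([], _windows())
    assert (c.guide_count, c.passenger_count) == (0, 0)


def test_unknown_window_is_an_error():
    with pytest.raises(ScaffoldError):
        count_strands([ReadRecord("r", "A" * 22, "22M", 0, 0, "nope")], _windows())


def test_quantify_conserves_reads():
    w = _windows()
    reads = [
        _read(w["guide"], name="ok1"),
        _read(w["guide"], length=17, name="short"),
        ReadRecord("ind", "A" * 22, "10M1I11M", 0, 0, w["guide"].id),
        _read(w["passenger"], name="ok2"),
    ]
    q = quantify(reads, w)
    assert q.n_total == 4
    assert q.n_accepted + sum(q.rejected.values()) == q.n_total
    assert q.rejected == {"too_short": 1, "indel": 1}


def test_ratio_values():
    r = guide_passenger_ratio(
        StrandCounts(1000, 10, 0.0, 0.0, 1010)
    )
    assert r.value == pytest.approx(100.0)
    inf = guide_passenger_ratio(StrandCounts(5, 0, 0.0, 0.0, 5))
    assert inf.infinite and inf.value == np.inf
    with pytest.raises(ScaffoldError):
        guide_passenger_ratio(StrandCounts(0, 0, 0.0, 0.0, 0))


# ---------------------------------------------------------------------------
# Precision profiles
# ---------------------------------------------------------------------------

def test_perfect_reads_give_full_fidelity():
    w = _windows()["guide"]
    reads = [_read(w, name=f"r{i}") for i in range(100)]
    prof = precision_profile(reads, w)
    assert prof.five_prime_fidelity == 100.0
    assert np.count_nonzero(prof.start_counts) == 1
    assert np.count_nonzero(prof.end_counts) == 1


def test_shifted_fraction_reduces_fidelity():
    w = _windows()["guide"]
    reads = [_read(w, name=f"r{i}") for i in range(98)]
    reads += [_read(w, start=11, name=f"s{i}") for i in range(2)]
    prof = precision_profile(reads, w)
    assert prof.five_prime_fidelity == pytest.approx(98.0)


def test_percentages_sum_to_100():
    w = _windows()["guide"]
    rng = np.random.default_rng(0)
    reads = [
        _read(w, start=int(10 + rng.integers(-2, 3)), length=int(rng.integers(18, 25)), name=f"r{i}")
        for i in range(500)
    ]
    prof = precision_profile(reads, w)
    assert prof.start_pct.sum() == pytest.approx(100.0, abs=1e-9)
    assert prof.end_pct.sum() == pytest.approx(100.0, abs=1e-9)


def test_zero_reads_is_an_error_not_nan():
    with pytest.raises(ScaffoldError):
        precision_profile([], _windows()["guide"])


def test_merged_read_sets_profile_like_separate_ones():
    """Per-scaffold isolation: merging libraries does not change profiles."""
    w = _windows()
    g_reads = [_read(w["guide"], name=f"g{i}") for i in range(50)]
    p_reads = [_read(w["passenger"], name=f"p{i}") for i in range(5)]
    merged = g_reads + p_reads
    prof_sep = precision_profile(g_reads, w["guide"])
    prof_merged = precision_profile(merged, w["guide"])
    assert np.array_equal(prof_sep.start_counts, prof_merged.start_counts)
    assert np.array_equal(prof_sep.end_counts, prof_merged.end_counts)
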