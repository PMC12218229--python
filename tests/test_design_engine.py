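"""Design engine: modification classes, determinant validation, screening."""

import re

import pytest

from amirnakit.design_engine import (
    Candidate,
    ConfigError,
    FlankRedesignError,
    ModificationSpec,
    PostGraftError,
    apply_all,
    apply_base_modification,
    apply_chc_insertion,
    apply_loop_swap,
    embed_duplex,
    screen_candidates,
    validate_scaffold,
)
from amirnakit.fixtures import MIR30A_LOOP, SCREENING_GUIDE
from amirnakit.scaffold_core import Interval, PriMiRNA, ScaffoldError, fold_pri, stem_pairs, fold

BASE_CHECKS = ("basal_GU", "stem_length", "flanks_unstructured", "single_hairpin")


@pytest.fixture(params=["let7a1", "mir26b"])
def parent(request, let7a1, mir26b):
    return {"let7a1": let7a1, "mir26b": mir26b}[request.param]


def test_base_modification_satisfies_base_determinants(parent, spec, service):
    s = apply_base_modification(parent, spec, service, seed=0)
    assert s.validation.passed_subset(BASE_CHECKS), s.validation.to_dict()
    # GU dinucleotide sits at offsets -14/-13 from the DROSHA site
    assert s.sequence[s.anchor - 14 : s.anchor - 12] == "GU"


def test_base_modified_stem_has_35_pairs(base_scaffold_let7, service):
    h = fold(
        base_scaffold_let7.sequence,
        service,
        arm5p=base_scaffold_let7.arm5p,
        arm3p=base_scaffold_let7.arm3p,
    )
    assert len(stem_pairs(h)) == 35
    assert len(stem_pairs(h, base_scaffold_let7.loop_interval)) == 35


def test_base_modification_is_idempotent(base_scaffold_let7, spec, service):
    again = apply_base_modification(base_scaffold_let7.to_pri(), spec, service, seed=0)
    assert again.sequence == base_scaffold_let7.sequence


def test_insufficient_parent_flank_is_an_error(spec, service):
    # miRBase stem-loop without pri context: arms 5 nt from the 5' end
    seq = (
        "UGGGAUGAGGUAGUAGGUUGUAUAGUUUUAGGGUCACACCCACCACUGGGAGAUAA"
        "CUAUACAAUCUACUGUCUUUCCUA"
    )
    p = PriMiRNA("bare", seq, Interval(5, 26), Interval(56, 76))
    with pytest.raises(FlankRedesignError):
        apply_base_modification(p, spec, service, seed=0)


def test_chc_insertion_debulges_and_places_bulge(parent, spec, service):
    s = apply_chc_insertion(parent, spec, service, seed=0)
    assert s.validation.passed_subset(("chc_bulge", "debulged_window")), s.validation.to_dict()


def test_chc_insertion_is_idempotent(mir26b, spec, service):
    s = apply_chc_insertion(mir26b, spec, service, seed=0)
    again = apply_chc_insertion(s.to_pri(), spec, service, seed=0)
    assert again.sequence == s.sequence


def test_chc_offset_outside_window_is_config_error():
    with pytest.raises(ConfigError):
        ModificationSpec(chc_offset=-20)


def test_empty_loop_sequence_is_config_error():
    with pytest.raises(ConfigError):
        ModificationSpec(loop_sequence="")


def test_loop_swap_places_configured_loop(parent, spec, service):
    s = apply_loop_swap(parent, spec, service)
    placed = s.sequence[s.loop_interval.start : s.loop_interval.end + 1]
    assert placed == MIR30A_LOOP
    assert s.validation.checks["loop_identity"].passed


def test_loop_swap_with_own_loop_is_identity(let7a1, service):
    h = fold_pri(let7a1, service)
    own = let7a1.sequence[h.loop.start : h.loop.end + 1]
    spec_own = ModificationSpec(loop_sequence=own)
    s = apply_loop_swap(let7a1, spec_own, service)
    assert s.sequence == let7a1.sequence


def test_apply_all_passes_every_determinant(parent, spec, service):
    s = apply_all(parent, spec, service, seed=0)
    assert s.validation.passed, s.validation.to_dict()


def test_apply_all_is_idempotent(all_scaffold_26b, spec, service):
    again = apply_all(all_scaffold_26b.to_pri(), spec, service, seed=0)
    assert again.sequence == all_scaffold_26b.sequence


def test_apply_all_is_seed_deterministic(mir26b, spec, service):
    a = apply_all(mir26b, spec, service, seed=11)
    b = apply_all(mir26b, spec, service, seed=11)
    assert a.sequence == b.sequence
    assert a.structure == b.structure


def test_wild_type_parent_lacks_engineered_determinants(parent, spec, service):
    from amirnakit.design_engine import _as_scaffold

    wt = _as_scaffold(parent, service, spec, ())
    failed = wt.validation.failures()
    assert "basal_GU" in failed or "chc_bulge" in failed


def test_validation_against_different_loop_spec_fails(all_scaffold_26b, service):
    other = ModificationSpec(loop_sequence="GUGAAGCCACAGAUG")
    report = validate_scaffold(all_scaffold_26b, other, service)
    assert not report.checks["loop_identity"].passed


def test_embedded_guide_reads_back(grafted_scaffold):
    arm = grafted_scaffold.arm5p
    assert (
        grafted_scaffold.sequence[arm.start : arm.end + 1] == SCREENING_GUIDE
    )
    assert grafted_scaffold.validation.passed


def test_embedding_same_duplex_is_identity(grafted_scaffold, spec, service):
    again = embed_duplex(
        grafted_scaffold, SCREENING_GUIDE, spec=spec, service=service, seed=0
    )
    assert again.sequence == grafted_scaffold.sequence


def test_self_hairpin_guide_is_rescued_by_complementary_passenger(
    all_scaffold_26b, spec, service
):
    # a strongly self-pairing guide could fold back on itself, but with a
    # fully complementary passenger the duplex helix dominates the MFE and
    # the graft still validates (confirmed against the folding oracle)
    hairpin_guide = "GGGGGGGGGGUUCGCCCCCCCC"
    s = embed_duplex(all_scaffold_26b, hairpin_guide, spec=spec, service=service, seed=0)
    assert s.validation.passed


def test_unpairable_duplex_fails_post_graft_validation(all_scaffold_26b, service):
    # guide grafted against an identical (non-complementary) passenger:
    # no duplex can form and the refold is no longer a single hairpin
    quick = ModificationSpec(max_attempts=4)
    g = "AAAAAAAAAACCCCCCCCCCCC"
    with pytest.raises(PostGraftError):
        embed_duplex(all_scaffold_26b, g, passenger=g, spec=quick, service=service, seed=0)


# ---------------------------------------------------------------------------
# Candidate screening
# ---------------------------------------------------------------------------

def _toy_pri(seq_3p_flank: str, name: str) -> PriMiRNA:
    guide = "UGAGGUAGUAGGUUGUAUAGUU"
    stem3 = "AACUAUACAACCUACUACCUCA"
    seq = "A" * 12 + guide + "GUGAAAC" + stem3 + seq_3p_flank
    a5 = Interval(12, 33)
    a3 = Interval(41, 62)
    return PriMiRNA(name, seq, a5, a3)


def _oracle_has_cnnc(p: PriMiRNA, lo=16, hi=21) -> bool:
    """Independent regex scan: CNNC starting lo..hi nt downstream of the 3p site."""
    return any(
        re.match("C..C", p.sequence[p.arm3p.end + d : p.arm3p.end + d + 4])
        for d in range(lo, hi + 1)
        if p.arm3p.end + d + 4 <= len(p.sequence)
    )


def test_screen_membership_matches_regex_oracle():
    pris = {}
    table = {}
    for i in range(20):
        # vary where (and whether) a CNNC motif lands in the 3' flank
        flank = list("A" * 30)
        if i % 3 != 0:
            pos = 10 + i % 12  # 0-based distance downstream of the 3p site
            flank[pos] = "C"
            flank[pos + 3] = "C"
        p = _toy_pri("".join(flank), f"mir{i:02d}")
        pris[p.id] = p
        table[p.id] = float(100 - i)
    hits = screen_candidates(table, pris, top_n=50)
    got = {c.id for c in hits}
    expected = {n for n, p in pris.items() if _oracle_has_cnnc(p)}
    assert got == expected


def test_screen_truncates_and_breaks_ties_by_id():
    pris = {f"m{i}": _toy_pri("A" * 17 + "CAAC" + "A" * 9, f"m{i}") for i in range(6)}
    table = {n: 5.0 for n in pris}
    hits = screen_candidates(table, pris, top_n=4)
    assert [c.id for c in hits] == sorted(pris)[:4]


def test_screen_empty_table_is_an_error():
    with pytest.raises(ScaffoldError):
        screen_candidates({}, {})
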