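"""Rule-based engineering of pri-miRNA hairpins into amiRNA scaffolds.

Four modification classes place the processing determinants that promote
efficient and precise DROSHA/DICER cleavage:

``base``
    GU dinucleotide at offsets -14/-13 from the DROSHA 5' cleavage site, an
    unstructured stem base (10 nt of unpaired flank on each side), and a
    stem of exactly 35 base pairs.
``chc``
    A single-nucleotide CHC bulge on the passenger-side basal strand at
    offset -6, with every 5'-strand position between offsets 0 and -13
    paired after refolding (the "debulged" window).
``loop``
    The endogenous terminal loop replaced by the miR-30a loop.
``all``
    All of the above combined.

The engine works constructively: it lays the scaffold out as
``flank5 | basal stem | duplex | loop | duplex' | basal stem' | flank3``
and tunes the basal pair count against the refolded MFE structure until the
stem enclosing the designated loop holds exactly ``stem_len_target`` pairs.
All stochastic choices (flank and basal fill-in nucleotides) come from a
seeded generator, so a fixed seed yields a byte-identical scaffold.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .scaffold_core import (
    CANONICAL_PAIRS,
    DEFAULT_MAX_PRI_LEN,
    FoldedHairpin,
    FoldingService,
    Interval,
    PriMiRNA,
    ScaffoldError,
    complement,
    fold,
    fold_pri,
    pair_table,
    revcomp,
    stem_pairs,
    terminal_loops,
    to_rna,
)
from .fixtures import MIR30A_LOOP

logger = logging.getLogger(__name__)

_IUPAC_H = frozenset("ACU")

CHECK_NAMES = (
    "basal_GU",
    "chc_bulge",
    "debulged_window",
    "stem_length",
    "loop_identity",
    "flanks_unstructured",
    "single_hairpin",
)


class DesignError(ScaffoldError):
    """Base class for design-engine failures."""


class ConfigError(DesignError):
    pass


class StemRedesignError(DesignError):
    pass


class FlankRedesignError(DesignError):
    pass


class DebulgeError(DesignError):
    pass


class LoopSwapError(DesignError):
    pass


class PostGraftError(DesignError):
    pass


@dataclass(frozen=True)
class ModificationSpec:
    """Tunable parameters of the modification classes.

    Offsets are relative to the DROSHA putative 5' cleavage site (offset 0 =
    first nucleotide of the 5p arm).  The basal dinucleotide occupies the
    two positions immediately below the debulge window (offsets -14/-13 by
    default, G at -14 and U at -13 following the published orientation; the
    motif literature also writes UG, hence the field is configurable).
    """

    basal_dinucleotide: str = "GU"
    chc_offset: int = -6
    chc_motif: str = "CHC"
    chc_bulge_h: str = "A"
    chc_bulge_strand: str = "3p"
    debulge_window: tuple[int, int] = (-13, 0)
    stem_len_target: int = 35
    loop_sequence: str = MIR30A_LOOP
    flank_unstructured_len: int = 10
    cnnc_window: tuple[int, int] = (16, 21)
    max_attempts: int = 50
    max_pri_len: int = DEFAULT_MAX_PRI_LEN

    def __post_init__(self) -> None:
        lo, hi = self.debulge_window
        if lo >= hi or hi > 0:
            raise ConfigError(f"invalid debulge_window {self.debulge_window}")
        if not lo <= self.chc_offset <= hi:
            raise ConfigError(
                f"chc_offset {self.chc_offset} outside debulge_window {self.debulge_window}"
            )
        if len(self.basal_dinucleotide) != 2 or not set(self.basal_dinucleotide) <= set("ACGU"):
            raise ConfigError("basal_dinucleotide must be an RNA 2-mer")
        if self.chc_bulge_h not in _IUPAC_H:
            raise ConfigError("chc_bulge_h must be A, C or U (IUPAC H)")
        if self.chc_bulge_strand not in ("3p", "5p"):
            raise ConfigError("chc_bulge_strand must be '5p' or '3p'")
        if not self.loop_sequence:
            raise ConfigError("loop_sequence must be non-empty")
        if self.stem_len_target < (hi - lo + 1):
            raise ConfigError("stem_len_target smaller than the debulge window")
        object.__setattr__(self, "loop_sequence", to_rna(self.loop_sequence))

    @property
    def basal_positions(self) -> tuple[int, int]:
        lo = self.debulge_window[0]
        return (lo - 1, lo)


@dataclass(frozen=True)
class CheckResult:
    passed: bool
    message: str = ""


@dataclass(frozen=True)
class ValidationReport:
    """Per-determinant validation of a refolded scaffold."""

    checks: Mapping[str, CheckResult]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks.values())

    def passed_subset(self, names: Sequence[str]) -> bool:
        return all(self.checks[n].passed for n in names)

    def failures(self) -> list[str]:
        return [n for n, c in self.checks.items() if not c.passed]

    def to_dict(self) -> dict:
        return {
            n: {"passed": c.passed, "message": c.message} for n, c in self.checks.items()
        }


@dataclass(frozen=True)
class EngineeredScaffold:
    """A modified hairpin with provenance and a validation report."""

    parent_id: str
    sequence: str
    structure: str
    applied_mods: tuple[str, ...]
    guide: str
    passenger: str
    guide_arm: str  # "5p" or "3p"
    arm5p: Interval
    arm3p: Interval
    loop_interval: Interval
    anchor: int
    validation: ValidationReport

    @property
    def id(self) -> str:
        return f"{self.parent_id}:{'+'.join(self.applied_mods) or 'wt'}"

    def to_pri(self, max_pri_len: int = DEFAULT_MAX_PRI_LEN) -> PriMiRNA:
        return PriMiRNA(self.id, self.sequence, self.arm5p, self.arm3p, max_pri_len)

    @classmethod
    def from_dict(cls, d: Mapping) -> "EngineeredScaffold":
        report = ValidationReport(
            {
                n: CheckResult(v["passed"], v.get("message", ""))
                for n, v in d.get("validation", {}).items()
            }
        )
        return cls(
            parent_id=d["parent_id"],
            sequence=d["sequence"],
            structure=d["structure"],
            applied_mods=tuple(d["applied_mods"]),
            guide=d["guide"],
            passenger=d["passenger"],
            guide_arm=d["guide_arm"],
            arm5p=Interval(*d["arm5p"]),
            arm3p=Interval(*d["arm3p"]),
            loop_interval=Interval(*d["loop_interval"]),
            anchor=d["anchor"],
            validation=report,
        )

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "parent_id": self.parent_id,
            "sequence": self.sequence,
            "structure": self.structure,
            "applied_mods": list(self.applied_mods),
            "guide": self.guide,
            "passenger": self.passenger,
            "guide_arm": self.guide_arm,
            "arm5p": [self.arm5p.start, self.arm5p.end],
            "arm3p": [self.arm3p.start, self.arm3p.end],
            "loop_interval": [self.loop_interval.start, self.loop_interval.end],
            "anchor": self.anchor,
            "validation": self.validation.to_dict(),
        }


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _enclosing_count(pt, loop: Interval) -> int:
    return sum(
        1 for i, j in enumerate(pt) if j is not None and j > i and i < loop.start and j > loop.end
    )


def _check_basal_gu(seq, anchor, spec) -> CheckResult:
    chars = []
    for off in spec.basal_positions:
        idx = anchor + off
        chars.append(seq[idx] if 0 <= idx < len(seq) else "-")
    got = "".join(chars)
    ok = got == spec.basal_dinucleotide
    return CheckResult(ok, f"offsets {spec.basal_positions}: expected {spec.basal_dinucleotide}, found {got}")


def _check_chc(seq, pt, anchor, spec) -> CheckResult:
    o = spec.chc_offset
    i_o, i_o1 = anchor + o, anchor + o + 1
    if not (0 <= i_o < len(seq)):
        return CheckResult(False, f"offset {o} outside sequence")
    j_o, j_o1 = pt[i_o], pt[i_o1]
    if j_o is None or j_o1 is None:
        return CheckResult(False, f"offsets {o}/{o + 1} not paired")
    if j_o != j_o1 + 2:
        return CheckResult(False, f"no single-nucleotide 3'-strand bulge between partners of {o} and {o + 1}")
    h = seq[j_o1 + 1]
    if pt[j_o1 + 1] is not None:
        return CheckResult(False, "bulge position is paired")
    context = (seq[j_o1], h, seq[j_o])
    if context[0] != "C" or context[2] != "C" or h not in _IUPAC_H:
        return CheckResult(False, f"bulge context {''.join(context)} does not match CHC")
    return CheckResult(True, f"CHC bulge ({''.join(context)}) opposite offset {o}")


def _check_debulge(seq, pt, anchor, spec) -> CheckResult:
    lo, hi = spec.debulge_window
    bad = []
    for off in range(lo, hi + 1):
        idx = anchor + off
        if idx < 0 or idx >= len(seq) or pt[idx] is None:
            bad.append(off)
            continue
        pair = (seq[idx], seq[pt[idx]])
        if pair not in CANONICAL_PAIRS:
            bad.append(off)
    if bad:
        return CheckResult(False, f"unpaired/non-canonical offsets in window: {bad}")
    return CheckResult(True, f"window {spec.debulge_window} fully paired")


def _check_stem_length(pt, loop: Interval, spec) -> CheckResult:
    n = _enclosing_count(pt, loop)
    return CheckResult(n == spec.stem_len_target, f"stem has {n} pairs (target {spec.stem_len_target})")


def _check_loop_identity(seq, loop: Interval, spec) -> CheckResult:
    got = seq[loop.start : loop.end + 1]
    ok = got == spec.loop_sequence
    return CheckResult(ok, f"loop sequence {got} vs configured {spec.loop_sequence}")


def _check_flanks(pt, flank_len: int) -> CheckResult:
    n = len(pt)
    bad = [i for i in range(min(flank_len, n)) if pt[i] is not None]
    bad += [i for i in range(max(0, n - flank_len), n) if pt[i] is not None]
    if bad:
        return CheckResult(False, f"paired flank positions: {bad}")
    return CheckResult(True, f"{flank_len} nt unpaired on both ends")


def _check_single_hairpin(pt, arm5p: Interval, arm3p: Interval, loop: Interval) -> CheckResult:
    region = Interval(arm5p.start, arm3p.end)
    loops = [lp for lp in terminal_loops(pt) if lp.overlaps(region)]
    if len(loops) != 1:
        return CheckResult(False, f"{len(loops)} terminal loops in the hairpin region")
    if not loops[0].overlaps(loop):
        return CheckResult(False, "terminal loop lies outside the designated loop interval")
    return CheckResult(True, "single hairpin with apex in the designated loop")


def validate_scaffold(
    s: EngineeredScaffold, spec: ModificationSpec, service: FoldingService
) -> ValidationReport:
    """Re-fold a scaffold and check every processing determinant.

    Each check reports a message with the offsets of any violation; the
    report passes overall only if every check passes.
    """
    seq = s.sequence
    structure = service.fold(seq)
    pt = pair_table(structure)
    checks = {
        "basal_GU": _check_basal_gu(seq, s.anchor, spec),
        "chc_bulge": _check_chc(seq, pt, s.anchor, spec),
        "debulged_window": _check_debulge(seq, pt, s.anchor, spec),
        "stem_length": _check_stem_length(pt, s.loop_interval, spec),
        "loop_identity": _check_loop_identity(seq, s.loop_interval, spec),
        "flanks_unstructured": _check_flanks(pt, spec.flank_unstructured_len),
        "single_hairpin": _check_single_hairpin(pt, s.arm5p, s.arm3p, s.loop_interval),
    }
    return ValidationReport(checks)


def _as_scaffold(
    p: PriMiRNA,
    service: FoldingService,
    spec: ModificationSpec,
    applied: tuple[str, ...],
    *,
    loop_interval: Interval | None = None,
    guide_arm: str = "5p",
) -> EngineeredScaffold:
    """View a pri-miRNA as a scaffold (used for identity results)."""
    h = fold_pri(p, service)
    s = EngineeredScaffold(
        parent_id=p.id,
        sequence=p.sequence,
        structure=h.structure,
        applied_mods=applied,
        guide=p.guide5p if guide_arm == "5p" else p.arm3p_seq,
        passenger=p.arm3p_seq if guide_arm == "5p" else p.guide5p,
        guide_arm=guide_arm,
        arm5p=p.arm5p,
        arm3p=p.arm3p,
        loop_interval=loop_interval if loop_interval is not None else h.loop,
        anchor=p.arm5p.start,
        validation=ValidationReport({}),
    )
    return replace(s, validation=validate_scaffold(s, spec, service))


# ---------------------------------------------------------------------------
# Constructive builder (base-containing modification sets)
# ---------------------------------------------------------------------------

def _sample_avoiding_runs(rng: random.Random, prev: str, alphabet: str = "ACGU") -> str:
    """Draw one base, avoiding homopolymer runs of 4 with the given context."""
    while True:
        b = rng.choice(alphabet)
        if len(prev) >= 3 and prev[-3:] == b * 3:
            continue
        return b


def _sample_flank(rng: random.Random, n: int) -> str:
    # A/C-only flanks cannot pair with each other, which keeps the stem base
    # unstructured in the MFE refold
    out = ""
    for _ in range(n):
        out += _sample_avoiding_runs(rng, out, "AC")
    return out


def _require_parent_flanks(p: PriMiRNA, spec: ModificationSpec) -> None:
    flank = spec.flank_unstructured_len
    left = p.arm5p.start
    right = len(p.sequence) - 1 - p.arm3p.end
    if left < flank or right < flank:
        raise FlankRedesignError(
            f"{p.id}: needs >= {flank} nt outside the arms on both sides "
            f"(found {left} on 5', {right} on 3')"
        )


@dataclass
class _Layout:
    sequence: str
    anchor: int
    arm5p: Interval
    arm3p: Interval
    loop_interval: Interval


def _assemble(
    parent: PriMiRNA,
    spec: ModificationSpec,
    *,
    core5: str,
    core3: str,
    loop_seq: str,
    b: int,
    flank5: str,
    flank3: str,
    with_chc: bool,
    overhang: int,
    rng: random.Random,
    use_parent_fill: bool,
) -> _Layout:
    """Lay out one scaffold candidate with a basal stem of b pairs."""
    flank = spec.flank_unstructured_len
    p_anchor = parent.arm5p.start
    lo_gu, hi_gu = spec.basal_positions  # e.g. -14, -13

    core3 = list(core3)
    if with_chc and overhang + 1 <= len(core3):
        # position 0 must pair: its partner sits `overhang` nts from the
        # passenger 3' end
        idx0 = len(core3) - overhang - 1
        if (core3[idx0], core5[0]) not in CANONICAL_PAIRS:
            core3[idx0] = complement(core5[0])
    core3 = "".join(core3)

    basal: dict[int, str] = {}
    # passenger tail pairs the offsets just below the cleavage site
    for k in range(overhang):
        basal[-(k + 1)] = complement(core3[-(overhang - k)])
    for off in range(-b, 0):
        if off in basal:
            continue
        if off == hi_gu:
            basal[off] = spec.basal_dinucleotide[1]
        elif off == lo_gu:
            basal[off] = spec.basal_dinucleotide[0]
        elif with_chc and off in (spec.chc_offset, spec.chc_offset + 1):
            basal[off] = "G"  # pairs the C/C context of the CHC bulge
        else:
            src = p_anchor + off
            if use_parent_fill and 0 <= src < len(parent.sequence):
                basal[off] = parent.sequence[src]
            else:
                prev = "".join(basal.get(o, "") for o in range(off - 3, off))
                basal[off] = _sample_avoiding_runs(rng, prev)
    basal5 = "".join(basal[o] for o in range(-b, 0))
    mirror = revcomp(basal5[: b - overhang])  # pairs offsets -b .. -(overhang+1)
    if with_chc:
        hpos = -spec.chc_offset - overhang - 1  # between partners of o+1 and o
        if hpos < 0 or hpos > len(mirror):
            raise ConfigError("chc_offset incompatible with basal geometry")
        mirror = mirror[:hpos] + spec.chc_bulge_h + mirror[hpos:]

    seq = flank5 + basal5 + core5 + loop_seq + core3 + mirror + flank3
    anchor = flank + b
    # force the basal dinucleotide even when it falls into the flank
    chars = list(seq)
    for off, base_ in zip(spec.basal_positions, spec.basal_dinucleotide):
        idx = anchor + off
        if 0 <= idx < len(chars):
            chars[idx] = base_
    seq = "".join(chars)

    loop_start = anchor + len(core5)
    loop_iv = Interval(loop_start, loop_start + len(loop_seq) - 1)
    arm5p = Interval(anchor, anchor + len(core5) - 1)
    arm3p = Interval(loop_iv.end + 1, loop_iv.end + len(core3))
    return _Layout(seq, anchor, arm5p, arm3p, loop_iv)


def _construct(
    parent: PriMiRNA,
    spec: ModificationSpec,
    service: FoldingService,
    seed: int,
    *,
    applied: tuple[str, ...],
    core5: str,
    core3: str,
    loop_seq: str,
    guide_arm: str = "5p",
    overhang: int = 2,
    required_checks: Sequence[str],
) -> EngineeredScaffold:
    """Build a scaffold and tune the basal stem until the target is met.

    The basal pair count starts at the width of the debulge window and is
    corrected by feedback against the refolded structure; stochastic
    components (flank / basal fill-in) are redrawn between attempts from the
    seeded generator.  Attempt 0 reuses the parent's own nucleotides, which
    makes reconstruction of an already-valid scaffold byte-identical.
    """
    if spec.chc_bulge_strand != "3p":
        raise ConfigError("only the 3p (passenger-side) CHC bulge strand is implemented")
    with_chc = "chc" in applied
    rng = random.Random(seed)
    flank = spec.flank_unstructured_len
    b = max(len(range(*spec.debulge_window)) + 1, overhang + 1)  # window width
    last_err = "no attempt made"
    flank5 = parent.sequence[:flank]
    flank3 = parent.sequence[-flank:]
    use_parent_fill = True

    for attempt in range(spec.max_attempts):
        if attempt > 0:
            flank5 = _sample_flank(rng, flank)
            flank3 = _sample_flank(rng, flank)
            use_parent_fill = False
        for _ in range(25):  # basal-length feedback
            lay = _assemble(
                parent,
                spec,
                core5=core5,
                core3=core3,
                loop_seq=loop_seq,
                b=b,
                flank5=flank5,
                flank3=flank3,
                with_chc=with_chc,
                overhang=overhang,
                rng=rng,
                use_parent_fill=use_parent_fill,
            )
            if len(lay.sequence) > spec.max_pri_len:
                raise StemRedesignError(
                    f"{parent.id}: stem redesign failed: length {len(lay.sequence)} "
                    f"exceeds budget {spec.max_pri_len}"
                )
            structure = service.fold(lay.sequence)
            pt = pair_table(structure)
            n_stem = _enclosing_count(pt, lay.loop_interval)
            if n_stem == spec.stem_len_target:
                break
            step = spec.stem_len_target - n_stem
            b += step
            if b < overhang + 1 or b > spec.max_pri_len:
                raise StemRedesignError(f"{parent.id}: stem redesign failed (basal length {b})")
        else:
            raise StemRedesignError(
                f"{parent.id}: stem redesign failed: no basal length reaches "
                f"{spec.stem_len_target} pairs"
            )

        candidate = EngineeredScaffold(
            parent_id=parent.id,
            sequence=lay.sequence,
            structure=structure,
            applied_mods=applied,
            guide=core5 if guide_arm == "5p" else core3,
            passenger=core3 if guide_arm == "5p" else core5,
            guide_arm=guide_arm,
            arm5p=lay.arm5p,
            arm3p=lay.arm3p,
            loop_interval=lay.loop_interval,
            anchor=lay.anchor,
            validation=ValidationReport({}),
        )
        report = validate_scaffold(candidate, spec, service)
        if report.passed_subset(required_checks):
            return replace(candidate, validation=report)
        last_err = "; ".join(
            f"{n}: {report.checks[n].message}" for n in required_checks if not report.checks[n].passed
        )

    if "flanks_unstructured" in last_err:
        raise FlankRedesignError(f"{parent.id}: flank redesign failed after {spec.max_attempts} attempts ({last_err})")
    if "chc" in last_err or "debulge" in last_err:
        raise DebulgeError(f"{parent.id}: debulge failed after {spec.max_attempts} attempts ({last_err})")
    raise DesignError(f"{parent.id}: design failed after {spec.max_attempts} attempts ({last_err})")


_BASE_CHECKS = ("basal_GU", "stem_length", "flanks_unstructured", "single_hairpin")
_CHC_CHECKS = ("chc_bulge", "debulged_window")
_LOOP_CHECKS = ("loop_identity", "single_hairpin")


def apply_base_modification(
    p: PriMiRNA,
    spec: ModificationSpec,
    service: FoldingService,
    seed: int = 0,
) -> EngineeredScaffold:
    """Base-of-stem modification: GU at -14/-13, unstructured base, 35-bp stem.

    The hairpin is rebuilt with the parent's duplex and terminal loop and a
    fully paired basal stem whose length is tuned so that the refolded stem
    holds exactly ``stem_len_target`` pairs.  If the parent already
    satisfies the base determinants it is returned unchanged.
    """
    h = fold_pri(p, service)
    _require_parent_flanks(p, spec)
    as_is = _as_scaffold(p, service, spec, ("base",))
    if as_is.validation.passed_subset(_BASE_CHECKS):
        return as_is
    endo_loop = p.sequence[h.loop.start : h.loop.end + 1]
    return _construct(
        p,
        spec,
        service,
        seed,
        applied=("base",),
        core5=p.guide5p,
        core3=p.arm3p_seq,
        loop_seq=endo_loop,
        required_checks=_BASE_CHECKS,
    )


def apply_chc_insertion(
    p: PriMiRNA,
    spec: ModificationSpec,
    service: FoldingService,
    seed: int = 0,
) -> EngineeredScaffold:
    """CHC bulge at offset -6 plus a fully paired 0..-13 window.

    Operates surgically on the parent: the 3'-strand segment pairing the
    debulge window is rewritten as the exact complement of the 5' strand,
    with the single bulged H nucleotide inserted between the C/C context
    opposite ``chc_offset``.
    """
    if spec.chc_bulge_strand != "3p":
        raise ConfigError("only the 3p (passenger-side) CHC bulge strand is implemented")
    h = fold_pri(p, service)
    _require_parent_flanks(p, spec)
    as_is = _as_scaffold(p, service, spec, ("chc",))
    if as_is.validation.passed_subset(_CHC_CHECKS):
        return as_is

    anchor = p.arm5p.start
    lo, hi = spec.debulge_window
    i_lo, i_hi = anchor + lo, anchor + hi
    if i_lo < 0:
        raise DebulgeError(f"{p.id}: insufficient basal context for window {spec.debulge_window}")
    s5 = list(p.sequence[i_lo : i_hi + 1])
    for off in (spec.chc_offset, spec.chc_offset + 1):
        s5[off - lo] = "G"
    js = [h.pairs[i] for i in range(i_lo, i_hi + 1) if h.pairs[i] is not None]
    if not js:
        raise DebulgeError(f"{p.id}: debulge window is entirely unpaired in the parent fold")
    jmin, jmax = min(js), max(js)
    new3 = revcomp("".join(s5))
    hpos = hi - spec.chc_offset  # between partners of chc_offset+1 and chc_offset
    if jmin + hpos <= p.arm3p.end:
        raise DebulgeError(f"{p.id}: CHC bulge would fall inside the 3p arm")
    new3 = new3[:hpos] + spec.chc_bulge_h + new3[hpos:]
    new_seq = p.sequence[:jmin] + new3 + p.sequence[jmax + 1 :]
    chars = list(new_seq)
    for i, c in zip(range(i_lo, i_hi + 1), s5):
        chars[i] = c
    new_seq = "".join(chars)

    new_pri = PriMiRNA(p.id, new_seq, p.arm5p, p.arm3p, p.max_pri_len)
    scaffold = _as_scaffold(new_pri, service, spec, ("chc",))
    if not scaffold.validation.passed_subset(_CHC_CHECKS):
        raise DebulgeError(
            f"{p.id}: debulge failed after refolding "
            f"({'; '.join(scaffold.validation.failures())})"
        )
    return scaffold


def apply_loop_swap(
    p: PriMiRNA,
    spec: ModificationSpec,
    service: FoldingService,
    seed: int = 0,
) -> EngineeredScaffold:
    """Replace the endogenous terminal loop with the configured loop.

    The refolded scaffold must keep a single hairpin whose apex lies in the
    swapped loop region with both arm sequences intact; otherwise a
    :class:`LoopSwapError` is raised.
    """
    h = fold_pri(p, service)
    old_loop = h.loop
    new_loop = spec.loop_sequence
    placed = Interval(old_loop.start, old_loop.start + len(new_loop) - 1)
    if p.sequence[old_loop.start : old_loop.end + 1] == new_loop:
        return _as_scaffold(p, service, spec, ("loop",), loop_interval=placed)
    new_seq = p.sequence[: old_loop.start] + new_loop + p.sequence[old_loop.end + 1 :]
    delta = len(new_loop) - len(old_loop)
    arm3p = p.arm3p.shift(delta) if p.arm3p.start > old_loop.end else p.arm3p
    try:
        new_pri = PriMiRNA(p.id, new_seq, p.arm5p, arm3p, p.max_pri_len)
        scaffold = _as_scaffold(new_pri, service, spec, ("loop",), loop_interval=placed)
    except ScaffoldError as exc:
        raise LoopSwapError(f"{p.id}: loop swap destabilized hairpin ({exc})") from exc
    ok = scaffold.validation.passed_subset(_LOOP_CHECKS)
    arms_intact = (
        scaffold.sequence[p.arm5p.start : p.arm5p.end + 1] == p.guide5p
        and scaffold.sequence[arm3p.start : arm3p.end + 1] == p.arm3p_seq
    )
    if not ok or not arms_intact:
        raise LoopSwapError(
            f"{p.id}: loop swap destabilized hairpin "
            f"({'; '.join(scaffold.validation.failures()) or 'arms disrupted'})"
        )
    return scaffold


def apply_all(
    p: PriMiRNA,
    spec: ModificationSpec,
    service: FoldingService,
    seed: int = 0,
) -> EngineeredScaffold:
    """All modifications combined: base -> CHC -> loop.

    The final scaffold must pass the full determinant report.  Stage
    failures propagate with the stage name in the error message.
    """
    _require_parent_flanks(p, spec)
    as_is = _as_scaffold(p, service, spec, ("base", "chc", "loop"))
    if as_is.validation.passed:
        return as_is
    try:
        scaffold = _construct(
            p,
            spec,
            service,
            seed,
            applied=("base", "chc", "loop"),
            core5=p.guide5p,
            core3=p.arm3p_seq,
            loop_seq=spec.loop_sequence,
            required_checks=CHECK_NAMES,
        )
    except StemRedesignError as exc:
        raise StemRedesignError(f"base stage: {exc}") from exc
    except FlankRedesignError as exc:
        raise FlankRedesignError(f"base stage: {exc}") from exc
    except DebulgeError as exc:
        raise DebulgeError(f"chc stage: {exc}") from exc
    except LoopSwapError as exc:
        raise LoopSwapError(f"loop stage: {exc}") from exc
    if not scaffold.validation.passed:
        raise DesignError(
            f"{p.id}: combined design failed checks: {scaffold.validation.failures()}"
        )
    return scaffold


def embed_duplex(
    s: EngineeredScaffold,
    guide: str,
    passenger: str | None = None,
    guide_arm: str = "5p",
    *,
    spec: ModificationSpec | None = None,
    service: FoldingService | None = None,
    seed: int = 0,
) -> EngineeredScaffold:
    """Graft a guide/passenger duplex into an engineered scaffold.

    The passenger defaults to the full reverse complement of the guide.
    The scaffold is rebuilt with its recorded modification set so that the
    basal complements track the new duplex; re-validation runs on the
    result and a :class:`PostGraftError` lists any determinant the graft
    breaks.
    """
    if spec is None:
        spec = ModificationSpec()
    if service is None:
        from .scaffold_core import ViennaFold

        service = ViennaFold()
    guide = to_rna(guide)
    lo, hi = 18, 25
    if not lo <= len(guide) <= hi:
        raise ConfigError(f"guide length {len(guide)} outside {lo}-{hi} nt")
    if guide_arm not in ("5p", "3p"):
        raise ConfigError("guide_arm must be '5p' or '3p'")
    derived = passenger is None
    passenger = revcomp(guide) if derived else to_rna(passenger)
    if guide == s.guide and passenger == s.passenger and guide_arm == s.guide_arm:
        return s

    core5, core3 = (guide, passenger) if guide_arm == "5p" else (passenger, guide)
    overhang = 0 if derived else 2
    if "base" not in s.applied_mods:
        raise ConfigError("embed_duplex requires a scaffold built with the base modification")
    # Rebuild from the scaffold itself as parent so flank/basal context is reused.
    base_parent = PriMiRNA(s.parent_id, s.sequence, s.arm5p, s.arm3p, spec.max_pri_len)
    loop_seq = (
        spec.loop_sequence
        if "loop" in s.applied_mods
        else s.sequence[s.loop_interval.start : s.loop_interval.end + 1]
    )
    applied = s.applied_mods
    req: tuple[str, ...] = tuple(
        n
        for n in CHECK_NAMES
        if (n in _BASE_CHECKS)
        or (n in _CHC_CHECKS and "chc" in applied)
        or (n == "loop_identity" and "loop" in applied)
    )
    try:
        return _construct(
            base_parent,
            spec,
            service,
            seed,
            applied=applied,
            core5=core5,
            core3=core3,
            loop_seq=loop_seq,
            guide_arm=guide_arm,
            overhang=overhang,
            required_checks=req,
        )
    except DesignError as exc:
        raise PostGraftError(f"post-graft validation failed: {exc}") from exc


@dataclass(frozen=True)
class Candidate:
    id: str
    abundance: float
    motif_start: int  # 0-based index of the CNNC match


def screen_candidates(
    expression_table: Mapping[str, float],
    sequences: Mapping[str, PriMiRNA],
    top_n: int = 15,
    *,
    cnnc_window: tuple[int, int] = (16, 21),
) -> list[Candidate]:
    """Rank pri-miRNAs carrying a downstream CNNC motif by abundance.

    The CNNC motif (C, any, any, C) must start within ``cnnc_window``
    nucleotides downstream of the 3p DROSHA cleavage site (the position
    after the annotated 3p arm).  Ties are broken lexicographically by id.
    """
    if not expression_table:
        raise ScaffoldError("empty expression table")
    w_lo, w_hi = cnnc_window
    hits: list[Candidate] = []
    for name, abundance in expression_table.items():
        if abundance < 0:
            raise ScaffoldError(f"negative abundance for {name}")
        if name not in sequences:
            continue
        p = sequences[name]
        seq = p.sequence
        for d in range(w_lo, w_hi + 1):
            start = p.arm3p.end + d
            if start + 3 >= len(seq):
                break
            if seq[start] == "C" and seq[start + 3] == "C":
                hits.append(Candidate(name, float(abundance), start))
                break
    hits.sort(key=lambda c: (-c.abundance, c.id))
    return hits[:top_n]
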