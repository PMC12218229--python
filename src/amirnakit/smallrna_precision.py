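"""Small-RNA-seq guide/passenger quantification and processing precision.

Each engineered scaffold gets its own pair of reference windows — the
mature guide or passenger strand extended by ``flank_len`` (default 10)
scaffold bases on each side, 42 bases for a canonical 22-nt strand — so
reads from different scaffolds can never cross-map.  Aligned reads are
accepted only if they are full-length matches (a single ``M`` CIGAR run of
18-24 nt, no insertions, deletions or clips) on the sense strand.  Counting
the accepted reads' start and end positions across the window as
percentages yields the processing-precision profile; the percentage of
reads starting exactly at the mature 5' nucleotide is the 5' fidelity.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scaffold_core import Interval, ScaffoldError, to_dna
from .design_engine import EngineeredScaffold

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

FLAG_REVERSE = 0x10
FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class ReferenceWindow:
    """A mature strand with its flanking scaffold context."""

    scaffold_id: str
    strand_role: str  # "guide" or "passenger"
    core: str
    left_flank: str
    right_flank: str

    @property
    def window(self) -> str:
        return self.left_flank + self.core + self.right_flank

    @property
    def id(self) -> str:
        return f"{self.scaffold_id}|{self.strand_role}"

    @property
    def expected_start(self) -> int:
        return len(self.left_flank)

    @property
    def expected_end(self) -> int:
        return len(self.left_flank) + len(self.core) - 1

    @property
    def label(self) -> str:
        """Window with the mature strand uppercase and flanks lowercase."""
        return self.left_flank.lower() + self.core.upper() + self.right_flank.lower()

    def __len__(self) -> int:
        return len(self.window)


def build_reference_windows(
    s: EngineeredScaffold, flank_len: int = 10
) -> dict[str, ReferenceWindow]:
    """Guide and passenger reference windows for one scaffold.

    Each window is the mature strand plus ``flank_len`` scaffold bases on
    each side; the scaffold must provide that much context or an error
    naming the missing side is raised.
    """
    arms = {"5p": s.arm5p, "3p": s.arm3p}
    roles = {
        "guide": arms[s.guide_arm],
        "passenger": arms["3p" if s.guide_arm == "5p" else "5p"],
    }
    out: dict[str, ReferenceWindow] = {}
    for role, arm in roles.items():
        if arm.start < flank_len:
            raise ScaffoldError(
                f"{s.id}/{role}: only {arm.start} nt of scaffold on the 5' side "
                f"(need {flank_len})"
            )
        if len(s.sequence) - 1 - arm.end < flank_len:
            raise ScaffoldError(
                f"{s.id}/{role}: only {len(s.sequence) - 1 - arm.end} nt of scaffold "
                f"on the 3' side (need {flank_len})"
            )
        out[role] = ReferenceWindow(
            scaffold_id=s.id,
            strand_role=role,
            core=s.sequence[arm.start : arm.end + 1],
            left_flank=s.sequence[arm.start - flank_len : arm.start],
            right_flank=s.sequence[arm.end + 1 : arm.end + 1 + flank_len],
        )
    return out


@dataclass(frozen=True)
class ReadRecord:
    """One aligned small-RNA read against a reference window."""

    name: str
    sequence: str
    cigar: str
    start: int  # 0-based position on the window
    flag: int = 0
    window_id: str = ""
    nm: int | None = None


@dataclass(frozen=True)
class Classification:
    accepted: bool
    reason: str | None = None
    match_len: int = 0


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples; '*' yields []."""
    if cigar == "*":
        return []
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return [(int(n), op) for n, op in ops]


def classify_read(
    r: ReadRecord, min_len: int = 18, max_len: int = 24, *, strict: bool = False
) -> Classification:
    """Accept a read only if it is a clean full-length sense match.

    Accepted reads have a CIGAR that is a single match run (e.g. ``22M``)
    of ``min_len``-``max_len`` nucleotides, are mapped, primary, and on the
    forward strand of the window.  Rejections carry a machine-readable
    reason (too_short, too_long, indel, clipped, mismatch, antisense,
    unmapped, secondary, supplementary, multi_segment).  ``strict`` demands
    an exact sequence match (``=`` ops, or an ``M`` run with NM tag 0).
    """
    if r.flag & FLAG_UNMAPPED:
        return Classification(False, "unmapped")
    if r.flag & FLAG_SECONDARY:
        return Classification(False, "secondary")
    if r.flag & FLAG_SUPPLEMENTARY:
        return Classification(False, "supplementary")
    if r.flag & FLAG_REVERSE:
        return Classification(False, "antisense")
    ops = parse_cigar(r.cigar)
    if not ops:
        return Classification(False, "unmapped")
    if any(op in "IDNP" for _, op in ops):
        return Classification(False, "indel")
    if any(op in "SH" for _, op in ops):
        return Classification(False, "clipped")
    if any(op == "X" for _, op in ops):
        return Classification(False, "mismatch")
    if len(ops) != 1:
        return Classification(False, "multi_segment")
    n, op = ops[0]
    if strict and op == "M" and (r.nm is None or r.nm > 0):
        return Classification(False, "mismatch" if r.nm else "unverified_match")
    if n < min_len:
        return Classification(False, "too_short", n)
    if n > max_len:
        return Classification(False, "too_long", n)
    return Classification(True, None, n)


def load_reads_sam(path: str | Path) -> list[ReadRecord]:
    """Read alignments from SAM/BAM into ReadRecords (window = reference)."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            nm = aln.get_tag("NM") if aln.has_tag("NM") else None
            out.append(
                ReadRecord(
                    name=aln.query_name or "",
                    sequence=aln.query_sequence or "",
                    cigar=aln.cigarstring or "*",
                    start=max(aln.reference_start, 0),
                    flag=aln.flag,
                    window_id=aln.reference_name or "",
                    nm=nm,
                )
            )
    return out


@dataclass(frozen=True)
class StrandCounts:
    """Raw and library-size normalized guide/passenger read counts."""

    guide_count: int
    passenger_count: int
    normalized_guide: float
    normalized_passenger: float
    library_size: int

    @property
    def total(self) -> int:
        return self.guide_count + self.passenger_count


def count_strands(
    reads: Iterable[ReadRecord],
    windows: Mapping[str, ReferenceWindow],
    *,
    library_size: int | None = None,
) -> StrandCounts:
    """Partition accepted reads between the guide and passenger windows.

    Normalized values are reads-per-million over ``library_size`` (all
    classified small-RNA reads; defaults to the reads given here).  A read
    assigned to an unknown window raises an error.
    """
    by_id = {w.id: role for role, w in windows.items()}
    counts = {"guide": 0, "passenger": 0}
    n = 0
    for r in reads:
        role = by_id.get(r.window_id)
        if role is None:
            raise ScaffoldError(f"read {r.name!r} assigned to unknown window {r.window_id!r}")
        counts[role] += 1
        n += 1
    lib = library_size if library_size is not None else n
    scale = 1e6 / lib if lib > 0 else 0.0
    return StrandCounts(
        guide_count=counts["guide"],
        passenger_count=counts["passenger"],
        normalized_guide=counts["guide"] * scale,
        normalized_passenger=counts["passenger"] * scale,
        library_size=lib,
    )


@dataclass(frozen=True)
class Ratio:
    """Guide/passenger fold change; infinite when no passenger reads."""

    value: float
    infinite: bool = False


def guide_passenger_ratio(c: StrandCounts) -> Ratio:
    """Fold change of raw guide over passenger counts."""
    if c.guide_count == 0 and c.passenger_count == 0:
        raise ScaffoldError("undefined ratio: no guide or passenger reads")
    if c.passenger_count == 0:
        return Ratio(math.inf, infinite=True)
    return Ratio(c.guide_count / c.passenger_count)


@dataclass(frozen=True)
class PrecisionProfile:
    """Per-position start/end percentages over a reference window."""

    window_id: str
    window_label: str
    start_counts: np.ndarray
    end_counts: np.ndarray
    start_pct: np.ndarray
    end_pct: np.ndarray
    expected_start: int
    expected_end: int
    n_reads: int

    @property
    def five_prime_fidelity(self) -> float:
        """Percent of reads starting exactly at the mature 5' nucleotide."""
        return float(self.start_pct[self.expected_start])

    @property
    def three_prime_fidelity(self) -> float:
        return float(self.end_pct[self.expected_end])

    def to_frame(self) -> pd.DataFrame:
        """Per-position table; positions are printed 1-based on the window."""
        scaffold_id, _, role = self.window_id.rpartition("|")
        n = len(self.start_counts)
        return pd.DataFrame(
            {
                "scaffold": scaffold_id,
                "role": role,
                "position": np.arange(1, n + 1),
                "base": list(self.window_label),
                "start_count": self.start_counts,
                "start_pct": self.start_pct,
                "end_count": self.end_counts,
                "end_pct": self.end_pct,
            }
        )


def precision_profile(
    reads: Sequence[ReadRecord], window: ReferenceWindow
) -> PrecisionProfile:
    """Start/end position profile of accepted reads on one window.

    ``start_pct[i]`` is the percentage of reads whose alignment starts at
    window position i (end analogous); both vectors sum to 100.  Zero
    accepted reads is an error, not a NaN profile.
    """
    n_pos = len(window)
    starts = np.zeros(n_pos, dtype=np.int64)
    ends = np.zeros(n_pos, dtype=np.int64)
    n = 0
    for r in reads:
        if r.window_id and r.window_id != window.id:
            continue
        cls = classify_read(r) if r.cigar else None
        length = cls.match_len if cls and cls.accepted else len(r.sequence)
        end = r.start + length - 1
        if r.start < 0 or end >= n_pos:
            raise ScaffoldError(
                f"read {r.name!r} spans [{r.start}, {end}] outside window {window.id}"
            )
        starts[r.start] += 1
        ends[end] += 1
        n += 1
    if n == 0:
        raise ScaffoldError(f"no accepted reads on window {window.id}")
    return PrecisionProfile(
        window_id=window.id,
        window_label=window.label,
        start_counts=starts,
        end_counts=ends,
        start_pct=100.0 * starts / n,
        end_pct=100.0 * ends / n,
        expected_start=window.expected_start,
        expected_end=window.expected_end,
        n_reads=n,
    )


@dataclass(frozen=True)
class QuantifyResult:
    """Classification ledger plus strand counts for one scaffold."""

    counts: StrandCounts
    n_total: int
    n_accepted: int
    rejected: Mapping[str, int]

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_accepted": self.n_accepted,
            "rejected": dict(self.rejected),
            "guide_count": self.counts.guide_count,
            "passenger_count": self.counts.passenger_count,
            "normalized_guide_rpm": self.counts.normalized_guide,
            "normalized_passenger_rpm": self.counts.normalized_passenger,
        }


def quantify(
    reads: Iterable[ReadRecord],
    windows: Mapping[str, ReferenceWindow],
    min_len: int = 18,
    max_len: int = 24,
    *,
    strict: bool = False,
) -> QuantifyResult:
    """Classify reads, then count guide and passenger strands.

    Conservation holds by construction: accepted + rejected = total.
    """
    accepted: list[ReadRecord] = []
    rejected: dict[str, int] = {}
    n_total = 0
    for r in reads:
        n_total += 1
        cls = classify_read(r, min_len, max_len, strict=strict)
        if cls.accepted:
            accepted.append(r)
        else:
            rejected[cls.reason] = rejected.get(cls.reason, 0) + 1
    counts = count_strands(accepted, windows)
    return QuantifyResult(
        counts=counts, n_total=n_total, n_accepted=len(accepted), rejected=rejected
    )


def accepted_reads(
    reads: Iterable[ReadRecord], min_len: int = 18, max_len: int = 24
) -> list[ReadRecord]:
    return [r for r in reads if classify_read(r, min_len, max_len).accepted]


def write_windows_fasta(
    windows: Mapping[str, ReferenceWindow], path: str | Path, *, alphabet: str = "dna"
) -> None:
    """Windows as FASTA; the mature strand is uppercase, flanks lowercase."""
    with open(path, "w") as fh:
        for role in sorted(windows):
            w = windows[role]
            label = to_dna(w.label.upper()) if alphabet == "dna" else w.label.upper()
            cased = "".join(
                c.lower() if w.label[i].islower() else c for i, c in enumerate(label)
            )
            fh.write(f">{w.id}\n")
            for i in range(0, len(cased), 60):
                fh.write(cased[i : i + 60] + "\n")


def read_windows_fasta(path: str | Path) -> dict[str, ReferenceWindow]:
    """Rebuild reference windows from a case-annotated windows FASTA."""
    out: dict[str, ReferenceWindow] = {}
    name, chunks = None, []
    with open(path) as fh:
        lines = list(fh) + [">"]
    for line in lines:
        line = line.rstrip("\n")
        if line.startswith(">"):
            if name is not None:
                seq = "".join(chunks)
                core = [i for i, c in enumerate(seq) if c.isupper()]
                if not core:
                    raise ScaffoldError(f"window {name!r} has no uppercase core")
                scaffold_id, _, role = name.rpartition("|")
                out[role] = ReferenceWindow(
                    scaffold_id=scaffold_id,
                    strand_role=role,
                    core=seq[core[0] : core[-1] + 1].upper(),
                    left_flank=seq[: core[0]].upper(),
                    right_flank=seq[core[-1] + 1 :].upper(),
                )
            name, chunks = line[1:].split()[0] if len(line) > 1 else None, []
        else:
            chunks.append(line)
    return out
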