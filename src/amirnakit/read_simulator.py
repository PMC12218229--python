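"""Seeded simulator of small-RNA reads from an engineered scaffold.

The simulator emulates the processing statistics of a maturing amiRNA:
reads are exact substrings of the guide or passenger reference window,
drawn with a configurable guide:passenger bias and with 5'/3' cleavage-site
jitter distributions over small offset shifts.  Reads are emitted in the
DNA alphabet (sequencer convention) as FASTQ together with ready-made SAM
alignments against the reference windows, so downstream quantification can
be exercised without an external aligner; a naive exact-match aligner is
bundled to exercise the FASTQ path in tests.

Everything is driven by one seed: the same configuration and seed produce
byte-identical FASTQ/SAM output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .scaffold_core import ScaffoldError, to_dna
from .design_engine import EngineeredScaffold
from .smallrna_precision import ReadRecord, ReferenceWindow, build_reference_windows


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated library.

    ``guide_fraction`` 0.998 corresponds to the ~500:1 guide:passenger
    abundance observed for well-processed scaffolds; jitter distributions
    are probability maps over offset shifts (point mass at 0 = perfectly
    precise processing).  Read lengths are clamped to the 18-24 nt band by
    resampling.
    """

    n_reads: int
    guide_fraction: float = 0.998
    start_jitter: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    end_jitter: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    length_band: tuple[int, int] = (18, 24)
    seed: int = 0
    max_resamples: int = 100

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ScaffoldError("n_reads must be non-negative")
        if not 0.0 <= self.guide_fraction <= 1.0:
            raise ScaffoldError("guide_fraction must be a probability")
        for name, dist in (("start_jitter", self.start_jitter), ("end_jitter", self.end_jitter)):
            if not math.isclose(sum(dist.values()), 1.0, abs_tol=1e-9):
                raise ScaffoldError(f"{name} probabilities must sum to 1")
            if any(p < 0 for p in dist.values()):
                raise ScaffoldError(f"{name} probabilities must be non-negative")


@dataclass(frozen=True)
class SimulatedRead:
    name: str
    window_id: str
    role: str
    start: int
    length: int
    sequence: str  # DNA
    start_shift: int
    end_shift: int


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated library.

    Aggregates are recomputable from the per-read records; they are None
    (flagged undefined) when the denominator is empty.
    """

    reads: tuple[SimulatedRead, ...]
    guide_count: int
    passenger_count: int
    ratio: float | None
    five_prime_fidelity: float | None

    @classmethod
    def from_reads(cls, reads: Sequence[SimulatedRead]) -> "SimTruth":
        g = sum(1 for r in reads if r.role == "guide")
        p = len(reads) - g
        ratio = (g / p) if p else (math.inf if g else None)
        guide_exact = sum(1 for r in reads if r.role == "guide" and r.start_shift == 0)
        fidelity = 100.0 * guide_exact / g if g else None
        return cls(tuple(reads), g, p, ratio, fidelity)


@dataclass(frozen=True)
class SimResult:
    reads: tuple[SimulatedRead, ...]
    truth: SimTruth
    windows: dict[str, ReferenceWindow]

    def to_read_records(self) -> list[ReadRecord]:
        """Aligner-free ingestion of the simulated reads."""
        return [
            ReadRecord(
                name=r.name,
                sequence=r.sequence,
                cigar=f"{r.length}M",
                start=r.start,
                flag=0,
                window_id=r.window_id,
                nm=0,
            )
            for r in self.reads
        ]


def _sample_shift(rng: np.random.Generator, dist: Mapping[int, float]) -> int:
    shifts = sorted(dist)
    probs = np.array([dist[s] for s in shifts], dtype=float)
    return int(rng.choice(shifts, p=probs / probs.sum()))


def simulate(s: EngineeredScaffold, cfg: SimulationConfig, flank_len: int = 10) -> SimResult:
    """Draw a seeded read library from a scaffold's reference windows.

    Every read is an exact substring of its window at the jittered
    coordinates; jitter combinations that push the read outside the length
    band (or the window) are resampled, with a hard cap per read.
    """
    windows = build_reference_windows(s, flank_len)
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_band
    reads: list[SimulatedRead] = []
    for i in range(cfg.n_reads):
        role = "guide" if rng.random() < cfg.guide_fraction else "passenger"
        w = windows[role]
        for _ in range(cfg.max_resamples):
            ds = _sample_shift(rng, cfg.start_jitter)
            de = _sample_shift(rng, cfg.end_jitter)
            start = w.expected_start + ds
            end = w.expected_end + de
            length = end - start + 1
            if lo <= length <= hi and start >= 0 and end < len(w):
                break
        else:
            raise ScaffoldError(
                f"jitter kept read {i} outside the length band after "
                f"{cfg.max_resamples} resamples"
            )
        reads.append(
            SimulatedRead(
                name=f"sim_{s.parent_id}_{i:06d}",
                window_id=w.id,
                role=role,
                start=start,
                length=length,
                sequence=to_dna(w.window[start : end + 1]),
                start_shift=ds,
                end_shift=de,
            )
        )
    return SimResult(tuple(reads), SimTruth.from_reads(reads), windows)


# ---------------------------------------------------------------------------
# Writers (deterministic text output) and the naive test aligner
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    """4-line FASTQ records with constant high base quality."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{'I' * r.length}\n")


def write_sam(
    reads: Sequence[SimulatedRead], windows: Mapping[str, ReferenceWindow], path: str | Path
) -> None:
    """SAM with @SQ headers naming each window; pure-match CIGARs."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for role in sorted(windows):
            w = windows[role]
            fh.write(f"@SQ\tSN:{w.id}\tLN:{len(w)}\n")
        for r in reads:
            fh.write(
                "\t".join(
                    [
                        r.name,
                        "0",
                        r.window_id,
                        str(r.start + 1),
                        "60",
                        f"{r.length}M",
                        "*",
                        "0",
                        "0",
                        r.sequence,
                        "I" * r.length,
                        "NM:i:0",
                    ]
                )
                + "\n"
            )


def write_truth(truth: SimTruth, tsv_path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "name": [r.name for r in truth.reads],
            "window": [r.window_id for r in truth.reads],
            "role": [r.role for r in truth.reads],
            "start_shift": [r.start_shift for r in truth.reads],
            "end_shift": [r.end_shift for r in truth.reads],
        }
    ).to_csv(tsv_path, sep="\t", index=False)


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    for i in range(0, len(lines) - 3, 4):
        out.append((lines[i][1:], lines[i + 1]))
    return out


def naive_exact_align(
    reads: Sequence[tuple[str, str]], windows: Mapping[str, ReferenceWindow]
) -> list[ReadRecord]:
    """Exact-substring alignment of raw reads against the windows.

    Test-only stand-in for a real aligner: each read is matched
    case-insensitively with U/T equivalence; when a read occurs in more
    than one window the lexicographically smallest window id wins (ties are
    possible only if guide and passenger windows share a substring).
    Unmatched reads are emitted as unmapped records.
    """
    refs = {w.id: to_dna(w.window).upper() for w in windows.values()}
    out = []
    for name, seq in reads:
        query = to_dna(seq.upper().replace("U", "T"))
        hits = []
        for wid in sorted(refs):
            pos = refs[wid].find(query)
            if pos >= 0:
                hits.append((wid, pos))
        if hits:
            wid, pos = hits[0]
            out.append(
                ReadRecord(
                    name=name,
                    sequence=query,
                    cigar=f"{len(query)}M",
                    start=pos,
                    flag=0,
                    window_id=wid,
                    nm=0,
                )
            )
        else:
            out.append(
                ReadRecord(name=name, sequence=query, cigar="*", start=0, flag=0x4)
            )
    return out
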