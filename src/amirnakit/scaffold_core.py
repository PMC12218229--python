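"""Domain types and secondary-structure plumbing for pri-miRNA hairpins.

Coordinate system
-----------------
All internal indices are 0-based on the full sequence.  A signed *offset*
overlay places offset 0 at the 5'-most nucleotide of the annotated 5p mature
arm, which is the putative DROSHA 5' cleavage site.  Negative offsets run
5'-ward into the basal stem and flank; positions on the 3' arm are addressed
through their pairing partners.  All processing determinants handled by the
design engine (basal GU at -14/-13, CHC bulge at -6, the 0..-13 debulged
window) are expressed in these offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: canonical pairs accepted in a debulged stem (Watson-Crick and GU wobble)
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

DEFAULT_MAX_PRI_LEN = 200
MATURE_LEN_RANGE = (18, 25)


class ScaffoldError(ValueError):
    """Base class for domain errors raised by this package."""


class AlphabetError(ScaffoldError):
    """Sequence contains characters outside the RNA alphabet."""


class NotAHairpinError(ScaffoldError):
    """The folded structure is not a single hairpin in the arm region."""


def to_rna(sequence: str) -> str:
    """Normalize a nucleotide string to the uppercase RNA alphabet.

    DNA input (``T``) is accepted and converted to ``U`` with a logged
    warning; any other character raises :class:`AlphabetError`.
    """
    seq = sequence.strip().upper()
    if "T" in seq:
        logger.warning("DNA input detected; converting T -> U")
        seq = seq.replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise AlphabetError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def to_dna(sequence: str) -> str:
    return sequence.upper().replace("U", "T")


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def revcomp(sequence: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(sequence))


@dataclass(frozen=True, order=True)
class Interval:
    """Closed interval [start, end] of 0-based positions."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ScaffoldError(f"invalid interval [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, i: int) -> bool:
        return self.start <= i <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def shift(self, delta: int) -> "Interval":
        return Interval(self.start + delta, self.end + delta)


@dataclass(frozen=True)
class PriMiRNA:
    """An annotated pri-miRNA: sequence plus mature 5p/3p arm intervals.

    The sequence is held in the RNA alphabet.  Arms must be 18-25 nt, lie
    within the sequence, and the 5p arm must end before the 3p arm starts.
    """

    id: str
    sequence: str
    arm5p: Interval
    arm3p: Interval
    max_pri_len: int = DEFAULT_MAX_PRI_LEN

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", to_rna(self.sequence))
        n = len(self.sequence)
        if n == 0:
            raise ScaffoldError("empty sequence")
        if n > self.max_pri_len:
            raise ScaffoldError(
                f"{self.id}: sequence length {n} exceeds max_pri_len {self.max_pri_len}"
            )
        for name, arm in (("arm5p", self.arm5p), ("arm3p", self.arm3p)):
            if arm.end >= n:
                raise ScaffoldError(f"{self.id}: {name} outside sequence")
            lo, hi = MATURE_LEN_RANGE
            if not lo <= len(arm) <= hi:
                raise ScaffoldError(
                    f"{self.id}: {name} length {len(arm)} outside {lo}-{hi} nt"
                )
        if self.arm5p.end >= self.arm3p.start:
            raise ScaffoldError(f"{self.id}: arm5p must end before arm3p starts")

    @property
    def guide5p(self) -> str:
        return self.sequence[self.arm5p.start : self.arm5p.end + 1]

    @property
    def arm3p_seq(self) -> str:
        return self.sequence[self.arm3p.start : self.arm3p.end + 1]


class FoldingService(Protocol):
    """Deterministic sequence -> minimum-free-energy dot-bracket structure."""

    def fold(self, sequence: str) -> str:  # pragma: no cover - protocol
        ...


class ViennaFold:
    """MFE folding backed by the ViennaRNA bindings.

    Results are memoized; ViennaRNA's MFE fold is deterministic, so repeated
    calls return byte-identical structures.
    """

    def __init__(self) -> None:
        self._cache: dict[str, str] = {}

    def fold(self, sequence: str) -> str:
        try:
            return self._cache[sequence]
        except KeyError:
            import RNA

            structure, _energy = RNA.fold(sequence)
            self._cache[sequence] = structure
            return structure


def pair_table(structure: str) -> tuple[int | None, ...]:
    """Map each position to its partner (or None) from dot-bracket notation.

    The result is an involution: ``pt[pt[i]] == i`` for every paired i.
    """
    pt: list[int | None] = [None] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ScaffoldError("unbalanced brackets in structure")
            j = stack.pop()
            pt[i] = j
            pt[j] = i
        elif c != ".":
            raise ScaffoldError(f"unexpected structure character {c!r}")
    if stack:
        raise ScaffoldError("unbalanced brackets in structure")
    return tuple(pt)


def terminal_loops(pt: Iterable[int | None]) -> list[Interval]:
    """Hairpin loops: unpaired stretches directly closed by a pair."""
    pt = tuple(pt)
    loops = []
    for i, j in enumerate(pt):
        if j is not None and j > i:
            if all(pt[k] is None for k in range(i + 1, j)):
                loops.append(Interval(i + 1, j - 1))
    return loops


@dataclass(frozen=True)
class HairpinOffsets:
    """Bidirectional map between absolute indices and DROSHA-anchored offsets."""

    anchor: int

    def offset(self, index: int) -> int:
        return index - self.anchor

    def index(self, offset: int) -> int:
        return self.anchor + offset


@dataclass(frozen=True)
class FoldedHairpin:
    """A folded sequence with its MFE structure and hairpin bookkeeping.

    ``loop`` is the single terminal loop between the annotated arms;
    ``anchor`` is the absolute index of offset 0 (the arm5p start).
    """

    sequence: str
    structure: str
    pairs: tuple[int | None, ...]
    loop: Interval
    anchor: int

    @property
    def offsets(self) -> HairpinOffsets:
        return HairpinOffsets(self.anchor)

    def partner(self, index: int) -> int | None:
        return self.pairs[index]

    def partner_at_offset(self, offset: int) -> int | None:
        return self.pairs[self.anchor + offset]

    def base_at_offset(self, offset: int) -> str:
        return self.sequence[self.anchor + offset]


def fold(
    sequence: str,
    service: FoldingService,
    *,
    arm5p: Interval | None = None,
    arm3p: Interval | None = None,
) -> FoldedHairpin:
    """Fold a sequence and validate single-hairpin topology.

    When arm annotations are given, exactly one terminal loop must lie
    between them (positions arm5p.start .. arm3p.end); side structures in
    the flanks are tolerated here and policed by the flank checks of the
    design engine.  Without annotations the whole sequence must fold into
    exactly one hairpin.
    """
    seq = to_rna(sequence)
    structure = service.fold(seq)
    if len(structure) != len(seq):
        raise ScaffoldError("folding service returned structure of wrong length")
    pt = pair_table(structure)
    loops = terminal_loops(pt)
    if arm5p is not None and arm3p is not None:
        region = Interval(arm5p.start, arm3p.end)
        in_region = [lp for lp in loops if lp.overlaps(region)]
        anchor = arm5p.start
    else:
        in_region = loops
        anchor = 0
    if len(in_region) == 0:
        raise NotAHairpinError("no terminal loop found in the hairpin region")
    if len(in_region) > 1:
        raise NotAHairpinError(
            f"branched structure: {len(in_region)} terminal loops in the hairpin region"
        )
    return FoldedHairpin(
        sequence=seq, structure=structure, pairs=pt, loop=in_region[0], anchor=anchor
    )


def fold_pri(p: PriMiRNA, service: FoldingService) -> FoldedHairpin:
    """Fold an annotated pri-miRNA, anchoring offset 0 at the arm5p start."""
    return fold(p.sequence, service, arm5p=p.arm5p, arm3p=p.arm3p)


@dataclass(frozen=True)
class StemReport:
    """Base pairs of a hairpin stem, basal junction first.

    ``pairs`` lists the pairs enclosing the reference loop from the basal
    junction to the loop-proximal pair; ``bulges`` lists unpaired positions
    lying between the outermost and innermost stem pairs on either strand.
    """

    pairs: tuple[tuple[int, int], ...]
    bulges: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.pairs)


def stem_pairs(h: FoldedHairpin, loop: Interval | None = None) -> StemReport:
    """Stem of a folded hairpin: all pairs enclosing the (given) loop.

    By default the structure's own terminal loop is used; the design engine
    passes the designated loop interval of an engineered scaffold so that
    pairs formed *inside* a partially self-paired loop region are not
    mistaken for stem pairs.
    """
    ref = loop if loop is not None else h.loop
    enclosing = [
        (i, j)
        for i, j in enumerate(h.pairs)
        if j is not None and j > i and i < ref.start and j > ref.end
    ]
    enclosing.sort()  # ascending i = basal junction -> loop-proximal
    if not enclosing:
        return StemReport(pairs=(), bulges=())
    (i_out, j_out), (i_in, j_in) = enclosing[0], enclosing[-1]
    stem_positions = {k for ij in enclosing for k in ij}
    bulges = tuple(
        k
        for k in list(range(i_out, i_in + 1)) + list(range(j_in, j_out + 1))
        if k not in stem_positions and h.pairs[k] is None
    )
    return StemReport(pairs=tuple(enclosing), bulges=bulges)


# ---------------------------------------------------------------------------
# File formats: FASTA (wrapped at 60 columns), arm-annotation TSV, Vienna
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path, *, alphabet: str = "rna") -> None:
    """Write sequences as FASTA wrapped at 60 columns (``alphabet``: rna|dna)."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            seq = to_dna(seq) if alphabet == "dna" else to_rna(seq)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_vienna(name: str, sequence: str, structure: str, path: str | Path) -> None:
    """Emit sequence + dot-bracket in Vienna format."""
    with open(path, "w") as fh:
        fh.write(f">{name}\n{sequence}\n{structure}\n")


def read_arm_annotations(path: str | Path) -> dict[str, tuple[Interval, Interval]]:
    """Read the arm-annotation TSV.

    Columns: id, arm5p_start, arm5p_end, arm3p_start, arm3p_end with 1-based
    closed intervals in the file; converted to 0-based internally.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["id", "arm5p_start", "arm5p_end", "arm3p_start", "arm3p_end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScaffoldError(f"annotation TSV missing columns: {missing}")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.id)] = (
            Interval(int(row.arm5p_start) - 1, int(row.arm5p_end) - 1),
            Interval(int(row.arm3p_start) - 1, int(row.arm3p_end) - 1),
        )
    return out


def load_pri_mirnas(
    fasta_path: str | Path, annot_path: str | Path, max_pri_len: int = DEFAULT_MAX_PRI_LEN
) -> dict[str, PriMiRNA]:
    """Join a FASTA file with its arm-annotation TSV into PriMiRNA objects."""
    seqs = read_fasta(fasta_path)
    arms = read_arm_annotations(annot_path)
    out = {}
    for name, seq in seqs.items():
        if name not in arms:
            raise ScaffoldError(f"no arm annotation for sequence {name!r}")
        a5, a3 = arms[name]
        out[name] = PriMiRNA(name, seq, a5, a3, max_pri_len=max_pri_len)
    return out
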