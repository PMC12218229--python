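"""Bundled sequence fixtures.

The two pri-miRNA parents carry the miRBase stem-loop sequences of
hsa-let-7a-1 (MI0000060) and hsa-mir-26b (MI0000084).  Because the design
engine needs flanking sequence below the basal stem, each stem-loop is
padded with 25 nt of synthetic, low-structure (A/C-only) sequence on both
sides; the pads are synthetic and stand in for the genomic pri context.

``SCREENING_GUIDE`` is a synthetic 22-nt guide standing in for the
reporter-targeting guide used in the screening assays (whose sequence is
not public); any 18-25 nt guide can be used in its place.

``MIR30A_LOOP`` is the loop region of the hsa-mir-30a precursor between its
annotated mature arms.  It is an editable default, not asserted ground
truth: the exact loop boundaries used for engineered scaffolds vary in the
literature.
"""

from __future__ import annotations

from importlib import resources

from .scaffold_core import PriMiRNA, load_pri_mirnas

#: loop region of hsa-mir-30a between the annotated 5p and 3p arms
MIR30A_LOOP = "CUGUGAAGCCACAGAUGGG"

#: synthetic 22-nt screening guide (see module docstring)
SCREENING_GUIDE = "UUAGUCGAGGAUCAUGCUUACC"


def _data_path(name: str):
    return resources.files("amirnakit.data").joinpath(name)


def load_fixture_pris() -> dict[str, PriMiRNA]:
    """All bundled pri-miRNA fixtures, keyed by id."""
    with resources.as_file(_data_path("fixtures.fasta")) as fa, resources.as_file(
        _data_path("fixtures_arms.tsv")
    ) as tsv:
        return load_pri_mirnas(fa, tsv)


def pri_let7a1() -> PriMiRNA:
    return load_fixture_pris()["pri-let-7a-1"]


def pri_mir26b() -> PriMiRNA:
    return load_fixture_pris()["pri-mir-26b"]
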