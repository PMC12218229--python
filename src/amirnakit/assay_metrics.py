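"""Closed-form calculators for the non-sequencing assay readouts.

Reporter knockdown: residual fluorescent-reporter expression is the ratio
of the mCherry X-median in transduced (GFP+) cells over non-transduced
(GFP-) cells of the same sample, so 1.0 means no silencing and 0.3 means
70% knockdown.

Vector genome integrity: two-dimensional droplet digital PCR probes both
ends of the cassette (CMV enhancer, hGH polyA); the percent of droplets
positive for both probes in the same droplet estimates the fraction of
intact genomes.  Whether the denominator should include probe-negative
droplets is ambiguous, so both modes are provided (default: positives
only) and the choice is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

from .scaffold_core import ScaffoldError


@dataclass(frozen=True)
class ReporterMeasurement:
    """Flow-cytometry mCherry X-medians for one sample."""

    sample_id: str
    mcherry_median_gfp_pos: float
    mcherry_median_gfp_neg: float

    def __post_init__(self) -> None:
        if self.mcherry_median_gfp_pos < 0 or self.mcherry_median_gfp_neg < 0:
            raise ScaffoldError(f"{self.sample_id}: medians must be non-negative")


@dataclass(frozen=True)
class ResidualExpression:
    sample_id: str
    ratio: float
    knockdown_pct: float


def residual_expression(m: ReporterMeasurement) -> ResidualExpression:
    """Residual reporter expression = median(GFP+) / median(GFP-).

    Also reports knockdown% = 100 * (1 - ratio).  The GFP- denominator must
    be positive.
    """
    if m.mcherry_median_gfp_neg <= 0:
        raise ScaffoldError(f"{m.sample_id}: GFP- median must be > 0")
    ratio = m.mcherry_median_gfp_pos / m.mcherry_median_gfp_neg
    return ResidualExpression(m.sample_id, ratio, 100.0 * (1.0 - ratio))


@dataclass(frozen=True)
class DropletCounts:
    """2D-ddPCR droplet partition for one rAAV sample."""

    double_positive: int
    cmv_only: int
    polya_only: int
    negative: int

    def __post_init__(self) -> None:
        for name in ("double_positive", "cmv_only", "polya_only", "negative"):
            if getattr(self, name) < 0:
                raise ScaffoldError(f"{name} must be non-negative")


@dataclass(frozen=True)
class IntactGenomeResult:
    percent: float
    denominator: str  # "positives" or "all"


def intact_genome_percent(
    d: DropletCounts, denominator: str = "positives"
) -> IntactGenomeResult:
    """Percent of droplets PCR-positive for both cassette ends.

    ``denominator="positives"`` divides by all probe-positive droplets
    (double + single positives); ``"all"`` additionally includes negative
    droplets.  No Poisson copies-per-droplet correction is applied: this is
    a droplet-fraction calculation.
    """
    if denominator not in ("positives", "all"):
        raise ScaffoldError("denominator must be 'positives' or 'all'")
    positives = d.double_positive + d.cmv_only + d.polya_only
    if positives == 0:
        raise ScaffoldError("no probe-positive droplets: intact% undefined")
    denom = positives + (d.negative if denominator == "all" else 0)
    return IntactGenomeResult(100.0 * d.double_positive / denom, denominator)
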