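"""Pooled allele-frequency estimation and false-positive variant filtering.

The pooled estimator is the fraction of reads carrying the variant among
all reads spanning a locus, with a 1% detection threshold.  Clonal
variant calls use a dual-sample rule: a site is called when the evolved
sample shows the variant in at least 35% of reads with adequate base
qualities (>= 40 central, >= 30 flanking), and is discarded as a false
positive when the matched wild-type control also shows it in 10% or more
of reads.  All thresholds are inclusive (>=) and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = [
    "CallerConfig",
    "AmpliconCounts",
    "FrequencyRecord",
    "VariantCall",
    "allele_frequency",
    "fp_filter_call",
    "call_zygosity",
    "call_frequency_table",
]


@dataclass(frozen=True)
class CallerConfig:
    detection_threshold: float = 0.01
    evolved_min_fraction: float = 0.35
    control_max_fraction: float = 0.10
    qual_central_min: float = 40.0
    qual_flank_min: float = 30.0
    control_min_coverage: int = 5
    homozygous_min_fraction: float = 0.90
    het_min_fraction: float = 0.35

    def __post_init__(self) -> None:
        if not (0 < self.detection_threshold < self.control_max_fraction
                < self.evolved_min_fraction <= self.homozygous_min_fraction <= 1):
            raise ValueError(
                "thresholds must satisfy 0 < detection < control_max < "
                "evolved_min <= homozygous_min <= 1"
            )
        if not 0 < self.het_min_fraction <= self.homozygous_min_fraction:
            raise ValueError("het_min_fraction must lie in (0, homozygous_min_fraction]")
        if self.qual_central_min < 0 or self.qual_flank_min < 0:
            raise ValueError("quality thresholds must be >= 0")
        if self.control_min_coverage < 0:
            raise ValueError("control_min_coverage must be >= 0")


@dataclass(frozen=True)
class AmpliconCounts:
    """Read counts for one locus in one sample."""

    locus_id: str
    sample_label: str
    total_reads: int
    alt_reads: int
    qual_central: float = 45.0
    qual_flank_min: float = 36.0

    def __post_init__(self) -> None:
        if not 0 <= self.alt_reads <= self.total_reads:
            raise ValueError(
                f"{self.locus_id}: need 0 <= alt_reads <= total_reads, "
                f"got {self.alt_reads}/{self.total_reads}"
            )
        if self.qual_central < 0 or self.qual_flank_min < 0:
            raise ValueError(f"{self.locus_id}: quality scores must be >= 0")


@dataclass(frozen=True)
class FrequencyRecord:
    locus_id: str
    sample_label: str
    frequency: float
    detected: bool


@dataclass(frozen=True)
class VariantCall:
    locus_id: str
    status: str  # "called" | "discarded_fp" | "not_called"
    evolved_fraction: float
    control_fraction: Optional[float]  # None when the control is uninformative
    zygosity: str  # "het" | "homo" | "ambiguous" | "none"
    control_informative: bool = True


def allele_frequency(counts: AmpliconCounts,
                     config: CallerConfig = CallerConfig()) -> FrequencyRecord:
    """Variant read fraction at a locus, with the detection flag.

    The frequency is alt_reads / total_reads; a locus is detected when
    the fraction reaches the (inclusive) detection threshold.
    """
    if counts.total_reads == 0:
        raise ValueError(f"{counts.locus_id}: no coverage (total_reads = 0)")
    freq = counts.alt_reads / counts.total_reads
    return FrequencyRecord(
        locus_id=counts.locus_id,
        sample_label=counts.sample_label,
        frequency=float(freq),
        detected=bool(freq >= config.detection_threshold),
    )


def call_zygosity(frequency: float, config: CallerConfig = CallerConfig()) -> str:
    """Zygosity of a clonal diploid from its variant read fraction.

    homo above homozygous_min_fraction, het in [het_min, homo_min), none
    below the detection threshold, ambiguous in between.
    """
    if frequency >= config.homozygous_min_fraction:
        return "homo"
    if frequency >= config.het_min_fraction:
        return "het"
    if frequency < config.detection_threshold:
        return "none"
    return "ambiguous"


def fp_filter_call(
    evolved: AmpliconCounts,
    control: AmpliconCounts,
    config: CallerConfig = CallerConfig(),
) -> VariantCall:
    """Dual-sample variant call with false-positive rejection.

    called: evolved fraction >= evolved_min AND base qualities pass AND
    the control fraction is below control_max.  discarded_fp: the evolved
    evidence passes but the control also shows the variant at or above
    control_max — the hallmark of a systematic miscall.  Controls with
    fewer than control_min_coverage reads are uninformative: the call is
    made on evolved evidence alone and flagged.
    """
    if evolved.total_reads == 0:
        raise ValueError(f"{evolved.locus_id}: evolved sample has no coverage")
    ev_frac = evolved.alt_reads / evolved.total_reads
    informative = control.total_reads >= config.control_min_coverage and control.total_reads > 0
    ctrl_frac = control.alt_reads / control.total_reads if informative else None

    evidence = (
        ev_frac >= config.evolved_min_fraction
        and evolved.qual_central >= config.qual_central_min
        and evolved.qual_flank_min >= config.qual_flank_min
    )
    if not evidence:
        status = "not_called"
    elif informative and ctrl_frac >= config.control_max_fraction:
        status = "discarded_fp"
    else:
        status = "called"
    zygosity = call_zygosity(ev_frac, config) if status == "called" else "none"
    return VariantCall(
        locus_id=evolved.locus_id,
        status=status,
        evolved_fraction=ev_frac,
        control_fraction=ctrl_frac,
        zygosity=zygosity,
        control_informative=informative,
    )


def call_frequency_table(counts: pd.DataFrame,
                         config: CallerConfig = CallerConfig()) -> pd.DataFrame:
    """Vector version of :func:`allele_frequency` over a counts table.

    ``counts`` needs columns sample, locus_id, total_reads, alt_reads.
    """
    if (counts["total_reads"] <= 0).any():
        bad = counts.loc[counts["total_reads"] <= 0, "locus_id"].tolist()
        raise ValueError(f"zero coverage at loci {bad}")
    out = counts[["sample", "locus_id"]].copy()
    out["frequency"] = counts["alt_reads"] / counts["total_reads"]
    out["detected"] = out["frequency"] >= config.detection_threshold
    return out
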