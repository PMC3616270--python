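"""Published behavioral summary statistics of larval crawling, as fixtures.

The package carries the pooled summary statistics measured from freely
crawling first-instar larvae (segment-boundary contraction timing) as a
small read-only table: normalized contraction duration, intersegmental
phase lag, absolute wave duration and duty cycle for forward waves at
25°C, plus the wave/animal counts of the 34°C forward and backward
recordings (whose per-quantity means were published only graphically and
are therefore carried as count-only entries).  Model runs are compared
against these pooled references in units of the reference SD.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:
    from .wave_metrics import WaveMetrics

__all__ = [
    "BehavioralSummary",
    "behavioral_summaries",
    "get_reference",
    "compare_to_reference",
    "fixture_sha256",
]

_FIXTURE = "behavioral_reference.csv"

#: Checksum pinning the packaged fixture; edits to the table break it.
FIXTURE_SHA256 = "fdd62d465f87d91be564139c86cd534c052d654605e44a712515023fa71dabf2"


@dataclass(frozen=True)
class BehavioralSummary:
    """One pooled behavioral statistic (mean ± SD over recorded waves)."""

    quantity: str
    condition: str
    mean: float | None
    sd: float | None
    n_waves: int
    n_animals: int

    def __post_init__(self) -> None:
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_waves <= 0 or self.n_animals <= 0:
            raise ValueError("counts must be positive")


def _fixture_bytes() -> bytes:
    return resources.files("larvacpg.data").joinpath(_FIXTURE).read_bytes()


def fixture_sha256() -> str:
    return hashlib.sha256(_fixture_bytes()).hexdigest()


def behavioral_summaries() -> tuple[BehavioralSummary, ...]:
    """All packaged behavioral summaries, immutable."""
    import io

    df = pd.read_csv(io.BytesIO(_fixture_bytes()))
    out = []
    for row in df.itertuples(index=False):
        mean = None if pd.isna(row.mean) else float(row.mean)
        sd = None if pd.isna(row.sd) else float(row.sd)
        out.append(
            BehavioralSummary(
                row.quantity, row.condition, mean, sd, int(row.n_waves), int(row.n_animals)
            )
        )
    return tuple(out)


def get_reference(quantity: str, condition: str = "forward_25C") -> BehavioralSummary:
    for s in behavioral_summaries():
        if s.quantity == quantity and s.condition == condition:
            return s
    raise KeyError(f"no reference for ({quantity}, {condition})")


@dataclass(frozen=True)
class DeviationReport:
    quantity: str
    model_mean: float
    reference_mean: float
    reference_sd: float
    standardized_deviation: float
    within_one_sd: bool


def compare_to_reference(metrics: "WaveMetrics", reference: BehavioralSummary) -> DeviationReport:
    """Standardized deviation of a model wave statistic from a reference.

    Supported quantities: normalized_contraction_duration (model mean
    across segments) and intersegmental_phase_lag (model mean across
    pairs).  Deviation = (model − reference mean) / reference SD.
    """
    if reference.mean is None or reference.sd is None:
        raise ValueError(f"reference ({reference.quantity}, {reference.condition}) is count-only")
    if reference.quantity == "normalized_contraction_duration":
        model_mean = metrics.mean_normalized_duration
    elif reference.quantity == "intersegmental_phase_lag":
        model_mean = metrics.mean_phase_lag
    else:
        raise ValueError(f"cannot compare model waves to quantity {reference.quantity!r}")
    dev = (model_mean - reference.mean) / reference.sd
    within = abs(dev) <= 1.0 + 1e-9  # roundoff guard at the 1-SD boundary
    return DeviationReport(
        reference.quantity, model_mean, reference.mean, reference.sd, dev, within
    )
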