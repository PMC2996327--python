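"""Ofm-index computation and strain classification.

The Ofm (originless fragment maintenance) index quantifies how specifically a
mutation destabilizes an origin-depleted chromosome derivative.  With loss
rates expressed as events per 10^5 divisions,

    index = (rate_5ORIΔ-ΔR_mutant − rate_5ORIΔ-ΔR_baseline)
          / (rate_0ORIΔ-ΔR_mutant − rate_0ORIΔ-ΔR_baseline)

i.e. the additional loss events suffered by the derivative with a long
inter-origin gap, per additional loss event suffered by the derivative with a
full origin complement.  An index near 1 indicates general chromosome
instability (e.g. a kinetochore defect); a large index indicates a specific
defect in maintaining the gapped derivative.

The index is scale-invariant, so raw per-division rates and ×10⁻⁵ display
units give identical values.  It is undefined when the denominator is zero or
negative (never ±inf), and a negative numerator with a positive denominator is
returned as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CONSTRUCT_5ORI_DR",
    "CONSTRUCT_0ORI_DR",
    "CONSTRUCT_5ORI_FULL",
    "CONSTRUCT_DL_6ORI",
    "StrainLossProfile",
    "OfmResult",
    "ofm_index",
    "ofm_index_sd",
    "round_half_away",
    "score_profile",
]

CONSTRUCT_5ORI_DR = "5ORIΔ-ΔR"
CONSTRUCT_0ORI_DR = "0ORIΔ-ΔR"
CONSTRUCT_5ORI_FULL = "5ORIΔ"
CONSTRUCT_DL_6ORI = "ΔL-6ORIΔ"

KNOWN_CONSTRUCTS = (
    CONSTRUCT_5ORI_DR,
    CONSTRUCT_0ORI_DR,
    CONSTRUCT_5ORI_FULL,
    CONSTRUCT_DL_6ORI,
)


@dataclass(frozen=True)
class StrainLossProfile:
    """Loss rates (×10⁻⁵ per division) of one strain across constructs.

    ``rates`` maps construct name to ``(rate_e5, sd_e5)``; ``sd_e5`` may be
    None when the table reports no uncertainty.  Constructs absent from the
    table ("ND") are simply missing keys.
    """

    strain: str
    rates: dict[str, tuple[float, Optional[float]]]

    def __post_init__(self) -> None:
        if not self.rates:
            raise ValueError(f"profile for {self.strain!r} has no construct rates")
        for construct, (rate, sd) in self.rates.items():
            if rate < 0:
                raise ValueError(f"{self.strain!r}/{construct!r}: negative rate")
            if sd is not None and sd < 0:
                raise ValueError(f"{self.strain!r}/{construct!r}: negative SD")

    def rate(self, construct: str) -> float:
        try:
            return self.rates[construct][0]
        except KeyError:
            raise KeyError(
                f"strain {self.strain!r} has no rate for construct {construct!r}"
            ) from None

    def sd(self, construct: str) -> Optional[float]:
        return self.rates[construct][1]


@dataclass(frozen=True)
class OfmResult:
    """Ofm index of one strain against a named baseline, with classification."""

    strain: str
    baseline: str
    index: Optional[float]
    index_sd: Optional[float]
    rounded_index: Optional[int]
    call: str  # "Ofm" | "non-Ofm" | "indeterminate"


def ofm_index(mut5: float, base5: float, mut0: float, base0: float) -> Optional[float]:
    """Ratio of additional loss events; ``None`` when the denominator is <= 0.

    All four rates must be non-negative and in common units.
    """
    for v in (mut5, base5, mut0, base0):
        if v < 0:
            raise ValueError("loss rates must be non-negative")
    denom = mut0 - base0
    if denom <= 0:
        return None
    return (mut5 - base5) / denom


def ofm_index_sd(
    mut5: float,
    sd5: float,
    base5: float,
    sdb5: float,
    mut0: float,
    sd0: float,
    base0: float,
    sdb0: float,
) -> float:
    """First-order delta-method SD of the ratio of differences.

    Assumes the four rate errors are independent.  For index
    ``R = A/B`` with ``A = mut5-base5`` and ``B = mut0-base0``:
    ``var(R) = var(A)/B² + A²·var(B)/B⁴``.
    """
    for s in (sd5, sdb5, sd0, sdb0):
        if s < 0:
            raise ValueError("SDs must be non-negative")
    index = ofm_index(mut5, base5, mut0, base0)
    if index is None:
        raise ValueError("Ofm index is undefined for these rates; SD unavailable")
    num = mut5 - base5
    denom = mut0 - base0
    var = (sd5**2 + sdb5**2) / denom**2 + num**2 * (sd0**2 + sdb0**2) / denom**4
    return math.sqrt(var)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (so −3.33 → −3, 18.6 → 19)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def score_profile(
    profile: StrainLossProfile,
    baseline_profile: StrainLossProfile,
    ofm_threshold: float = 20.0,
    non_ofm_threshold: float = 10.0,
    destabilization_fold: float = 2.0,
) -> OfmResult:
    """Compute the Ofm index of ``profile`` against ``baseline_profile``.

    The baseline strain supplies *both* reference rates (numerator and
    denominator): this is the convention that reproduces all alternate-baseline
    values printed for the mec1Δ/rad53Δ/triple-mutant rows of the packaged
    loss-rate table.

    Classification policy (configurable):

    - ``Ofm``: index defined, ≥ ``ofm_threshold``, and the gapped derivative is
      destabilized at least ``destabilization_fold``-fold over baseline;
    - ``non-Ofm``: index defined and < ``non_ofm_threshold``;
    - ``indeterminate`` otherwise (including an undefined index or scoring a
      strain against itself).
    """
    for construct in (CONSTRUCT_5ORI_DR, CONSTRUCT_0ORI_DR):
        for p in (profile, baseline_profile):
            if construct not in p.rates:
                raise KeyError(
                    f"strain {p.strain!r} is missing a rate for construct {construct!r}"
                )
    mut5, sd5 = profile.rates[CONSTRUCT_5ORI_DR]
    mut0, sd0 = profile.rates[CONSTRUCT_0ORI_DR]
    base5, sdb5 = baseline_profile.rates[CONSTRUCT_5ORI_DR]
    base0, sdb0 = baseline_profile.rates[CONSTRUCT_0ORI_DR]

    if profile.strain == baseline_profile.strain:
        index = None
    else:
        index = ofm_index(mut5, base5, mut0, base0)

    index_sd = None
    if index is not None and None not in (sd5, sd0, sdb5, sdb0):
        index_sd = ofm_index_sd(mut5, sd5, base5, sdb5, mut0, sd0, base0, sdb0)

    if index is None:
        call = "indeterminate"
    elif index >= ofm_threshold and mut5 >= destabilization_fold * base5:
        call = "Ofm"
    elif index < non_ofm_threshold:
        call = "non-Ofm"
    else:
        call = "indeterminate"

    return OfmResult(
        strain=profile.strain,
        baseline=baseline_profile.strain,
        index=index,
        index_sd=index_sd,
        rounded_index=None if index is None else round_half_away(index),
        call=call,
    )
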