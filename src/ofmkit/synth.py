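"""Virtual strain panels and end-to-end screen simulation.

Generates complete synthetic experiments — strains with known per-division
loss rates for the gapped (5ORIΔ-ΔR) and full-origin (0ORIΔ-ΔR) derivatives,
duplicate-chromoductant sectoring observations, and fluctuation assays — so
the whole pipeline (sector → screen call → rate estimation → Ofm index) can be
exercised against ground truth with no external data.

Strain archetypes are anchored to the wild-type reference rates
(2.1×10⁻³ per division for the gapped derivative, 3×10⁻⁵ for the full-origin
derivative):

``wildtype_like``
    both rates at the anchors;
``ofm_like``
    gapped-derivative rate multiplied log-uniformly by 5–50, full-origin rate
    by 1–4 (a specific gap-maintenance defect);
``general_instability``
    both rates multiplied by a common log-uniform 10³–10⁴ factor (a
    kinetochore-like transmission defect whose full-origin derivative sectors
    heavily, the pattern that disqualifies a strain as an Ofm mutant);
``intermediate``
    a mild common destabilization (2–5× gapped, 1–2× full-origin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fluctuation import FluctuationAssay, estimate_auto, simulate_assay
from .scoring import (
    CONSTRUCT_0ORI_DR,
    CONSTRUCT_5ORI_DR,
    StrainLossProfile,
    score_profile,
)
from .sectoring import classify_sectors, lower_median, screen_call, simulate_colonies

__all__ = [
    "ARCHETYPES",
    "WT_RATE_GAPPED",
    "WT_RATE_FULL",
    "VirtualStrain",
    "ScreenParams",
    "VirtualScreenResult",
    "make_panel",
    "run_virtual_screen",
]

ARCHETYPES = ("wildtype_like", "ofm_like", "general_instability", "intermediate")

#: Wild-type anchor loss rates (per division).
WT_RATE_GAPPED = 2.1e-3
WT_RATE_FULL = 3.0e-5

RATE_FLOOR = 2.0e-6
RATE_CEIL = 0.5


@dataclass(frozen=True)
class VirtualStrain:
    """A strain with known true loss rates for the two screen constructs."""

    strain: str
    true_rates: dict[str, float]
    archetype: str

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        for construct, rate in self.true_rates.items():
            if not RATE_FLOOR <= rate <= RATE_CEIL:
                raise ValueError(
                    f"{self.strain}/{construct}: rate {rate} outside "
                    f"[{RATE_FLOOR}, {RATE_CEIL}]"
                )

    def true_ofm_index(self, base_gapped: float = WT_RATE_GAPPED, base_full: float = WT_RATE_FULL) -> Optional[float]:
        """Ofm index from the true rates (scale-invariant; None if undefined)."""
        denom = self.true_rates[CONSTRUCT_0ORI_DR] - base_full
        if denom <= 0:
            return None
        return (self.true_rates[CONSTRUCT_5ORI_DR] - base_gapped) / denom


def _clip(rate: float) -> float:
    return float(np.clip(rate, RATE_FLOOR, RATE_CEIL))


def make_panel(
    n_strains: int,
    archetype_mix: Mapping[str, float],
    seed: int,
) -> list[VirtualStrain]:
    """Deterministically generate a panel of virtual strains.

    ``archetype_mix`` maps archetype name to its proportion (must sum to 1).
    Counts are apportioned by largest remainder so the panel size is exact.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    mix = dict(archetype_mix)
    for a in mix:
        if a not in ARCHETYPES:
            raise ValueError(f"unknown archetype {a!r}")
    total = sum(mix.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"archetype proportions must sum to 1 (got {total})")

    quotas = {a: n_strains * p for a, p in mix.items()}
    counts = {a: int(np.floor(q)) for a, q in quotas.items()}
    leftover = n_strains - sum(counts.values())
    for a in sorted(mix, key=lambda a: quotas[a] - counts[a], reverse=True)[:leftover]:
        counts[a] += 1

    rng = np.random.default_rng(seed)
    panel: list[VirtualStrain] = []
    i = 0
    for archetype in ARCHETYPES:
        for _ in range(counts.get(archetype, 0)):
            i += 1
            if archetype == "wildtype_like":
                m5, m0 = 1.0, 1.0
            elif archetype == "ofm_like":
                m5 = float(np.exp(rng.uniform(np.log(5.0), np.log(50.0))))
                m0 = float(rng.uniform(1.0, 4.0))
            elif archetype == "general_instability":
                m5 = m0 = float(np.exp(rng.uniform(np.log(1e3), np.log(1e4))))
            else:  # intermediate
                m5 = float(np.exp(rng.uniform(np.log(2.0), np.log(5.0))))
                m0 = float(rng.uniform(1.0, 2.0))
            panel.append(
                VirtualStrain(
                    strain=f"v{i:04d}_{archetype}",
                    true_rates={
                        CONSTRUCT_5ORI_DR: _clip(WT_RATE_GAPPED * m5),
                        CONSTRUCT_0ORI_DR: _clip(WT_RATE_FULL * m0),
                    },
                    archetype=archetype,
                )
            )
    return panel


@dataclass(frozen=True)
class ScreenParams:
    """Sizes of the virtual sectoring screen and follow-up fluctuation assays.

    Culture sizes are chosen so the expected loss events per culture
    ``m = rate × N`` sit in the estimators' working range at the anchor rates:
    1000 cells/culture for the gapped derivative (wild-type m ≈ 2) and 10⁵ for
    the much more stable full-origin derivative (wild-type m ≈ 3).
    """

    generations: int = 10
    n_colonies: int = 500
    n_cultures: int = 50
    culture_size_gapped: int = 1_000
    culture_size_full: int = 100_000


@dataclass(frozen=True)
class VirtualScreenResult:
    """Per-strain screen outcome plus the archetype-vs-verdict confusion matrix."""

    per_strain: pd.DataFrame
    confusion: pd.DataFrame
    baseline: StrainLossProfile
    seed: int

    def sensitivity(self, archetype: str = "ofm_like", verdict: str = "Ofm") -> float:
        sub = self.per_strain[self.per_strain["archetype"] == archetype]
        if len(sub) == 0:
            return float("nan")
        return float((sub["verdict"] == verdict).mean())


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _estimate_rate_e5(rate_seed: int, rate: float, size: int, n_cultures: int, label: str) -> float:
    assay = simulate_assay(rate, size, n_cultures, seed=rate_seed, label=label)
    return estimate_auto(assay).rate_e5


def run_virtual_screen(
    panel: Sequence[VirtualStrain],
    params: ScreenParams = ScreenParams(),
    seed: int = 0,
) -> VirtualScreenResult:
    """Run the full virtual screen over a strain panel.

    For every strain, duplicate chromoductants of both derivatives are grown as
    ``n_colonies`` colonies each; median sector counts are classified and
    combined into a screen verdict.  Strains that are hits (any verdict except
    ``not_a_hit``) get follow-up fluctuation assays for both derivatives, an
    estimated Ofm index against a simulated wild-type reference, and a
    rate-based call.  Deterministic given ``seed``.
    """
    master = np.random.default_rng(seed)

    # Simulated wild-type reference assays supply the baseline rates.
    base5_e5 = _estimate_rate_e5(
        _child_seed(master), WT_RATE_GAPPED, params.culture_size_gapped,
        params.n_cultures, "reference|gapped",
    )
    base0_e5 = _estimate_rate_e5(
        _child_seed(master), WT_RATE_FULL, params.culture_size_full,
        params.n_cultures, "reference|full",
    )
    baseline = StrainLossProfile(
        "virtual wild type",
        {CONSTRUCT_5ORI_DR: (base5_e5, None), CONSTRUCT_0ORI_DR: (base0_e5, None)},
    )

    rows = []
    for strain in panel:
        r5 = strain.true_rates[CONSTRUCT_5ORI_DR]
        r0 = strain.true_rates[CONSTRUCT_0ORI_DR]

        classes = {}
        for construct, rate in ((CONSTRUCT_5ORI_DR, r5), (CONSTRUCT_0ORI_DR, r0)):
            for rep in (1, 2):
                rng = np.random.default_rng(_child_seed(master))
                counts = simulate_colonies(rate, params.generations, params.n_colonies, rng)
                classes[(construct, rep)] = classify_sectors(lower_median(counts))
        verdict = screen_call(
            classes[(CONSTRUCT_5ORI_DR, 1)],
            classes[(CONSTRUCT_5ORI_DR, 2)],
            classes[(CONSTRUCT_0ORI_DR, 1)],
            classes[(CONSTRUCT_0ORI_DR, 2)],
        )

        est5_e5 = est0_e5 = est_index = None
        rate_call = ""
        if verdict != "not_a_hit":
            est5_e5 = _estimate_rate_e5(
                _child_seed(master), r5, params.culture_size_gapped,
                params.n_cultures, f"{strain.strain}|gapped",
            )
            est0_e5 = _estimate_rate_e5(
                _child_seed(master), r0, params.culture_size_full,
                params.n_cultures, f"{strain.strain}|full",
            )
            profile = StrainLossProfile(
                strain.strain,
                {CONSTRUCT_5ORI_DR: (est5_e5, None), CONSTRUCT_0ORI_DR: (est0_e5, None)},
            )
            result = score_profile(profile, baseline)
            est_index = result.index
            rate_call = result.call

        true_index = strain.true_ofm_index()
        rows.append(
            {
                "strain": strain.strain,
                "archetype": strain.archetype,
                "true_rate5": r5,
                "true_rate0": r0,
                "class5_rep1": classes[(CONSTRUCT_5ORI_DR, 1)],
                "class5_rep2": classes[(CONSTRUCT_5ORI_DR, 2)],
                "class0_rep1": classes[(CONSTRUCT_0ORI_DR, 1)],
                "class0_rep2": classes[(CONSTRUCT_0ORI_DR, 2)],
                "verdict": verdict,
                "est_rate5_e5": np.nan if est5_e5 is None else est5_e5,
                "est_rate0_e5": np.nan if est0_e5 is None else est0_e5,
                "est_index": np.nan if est_index is None else est_index,
                "true_index": np.nan if true_index is None else true_index,
                "rate_call": rate_call,
            }
        )

    per_strain = pd.DataFrame(rows)
    confusion = pd.crosstab(per_strain["archetype"], per_strain["verdict"])
    return VirtualScreenResult(per_strain, confusion, baseline, seed)
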