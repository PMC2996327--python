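"""Stochastic replication of chromosome III derivatives with inter-origin gaps.

Each simulated cell replicates a linear construct carrying a set of origins.
Per cell:

- every origin is independently *competent* (licensed) with probability ``p``
  (its efficiency class) and, if competent, draws a firing time from a normal
  distribution truncated at 0 (minutes into S phase);
- an origin actually fires only if its locus is still unreplicated at its
  drawn time — this single rule implements dormancy: dormant origins carry a
  late mean firing time and are normally replicated passively by an incoming
  fork before that time, firing only when forks are delayed or removed;
- firing launches two forks moving outward at constant speed; each fork
  independently arrests permanently after an exponentially distributed travel
  distance with per-kb hazard ``-ln(1-f)`` (so it survives ``d`` kb with
  probability ``(1-f)^d``);
- replication may continue past S phase until ``available_min`` (mitosis);
  the cell is scored incomplete if any position is unreplicated at that time.

Incomplete replication is equated with loss of the construct; the simulator's
claims are orderings and ratios between constructs and regimes, not absolute
loss rates.  Regimes encode checkpoint-mutant caricatures: a wild-type-like
regime restores crippled forks perfectly (no permanent arrest), a rad9-like
regime lets forks arrest with distance (no restoration), and mec1/mrc1-like
regimes slow forks with little permanent arrest.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

__all__ = [
    "OriginSpec",
    "ConstructMap",
    "ReplicationRegime",
    "SimOutcome",
    "fork_reach",
    "simulate_replication",
    "builtin_construct",
    "builtin_regime",
    "BUILTIN_CONSTRUCTS",
    "BUILTIN_REGIMES",
    "regime_contrast",
]


@dataclass(frozen=True)
class OriginSpec:
    """One replication origin: position, licensing probability, firing time."""

    name: str
    position_kb: float
    competence: float
    t_mean_min: float
    t_sd_min: float
    dormant: bool = False

    def __post_init__(self) -> None:
        if self.position_kb < 0:
            raise ValueError(f"{self.name}: position must be >= 0")
        if not 0.0 <= self.competence <= 1.0:
            raise ValueError(f"{self.name}: competence must be in [0, 1]")
        if self.t_sd_min < 0:
            raise ValueError(f"{self.name}: t_sd_min must be >= 0")


@dataclass(frozen=True)
class ConstructMap:
    """A linear chromosome construct and its origin complement."""

    name: str
    length_kb: float
    origins: tuple[OriginSpec, ...]
    notes: str = ""

    def __post_init__(self) -> None:
        if self.length_kb <= 0:
            raise ValueError("length_kb must be positive")
        origins = tuple(sorted(self.origins, key=lambda o: o.position_kb))
        object.__setattr__(self, "origins", origins)
        positions = [o.position_kb for o in origins]
        if any(p > self.length_kb for p in positions):
            raise ValueError(f"{self.name}: origin beyond construct end")
        if len(set(positions)) != len(positions):
            raise ValueError(f"{self.name}: duplicate origin positions")

    def with_origin(self, origin: OriginSpec) -> "ConstructMap":
        return replace(self, origins=self.origins + (origin,))

    def without_dormant(self) -> "ConstructMap":
        return replace(self, origins=tuple(o for o in self.origins if not o.dormant))


@dataclass(frozen=True)
class ReplicationRegime:
    """Kinetic and fork-failure parameters of a simulation regime."""

    name: str
    fork_speed_kb_min: float = 2.3
    s_phase_min: float = 55.0
    available_min: float = 170.0
    fork_fail_per_kb: float = 0.0
    dormant_enabled: bool = True

    def __post_init__(self) -> None:
        if self.fork_speed_kb_min <= 0 or self.s_phase_min <= 0:
            raise ValueError("speeds and durations must be positive")
        if self.available_min < self.s_phase_min:
            raise ValueError("available_min must be >= s_phase_min")
        if not 0.0 <= self.fork_fail_per_kb < 1.0:
            raise ValueError("fork_fail_per_kb must be in [0, 1)")


@dataclass(frozen=True)
class SimOutcome:
    """Monte-Carlo summary of a replication simulation."""

    construct: str
    regime: str
    incomplete_fraction: float
    incomplete_se: float
    origin_firing_fraction: dict[str, float]
    mean_unreplicated_kb: float
    n: int
    seed: int


def fork_reach(speed_kb_min: float, time_min: float) -> float:
    """Distance (kb) a fork travels in ``time_min`` at constant speed."""
    if speed_kb_min <= 0 or time_min < 0:
        raise ValueError("speed must be positive and time non-negative")
    return speed_kb_min * time_min


def _origin_stream_seed(seed: int, origin_name: str) -> list[int]:
    """Stable per-origin substream key: adding/removing other origins leaves
    this origin's draws unchanged (common random numbers for monotonicity
    experiments)."""
    digest = hashlib.sha256(origin_name.encode("utf-8")).digest()
    return [int(seed) % 2**31, int.from_bytes(digest[:4], "big") % 2**31]


def _draw_origin_arrays(
    origin: OriginSpec, regime: ReplicationRegime, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(_origin_stream_seed(seed, origin.name))
    competent = rng.random(n) < origin.competence
    if origin.t_sd_min > 0:
        a = (0.0 - origin.t_mean_min) / origin.t_sd_min
        t = truncnorm.rvs(
            a, np.inf, loc=origin.t_mean_min, scale=origin.t_sd_min, size=n, random_state=rng
        )
    else:
        t = np.full(n, origin.t_mean_min)
    f = regime.fork_fail_per_kb
    if f > 0:
        scale = -1.0 / np.log1p(-f)  # mean arrest distance in kb
        arrest_left = rng.exponential(scale, size=n)
        arrest_right = rng.exponential(scale, size=n)
    else:
        arrest_left = np.full(n, np.inf)
        arrest_right = np.full(n, np.inf)
    return competent, t, arrest_left, arrest_right


def _covered(x: float, t: float, forks: list[tuple[float, float, int, float]], v: float) -> bool:
    """Is position ``x`` replicated at time ``t`` by any already-launched fork?"""
    for (x0, t0, direction, dmax) in forks:
        if t0 >= t:
            continue
        reach = min(v * (t - t0), dmax)
        if direction > 0:
            if x0 <= x <= x0 + reach:
                return True
        else:
            if x0 - reach <= x <= x0:
                return True
    return False


def simulate_replication(
    construct: ConstructMap, regime: ReplicationRegime, n: int, seed: int
) -> SimOutcome:
    """Monte-Carlo replication of ``construct`` under ``regime`` over ``n`` cells."""
    if n < 1:
        raise ValueError("n must be >= 1")
    origins = [
        o for o in construct.origins if regime.dormant_enabled or not o.dormant
    ]
    for o in origins:
        if not 0.0 <= o.position_kb <= construct.length_kb:
            raise ValueError(f"origin {o.name} outside [0, {construct.length_kb}]")

    v = regime.fork_speed_kb_min
    avail = regime.available_min
    length = construct.length_kb

    draws = [_draw_origin_arrays(o, regime, n, seed) for o in origins]
    fired_counts = {o.name: 0 for o in origins}
    incomplete = 0
    unreplicated_total = 0.0

    for cell in range(n):
        cand = []
        for i, o in enumerate(origins):
            competent, t, aL, aR = draws[i]
            if competent[cell] and t[cell] < avail:
                cand.append((t[cell], o.position_kb, aL[cell], aR[cell], o.name))
        cand.sort()
        forks: list[tuple[float, float, int, float]] = []
        for (t0, x0, aL, aR, name) in cand:
            if _covered(x0, t0, forks, v):
                continue
            fired_counts[name] += 1
            budget = v * (avail - t0)
            forks.append((x0, t0, -1, min(aL, budget)))
            forks.append((x0, t0, +1, min(aR, budget)))

        if not forks:
            incomplete += 1
            unreplicated_total += length
            continue
        intervals = []
        for (x0, t0, direction, dmax) in forks:
            if direction > 0:
                intervals.append((x0, min(x0 + dmax, length)))
            else:
                intervals.append((max(x0 - dmax, 0.0), x0))
        intervals.sort()
        covered = 0.0
        lo, hi = intervals[0]
        gap = lo  # unreplicated before first interval
        for (a, b) in intervals[1:]:
            if a <= hi:
                hi = max(hi, b)
            else:
                covered += hi - lo
                gap += a - hi
                lo, hi = a, b
        covered += hi - lo
        gap += length - hi
        if gap > 1e-9:
            incomplete += 1
            unreplicated_total += gap

    q = incomplete / n
    return SimOutcome(
        construct=construct.name,
        regime=regime.name,
        incomplete_fraction=q,
        incomplete_se=float(np.sqrt(q * (1.0 - q) / n)),
        origin_firing_fraction={name: c / n for name, c in fired_counts.items()},
        mean_unreplicated_kb=unreplicated_total / n,
        n=n,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Packaged constructs and regimes
# ---------------------------------------------------------------------------
# Geometry (kb, full-length coordinates, documented in docs/methods.md):
# the efficient-origin deletions span ARS305Δ(40)–ARS310Δ(140), a ~100-kb gap;
# ARS313 sits 20 kb and ARS315 50 kb distal to the ARS310 deletion.  The
# ΔR fragments are cut 10 kb right of ARS310, the ΔL fragment 5 kb right of
# ARS304 (coordinates rebased to its own left end).  Efficiency classes:
# active in >=90% of cycles -> p=0.9 (early firing); 15-25% -> p=0.2;
# dormant (not detectably active) -> p=0.9 licensed but late t_mean, fired
# only when incoming forks are delayed.

_EFF = dict(competence=0.9, t_mean_min=15.0, t_sd_min=5.0)
_INEFF = dict(competence=0.2, t_mean_min=25.0, t_sd_min=6.0)
_DORM = dict(competence=0.9, t_mean_min=55.0, t_sd_min=5.0, dormant=True)


def _dormant_left() -> tuple[OriginSpec, ...]:
    return (
        OriginSpec("ARS301", 8.0, **_DORM),
        OriginSpec("ARS302/303/320", 14.0, **_DORM),
        OriginSpec("ARS304", 25.0, **_DORM),
    )


def _efficient_set() -> tuple[OriginSpec, ...]:
    return (
        OriginSpec("ARS305", 40.0, **_EFF),
        OriginSpec("ARS306", 70.0, **_EFF),
        OriginSpec("ARS307", 95.0, **_EFF),
        OriginSpec("ARS309", 120.0, **_EFF),
        OriginSpec("ARS310", 140.0, **_EFF),
    )


def _build_constructs() -> dict[str, ConstructMap]:
    ars308 = OriginSpec("ARS308", 110.0, **_INEFF)
    ars313 = OriginSpec("ARS313", 160.0, **_INEFF)
    ars315 = OriginSpec("ARS315", 190.0, **_EFF)
    return {
        "0ORIΔ-ΔR": ConstructMap(
            "0ORIΔ-ΔR",
            150.0,
            _dormant_left() + _efficient_set() + (ars308,),
            notes="full origin complement, fragmented right of ARS310",
        ),
        "5ORIΔ-ΔR": ConstructMap(
            "5ORIΔ-ΔR",
            150.0,
            _dormant_left() + (ars308,),
            notes="five efficient origins deleted; only HML-associated dormant "
            "origins remain left of the gap",
        ),
        "5ORIΔ": ConstructMap(
            "5ORIΔ",
            200.0,
            _dormant_left() + (ars308, ars313, ars315),
            notes="full-length chromosome with the five efficient origins "
            "deleted; retains origins distal to the ARS310 deletion",
        ),
        "ΔL-6ORIΔ": ConstructMap(
            "ΔL-6ORIΔ",
            170.0,
            (
                OriginSpec("ARS313", 130.0, **_INEFF),
                OriginSpec("ARS315", 160.0, **_EFF),
            ),
            notes="left end and HML-associated dormant origins removed, "
            "ARS308 removed by the CEN4 replacement",
        ),
    }


BUILTIN_CONSTRUCTS = _build_constructs()

BUILTIN_REGIMES = {
    # Wild type: crippled forks are restored, so no permanent arrest.
    "wild_type": ReplicationRegime("wild_type", 2.3, 55.0, 170.0, 0.0, True),
    # DNA-damage-response defective: forks arrest with distance and stay dead
    # (f chosen so ~10% of single forks fail across the 100-kb gap).
    "rad9_like": ReplicationRegime("rad9_like", 2.3, 55.0, 170.0, 1e-3, True),
    # Slow but stable forks (fork progression defect, mild arrest).
    "mec1_like": ReplicationRegime("mec1_like", 1.15, 55.0, 170.0, 2e-4, True),
    "mrc1_like": ReplicationRegime("mrc1_like", 1.15, 55.0, 170.0, 2e-4, True),
}


def builtin_construct(name: str) -> ConstructMap:
    """Packaged origin map for one of the four chromosome III derivatives."""
    try:
        return BUILTIN_CONSTRUCTS[name]
    except KeyError:
        raise KeyError(
            f"unknown construct {name!r}; known: {sorted(BUILTIN_CONSTRUCTS)}"
        ) from None


def builtin_regime(name: str) -> ReplicationRegime:
    """Packaged replication regime by name."""
    try:
        return BUILTIN_REGIMES[name]
    except KeyError:
        raise KeyError(f"unknown regime {name!r}; known: {sorted(BUILTIN_REGIMES)}") from None


def regime_contrast(
    construct_a: ConstructMap,
    construct_b: ConstructMap,
    regime1: ReplicationRegime,
    regime2: ReplicationRegime,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Incomplete-fraction ratios A/B under two regimes, with propagated SE.

    One row per regime with the two incomplete fractions, their ratio and its
    delta-method SE; the ratio is NaN when the denominator fraction is zero.
    """
    rows = []
    for regime in (regime1, regime2):
        a = simulate_replication(construct_a, regime, n, seed)
        b = simulate_replication(construct_b, regime, n, seed)
        if b.incomplete_fraction > 0:
            ratio = a.incomplete_fraction / b.incomplete_fraction
            if a.incomplete_fraction > 0:
                ratio_se = ratio * np.sqrt(
                    (a.incomplete_se / a.incomplete_fraction) ** 2
                    + (b.incomplete_se / b.incomplete_fraction) ** 2
                )
            else:
                ratio_se = np.nan
        else:
            ratio, ratio_se = np.nan, np.nan
        rows.append(
            {
                "regime": regime.name,
                "construct_a": construct_a.name,
                "construct_b": construct_b.name,
                "incomplete_a": a.incomplete_fraction,
                "incomplete_b": b.incomplete_fraction,
                "ratio": ratio,
                "ratio_se": ratio_se,
            }
        )
    df = pd.DataFrame(rows)
    if np.isfinite(df["ratio"]).all():
        df.attrs["ratio_ordering"] = (
            "regime1_larger"
            if df["ratio"].iloc[0] > df["ratio"].iloc[1]
            else "regime2_larger_or_equal"
        )
    return df
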