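"""Tab-delimited input/output for assays, loss-rate tables and origin maps.

Conventions shared by all formats:

- UTF-8 TSV with a header row;
- rates in files are in ×10⁻⁵-per-division display units (matching the
  published loss-rate tables); internal computation uses raw probabilities,
  converted only at this boundary;
- the missing-value tokens ``ND``, ``N.D.`` and ``Not defined`` (exactly,
  case-sensitive) mark constructs a table does not report.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fluctuation import FluctuationAssay, LossRateEstimate
from .replication import ConstructMap, OriginSpec
from .scoring import OfmResult, StrainLossProfile

__all__ = [
    "MISSING_TOKENS",
    "packaged_table2_path",
    "load_rates",
    "write_rates",
    "load_assays",
    "write_assays",
    "write_estimates",
    "write_ofm_results",
    "load_origin_map",
    "write_origin_map",
]

MISSING_TOKENS = ("ND", "N.D.", "Not defined")

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input table (message names the file and offending content)."""


def packaged_table2_path() -> Path:
    """Path to the packaged transcription of the checkpoint-mutant loss-rate table."""
    return Path(resources.files("ofmkit.data").joinpath("table2.tsv"))  # type: ignore[arg-type]


def _read_tsv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_rate(value: str, path: PathLike, line: int, column: str) -> Optional[float]:
    if value in MISSING_TOKENS or value == "":
        return None
    try:
        rate = float(value)
    except ValueError:
        raise ParseError(
            f"{path}: line {line}, column {column!r}: {value!r} is not a number "
            f"or one of the missing-value tokens {MISSING_TOKENS}"
        ) from None
    if rate < 0:
        raise ParseError(f"{path}: line {line}, column {column!r}: negative rate {rate}")
    return rate


def load_rates(path: PathLike) -> list[StrainLossProfile]:
    """Read a long-format loss-rate TSV into per-strain profiles.

    Columns: ``strain``, ``construct``, ``rate_e5`` and optionally ``sd_e5``.
    Rows whose rate is a missing-value token are dropped from the profile;
    unknown construct names are preserved as-is.
    """
    df = _read_tsv(path, ["strain", "construct", "rate_e5"])
    has_sd = "sd_e5" in df.columns
    profiles: dict[str, dict[str, tuple[float, Optional[float]]]] = {}
    order: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rate = _parse_rate(row.rate_e5, path, i, "rate_e5")
        if rate is None:
            continue
        sd = _parse_rate(row.sd_e5, path, i, "sd_e5") if has_sd else None
        if row.strain not in profiles:
            profiles[row.strain] = {}
            order.append(row.strain)
        profiles[row.strain][row.construct] = (rate, sd)
    if not profiles:
        raise ParseError(f"{path}: no usable loss-rate rows")
    return [StrainLossProfile(strain, profiles[strain]) for strain in order]


def write_rates(profiles: Sequence[StrainLossProfile], path: PathLike) -> None:
    """Write profiles back to the long-format loss-rate TSV (round-trips load_rates)."""
    rows = []
    for p in profiles:
        for construct, (rate, sd) in p.rates.items():
            rows.append(
                {
                    "strain": p.strain,
                    "construct": construct,
                    "rate_e5": _fmt(rate),
                    "sd_e5": "" if sd is None else _fmt(sd),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def load_assays(path: PathLike) -> list[tuple[str, str, FluctuationAssay]]:
    """Read a fluctuation-assay TSV into (strain, construct, assay) triples.

    Columns: ``strain``, ``construct``, ``culture_id``, ``loss_count``,
    ``culture_size``, optional ``cells_sampled``.  Culture size (and sampling)
    must be constant within a strain/construct group.
    """
    df = _read_tsv(path, ["strain", "construct", "culture_id", "loss_count", "culture_size"])
    out = []
    for (strain, construct), group in df.groupby(["strain", "construct"], sort=False):
        try:
            counts = tuple(int(c) for c in group["loss_count"])
            sizes = {int(s) for s in group["culture_size"]}
        except ValueError as exc:
            raise ParseError(f"{path}: non-integer count or size in {strain}/{construct}: {exc}")
        if len(sizes) != 1:
            raise ParseError(
                f"{path}: culture_size must be constant within {strain}/{construct}"
            )
        sampled = None
        if "cells_sampled" in group.columns:
            vals = {v for v in group["cells_sampled"] if v != ""}
            if len(vals) > 1:
                raise ParseError(
                    f"{path}: cells_sampled must be constant within {strain}/{construct}"
                )
            if vals:
                sampled = int(vals.pop())
        assay = FluctuationAssay(f"{strain}|{construct}", counts, sizes.pop(), sampled)
        out.append((strain, construct, assay))
    return out


def write_assays(
    records: Sequence[tuple[str, str, FluctuationAssay]], path: PathLike
) -> None:
    rows = []
    for strain, construct, assay in records:
        for i, count in enumerate(assay.culture_counts):
            rows.append(
                {
                    "strain": strain,
                    "construct": construct,
                    "culture_id": i,
                    "loss_count": count,
                    "culture_size": assay.culture_size,
                    "cells_sampled": "" if assay.cells_sampled is None else assay.cells_sampled,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_estimates(
    records: Sequence[tuple[str, str, LossRateEstimate]], path: PathLike
) -> None:
    """Write loss-rate estimates with rates in both raw and ×10⁻⁵ display units."""
    rows = []
    for strain, construct, est in records:
        rows.append(
            {
                "strain": strain,
                "construct": construct,
                "method": est.method,
                "m_hat": _fmt(est.m_hat),
                "rate_per_division": _fmt(est.rate_per_division),
                "rate_e5": _fmt(est.rate_e5),
                "ci_low_e5": "" if est.ci_low is None else _fmt(est.ci_low * 1e5),
                "ci_high_e5": "" if est.ci_high is None else _fmt(est.ci_high * 1e5),
                "n_cultures": est.n_cultures,
                "seed": "" if est.seed is None else est.seed,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ofm_results(results: Sequence[OfmResult], path: PathLike) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "strain": r.strain,
                "baseline": r.baseline,
                "index": "Not defined" if r.index is None else _fmt(r.index),
                "index_sd": "" if r.index_sd is None else _fmt(r.index_sd),
                "rounded_index": "Not defined" if r.rounded_index is None else r.rounded_index,
                "call": r.call,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_origin_map(path: PathLike, name: str = "custom", length_kb: Optional[float] = None) -> ConstructMap:
    """Read an origin-map TSV: ``origin``, ``position_kb``, ``competence``,
    ``t_mean_min``, ``t_sd_min``, ``dormant`` (true/false).

    ``length_kb`` defaults to 10 kb beyond the last origin.
    """
    df = _read_tsv(
        path, ["origin", "position_kb", "competence", "t_mean_min", "t_sd_min", "dormant"]
    )
    origins = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            origins.append(
                OriginSpec(
                    name=row.origin,
                    position_kb=float(row.position_kb),
                    competence=float(row.competence),
                    t_mean_min=float(row.t_mean_min),
                    t_sd_min=float(row.t_sd_min),
                    dormant=str(row.dormant).strip().lower() in ("true", "1", "yes"),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from None
    if not origins:
        raise ParseError(f"{path}: no origins")
    if length_kb is None:
        length_kb = max(o.position_kb for o in origins) + 10.0
    return ConstructMap(name, length_kb, tuple(origins))


def write_origin_map(construct: ConstructMap, path: PathLike) -> None:
    rows = [
        {
            "origin": o.name,
            "position_kb": _fmt(o.position_kb),
            "competence": _fmt(o.competence),
            "t_mean_min": _fmt(o.t_mean_min),
            "t_sd_min": _fmt(o.t_sd_min),
            "dormant": str(o.dormant).lower(),
        }
        for o in construct.origins
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
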