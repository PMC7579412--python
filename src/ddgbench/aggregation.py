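"""Multi-run convergence aggregation of ΔΔG energy streams.

A ΔΔG engine emits a stream of model energies (Rosetta Energy Units) per
variant, one per generated model, in generation order.  The aggregation
rule consumes models one at a time and stops as soon as the two lowest
energies seen so far agree to within a tolerance (default 1 REU), or after
a maximum of 5 models; in either case the lowest — not the average — energy
is kept.  ΔΔG is the converged mutant minimum minus the converged wild-type
minimum.  A legacy mode reproduces the older fixed protocol: the mean of
exactly three models per variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .taxonomy import ValidationError

__all__ = [
    "EnergyStream",
    "ConvergenceResult",
    "converge",
    "ddg_from_streams",
    "aggregate_table",
    "read_energy_table",
]


@dataclass
class EnergyStream:
    """Ordered model energies (REU) for one variant of one mutation."""

    energies: Sequence[float]
    variant: str = "mut"  # "wt" or "mut"

    def __post_init__(self):
        if self.variant not in ("wt", "mut"):
            raise ValidationError(f"variant must be 'wt' or 'mut', got {self.variant!r}")
        for e in self.energies:
            if not math.isfinite(e):
                raise ValidationError(f"non-finite energy in stream: {e!r}")

    def __iter__(self) -> Iterator[float]:
        return iter(self.energies)


@dataclass(frozen=True)
class ConvergenceResult:
    final_energy: float
    models_used: int


class StreamExhausted(ValueError):
    pass


def converge(
    stream: EnergyStream | Iterable[float],
    tol: float = 1.0,
    max_models: int = 5,
) -> ConvergenceResult:
    """Consume models until the two lowest energies agree, or best-of-max.

    After at least two models, stop when |second lowest − lowest| ≤ tol over
    everything consumed so far; otherwise stop at ``max_models``.  The
    returned energy is the minimum of the consumed prefix.  The stream must
    be able to supply ``max_models`` values if convergence never triggers.
    """
    if tol < 0:
        raise ValidationError(f"tol must be ≥ 0, got {tol}")
    if max_models < 2:
        raise ValidationError(f"max_models must be ≥ 2, got {max_models}")
    it = iter(stream)
    lowest: list[float] = []  # two smallest so far
    used = 0
    while used < max_models:
        try:
            e = next(it)
        except StopIteration:
            raise StreamExhausted(
                f"energy stream exhausted after {used} models "
                f"(need up to {max_models})"
            ) from None
        if not math.isfinite(e):
            raise ValidationError(f"non-finite energy in stream: {e!r}")
        used += 1
        lowest = sorted(lowest + [e])[:2]
        if used >= 2 and lowest[1] - lowest[0] <= tol:
            break
    return ConvergenceResult(final_energy=lowest[0], models_used=used)


def ddg_from_streams(
    wt: EnergyStream | Iterable[float],
    mut: EnergyStream | Iterable[float],
    tol: float = 1.0,
    max_models: int = 5,
    scale: tuple[float, float] = (1.0, 0.0),
    legacy_mean3: bool = False,
) -> float:
    """ΔΔG = aggregated(mut) − aggregated(wt), optionally rescaled.

    In legacy mode each variant is the mean of its first three models
    instead of the converged minimum.  ``scale = (slope, intercept)``
    applies an affine REU→kcal/mol map to the raw ΔΔG (identity default).
    """
    if legacy_mean3:
        def mean3(stream):
            vals = []
            it = iter(stream)
            for _ in range(3):
                try:
                    vals.append(next(it))
                except StopIteration:
                    raise StreamExhausted(
                        "legacy mode needs 3 models per variant"
                    ) from None
            return sum(vals) / 3.0
        ddg = mean3(mut) - mean3(wt)
    else:
        ddg = (
            converge(mut, tol=tol, max_models=max_models).final_energy
            - converge(wt, tol=tol, max_models=max_models).final_energy
        )
    slope, intercept = scale
    return slope * ddg + intercept


def read_energy_table(path) -> pd.DataFrame:
    """Read a TSV/CSV of per-model energies.

    Columns: ``variant`` ("wt"/"mut"), ``model_index``, ``energy``, and
    optionally ``record_id`` to aggregate several mutations from one file.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    for col in ("variant", "model_index", "energy"):
        if col not in df.columns:
            raise ValidationError(f"required column {col!r} not found in {path}")
    if "record_id" not in df.columns:
        df["record_id"] = "mutation"
    return df


def aggregate_table(
    df: pd.DataFrame,
    tol: float = 1.0,
    max_models: int = 5,
    scale: tuple[float, float] = (1.0, 0.0),
    legacy_mean3: bool = False,
) -> pd.DataFrame:
    """Aggregate an energy table into one ΔΔG row per record_id."""
    rows = []
    for rid, group in df.groupby("record_id", sort=True):
        streams = {}
        for variant in ("wt", "mut"):
            sub = group[group["variant"] == variant].sort_values("model_index")
            if sub.empty:
                raise ValidationError(f"record {rid}: no {variant!r} energies")
            streams[variant] = EnergyStream(list(sub["energy"]), variant=variant)
        ddg = ddg_from_streams(
            streams["wt"], streams["mut"], tol=tol, max_models=max_models,
            scale=scale, legacy_mean3=legacy_mean3,
        )
        row = {"record_id": rid, "ddg_pred": ddg}
        if not legacy_mean3:
            for variant in ("wt", "mut"):
                res = converge(streams[variant], tol=tol, max_models=max_models)
                row[f"{variant}_models_used"] = res.models_used
                row[f"{variant}_energy"] = res.final_energy
        rows.append(row)
    return pd.DataFrame(rows)
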