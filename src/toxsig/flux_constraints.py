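"""MFA-derived flux constraints.

In vivo metabolic flux analysis reports fluxes relative to citrate synthase
(fixed at 100). This module converts those relative estimates to absolute
units (umol kg^-1 min^-1) through a single anchor reaction with a known
absolute flux (e.g. the glucose-output flux fixed by the tracer infusion
rate and body weight), and turns them into LP bounds v +- k*sd imposed on a
copy of the network. Literature uptake/secretion rates for exchange
reactions use the standard constraint-based sign convention: uptake is a
negative exchange flux, secretion positive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model_io import MetabolicNetwork

__all__ = [
    "FluxEstimate",
    "ExchangeRate",
    "ConstraintSet",
    "read_flux_table",
    "relative_to_absolute",
    "constraints_from_mfa",
    "exchange_constraints",
    "apply_constraints",
    "previous_bounds",
]


@dataclass(frozen=True)
class FluxEstimate:
    """One reaction's MFA flux estimate; absolute fields are filled by
    :func:`relative_to_absolute`."""

    reaction: str
    relative_value: float
    sd_relative: float
    absolute_value: float | None = None
    sd_absolute: float | None = None

    def __post_init__(self):
        if self.sd_relative < 0:
            raise ValueError(f"{self.reaction}: sd must be >= 0")


@dataclass(frozen=True)
class ExchangeRate:
    reaction: str
    direction: str  # "uptake" | "secretion"
    rate: float

    def __post_init__(self):
        if self.direction not in ("uptake", "secretion"):
            raise ValueError(f"{self.reaction}: direction must be uptake or secretion")
        if not (self.rate >= 0):
            raise ValueError(f"{self.reaction}: rate must be >= 0")


@dataclass(frozen=True)
class ConstraintSet:
    """Reaction id -> (lower, upper) flux bounds."""

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        for rid, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"{rid}: lower bound {lo} > upper bound {hi}")
        object.__setattr__(self, "bounds", dict(self.bounds))


def read_flux_table(path) -> list[FluxEstimate]:
    """Read a flux TSV: columns reaction, relative_value, sd (and optionally
    model_reaction_id, which overrides the reaction id for network mapping)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        rid = getattr(row, "model_reaction_id", None) or row.reaction
        out.append(FluxEstimate(reaction=str(rid),
                                relative_value=float(row.relative_value),
                                sd_relative=float(row.sd)))
    return out


def relative_to_absolute(
    estimates: Sequence[FluxEstimate], anchor_reaction: str, anchor_absolute: float
) -> list[FluxEstimate]:
    """Rescale relative fluxes to absolute units through one anchor reaction.

    scale = anchor_absolute / anchor_relative; values and sds scale alike.
    """
    by_id = {e.reaction: e for e in estimates}
    if anchor_reaction not in by_id:
        raise ValueError(f"anchor reaction {anchor_reaction!r} not in the estimates")
    anchor_rel = by_id[anchor_reaction].relative_value
    if anchor_rel == 0:
        raise ValueError(f"anchor reaction {anchor_reaction!r} has zero relative flux")
    if not anchor_absolute > 0:
        raise ValueError("anchor_absolute must be positive")
    scale = anchor_absolute / anchor_rel
    return [
        replace(e, absolute_value=e.relative_value * scale,
                sd_absolute=e.sd_relative * abs(scale))
        for e in estimates
    ]


def constraints_from_mfa(
    estimates: Sequence[FluxEstimate],
    network: MetabolicNetwork,
    k: float = 2.0,
) -> ConstraintSet:
    """Bounds (v - k*sd, v + k*sd) from converted MFA estimates.

    The lower bound is clipped to the reaction's structural lower bound
    (0 for irreversible reactions); a lower bound above the structural upper
    bound is an error, as is an estimate whose id has no network reaction.
    """
    unmapped = [e.reaction for e in estimates if e.reaction not in network.reaction_index]
    if unmapped:
        raise ValueError(f"flux estimates for unknown reactions: {unmapped}")
    bounds = {}
    for e in estimates:
        if e.absolute_value is None:
            raise ValueError(f"{e.reaction}: run relative_to_absolute first")
        rxn = network.reaction(e.reaction)
        lo = max(e.absolute_value - k * e.sd_absolute, rxn.lower_bound)
        hi = min(e.absolute_value + k * e.sd_absolute, rxn.upper_bound)
        if lo > rxn.upper_bound or hi < rxn.lower_bound or lo > hi:
            raise ValueError(
                f"{e.reaction}: MFA bounds ({lo:.4g}, {hi:.4g}) incompatible with "
                f"structural bounds ({rxn.lower_bound}, {rxn.upper_bound})"
            )
        bounds[e.reaction] = (lo, hi)
    return ConstraintSet(bounds=bounds)


def exchange_constraints(rates: Iterable[ExchangeRate]) -> ConstraintSet:
    """Exchange bounds: uptake rate u -> (-u, 0); secretion rate s -> (0, s)."""
    bounds = {}
    for r in rates:
        bounds[r.reaction] = (-r.rate, 0.0) if r.direction == "uptake" else (0.0, r.rate)
    return ConstraintSet(bounds=bounds)


def apply_constraints(network: MetabolicNetwork, cs: ConstraintSet) -> MetabolicNetwork:
    """Copy of the network with the constraint bounds substituted in."""
    unknown = [rid for rid in cs.bounds if rid not in network.reaction_index]
    if unknown:
        raise ValueError(f"constraints for unknown reactions: {unknown}")
    return network.with_bounds(cs.bounds)


def previous_bounds(network: MetabolicNetwork, cs: ConstraintSet) -> ConstraintSet:
    """The inverse constraint set: applying it after ``cs`` restores the
    original bounds exactly."""
    return ConstraintSet(
        bounds={
            rid: (network.reaction(rid).lower_bound, network.reaction(rid).upper_bound)
            for rid in cs.bounds
            if rid in network.reaction_index
        }
    )
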