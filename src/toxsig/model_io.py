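"""Metabolic network data structures and file formats.

The network container is deliberately small: metabolites, reactions with
stoichiometry, flux bounds and gene-protein-reaction (GPR) rules. It houses
the stoichiometric matrix S (one row per metabolite, one column per reaction)
used by the flux-based scoring layer. Serialization is a documented JSON
schema (see :func:`write_network`); a two-file TSV representation is also
supported. Gene sets (pathways, injury modules) use the standard GMT format.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "GprExpression",
    "GeneSet",
    "GprParseError",
    "NetworkValidationError",
    "parse_gpr",
    "evaluate_gpr",
    "add_demand_reaction",
    "read_network",
    "write_network",
    "read_gene_sets",
    "write_gene_sets",
]


class NetworkValidationError(ValueError):
    """A network violates a structural invariant (duplicate or dangling ids)."""


class GprParseError(ValueError):
    """A GPR rule string is malformed; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    extracellular: bool = False

    def __post_init__(self):
        if not self.id:
            raise NetworkValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise NetworkValidationError(f"metabolite {self.id!r}: empty compartment")


@dataclass(frozen=True)
class Reaction:
    """A reaction: signed stoichiometry (negative = consumed), flux bounds, GPR.

    Bounds are in arbitrary consistent units (umol kg^-1 min^-1 when
    MFA-constrained); ``math.inf`` marks an unbounded direction and is mapped
    to a finite sentinel only inside the LP layer.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = math.inf
    gpr: str = ""
    subsystem: str = ""

    def __post_init__(self):
        if not self.id:
            raise NetworkValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise NetworkValidationError(f"reaction {self.id!r}: empty stoichiometry")
        for met, coef in self.stoichiometry.items():
            if coef == 0:
                raise NetworkValidationError(
                    f"reaction {self.id!r}: zero coefficient for {met!r}"
                )
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


class MetabolicNetwork:
    """An immutable-by-convention stoichiometric network.

    Parameters
    ----------
    metabolites, reactions
        Validated on construction: ids must be unique and every stoichiometry
        key must resolve to a metabolite.
    """

    def __init__(self, metabolites: Sequence[Metabolite], reactions: Sequence[Reaction]):
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.metabolite_index = {}
        for i, m in enumerate(self.metabolites):
            if m.id in self.metabolite_index:
                raise NetworkValidationError(f"duplicate metabolite id {m.id!r}")
            self.metabolite_index[m.id] = i
        self.reaction_index = {}
        for j, r in enumerate(self.reactions):
            if r.id in self.reaction_index:
                raise NetworkValidationError(f"duplicate reaction id {r.id!r}")
            self.reaction_index[r.id] = j
        for r in self.reactions:
            for met_id in r.stoichiometry:
                if met_id not in self.metabolite_index:
                    raise NetworkValidationError(
                        f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                    )

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self.metabolite_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self.reaction_index[rxn_id]]

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S, shape (n_metabolites, n_reactions)."""
        S = np.zeros((self.n_metabolites, self.n_reactions))
        for j, r in enumerate(self.reactions):
            for met_id, coef in r.stoichiometry.items():
                S[self.metabolite_index[met_id], j] = coef
        return S

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def extracellular_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites if m.extracellular]

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(list(self.metabolites), list(self.reactions))

    def with_bounds(self, new_bounds: Mapping[str, tuple[float, float]]) -> "MetabolicNetwork":
        """Copy with the listed reactions' bounds replaced."""
        reactions = []
        for r in self.reactions:
            if r.id in new_bounds:
                lo, hi = new_bounds[r.id]
                reactions.append(replace(r, lower_bound=lo, upper_bound=hi))
            else:
                reactions.append(r)
        return MetabolicNetwork(list(self.metabolites), reactions)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return self.metabolites == other.metabolites and self.reactions == other.reactions

    def __repr__(self) -> str:
        return (
            f"MetabolicNetwork({self.n_metabolites} metabolites, "
            f"{self.n_reactions} reactions)"
        )


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

#: Parsed GPR tree: either a gene id (leaf) or ("and"|"or", [children]).
GprExpression = Union[str, tuple]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule: str) -> GprExpression | None:
    """Parse a GPR rule into a tree.

    Grammar: gene tokens combined with case-insensitive ``and`` / ``or`` and
    parentheses; ``and`` binds tighter than ``or``. Encodes enzyme complexes
    (and) versus isozymes (or). Returns ``None`` for an empty rule.

    Raises
    ------
    GprParseError
        On unbalanced parentheses or a missing operand, with the character
        position of the offending token.
    """
    if rule is None or not rule.strip():
        return None
    tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(rule)]
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, len(rule))

    def parse_or():
        nonlocal pos
        children = [parse_and()]
        while peek()[0] is not None and peek()[0].lower() == "or":
            pos += 1
            children.append(parse_and())
        return children[0] if len(children) == 1 else ("or", children)

    def parse_and():
        nonlocal pos
        children = [parse_atom()]
        while peek()[0] is not None and peek()[0].lower() == "and":
            pos += 1
            children.append(parse_atom())
        return children[0] if len(children) == 1 else ("and", children)

    def parse_atom():
        nonlocal pos
        tok, at = peek()
        if tok is None:
            raise GprParseError("unexpected end of rule, operand expected", at)
        if tok == "(":
            pos += 1
            node = parse_or()
            tok2, at2 = peek()
            if tok2 != ")":
                raise GprParseError("unbalanced parenthesis", at2)
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"operand expected, found {tok!r}", at)
        pos += 1
        return tok

    tree = parse_or()
    tok, at = peek()
    if tok is not None:
        raise GprParseError(f"unexpected token {tok!r}", at)
    return tree


def evaluate_gpr(
    expr: GprExpression | None,
    gene_values: Mapping[str, float],
    default: float = 0.0,
) -> float:
    """Aggregate per-gene values through a GPR tree.

    AND nodes take the minimum of their children (complex limited by its
    least-changed subunit), OR nodes the maximum (best-expressed isozyme).
    Genes absent from ``gene_values`` contribute ``default`` (0: no measured
    change is neutral). An empty rule (``None``) evaluates to ``default``.
    """
    if expr is None:
        return float(default)
    if isinstance(expr, str):
        return float(gene_values.get(expr, default))
    op, children = expr
    vals = [evaluate_gpr(c, gene_values, default) for c in children]
    return min(vals) if op == "and" else max(vals)


def gpr_genes(expr: GprExpression | None) -> set[str]:
    """All gene ids appearing in a parsed GPR tree."""
    if expr is None:
        return set()
    if isinstance(expr, str):
        return {expr}
    out: set[str] = set()
    for c in expr[1]:
        out |= gpr_genes(c)
    return out


# ---------------------------------------------------------------------------
# Demand reactions
# ---------------------------------------------------------------------------

def demand_reaction_id(metabolite_id: str) -> str:
    return f"DM_{metabolite_id}"


def add_demand_reaction(
    network: MetabolicNetwork,
    metabolite_id: str,
    allow_intracellular: bool = False,
) -> MetabolicNetwork:
    """Return a copy of ``network`` with an irreversible sink for a metabolite.

    The demand reaction consumes exactly one unit ({met: -1}) with bounds
    [0, inf); its flux quantifies the network's capacity to produce the
    metabolite. Only extracellular metabolites (those that can appear in
    blood) are scoreable by default; pass ``allow_intracellular=True`` to
    override.
    """
    if metabolite_id not in network.metabolite_index:
        raise KeyError(f"unknown metabolite {metabolite_id!r}")
    met = network.metabolite(metabolite_id)
    if not met.extracellular and not allow_intracellular:
        raise ValueError(
            f"metabolite {metabolite_id!r} is not extracellular; "
            "pass allow_intracellular=True to add a demand anyway"
        )
    rxn = Reaction(
        id=demand_reaction_id(metabolite_id),
        stoichiometry={metabolite_id: -1.0},
        lower_bound=0.0,
        upper_bound=math.inf,
        gpr="",
        subsystem="demand",
    )
    if rxn.id in network.reaction_index:
        raise NetworkValidationError(f"demand reaction {rxn.id!r} already present")
    return MetabolicNetwork(list(network.metabolites), list(network.reactions) + [rxn])


# ---------------------------------------------------------------------------
# Network serialization (JSON schema + TSV pair)
# ---------------------------------------------------------------------------

def _bound_to_json(x: float):
    if x == math.inf:
        return "inf"
    if x == -math.inf:
        return "-inf"
    return x


def _bound_from_json(x) -> float:
    if isinstance(x, str):
        if x == "inf":
            return math.inf
        if x == "-inf":
            return -math.inf
        return float(x)
    return float(x)


def network_to_dict(network: MetabolicNetwork) -> dict:
    return {
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "extracellular": m.extracellular,
            }
            for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: v for k, v in r.stoichiometry.items()},
                "lower_bound": _bound_to_json(r.lower_bound),
                "upper_bound": _bound_to_json(r.upper_bound),
                "gpr": r.gpr,
                "subsystem": r.subsystem,
            }
            for r in network.reactions
        ],
    }


def network_from_dict(data: Mapping) -> MetabolicNetwork:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                extracellular=bool(m.get("extracellular", False)),
            )
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=_bound_from_json(r.get("lower_bound", 0.0)),
                upper_bound=_bound_from_json(r.get("upper_bound", "inf")),
                gpr=r.get("gpr", ""),
                subsystem=r.get("subsystem", ""),
            )
            for r in data["reactions"]
        ]
    except KeyError as exc:
        raise NetworkValidationError(f"missing required field {exc}") from exc
    return MetabolicNetwork(mets, rxns)


def write_network(network: MetabolicNetwork, path) -> None:
    """Write a network as JSON (``metabolites[]`` / ``reactions[]`` schema)."""
    Path(path).write_text(json.dumps(network_to_dict(network), indent=1) + "\n")


def read_network(path, format: str = "json") -> MetabolicNetwork:
    """Read and validate a network file.

    ``format="json"`` reads the documented JSON schema; ``format="tsv-pair"``
    reads ``<stem>.reactions.tsv`` + ``<stem>.stoich.tsv`` written by
    :func:`write_network_tsv`.
    """
    path = Path(path)
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise NetworkValidationError(f"malformed network JSON in {path}: {exc}") from exc
        return network_from_dict(data)
    if format == "tsv-pair":
        return read_network_tsv(path)
    raise ValueError(f"unknown network format {format!r}")


def write_network_tsv(network: MetabolicNetwork, stem) -> tuple[Path, Path]:
    """Write the TSV-pair representation.

    ``<stem>.reactions.tsv`` holds the reaction table (id, bounds, gpr,
    subsystem); ``<stem>.stoich.tsv`` holds stoichiometry triplets
    (reaction, metabolite, coefficient). Metabolite records are stored in the
    stoich file under the reserved reaction id ``#metabolite`` (coefficient
    1/0 encodes the extracellular flag).
    """
    stem = Path(stem)
    rxn_path = stem.with_suffix(".reactions.tsv")
    sto_path = stem.with_suffix(".stoich.tsv")
    pd.DataFrame(
        [
            {
                "id": r.id,
                "lower_bound": _bound_to_json(r.lower_bound),
                "upper_bound": _bound_to_json(r.upper_bound),
                "gpr": r.gpr,
                "subsystem": r.subsystem,
            }
            for r in network.reactions
        ]
    ).to_csv(rxn_path, sep="\t", index=False)
    rows = []
    for m in network.metabolites:
        rows.append(
            {
                "reaction": "#metabolite",
                "metabolite": m.id,
                "coefficient": 1.0 if m.extracellular else 0.0,
                "compartment": m.compartment,
                "name": m.name,
            }
        )
    for r in network.reactions:
        for met, coef in r.stoichiometry.items():
            rows.append(
                {
                    "reaction": r.id,
                    "metabolite": met,
                    "coefficient": coef,
                    "compartment": "",
                    "name": "",
                }
            )
    pd.DataFrame(rows).to_csv(sto_path, sep="\t", index=False)
    return rxn_path, sto_path


def read_network_tsv(stem) -> MetabolicNetwork:
    stem = Path(stem)
    rxn_df = pd.read_csv(stem.with_suffix(".reactions.tsv"), sep="\t", keep_default_na=False)
    sto_df = pd.read_csv(stem.with_suffix(".stoich.tsv"), sep="\t", keep_default_na=False)
    mets = []
    stoich: dict[str, dict[str, float]] = {}
    for row in sto_df.itertuples(index=False):
        if row.reaction == "#metabolite":
            mets.append(
                Metabolite(
                    id=row.metabolite,
                    name=str(row.name) if row.name else "",
                    compartment=str(row.compartment) or "c",
                    extracellular=bool(float(row.coefficient)),
                )
            )
        else:
            stoich.setdefault(row.reaction, {})[row.metabolite] = float(row.coefficient)
    rxns = [
        Reaction(
            id=row.id,
            stoichiometry=stoich.get(row.id, {}),
            lower_bound=_bound_from_json(row.lower_bound),
            upper_bound=_bound_from_json(row.upper_bound),
            gpr=str(row.gpr),
            subsystem=str(row.subsystem),
        )
        for row in rxn_df.itertuples(index=False)
    ]
    return MetabolicNetwork(mets, rxns)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named gene set: a KEGG-style pathway or a liver-injury module."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate genes")
        object.__setattr__(self, "genes", tuple(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


def read_gene_sets(path) -> list[GeneSet]:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are dropped (first occurrence kept) with a
    logged warning; a line with fewer than 3 fields is a parse error.
    """
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}: line {lineno}: GMT line needs name, description and "
                f"at least one gene ({len(fields)} fields found)"
            )
        name, description, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        unique = list(dict.fromkeys(genes))
        if len(unique) != len(genes):
            logger.warning(
                "%s: line %d (%s): %d duplicate gene(s) removed",
                path, lineno, name, len(genes) - len(unique),
            )
        sets.append(GeneSet(name=name, genes=tuple(unique), description=description))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path) -> None:
    lines = [
        "\t".join([s.name, s.description or "na", *s.genes]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")
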