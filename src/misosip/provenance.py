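"""Atom-level carbon provenance through biosynthetic pathway graphs.

A pathway is a directed acyclic set of reactions, each mapping every carbon
atom of its product to either a specific atom of a reactant compound or to
one of the source pools (methanol-derived methyl carbon, ``MEOH``, or
dissolved inorganic carbon, ``DIC``).  Propagating these maps in
topological order yields, for every compound, the fraction of each carbon
atom that originates from each source -- a purely stoichiometric accounting
with no flux or thermodynamic content.

Two pathway definitions ship with the package: the methanogen nucleotide
network (ribose-5-phosphate plus pyrimidine and purine bases) and the
archaeal isoprenoid lipid network (mevalonate route to GGPP and the
phytanyl side chains).  Their maps encode standard biosynthetic atom fates
for methylotrophic methanogens assimilating carbon via CODH/ACS.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import PathwayValidationError

BUNDLED_PATHWAYS = ("nucleotide_biosynthesis", "lipid_biosynthesis")


@dataclass(frozen=True)
class CompoundSpec:
    """A compound as an ordered list of carbon-atom slots."""

    name: str
    n_carbons: int

    def __post_init__(self):
        if self.n_carbons < 1:
            raise PathwayValidationError(
                f"compound {self.name!r}: carbon count must be >= 1"
            )


@dataclass(frozen=True)
class AtomMap:
    """One reaction: per-product-atom assignment plus explicitly lost atoms.

    Each entry of ``assignments`` is either a source id (str) or a
    ``(reactant_name, atom_index)`` pair; ``lost`` lists reactant atoms not
    carried into the product (e.g. a decarboxylated carboxyl).
    """

    product: str
    assignments: tuple
    lost: tuple = ()
    note: str = ""

    @property
    def reactants(self) -> set[str]:
        return {a[0] for a in self.assignments if not isinstance(a, str)} | {
            a[0] for a in self.lost
        }


@dataclass
class PathwayGraph:
    """Validated DAG of reactions over compounds and source pools."""

    compounds: dict[str, CompoundSpec]
    reactions: list[AtomMap]
    sources: tuple[str, ...]
    name: str = "pathway"

    def __post_init__(self):
        self._validate()

    def _validate(self):
        produced: dict[str, AtomMap] = {}
        for rxn in self.reactions:
            if rxn.product not in self.compounds:
                raise PathwayValidationError(
                    f"reaction for {rxn.product!r}: product not declared"
                )
            if rxn.product in produced:
                raise PathwayValidationError(
                    f"compound {rxn.product!r} produced by more than one reaction"
                )
            produced[rxn.product] = rxn
            n = self.compounds[rxn.product].n_carbons
            if len(rxn.assignments) != n:
                raise PathwayValidationError(
                    f"reaction for {rxn.product!r}: {len(rxn.assignments)} atom "
                    f"assignments for a {n}-carbon compound"
                )
            per_reactant: dict[str, Counter] = {}
            for a in tuple(rxn.assignments) + tuple(rxn.lost):
                if isinstance(a, str):
                    if a not in self.sources:
                        raise PathwayValidationError(
                            f"reaction for {rxn.product!r}: unknown source id {a!r}"
                        )
                    continue
                comp, idx = a
                if comp not in self.compounds:
                    raise PathwayValidationError(
                        f"reaction for {rxn.product!r}: unknown reactant {comp!r}"
                    )
                if not (0 <= idx < self.compounds[comp].n_carbons):
                    raise PathwayValidationError(
                        f"reaction for {rxn.product!r}: reactant atom "
                        f"{comp}[{idx}] does not exist"
                    )
                per_reactant.setdefault(comp, Counter())[idx] += 1
            # carbon conservation: the referenced atoms of each reactant must
            # form whole copies of that reactant's full atom set
            for comp, counts in per_reactant.items():
                n_inst = max(counts.values())
                full = Counter(
                    {i: n_inst for i in range(self.compounds[comp].n_carbons)}
                )
                if counts != full:
                    raise PathwayValidationError(
                        f"reaction for {rxn.product!r}: atoms of reactant "
                        f"{comp!r} are not fully accounted for "
                        f"(assignments + lost must cover {n_inst} whole "
                        "copies of the reactant)"
                    )
        missing = set(self.compounds) - set(produced)
        if missing:
            raise PathwayValidationError(
                f"compounds never produced by any reaction: {sorted(missing)}"
            )
        ts = TopologicalSorter(
            {rxn.product: rxn.reactants for rxn in self.reactions}
        )
        try:
            self._order = tuple(ts.static_order())
        except CycleError as e:
            raise PathwayValidationError(f"pathway contains a cycle: {e.args[1]}")

    @property
    def topological_order(self) -> tuple[str, ...]:
        return self._order


@dataclass(frozen=True)
class ProvenanceResult:
    """Per-atom and aggregate source fractions for every compound.

    ``atom_fractions[name]`` is an (n_atoms, n_sources) array whose rows sum
    to 1; columns follow ``sources`` order.
    """

    sources: tuple[str, ...]
    atom_fractions: dict[str, np.ndarray]

    def aggregate(self, compound: str) -> np.ndarray:
        """Mean source-fraction vector over the compound's atoms."""
        if compound not in self.atom_fractions:
            raise KeyError(f"unknown compound {compound!r}")
        return self.atom_fractions[compound].mean(axis=0)


def _parse_assignment(raw):
    if isinstance(raw, str):
        return raw
    comp, idx = raw
    return (str(comp), int(idx))


def load_pathway(path_or_name: str | Path) -> PathwayGraph:
    """Load and validate a pathway definition.

    Accepts a filesystem path to a JSON definition, or the name of a
    bundled network (``"nucleotide_biosynthesis"`` or
    ``"lipid_biosynthesis"``).
    """
    if isinstance(path_or_name, str) and path_or_name in BUNDLED_PATHWAYS:
        text = (
            resources.files("misosip.data")
            .joinpath(f"{path_or_name}.json")
            .read_text()
        )
    else:
        text = Path(path_or_name).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise PathwayValidationError(f"pathway file is not valid JSON: {e}")
    try:
        compounds = {
            c["name"]: CompoundSpec(c["name"], int(c["n_carbons"]))
            for c in doc["compounds"]
        }
        reactions = [
            AtomMap(
                product=r["product"],
                assignments=tuple(_parse_assignment(a) for a in r["assignments"]),
                lost=tuple(_parse_assignment(a) for a in r.get("lost", [])),
                note=r.get("note", ""),
            )
            for r in doc["reactions"]
        ]
        sources = tuple(doc["sources"])
    except (KeyError, TypeError, ValueError) as e:
        raise PathwayValidationError(f"malformed pathway document: {e!r}")
    return PathwayGraph(compounds, reactions, sources, doc.get("name", "pathway"))


def propagate(graph: PathwayGraph) -> ProvenanceResult:
    """Propagate source provenance through the graph in topological order.

    Each product atom inherits the provenance vector of its mapped reactant
    atom, or the pure unit vector of its source pool.  Deterministic; one
    pass over the reactions.
    """
    src_index = {s: i for i, s in enumerate(graph.sources)}
    n_src = len(graph.sources)
    vectors: dict[str, np.ndarray] = {}
    by_product = {r.product: r for r in graph.reactions}
    for name in graph.topological_order:
        rxn = by_product[name]
        rows = np.empty((len(rxn.assignments), n_src))
        for i, a in enumerate(rxn.assignments):
            if isinstance(a, str):
                row = np.zeros(n_src)
                row[src_index[a]] = 1.0
                rows[i] = row
            else:
                comp, idx = a
                rows[i] = vectors[comp][idx]
        vectors[name] = rows
    return ProvenanceResult(graph.sources, vectors)


def compound_source_fraction(result: ProvenanceResult, compound: str,
                             source: str) -> float:
    """Aggregate fraction of a compound's carbon from one source pool."""
    if source not in result.sources:
        raise KeyError(f"unknown source {source!r}")
    return float(result.aggregate(compound)[result.sources.index(source)])


def predict_fraction_13c(result: ProvenanceResult, compound: str,
                         pool_fractions: dict[str, float]) -> float:
    """Predicted bulk fractional 13C abundance of a compound.

    ``pool_fractions`` maps each source id to its fractional abundance F.
    The prediction is affine in each source F; with all pools equal it
    returns that common value.
    """
    missing = set(result.sources) - set(pool_fractions)
    if missing:
        raise KeyError(f"pool_fractions missing sources: {sorted(missing)}")
    agg = result.aggregate(compound)
    return float(sum(agg[i] * pool_fractions[s]
                     for i, s in enumerate(result.sources)))


def aggregate_macromolecule(result: ProvenanceResult,
                            composition: list[tuple[str, int]],
                            source: str = "MEOH") -> float:
    """Carbon-weighted source fraction of a macromolecule.

    ``composition`` lists (compound, count) pairs, e.g. a mean
    ribonucleotide as ribose plus a base; the result is the mean over all
    carbon atoms of all constituent compounds.
    """
    if not composition:
        raise ValueError("empty macromolecule composition")
    if source not in result.sources:
        raise KeyError(f"unknown source {source!r}")
    j = result.sources.index(source)
    num = 0.0
    den = 0.0
    for compound, count in composition:
        if count < 1:
            raise ValueError(f"count for {compound!r} must be >= 1")
        atoms = result.atom_fractions.get(compound)
        if atoms is None:
            raise KeyError(f"unknown compound {compound!r}")
        num += count * atoms[:, j].sum()
        den += count * atoms.shape[0]
    return num / den
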