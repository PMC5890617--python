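"""The PARITY similarity score and Markush R-group instantiation.

PARITY (Proportion of Atoms Residing in Identical Topology) compares a
bound ligand B against a cognate ligand C by finding the maximum common
substructure on the most permissive basis — any atom may match any atom,
any bond any bond — and then counting, over the best such mapping, the
number N_sim of mapped atom pairs whose element symbols agree.  The
score is a Tanimoto-style intersection over union:

    S = I / U = N_sim / (N_B + N_C - N_sim)

with N_B, N_C the heavy-atom counts of the two molecules.  Because the
mapping itself ignores atom identity, a single element change in the
middle of a molecule lowers the score only slightly, instead of
shattering the common substructure the way a strict (element-matched)
MCS does; ``strict_mcs_score`` computes that strict variant for
comparison.

"Same type" means same element symbol: formal charge and aromaticity do
not take part in agreement counting, and bond orders are never compared.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

from .mcs import (
    DEFAULT_NODE_BUDGET,
    DEFAULT_TIME_BUDGET,
    best_common_subgraph,
    enumerate_max_common_subgraphs,
)
from .molecule import Atom, Molecule

logger = logging.getLogger(__name__)

__all__ = [
    "MappingSource",
    "AtomMapping",
    "SimilarityResult",
    "permissive_mcs",
    "parity_score",
    "strict_mcs_score",
    "substitute_r_group",
    "round_half_up",
]


class MappingSource(enum.Enum):
    PERMISSIVE_MCS = "permissive_mcs"
    STRICT_MCS = "strict_mcs"


@dataclass(frozen=True)
class AtomMapping:
    """Injective atom correspondence (index in B, index in C)."""

    pairs: tuple[tuple[int, int], ...]
    source: MappingSource

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SimilarityResult:
    """PARITY score with its components and the winning mapping."""

    score: float
    n_b: int
    n_c: int
    n_sim: int
    mapping: AtomMapping
    truncated: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_sim <= max(min(self.n_b, self.n_c), 0):
            raise ValueError(f"n_sim={self.n_sim} outside [0, min(n_b, n_c)]")

    @property
    def intersection(self) -> int:
        """I, the numerator of the Tanimoto formula."""
        return self.n_sim

    @property
    def union(self) -> int:
        """U = N_B + N_C - N_sim, the denominator."""
        return self.n_b + self.n_c - self.n_sim

    @property
    def rounded(self) -> float:
        """Score at 2-decimal reporting precision (half-up)."""
        return round_half_up(self.score, 2)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with halves away from zero (0.875 -> 0.88)."""
    scale = 10 ** ndigits
    return math.floor(x * scale + 0.5 + 1e-9) / scale


def _check_args(b: Molecule, c: Molecule) -> None:
    for m in (b, c):
        if m.is_empty:
            raise ValueError(f"molecule {m.id!r} is empty")
        if m.is_markush:
            raise ValueError(
                f"molecule {m.id!r} has R-group atoms; apply substitute_r_group first"
            )


def permissive_mcs(
    b: Molecule,
    c: Molecule,
    *,
    cap: int = 1000,
    node_budget: int = DEFAULT_NODE_BUDGET,
    time_budget: float | None = DEFAULT_TIME_BUDGET,
) -> list[AtomMapping]:
    """All maximum permissive (topology-only) MCS mappings, up to ``cap``."""
    _check_args(b, c)
    mappings, truncated = enumerate_max_common_subgraphs(
        b.elements, b.adjacency(), c.elements, c.adjacency(),
        element_match=False, cap=cap,
        node_budget=node_budget, time_budget=time_budget,
    )
    if truncated:
        logger.warning(
            "permissive MCS %s vs %s: enumeration truncated at %d mappings",
            b.id, c.id, cap,
        )
    return [AtomMapping(p, MappingSource.PERMISSIVE_MCS) for p in mappings]


def _score(b: Molecule, c: Molecule, *, element_match: bool,
           node_budget: int, time_budget: float | None,
           connected: bool) -> SimilarityResult:
    _check_args(b, c)
    source = MappingSource.STRICT_MCS if element_match else MappingSource.PERMISSIVE_MCS
    if not connected:
        # disconnected matching: any injective assignment is a common
        # subgraph, so the optimum is counting shared elements
        counts_b = b.element_multiset()
        counts_c = c.element_multiset()
        n_sim = sum(min(n, counts_c.get(e, 0)) for e, n in counts_b.items())
        size = min(b.n_atoms, c.n_atoms)
        if element_match:
            size = n_sim
        score = n_sim / (b.n_atoms + c.n_atoms - n_sim) if n_sim else 0.0
        return SimilarityResult(score, b.n_atoms, c.n_atoms, n_sim,
                                AtomMapping((), source))
    out = best_common_subgraph(
        b.elements, b.adjacency(), c.elements, c.adjacency(),
        element_match=element_match,
        agreement_objective=not element_match,
        node_budget=node_budget, time_budget=time_budget,
    )
    n_sim = out.size if element_match else out.agree
    denom = b.n_atoms + c.n_atoms - n_sim
    score = n_sim / denom if denom else 0.0
    return SimilarityResult(
        score=score, n_b=b.n_atoms, n_c=c.n_atoms, n_sim=n_sim,
        mapping=AtomMapping(out.pairs, source), truncated=out.truncated,
    )


def parity_score(
    b: Molecule,
    c: Molecule,
    *,
    node_budget: int = DEFAULT_NODE_BUDGET,
    time_budget: float | None = DEFAULT_TIME_BUDGET,
    connected: bool = True,
) -> SimilarityResult:
    """PARITY similarity of bound molecule ``b`` and cognate ``c``.

    N_sim is the maximum number of element-agreeing mapped pairs over
    every connected permissive common-substructure mapping (including
    all maximum mappings and their automorphisms), which makes the score
    well defined, symmetric in its arguments, and never smaller than the
    strict-MCS score, whose mapping is always a feasible candidate.
    """
    return _score(b, c, element_match=False,
                  node_budget=node_budget, time_budget=time_budget,
                  connected=connected)


def strict_mcs_score(
    b: Molecule,
    c: Molecule,
    *,
    node_budget: int = DEFAULT_NODE_BUDGET,
    time_budget: float | None = DEFAULT_TIME_BUDGET,
    connected: bool = True,
) -> SimilarityResult:
    """Same Tanimoto formula but mapped atoms must share an element.

    Bond orders remain permissive.  Provided for comparison only; it is
    the score that collapses under a single central-atom change.
    """
    return _score(b, c, element_match=True,
                  node_budget=node_budget, time_budget=time_budget,
                  connected=connected)


# ---------------------------------------------------------------------------
# Markush (R-group) handling


def _connected_components(n: int, adj: list[set[int]], keep: set[int]) -> list[set[int]]:
    comps: list[set[int]] = []
    seen: set[int] = set()
    for start in sorted(keep):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        seen.add(start)
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y in keep and y not in seen:
                    seen.add(y)
                    comp.add(y)
                    stack.append(y)
        comps.append(comp)
    return comps


def _drop_r_atoms(cognate: Molecule) -> tuple[Molecule, list[tuple[int, list[int]]]]:
    """Core molecule without R atoms + (r_atom, core neighbours) records."""
    adj = cognate.adjacency()
    core_old = [a.index for a in cognate.atoms if not a.is_r_group]
    remap = {old: new for new, old in enumerate(core_old)}
    atoms = tuple(
        Atom(index=remap[a.index], element_kind=a.element_kind,
             formal_charge=a.formal_charge)
        for a in cognate.atoms if not a.is_r_group
    )
    bonds = tuple(
        (min(remap[i], remap[j]), max(remap[i], remap[j]), order)
        for i, j, order in cognate.bonds
        if i in remap and j in remap
    )
    attachments = []
    for a in cognate.atoms:
        if a.is_r_group:
            neighbours = sorted(remap[x] for x in adj[a.index] if x in remap)
            attachments.append((a.index, neighbours))
    return Molecule(cognate.id, atoms, bonds), attachments


def substitute_r_group(
    cognate: Molecule,
    bound: Molecule,
    *,
    cap: int = 500,
    node_budget: int = DEFAULT_NODE_BUDGET,
    time_budget: float | None = DEFAULT_TIME_BUDGET,
) -> Molecule:
    """Instantiate a Markush cognate against a concrete bound molecule.

    The non-R core of the cognate is anchored into the bound molecule by
    an element-agreeing common-substructure match; for each R atom, the
    bound fragment(s) hanging off the image of its attachment atom —
    bound atoms not consumed by the match — are grafted in place of R.
    Among equally large anchor mappings the one grafting the most atoms
    is used.  An R whose attachment cannot be placed is deleted (treated
    as hydrogen).  The result carries id ``<cognate>~<bound>``.
    """
    if not cognate.is_markush:
        raise ValueError(f"cognate {cognate.id!r} has no R-group atom")
    if bound.is_markush:
        raise ValueError(f"bound molecule {bound.id!r} must not be a Markush structure")
    out_id = f"{cognate.id}~{bound.id}"

    core, attachments = _drop_r_atoms(cognate)
    if core.is_empty or bound.is_empty:
        return core.with_id(out_id)

    mappings, _trunc = enumerate_max_common_subgraphs(
        core.elements, core.adjacency(), bound.elements, bound.adjacency(),
        element_match=True, cap=cap,
        node_budget=node_budget, time_budget=time_budget,
    )
    if not mappings:
        return core.with_id(out_id)

    bound_adj = bound.adjacency()
    bound_bonds = {(i, j) for i, j, _ in bound.bonds}

    def faithful(pairs: tuple[tuple[int, int], ...]) -> bool:
        # every core bond between mapped atoms must exist in the bound
        # molecule, otherwise grafting can invent topology neither
        # molecule has (the match is non-induced, so this can happen)
        fwd = dict(pairs)
        for i, j, _ in core.bonds:
            if i in fwd and j in fwd:
                key = (min(fwd[i], fwd[j]), max(fwd[i], fwd[j]))
                if key not in bound_bonds:
                    return False
        return True

    def graft_plan(pairs: tuple[tuple[int, int], ...]):
        fwd = dict(pairs)            # core index -> bound index
        matched_bound = set(fwd.values())
        unmatched = set(range(bound.n_atoms)) - matched_bound
        comps = _connected_components(bound.n_atoms, bound_adj, unmatched)
        claimed: list[set[int]] = []
        taken: set[int] = set()
        for _r, neighbours in attachments:
            images = {fwd[n] for n in neighbours if n in fwd}
            for comp in comps:
                if comp & taken:
                    continue
                if any(bound_adj[x] & images for x in comp):
                    claimed.append(comp)
                    taken |= comp
        return fwd, sorted(taken)

    best_pairs = None
    best_key = (-1, -1)
    for pairs in mappings:
        _fwd, grafted = graft_plan(pairs)
        key = (1 if faithful(pairs) else 0, len(grafted))
        if key > best_key:
            best_key = key
            best_pairs = pairs
    assert best_pairs is not None
    fwd, grafted = graft_plan(best_pairs)

    # assemble: core atoms keep their order, grafted bound atoms appended
    atoms = list(core.atoms)
    graft_remap: dict[int, int] = {}
    for bidx in grafted:
        src = bound.atoms[bidx]
        graft_remap[bidx] = len(atoms)
        atoms.append(Atom(index=len(atoms), element_kind=src.element_kind,
                          formal_charge=src.formal_charge))

    rev = {v: k for k, v in fwd.items()}  # bound index -> core index
    bonds = {(i, j): order for i, j, order in core.bonds}
    for i, j, order in bound.bonds:
        gi, gj = i in graft_remap, j in graft_remap
        if gi and gj:
            a, b_ = graft_remap[i], graft_remap[j]
        elif gi and j in rev:
            a, b_ = graft_remap[i], rev[j]
        elif gj and i in rev:
            a, b_ = rev[i], graft_remap[j]
        else:
            continue
        key = (min(a, b_), max(a, b_))
        bonds.setdefault(key, order)

    return Molecule(
        out_id,
        tuple(atoms),
        tuple(sorted((i, j, order) for (i, j), order in bonds.items())),
    )
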