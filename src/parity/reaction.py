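"""Reaction-level aggregation of PARITY scores.

A structure's bound ligands are compared against one side of a reaction
(its cognate reactants, or its cognate products) by greedy matching on
the pairwise PARITY matrix: the highest-scoring unmatched (cognate,
bound) pair is matched repeatedly until one set is exhausted.  Surplus
bound ligands are discarded; cognates left without a partner count as
matched to an empty molecule and contribute I = 0, U = N_C.  The side
score is then

    S_side = sum_m I_{C_m B_m} / sum_m U_{C_m B_m}

and the reaction score is the better of the two sides, with the side
(r or p) recorded.  Water, protons and dihydrogen are dropped from the
cognate lists before matching, since crystallographic water is solvent
and hydrogen positions are unresolved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .molecule import Molecule
from .score import (
    AtomMapping,
    MappingSource,
    SimilarityResult,
    parity_score,
    substitute_r_group,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_EXCLUDED_COGNATES",
    "Reaction",
    "BoundLigandSet",
    "MatchedPair",
    "ReactionMatchResult",
    "filter_cognates",
    "pairwise_score",
    "greedy_match",
    "combined_side_score",
    "score_reaction",
    "bin_score",
]

#: KEGG compounds never used as cognate match targets: water, proton, H2
DEFAULT_EXCLUDED_COGNATES = frozenset({"C00001", "C00080", "C00282"})


@dataclass(frozen=True)
class Reaction:
    """Cognate compounds on each side of a catalysed reaction."""

    id: str
    reactants: tuple[Molecule, ...]
    products: tuple[Molecule, ...]

    def side(self, label: str) -> tuple[Molecule, ...]:
        if label == "r":
            return self.reactants
        if label == "p":
            return self.products
        raise ValueError(f"side must be 'r' or 'p', got {label!r}")


@dataclass(frozen=True)
class BoundLigandSet:
    """Non-polymer components observed in one structure."""

    structure_id: str
    ligands: tuple[Molecule, ...] = ()

    @property
    def is_empty(self) -> bool:
        return not self.ligands


@dataclass(frozen=True)
class MatchedPair:
    """One cognate slot: its bound partner (or None) and the pair score."""

    bound_id: str | None
    cognate_id: str
    result: SimilarityResult

    @property
    def is_unmatched(self) -> bool:
        return self.bound_id is None


@dataclass(frozen=True)
class ReactionMatchResult:
    side: str                              # "r" or "p"
    pairs: tuple[MatchedPair, ...]
    combined_score: float
    none_bound: bool
    both_sides_empty: bool = False
    structure_id: str = ""
    reaction_id: str = ""


def filter_cognates(
    side: Sequence[Molecule],
    excluded: frozenset[str] | set[str] = DEFAULT_EXCLUDED_COGNATES,
) -> list[Molecule]:
    """Drop excluded cognate species (water/proton/dihydrogen by default)."""
    return [m for m in side if m.id not in excluded]


def _effective_atom_count(m: Molecule) -> int:
    """Heavy atoms excluding R placeholders (used for unmatched cognates)."""
    return sum(1 for a in m.atoms if not a.is_r_group)


def _unmatched_result(cognate: Molecule) -> SimilarityResult:
    n_c = _effective_atom_count(cognate)
    return SimilarityResult(
        score=0.0, n_b=0, n_c=n_c, n_sim=0,
        mapping=AtomMapping((), MappingSource.PERMISSIVE_MCS),
    )


def pairwise_score(bound: Molecule, cognate: Molecule, **kwargs) -> SimilarityResult:
    """PARITY for one (bound, cognate) pair, instantiating Markush cognates.

    R-group substitution happens here, per pair, so different bound
    ligands can instantiate the same generic cognate differently.
    Degenerate pairs (an empty molecule on either side) score 0.
    """
    if cognate.is_markush:
        cognate = substitute_r_group(cognate, bound, **kwargs)
    if bound.is_empty or cognate.is_empty:
        return SimilarityResult(
            score=0.0, n_b=bound.n_atoms, n_c=cognate.n_atoms, n_sim=0,
            mapping=AtomMapping((), MappingSource.PERMISSIVE_MCS),
        )
    return parity_score(bound, cognate, **kwargs)


def greedy_match(
    bound: BoundLigandSet,
    cognates: Sequence[Molecule],
    **kwargs,
) -> list[MatchedPair]:
    """Greedy assignment: always match the next most similar pair.

    Ties are broken toward the cognate with more heavy atoms, then the
    lexicographically smaller cognate ID, then the smaller bound ID.
    Pairs scoring 0 are never matched, so their cognates stay unmatched
    and their bound ligands are discarded.  Duplicate cognate compounds
    are separate slots, each needing its own bound partner.
    """
    matrix: dict[tuple[int, int], SimilarityResult] = {}
    for ci, cognate in enumerate(cognates):
        for bi, ligand in enumerate(bound.ligands):
            matrix[(ci, bi)] = pairwise_score(ligand, cognate, **kwargs)

    order = sorted(
        matrix,
        key=lambda k: (
            -matrix[k].score,
            -_effective_atom_count(cognates[k[0]]),
            cognates[k[0]].id,
            bound.ligands[k[1]].id,
            k[0],
            k[1],
        ),
    )
    assigned: dict[int, tuple[int, SimilarityResult]] = {}
    used_bound: set[int] = set()
    for ci, bi in order:
        res = matrix[(ci, bi)]
        if res.score <= 0:
            break
        if ci in assigned or bi in used_bound:
            continue
        assigned[ci] = (bi, res)
        used_bound.add(bi)

    pairs: list[MatchedPair] = []
    matched_order = sorted(assigned, key=lambda ci: (-assigned[ci][1].score, ci))
    for ci in matched_order:
        bi, res = assigned[ci]
        pairs.append(MatchedPair(bound.ligands[bi].id, cognates[ci].id, res))
    for ci, cognate in enumerate(cognates):
        if ci not in assigned:
            pairs.append(MatchedPair(None, cognate.id, _unmatched_result(cognate)))
    return pairs


def combined_side_score(pairs: Sequence[MatchedPair]) -> float:
    """Sum of intersections over sum of unions across all cognate slots."""
    if not pairs:
        logger.warning("combined_side_score called with no pairs")
        return 0.0
    total_i = sum(p.result.intersection for p in pairs)
    total_u = sum(p.result.union for p in pairs)
    return total_i / total_u if total_u else 0.0


def score_reaction(
    bound: BoundLigandSet,
    reaction: Reaction,
    excluded: frozenset[str] | set[str] = DEFAULT_EXCLUDED_COGNATES,
    **kwargs,
) -> ReactionMatchResult:
    """Score bound ligands against both reaction sides; keep the better.

    A tie between sides reports side "r".  A side left empty by the
    exclusion filter is skipped with a warning; if both sides empty the
    result carries ``both_sides_empty`` and score 0.
    """
    none_bound = bound.is_empty
    candidates: list[ReactionMatchResult] = []
    for label in ("r", "p"):
        cognates = filter_cognates(reaction.side(label), excluded)
        if not cognates:
            logger.warning(
                "reaction %s: side %s empty after cognate filtering, skipped",
                reaction.id, label,
            )
            continue
        pairs = tuple(greedy_match(bound, cognates, **kwargs))
        candidates.append(
            ReactionMatchResult(
                side=label,
                pairs=pairs,
                combined_score=combined_side_score(pairs),
                none_bound=none_bound,
                structure_id=bound.structure_id,
                reaction_id=reaction.id,
            )
        )
    if not candidates:
        return ReactionMatchResult(
            side="r", pairs=(), combined_score=0.0, none_bound=none_bound,
            both_sides_empty=True,
            structure_id=bound.structure_id, reaction_id=reaction.id,
        )
    # max by score; stable order (r first) resolves ties toward r
    best = candidates[0]
    for cand in candidates[1:]:
        if cand.combined_score > best.combined_score:
            best = cand
    return best


def bin_score(s: float) -> float:
    """Round a score to the nearest multiple of 0.05 (halves round up)."""
    if not (0.0 <= s <= 1.0) or math.isnan(s):
        raise ValueError(f"score {s!r} outside [0, 1]")
    return math.floor(s * 20 + 0.5 + 1e-9) / 20
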