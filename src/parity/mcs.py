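"""Connected maximum-common-substructure search.

The matcher treats both molecules as unlabelled graphs: any atom may map
to any atom and any bond to any bond (the "most permissive" policy), or,
in strict mode, mapped atoms must share an element symbol (bond orders
are never compared).  The common substructure is the standard
*non-induced* connected common subgraph: a mapped bond must exist in
both molecules, but an unmapped bond on one side does not block a match.

Search is a branch-and-bound over atom pairs.  A mapping is grown from a
root pair (its lexicographically smallest pair, which makes every
mapping reachable exactly once) by repeatedly branching on the smallest
candidate pair that would extend the common subgraph while staying
connected: either include it, or exclude it from the whole subtree.  The
objective is lexicographic — first mapping cardinality, then the number
of mapped pairs whose elements agree — which is exactly what the PARITY
score needs: the best element agreement over all maximum permissive
mappings.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence

__all__ = ["MCSOutcome", "best_common_subgraph", "enumerate_max_common_subgraphs"]

#: default cap on search-tree nodes before giving up with best-so-far
DEFAULT_NODE_BUDGET = 5_000_000
#: default per-pair wall-clock budget in seconds
DEFAULT_TIME_BUDGET = 60.0


@dataclass(frozen=True)
class MCSOutcome:
    """Best mapping found: cardinality, element agreements, atom pairs."""

    size: int
    agree: int
    pairs: tuple[tuple[int, int], ...]
    truncated: bool = False


class _BudgetExceeded(Exception):
    pass


class _Search:
    def __init__(
        self,
        elems_b: Sequence[str],
        adj_b: Sequence[set[int]],
        elems_c: Sequence[str],
        adj_c: Sequence[set[int]],
        *,
        element_match: bool,
        enumerate_all: bool,
        agreement_objective: bool,
        cap: int,
        node_budget: int,
        time_budget: float | None,
    ):
        self.elems_b = elems_b
        self.adj_b = adj_b
        self.elems_c = elems_c
        self.adj_c = adj_c
        self.nB = len(elems_b)
        self.nC = len(elems_c)
        self.element_match = element_match
        self.enumerate_all = enumerate_all
        # True: maximise element agreements over ALL connected mappings
        # (the PARITY objective); False: maximise mapping cardinality
        self.agreement_objective = agreement_objective
        self.cap = cap
        self.node_budget = node_budget
        self.deadline = time.monotonic() + time_budget if time_budget else None
        self.nodes = 0
        self.truncated = False
        self.best: tuple[int, int, tuple[tuple[int, int], ...]] = (0, -1, ())
        self.collected: list[tuple[tuple[int, int], ...]] = []
        # mutable search state
        self.mapping: list[tuple[int, int]] = []
        self.used_b = [False] * self.nB
        self.used_c = [False] * self.nC

    # -- bookkeeping -------------------------------------------------------

    def _tick(self) -> None:
        self.nodes += 1
        if self.nodes > self.node_budget:
            self.truncated = True
            raise _BudgetExceeded
        if self.deadline is not None and self.nodes % 2048 == 0:
            if time.monotonic() > self.deadline:
                self.truncated = True
                raise _BudgetExceeded

    def _key(self, size: int, agree: int) -> tuple[int, int]:
        return (agree, size) if self.agreement_objective else (size, agree)

    def _record(self, agree: int) -> None:
        size = len(self.mapping)
        if self._key(size, agree) > self._key(self.best[0], self.best[1]):
            self.best = (size, agree, tuple(self.mapping))
        if self.enumerate_all and size > 0:
            if self.collected and size > len(self.collected[0]):
                self.collected = []
            if not self.collected or size == len(self.collected[0]):
                if len(self.collected) < self.cap:
                    self.collected.append(tuple(self.mapping))
                else:
                    self.truncated = True

    # -- core recursion ----------------------------------------------------

    def _candidates(self, root_u: int, excluded: frozenset[tuple[int, int]]) -> list[tuple[int, int]]:
        out = []
        for u in range(root_u + 1, self.nB):
            if self.used_b[u]:
                continue
            b_neigh = self.adj_b[u]
            images: set[int] = set()
            for x, y in self.mapping:
                if x in b_neigh:
                    images |= self.adj_c[y]
            for v in sorted(images):
                if self.used_c[v]:
                    continue
                if self.element_match and self.elems_b[u] != self.elems_c[v]:
                    continue
                if (u, v) in excluded:
                    continue
                out.append((u, v))
        return out

    def _prune(self, agree: int, root_u: int) -> bool:
        size = len(self.mapping)
        free_b = sum(1 for u in range(root_u + 1, self.nB) if not self.used_b[u])
        rem = min(free_b, self.nC - size)
        if self.enumerate_all:
            return size + rem < self.best[0]
        return self._key(size + rem, agree + rem) <= self._key(self.best[0], self.best[1])

    def _extend(self, agree: int, root_u: int, excluded: frozenset[tuple[int, int]]) -> None:
        self._tick()
        self._record(agree)
        if self._prune(agree, root_u):
            return
        cands = self._candidates(root_u, excluded)
        banned: set[tuple[int, int]] = set()
        for u, v in cands:
            if self._prune(agree, root_u):
                return
            self.mapping.append((u, v))
            self.used_b[u] = True
            self.used_c[v] = True
            gain = 1 if self.elems_b[u] == self.elems_c[v] else 0
            self._extend(agree + gain, root_u, excluded | frozenset(banned))
            self.mapping.pop()
            self.used_b[u] = False
            self.used_c[v] = False
            banned.add((u, v))

    def run(self) -> None:
        try:
            for ru in range(self.nB):
                # a root can anchor at most nB - ru atoms (and agreements)
                if not self.enumerate_all:
                    target = self.best[1] if self.agreement_objective else self.best[0]
                    if self.nB - ru < target:
                        break
                if self.enumerate_all and self.collected and self.nB - ru < len(self.collected[0]):
                    break
                for rv in range(self.nC):
                    if self.element_match and self.elems_b[ru] != self.elems_c[rv]:
                        continue
                    self.mapping.append((ru, rv))
                    self.used_b[ru] = True
                    self.used_c[rv] = True
                    gain = 1 if self.elems_b[ru] == self.elems_c[rv] else 0
                    self._extend(gain, ru, frozenset())
                    self.mapping.pop()
                    self.used_b[ru] = False
                    self.used_c[rv] = False
        except _BudgetExceeded:
            pass


def best_common_subgraph(
    elems_b: Sequence[str],
    adj_b: Sequence[set[int]],
    elems_c: Sequence[str],
    adj_c: Sequence[set[int]],
    *,
    element_match: bool = False,
    agreement_objective: bool = False,
    node_budget: int = DEFAULT_NODE_BUDGET,
    time_budget: float | None = DEFAULT_TIME_BUDGET,
) -> MCSOutcome:
    """Best connected common subgraph.

    With ``agreement_objective`` the search maximises the number of
    element-agreeing mapped pairs over all connected common subgraphs
    (the PARITY objective); otherwise it maximises cardinality, breaking
    ties by agreement.
    """
    if not elems_b or not elems_c:
        return MCSOutcome(0, 0, ())
    s = _Search(
        elems_b, adj_b, elems_c, adj_c,
        element_match=element_match, enumerate_all=False,
        agreement_objective=agreement_objective, cap=0,
        node_budget=node_budget, time_budget=time_budget,
    )
    s.run()
    size, agree, pairs = s.best
    return MCSOutcome(size, max(agree, 0), pairs, s.truncated)


def enumerate_max_common_subgraphs(
    elems_b: Sequence[str],
    adj_b: Sequence[set[int]],
    elems_c: Sequence[str],
    adj_c: Sequence[set[int]],
    *,
    element_match: bool = False,
    cap: int = 1000,
    node_budget: int = DEFAULT_NODE_BUDGET,
    time_budget: float | None = DEFAULT_TIME_BUDGET,
) -> tuple[list[tuple[tuple[int, int], ...]], bool]:
    """All maximum-cardinality mappings (deterministic order, up to cap)."""
    if not elems_b or not elems_c:
        return [], False
    s = _Search(
        elems_b, adj_b, elems_c, adj_c,
        element_match=element_match, enumerate_all=True,
        agreement_objective=False, cap=cap,
        node_budget=node_budget, time_budget=time_budget,
    )
    s.run()
    return s.collected, s.truncated
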