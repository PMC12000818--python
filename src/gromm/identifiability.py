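"""Executable identifiability checkers for the dimension-grouped model.

The model parameters ``(L, Lambda, Phi)`` are identifiable from the observed
response distribution under rank conditions on the conditional probability
tables, with two regimes:

* **strict, per-item**: every group contains at least three items whose
  ``d_j x K`` table has full column rank ``K``; if additionally no item has
  all columns identical, the grouping ``L`` is identified too;
* **strict, Khatri-Rao**: each group's items can be split into three parts
  whose Khatri-Rao-product tables ``⊙_{j in part} Lambda_j`` have full
  column rank ``K`` — this allows ``d_j < K``;
* **generic**: it suffices that each part's category-count product
  ``prod_{j in part} d_j`` reaches ``K``; the rank condition then holds for
  all parameter values outside a Lebesgue-measure-zero set.

The checkers operate on concrete (fitted or simulated) parameter values and
report numerical column ranks, so they serve as preflight diagnostics rather
than symbolic proofs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model_core import Grouping, ItemDomain, ItemProbTables, khatri_rao_chain

__all__ = [
    "PartitionPlan",
    "CheckReport",
    "numerical_rank",
    "has_distinct_columns",
    "check_strict",
    "check_krp",
    "check_generic",
    "find_partition",
]

#: default relative tolerance on singular values for numerical rank
DEFAULT_RANK_TOL = 1e-8


@dataclass(frozen=True)
class PartitionPlan:
    """Per-group split of the group's items into three disjoint parts.

    ``parts[g]`` is a triple of item-index tuples whose union must be exactly
    the set of items assigned to group ``g``.
    """

    parts: tuple[tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]], ...]

    def __init__(self, parts: Sequence[Sequence[Sequence[int]]]):
        norm = tuple(
            tuple(tuple(int(j) for j in part) for part in triple)
            for triple in parts)
        for g, triple in enumerate(norm):
            if len(triple) != 3:
                raise ValueError(f"group {g} needs exactly three parts")
            flat = [j for part in triple for j in part]
            if len(flat) != len(set(flat)):
                raise ValueError(f"group {g} has overlapping parts")
        object.__setattr__(self, "parts", norm)

    @property
    def G(self) -> int:
        return len(self.parts)

    def validate_against(self, grouping: Grouping) -> None:
        if self.G != grouping.G:
            raise ValueError(f"plan covers {self.G} groups, grouping has {grouping.G}")
        for g, triple in enumerate(self.parts):
            members = set(j for part in triple for j in part)
            expected = set(grouping.items_in(g).tolist())
            if members != expected:
                raise ValueError(
                    f"plan for group {g} covers items {sorted(members)} but the "
                    f"group contains {sorted(expected)}")


@dataclass
class CheckReport:
    """Outcome of an identifiability check.

    ``passed`` is the conjunction of every condition the check evaluated.
    ``lambda_phi_ok`` flags the conditions identifying the continuous
    parameters ``(Lambda, Phi)``; ``l_ok`` flags the extra per-item
    distinct-columns condition needed to also identify the grouping ``L``
    (and with it the Dirichlet concentrations when ``G >= 2``).
    """

    passed: bool
    lambda_phi_ok: bool
    l_ok: Optional[bool] = None
    details: dict = field(default_factory=dict)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def numerical_rank(M: np.ndarray, rank_tol: float = DEFAULT_RANK_TOL) -> int:
    """Number of singular values exceeding ``rank_tol`` times the largest."""
    M = np.asarray(M, dtype=float)
    sv = np.linalg.svd(M, compute_uv=False)
    if sv.size == 0 or sv[0] == 0.0:
        return 0
    return int(np.sum(sv > rank_tol * sv[0]))


def has_distinct_columns(M: np.ndarray, tol: float = DEFAULT_RANK_TOL) -> bool:
    """True unless every pair of columns agrees entrywise within ``tol``."""
    M = np.asarray(M, dtype=float)
    K = M.shape[1]
    if K < 2:  # vacuous with a single column
        return True
    for a, b in itertools.combinations(range(K), 2):
        if np.abs(M[:, a] - M[:, b]).max() > tol:
            return True
    return False


def _distinct_all_items(tables: ItemProbTables, tol: float) -> tuple[bool, list]:
    offending = [j for j in range(tables.p)
                 if not has_distinct_columns(tables[j], tol)]
    return len(offending) == 0, offending


def check_strict(grouping: Grouping, tables: ItemProbTables,
                 rank_tol: float = DEFAULT_RANK_TOL) -> CheckReport:
    """Per-item full-rank conditions for strict identifiability.

    Condition (a): every group contains at least three items whose table has
    numerical column rank ``K`` — identifies ``(Lambda, Phi)``.  Condition
    (b): no item's table has all columns identical — together with (a) it
    identifies the grouping ``L`` as well.  ``passed`` requires both;
    the two flags are reported separately.
    """
    K = tables.K
    per_group = {}
    a_ok = True
    for g in range(grouping.G):
        items = grouping.items_in(g)
        ranks = {int(j): numerical_rank(tables[j], rank_tol) for j in items}
        full = [j for j, r in ranks.items() if r == K]
        per_group[g] = {"items": items.tolist(), "full_rank_items": full,
                        "ranks": ranks}
        if len(full) < 3:
            a_ok = False
    b_ok, offending = _distinct_all_items(tables, rank_tol)
    return CheckReport(
        passed=a_ok and b_ok, lambda_phi_ok=a_ok, l_ok=b_ok,
        details={"groups": per_group, "identical_column_items": offending,
                 "K": K})


def check_krp(grouping: Grouping, tables: ItemProbTables, plan: PartitionPlan,
              rank_tol: float = DEFAULT_RANK_TOL) -> CheckReport:
    """Khatri-Rao-product rank conditions for strict identifiability.

    For every group ``g`` and part ``m`` of the supplied partition plan, the
    chained Khatri-Rao product of the part's tables must have numerical
    column rank ``K``; every item must additionally pass the
    distinct-columns check for the grouping to be identified.
    """
    plan.validate_against(grouping)
    K = tables.K
    ranks_ok = True
    part_info = {}
    for g, triple in enumerate(plan.parts):
        for m, part in enumerate(triple):
            if len(part) == 0:
                ranks_ok = False
                part_info[(g, m)] = {"items": [], "rank": 0, "rows": 0}
                continue
            krp = khatri_rao_chain([tables[j] for j in part])
            r = numerical_rank(krp, rank_tol)
            part_info[(g, m)] = {"items": list(part), "rank": r,
                                 "rows": krp.shape[0]}
            if r < K:
                ranks_ok = False
    b_ok, offending = _distinct_all_items(tables, rank_tol)
    return CheckReport(
        passed=ranks_ok and b_ok, lambda_phi_ok=ranks_ok, l_ok=b_ok,
        details={"parts": part_info, "identical_column_items": offending,
                 "K": K})


def _part_log_product(domain: ItemDomain, part: Sequence[int]) -> float:
    return float(sum(math.log(domain.d[j]) for j in part))


def find_partition(domain: ItemDomain, grouping: Grouping, K: int,
                   exhaustive_limit: int = 12) -> Optional[PartitionPlan]:
    """Search for a three-way split of each group with part products >= K.

    Greedy balance first: items sorted by decreasing ``log d_j`` go to the
    part with the smallest current log-product.  If the greedy split fails
    for a group with at most ``exhaustive_limit`` items, all ``3^m``
    assignments are enumerated.  Returns ``None`` when some group admits no
    valid split.
    """
    logK = math.log(K)
    triples = []
    for g in range(grouping.G):
        items = grouping.items_in(g).tolist()
        triple = _greedy_split(domain, items)
        if not _split_ok(domain, triple, logK) and len(items) <= exhaustive_limit:
            triple = _exhaustive_split(domain, items, logK)
        if triple is None or not _split_ok(domain, triple, logK):
            return None
        triples.append(triple)
    return PartitionPlan(triples)


def _greedy_split(domain, items):
    order = sorted(items, key=lambda j: -math.log(domain.d[j]))
    parts = [[], [], []]
    loads = [0.0, 0.0, 0.0]
    for j in order:
        m = int(np.argmin(loads))
        parts[m].append(j)
        loads[m] += math.log(domain.d[j])
    return tuple(tuple(part) for part in parts)


def _split_ok(domain, triple, logK):
    if triple is None:
        return False
    eps = 1e-12
    return all(part and _part_log_product(domain, part) >= logK - eps
               for part in triple)


def _exhaustive_split(domain, items, logK):
    for assignment in itertools.product(range(3), repeat=len(items)):
        parts = [[], [], []]
        for j, m in zip(items, assignment):
            parts[m].append(j)
        triple = tuple(tuple(part) for part in parts)
        if _split_ok(domain, triple, logK):
            return triple
    return None


def check_generic(domain: ItemDomain, grouping: Grouping, K: int,
                  plan: Optional[PartitionPlan] = None) -> CheckReport:
    """Dimension-count conditions for generic identifiability.

    Passes iff each group can be split into three parts whose category-count
    products all reach ``K`` (supplied via ``plan`` or found by search).
    Under this condition the Khatri-Rao rank conditions hold for all
    parameters outside a measure-zero set.
    """
    logK = math.log(K)
    if plan is not None:
        plan.validate_against(grouping)
    else:
        plan = find_partition(domain, grouping, K)
        if plan is None:
            return CheckReport(
                passed=False, lambda_phi_ok=False, l_ok=None,
                details={"reason": "no valid three-way partition found", "K": K})
    part_info = {}
    ok = True
    for g, triple in enumerate(plan.parts):
        for m, part in enumerate(triple):
            prod = int(np.prod([domain.d[j] for j in part])) if part else 0
            part_info[(g, m)] = {"items": list(part), "d_product": prod}
            if prod < K:
                ok = False
    return CheckReport(passed=ok, lambda_phi_ok=ok, l_ok=None,
                       details={"parts": part_info, "plan": plan, "K": K})
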