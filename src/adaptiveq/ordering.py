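"""Choosing the priority order of clinical conditions.

The priority order ``≺`` decides which condition of a rule is asked first;
a good order minimizes the number of distinct clinical conditions shown on
the *initial* questionnaire screen, i.e. before any clinical condition has
been entered (drugs and labs are already known).  The problem is NP-hard —
it embeds a Generalized Traveling Salesman Problem — so this module offers:

* :func:`occurrence_order` — the production heuristic: sort conditions by
  decreasing number of rules they occur in (patient-independent);
* :func:`brute_force_order` — the exact optimum by enumerating permutations
  of the conditions that actually occur in rules (small instances only);
* :func:`stochastic_order` — a seeded random-restart hill-climbing search
  over adjacent transpositions, patient-specific, pluggable so other
  permutation metaheuristics can be swapped in;
* :func:`build_gtsp` / :func:`gtsp_bruteforce` — the GTSP formulation over
  the 2^n subsets of conditions, used as an independent oracle for the
  objective on restricted rule bases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .display_compiler import ConditionOrder, compile_all
from .engine import PatientProfile, displayed_conditions
from .rule_model import RuleBase

__all__ = [
    "occurrence_order",
    "initial_display_count",
    "brute_force_order",
    "stochastic_order",
    "GtspInstance",
    "GtspResult",
    "build_gtsp",
    "gtsp_bruteforce",
]


def occurrence_order(rb: RuleBase) -> ConditionOrder:
    """Sort clinical conditions by decreasing number of rules mentioning them.

    A condition counts once per rule, whatever slot it occupies (present,
    absent, or union member).  Ties — and conditions absent from every rule —
    keep catalogue declaration order, so the result is deterministic and
    independent of the patient.
    """
    counts = {cid: 0 for cid in rb.clinical_ids}
    for rule in rb.rules:
        for cid in rule.premise.clinical_ids():
            counts[cid] += 1
    decl = {cid: i for i, cid in enumerate(rb.clinical_ids)}
    ordered = sorted(rb.clinical_ids, key=lambda c: (-counts[c], decl[c]))
    return ConditionOrder(tuple(ordered))


def initial_display_count(
    rb: RuleBase, order: ConditionOrder, nonclinical: Iterable[str] = ()
) -> int:
    """Number of distinct clinical conditions on the initial screen.

    Compiles the display rules under ``order`` and evaluates them against a
    profile with the given drugs/labs and no clinical condition entered.
    """
    profile = PatientProfile(nonclinical_true=frozenset(nonclinical))
    return len(displayed_conditions(compile_all(rb, order), profile))


# ---------------------------------------------------------------------------
# Fast objective used inside the search loops.
#
# With no clinical condition entered, only the `p`, `a1` and `u1` display
# rules can fire (`a2`/`u2` carry a positive clinical literal), and each
# premise reduces to membership tests on the drug set plus priority
# comparisons — so the objective can be evaluated per permutation without
# materializing display rules.  `initial_display_count` (the compile-and-run
# route) and this evaluator are checked against each other in the test suite.


class _FastObjective:
    def __init__(self, rb: RuleBase, nonclinical: Iterable[str]):
        drugs = frozenset(nonclinical)
        self.rules = []
        for r in rb.rules:
            drug_ok = r.present_nonclinical <= drugs and not (
                r.absent_nonclinical & drugs
            )
            unions = [
                (tuple(u.clinical), bool(u.nonclinical & drugs)) for u in r.unions
            ]
            # u1 of union k also moves D^uk to the absent slot
            u1_ok = [
                drug_ok and not (u.nonclinical & drugs) for u in r.unions
            ]
            self.rules.append(
                (tuple(r.present_clinical), tuple(r.absent_clinical), unions,
                 drug_ok, u1_ok)
            )

    def __call__(self, rank: dict[str, int]) -> int:
        displayed: set[str] = set()
        for cp, ca, unions, drug_ok, u1_ok in self.rules:
            if drug_ok:
                if cp:
                    # `p` rule of the ≺-first present condition
                    x = min(cp, key=rank.__getitem__)
                    rx = rank[x]
                    if all(
                        sat
                        for members, sat in unions
                        if all(rank[c] < rx for c in members)
                    ):
                        displayed.add(x)
                elif ca and all(sat for _, sat in unions):
                    displayed.update(ca)  # `a1` rules fire for every absent member
            for k, (members, _) in enumerate(unions):
                if not members or not u1_ok[k]:
                    continue
                for x in members:
                    rx = rank[x]
                    if any(rank[c] < rx for c in cp):
                        continue
                    if all(
                        sat
                        for z, (mz, sat) in enumerate(unions)
                        if z != k and all(rank[c] < rx for c in mz)
                    ):
                        displayed.add(x)
        return len(displayed)


def _occurring(rb: RuleBase) -> tuple[str, ...]:
    mentioned: set[str] = set()
    for r in rb.rules:
        mentioned |= r.premise.clinical_ids()
    return tuple(c for c in rb.clinical_ids if c in mentioned)


def _complete(rb: RuleBase, perm: Sequence[str]) -> ConditionOrder:
    rest = tuple(c for c in rb.clinical_ids if c not in set(perm))
    return ConditionOrder(tuple(perm) + rest)


def brute_force_order(
    rb: RuleBase, nonclinical: Iterable[str] = (), cap: int = 9
) -> tuple[ConditionOrder, int]:
    """Exact optimum of the initial-display objective by full enumeration.

    Only conditions occurring in at least one rule are permuted; the others
    cannot affect the objective and are appended in declaration order.  The
    returned order is the lexicographically smallest optimal permutation (by
    declaration index).  Refuses instances with more than ``cap`` occurring
    conditions.
    """
    occurring = _occurring(rb)
    if len(occurring) > cap:
        raise ValueError(
            f"{len(occurring)} occurring conditions exceed the brute-force cap {cap}"
        )
    objective = _FastObjective(rb, nonclinical)
    best_perm: tuple[str, ...] = occurring
    best = objective({c: i for i, c in enumerate(occurring)}) if occurring else 0
    for perm in itertools.permutations(occurring):
        value = objective({c: i for i, c in enumerate(perm)})
        if value < best:
            best, best_perm = value, perm
    return _complete(rb, best_perm), best


def _hill_climb(
    objective: Callable[[dict[str, int]], int], start: tuple[str, ...]
) -> tuple[tuple[str, ...], int]:
    """Greedy descent over adjacent transpositions until a local optimum."""
    seq = list(start)
    value = objective({c: i for i, c in enumerate(seq)})
    improved = True
    while improved:
        improved = False
        for i in range(len(seq) - 1):
            seq[i], seq[i + 1] = seq[i + 1], seq[i]
            v = objective({c: k for k, c in enumerate(seq)})
            if v < value:
                value = v
                improved = True
            else:
                seq[i], seq[i + 1] = seq[i + 1], seq[i]
    return tuple(seq), value


def stochastic_order(
    rb: RuleBase,
    nonclinical: Iterable[str] = (),
    iterations: int = 50,
    seed: int = 0,
    optimizer: Callable[
        [Callable[[dict[str, int]], int], tuple[str, ...], np.random.Generator],
        tuple[tuple[str, ...], int],
    ]
    | None = None,
) -> tuple[ConditionOrder, int]:
    """Seeded stochastic search for a near-optimal, patient-specific order.

    The default optimizer is random-restart hill climbing over adjacent
    transpositions: the first restart starts from the occurrence heuristic
    (so the result is never worse than the heuristic), the remaining
    ``iterations - 1`` restarts from random permutations.  A different
    permutation metaheuristic can be plugged in via ``optimizer``, a callable
    ``(objective, start, rng) -> (permutation, value)``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    occurring = _occurring(rb)
    objective = _FastObjective(rb, nonclinical)
    rng = np.random.default_rng(seed)
    heur_start = tuple(
        c for c in occurrence_order(rb).sequence if c in set(occurring)
    )
    climb = optimizer if optimizer is not None else (
        lambda obj, start, _rng: _hill_climb(obj, start)
    )

    best_perm, best = climb(objective, heur_start, rng)
    for _ in range(iterations - 1):
        start = tuple(rng.permutation(np.array(occurring, dtype=object)))
        perm, value = climb(objective, start, rng)
        if value < best:
            best_perm, best = perm, value
    return _complete(rb, best_perm), int(best)


# ---------------------------------------------------------------------------
# GTSP formulation (oracle for restricted rule bases)


@dataclass(frozen=True)
class GtspInstance:
    """The ordering problem over a restricted rule base as a GTSP.

    Restricted rules have only present clinical conditions, and every patient
    condition is taken as false.  Towns are the 2^n subsets of the clinical
    conditions — the set already placed in the order under construction — and
    area A_k holds the subsets of size k, so a tour visiting one town per
    area in area order grows the order one condition at a time.  The distance
    matrix charges 1 exactly when the added condition is displayed, i.e. when
    some rule contains it and no already-ordered condition.
    """

    clinical_ids: tuple[str, ...]
    towns: tuple[frozenset[str], ...]
    matrix: np.ndarray  # 2^n x 2^n, entries in {0, 1, +inf}

    @property
    def n(self) -> int:
        return len(self.clinical_ids)

    @property
    def areas(self) -> tuple[tuple[int, ...], ...]:
        """Town indices grouped by cardinality (area A_0 ... A_n)."""
        out: list[list[int]] = [[] for _ in range(self.n + 1)]
        for i, t in enumerate(self.towns):
            out[len(t)].append(i)
        return tuple(tuple(a) for a in out)

    def town_index(self, town: frozenset[str]) -> int:
        return self._index[town]  # type: ignore[attr-defined]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {t: i for i, t in enumerate(self.towns)}
        )


@dataclass(frozen=True)
class GtspResult:
    tour: tuple[frozenset[str], ...]
    cost: int
    order: ConditionOrder


def build_gtsp(rb: RuleBase, cap: int = 6) -> GtspInstance:
    """Build the GTSP instance for a restricted rule base.

    Every rule must have only its present-clinical slot non-empty; the
    catalogue must hold at most ``cap`` clinical conditions (towns are
    materialized explicitly, 2^n of them).
    """
    for r in rb.rules:
        if (
            r.present_nonclinical
            or r.absent_clinical
            or r.absent_nonclinical
            or r.unions
        ):
            raise ValueError(
                f"rule {r.id} is not of the restricted present-clinical-only form"
            )
    ids = rb.clinical_ids
    n = len(ids)
    if n > cap:
        raise ValueError(f"{n} clinical conditions exceed the GTSP cap {cap}")
    decl = {c: i for i, c in enumerate(ids)}
    towns = tuple(
        frozenset(sub)
        for size in range(n + 1)
        for sub in itertools.combinations(ids, size)
    )
    # itertools.combinations over the declaration-ordered ids gives a
    # deterministic town enumeration sorted by (size, lexicographic indices)
    cps = [r.present_clinical for r in rb.rules]
    size = len(towns)
    matrix = np.zeros((size, size))
    for i, ti in enumerate(towns):
        for j, tj in enumerate(towns):
            if len(ti) == n and len(tj) == 0:
                matrix[i, j] = 0.0  # closing edge of the loop
            elif len(tj) != len(ti) + 1:
                matrix[i, j] = np.inf  # areas must be visited in order
            elif any((tj - ti) <= cp and not (ti & cp) for cp in cps):
                matrix[i, j] = 1.0  # the move displays a new condition
            else:
                matrix[i, j] = 0.0
    del decl
    return GtspInstance(clinical_ids=ids, towns=towns, matrix=matrix)


def gtsp_bruteforce(instance: GtspInstance) -> GtspResult:
    """Minimal tour through one town per area, in area order.

    Towns encode partial orders under construction, which grow by one
    condition at a time, so consecutive towns are nested (each one adds a
    single condition to its predecessor); the tour closes back to the empty
    town at cost 0.  Returns the optimal tour, its cost, and the condition
    order recovered from the successive town differences — the
    lexicographically smallest (by declaration index) among the optima.
    """
    ids = instance.clinical_ids
    idx = instance.town_index
    M = instance.matrix
    empty = idx(frozenset())
    best_cost = np.inf
    best_perm: tuple[str, ...] | None = None
    for perm in itertools.permutations(ids):
        cost = 0.0
        town: frozenset[str] = frozenset()
        i = empty
        for c in perm:
            nxt = town | {c}
            j = idx(nxt)
            cost += M[i, j]
            town, i = nxt, j
        cost += M[i, empty]  # closing edge
        if cost < best_cost:
            best_cost, best_perm = cost, perm
    assert best_perm is not None
    tour = [frozenset()]
    for c in best_perm:
        tour.append(tour[-1] | {c})
    return GtspResult(
        tour=tuple(tour), cost=int(best_cost), order=ConditionOrder(best_perm)
    )
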