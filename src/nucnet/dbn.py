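"""Constrained two-slice Bayesian-network structure learning.

A stationary process along the nucleosome array is modeled by a transition
network repeated at consecutive positions: 2n nodes, the n mark variables at
the "before" nucleosome and the same n at the "after" nucleosome. Learning
the transition network from the stacked pair data is equivalent to learning
an ordinary Bayesian network on the 2n-dimensional rows under tier
constraints: edges among before-slice nodes and edges from the after slice
back to the before slice are forbidden; only before->after and intra-after
edges are allowed. Any such graph is acyclic iff its intra-after subgraph is.

Structure search is greedy hill climbing from the empty graph over
add/delete/reverse moves with a decomposable penalized score; the learned
DAG is then summarized as a PDAG: all inter-slice edges are compelled by the
tier constraint (background knowledge), v-structures seed further
orientations, and Meek's rules R1-R4 propagate them; the remaining
intra-after edges are reversible (undirected).

Edge records are plain tuples throughout:
``("compelled", source, target)`` for a directed edge and
``("undirected", a, b)`` with ``a < b`` for a reversible one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BEFORE, AFTER = "before", "after"


def node_label(mark: str, slice_tag: str) -> str:
    return f"{mark}@{slice_tag}"


@dataclass(frozen=True)
class TransitionDataset:
    """Stacked pair data: one row per nucleosome pair, columns the n mark
    values at the before nucleosome followed by the same n at the after."""

    data: np.ndarray  # (m, 2n) float
    marks: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != 2 * len(self.marks):
            raise ValueError("data must be (m, 2n) for n marks")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in transition data")

    @property
    def n(self) -> int:
        return len(self.marks)

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def node_labels(self) -> list[str]:
        return [node_label(mk, BEFORE) for mk in self.marks] + [
            node_label(mk, AFTER) for mk in self.marks
        ]


@dataclass(frozen=True)
class StructureConstraints:
    """Tier constraints of the two-slice template over node indices
    0..n-1 (before) and n..2n-1 (after)."""

    n: int

    def allows(self, u: int, v: int) -> bool:
        if v < self.n:  # nothing may point into the before slice
            return False
        return u != v  # before->after and intra-after edges allowed

    def is_before(self, u: int) -> bool:
        return u < self.n


@dataclass(frozen=True)
class ScoreConfig:
    """Penalized-score settings. ``lam`` multiplies the complexity penalty
    (larger -> sparser graphs); ``max_parents`` caps in-degree."""

    lam: float = 2.0
    score: str = "gaussian_bic"  # or "kernel_regression"
    max_parents: int = 4

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.score not in ("gaussian_bic", "kernel_regression"):
            raise ValueError(f"unknown score family {self.score!r}")


@dataclass
class ConstrainedDAG:
    """A DAG satisfying the tier constraints, stored as parent sets."""

    node_labels: list[str]
    parents: dict[int, frozenset[int]]
    total_score: float = float("nan")

    def edges(self) -> set[tuple[int, int]]:
        return {(u, v) for v, ps in self.parents.items() for u in ps}

    def edge_labels(self) -> set[tuple[str, str]]:
        return {
            (self.node_labels[u], self.node_labels[v]) for u, v in self.edges()
        }


@dataclass
class PDAG:
    """Compelled (directed) and reversible (undirected) edges of the
    constraint-respecting Markov equivalence class of a DAG."""

    node_labels: list[str]
    compelled: set[tuple[str, str]]
    reversible: set[tuple[str, str]]  # stored with a < b

    def records(self) -> frozenset[tuple[str, str, str]]:
        recs = {("compelled", u, v) for u, v in self.compelled}
        recs |= {("undirected", a, b) for a, b in self.reversible}
        return frozenset(recs)


def _loo_nadaraya_watson_rss(y: np.ndarray, X: np.ndarray | None) -> float:
    """Leave-one-out residual sum of squares of a Nadaraya-Watson regression
    with a Gaussian kernel and median-heuristic bandwidth; parent-free nodes
    fall back to the leave-one-out mean."""
    m = y.shape[0]
    if X is None or X.shape[1] == 0:
        s, ss = y.sum(), float(np.sum((y - y.mean()) ** 2))
        # LOO mean residual: (y_i - mean_{-i})^2 = ((m*(y_i - ybar))/(m-1))^2
        resid = (y - (s - y) / (m - 1)) * 1.0
        return float(np.sum(resid**2))
    Z = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    d2 = np.sum((Z[:, None, :] - Z[None, :, :]) ** 2, axis=-1)
    iu = np.triu_indices(m, k=1)
    med = float(np.median(d2[iu]))
    h2 = med if med > 0 else 1.0
    K = np.exp(-d2 / (2 * h2))
    np.fill_diagonal(K, 0.0)
    w = K.sum(axis=1)
    yhat = np.where(w > 0, K @ y / np.where(w > 0, w, 1.0), y.mean())
    return float(np.sum((y - yhat) ** 2))


def local_score(
    node: int,
    parent_set: Iterable[int],
    data: TransitionDataset,
    cfg: ScoreConfig = ScoreConfig(),
) -> float:
    """Decomposable penalized regression score of ``node`` given its parents.

    For the ``gaussian_bic`` family::

        score = -(m/2) ln(RSS/m) - lam (|parents|+1) ln(m)/2

    with RSS the residual sum of squares of the least-squares regression of
    the node on its parents (with intercept). The ``kernel_regression``
    family replaces RSS with the leave-one-out residual sum of a
    Nadaraya-Watson fit. Higher is better. RSS is floored at machine epsilon
    times the node's total variance so a perfect fit scores finitely yet
    above any noisy alternative.
    """
    parents = sorted(set(parent_set))
    if node in parents:
        raise ValueError("node cannot be its own parent")
    if len(parents) > cfg.max_parents:
        raise ValueError("parent set exceeds max_parents")
    m = data.m
    if m < len(parents) + 2:
        raise ValueError(
            f"underdetermined: {m} samples for {len(parents)} parents"
        )
    y = data.data[:, node]
    if cfg.score == "kernel_regression":
        X = data.data[:, parents] if parents else None
        rss = _loo_nadaraya_watson_rss(y, X)
    else:
        if parents:
            X = np.column_stack([np.ones(m), data.data[:, parents]])
            _, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            if res.size:
                rss = float(res[0])
            else:
                beta = np.linalg.lstsq(X, y, rcond=None)[0]
                rss = float(np.sum((y - X @ beta) ** 2))
        else:
            rss = float(np.sum((y - y.mean()) ** 2))
    tot_var = float(np.sum((y - y.mean()) ** 2))
    floor = np.finfo(float).eps * max(tot_var, np.finfo(float).tiny)
    rss = max(rss, floor, np.finfo(float).tiny)
    return -(m / 2) * math.log(rss / m) - cfg.lam * (len(parents) + 1) * math.log(m) / 2


def _after_subgraph_acyclic(parents: dict[int, frozenset[int]], n: int) -> bool:
    # Kahn's algorithm on the intra-after subgraph
    nodes = [v for v in parents if v >= n]
    indeg = {v: 0 for v in nodes}
    children: dict[int, list[int]] = {v: [] for v in nodes}
    for v, ps in parents.items():
        if v < n:
            continue
        for u in ps:
            if u >= n:
                indeg[v] += 1
                children[u].append(v)
    queue = [v for v in nodes if indeg[v] == 0]
    seen = 0
    while queue:
        u = queue.pop()
        seen += 1
        for w in children[u]:
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    return seen == len(nodes)


def assemble_transition_data(
    pairs: Sequence, matrix: pd.DataFrame, marks: Sequence[str]
) -> TransitionDataset:
    """Build the stacked (m, 2n) dataset from nucleosome pairs and the
    per-nucleosome signal matrix; one row per pair, before-slot values first.

    Rows are ordered deterministically by (anchor id, side, after slot).
    Pairs referencing nucleosomes absent from the matrix raise with the
    offending ids listed.
    """
    marks = list(marks)
    missing_marks = [mk for mk in marks if mk not in matrix.columns]
    if missing_marks:
        raise KeyError(f"marks absent from signal matrix: {missing_marks}")
    missing = sorted(
        {
            nu.nucleosome.id
            for p in pairs
            for nu in (p.before, p.after)
            if nu.nucleosome.id not in matrix.index
        }
    )
    if missing:
        raise KeyError(f"pairs reference nucleosomes absent from matrix: {missing[:10]}")
    ordered = sorted(pairs, key=lambda p: (p.anchor_id, p.side, p.after.slot))
    sub = matrix[marks]
    rows = [
        np.concatenate(
            [
                sub.loc[p.before.nucleosome.id].to_numpy(dtype=float),
                sub.loc[p.after.nucleosome.id].to_numpy(dtype=float),
            ]
        )
        for p in ordered
    ]
    data = np.array(rows) if rows else np.empty((0, 2 * len(marks)))
    return TransitionDataset(data=data, marks=tuple(marks))


def learn_structure(
    data: TransitionDataset,
    constraints: StructureConstraints | None = None,
    cfg: ScoreConfig = ScoreConfig(),
    seed: int | None = None,
    tabu_steps: int = 10,
) -> ConstrainedDAG:
    """Score-based search from the empty graph over add/delete/reverse moves.

    Greedy hill climbing applies the single best score-improving move at each
    step, with ties broken lexicographically by (source label, target label,
    move kind); only constraint-legal, acyclic graphs with bounded in-degree
    are visited. After the greedy phase stalls, a short deterministic tabu
    phase takes the best not-yet-visited move — improving or not — for up to
    ``tabu_steps`` consecutive non-improving steps, which escapes the
    near-tie traps where a misoriented edge can only be repaired by a
    reverse-then-delete sequence; the best-scoring graph ever visited is
    returned. The procedure is deterministic given the data and configuration
    (``seed`` is accepted for interface uniformity; the search draws no
    random numbers) and is invariant to row order of the dataset.
    """
    n = data.n
    if constraints is None:
        constraints = StructureConstraints(n)
    min_m = max(30, 5 * n)
    if data.m < min_m:
        raise ValueError(f"need >= {min_m} samples for {n} marks, got {data.m}")
    labels = data.node_labels
    nodes = list(range(2 * n))
    parents: dict[int, frozenset[int]] = {v: frozenset() for v in nodes}
    cache: dict[tuple[int, frozenset[int]], float] = {}

    def sc(v: int, ps: frozenset[int]) -> float:
        key = (v, ps)
        if key not in cache:
            cache[key] = local_score(v, ps, data, cfg)
        return cache[key]

    def graph_key(ps: dict[int, frozenset[int]]) -> frozenset:
        return frozenset((u, v) for v, s in ps.items() for u in s)

    legal = [(u, v) for u in nodes for v in nodes if constraints.allows(u, v)]

    def best_move(exclude: set | None) -> tuple | None:
        """Best legal move; with ``exclude`` set, the best move to an
        unvisited graph regardless of sign."""

        def consider(move: tuple, best: tuple | None) -> tuple | None:
            if exclude is None and move[0] <= 1e-9:
                return best
            if exclude is not None and graph_key(move[4]) in exclude:
                return best
            if best is None or _move_better(move, best):
                return move
            return best

        best: tuple | None = None  # (delta, src, tgt, kind, new parents)
        for u, v in legal:
            if u not in parents[v]:
                if len(parents[v]) >= cfg.max_parents:
                    continue
                cand = {**parents, v: parents[v] | {u}}
                if u >= n and not _after_subgraph_acyclic(cand, n):
                    continue
                delta = sc(v, cand[v]) - sc(v, parents[v])
                best = consider((delta, labels[u], labels[v], "add", cand), best)
            else:
                cand = {**parents, v: parents[v] - {u}}
                delta = sc(v, cand[v]) - sc(v, parents[v])
                best = consider((delta, labels[u], labels[v], "delete", cand), best)
                if constraints.allows(v, u) and len(parents[u]) < cfg.max_parents:
                    cand2 = {**parents, v: parents[v] - {u}, u: parents[u] | {v}}
                    if _after_subgraph_acyclic(cand2, n):
                        delta2 = delta + sc(u, cand2[u]) - sc(u, parents[u])
                        best = consider(
                            (delta2, labels[u], labels[v], "reverse", cand2), best
                        )
        return best

    def total_of(ps: dict[int, frozenset[int]]) -> float:
        return sum(sc(v, ps[v]) for v in nodes)

    visited = {graph_key(parents)}
    best_parents, best_total = parents, total_of(parents)
    current_total = best_total
    stalled = 0
    max_moves = 50 * len(legal)
    for _ in range(max_moves):
        move = best_move(None)
        if move is None:
            if stalled >= tabu_steps:
                break
            move = best_move(visited)
            if move is None:
                break
        parents = move[4]
        current_total += move[0]
        visited.add(graph_key(parents))
        if current_total > best_total + 1e-9:
            best_parents, best_total = parents, current_total
            stalled = 0
        else:
            stalled += 1

    return ConstrainedDAG(
        node_labels=labels, parents=best_parents, total_score=total_of(best_parents)
    )


def _move_better(a: tuple, b: tuple) -> bool:
    # larger delta wins; ties by lexicographic (source, target, kind)
    if a[0] != b[0]:
        return a[0] > b[0]
    return (a[1], a[2], a[3]) < (b[1], b[2], b[3])


# ---------------------------------------------------------------------------
# PDAG construction: v-structures + tier background knowledge + Meek's rules


def _meek_closure(
    nodes: Sequence[str],
    directed: set[tuple[str, str]],
    undirected: set[frozenset],
) -> tuple[set[tuple[str, str]], set[frozenset]]:
    def adjacent(x: str, y: str) -> bool:
        return (
            (x, y) in directed
            or (y, x) in directed
            or frozenset((x, y)) in undirected
        )

    changed = True
    while changed:
        changed = False
        for e in list(undirected):
            a, b = tuple(e)
            for x, y in ((a, b), (b, a)):
                if _meek_orients(x, y, nodes, directed, undirected, adjacent):
                    undirected.discard(e)
                    directed.add((x, y))
                    changed = True
                    break
            if changed:
                break
    return directed, undirected


def _meek_orients(x, y, nodes, directed, undirected, adjacent) -> bool:
    """Do Meek's rules R1-R4 force the undirected edge x-y to x->y?"""
    # R1: some a -> x with a, y non-adjacent
    for a, bb in directed:
        if bb == x and a != y and not adjacent(a, y):
            return True
    # R2: directed path x -> c -> y
    for xx, c in directed:
        if xx == x and (c, y) in directed:
            return True
    # R3: x - c, x - d undirected; c -> y, d -> y; c, d non-adjacent
    cands = [
        c
        for c in nodes
        if frozenset((x, c)) in undirected and (c, y) in directed
    ]
    for c, d in combinations(cands, 2):
        if not adjacent(c, d):
            return True
    # R4: x - d undirected, d -> c, c -> y, with d, y non-adjacent
    for d, c in directed:
        if (
            frozenset((x, d)) in undirected
            and (c, y) in directed
            and not adjacent(d, y)
        ):
            return True
    return False


def to_pdag(
    dag: ConstrainedDAG, constraints: StructureConstraints | None = None
) -> PDAG:
    """Partition the learned DAG's edges into compelled and reversible.

    All before->after edges are compelled outright — the tier constraint is
    background knowledge fixing their direction. Intra-after orientations are
    seeded by the DAG's v-structures (a -> c <- b with a, b non-adjacent) and
    propagated by Meek's rules R1-R4; whatever remains undirected is
    reversible. Idempotent and skeleton-preserving by construction.
    """
    labels = dag.node_labels
    if constraints is None:
        constraints = StructureConstraints(len(labels) // 2)
    n = constraints.n
    edges = dag.edges()
    adj: dict[int, set[int]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    directed: set[tuple[str, str]] = set()
    undirected: set[frozenset] = set()
    for u, v in edges:
        if constraints.is_before(u):
            directed.add((labels[u], labels[v]))
        else:
            undirected.add(frozenset((labels[u], labels[v])))
    # v-structures: common child with non-adjacent parents compels both edges
    for v, ps in dag.parents.items():
        for a, b in combinations(sorted(ps), 2):
            if b not in adj.get(a, set()):
                for u in (a, b):
                    e = frozenset((labels[u], labels[v]))
                    if e in undirected:
                        undirected.discard(e)
                        directed.add((labels[u], labels[v]))

    directed, undirected = _meek_closure(labels, directed, undirected)
    reversible = {tuple(sorted(e)) for e in undirected}
    return PDAG(node_labels=labels, compelled=directed, reversible=reversible)


# ---------------------------------------------------------------------------
# Resampling stability and consensus


def candidate_edge_universe(marks: Sequence[str]) -> frozenset:
    """Every constraint-legal edge record on the 2n-node template."""
    recs = set()
    for a in marks:
        for b in marks:
            recs.add(("compelled", node_label(a, BEFORE), node_label(b, AFTER)))
            if a != b:
                recs.add(("compelled", node_label(a, AFTER), node_label(b, AFTER)))
    for a, b in combinations(sorted(marks), 2):
        la, lb = sorted((node_label(a, AFTER), node_label(b, AFTER)))
        recs.add(("undirected", la, lb))
    return frozenset(recs)


def select_cv_edges(counts: dict, inclusion_count: int = 7) -> frozenset:
    """Edges recurring in at least ``inclusion_count`` resampled PDAGs."""
    return frozenset(r for r, c in counts.items() if c >= inclusion_count)


def cross_validate(
    data: TransitionDataset,
    constraints: StructureConstraints | None = None,
    cfg: ScoreConfig = ScoreConfig(),
    folds: int = 10,
    keep_fraction: float = 0.9,
    inclusion_count: int = 7,
    seed: int = 0,
):
    """Resampling stability of the learned network.

    Learns one PDAG on each of ``folds`` independent uniform subsamples
    (``keep_fraction`` of rows, without replacement), counts how often each
    edge record recurs, and keeps records appearing in at least
    ``inclusion_count`` PDAGs as the cross-validated network. Stability is
    summarized as an ROC curve obtained by sweeping the recurrence threshold
    from ``folds`` down to 0 against the full-data PDAG as reference, over
    the universe of constraint-legal edges; AUC by the trapezoid rule.

    Returns ``(cv_edges, frequency_table, roc_points, auc)`` where
    ``frequency_table`` maps edge record -> count.
    """
    if constraints is None:
        constraints = StructureConstraints(data.n)
    rng = np.random.default_rng(seed)
    m = data.m
    k = int(round(keep_fraction * m))
    counts: dict[tuple, int] = {}
    for _ in range(folds):
        idx = np.sort(rng.choice(m, size=k, replace=False))
        sub = TransitionDataset(data=data.data[idx], marks=data.marks)
        pdag = to_pdag(learn_structure(sub, constraints, cfg), constraints)
        for rec in pdag.records():
            counts[rec] = counts.get(rec, 0) + 1

    cv_edges = select_cv_edges(counts, inclusion_count)
    reference = to_pdag(learn_structure(data, constraints, cfg), constraints).records()
    universe = candidate_edge_universe(data.marks)
    pos = len(reference)
    neg = len(universe) - pos
    roc = []
    for thresh in range(folds + 1, -1, -1):
        pred = (
            universe
            if thresh == 0
            else frozenset(r for r, c in counts.items() if c >= thresh)
        )
        tp = len(pred & reference)
        fp = len(pred - reference)
        roc.append((fp / neg if neg else 0.0, tp / pos if pos else 1.0))
    auc = float(np.trapezoid([p[1] for p in roc], [p[0] for p in roc]))
    return cv_edges, counts, roc, auc


def _compatible(rec: tuple, net: frozenset) -> bool:
    """Is an edge record present in a network with compatible orientation?
    Identical direction matches; an undirected edge matches either."""
    kind, a, b = rec
    und = ("undirected",) + tuple(sorted((a, b)))
    if kind == "compelled":
        return rec in net or und in net
    return (
        und in net
        or ("compelled", a, b) in net
        or ("compelled", b, a) in net
    )


@dataclass
class ConsensusNetwork:
    """Edges supported by at least a fraction of independently learned
    networks (different anchor kinds / sides / inclusion levels)."""

    edges: list[tuple[tuple, float]]  # (edge record, support fraction)
    settings: list[str]

    def records(self) -> frozenset:
        return frozenset(r for r, _ in self.edges)


def build_consensus(
    networks: Sequence[tuple[str, frozenset]], min_fraction: float = 0.5
) -> ConsensusNetwork:
    """Keep edges appearing, with compatible orientation, in at least
    ``ceil(min_fraction * N)`` of the N input networks.

    When both directions of a skeleton edge independently reach the
    threshold, the edge is reported undirected (its direction is not
    consensual); an undirected record is dropped when a directed form of the
    same skeleton edge is retained.
    """
    if len(networks) < 2:
        raise ValueError("consensus needs at least 2 networks")
    nets = [net for _, net in networks]
    need = math.ceil(min_fraction * len(nets))
    candidates = set().union(*nets)
    support = {
        rec: sum(_compatible(rec, net) for net in nets) for rec in candidates
    }
    retained = {rec for rec, s in support.items() if s >= need}

    by_skel: dict[tuple, list[tuple]] = {}
    for rec in retained:
        by_skel.setdefault(tuple(sorted(rec[1:])), []).append(rec)
    final: list[tuple[tuple, float]] = []
    for skel, recs in sorted(by_skel.items()):
        directed = sorted(r for r in recs if r[0] == "compelled")
        if len(directed) == 1:
            rec = directed[0]
        elif len(directed) == 2:  # both directions pass: direction not consensual
            rec = ("undirected",) + skel
        else:
            rec = ("undirected",) + skel
        frac = support.get(rec, max(support[r] for r in recs)) / len(nets)
        final.append((rec, frac))
    return ConsensusNetwork(edges=final, settings=[name for name, _ in networks])
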