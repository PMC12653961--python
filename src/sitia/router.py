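"""Laser route planning over female targets.

The laser starts from a fixed origin and must visit every targeted fly once —
an *open-path* traveling-salesman problem (no return leg) in pixel units.
Three heuristics are provided, mirroring the options a sorting workstation
would offer, plus an exhaustive oracle for small instances:

* ``route_unoptimized`` — detection-index order, the comparison baseline
* ``route_greedy``      — nearest unvisited neighbor from the origin
* ``route_local_search``— 2-opt segment reversal, best-improvement sweeps
* ``route_aco``         — ant colony optimization with pheromone trails
* ``route_brute_force`` — exact minimum by enumeration (<= 9 targets)

All stochastic steps are seeded and reproducible.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

BRUTE_FORCE_MAX_TARGETS = 9


@dataclass(frozen=True)
class RouteInstance:
    """A routing problem: the laser origin and the target points (px)."""

    origin: tuple[float, float]
    targets: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        targets = tuple((float(x), float(y)) for x, y in self.targets)
        if len(set(targets)) != len(targets):
            raise ValueError("targets must be distinct")
        object.__setattr__(self, "targets", targets)
        object.__setattr__(
            self, "origin", (float(self.origin[0]), float(self.origin[1]))
        )

    @property
    def n(self) -> int:
        return len(self.targets)

    def points(self) -> np.ndarray:
        """Origin plus targets as an (n+1, 2) array; row 0 is the origin."""
        return np.array([self.origin, *self.targets], dtype=float)

    def distance_matrix(self) -> np.ndarray:
        pts = self.points()
        diff = pts[:, None, :] - pts[None, :, :]
        return np.hypot(diff[..., 0], diff[..., 1])

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"origin": list(self.origin), "targets": [list(t) for t in self.targets]}
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "RouteInstance":
        text = (
            Path(text_or_path).read_text()
            if isinstance(text_or_path, Path)
            else text_or_path
        )
        doc = json.loads(text)
        return cls(tuple(doc["origin"]), tuple(tuple(t) for t in doc["targets"]))


@dataclass(frozen=True)
class Route:
    """An ordered visit sequence over target indices and its open-path length."""

    order: tuple[int, ...]
    length_px: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"order": list(self.order), "length_px": self.length_px})
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "Route":
        text = (
            Path(text_or_path).read_text()
            if isinstance(text_or_path, Path)
            else text_or_path
        )
        doc = json.loads(text)
        return cls(tuple(doc["order"]), float(doc["length_px"]))


def _check_permutation(instance: RouteInstance, order) -> np.ndarray:
    order = np.asarray(order, dtype=int)
    if sorted(order.tolist()) != list(range(instance.n)):
        raise ValueError("order is not a permutation of all target indices")
    return order


def path_length(instance: RouteInstance, order) -> float:
    """Open-path length: origin -> first target -> ... -> last target."""
    order = _check_permutation(instance, order)
    if order.size == 0:
        return 0.0
    pts = instance.points()
    seq = pts[np.concatenate(([0], order + 1))]
    return float(np.hypot(*(np.diff(seq, axis=0).T)).sum())


def _make_route(instance: RouteInstance, order) -> Route:
    return Route(tuple(int(i) for i in order), path_length(instance, order))


def route_unoptimized(instance: RouteInstance) -> Route:
    """Visit targets in detection-index order (the no-optimization baseline)."""
    return _make_route(instance, range(instance.n))


def route_greedy(instance: RouteInstance) -> Route:
    """Nearest-unvisited-neighbor from the origin; ties go to the lower index."""
    n = instance.n
    if n == 0:
        return Route((), 0.0)
    dm = instance.distance_matrix()
    visited = np.zeros(n, dtype=bool)
    current = 0  # index into points(): 0 is the origin
    order = []
    for _ in range(n):
        dists = dm[current, 1:].copy()
        dists[visited] = np.inf
        nxt = int(np.argmin(dists))  # argmin returns the lowest tied index
        order.append(nxt)
        visited[nxt] = True
        current = nxt + 1
    return _make_route(instance, order)


def route_local_search(
    instance: RouteInstance, initial: Route, max_sweeps: int = 1000
) -> Route:
    """2-opt segment reversal with best-improvement sweeps.

    Each sweep evaluates every segment reversal of the open path and applies
    the single best strictly improving move; terminates at a 2-opt-optimal
    route or after ``max_sweeps``.  The result is never longer than the
    initial route.
    """
    order = np.array(_check_permutation(instance, initial.order))
    n = instance.n
    if n < 3:
        return _make_route(instance, order)
    dm = instance.distance_matrix()
    for _ in range(max_sweeps):
        seq = np.concatenate(([0], order + 1))  # point indices, origin first
        m = seq.size
        # reversing seq[i..j] (1 <= i <= j <= m-1) changes two boundary edges;
        # when j is the path end there is no outgoing edge
        best_delta = -1e-9
        best_move = None
        for i in range(1, m - 1):
            j = np.arange(i, m)
            out_edge = np.zeros(j.size)
            inner = j < m - 1
            out_edge[inner] = dm[seq[j[inner]], seq[j[inner] + 1]]
            new_out = np.zeros(j.size)
            new_out[inner] = dm[seq[i], seq[j[inner] + 1]]
            delta = (dm[seq[i - 1], seq[j]] + new_out) - (
                dm[seq[i - 1], seq[i]] + out_edge
            )
            k = int(np.argmin(delta))
            if delta[k] < best_delta:
                best_delta = float(delta[k])
                best_move = (i, int(j[k]))
        if best_move is None:
            break
        i, j = best_move
        order[i - 1 : j] = order[i - 1 : j][::-1]
    return _make_route(instance, order)


@dataclass(frozen=True)
class AcoParams:
    """Ant-colony parameters: trail weight alpha, visibility weight beta,
    evaporation rate, and deposit scale (Q in deposit Q/L).

    ``refine_sweeps`` bounds the 2-opt polish applied to each iteration's
    best constructed tour — the standard coupling of ant construction with
    local search for TSP-type problems; set it to 0 for pure construction.
    """

    n_ants: int = 20
    n_iterations: int = 100
    alpha: float = 1.0
    beta: float = 2.0
    evaporation: float = 0.5
    deposit: float | None = None  # default: mean pairwise distance of the instance
    refine_sweeps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ants < 1 or self.n_iterations < 1:
            raise ValueError("n_ants and n_iterations must be positive")
        if not 0.0 < self.evaporation < 1.0:
            raise ValueError("evaporation must be in (0, 1)")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.refine_sweeps < 0:
            raise ValueError("refine_sweeps must be non-negative")
        if self.deposit is not None and self.deposit <= 0:
            raise ValueError("deposit must be positive")


def route_aco(instance: RouteInstance, params: AcoParams | None = None) -> Route:
    """Ant colony optimization over the open path.

    Ants construct routes probabilistically from pheromone (weight ``alpha``)
    and visibility 1/distance (weight ``beta``); trails evaporate each
    iteration and every ant deposits Q/length on its route's edges.  The
    best route found over all iterations is returned; pheromones are floored
    to stay strictly positive.
    """
    params = params or AcoParams()
    n = instance.n
    if n == 0:
        return Route((), 0.0)
    if n == 1:
        return _make_route(instance, [0])
    rng = np.random.default_rng(params.seed)
    dm = instance.distance_matrix()
    q = params.deposit if params.deposit is not None else float(
        dm[np.triu_indices_from(dm, k=1)].mean()
    )
    with np.errstate(divide="ignore"):
        visibility = np.where(dm > 0, 1.0 / np.maximum(dm, 1e-12), 0.0)
    tau = np.full_like(dm, 1.0)
    tau_floor = 1e-12
    best_order: np.ndarray | None = None
    best_len = np.inf
    n_ants = params.n_ants
    for _ in range(params.n_iterations):
        # all ants walk in lockstep: rows are ants, current holds point indices
        current = np.zeros(n_ants, dtype=int)  # start at the origin (point 0)
        unvisited = np.ones((n_ants, n), dtype=bool)
        orders = np.empty((n_ants, n), dtype=int)
        for step in range(n):
            weights = (
                tau[current, 1:] ** params.alpha
                * visibility[current, 1:] ** params.beta
            )
            weights = np.where(unvisited, weights, 0.0)
            totals = weights.sum(axis=1, keepdims=True)
            # degenerate rows (all-zero weight) fall back to uniform choice
            fallback = unvisited / unvisited.sum(axis=1, keepdims=True)
            probs = np.where(totals > 0, weights / np.where(totals == 0, 1, totals), fallback)
            r = rng.random((n_ants, 1))
            choice = (probs.cumsum(axis=1) < r).sum(axis=1)
            choice = np.minimum(choice, n - 1)
            # guard against landing on a visited target through rounding
            bad = ~unvisited[np.arange(n_ants), choice]
            if bad.any():
                for a in np.flatnonzero(bad):
                    choice[a] = int(np.flatnonzero(unvisited[a])[0])
            orders[:, step] = choice
            unvisited[np.arange(n_ants), choice] = False
            current = choice + 1
        seqs = np.concatenate(
            [np.zeros((n_ants, 1), dtype=int), orders + 1], axis=1
        )
        lengths = dm[seqs[:, :-1], seqs[:, 1:]].sum(axis=1)
        k = int(np.argmin(lengths))
        it_order, it_len = orders[k], float(lengths[k])
        if params.refine_sweeps > 0 and n >= 3:
            refined = route_local_search(
                instance, Route(tuple(int(i) for i in it_order), it_len),
                max_sweeps=params.refine_sweeps,
            )
            it_order = np.array(refined.order, dtype=int)
            it_len = refined.length_px
        if it_len < best_len:
            best_len = it_len
            best_order = it_order.copy()
        tau *= 1.0 - params.evaporation
        for a in range(n_ants):
            edges = (seqs[a, :-1], seqs[a, 1:])
            amount = q / lengths[a]
            tau[edges] += amount
            tau[edges[::-1]] += amount
        # elitist reinforcement along the refined best-so-far tour
        best_seq = np.concatenate(([0], best_order + 1))
        eb = (best_seq[:-1], best_seq[1:])
        elite = n_ants * q / (2.0 * best_len)
        tau[eb] += elite
        tau[eb[::-1]] += elite
        np.maximum(tau, tau_floor, out=tau)
    return _make_route(instance, best_order)


def route_brute_force(instance: RouteInstance) -> Route:
    """Exact optimum by exhaustive enumeration; limited to small instances."""
    n = instance.n
    if n > BRUTE_FORCE_MAX_TARGETS:
        raise ValueError(
            f"brute force is capped at {BRUTE_FORCE_MAX_TARGETS} targets (got {n})"
        )
    if n == 0:
        return Route((), 0.0)
    dm = instance.distance_matrix()
    perms = np.array(list(itertools.permutations(range(n))), dtype=int)
    seqs = np.concatenate(
        [np.zeros((perms.shape[0], 1), dtype=int), perms + 1], axis=1
    )
    lengths = dm[seqs[:, :-1], seqs[:, 1:]].sum(axis=1)
    k = int(np.argmin(lengths))
    return Route(tuple(int(i) for i in perms[k]), float(lengths[k]))


METHODS = ("unoptimized", "greedy", "local_search", "aco")


def plan_route(
    instance: RouteInstance,
    method: str = "aco",
    aco_params: AcoParams | None = None,
    max_sweeps: int = 1000,
) -> Route:
    """Dispatch to one planning method by name (2-opt starts from greedy)."""
    if method == "unoptimized":
        return route_unoptimized(instance)
    if method == "greedy":
        return route_greedy(instance)
    if method == "local_search":
        return route_local_search(instance, route_greedy(instance), max_sweeps)
    if method == "aco":
        return route_aco(instance, aco_params)
    if method == "brute_force":
        return route_brute_force(instance)
    raise ValueError(f"unknown routing method {method!r}; choose from {METHODS}")


def compare_optimizers(
    instances: list[RouteInstance],
    aco_params: AcoParams | None = None,
    methods: tuple[str, ...] = METHODS,
) -> pd.DataFrame:
    """Mean +/- sd path length per method and percent reduction vs baseline.

    Percent reduction is ``100 * (L0 - L) / L0`` against the unoptimized
    route of the same instance, averaged over instances.
    """
    if not instances:
        raise ValueError("need at least one instance")
    lengths = {m: [] for m in methods}
    base = []
    for i, inst in enumerate(instances):
        l0 = route_unoptimized(inst).length_px
        base.append(l0)
        for m in methods:
            if m == "unoptimized":
                lengths[m].append(l0)
                continue
            p = aco_params
            if m == "aco":
                p = p or AcoParams()
                # per-instance seed offset keeps runs independent but reproducible
                p = AcoParams(**{**p.__dict__, "seed": p.seed + i})
            lengths[m].append(plan_route(inst, m, aco_params=p).length_px)
    rows = []
    base = np.array(base)
    for m in methods:
        arr = np.array(lengths[m])
        reduction = 100.0 * (base - arr) / base
        rows.append(
            {
                "method": m,
                "mean_length_px": arr.mean(),
                "sd_length_px": arr.std(ddof=1) if arr.size > 1 else 0.0,
                "mean_reduction_pct": reduction.mean(),
                "sd_reduction_pct": reduction.std(ddof=1) if arr.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def random_instances(
    n_instances: int,
    n_targets: int,
    width: float = 4000.0,
    height: float = 3000.0,
    seed: int = 0,
) -> list[RouteInstance]:
    """Seeded instances with uniformly placed targets (origin at top-left)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_instances):
        pts = rng.uniform((0, 0), (width, height), size=(n_targets, 2))
        out.append(RouteInstance((0.0, 0.0), tuple(map(tuple, pts))))
    return out
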