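"""Tabular Q-learning corridor planner.

The risk field is treated as a graph whose nodes are voxels and whose edges
connect adjacent voxels (6- or 26-connectivity). The Q-table stores one
value per ordered adjacent pair (node, neighbour) — connection values rather
than abstract actions — and reads -1 for every non-adjacent pair, the
sentinel for "no transition". Training runs epsilon-greedy episodes from the
entry voxel towards a target region, updating values with the
temporal-difference rule

    Q(s, a) <- Q(s, a) + alpha * (R + gamma * best_next - Q(s, a))

in its penalty-minimising form: R is the cost of stepping into the
neighbour (a per-move base cost plus that voxel's risk), ``best_next`` is
the *minimum* outgoing Q-value of the neighbour (0 at an absorbing target),
and the greedy policy descends to the minimum-Q successor. Lower Q means a
safer corridor; the sum of Q-values along the extracted path is the
Q-learning score, and the sum of per-voxel risk along it is the Qr score.

Because the environment is deterministic, a learning rate of 1 makes each
update an exact asynchronous value-iteration sweep over the visited edge,
which is the package default. A Dijkstra oracle over the same graph provides
the exact optimum for validation.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    BoundsError,
    InvalidPathError,
    InvalidSpecError,
    NonConvergenceError,
    NoTransitionError,
    UnreachableError,
)
from .volume import Index, RiskVolume

NO_TRANSITION = -1.0

_logger = logging.getLogger("qpath.planner")

_OFFSETS_6 = np.array(
    [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)],
    dtype=np.int64,
)
_OFFSETS_26 = np.array(
    [(di, dj, dk)
     for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
     if (di, dj, dk) != (0, 0, 0)],
    dtype=np.int64,
)


@dataclass(frozen=True)
class QLearningConfig:
    """Hyperparameters of the planner.

    alpha : learning rate in (0, 1]; 1.0 is exact for this deterministic graph.
    gamma : discount factor in (0, 1]; 1.0 makes Q converge to total path cost.
    epsilon_start/min/decay : epsilon-greedy exploration schedule
        (geometric decay per episode, floored at epsilon_min).
    episodes_max : hard cap on training episodes.
    stable_episodes : stop early once the greedy path is unchanged this many
        consecutive episodes.
    step_cost : base penalty per move, added to the destination voxel's risk;
        keeps shortest-in-steps paths preferred across zero-risk plateaus.
    barrier_threshold : if set, voxels with risk >= threshold are removed from
        the graph entirely instead of merely penalised.
    connectivity : 6 (faces) or 26 (faces+edges+corners).
    scale_diagonal : multiply step_cost by the physical step length in mm, so
        diagonal moves cost proportionally more.
    goal_terminal : treat the target region as absorbing (best_next = 0 there).
    seed : seeds both the random Q-table fill and exploration; fixing it makes
        the whole pipeline bit-reproducible.
    """

    alpha: float = 1.0
    gamma: float = 1.0
    epsilon_start: float = 1.0
    epsilon_min: float = 0.05
    epsilon_decay: float = 0.995
    episodes_max: int = 3000
    stable_episodes: int = 200
    step_cost: float = 0.01
    barrier_threshold: float | None = None
    connectivity: int = 26
    seed: int = 0
    goal_terminal: bool = True
    scale_diagonal: bool = False
    max_steps_per_episode: int | None = None
    backward_replay: bool = True
    replay_sweeps: int = 1
    exploration: str = "uniform"
    q_init_scale: float = 0.01

    # q_init_scale: adjacent pairs are initialised with q_init_scale * U[0,1).
    # Keeping the random fill below the smallest move cost makes every
    # initial value an underestimate of the true cost-to-go (an admissible
    # heuristic), so an edge the behaviour policy has not yet sampled can
    # only attract the greedy policy, never hide a better corridor behind an
    # overestimate; greedy descent plus replay then reliably converges to
    # the optimum. Set to 1.0 for unscaled [0, 1) initialisation.

    # backward_replay: at episode end, re-apply the update along the
    # episode's transitions in reverse, so information from the target
    # propagates down the whole walk instead of one step per visit.
    # replay_sweeps: Dyna-style planning — per episode, this many synchronous
    # Bellman sweeps over every transition visited so far, which keeps
    # remembered transitions consistent with current downstream values.
    # exploration: the non-greedy arm of the epsilon-greedy policy;
    # "uniform" draws uniformly over the node's neighbours, "least_visited"
    # picks the least-traversed outgoing edge.

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise InvalidSpecError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0.0 < self.gamma <= 1.0:
            raise InvalidSpecError(f"gamma must be in (0, 1], got {self.gamma}")
        for name in ("epsilon_start", "epsilon_min", "epsilon_decay"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError(f"{name} must be in [0, 1], got {v}")
        if self.connectivity not in (6, 26):
            raise InvalidSpecError(
                f"connectivity must be 6 or 26, got {self.connectivity}")
        if self.step_cost < 0:
            raise InvalidSpecError(f"step_cost must be >= 0, got {self.step_cost}")
        if self.episodes_max < 1 or self.stable_episodes < 1:
            raise InvalidSpecError("episodes_max and stable_episodes must be >= 1")
        if self.barrier_threshold is not None and not 0.0 < self.barrier_threshold <= 1.0:
            raise InvalidSpecError(
                f"barrier_threshold must be in (0, 1], got {self.barrier_threshold}")
        if self.exploration not in ("uniform", "least_visited"):
            raise InvalidSpecError(
                f"exploration must be 'uniform' or 'least_visited', "
                f"got {self.exploration!r}")
        if self.replay_sweeps < 0:
            raise InvalidSpecError("replay_sweeps must be >= 0")
        if not 0.0 < self.q_init_scale <= 1.0:
            raise InvalidSpecError(
                f"q_init_scale must be in (0, 1], got {self.q_init_scale}")

    def offsets(self) -> np.ndarray:
        return _OFFSETS_6 if self.connectivity == 6 else _OFFSETS_26

    def replace(self, **kw) -> "QLearningConfig":
        return replace(self, **kw)


@dataclass
class VoxelPath:
    """An ordered sequence of adjacent voxel indices."""

    nodes: list

    def __post_init__(self):
        self.nodes = [tuple(int(c) for c in n) for n in self.nodes]
        if not self.nodes:
            raise InvalidPathError("a path needs at least one node")
        for a, b in zip(self.nodes, self.nodes[1:]):
            d = max(abs(x - y) for x, y in zip(a, b))
            if d == 0 or d > 1:
                raise InvalidPathError(f"nodes {a} and {b} are not adjacent")
        if len(set(self.nodes)) != len(self.nodes):
            warnings.warn("path revisits a node (cycle)", stacklevel=2)

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)


@dataclass
class PlanResult:
    """Outcome of a planning run: the corridor and its scores."""

    path: VoxelPath
    q_score: float
    qr_score: float
    converged: bool
    episodes_run: int

    def to_dict(self) -> dict:
        return {
            "path": [list(n) for n in self.path.nodes],
            "q_score": self.q_score,
            "qr_score": self.qr_score,
            "converged": self.converged,
            "episodes_run": self.episodes_run,
        }


class QTable:
    """Sparse (node, neighbour) -> Q-value map over a voxel grid.

    Backed by a CSR-style adjacency (one sorted neighbour array per node) so
    lookups, argmin and updates on a node's outgoing edges are O(degree).
    Any query for a non-adjacent ordered pair reads the -1 sentinel.
    """

    def __init__(self, shape, indptr, indices, values, valid):
        self.shape = tuple(shape)
        self._indptr = indptr     # (N+1,) int64 over flattened grid
        self._indices = indices   # (E,) int64 flat neighbour ids, sorted per node
        self._values = values     # (E,) float64 Q-values
        self._valid = valid       # (N,) bool, False for barrier-excluded voxels
        self.terminal: frozenset = frozenset()
        self.episodes_run: int = 0
        self.converged: bool = False

    # -- node helpers -------------------------------------------------
    def _flat(self, node) -> int:
        node = tuple(int(c) for c in node)
        if not all(0 <= c < d for c, d in zip(node, self.shape)):
            raise BoundsError(f"node {node} outside grid of shape {self.shape}")
        return int(np.ravel_multi_index(node, self.shape))

    def _unflat(self, flat: int) -> Index:
        return tuple(int(c) for c in np.unravel_index(int(flat), self.shape))

    def is_node(self, node) -> bool:
        return bool(self._valid[self._flat(node)])

    def neighbors(self, node) -> list:
        u = self._flat(node)
        return [self._unflat(v) for v in
                self._indices[self._indptr[u]:self._indptr[u + 1]]]

    @property
    def n_edges(self) -> int:
        return int(self._indices.size)

    # -- Q-value access ----------------------------------------------
    def _edge_pos(self, uf: int, vf: int) -> int:
        lo, hi = self._indptr[uf], self._indptr[uf + 1]
        pos = lo + int(np.searchsorted(self._indices[lo:hi], vf))
        if pos < hi and self._indices[pos] == vf:
            return pos
        return -1

    def get(self, u, v) -> float:
        """Q(u, v), or -1 when u and v are not adjacent."""
        pos = self._edge_pos(self._flat(u), self._flat(v))
        return float(self._values[pos]) if pos >= 0 else NO_TRANSITION

    def set(self, u, v, value: float) -> None:
        pos = self._edge_pos(self._flat(u), self._flat(v))
        if pos < 0:
            raise NoTransitionError(f"no transition {tuple(u)} -> {tuple(v)}")
        self._values[pos] = float(value)

    def min_outgoing(self, node) -> float:
        """Minimum finite outgoing Q of ``node``; 0 if terminal or isolated."""
        uf = self._flat(node)
        if uf in self.terminal:
            return 0.0
        lo, hi = self._indptr[uf], self._indptr[uf + 1]
        if hi == lo:
            return 0.0
        return float(self._values[lo:hi].min())


def build_adjacency(risk: RiskVolume, config: QLearningConfig):
    """CSR adjacency of the voxel grid under the configured connectivity.

    Voxels at or above ``barrier_threshold`` (when set) are dropped from the
    node set. Returns (indptr, indices, valid, weights) where ``weights`` is
    the per-edge move penalty step_cost(+scaling) + risk[destination].
    """
    shape = risk.shape
    n = int(np.prod(shape))
    valid = np.ones(shape, dtype=bool)
    if config.barrier_threshold is not None:
        valid = risk.risk < config.barrier_threshold
    coords = np.argwhere(valid)
    spacing = np.asarray(risk.spacing_mm)
    edges_u, edges_v, edges_w = [], [], []
    flat_risk = risk.risk.ravel()
    for off in config.offsets():
        dest = coords + off
        ok = np.all((dest >= 0) & (dest < np.asarray(shape)), axis=1)
        src_f = np.ravel_multi_index(coords[ok].T, shape)
        dst_f = np.ravel_multi_index(dest[ok].T, shape)
        keep = valid.ravel()[dst_f]
        src_f, dst_f = src_f[keep], dst_f[keep]
        step = config.step_cost
        if config.scale_diagonal:
            step = config.step_cost * float(np.linalg.norm(off * spacing))
        edges_u.append(src_f)
        edges_v.append(dst_f)
        edges_w.append(np.full(src_f.size, step) + flat_risk[dst_f])
    if edges_u:
        u = np.concatenate(edges_u)
        v = np.concatenate(edges_v)
        w = np.concatenate(edges_w)
        order = np.lexsort((v, u))
        u, v, w = u[order], v[order], w[order]
    else:
        u = v = np.empty(0, dtype=np.int64)
        w = np.empty(0, dtype=np.float64)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr[1:], u, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, v.astype(np.int64), valid.ravel(), w


def init_qtable(risk: RiskVolume, config: QLearningConfig) -> QTable:
    """Random-filled Q-table: one uniform draw from [0, q_init_scale) per
    ordered adjacent pair, -1 everywhere else. Identical seeds give
    identical tables."""
    indptr, indices, valid, _ = build_adjacency(risk, config)
    rng = np.random.default_rng(config.seed)
    values = config.q_init_scale * rng.random(indices.size)
    return QTable(risk.shape, indptr, indices, values, valid)


def bellman_update(q: QTable, s, a, penalty: float, config: QLearningConfig,
                   best_next: float | None = None) -> float:
    """One temporal-difference update of Q(s, a); returns the new value.

    ``penalty`` is the move cost R. ``best_next`` defaults to the minimum
    finite outgoing Q of ``a`` (0 if ``a`` is terminal or has no successor).
    """
    sf, af = q._flat(s), q._flat(a)
    pos = q._edge_pos(sf, af)
    if pos < 0:
        raise NoTransitionError(f"no transition {tuple(s)} -> {tuple(a)}")
    if best_next is None:
        best_next = q.min_outgoing(a)
    old = q._values[pos]
    new = old + config.alpha * (penalty + config.gamma * best_next - old)
    q._values[pos] = new
    return float(new)


def _check_endpoints(risk: RiskVolume, entry, target, config: QLearningConfig):
    geom = risk.geometry
    entry = tuple(int(c) for c in entry)
    target = frozenset(tuple(int(c) for c in t) for t in target)
    if not target:
        raise InvalidSpecError("target set is empty")
    if not geom.contains(entry):
        raise BoundsError(f"entry {entry} outside grid {risk.shape}")
    for t in target:
        if not geom.contains(t):
            raise BoundsError(f"target voxel {t} outside grid {risk.shape}")
    if config.barrier_threshold is not None:
        if risk.risk[entry] >= config.barrier_threshold:
            raise InvalidSpecError("entry voxel is excluded by barrier_threshold")
    return entry, target


def _reachable(indptr, indices, src_f: int, target_f: set) -> bool:
    n = indptr.size - 1
    seen = np.zeros(n, dtype=bool)
    seen[src_f] = True
    stack = [src_f]
    while stack:
        u = stack.pop()
        if u in target_f:
            return True
        for v in indices[indptr[u]:indptr[u + 1]]:
            if not seen[v]:
                seen[v] = True
                stack.append(int(v))
    return False


def train(risk: RiskVolume, entry, target, config: QLearningConfig) -> QTable:
    """Run epsilon-greedy episodes from ``entry`` until the greedy path is
    stable or ``episodes_max`` is reached; returns the trained table.

    The returned table carries ``episodes_run`` and ``converged`` (True when
    the early-stop stability window was met). All randomness — the initial
    table fill, the exploration draws — comes from ``config.seed``.
    """
    entry, target = _check_endpoints(risk, entry, target, config)
    if entry in target:
        raise InvalidSpecError("entry lies inside the target region")
    indptr, indices, valid, weights = build_adjacency(risk, config)
    q = QTable(risk.shape, indptr, indices,
               config.q_init_scale *
               np.random.default_rng(config.seed).random(indices.size), valid)
    shape = risk.shape
    target_f = {int(np.ravel_multi_index(t, shape)) for t in target}
    entry_f = int(np.ravel_multi_index(entry, shape))
    if not valid[entry_f] or not any(valid[t] for t in target_f):
        raise UnreachableError("entry or target excluded by barrier_threshold")
    if not _reachable(indptr, indices, entry_f, target_f):
        raise UnreachableError(
            "target not reachable from entry under the configured graph")
    if config.goal_terminal:
        q.terminal = frozenset(target_f)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    eps = config.epsilon_start
    step_cap = config.max_steps_per_episode or 4 * sum(shape)
    vals, ind, ptr = q._values, q._indices, q._indptr
    alpha, gamma = config.alpha, config.gamma
    goal_terminal = config.goal_terminal
    logger = _logger
    last_path = None
    stable = 0
    episodes = 0

    def update(k: int) -> None:
        a = int(ind[k])
        if a in target_f and goal_terminal:
            best_next = 0.0
        else:
            alo, ahi = ptr[a], ptr[a + 1]
            best_next = float(vals[alo:ahi].min()) if ahi > alo else 0.0
        vals[k] += alpha * (float(weights[k]) + gamma * best_next - vals[k])

    least_visited = config.exploration == "least_visited"
    visit_counts = np.zeros(ind.size, dtype=np.int64) if least_visited else None
    visited_mask = np.zeros(ind.size, dtype=bool)
    target_list = np.fromiter(target_f, dtype=np.int64)
    seg_starts = np.minimum(ptr[:-1], max(ind.size - 1, 0))
    seg_valid = np.diff(ptr) > 0

    def replay_sweep() -> None:
        """One synchronous Bellman pass over every visited transition."""
        visited_idx = np.flatnonzero(visited_mask)
        if visited_idx.size == 0 or ind.size == 0:
            return
        node_min = np.where(
            seg_valid, np.minimum.reduceat(vals, seg_starts), 0.0)
        if goal_terminal:
            node_min[target_list] = 0.0
        best_next = node_min[ind[visited_idx]]
        vals[visited_idx] += alpha * (
            weights[visited_idx] + gamma * best_next - vals[visited_idx])

    for episodes in range(1, config.episodes_max + 1):
        s = entry_f
        visited_edges = []
        for _ in range(step_cap):
            lo, hi = ptr[s], ptr[s + 1]
            if hi == lo:
                break  # dead end (isolated by barriers)
            if rng.random() < eps:
                if least_visited:
                    k = lo + int(np.argmin(visit_counts[lo:hi]))
                else:
                    k = lo + int(rng.integers(hi - lo))
            else:
                k = lo + int(np.argmin(vals[lo:hi]))
            if least_visited:
                visit_counts[k] += 1
            update(k)
            visited_edges.append(k)
            visited_mask[k] = True
            s = int(ind[k])
            if s in target_f:
                break
        if config.backward_replay:
            # propagate fresh cost-to-go information back along the episode
            for k in reversed(visited_edges):
                update(k)
        for _ in range(config.replay_sweeps):
            replay_sweep()
        eps = max(config.epsilon_min, eps * config.epsilon_decay)
        path = _greedy_flat(q, entry_f, target_f)
        if logger.isEnabledFor(logging.DEBUG):
            cost = (sum(float(weights[q._edge_pos(a, b)])
                        for a, b in zip(path, path[1:]))
                    if path else None)
            logger.debug("episode=%d epsilon=%.3f greedy_len=%s greedy_cost=%s",
                         episodes, eps,
                         len(path) if path else None,
                         f"{cost:.4f}" if cost is not None else None)
        if path is not None and path == last_path:
            stable += 1
            if stable >= config.stable_episodes:
                q.converged = True
                break
        else:
            stable = 0
            last_path = path
    q.episodes_run = episodes
    return q


def _greedy_flat(q: QTable, entry_f: int, target_f: set):
    """Greedy flat-index path, or None on a cycle/dead end."""
    vals, ind, ptr = q._values, q._indices, q._indptr
    path = [entry_f]
    seen = {entry_f}
    s = entry_f
    n_nodes = ptr.size - 1
    while s not in target_f:
        lo, hi = ptr[s], ptr[s + 1]
        if hi == lo:
            return None
        s = int(ind[lo + int(np.argmin(vals[lo:hi]))])
        if s in seen or len(path) > n_nodes:
            return None
        path.append(s)
        seen.add(s)
    return path


def extract_path(q: QTable, entry, target) -> VoxelPath:
    """Deterministic greedy descent: from ``entry``, repeatedly step to the
    neighbour with the minimum finite Q (ties broken by lexicographic voxel
    order) until the target region is reached.

    Raises :class:`~qpath.errors.NonConvergenceError` on a revisited node or
    a dead end — the signature of an insufficiently trained table.
    """
    entry = tuple(int(c) for c in entry)
    target = frozenset(tuple(int(c) for c in t) for t in target)
    if entry in target:
        return VoxelPath([entry])
    entry_f = q._flat(entry)
    target_f = {q._flat(t) for t in target}
    vals, ind, ptr = q._values, q._indices, q._indptr
    path = [entry_f]
    seen = {entry_f}
    s = entry_f
    n_nodes = ptr.size - 1
    while s not in target_f:
        lo, hi = ptr[s], ptr[s + 1]
        if hi == lo:
            raise NonConvergenceError(
                f"dead end at {q._unflat(s)} during greedy extraction")
        # neighbour ids are sorted ascending, so argmin's first-minimum rule
        # is exactly the lexicographic tie-break
        s = int(ind[lo + int(np.argmin(vals[lo:hi]))])
        if s in seen or len(path) > n_nodes:
            raise NonConvergenceError(
                f"cycle at {q._unflat(s)} during greedy extraction")
        path.append(s)
        seen.add(s)
    return VoxelPath([q._unflat(f) for f in path])


def q_score(q: QTable, path: VoxelPath) -> float:
    """Sum of the Q-values of the path's transitions (0 for a single node)."""
    total = 0.0
    for a, b in zip(path.nodes, path.nodes[1:]):
        v = q.get(a, b)
        if v == NO_TRANSITION:
            raise InvalidPathError(f"path uses non-transition {a} -> {b}")
        total += v
    return total


def path_penalty_cost(risk: RiskVolume, path: VoxelPath,
                      config: QLearningConfig) -> float:
    """Total move penalty sum(step_cost + risk[dest]) along a path — the
    quantity both the planner and the Dijkstra oracle minimise."""
    spacing = np.asarray(risk.spacing_mm)
    total = 0.0
    for a, b in zip(path.nodes, path.nodes[1:]):
        step = config.step_cost
        if config.scale_diagonal:
            off = np.asarray(b) - np.asarray(a)
            step = config.step_cost * float(np.linalg.norm(off * spacing))
        total += step + float(risk.risk[b])
    return total


def plan(risk: RiskVolume, entry, target, config: QLearningConfig) -> PlanResult:
    """Train, extract the greedy corridor, and score it.

    Returns a :class:`PlanResult` whose ``q_score`` is the summed Q-values
    along the corridor and whose ``qr_score`` is the summed per-voxel risk
    (entry voxel included, each voxel once).
    """
    from .geometry import path_total_risk

    entry_t, target_t = _check_endpoints(risk, entry, target, config)
    if entry_t in target_t:
        path = VoxelPath([entry_t])
        return PlanResult(path, 0.0, path_total_risk(path, risk), True, 0)
    q = train(risk, entry_t, target_t, config)
    path = extract_path(q, entry_t, target_t)
    return PlanResult(
        path=path,
        q_score=q_score(q, path),
        qr_score=path_total_risk(path, risk),
        converged=q.converged,
        episodes_run=q.episodes_run,
    )


def dijkstra_oracle(risk: RiskVolume, entry, target,
                    config: QLearningConfig) -> tuple[VoxelPath, float]:
    """Exact minimum-penalty path by Dijkstra over the same voxel graph.

    Minimises sum(step_cost + risk[destination]) over entry->target paths
    under the configured connectivity and barriers; ties are broken by
    lexicographic (flat-index) node order. Serves as the independent optimum
    against which the learned planner is validated.
    """
    entry, target = _check_endpoints(risk, entry, target, config)
    if entry in target:
        return VoxelPath([entry]), 0.0
    shape = risk.shape
    indptr, indices, valid, weights = build_adjacency(risk, config)
    entry_f = int(np.ravel_multi_index(entry, shape))
    target_f = {int(np.ravel_multi_index(t, shape)) for t in target}
    if not valid[entry_f]:
        raise UnreachableError("entry voxel excluded by barrier_threshold")
    n = indptr.size - 1
    dist = np.full(n, np.inf)
    pred = np.full(n, -1, dtype=np.int64)
    dist[entry_f] = 0.0
    heap = [(0.0, entry_f)]
    goal = -1
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        if u in target_f:
            goal = u
            break
        for k in range(indptr[u], indptr[u + 1]):
            v = int(indices[k])
            nd = d + float(weights[k])
            if nd < dist[v] - 1e-15:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
    if goal < 0:
        raise UnreachableError(
            "target not reachable from entry under the configured graph")
    chain = [goal]
    while chain[-1] != entry_f:
        chain.append(int(pred[chain[-1]]))
    chain.reverse()
    nodes = [tuple(int(c) for c in np.unravel_index(f, shape)) for f in chain]
    return VoxelPath(nodes), float(dist[goal])
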