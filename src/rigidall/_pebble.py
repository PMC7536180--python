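"""(6,6) body-bar pebble game kernel.

Bodies carry 6 pebbles; a bar between two bodies is accepted iff 7 pebbles
can be gathered on its endpoints (6 held + 1 free).  Accepted bars are
directed edges that consume one pebble of their tail; pebble searches are
depth-first and reverse the traversed path when a free pebble is found.

The kernel operates on flat numpy arrays so that it can be JIT-compiled
with numba when available; the same code runs (slowly) in pure Python
otherwise.  Out-degree is bounded by 6 (pebbles + out-edges = 6 per body),
so adjacency is a fixed ``(n, 6)`` table.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # noqa: D103 - transparent fallback
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


K = 6  # pebbles per body == trivial motions of a rigid body in 3-space


@njit(cache=False)
def _gather_one(pebbles, adj, nadj, pinned, visited, vstamp, parn, pars,
                stack, start):
    """Move one free pebble onto ``start`` if reachable; returns 1/0.

    Pinned bodies may be traversed but their pebbles are not taken.
    """
    vstamp[0] += 1
    stamp = vstamp[0]
    visited[start] = stamp
    stack[0] = start
    sp = 1
    while sp > 0:
        sp -= 1
        u = stack[sp]
        for s in range(nadj[u]):
            v = adj[u, s]
            if visited[v] == stamp:
                continue
            visited[v] = stamp
            parn[v] = u
            pars[v] = s
            if pebbles[v] > 0 and pinned[v] == 0:
                # success: move pebble to start, reversing the path
                pebbles[v] -= 1
                node = v
                while node != start:
                    pu = parn[node]
                    ps = pars[node]
                    nadj[pu] -= 1
                    adj[pu, ps] = adj[pu, nadj[pu]]
                    adj[node, nadj[node]] = pu
                    nadj[node] += 1
                    node = pu
                pebbles[start] += 1
                return 1
            stack[sp] = v
            sp += 1
    return 0


@njit(cache=False)
def _insert_edge(pebbles, adj, nadj, pinned, visited, vstamp, parn, pars,
                 stack, u, v, bars):
    """Insert ``bars`` parallel bars between u and v; returns accepted count."""
    accepted = 0
    for _ in range(bars):
        while pebbles[u] + pebbles[v] < K + 1:
            moved = 0
            if pebbles[u] < K:
                pinned[v] += 1
                moved = _gather_one(pebbles, adj, nadj, pinned, visited,
                                    vstamp, parn, pars, stack, u)
                pinned[v] -= 1
            if moved == 0 and pebbles[v] < K:
                pinned[u] += 1
                moved = _gather_one(pebbles, adj, nadj, pinned, visited,
                                    vstamp, parn, pars, stack, v)
                pinned[u] -= 1
            if moved == 0:
                return accepted  # remaining parallel bars are redundant too
        pebbles[u] -= 1
        adj[u, nadj[u]] = v
        nadj[u] += 1
        accepted += 1
    return accepted


@njit(cache=False)
def _run_game(pebbles, adj, nadj, pinned, visited, vstamp, parn, pars,
              stack, eu, ev, ebars, accepted):
    for e in range(eu.size):
        accepted[e] = _insert_edge(pebbles, adj, nadj, pinned, visited,
                                   vstamp, parn, pars, stack,
                                   eu[e], ev[e], ebars[e])


@njit(cache=False)
def _collect_on_set(pebbles, adj, nadj, pinned, visited, vstamp, parn, pars,
                    stack, members):
    """Maximum number of pebbles gatherable onto ``members`` (greedy pinning)."""
    total = 0
    for i in range(members.size):
        b = members[i]
        while pebbles[b] < K:
            if _gather_one(pebbles, adj, nadj, pinned, visited, vstamp,
                           parn, pars, stack, b) == 0:
                break
        pinned[b] += 1
        total += pebbles[b]
    for i in range(members.size):
        pinned[members[i]] -= 1
    return total


@njit(cache=False)
def _decompose(pebbles, adj, nadj, pinned, visited, vstamp, parn, pars,
               stack, indptr, indices):
    """Partition bodies into maximal mutually-rigid clusters.

    For each unlabeled seed u (ascending id): gather 6 pebbles on u, then
    test boundary bodies w by searching for a free pebble reachable from w
    (u's pebbles excluded).  A failed search proves every visited body rigid
    with u; a successful one proves w flexible relative to u.
    """
    n = pebbles.size
    labels = np.full(n, -1, np.int64)
    mark = np.full(n, -1, np.int64)
    vlist = np.empty(n, np.int64)
    qcap = indices.size + n + 8
    queue = np.empty(qcap, np.int64)
    for u in range(n):
        if labels[u] != -1:
            continue
        while pebbles[u] < K:
            if _gather_one(pebbles, adj, nadj, pinned, visited, vstamp,
                           parn, pars, stack, u) == 0:
                break
        labels[u] = u
        qh = 0
        qt = 0
        for j in range(indptr[u], indptr[u + 1]):
            queue[qt] = indices[j]
            qt += 1
        while qh < qt:
            w = queue[qh]
            qh += 1
            if labels[w] != -1 or mark[w] == u:
                continue
            vstamp[0] += 1
            stamp = vstamp[0]
            visited[w] = stamp
            stack[0] = w
            sp = 1
            found = 0
            count = 0
            vlist[count] = w
            count += 1
            if pebbles[w] > 0:
                found = 1
            while sp > 0 and found == 0:
                sp -= 1
                x = stack[sp]
                for s in range(nadj[x]):
                    y = adj[x, s]
                    if visited[y] == stamp:
                        continue
                    visited[y] = stamp
                    if y == u:
                        continue  # seed: pebbles pinned, no out-edges
                    if labels[y] == u:
                        continue  # already in cluster: pebble-free region
                    if mark[y] == u or pebbles[y] > 0:
                        found = 1
                        break
                    vlist[count] = y
                    count += 1
                    stack[sp] = y
                    sp += 1
            if found == 1:
                mark[w] = u
            else:
                # every body visited by the failed search is rigid with u
                for t in range(count):
                    x = vlist[t]
                    if labels[x] == -1:
                        labels[x] = u
                        for j in range(indptr[x], indptr[x + 1]):
                            if qt < qcap:
                                queue[qt] = indices[j]
                                qt += 1
    return labels


class PebbleState:
    """Mutable pebble-game state for one constraint graph."""

    __slots__ = ("n", "pebbles", "adj", "nadj", "pinned", "visited",
                 "vstamp", "parn", "pars", "stack")

    def __init__(self, n: int):
        self.n = n
        self.pebbles = np.full(n, K, dtype=np.int64)
        self.adj = np.zeros((n, K), dtype=np.int64)
        self.nadj = np.zeros(n, dtype=np.int64)
        self.pinned = np.zeros(n, dtype=np.int64)
        self.visited = np.zeros(n, dtype=np.int64)
        self.vstamp = np.zeros(1, dtype=np.int64)
        self.parn = np.zeros(n, dtype=np.int64)
        self.pars = np.zeros(n, dtype=np.int64)
        self.stack = np.zeros(max(n, 1), dtype=np.int64)

    def copy(self) -> "PebbleState":
        other = PebbleState.__new__(PebbleState)
        other.n = self.n
        for name in ("pebbles", "adj", "nadj", "pinned", "visited",
                     "vstamp", "parn", "pars", "stack"):
            setattr(other, name, getattr(self, name).copy())
        return other

    def _args(self):
        return (self.pebbles, self.adj, self.nadj, self.pinned,
                self.visited, self.vstamp, self.parn, self.pars, self.stack)

    # -- public operations -------------------------------------------------

    def insert_edges(self, eu: np.ndarray, ev: np.ndarray,
                     ebars: np.ndarray) -> np.ndarray:
        """Play all bars of the given edges; returns accepted-bar counts."""
        eu = np.ascontiguousarray(eu, dtype=np.int64)
        ev = np.ascontiguousarray(ev, dtype=np.int64)
        ebars = np.ascontiguousarray(ebars, dtype=np.int64)
        if eu.size and (eu.min() < 0 or max(eu.max(), ev.max()) >= self.n):
            raise ValueError("edge endpoint out of range")
        if np.any(eu == ev):
            raise ValueError("self-edges are not allowed")
        accepted = np.zeros(eu.size, dtype=np.int64)
        _run_game(*self._args(), eu, ev, ebars, accepted)
        return accepted

    def free_pebbles(self) -> int:
        return int(self.pebbles.sum())

    def collect_on(self, members: np.ndarray) -> int:
        """Max pebbles gatherable on a body set (mutates the state)."""
        members = np.unique(np.asarray(members, dtype=np.int64))
        if members.size == 0:
            raise ValueError("empty body set")
        return int(_collect_on_set(*self._args(), members))

    def decompose(self, indptr: np.ndarray, indices: np.ndarray) -> np.ndarray:
        """Rigid-cluster labels (smallest member id per cluster)."""
        return np.asarray(
            _decompose(*self._args(),
                       np.ascontiguousarray(indptr, dtype=np.int64),
                       np.ascontiguousarray(indices, dtype=np.int64))
        )
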