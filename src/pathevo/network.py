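"""Layered stochastic path networks.

The heritable substrate of the path evolution algorithm is a rooted, layered,
feed-forward network.  A single *start node* occupies layer 0; layers ``1..L``
hold phenotype-labelled nodes.  Every edge carries a transition probability and
the outflow of each node is kept normalized to one, so a random walk from the
start node ("traversal") selects exactly one node per layer and terminates on
reaching layer ``L``.  A *path* is one such walk; its *phenotype* is the ordered
sequence of node labels along it, and its *frequency* is the product of the
transition probabilities along its edges.

Coordinates are 0-based: phenotype position ``i`` corresponds to layer ``i+1``.

Node labels are either binary symbols (``0``/``1``) or real values clipped to
``[-1, 1]`` depending on the network's ``scheme``.
"""

from __future__ import annotations

import math
import random
from typing import Iterator

__all__ = [
    "BrokenNetworkError",
    "InvalidPathError",
    "EnumerationCapError",
    "LayeredPathNetwork",
    "init_network",
    "phenotype_str",
]

BINARY = "binary"
CONTINUOUS = "continuous"

#: default ceiling on exact path enumeration
ENUMERATION_CAP = 10**6

NORM_TOL = 1e-9


class BrokenNetworkError(RuntimeError):
    """A reachable node short of the final layer has no outgoing edges."""


class InvalidPathError(ValueError):
    """A node sequence is not a start-to-finish path of the network."""


class EnumerationCapError(RuntimeError):
    """Exact path enumeration would exceed the configured cap."""


def _clip_label(scheme: str, value) -> float | int:
    if scheme == BINARY:
        iv = int(value)
        if iv not in (0, 1):
            raise ValueError(f"binary label must be 0 or 1, got {value!r}")
        return iv
    return min(1.0, max(-1.0, float(value)))


class LayeredPathNetwork:
    """Layered DAG with normalized outflow weights and labelled nodes.

    Parameters
    ----------
    L : int
        Number of phenotype layers (path length).
    scheme : {"binary", "continuous"}
        Kind of node label.
    max_nodes_per_layer : int
        Cap on layer growth.  Structural operators refuse to create nodes in a
        layer at or above the cap; initialization with ``N`` parallel chains
        may exceed it (the cap gates growth, not construction).
    """

    def __init__(self, L: int, scheme: str = BINARY, max_nodes_per_layer: int = 1000):
        if L < 1:
            raise ValueError("L must be >= 1")
        if scheme not in (BINARY, CONTINUOUS):
            raise ValueError(f"unknown scheme {scheme!r}")
        if max_nodes_per_layer < 1:
            raise ValueError("max_nodes_per_layer must be >= 1")
        self.L = L
        self.scheme = scheme
        self.max_nodes_per_layer = max_nodes_per_layer
        self.layers: list[list[int]] = [[] for _ in range(L + 1)]
        self.label: dict[int, int | float | None] = {}
        self.layer_of: dict[int, int] = {}
        self.out_t: dict[int, list[int]] = {}
        self.out_w: dict[int, list[float]] = {}
        self.preds: dict[int, set[int]] = {}
        self.last_active: dict[int, int] = {}
        self._next_id = 0
        self.start = self.add_node(0, None)

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    def add_node(self, layer: int, label, generation: int = 0) -> int:
        if not (0 <= layer <= self.L):
            raise ValueError(f"layer {layer} out of range [0, {self.L}]")
        if layer == 0 and self.layers[0]:
            raise ValueError("layer 0 holds exactly one start node")
        nid = self._next_id
        self._next_id += 1
        self.layers[layer].append(nid)
        self.label[nid] = None if layer == 0 else _clip_label(self.scheme, label)
        self.layer_of[nid] = layer
        self.out_t[nid] = []
        self.out_w[nid] = []
        self.preds[nid] = set()
        self.last_active[nid] = generation
        return nid

    def add_edge(self, u: int, v: int, w: float) -> None:
        """Insert edge ``u -> v`` with raw weight ``w`` (no renormalization)."""
        if self.layer_of[v] != self.layer_of[u] + 1:
            raise ValueError("edges must connect adjacent layers, forward")
        if w <= 0:
            raise ValueError("edge weight must be positive")
        if v in self.out_t[u]:
            raise ValueError(f"edge {u}->{v} already exists")
        self.out_t[u].append(v)
        self.out_w[u].append(w)
        self.preds[v].add(u)

    def remove_edge(self, u: int, v: int) -> None:
        i = self.out_t[u].index(v)
        del self.out_t[u][i]
        del self.out_w[u][i]
        self.preds[v].discard(u)

    def remove_node(self, n: int) -> None:
        if n == self.start:
            raise ValueError("cannot remove the start node")
        for p in list(self.preds[n]):
            self.remove_edge(p, n)
            if self.out_t[p]:
                self.normalize(p)
        for v in list(self.out_t[n]):
            self.remove_edge(n, v)
        self.layers[self.layer_of[n]].remove(n)
        for d in (self.label, self.layer_of, self.out_t, self.out_w,
                  self.preds, self.last_active):
            del d[n]

    def edge_weight(self, u: int, v: int) -> float:
        try:
            return self.out_w[u][self.out_t[u].index(v)]
        except (ValueError, KeyError):
            raise InvalidPathError(f"no edge {u}->{v}") from None

    def set_edge_weight(self, u: int, v: int, w: float) -> None:
        self.out_w[u][self.out_t[u].index(v)] = w

    def ensure_edge_at_least(self, u: int, v: int, w: float) -> bool:
        """Create ``u -> v`` with weight ``w``, or raise an existing weight to
        at least ``w``.  Returns True if a new edge was created.  The caller
        renormalizes ``u``."""
        if v in self.out_t[u]:
            i = self.out_t[u].index(v)
            if self.out_w[u][i] < w:
                self.out_w[u][i] = w
            return False
        self.add_edge(u, v, w)
        return True

    def normalize(self, u: int) -> None:
        ws = self.out_w[u]
        if not ws:
            return
        s = sum(ws)
        if s <= 0:
            raise BrokenNetworkError(f"node {u} outflow sums to {s}")
        self.out_w[u] = [w / s for w in ws]

    @property
    def n_nodes(self) -> int:
        return len(self.layer_of)

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self.out_t.values())

    # ------------------------------------------------------------------
    # traversal and enumeration
    # ------------------------------------------------------------------
    def traverse(self, gamma: float = 0.0, rng: random.Random | None = None) -> tuple[int, ...]:
        """Generate one path by roulette-wheel traversal from the start node.

        With probability ``gamma`` at each step the next node is chosen
        uniformly among the outflow targets instead of weight-proportionally
        (epsilon-uniform exploration noise).
        """
        if rng is None:
            rng = random
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        cur = self.start
        path = [cur]
        for _ in range(self.L):
            ts = self.out_t[cur]
            if not ts:
                raise BrokenNetworkError(
                    f"node {cur} (layer {self.layer_of[cur]}) has no outflow")
            if len(ts) == 1:
                cur = ts[0]
            elif gamma > 0.0 and rng.random() < gamma:
                cur = ts[int(rng.random() * len(ts))]
            else:
                ws = self.out_w[cur]
                r = rng.random() * sum(ws)
                acc = 0.0
                cur = ts[-1]
                for t, w in zip(ts, ws):
                    acc += w
                    if r < acc:
                        cur = t
                        break
            path.append(cur)
        return tuple(path)

    def path_probability(self, path: tuple[int, ...]) -> float:
        self._check_path(path)
        p = 1.0
        for u, v in zip(path, path[1:]):
            p *= self.edge_weight(u, v)
        return p

    def _check_path(self, path: tuple[int, ...]) -> None:
        if len(path) != self.L + 1 or path[0] != self.start:
            raise InvalidPathError("path must run from the start node through layer L")
        for i, n in enumerate(path):
            if self.layer_of.get(n) != i:
                raise InvalidPathError(f"node {n} is not in layer {i}")

    def iter_paths(self, cap: int = ENUMERATION_CAP) -> Iterator[tuple[tuple[int, ...], float]]:
        """Depth-first enumeration of all paths with their probabilities."""
        count = 0
        stack: list[tuple[list[int], float]] = [([self.start], 1.0)]
        while stack:
            prefix, prob = stack.pop()
            u = prefix[-1]
            if len(prefix) == self.L + 1:
                count += 1
                if count > cap:
                    raise EnumerationCapError(f"more than {cap} paths")
                yield tuple(prefix), prob
                continue
            ts, ws = self.out_t[u], self.out_w[u]
            if not ts:
                raise BrokenNetworkError(
                    f"node {u} (layer {self.layer_of[u]}) has no outflow")
            for v, w in zip(ts, ws):
                stack.append((prefix + [v], prob * w))

    def enumerate_paths(self, cap: int = ENUMERATION_CAP) -> list[tuple[tuple[int, ...], float]]:
        return list(self.iter_paths(cap))

    def phenotype_of(self, path: tuple[int, ...]) -> tuple:
        """Ordered labels of the path's layer-1..L nodes."""
        return tuple(self.label[n] for n in path[1:])

    def phenotype_frequencies(self, cap: int = ENUMERATION_CAP) -> dict[tuple, float]:
        """Exact phenotype frequencies q_i: summed probabilities of all paths
        sharing a phenotype."""
        freqs: dict[tuple, float] = {}
        for path, prob in self.iter_paths(cap):
            ph = self.phenotype_of(path)
            freqs[ph] = freqs.get(ph, 0.0) + prob
        return freqs

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Assert the structural invariants; raise AssertionError on breach."""
        assert len(self.layers[0]) == 1, "exactly one start node"
        for layer in range(1, self.L + 1):
            assert self.layers[layer], f"layer {layer} is empty"
        for n, layer in self.layer_of.items():
            for v in self.out_t[n]:
                assert self.layer_of[v] == layer + 1, "layer-monotone edges"
                assert n in self.preds[v]
            ws = self.out_w[n]
            if ws:
                assert abs(sum(ws) - 1.0) < NORM_TOL, (
                    f"node {n} outflow sums to {sum(ws)}")
                assert all(w > 0 for w in ws), "positive weights"
            if layer == 0 or layer > 0 and self.label[n] is not None:
                pass
            if layer > 0:
                assert self.label[n] is not None, "non-start nodes carry labels"

    # ------------------------------------------------------------------
    # serialization: two-section plain text
    # ------------------------------------------------------------------
    def to_text(self) -> str:
        lines = [f"# layered path network L={self.L} scheme={self.scheme} "
                 f"cap={self.max_nodes_per_layer}", "[nodes]"]
        for layer in range(self.L + 1):
            for n in self.layers[layer]:
                lab = self.label[n]
                s = "-" if lab is None else (f"{lab:.12g}" if self.scheme == CONTINUOUS
                                             else str(lab))
                lines.append(f"{n}\t{layer}\t{s}")
        lines.append("[edges]")
        for layer in range(self.L + 1):
            for n in self.layers[layer]:
                for v, w in zip(self.out_t[n], self.out_w[n]):
                    lines.append(f"{n}\t{v}\t{w:.12g}")
        return "\n".join(lines) + "\n"

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "LayeredPathNetwork":
        header = None
        section = None
        nodes: list[tuple[int, int, str]] = []
        edges: list[tuple[int, int, float]] = []
        for raw in text.splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header = line
                continue
            if line in ("[nodes]", "[edges]"):
                section = line
                continue
            parts = line.split("\t")
            if section == "[nodes]":
                nodes.append((int(parts[0]), int(parts[1]), parts[2]))
            elif section == "[edges]":
                edges.append((int(parts[0]), int(parts[1]), float(parts[2])))
            else:
                raise ValueError(f"line outside any section: {raw!r}")
        if header is None:
            raise ValueError("missing header line")
        fields = dict(tok.split("=") for tok in header[1:].split() if "=" in tok)
        net = cls.__new__(cls)
        net.L = int(fields["L"])
        net.scheme = fields["scheme"]
        net.max_nodes_per_layer = int(fields.get("cap", 1000))
        net.layers = [[] for _ in range(net.L + 1)]
        net.label, net.layer_of = {}, {}
        net.out_t, net.out_w, net.preds, net.last_active = {}, {}, {}, {}
        for nid, layer, lab in nodes:
            net.layers[layer].append(nid)
            if lab == "-":
                net.label[nid] = None
            elif net.scheme == BINARY:
                net.label[nid] = int(lab)
            else:
                net.label[nid] = float(lab)
            net.layer_of[nid] = layer
            net.out_t[nid], net.out_w[nid] = [], []
            net.preds[nid] = set()
            net.last_active[nid] = 0
        for u, v, w in edges:
            net.out_t[u].append(v)
            net.out_w[u].append(w)
            net.preds[v].add(u)
        net._next_id = max(net.layer_of, default=-1) + 1
        net.start = net.layers[0][0]
        return net

    @classmethod
    def load(cls, path: str) -> "LayeredPathNetwork":
        with open(path) as fh:
            return cls.from_text(fh.read())

    def copy(self) -> "LayeredPathNetwork":
        return LayeredPathNetwork.from_text(self.to_text())


def init_network(N: int, L: int, scheme: str = BINARY,
                 max_nodes_per_layer: int = 1000,
                 rng: random.Random | None = None) -> LayeredPathNetwork:
    """Initialize ``N`` parallel chains of length ``L`` with random labels.

    The start node fans out to the head of each chain with weight ``1/N``;
    within-chain edges have weight 1.  Binary labels are fair coin flips,
    continuous labels uniform on [-1, 1].
    """
    if N < 1 or L < 1:
        raise ValueError("N and L must be >= 1")
    if rng is None:
        rng = random.Random()
    net = LayeredPathNetwork(L, scheme, max_nodes_per_layer)
    for _ in range(N):
        prev = net.start
        w = 1.0 / N
        for layer in range(1, L + 1):
            lab = (rng.randint(0, 1) if scheme == BINARY
                   else rng.uniform(-1.0, 1.0))
            nid = net.add_node(layer, lab)
            net.add_edge(prev, nid, w)
            prev, w = nid, 1.0
    return net


def phenotype_str(phenotype: tuple) -> str:
    """Render a binary phenotype tuple as a compact 0/1 string."""
    return "".join(str(int(b)) for b in phenotype)
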