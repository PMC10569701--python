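"""Parametric FSIN morphologies, SWC I/O, morphometrics and scaling.

Artificial fast-spiking interneuron (FSIN) morphologies are built from a small
set of interpretable parameters: the number of primary dendrites, the length of
nonterminal and terminal segments, and the dendritic diameter at the base and
at the tips.  Every dendrite is an identical binary tree whose terminal
segments sit at a fixed branch order, mirroring the stereotyped dendritic
architecture of cortical basket cells.  Dendritic diameter tapers linearly
with path distance from the soma.  A single unbranched axon is attached to the
soma.

Because the trees are parametric, every morphometric has a closed form, e.g.::

    total dendritic length = n_primary * (sum_{k<order} 2**(k-1) * NT
                                          + 2**(order-1) * T)
    branch points          = n_primary * (2**(order-1) - 1)

which the morphometric extractor recovers exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

SOMA, AXON, DEND = 1, 2, 3
_STRUCT_NAMES = {SOMA: "soma", AXON: "axon", DEND: "dendrite"}


@dataclass(frozen=True)
class MorphoParams:
    """Parameters of the artificial FSIN morphology.

    Lengths and diameters in µm.  ``terminal_order`` is the branch order of the
    terminal segments (primary dendrite = order 1).
    """

    n_primary: int
    nonterminal_len: float
    terminal_len: float
    diam_base: float = 1.25
    diam_terminal: float = 0.35
    terminal_order: int = 3
    axon_length: float = 500.0
    axon_diam: float = 0.2
    soma_diam: float = 15.0

    def __post_init__(self) -> None:
        for name in ("nonterminal_len", "terminal_len", "diam_base",
                     "diam_terminal", "axon_length", "axon_diam", "soma_diam"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_primary < 1:
            raise ValueError(f"n_primary must be >= 1, got {self.n_primary}")
        if self.terminal_order < 1:
            raise ValueError(f"terminal_order must be >= 1, got {self.terminal_order}")
        if self.diam_terminal > self.diam_base:
            raise ValueError("diam_terminal must not exceed diam_base")

    @property
    def tip_path_length(self) -> float:
        """Path distance from soma to any dendritic tip."""
        return (self.terminal_order - 1) * self.nonterminal_len + self.terminal_len

    @property
    def total_dendritic_length(self) -> float:
        nt = sum(2 ** (k - 1) for k in range(1, self.terminal_order)) * self.nonterminal_len
        t = 2 ** (self.terminal_order - 1) * self.terminal_len
        return self.n_primary * (nt + t)

    @property
    def n_branch_points(self) -> int:
        return self.n_primary * (2 ** (self.terminal_order - 1) - 1)


class NeuronTree:
    """Rooted branched morphology stored as parallel arrays (SWC-compatible).

    Node ids are 1-based (SWC convention); internally nodes are indexed 0-based
    with ``parent[i] == -1`` for the root.  ``cut[i]`` marks a terminal that was
    truncated (e.g. by slicing) rather than a true terminal; it is carried as an
    explicit annotation, never inferred from geometry.
    """

    def __init__(self, struct, xyz, radius, parent, cut=None):
        self.struct = np.asarray(struct, dtype=np.int32)
        self.xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        self.radius = np.asarray(radius, dtype=float)
        self.parent = np.asarray(parent, dtype=np.int64)
        n = self.struct.size
        self.cut = np.zeros(n, bool) if cut is None else np.asarray(cut, bool)
        self._validate()

    # -- structural helpers -------------------------------------------------
    def _validate(self) -> None:
        n = self.struct.size
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        if self.struct[roots[0]] != SOMA:
            raise ValueError("root node must be a soma node")
        if np.any(self.radius <= 0):
            raise ValueError("all radii must be positive")
        if np.any(self.parent >= n):
            raise ValueError("parent id out of range")
        # acyclicity/connectivity: every node must reach the root
        order = self.topological_order()
        if order.size != n:
            raise ValueError("tree is not connected/acyclic")

    def __len__(self) -> int:
        return self.struct.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> list:
        ch = [[] for _ in range(len(self))]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def topological_order(self) -> np.ndarray:
        """Node indices ordered root-first so that parents precede children."""
        ch = [[] for _ in range(len(self))]
        for i, p in enumerate(self.parent):
            if 0 <= p < len(self):
                ch[p].append(i)
        out, stack = [], [int(np.flatnonzero(self.parent < 0)[0])]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(reversed(ch[i]))
        return np.asarray(out, dtype=np.int64)

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of the edge from each node to its parent (0 at root)."""
        L = np.zeros(len(self))
        has_par = self.parent >= 0
        d = self.xyz[has_par] - self.xyz[self.parent[has_par]]
        L[has_par] = np.linalg.norm(d, axis=1)
        return L

    def path_distance(self) -> np.ndarray:
        """Path distance from the soma (root) to each node, µm."""
        L = self.edge_lengths()
        dist = np.zeros(len(self))
        for i in self.topological_order():
            p = self.parent[i]
            if p >= 0:
                dist[i] = dist[p] + L[i]
        return dist

    def branch_order(self) -> np.ndarray:
        """Branch order of the edge ending at each node (primary = 1, soma = 0).

        The order increments at every dendritic branch point (node with two or
        more children of the same structure type).
        """
        ch = self.children()
        order = np.zeros(len(self), dtype=np.int32)
        root = self.root
        for i in self.topological_order():
            p = self.parent[i]
            if p < 0:
                continue
            if p == root:
                order[i] = 1
            else:
                same = [c for c in ch[p] if self.struct[c] == self.struct[p]]
                order[i] = order[p] + (1 if len(same) >= 2 else 0)
        return order

    def tips(self, struct: int | None = DEND) -> np.ndarray:
        ch = self.children()
        idx = [i for i in range(len(self)) if not ch[i]]
        if struct is not None:
            idx = [i for i in idx if self.struct[i] == struct]
        return np.asarray(idx, dtype=np.int64)

    def branch_points(self, struct: int = DEND) -> np.ndarray:
        ch = self.children()
        out = []
        for i in range(len(self)):
            if self.struct[i] != struct or i == self.root:
                continue
            nchild = sum(1 for c in ch[i] if self.struct[c] == struct)
            if nchild >= 2:
                out.append(i)
        return np.asarray(out, dtype=np.int64)

    def segments(self, struct: int = DEND) -> list:
        """Unbranched stretches as lists of node indices (first node = origin).

        A segment runs between consecutive topological points (soma, branch
        point, tip).  The origin node (soma or branch point) is included so the
        segment's length is the sum of its edge lengths.
        """
        ch = self.children()
        root = self.root
        segs = []
        # segment starts: children (of matching struct) of soma or of branch pts
        starts = []
        for i in range(len(self)):
            for c in ch[i]:
                if self.struct[c] != struct:
                    continue
                same = [k for k in ch[i] if self.struct[k] == self.struct[c]]
                if i == root or len(same) >= 2 or self.struct[i] != struct:
                    starts.append((i, c))
        for origin, first in starts:
            seg = [origin, first]
            node = first
            while True:
                nxt = [c for c in ch[node] if self.struct[c] == struct]
                if len(nxt) != 1:
                    break
                node = nxt[0]
                seg.append(node)
            segs.append(seg)
        return segs

    def copy(self) -> "NeuronTree":
        return NeuronTree(self.struct.copy(), self.xyz.copy(),
                          self.radius.copy(), self.parent.copy(), self.cut.copy())


@dataclass
class MorphoFeatures:
    """Morphometric features of a dendritic arbor (lengths in µm)."""

    total_dendritic_length: float
    n_branch_points: int
    n_primary_dendrites: int
    mean_diam_per_branch_order: dict
    mean_tip_to_soma_path: float
    mean_nonterminal_segment_len: float
    median_terminal_segment_len: float


def generate_morphology(params: MorphoParams, geometry_seed: int = 0,
                        node_step: float = 10.0,
                        segment_length_fn=None) -> NeuronTree:
    """Build an artificial FSIN morphology from ``params``.

    Each of the ``n_primary`` dendrites is an identical binary tree: segments at
    branch orders below ``terminal_order`` have length ``nonterminal_len``;
    terminal-order segments have length ``terminal_len``.  Diameter tapers
    linearly with path distance from ``diam_base`` at the soma to
    ``diam_terminal`` at the tips, with each node's radius sampled at the
    midpoint of its edge.  Dendrites are laid out as straight radial lines in
    the xy-plane (3-D placement is cosmetic; path metrics do not depend on it).
    The axon is a single unbranched cable along -z.

    Parameters
    ----------
    geometry_seed:
        Seeds the small angular jitter of the 3-D embedding only.
    node_step:
        Maximum spacing of SWC nodes along a segment, so the linear taper is
        sampled with adequate resolution.
    segment_length_fn:
        Optional ``f(dendrite, order, index_in_order) -> length`` override used
        by the synthetic-morphology generator to jitter segment lengths.
    """
    rng = np.random.default_rng(geometry_seed)
    p = params
    tip_path = p.tip_path_length

    struct = [SOMA]
    xyz = [(0.0, 0.0, 0.0)]
    radius = [p.soma_diam / 2.0]
    parent = [-1]

    def diam_at(path_mid: float) -> float:
        f = min(path_mid / tip_path, 1.0) if tip_path > 0 else 0.0
        return p.diam_base + (p.diam_terminal - p.diam_base) * f

    def add_straight(par_idx, origin, direction, origin_path, length, stype,
                     diam_fn=None):
        """Append nodes every <= node_step µm along a straight run; return last idx."""
        n_nodes = max(1, math.ceil(length / node_step))
        step = length / n_nodes
        idx = par_idx
        for k in range(1, n_nodes + 1):
            pos = origin + direction * (step * k)
            mid = origin_path + step * (k - 0.5)
            d = diam_fn(mid) if diam_fn else diam_at(mid)
            struct.append(stype)
            xyz.append(tuple(pos))
            radius.append(d / 2.0)
            parent.append(idx)
            idx = len(struct) - 1
        return idx

    for dend in range(p.n_primary):
        base_angle = 2 * math.pi * dend / p.n_primary + rng.uniform(-0.05, 0.05)
        # each entry: (parent idx, origin xyz, angle, path distance at origin)
        frontier = [(0, np.zeros(3), base_angle, 0.0)]
        for order in range(1, p.terminal_order + 1):
            default_len = p.terminal_len if order == p.terminal_order else p.nonterminal_len
            spread = 0.5 / order  # fan-out half-angle, purely cosmetic
            new_frontier = []
            for j, (par_idx, origin, angle, opath) in enumerate(frontier):
                length = (segment_length_fn(dend, order, j)
                          if segment_length_fn else default_len)
                direction = np.array([math.cos(angle), math.sin(angle), 0.0])
                last = add_straight(par_idx, origin, direction, opath, length, DEND)
                end = origin + direction * length
                if order < p.terminal_order:
                    new_frontier.append((last, end, angle - spread, opath + length))
                    new_frontier.append((last, end, angle + spread, opath + length))
            frontier = new_frontier

    # axon: straight along -z, constant diameter
    add_straight(0, np.zeros(3), np.array([0.0, 0.0, -1.0]), 0.0,
                 p.axon_length, AXON, diam_fn=lambda _m: p.axon_diam)

    return NeuronTree(struct, xyz, radius, parent)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def write_swc(tree: NeuronTree, path, sidecar: bool = True) -> None:
    """Write a 7-column SWC file; cut-terminal flags go to a ``<path>.cut`` sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(len(tree)):
            par = tree.parent[i] + 1 if tree.parent[i] >= 0 else -1
            x, y, z = tree.xyz[i]
            fh.write(f"{i + 1} {tree.struct[i]} {x:.6f} {y:.6f} {z:.6f} "
                     f"{tree.radius[i]:.6f} {par}\n")
    cut_ids = np.flatnonzero(tree.cut)
    side = path.with_suffix(path.suffix + ".cut")
    if sidecar and cut_ids.size:
        with open(side, "w") as fh:
            for i in cut_ids:
                fh.write(f"{i + 1} cut_terminal\n")
    elif side.exists():
        side.unlink()


class SWCError(ValueError):
    pass


def read_swc(path) -> NeuronTree:
    """Read a 7-column SWC file (and its ``.cut`` sidecar if present)."""
    path = Path(path)
    ids, struct, xyz, radius, parent_ids = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                ids.append(int(parts[0]))
                struct.append(int(parts[1]))
                xyz.append(tuple(float(v) for v in parts[2:5]))
                radius.append(float(parts[5]))
                parent_ids.append(int(parts[6]))
            except ValueError as e:
                raise SWCError(f"{path}:{lineno}: malformed value ({e})") from None
            if radius[-1] <= 0:
                raise SWCError(f"{path}:{lineno}: non-positive radius")
    if not ids:
        raise SWCError(f"{path}: no nodes")
    id_to_idx = {nid: k for k, nid in enumerate(ids)}
    if len(id_to_idx) != len(ids):
        raise SWCError(f"{path}: duplicate node ids")
    parent = []
    for k, pid in enumerate(parent_ids):
        if pid == -1:
            parent.append(-1)
        elif pid not in id_to_idx:
            raise SWCError(f"{path}: node {ids[k]} references missing parent {pid}")
        else:
            parent.append(id_to_idx[pid])
    n_roots = sum(1 for p in parent if p < 0)
    if n_roots != 1:
        raise SWCError(f"{path}: expected exactly one root, found {n_roots}")
    cut = np.zeros(len(ids), bool)
    side = path.with_suffix(path.suffix + ".cut")
    if side.exists():
        with open(side) as fh:
            for line in fh:
                parts = line.split()
                if parts and parts[1] == "cut_terminal":
                    cut[id_to_idx[int(parts[0])]] = True
    try:
        return NeuronTree(struct, xyz, radius, parent, cut)
    except ValueError as e:
        raise SWCError(f"{path}: {e}") from None


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

def morphometrics(tree: NeuronTree, exclude_cut_terminals: bool = False) -> MorphoFeatures:
    """Compute the dendritic morphometric feature set.

    With ``exclude_cut_terminals`` set, tip-path and terminal-segment statistics
    are computed only over terminals annotated as true terminals (the rest of
    the features are unaffected).  If no true terminal remains, those statistics
    are reported as NaN.
    """
    is_dend = tree.struct == DEND
    if not np.any(is_dend):
        raise ValueError("tree has no dendrites")
    L = tree.edge_lengths()
    total_len = float(L[is_dend].sum())

    bps = tree.branch_points(DEND)
    ch = tree.children()
    root = tree.root
    n_primary = sum(1 for c in ch[root] if tree.struct[c] == DEND)

    order = tree.branch_order()
    orders = np.unique(order[is_dend])
    diam_per_order = {}
    for o in orders:
        sel = is_dend & (order == o)
        w = L[sel]
        diam_per_order[int(o)] = float(np.average(2 * tree.radius[sel], weights=w)
                                       if w.sum() > 0 else np.mean(2 * tree.radius[sel]))

    dist = tree.path_distance()
    tips = tree.tips(DEND)
    segs = tree.segments(DEND)
    seg_len = [float(sum(L[i] for i in seg[1:])) for seg in segs]
    seg_is_terminal = [len(ch[seg[-1]]) == 0 for seg in segs]
    seg_tip_cut = [tree.cut[seg[-1]] if seg_is_terminal[k] else False
                   for k, seg in enumerate(segs)]

    if exclude_cut_terminals:
        good_tips = np.asarray([t for t in tips if not tree.cut[t]], dtype=np.int64)
    else:
        good_tips = tips
    tip_path = float(np.mean(dist[good_tips])) if good_tips.size else float("nan")

    nonterm = [l for l, it in zip(seg_len, seg_is_terminal) if not it]
    term = [l for k, (l, it) in enumerate(zip(seg_len, seg_is_terminal))
            if it and not (exclude_cut_terminals and seg_tip_cut[k])]
    return MorphoFeatures(
        total_dendritic_length=total_len,
        n_branch_points=int(bps.size),
        n_primary_dendrites=int(n_primary),
        mean_diam_per_branch_order=diam_per_order,
        mean_tip_to_soma_path=tip_path,
        mean_nonterminal_segment_len=float(np.mean(nonterm)) if nonterm else float("nan"),
        median_terminal_segment_len=float(np.median(term)) if term else float("nan"),
    )


def scale_dendrites(tree: NeuronTree, factor: float) -> NeuronTree:
    """Scale all dendritic segment lengths by ``factor``.

    Dendritic node positions are scaled about the soma, which multiplies every
    dendritic edge length by ``factor`` while leaving diameters, topology and
    the axon untouched.
    """
    if factor <= 0:
        raise ValueError(f"factor must be positive, got {factor}")
    out = tree.copy()
    soma_pos = tree.xyz[tree.root]
    is_dend = tree.struct == DEND
    out.xyz[is_dend] = soma_pos + factor * (tree.xyz[is_dend] - soma_pos)
    return out
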