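"""Root-system-architecture graphs from binary masks.

Each plant mask is skeletonized, the skeleton is traversed depth-first
from the seed (topmost skeleton pixel unless a hint is given), and a
graph is built whose nodes are the seed, bifurcations (pixels with 3+
skeleton neighbours) and tips (degree-1 pixels).  Edges store the
traversed pixel path and its arc length (1 px per 4-neighbour step,
sqrt(2) per diagonal, scaled by mm/px).

Labels are assigned per frame and propagated through time: in the
first frame the unique seed-to-tip path is the main root (MR); later
the MR tip is the node nearest the previous MR tip, branches off the
seed-to-MR-tip path are lateral roots (LRs), and LR tips keep their
identity by nearest-neighbour matching, so an LR that touches the MR
or another LR is still reported as a tip.  Labelled graph sequences
can be exported to RSML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from lxml import etree
from skimage.morphology import skeletonize as _skimage_skeletonize

__all__ = [
    "Skeleton", "RootGraph", "skeletonize_mask", "graph_from_skeleton",
    "label_roots", "simplify_graph", "write_rsml", "read_rsml",
]

# DFS neighbour order: clockwise starting from "down" (row grows downward)
_NEIGHBOURS = ((1, 0), (1, -1), (0, -1), (-1, -1),
               (-1, 0), (-1, 1), (0, 1), (1, 1))
_SQRT2 = float(np.sqrt(2.0))


@dataclass
class Skeleton:
    """1-px-wide medial representation of a root mask."""

    image: np.ndarray           # bool array

    @property
    def pixels(self) -> np.ndarray:
        return np.argwhere(self.image)

    def __len__(self) -> int:
        return int(self.image.sum())


@dataclass
class RootGraph:
    """Labelled skeleton graph of one plant at one time point.

    Nodes are (row, col) pixel tuples with a ``label`` attribute in
    {seed, mr_tip, bifurcation, lr_tip}; edges carry ``path`` (pixel
    list), ``length_mm`` and, once labelled, ``root`` ("MR" or an
    integer LR identifier).
    """

    graph: nx.Graph
    seed: tuple[int, int]
    mm_per_px: float = 1.0
    timestamp_h: float | None = None
    labelled: bool = False
    tracking_failure: bool = False

    @property
    def tips(self) -> list[tuple[int, int]]:
        return [n for n in self.graph.nodes if self.graph.degree(n) <= 1
                and n != self.seed]

    @property
    def mr_tip(self) -> tuple[int, int] | None:
        for n, d in self.graph.nodes(data=True):
            if d.get("label") == "mr_tip":
                return n
        return None

    @property
    def lr_tips(self) -> dict[int, tuple[int, int]]:
        return {d["lr_id"]: n for n, d in self.graph.nodes(data=True)
                if d.get("label") == "lr_tip"}

    @property
    def mr_length_mm(self) -> float:
        return float(sum(d["length_mm"] for _, _, d in
                         self.graph.edges(data=True) if d.get("root") == "MR"))

    @property
    def lr_lengths_mm(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for _, _, d in self.graph.edges(data=True):
            r = d.get("root")
            if isinstance(r, int):
                out[r] = out.get(r, 0.0) + d["length_mm"]
        return out

    @property
    def total_length_mm(self) -> float:
        return float(sum(d["length_mm"]
                         for _, _, d in self.graph.edges(data=True)))


def path_length_mm(path, mm_per_px: float) -> float:
    """Arc length of an 8-connected pixel path."""
    p = np.asarray(path)
    if len(p) < 2:
        return 0.0
    steps = np.abs(np.diff(p, axis=0))
    return float(np.where(steps.sum(axis=1) == 2, _SQRT2, 1.0).sum()
                 * mm_per_px)


def skeletonize_mask(mask: np.ndarray) -> Skeleton:
    """Topology-preserving thinning of a binary mask.

    An empty mask yields an empty skeleton; connectivity of the single
    input component is preserved by the thinning algorithm.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return Skeleton(np.zeros_like(mask))
    return Skeleton(_skimage_skeletonize(mask).astype(bool))


def _adjacency(image: np.ndarray):
    """8-neighbourhood adjacency of skeleton pixels, DFS order fixed."""
    pix = set(map(tuple, np.argwhere(image)))
    adj = {}
    for (r, c) in pix:
        adj[(r, c)] = [(r + dr, c + dc) for dr, dc in _NEIGHBOURS
                       if (r + dr, c + dc) in pix]
    return adj


def _prune_spurs(g: nx.Graph, seed, prune_px: float, mm_per_px: float):
    """Remove junction-attached leaf twigs shorter than ``prune_px``.

    Thinning a stroke several pixels wide leaves 1-2 px side twigs at
    junctions and blunt ends; genuine young laterals are longer than
    the stroke width, so a sub-stroke threshold separates the two.
    After pruning, chains through now-degree-2 junctions are re-merged.
    """
    limit = prune_px * mm_per_px
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if n == seed or g.degree(n) != 1:
                continue
            (nb,) = g.neighbors(n)
            if g.degree(nb) >= 3 and g.edges[n, nb]["length_mm"] < limit:
                g.remove_node(n)
                changed = True
        for n in list(g.nodes):
            if n == seed or g.degree(n) != 2:
                continue
            (a, da), (b, db) = [(x, g.edges[n, x]) for x in g.neighbors(n)]
            if a == b or g.has_edge(a, b):
                continue
            pa = da["path"] if da["path"][-1] == n else da["path"][::-1]
            pb = db["path"] if db["path"][0] == n else db["path"][::-1]
            g.add_edge(a, b, path=pa + pb[1:],
                       length_mm=da["length_mm"] + db["length_mm"],
                       root=None)
            g.remove_node(n)
            changed = True


def graph_from_skeleton(skeleton: Skeleton,
                        seed_hint: tuple[int, int] | None = None,
                        mm_per_px: float = 1.0,
                        timestamp_h: float | None = None,
                        prune_px: float = 3.0) -> RootGraph:
    """Condensed graph from a one-component skeleton via DFS.

    The traversal starts at the seed: the topmost skeleton pixel
    (minimum row, then minimum column), or the skeleton pixel nearest
    ``seed_hint``.  Neighbours are visited in a fixed clockwise order
    starting from "down", so traversal and bifurcation tie-breaks are
    deterministic.  Non-tree (cycle-closing) adjacencies are ignored;
    the DFS tree is condensed so that only the seed, bifurcations and
    tips remain as nodes, with pixel paths and arc lengths on edges.
    """
    if len(skeleton) == 0:
        raise ValueError("cannot build a graph from an empty skeleton")
    adj = _adjacency(skeleton.image)
    pixels = sorted(adj)
    # connectivity check
    comp_seen = {pixels[0]}
    stack = [pixels[0]]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in comp_seen:
                comp_seen.add(nb)
                stack.append(nb)
    if len(comp_seen) != len(pixels):
        raise ValueError("skeleton has multiple connected components")

    if seed_hint is not None:
        arr = np.asarray(pixels)
        seed = tuple(arr[np.argmin(((arr - np.asarray(seed_hint)) ** 2)
                                   .sum(axis=1))])
    else:
        seed = min(pixels)          # min row, then min col

    # iterative DFS building a tree over skeleton pixels
    parent: dict = {seed: None}
    children: dict = {p: [] for p in pixels}
    stack = [seed]
    visited = {seed}
    order = []
    while stack:
        cur = stack.pop()
        order.append(cur)
        # push reversed so the first-listed neighbour is explored first
        for nb in reversed(adj[cur]):
            if nb not in visited:
                visited.add(nb)
                parent[nb] = cur
                children[cur].append(nb)
                stack.append(nb)
    for c in children.values():
        c.reverse()   # restore clockwise-from-down priority

    def is_node(p):
        deg = len(children[p]) + (0 if parent[p] is None else 1)
        return p == seed or deg != 2

    g = nx.Graph()
    g.add_node(seed, label=None)
    stack = [(seed, child) for child in children[seed]]
    while stack:
        node, first = stack.pop()
        path = [node, first]
        cur = first
        while not is_node(cur):
            nxt = children[cur][0]
            path.append(nxt)
            cur = nxt
        g.add_node(cur, label=None)
        g.add_edge(node, cur, path=path,
                   length_mm=path_length_mm(path, mm_per_px), root=None)
        for child in children[cur]:
            stack.append((cur, child))
    if prune_px > 0:
        _prune_spurs(g, seed, prune_px, mm_per_px)
    return RootGraph(graph=g, seed=seed, mm_per_px=mm_per_px,
                     timestamp_h=timestamp_h)


def _nearest(node, candidates, gate_px=None):
    if not candidates:
        return None
    arr = np.asarray(candidates, dtype=float)
    d = np.sqrt(((arr - np.asarray(node, dtype=float)) ** 2).sum(axis=1))
    i = int(np.argmin(d))
    if gate_px is not None and d[i] > gate_px:
        return None
    return candidates[i]


def label_roots(graph: RootGraph, prev_graph: RootGraph | None = None,
                gate_px: float = 20.0) -> RootGraph:
    """Assign seed/MR/LR labels, tracking identities across frames.

    First frame: the seed-to-deepest-tip path is the MR (in early
    growth there is only the MR, seed at top, tip at bottom).  Later
    frames: the MR tip is the node nearest the previous MR tip; every
    previous LR tip is matched to its nearest current node, so a tip
    stays a tip even when its root collides with the MR or another LR;
    unmatched tips start new LRs.  If the previous MR tip has no match
    within ``gate_px`` the frame is flagged as a tracking failure and
    the fallback (deepest tip) is used.
    """
    g = graph.graph
    nodes = list(g.nodes)
    for n in nodes:
        g.nodes[n]["label"] = None
        g.nodes[n].pop("lr_id", None)
    for _, _, d in g.edges(data=True):
        d["root"] = None

    seed = graph.seed
    g.nodes[seed]["label"] = "seed"
    graph.tracking_failure = False

    if len(nodes) == 1:     # seed only, nothing grown yet
        graph.labelled = True
        return graph

    leaves = [n for n in nodes if g.degree(n) == 1 and n != seed]
    if not leaves:
        leaves = [max(nodes)]

    def deepest_tip():
        # tip of the longest seed->leaf path (ties: lowest then leftmost)
        best, best_len = None, -1.0
        for leaf in leaves:
            length = nx.shortest_path_length(g, seed, leaf, weight="length_mm")
            if length > best_len or (length == best_len and leaf < best):
                best, best_len = leaf, length
        return best

    if prev_graph is None or prev_graph.mr_tip is None:
        mr_tip = deepest_tip()
    else:
        # the MR tip stays a tip; only if no leaf is in reach (e.g. the
        # tip merged into another root) fall back to any non-seed node
        mr_tip = _nearest(prev_graph.mr_tip, leaves, gate_px)
        if mr_tip is None:
            mr_tip = _nearest(prev_graph.mr_tip,
                              [n for n in nodes if n != seed], gate_px)
        if mr_tip is None:
            graph.tracking_failure = True
            mr_tip = deepest_tip()
    g.nodes[mr_tip]["label"] = "mr_tip"

    mr_path = nx.shortest_path(g, seed, mr_tip, weight="length_mm")
    mr_nodes = set(mr_path)
    for a, b in zip(mr_path[:-1], mr_path[1:]):
        g.edges[a, b]["root"] = "MR"

    # ---- lateral roots: match previous tips, then register new ones
    next_id = 1
    assigned_tips: set = set()
    matches: list[tuple[int, tuple[int, int]]] = []
    if prev_graph is not None:
        next_id = max(prev_graph.lr_tips.keys(), default=0) + 1
        candidates = [n for n in nodes if n not in (seed, mr_tip)]
        for lr_id in sorted(prev_graph.lr_tips):
            tip = _nearest(prev_graph.lr_tips[lr_id],
                           [c for c in candidates if c not in assigned_tips],
                           gate_px)
            if tip is not None:
                matches.append((lr_id, tip))
                assigned_tips.add(tip)
    for leaf in sorted(leaves):
        if leaf != mr_tip and leaf not in assigned_tips:
            matches.append((next_id, leaf))
            assigned_tips.add(leaf)
            next_id += 1

    claimed: set = set()
    for lr_id, tip in matches:
        g.nodes[tip]["label"] = "lr_tip"
        g.nodes[tip]["lr_id"] = lr_id
        # walk from the tip toward the MR, claiming unclaimed edges
        target = _nearest(tip, list(mr_nodes))
        path = nx.shortest_path(g, tip, target, weight="length_mm")
        for a, b in zip(path[:-1], path[1:]):
            e = frozenset((a, b))
            if g.edges[a, b]["root"] is None and e not in claimed:
                g.edges[a, b]["root"] = lr_id
                claimed.add(e)

    # orphan edges (side branches of LRs whose path merged): absorb into
    # the LR of a labelled neighbouring edge, iterating to a fixpoint so
    # chains of orphans resolve deterministically
    changed = True
    while changed:
        changed = False
        for a, b, d in g.edges(data=True):
            if d["root"] is not None:
                continue
            lr = [g.edges[e]["root"] for n in (a, b) for e in g.edges(n)
                  if isinstance(g.edges[e]["root"], int)]
            if lr:
                d["root"] = min(lr)
                changed = True
            elif a in mr_nodes or b in mr_nodes:
                d["root"] = "MR"
                changed = True

    for n in nodes:
        if g.nodes[n]["label"] is None:
            g.nodes[n]["label"] = ("bifurcation" if g.degree(n) >= 3
                                   else "internal")
    graph.labelled = True
    return graph


def simplify_graph(graph: RootGraph) -> RootGraph:
    """Collapse unlabelled degree-2 nodes, preserving arc lengths.

    The result keeps only the seed, bifurcations and tips, with each
    merged edge's length equal to the sum of its parts (and the
    concatenated pixel path).
    """
    g = graph.graph.copy()
    removable = [n for n in g.nodes
                 if g.degree(n) == 2
                 and g.nodes[n].get("label") in (None, "internal")]
    for n in removable:
        (a, da), (b, db) = [(nb, g.edges[n, nb]) for nb in g.neighbors(n)]
        if a == b or g.has_edge(a, b):
            continue    # keep nodes whose removal would create multi-edges
        pa = da["path"] if da["path"][-1] == n else da["path"][::-1]
        pb = db["path"] if db["path"][0] == n else db["path"][::-1]
        root = da.get("root") if da.get("root") == db.get("root") else None
        if root is None:
            continue    # never merge across root-class boundaries
        g.add_edge(a, b, path=pa + pb[1:],
                   length_mm=da["length_mm"] + db["length_mm"], root=root)
        g.remove_node(n)
    out = RootGraph(graph=g, seed=graph.seed, mm_per_px=graph.mm_per_px,
                    timestamp_h=graph.timestamp_h, labelled=graph.labelled,
                    tracking_failure=graph.tracking_failure)
    return out


# ------------------------------------------------------------- RSML

_RSML_VERSION = "1.0"


def _root_element(graph: RootGraph, root_key, parent_el, root_id: str,
                  label: str):
    edges = [(a, b, d) for a, b, d in graph.graph.edges(data=True)
             if d.get("root") == root_key]
    if not edges:
        return
    # order the pixel path from origin to tip
    if root_key == "MR":
        origin, tip = graph.seed, graph.mr_tip
    else:
        tip = {d["lr_id"]: n for n, d in graph.graph.nodes(data=True)
               if d.get("lr_id") is not None}.get(root_key)
        sub = nx.Graph((a, b) for a, b, _ in edges)
        ends = [n for n in sub.nodes if sub.degree(n) == 1]
        origin = min((e for e in ends if e != tip), default=tip)
    sub = nx.Graph()
    for a, b, d in edges:
        sub.add_edge(a, b, **d)
    try:
        node_seq = nx.shortest_path(sub, origin, tip, weight="length_mm")
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        node_seq = list(sub.nodes)
    pts: list = []
    for a, b in zip(node_seq[:-1], node_seq[1:]):
        p = sub.edges[a, b]["path"]
        if p[0] != a:
            p = p[::-1]
        pts.extend(p if not pts else p[1:])
    if not pts:
        pts = [origin]
    length = sum(d["length_mm"] for _, _, d in edges)

    el = etree.SubElement(parent_el, "root",
                          ID=root_id, label=label)
    props = etree.SubElement(el, "properties")
    etree.SubElement(props, "length").text = f"{length:.9f}"
    geom = etree.SubElement(el, "geometry")
    poly = etree.SubElement(geom, "polyline")
    s = graph.mm_per_px
    for r, c in pts:
        etree.SubElement(poly, "point", x=f"{c * s:.9f}", y=f"{r * s:.9f}")
    return el


def _scene_element(graph: RootGraph, parent, plant_id: str):
    scene = etree.SubElement(parent, "scene")
    plant = etree.SubElement(scene, "plant", ID=plant_id, label=plant_id)
    mr_el = _root_element(graph, "MR", plant, f"{plant_id}_MR", "MR")
    host = mr_el if mr_el is not None else plant
    for lr_id in sorted(graph.lr_lengths_mm):
        _root_element(graph, lr_id, host, f"{plant_id}_LR{lr_id}", "LR")
    return scene


def write_rsml(graph_sequence, path, plant_id: str = "plant1",
               consolidated: bool = False) -> list[Path]:
    """Export labelled graphs to RSML 1.0 documents.

    One document per time step named ``<plant>_<frame>.rsml``; with
    ``consolidated=True`` a single file holds one scene per time step.
    Each root is a polyline in mm with its arc length as a property;
    metadata records the time stamp and image resolution.
    """
    graphs = list(graph_sequence)
    if any(not g.labelled for g in graphs):
        raise ValueError("write_rsml requires labelled graphs")
    path = Path(path)

    def document(gs):
        rsml = etree.Element("rsml", version=_RSML_VERSION)
        md = etree.SubElement(rsml, "metadata")
        etree.SubElement(md, "version").text = "1"
        etree.SubElement(md, "unit").text = "mm"
        etree.SubElement(md, "resolution").text = str(gs[0].mm_per_px)
        etree.SubElement(md, "software").text = "chronorsa"
        prop = etree.SubElement(md, "property-definitions")
        pd = etree.SubElement(prop, "property-definition")
        etree.SubElement(pd, "label").text = "length"
        etree.SubElement(pd, "type").text = "float"
        etree.SubElement(pd, "unit").text = "mm"
        if gs[0].timestamp_h is not None:
            etree.SubElement(md, "last-modified").text = str(gs[-1].timestamp_h)
        for g in gs:
            sc = _scene_element(g, rsml, plant_id)
            if g.timestamp_h is not None:
                sc.set("label", f"t={g.timestamp_h}h")
        return rsml

    written = []
    if consolidated:
        path.parent.mkdir(parents=True, exist_ok=True)
        doc = document(graphs)
        etree.ElementTree(doc).write(str(path), pretty_print=True,
                                     xml_declaration=True, encoding="UTF-8")
        written.append(path)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, g in enumerate(graphs):
            f = path / f"{plant_id}_{i:05d}.rsml"
            etree.ElementTree(document([g])).write(
                str(f), pretty_print=True, xml_declaration=True,
                encoding="UTF-8")
            written.append(f)
    return written


def read_rsml(path):
    """Parse an RSML file back into per-root polylines (mm) and lengths.

    Returns a list of scenes; each scene is a dict mapping root ID to
    ``{"label", "polyline" (n,2 mm array, (y,x) i.e. (row,col)),
    "length"}``.
    """
    tree = etree.parse(str(path))
    scenes = []
    for scene in tree.getroot().iter("scene"):
        roots = {}
        for root in scene.iter("root"):
            pts = [(float(p.get("y")), float(p.get("x")))
                   for p in root.findall("geometry/polyline/point")]
            length_el = root.find("properties/length")
            roots[root.get("ID")] = {
                "label": root.get("label"),
                "polyline": np.asarray(pts),
                "length": float(length_el.text) if length_el is not None
                else None,
            }
        scenes.append(roots)
    return scenes
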