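"""Synthetic cerebral vascular networks and steady Poiseuille hemodynamics.

The graphs generated here stand in for image-derived whole-brain
microvascular networks: a binary arterial tree feeds a random-geometric
capillary mesh which drains into a mirrored venous tree, giving a
fully-connected artery -> capillary -> vein closure.  Steady pressures and
flows are obtained from a linear (Kirchhoff) solve with Poiseuille edge
conductances, after which every edge is oriented along its flow so the
network is a DAG from inlets to outlets.

Units are fixed repo-wide: micrometres for geometry, Pa for pressure,
Pa*s for viscosity, um^3/s for volumetric flow, mm/s for velocity and
seconds for time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

VESSEL_CLASSES = ("artery", "arteriole", "capillary", "venule", "vein")


class GraphConfigError(ValueError):
    """Raised for unsatisfiable or inconsistent generator settings."""


class HemodynamicsError(RuntimeError):
    """Raised when the pressure system is singular (disconnected parts)."""


@dataclass
class GraphConfig:
    """Settings for the surrogate network generator.

    The defaults aim for a cortical-patch-scale network in which median
    capillary velocities sit well below arteriolar ones (sub-2 mm/s
    capillary regime) once solved with the default pressure drop.
    """

    n_capillaries: int = 60            # number of capillary chains
    n_arterial_terminals: int = 2
    n_venous_terminals: int = 2
    domain_um: tuple[float, float, float] = (1800.0, 40.0, 2400.0)
    radius_artery_um: float = 4.5
    radius_arteriole_um: float = 3.0
    radius_capillary_mean_um: float = 2.0
    radius_capillary_sd_um: float = 0.3
    radius_capillary_clip_um: tuple[float, float] = (1.5, 2.6)
    radius_venule_um: float = 3.2
    radius_vein_um: float = 5.0
    chain_hops: tuple[int, int] = (2, 5)   # capillary edges per chain (incl)
    n_cross_links: int = 5
    capillary_span: tuple[float, float] = (0.40, 0.60)  # x extent of the bed
    single_capillary_rule: str = "chain"  # or "edge"
    seed: int = 0

    def validate(self) -> None:
        if self.n_capillaries < 1:
            raise GraphConfigError("at least one capillary node is required")
        if self.n_arterial_terminals < 1 or self.n_venous_terminals < 1:
            raise GraphConfigError("need >= 1 arterial and venous terminal")
        lo, hi = self.radius_capillary_clip_um
        if not (self.radius_artery_um > self.radius_arteriole_um > hi):
            raise GraphConfigError(
                "radius ordering must satisfy artery > arteriole > capillary"
            )
        if self.single_capillary_rule not in ("chain", "edge"):
            raise GraphConfigError("single_capillary_rule must be chain|edge")


@dataclass
class VascularGraph:
    """Directed vessel network backed by a :class:`networkx.MultiDiGraph`.

    Node attributes: ``pos`` (3-vector, um), ``pressure`` (Pa, once solved).
    Edge attributes: ``id``, ``radius_um``, ``length_um``, ``vessel_class``,
    ``flow_um3_s`` (signed with edge direction) and ``mean_velocity_mm_s``.
    """

    g: nx.MultiDiGraph
    inlets: list = field(default_factory=list)
    outlets: list = field(default_factory=list)

    # -- basic accessors -------------------------------------------------
    def edges(self) -> Iterator[tuple]:
        return self.g.edges(keys=True, data=True)

    def edge_by_id(self, edge_id: int) -> tuple:
        return self._edge_index()[edge_id]

    def _edge_index(self) -> dict:
        idx = getattr(self, "_eidx", None)
        if idx is None or len(idx) != self.g.number_of_edges():
            idx = {d["id"]: (u, v, k, d) for u, v, k, d in self.edges()}
            self._eidx = idx
        return idx

    @property
    def solved(self) -> bool:
        return all("flow_um3_s" in d for _, _, _, d in self.edges())

    def boundary_nodes(self) -> set:
        return set(self.inlets) | set(self.outlets)

    def conservation_residuals(self) -> dict:
        """Signed flow imbalance at each internal node (um^3/s)."""
        res = {}
        for n in self.g.nodes:
            if n in self.boundary_nodes():
                continue
            inflow = sum(d["flow_um3_s"] for *_, d in self.g.in_edges(n, data=True))
            outflow = sum(d["flow_um3_s"] for *_, d in self.g.out_edges(n, data=True))
            res[n] = inflow - outflow
        return res


class PathSample(NamedTuple):
    """One inlet-to-outlet route traversing a single capillary stretch."""

    edge_ids: tuple
    capillary_span: tuple  # (first, last+1) indices into edge_ids
    min_diameter_um: float


class PathEnumeration(NamedTuple):
    paths: list
    truncated: bool

    def __iter__(self):
        return iter(self.paths)

    def __len__(self):
        return len(self.paths)


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def build_graph(nodes: dict, edges: Sequence[dict],
                inlets: Sequence, outlets: Sequence) -> VascularGraph:
    """Assemble a :class:`VascularGraph` from explicit node/edge tables.

    ``nodes`` maps node id -> 3-vector position (um); each edge dict needs
    ``tail, head, radius_um, vessel_class`` and optionally ``length_um``
    (defaults to the inter-node distance) and ``id``.
    """
    g = nx.MultiDiGraph()
    for n, pos in nodes.items():
        g.add_node(n, pos=np.asarray(pos, dtype=float))
    for i, e in enumerate(edges):
        u, v = e["tail"], e["head"]
        length = e.get("length_um")
        if length is None:
            length = float(np.linalg.norm(g.nodes[u]["pos"] - g.nodes[v]["pos"]))
        g.add_edge(u, v, id=e.get("id", i), radius_um=float(e["radius_um"]),
                   length_um=float(length), vessel_class=e["vessel_class"])
    return VascularGraph(g=g, inlets=list(inlets), outlets=list(outlets))


def _binary_tree(prefix: str, n_terminals: int, x0: float, x1: float,
                 z_lo: float, z_hi: float, y: float,
                 root_radius: float, terminal_radius: float,
                 trunk_class: str, terminal_class: str, reverse: bool):
    """Node/edge lists for a planar binary tree fanning from x0 to x1.

    ``reverse=True`` orients edges child->parent (venous side).
    Radii taper from the root by Murray's law (factor 2**(-1/3) per level)
    and are floored at ``terminal_radius``; the last level is always of
    ``terminal_class`` so both trunk and terminal classes are present.
    """
    depth = max(1, int(np.ceil(np.log2(max(n_terminals, 1)))) + 1)
    nodes, edges = {}, []
    root = f"{prefix}_root"
    nodes[root] = (x0, y, 0.5 * (z_lo + z_hi))
    prev = [root]
    terminals: list = []
    for level in range(1, depth + 1):
        n_here = min(2 ** level, n_terminals) if level == depth else min(2 ** level, n_terminals)
        # keep at least as many nodes as parents so chains stay connected
        n_here = max(n_here, len(prev)) if level < depth else n_terminals
        x = x0 + (x1 - x0) * level / depth
        zs = np.linspace(z_lo, z_hi, n_here + 2)[1:-1]
        cur = []
        for j in range(n_here):
            nid = f"{prefix}_{level}_{j}"
            nodes[nid] = (x, y, float(zs[j]))
            parent = prev[int(j * len(prev) / n_here)]
            radius = max(root_radius * 2 ** (-(level - 1) / 3.0), terminal_radius)
            vclass = terminal_class if level == depth else trunk_class
            if level == depth:
                radius = terminal_radius
            tail, head = (nid, parent) if reverse else (parent, nid)
            edges.append(dict(tail=tail, head=head, radius_um=radius,
                              vessel_class=vclass))
            cur.append(nid)
        prev = cur
    terminals = prev
    return nodes, edges, root, terminals


def generate_graph(config: GraphConfig) -> VascularGraph:
    """Generate a surrogate arterio-capillary-venous network.

    Deterministic under a fixed ``config.seed``.  The returned graph is
    unsolved (no flows); run :func:`solve_hemodynamics` next.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    Lx, Ly, Lz = config.domain_um

    nodes: dict = {}
    edges: list = []

    x_lo, x_hi = config.capillary_span
    a_nodes, a_edges, a_root, a_term = _binary_tree(
        "a", config.n_arterial_terminals, 0.0, x_lo * Lx, 0.0, Lz, Ly / 2,
        config.radius_artery_um, config.radius_arteriole_um,
        "artery", "arteriole", reverse=False)
    v_nodes, v_edges, v_root, v_term = _binary_tree(
        "v", config.n_venous_terminals, Lx, x_hi * Lx, 0.0, Lz, Ly / 2,
        config.radius_vein_um, config.radius_venule_um,
        "vein", "venule", reverse=True)
    nodes.update(a_nodes)
    nodes.update(v_nodes)
    edges += a_edges + v_edges

    # capillary mesh: parallel multi-hop chains from arteriole terminals to
    # venule terminals, plus a few cross-links between neighbouring chains.
    # Chains in parallel give each arteriole a high fan-in so arteriolar
    # velocities sit well above capillary ones (the U-shape contrast).
    def cap_radius():
        lo, hi = config.radius_capillary_clip_um
        r = rng.normal(config.radius_capillary_mean_um, config.radius_capillary_sd_um)
        return float(np.clip(r, lo, hi))

    a_term_sorted = sorted(a_term, key=lambda n: nodes[n][2])
    v_term_sorted = sorted(v_term, key=lambda n: nodes[n][2])
    n_chain = config.n_capillaries
    hop_lo, hop_hi = config.chain_hops
    chain_mids: list[list] = []
    for ci in range(n_chain):
        # each chain occupies its own z lane so dwelling bubbles from
        # different chains do not pile onto the same pixels
        lane_z = (0.05 + 0.90 * (ci + 0.5) / n_chain) * Lz
        src = min(a_term_sorted, key=lambda n: abs(nodes[n][2] - lane_z))
        dst = min(v_term_sorted, key=lambda n: abs(nodes[n][2] - lane_z))
        hops = int(rng.integers(hop_lo, hop_hi + 1))
        x0c, x1c = x_lo * Lx, x_hi * Lx
        mids = []
        for h in range(1, hops):
            frac_h = h / hops
            p = np.array([x0c + frac_h * (x1c - x0c), rng.uniform(0, Ly),
                          lane_z + rng.normal(0.0, 0.015 * Lz)])
            nid = f"c{ci}_{h}"
            nodes[nid] = tuple(np.clip(p, [0, 0, 0], [Lx, Ly, Lz]))
            mids.append(nid)
        if not mids:     # single-hop chain: direct terminal-to-terminal edge
            chain_mids.append(mids)
            edges.append(dict(tail=src, head=dst, radius_um=cap_radius(),
                              vessel_class="capillary"))
            continue
        chain_mids.append(mids)
        seqn = [src] + mids + [dst]
        for u, v in zip(seqn[:-1], seqn[1:]):
            edges.append(dict(tail=u, head=v, radius_um=cap_radius(),
                              vessel_class="capillary"))

    # cross-links between middles of z-adjacent chains (mesh character)
    with_mids = [ci for ci in range(n_chain) if chain_mids[ci]]
    order = sorted(with_mids,
                   key=lambda ci: nodes[chain_mids[ci][0]][2])
    for _ in range(config.n_cross_links):
        if len(order) < 2:
            break
        i = int(rng.integers(len(order) - 1))
        a = chain_mids[order[i]]
        b = chain_mids[order[i + 1]]
        u = a[int(rng.integers(len(a)))]
        v = b[int(rng.integers(len(b)))]
        edges.append(dict(tail=u, head=v, radius_um=cap_radius(),
                          vessel_class="capillary"))

    for i, e in enumerate(edges):
        e["id"] = i
    vg = build_graph(nodes, edges, inlets=[a_root], outlets=[v_root])
    _prune_dead_ends(vg)
    return vg


def _prune_dead_ends(vg: VascularGraph) -> None:
    """Iteratively drop internal nodes with total degree 1 (no-flow stubs)."""
    boundary = vg.boundary_nodes()
    while True:
        und = vg.g.to_undirected(as_view=False)
        dead = [n for n in vg.g.nodes
                if n not in boundary and und.degree(n) <= 1]
        if not dead:
            return
        vg.g.remove_nodes_from(dead)


# ---------------------------------------------------------------------------
# hemodynamics
# ---------------------------------------------------------------------------

def poiseuille_conductance(radius_um: float, length_um: float,
                           viscosity_pa_s: float) -> float:
    """Hydraulic conductance pi*R^4/(8*mu*L) in um^3/(s*Pa)."""
    return np.pi * radius_um ** 4 / (8.0 * viscosity_pa_s * length_um)


def solve_hemodynamics(vg: VascularGraph, inlet_pressure_pa: float = 36000.0,
                       outlet_pressure_pa: float = 0.0,
                       viscosity_pa_s: float = 3.5e-3) -> VascularGraph:
    """Solve node pressures and edge flows; orient edges along the flow.

    Pressure-driven boundary conditions: every inlet node is clamped to
    ``inlet_pressure_pa`` and every outlet to ``outlet_pressure_pa``; the
    internal pressures solve the weighted graph Laplacian system (Kirchhoff
    balance with Poiseuille conductances).  Edges are re-oriented so flow is
    non-negative along the stored direction, which makes the network a DAG
    (pressure strictly decreases along every flow-carrying edge).
    """
    if inlet_pressure_pa <= outlet_pressure_pa:
        raise ValueError("inlet pressure must exceed outlet pressure")
    g = vg.g
    und = g.to_undirected(as_view=True)
    boundary = vg.boundary_nodes()
    for comp in nx.connected_components(nx.Graph(und)):
        if not (comp & boundary):
            raise HemodynamicsError(
                f"component without boundary node (singular system): {sorted(comp)[:5]}...")

    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    free = [n for n in nodes if n not in boundary]
    fidx = {n: i for i, n in enumerate(free)}
    fixed_p = {n: (inlet_pressure_pa if n in vg.inlets else outlet_pressure_pa)
               for n in boundary}

    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    rows, cols, vals = [], [], []
    b = np.zeros(len(free))
    diag = np.zeros(len(free))
    for u, v, k, d in g.edges(keys=True, data=True):
        c = poiseuille_conductance(d["radius_um"], d["length_um"], viscosity_pa_s)
        for a, bnode in ((u, v), (v, u)):
            if a in fidx:
                diag[fidx[a]] += c
                if bnode in fidx:
                    rows.append(fidx[a]); cols.append(fidx[bnode]); vals.append(-c)
                else:
                    b[fidx[a]] += c * fixed_p[bnode]
    if free:
        A = sp.coo_matrix((vals, (rows, cols)), shape=(len(free), len(free))).tocsr()
        A += sp.diags(diag)
        p_free = spla.spsolve(A.tocsc(), b)
    else:
        p_free = np.array([])

    pressure = {}
    for n in nodes:
        pressure[n] = fixed_p[n] if n in boundary else float(p_free[fidx[n]])
    nx.set_node_attributes(g, pressure, "pressure")

    # flows, with re-orientation so flow >= 0 along stored direction
    flips = []
    for u, v, k, d in list(g.edges(keys=True, data=True)):
        c = poiseuille_conductance(d["radius_um"], d["length_um"], viscosity_pa_s)
        q = c * (pressure[u] - pressure[v])
        if q < 0:
            flips.append((u, v, k, dict(d)))
        else:
            d["flow_um3_s"] = q
            d["mean_velocity_mm_s"] = q / (np.pi * d["radius_um"] ** 2) / 1e3
    for u, v, k, d in flips:
        c = poiseuille_conductance(d["radius_um"], d["length_um"], viscosity_pa_s)
        q = c * (pressure[v] - pressure[u])
        g.remove_edge(u, v, k)
        d["flow_um3_s"] = q
        d["mean_velocity_mm_s"] = q / (np.pi * d["radius_um"] ** 2) / 1e3
        g.add_edge(v, u, **d)
    vg._eidx = None  # invalidate edge index cache
    return vg


# ---------------------------------------------------------------------------
# path enumeration
# ---------------------------------------------------------------------------

def _single_capillary_span(classes: Sequence[str], rule: str):
    """Return (start, stop) of the single capillary stretch, or None.

    ``chain``: exactly one maximal run of consecutive capillary edges.
    ``edge``: exactly one capillary edge.
    """
    is_cap = [c == "capillary" for c in classes]
    if not any(is_cap):
        return None
    runs = []
    i = 0
    while i < len(is_cap):
        if is_cap[i]:
            j = i
            while j < len(is_cap) and is_cap[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    if len(runs) != 1:
        return None
    if rule == "edge" and runs[0][1] - runs[0][0] != 1:
        return None
    return runs[0]


def enumerate_paths(vg: VascularGraph, max_paths: int | None = None,
                    rule: str = "chain") -> PathEnumeration:
    """Enumerate inlet-to-outlet routes that traverse a single capillary.

    Runs a deterministic DFS (successors visited in sorted order) over the
    flow-oriented DAG; each surviving path yields a :class:`PathSample`.
    Returns a :class:`PathEnumeration` whose ``truncated`` flag is set when
    ``max_paths`` cut the enumeration short.
    """
    if not vg.solved:
        raise RuntimeError("solve hemodynamics before enumerating paths")
    g = vg.g
    out: list[PathSample] = []
    truncated = False

    def dfs(node, edge_list):
        nonlocal truncated
        if truncated:
            return
        if node in vg.outlets and edge_list:
            classes = [d["vessel_class"] for *_, d in edge_list]
            span = _single_capillary_span(classes, rule)
            if span is not None:
                if max_paths is not None and len(out) >= max_paths:
                    truncated = True
                    return
                ids = tuple(d["id"] for *_, d in edge_list)
                min_d = 2.0 * min(d["radius_um"] for *_, d in edge_list)
                out.append(PathSample(ids, span, min_d))
            return
        succ = sorted(g.out_edges(node, keys=True, data=True),
                      key=lambda e: (str(e[1]), e[2]))
        for u, v, k, d in succ:
            dfs(v, edge_list + [(u, v, k, d)])

    for inlet in sorted(vg.inlets, key=str):
        dfs(inlet, [])
        if truncated:
            break
    if not out:
        warnings.warn("no inlet-to-outlet path found", stacklevel=2)
    return PathEnumeration(out, truncated)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def to_graphml(vg: VascularGraph, path: str) -> None:
    g = nx.MultiDiGraph()
    for n, d in vg.g.nodes(data=True):
        pos = d["pos"]
        g.add_node(n, x_um=float(pos[0]), y_um=float(pos[1]), z_um=float(pos[2]),
                   pressure_pa=float(d.get("pressure", np.nan)),
                   is_inlet=n in vg.inlets, is_outlet=n in vg.outlets)
    for u, v, k, d in vg.edges():
        g.add_edge(u, v, k, **{kk: vv for kk, vv in d.items()})
    nx.write_graphml(g, path)


def from_graphml(path: str) -> VascularGraph:
    raw = nx.read_graphml(path, force_multigraph=True)
    g = nx.MultiDiGraph()
    inlets, outlets = [], []
    for n, d in raw.nodes(data=True):
        g.add_node(n, pos=np.array([d["x_um"], d["y_um"], d["z_um"]]),
                   pressure=d.get("pressure_pa", np.nan))
        if d.get("is_inlet"):
            inlets.append(n)
        if d.get("is_outlet"):
            outlets.append(n)
    for u, v, k, d in raw.edges(keys=True, data=True):
        g.add_edge(u, v, **{kk: (int(vv) if kk == "id" else vv) for kk, vv in d.items()})
    return VascularGraph(g=g, inlets=inlets, outlets=outlets)


def to_edge_csv(vg: VascularGraph, path: str) -> None:
    rows = [dict(edge_id=d["id"], tail=u, head=v, radius_um=d["radius_um"],
                 length_um=d["length_um"], vessel_class=d["vessel_class"],
                 flow_um3_s=d.get("flow_um3_s", np.nan),
                 mean_velocity_mm_s=d.get("mean_velocity_mm_s", np.nan))
            for u, v, k, d in vg.edges()]
    pd.DataFrame(rows).to_csv(path, index=False)
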