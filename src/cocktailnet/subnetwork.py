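"""Detection of the subnetwork affected by a drug via a network-flow program.

A drug first hits its target genes; the perturbation then propagates through
the interaction network, so the affected genes form a connected region around
the targets.  Finding that region is cast as a constrained maximum-weight
connected subgraph problem: select R genes, all targets included, maximising
the total differential-expression weight, with connectivity enforced by a
single-commodity flow construction.

A dummy drug node S is added with one arc to each target H_k.  Every
background edge contributes arcs in both directions.  Decision variables are
x_i in {0,1} (gene i selected) and Z_ij >= 0 (flow on arc i->j):

    maximise    sum_i w_i x_i
    subject to  sum_k Z_{S,H_k} = R                  (R units injected)
                inflow(i) - outflow(i) = x_i          for every gene i
                Z_ij <= R x_i ,  Z_ij <= R x_j        for every non-dummy arc
                x_{H_k} = 1                           for every target
                Z >= 0,  x in {0,1}

Each selected gene absorbs exactly one unit of flow, so flow can only reach
a gene through a chain of selected genes back to a target: every connected
component of the selection contains a target, and summing the conservation
constraints gives sum_i x_i = R.  The integer program is NP-hard, so in
practice x is relaxed to [0,1] and the LP is solved (HiGHS); all genes with
x above a small threshold define the subnetwork, whose size can therefore
exceed R somewhat.  The exact binary mode (HiGHS MILP) is retained as an
oracle for small instances.

Because the useful subnetwork size is unknown, R is scanned from the minimal
size that can connect the targets up to 10% of the network, and candidate
subnetworks are compared by the Z-score-like normalised score
sum_{i in S} w_i / sqrt(|S|); the maximiser is reported.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .network import MolecularNetwork

logger = logging.getLogger(__name__)

#: x values above this threshold are taken as selected in relaxed solutions
SELECTION_THRESHOLD = 1e-6

#: |x - round(x)| below this counts as integral
INTEGRALITY_TOL = 1e-6


class InfeasibleModelError(RuntimeError):
    """Raised when the flow model has no feasible subnetwork."""


@dataclass
class FlowModel:
    """Assembled flow program for one (network, targets, R) instance."""

    nodes: list[str]
    arcs: list[tuple[str, str]]          # both directions of each edge
    targets: list[str]                   # dummy node S feeds these
    R: int
    weights: np.ndarray                  # aligned with nodes
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def _matrices(self):
        """Sparse (c, A_eq, b_eq, A_ub, b_ub, lb, ub) for the program.

        Variable layout: x (n genes), Z on background arcs (m), Z on dummy
        arcs S->H_k (t).
        """
        n, m, t = self.n_nodes, self.n_arcs, len(self.targets)
        idx = {g: i for i, g in enumerate(self.nodes)}
        N = n + m + t
        R = float(self.R)

        c = np.zeros(N)
        c[:n] = -self.weights  # linprog/milp minimise

        eq_rows, eq_cols, eq_vals = [], [], []
        # row 0: total dummy outflow = R
        for k in range(t):
            eq_rows.append(0)
            eq_cols.append(n + m + k)
            eq_vals.append(1.0)
        # rows 1..n: inflow - outflow - x_i = 0
        for a, (u, v) in enumerate(self.arcs):
            eq_rows += [1 + idx[v], 1 + idx[u]]
            eq_cols += [n + a, n + a]
            eq_vals += [1.0, -1.0]
        for k, h in enumerate(self.targets):
            eq_rows.append(1 + idx[h])
            eq_cols.append(n + m + k)
            eq_vals.append(1.0)
        for i in range(n):
            eq_rows.append(1 + i)
            eq_cols.append(i)
            eq_vals.append(-1.0)
        A_eq = sp.csr_matrix((eq_vals, (eq_rows, eq_cols)), shape=(1 + n, N))
        b_eq = np.zeros(1 + n)
        b_eq[0] = R

        # capacity coupling: Z_a - R x_u <= 0 and Z_a - R x_v <= 0
        ub_rows, ub_cols, ub_vals = [], [], []
        for a, (u, v) in enumerate(self.arcs):
            r0 = 2 * a
            ub_rows += [r0, r0, r0 + 1, r0 + 1]
            ub_cols += [n + a, idx[u], n + a, idx[v]]
            ub_vals += [1.0, -R, 1.0, -R]
        A_ub = sp.csr_matrix((ub_vals, (ub_rows, ub_cols)), shape=(2 * m, N))
        b_ub = np.zeros(2 * m)

        lb = np.zeros(N)
        ub = np.concatenate([np.ones(n), np.full(m + t, R)])
        for h in self.targets:
            lb[idx[h]] = 1.0
        return c, A_eq, b_eq, A_ub, b_ub, lb, ub


@dataclass
class FlowSolution:
    x: pd.Series           # per-gene selection value
    z: dict[tuple[str, str], float]
    objective: float
    exact: bool


@dataclass
class SubnetworkResult:
    """Extracted affected subnetwork and its scores."""

    genes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    r_requested: int
    objective: float
    normalized_score: float
    lp_integral: bool
    targets: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return len(self.genes)


def build_model(
    net: MolecularNetwork,
    targets: Iterable[str],
    R: int,
    weights: Mapping[str, float] | None = None,
) -> FlowModel:
    """Assemble the flow program; validates targets and R.

    Weights default to the network's node weights; genes without a weight
    get 0.  A target absent from the background network is an error (such
    drugs are excluded upstream).
    """
    targets = sorted(set(targets))
    missing = [h for h in targets if h not in net.nodes]
    if missing:
        raise InfeasibleModelError(f"targets not in background network: {missing}")
    if not targets:
        raise ValueError("need at least one target")
    if R < len(targets):
        raise ValueError(f"R={R} smaller than number of targets {len(targets)}")
    nodes = sorted(net.nodes)
    if weights is None:
        weights = net.node_weights or {}
    w = np.array([float(weights.get(g, 0.0)) for g in nodes])
    if (w < 0).any():
        raise ValueError("node weights must be non-negative")
    arcs: list[tuple[str, str]] = []
    for a, b in sorted(net.edges):
        arcs.append((a, b))
        arcs.append((b, a))
    return FlowModel(nodes=nodes, arcs=arcs, targets=targets, R=int(R),
                     weights=w, graph=net.graph)


def solve(model: FlowModel, exact: bool = False) -> FlowSolution:
    """Solve the flow program: LP relaxation by default, binary x if exact."""
    c, A_eq, b_eq, A_ub, b_ub, lb, ub = model._matrices()
    n = model.n_nodes
    if exact:
        integrality = np.zeros(len(c))
        integrality[:n] = 1
        cons = [LinearConstraint(A_eq, b_eq, b_eq)]
        if A_ub.shape[0]:
            cons.append(LinearConstraint(A_ub, -np.inf, b_ub))
        res = milp(c, constraints=cons, integrality=integrality, bounds=Bounds(lb, ub))
    else:
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=np.column_stack([lb, ub]), method="highs")
    if res.status != 0 or res.x is None:
        raise InfeasibleModelError(
            f"no feasible subnetwork of size R={model.R} for targets {model.targets}"
        )
    x = pd.Series(res.x[:n], index=model.nodes)
    z = {arc: float(res.x[n + a]) for a, arc in enumerate(model.arcs)}
    for k, h in enumerate(model.targets):
        z[("S", h)] = float(res.x[n + model.n_arcs + k])
    return FlowSolution(x=x, z=z, objective=float(-res.fun), exact=exact)


def extract_subnetwork(
    model: FlowModel,
    solution: FlowSolution,
    threshold: float = SELECTION_THRESHOLD,
) -> SubnetworkResult:
    """Read the selected gene set off a solution.

    All genes with x above the threshold are taken (a relaxed solution can
    therefore exceed R).  Components of the induced subgraph that contain no
    target are discarded (logged): flow cannot have reached them, so any
    above-threshold x there is numerical noise.
    """
    x = solution.x
    genes = set(x.index[x > threshold])
    genes.update(model.targets)
    sub = model.graph.subgraph(genes)
    kept: set[str] = set()
    for comp in nx.connected_components(sub):
        if comp & set(model.targets):
            kept |= comp
    if kept != genes:
        logger.info("extract_subnetwork: dropped %d genes in target-free components",
                    len(genes - kept))
    genes = kept
    widx = {g: i for i, g in enumerate(model.nodes)}
    wsum = float(sum(model.weights[widx[g]] for g in genes))
    lp_integral = bool(np.all(np.abs(x - np.round(x)) <= INTEGRALITY_TOL))
    edges = tuple(sorted(tuple(sorted(e)) for e in model.graph.subgraph(genes).edges))
    return SubnetworkResult(
        genes=tuple(sorted(genes)),
        edges=edges,
        r_requested=model.R,
        objective=solution.objective,
        normalized_score=wsum / np.sqrt(len(genes)) if genes else 0.0,
        lp_integral=lp_integral,
        targets=tuple(model.targets),
    )


def _lexicographic_shortest_path(graph: nx.Graph, a: str, b: str) -> list[str]:
    """Deterministic shortest path: BFS with lexicographic neighbour order."""
    parent = {a: None}
    frontier = [a]
    while frontier:
        nxt = []
        for u in frontier:
            for v in sorted(graph.neighbors(u)):
                if v not in parent:
                    parent[v] = u
                    nxt.append(v)
            if b in parent:
                break
        if b in parent:
            break
        frontier = nxt
    if b not in parent:
        raise InfeasibleModelError(f"targets {a} and {b} are not connected")
    path = [b]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path[::-1]


def r_bounds(net: MolecularNetwork, targets: Iterable[str]) -> tuple[int, int]:
    """Bounds for the subnetwork-size scan.

    The lower bound is the number of distinct nodes on one (deterministic)
    shortest path per unordered target pair — the smallest selection that can
    still connect all targets.  The upper bound caps the subnetwork at 10% of
    the network, on the grounds that a single drug perturbs only a small part
    of the system; it is never below the lower bound.
    """
    targets = sorted(set(targets))
    missing = [h for h in targets if h not in net.nodes]
    if missing:
        raise InfeasibleModelError(f"targets not in network: {missing}")
    if len(targets) <= 1:
        r_min = 1
    else:
        union: set[str] = set()
        for a, b in itertools.combinations(targets, 2):
            union.update(_lexicographic_shortest_path(net.graph, a, b))
        r_min = len(union)
    r_max = max(r_min, int(0.1 * net.n_nodes))
    return r_min, r_max


def _better(cand: SubnetworkResult, best: SubnetworkResult | None,
            tol: float = 1e-12) -> bool:
    if best is None:
        return True
    if cand.normalized_score > best.normalized_score + tol:
        return True
    if abs(cand.normalized_score - best.normalized_score) <= tol:
        if cand.size < best.size:
            return True
        if cand.size == best.size and cand.genes < best.genes:
            return True
    return False


def find_affected_subnetwork(
    net: MolecularNetwork,
    weights: Mapping[str, float],
    targets: Iterable[str],
    r_step: int = 1,
    exact: bool = False,
    threshold: float = SELECTION_THRESHOLD,
    return_scan: bool = False,
) -> SubnetworkResult | tuple[SubnetworkResult, pd.DataFrame]:
    """Scan R over its bounds and return the best-scoring subnetwork.

    Candidates across R are compared by the normalised score
    sum(w) / sqrt(size); ties prefer the smaller set, then the
    lexicographically smallest gene tuple.
    """
    if r_step < 1:
        raise ValueError("r_step must be >= 1")
    r_min, r_max = r_bounds(net, targets)
    best: SubnetworkResult | None = None
    rows = []
    for R in range(r_min, r_max + 1, r_step):
        model = build_model(net, targets, R, weights=weights)
        result = extract_subnetwork(model, solve(model, exact=exact), threshold=threshold)
        rows.append({"R": R, "size": result.size, "objective": result.objective,
                     "normalized_score": result.normalized_score,
                     "lp_integral": result.lp_integral})
        if _better(result, best):
            best = result
    assert best is not None
    scan = pd.DataFrame(rows)
    return (best, scan) if return_scan else best


def brute_force_oracle(
    net: MolecularNetwork,
    weights: Mapping[str, float],
    targets: Iterable[str],
    R: int,
) -> tuple[tuple[str, ...], float]:
    """Exhaustive reference maximiser for tiny instances (|V| <= 16).

    Enumerates every size-R gene set containing all targets in which each
    connected component of the induced subgraph contains at least one target
    (the feasible region of the flow program, i.e. connectivity through the
    dummy node), and returns the set maximising the total weight.  Ties break
    to the lexicographically smallest gene tuple.
    """
    nodes = sorted(net.nodes)
    if len(nodes) > 16:
        raise ValueError("brute_force_oracle limited to |V| <= 16")
    targets = sorted(set(targets))
    missing = [h for h in targets if h not in net.nodes]
    if missing:
        raise InfeasibleModelError(f"targets not in network: {missing}")
    if R < len(targets):
        raise ValueError("R smaller than number of targets")
    others = [g for g in nodes if g not in targets]
    tset = set(targets)
    best_set: tuple[str, ...] | None = None
    best_w = -np.inf
    for extra in itertools.combinations(others, R - len(targets)):
        sel = tset | set(extra)
        feasible = all(
            bool(comp & tset) for comp in nx.connected_components(net.graph.subgraph(sel))
        )
        if not feasible:
            continue
        w = sum(float(weights.get(g, 0.0)) for g in sel)
        key = tuple(sorted(sel))
        if w > best_w + 1e-12 or (abs(w - best_w) <= 1e-12 and (best_set is None or key < best_set)):
            best_w, best_set = w, key
    if best_set is None:
        raise InfeasibleModelError(f"infeasible: no size-{R} selection connects targets {targets}")
    return best_set, float(best_w)


class AffectedSubnetworkModel:
    """Model object bundling the background network, node weights and targets.

    Mirrors the familiar model/results split: construct from data, then
    ``fit()`` solves the flow program (scanning R unless one is given) and
    returns an :class:`AffectedSubnetworkResults`.
    """

    def __init__(
        self,
        network: MolecularNetwork,
        weights: Mapping[str, float] | pd.Series,
        targets: Iterable[str],
    ):
        self.network = network
        self.weights = dict(pd.Series(weights, dtype=float).items())
        self.targets = sorted(set(targets))
        missing = [h for h in self.targets if h not in network.nodes]
        if missing:
            raise InfeasibleModelError(f"targets not in background network: {missing}")

    @classmethod
    def from_profile(cls, network: MolecularNetwork, profile, targets):
        """Build from an :class:`~cocktailnet.expression.ExpressionProfile`."""
        w = profile.weights.reindex(sorted(network.nodes)).fillna(0.0)
        return cls(network, w, targets)

    def fit(
        self,
        r: int | None = None,
        method: str = "relaxed",
        r_step: int = 1,
        threshold: float = SELECTION_THRESHOLD,
    ) -> "AffectedSubnetworkResults":
        exact = {"relaxed": False, "exact": True}.get(method)
        if exact is None:
            raise ValueError(f"unknown method {method!r}")
        if r is None:
            best, scan = find_affected_subnetwork(
                self.network, self.weights, self.targets,
                r_step=r_step, exact=exact, threshold=threshold, return_scan=True,
            )
        else:
            model = build_model(self.network, self.targets, r, weights=self.weights)
            best = extract_subnetwork(model, solve(model, exact=exact), threshold=threshold)
            scan = pd.DataFrame([{"R": r, "size": best.size, "objective": best.objective,
                                  "normalized_score": best.normalized_score,
                                  "lp_integral": best.lp_integral}])
        return AffectedSubnetworkResults(self, best, scan, method)


@dataclass
class AffectedSubnetworkResults:
    """Fitted affected subnetwork plus the R-scan diagnostics."""

    model: AffectedSubnetworkModel
    subnetwork: SubnetworkResult
    scan: pd.DataFrame
    method: str

    @property
    def genes(self) -> tuple[str, ...]:
        return self.subnetwork.genes

    @property
    def normalized_score(self) -> float:
        return self.subnetwork.normalized_score

    def summary(self) -> str:
        s = self.subnetwork
        lines = [
            "Affected subnetwork (network-flow model)",
            "=" * 44,
            f"targets:           {', '.join(s.targets)}",
            f"method:            {self.method}",
            f"R requested:       {s.r_requested} (scan of {len(self.scan)} values)",
            f"genes selected:    {s.size}",
            f"edges induced:     {len(s.edges)}",
            f"objective sum(w):  {s.objective:.6f}",
            f"normalized score:  {s.normalized_score:.6f}",
            f"LP integral:       {s.lp_integral}",
        ]
        return "\n".join(lines)
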