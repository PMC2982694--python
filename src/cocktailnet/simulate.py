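"""Synthetic fixtures with the statistical structure the method assumes.

Real inputs to the pipeline are large: a curated interaction network, a
perturbation compendium of drug-treated microarrays, and disease / essential
gene catalogues.  This module generates miniature but structurally faithful
stand-ins: a connected background network, drugs with targets and a planted
connected "affected module" around each target, probe-level case/control
matrices with log-normal noise, and ground truth for every planted quantity.

The planted perturbation model mirrors the method's assumption that a drug
first hits its targets and the effect decays as it propagates: a module gene
at hop distance d from the nearest target has true log2 ratio
``effect_size * decay**d``; genes outside the module sit at baseline.  Case
intensities are ``baseline * 2**(mu + eps)`` with ``eps ~ N(0, noise_sd)``
drawn per probe and sample; control samples sit exactly at the baseline
intensity (100 units) so that ratios are recovered exactly at zero noise.

Emitted tables deliberately include the wrinkles the preprocessing stage
must handle: two probes per gene, one composite ``"A /// B"`` probe, samples
from a second cell line, a zero-effect decoy perturbagen (so no batch
contains a single drug only), and the historically split batch ids "2"/"2a".
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import MolecularNetwork

BASELINE = 100.0
DEFAULT_DOSE = 10.0
DECOY_DRUG = "DECOY"
OFF_CELL_LINE = "HL60"
NETWORK_MODELS = ("erdos_renyi", "scale_free")
INTERACTIONS = ("additive", "synergistic_on_disease")


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_network(
    n_nodes: int,
    model: str = "scale_free",
    param: float = 2,
    seed: int = 0,
) -> MolecularNetwork:
    """Random connected background network with synthetic gene symbols.

    ``model`` is ``scale_free`` (Barabási–Albert, ``param`` = edges per new
    node) or ``erdos_renyi`` (``param`` = edge probability).  The largest
    connected component is kept and nodes are relabeled G0001, G0002, ...
    in a seed-stable order.
    """
    if n_nodes < 5:
        raise ValueError("need n_nodes >= 5")
    if model == "scale_free":
        m = int(param)
        if not 1 <= m < n_nodes:
            raise ValueError(f"scale_free needs 1 <= m < n_nodes, got {param}")
        g = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    elif model == "erdos_renyi":
        p = float(param)
        if not 0 < p <= 1:
            raise ValueError(f"erdos_renyi needs 0 < p <= 1, got {param}")
        g = nx.gnp_random_graph(n_nodes, p, seed=seed)
    else:
        raise ValueError(f"unknown network model {model!r}")
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp)
    mapping = {old: _gene_name(i + 1) for i, old in enumerate(sorted(g.nodes))}
    return MolecularNetwork(nx.relabel_nodes(g, mapping, copy=True))


def grow_module(
    net: MolecularNetwork, targets: list[str], module_size: int
) -> tuple[list[str], dict[str, int]]:
    """Connected module around the targets by breadth-first expansion.

    Returns the module genes and each gene's hop distance from the nearest
    target.  Deterministic: neighbours are visited in lexicographic order.
    """
    targets = sorted(set(targets))
    missing = [t for t in targets if t not in net.nodes]
    if missing:
        raise ValueError(f"targets not in network: {missing}")
    if module_size < len(targets):
        raise ValueError("module_size smaller than number of targets")
    # seed with one shortest path per target pair so the module is connected
    from .subnetwork import _lexicographic_shortest_path

    seed: set[str] = set(targets)
    for a, b in itertools.combinations(targets, 2):
        seed.update(_lexicographic_shortest_path(net.graph, a, b))
    if len(seed) > module_size:
        raise ValueError(
            f"module_size {module_size} too small to connect targets {targets}"
        )
    # hop distances from the nearest target (multi-source BFS)
    hops = {t: 0 for t in targets}
    queue = deque(targets)
    order: list[str] = []
    while queue:
        u = queue.popleft()
        for v in sorted(net.graph.neighbors(u)):
            if v not in hops:
                hops[v] = hops[u] + 1
                order.append(v)
                queue.append(v)
    module = sorted(seed)
    for v in order:
        if len(module) >= module_size:
            break
        if v not in seed:
            module.append(v)
    if len(module) < module_size:
        raise ValueError(
            f"module cannot reach size {module_size} from targets {targets}"
        )
    return module, {g: hops[g] for g in module}


def random_flow_instance(
    seed: int,
) -> tuple[MolecularNetwork, dict[str, float], list[str], int]:
    """Small random weighted instance for validating the flow model.

    Returns (network, weights, targets, R) with |V| <= 12, 1-3 targets and
    R within reach of exhaustive enumeration.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 13))
    g = nx.gnp_random_graph(n, float(rng.uniform(0.25, 0.55)),
                            seed=int(rng.integers(0, 2**31)))
    comp = max(nx.connected_components(g), key=len)
    g = nx.relabel_nodes(g.subgraph(comp).copy(), {o: f"N{o:02d}" for o in comp})
    net = MolecularNetwork(g)
    nodes = sorted(net.nodes)
    weights = {v: float(rng.uniform(0.0, 5.0)) for v in nodes}
    k = min(int(rng.integers(1, 4)), len(nodes))
    targets = sorted(rng.choice(nodes, size=k, replace=False).tolist())
    R = int(rng.integers(k, min(len(nodes), k + 4) + 1))
    return net, weights, targets, R


@dataclass
class PerturbationData:
    """Probe-level expression fixture for one or more treatments."""

    probe_matrix: pd.DataFrame          # probes x samples
    metadata: pd.DataFrame              # SampleMetadata columns
    probe_map: pd.Series                # probe -> symbol string
    true_log2: dict[str, pd.Series]     # treatment -> per-gene log2 ratio


def _emit_expression(
    net: MolecularNetwork,
    mu_by_treatment: dict[str, pd.Series],
    noise_sd: float,
    seed: int,
    n_batches: int = 2,
    n_case_reps: int = 2,
    n_controls: int = 2,
    dose: float = DEFAULT_DOSE,
    cell_line: str = "MCF7",
) -> PerturbationData:
    """Shared emission machinery for planted perturbations.

    Controls sit exactly at the baseline; cases get per-probe log2 noise.
    A decoy zero-effect perturbagen is added when only one treatment is
    present, so the single-perturbagen batch filter never erases the fixture.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(net.nodes)
    mu_by_treatment = {
        t: pd.Series(mu, dtype=float).reindex(genes).fillna(0.0)
        for t, mu in mu_by_treatment.items()
    }
    treatments = dict(mu_by_treatment)
    if len(treatments) == 1:
        treatments[DECOY_DRUG] = pd.Series(0.0, index=genes)

    # two genes unperturbed under every treatment host the composite probe
    quiet = [g for g in genes
             if all((mu[g] == 0.0) for mu in treatments.values())]
    pseudo_pair = quiet[:2] if len(quiet) >= 2 else genes[:2]

    probes = [f"{g}|p{k}" for g in genes for k in (1, 2)] + ["PSEUDO|p1"]
    probe_map = pd.Series(
        {f"{g}|p{k}": g for g in genes for k in (1, 2)}
        | {"PSEUDO|p1": " /// ".join(pseudo_pair)}
    )

    batch_ids = (["2", "2a"] + [str(i) for i in range(3, n_batches + 1)])[:n_batches]
    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    gene_pos = {g: i for i, g in enumerate(genes)}

    def _sample_values(mu: pd.Series, noisy: bool, scale: float = 1.0) -> np.ndarray:
        vals = np.empty(len(probes))
        base = mu.to_numpy()
        for k in range(2):
            eps = rng.normal(0.0, noise_sd, size=len(genes)) if noisy and noise_sd > 0 else 0.0
            vals[k::2][: len(genes)] = scale * BASELINE * 2.0 ** (base + eps)
        per_probe = vals[: 2 * len(genes)]
        i, j = gene_pos[pseudo_pair[0]], gene_pos[pseudo_pair[1]]
        g1 = per_probe[2 * i: 2 * i + 2].mean()
        g2 = per_probe[2 * j: 2 * j + 2].mean()
        vals[-1] = 0.5 * (g1 + g2)
        return vals

    zero_mu = pd.Series(0.0, index=genes)
    for b in batch_ids:
        ctrl_ids = [f"b{b}_ctrl{k}" for k in range(1, n_controls + 1)]
        for cid in ctrl_ids:
            columns[cid] = _sample_values(zero_mu, noisy=False)
            meta_rows.append(dict(sample_id=cid, batch_id=b, cell_line=cell_line,
                                  perturbagen="CONTROL", dose=0.0, control_ids=[]))
        for label, mu in treatments.items():
            for k in range(1, n_case_reps + 1):
                sid = f"b{b}_{label}_case{k}"
                columns[sid] = _sample_values(mu, noisy=True)
                meta_rows.append(dict(sample_id=sid, batch_id=b, cell_line=cell_line,
                                      perturbagen=label, dose=dose,
                                      control_ids=list(ctrl_ids)))
        # off-cell-line pair with shifted intensities; must be filtered out
        oc_ctrl, oc_case = f"b{b}_{OFF_CELL_LINE}_ctrl", f"b{b}_{OFF_CELL_LINE}_case"
        columns[oc_ctrl] = _sample_values(zero_mu, noisy=False, scale=1.5)
        first = next(iter(treatments))
        columns[oc_case] = _sample_values(treatments[first], noisy=True, scale=3.0)
        meta_rows.append(dict(sample_id=oc_ctrl, batch_id=b, cell_line=OFF_CELL_LINE,
                              perturbagen="CONTROL", dose=0.0, control_ids=[]))
        meta_rows.append(dict(sample_id=oc_case, batch_id=b, cell_line=OFF_CELL_LINE,
                              perturbagen=first, dose=dose, control_ids=[oc_ctrl]))

    probe_matrix = pd.DataFrame(columns, index=probes)
    probe_matrix.index.name = "probe"
    metadata = pd.DataFrame(meta_rows)
    return PerturbationData(probe_matrix, metadata, probe_map,
                            true_log2=mu_by_treatment)


def plant_perturbation(
    net: MolecularNetwork,
    targets: list[str],
    module_size: int,
    effect_size: float,
    decay: float = 0.85,
    noise_sd: float = 0.2,
    seed: int = 0,
    drug_label: str = "DRUG",
    **emit_kwargs,
) -> PerturbationData:
    """Probe matrix + metadata for one drug with a planted affected module."""
    module, hops = grow_module(net, targets, module_size)
    mu = pd.Series(0.0, index=sorted(net.nodes))
    for g in module:
        mu[g] = effect_size * decay ** hops[g]
    return _emit_expression(net, {drug_label: mu}, noise_sd, seed, **emit_kwargs)


@dataclass
class DrugTruth:
    targets: tuple[str, ...]
    module: tuple[str, ...]
    effect_size: float
    true_log2: pd.Series


@dataclass
class SyntheticScenario:
    """One fully specified synthetic study: network, gene sets, drugs, truth."""

    network: MolecularNetwork
    disease_genes: set[str]
    essential_genes: set[str]
    drugs: dict[str, DrugTruth]
    noise_sd: float
    seed: int
    expression: PerturbationData = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def drug_names(self) -> list[str]:
        return sorted(self.drugs)

    def targets_map(self) -> dict[str, tuple[str, ...]]:
        return {d: t.targets for d, t in self.drugs.items()}


def default_scenario(
    seed: int = 0,
    n_nodes: int = 200,
    n_drugs: int = 5,
    module_size: int = 8,
    effect_size: float = 1.5,
    decay: float = 0.85,
    noise_sd: float = 0.2,
    n_disease: int = 20,
    n_essential: int = 30,
    n_overlap: int = 3,
    disease_placement: str = "mixed",
    essential_placement: str = "mixed",
) -> SyntheticScenario:
    """Default study conditions: 200-node scale-free network, 5 drugs with
    1–2 targets each, 20 disease genes, 30 essential genes (3 of them also
    disease genes), log2 noise SD 0.2.

    ``disease_placement`` / ``essential_placement`` control where the gene
    sets fall relative to the planted modules: ``"mixed"`` (some in each
    module, rest elsewhere), ``"in_modules"`` (drawn from module genes) or
    ``"outside_modules"`` (drawn avoiding all modules).
    """
    rng = np.random.default_rng(seed)
    net = generate_network(n_nodes, "scale_free", 2, seed=seed)
    genes = sorted(net.nodes)

    drugs: dict[str, DrugTruth] = {}
    used_targets: set[str] = set()
    mu_by_drug: dict[str, pd.Series] = {}
    for i in range(n_drugs):
        name = f"DRUG{chr(ord('A') + i)}"
        n_targets = 1 + int(rng.integers(0, 2))
        candidates = [g for g in genes if g not in used_targets]
        first = str(rng.choice(candidates))
        targets = [first]
        if n_targets == 2:
            # second target within two hops so the module can connect them
            near = sorted(set(nx.single_source_shortest_path_length(
                net.graph, first, cutoff=2)) - {first} - used_targets)
            if near:
                targets.append(str(rng.choice(near)))
        targets = sorted(targets)
        used_targets.update(targets)
        module, hops = grow_module(net, targets, module_size)
        mu = pd.Series(0.0, index=genes)
        for g in module:
            mu[g] = effect_size * decay ** hops[g]
        mu_by_drug[name] = mu
        drugs[name] = DrugTruth(tuple(targets), tuple(sorted(module)),
                                effect_size, mu)

    all_module = sorted(set().union(*(d.module for d in drugs.values())))
    off_module = [g for g in genes if g not in set(all_module)]

    def _place(n: int, placement: str, forbid: set[str] = frozenset()) -> set[str]:
        if placement == "in_modules":
            pool = [g for g in all_module if g not in forbid]
            return set(rng.choice(pool, size=min(n, len(pool)), replace=False).tolist())
        if placement == "outside_modules":
            pool = [g for g in off_module if g not in forbid]
            return set(rng.choice(pool, size=min(n, len(pool)), replace=False).tolist())
        if placement == "mixed":
            picked: set[str] = set()
            for d in sorted(drugs):
                pool = [g for g in drugs[d].module if g not in forbid | picked]
                k = min(2, len(pool))
                picked |= set(rng.choice(pool, size=k, replace=False).tolist())
            pool = [g for g in off_module if g not in forbid | picked]
            extra = max(0, n - len(picked))
            picked |= set(rng.choice(pool, size=min(extra, len(pool)), replace=False).tolist())
            return picked
        raise ValueError(f"unknown placement {placement!r}")

    disease = _place(n_disease, disease_placement)
    essential = set(rng.choice(sorted(disease), size=min(n_overlap, len(disease)),
                               replace=False).tolist())
    essential |= _place(n_essential - len(essential), essential_placement, forbid=disease)

    expr_seed = int(rng.integers(0, 2**31 - 1))
    expression = _emit_expression(net, mu_by_drug, noise_sd, seed=expr_seed)
    return SyntheticScenario(network=net, disease_genes=disease,
                             essential_genes=essential, drugs=drugs,
                             noise_sd=noise_sd, seed=seed, expression=expression)


def make_combo_truth(
    scenario: SyntheticScenario,
    drug_a: str,
    drug_b: str,
    interaction: str = "additive",
    boost: float = 2.0,
    seed: int | None = None,
) -> PerturbationData:
    """Ground-truth expression fixture for a two-drug combination.

    ``additive``: per-gene true ratio 1 + (r_a - 1) + (r_b - 1).
    ``synergistic_on_disease``: disease genes get their combined additive
    deviation multiplied by ``boost`` (>= 1.5).
    """
    if interaction not in INTERACTIONS:
        raise ValueError(f"unknown interaction {interaction!r}")
    for d in (drug_a, drug_b):
        if d not in scenario.drugs:
            raise ValueError(f"drug {d!r} not in scenario")
    if interaction == "synergistic_on_disease" and boost < 1.5:
        raise ValueError("boost must be >= 1.5")
    ra = 2.0 ** scenario.drugs[drug_a].true_log2
    rb = 2.0 ** scenario.drugs[drug_b].true_log2
    dev = (ra - 1.0) + (rb - 1.0)
    if interaction == "synergistic_on_disease":
        in_disease = dev.index.isin(scenario.disease_genes)
        dev = dev.where(~in_disease, dev * boost)
    ratio = (1.0 + dev).clip(lower=0.01)
    mu = np.log2(ratio)
    label = f"{drug_a}+{drug_b}"
    if seed is None:
        seed = scenario.seed + 104729
    return _emit_expression(scenario.network, {label: mu},
                            scenario.noise_sd, seed=seed)


def scenario_edge_records(scenario: SyntheticScenario, seed: int | None = None):
    """Split the scenario network into raw ppi/pdi/signaling edge lists.

    The lists include deliberate noise that the network-assembly stage must
    remove — self-interactions, duplicate PPI records, singly-supported PPI
    edges, an edge to a non-expressed gene, and a disconnected expressed
    pair — so that rebuilding from these files recovers the scenario network
    exactly.  Returns (ppi, pdi, signaling, expressed_genes).
    """
    from .network import InteractionRecord

    rng = np.random.default_rng(scenario.seed + 7919 if seed is None else seed)
    edges = sorted(scenario.network.edges)
    assign = rng.integers(0, 3, size=len(edges))
    ppi, pdi, sig = [], [], []
    for (a, b), which in zip(edges, assign):
        if which == 0:
            ppi.append(InteractionRecord(a, b, "ppi", int(rng.integers(2, 5))))
        elif which == 1:
            pdi.append(InteractionRecord(a, b, "protein_dna", directed=True))
        else:
            sig.append(InteractionRecord(a, b, "signaling", directed=True))
    genes = sorted(scenario.network.nodes)
    # noise records, all removable by the assembly rules
    ppi.append(InteractionRecord(genes[0], genes[0], "ppi", 5))          # self-loop
    if ppi:
        first = ppi[0]
        ppi.append(InteractionRecord(first.gene_a, first.gene_b, "ppi", 1))  # duplicate
    non_adj = next((a, b) for a, b in itertools.combinations(genes[:10], 2)
                   if not scenario.network.graph.has_edge(a, b))
    ppi.append(InteractionRecord(*non_adj, "ppi", 1))                    # under-supported
    pdi.append(InteractionRecord(genes[1], "XNOTEXPR", "protein_dna", directed=True))
    sig.append(InteractionRecord("XISL1", "XISL2", "signaling", directed=True))
    expressed = genes + ["XISL1", "XISL2"]
    return ppi, pdi, sig, expressed
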