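"""Readers and writers for the tab-separated formats shared by all stages.

Every table is TSV with a mandatory header; nested results are JSON.
Networks can additionally be exported as GraphML and SIF for visualisation
tools.  Gene sets are plain one-symbol-per-line files or GMT.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .combine import ComboPrediction
from .expression import META_COLUMNS, ExpressionProfile
from .network import InteractionRecord, MolecularNetwork
from .subnetwork import SubnetworkResult

logger = logging.getLogger(__name__)


# -- edge lists ----------------------------------------------------------
def read_edge_list(path, source_type: str = "ppi") -> list[InteractionRecord]:
    """Read `gene_a<TAB>gene_b[<TAB>evidence_count]` with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns gene_a, gene_b")
    directed = source_type in ("protein_dna", "signaling")
    records = []
    for _, row in df.iterrows():
        ev = int(row["evidence_count"]) if "evidence_count" in df.columns and pd.notna(row.get("evidence_count")) else 0
        records.append(InteractionRecord(row["gene_a"], row["gene_b"],
                                         source_type, ev, directed=directed))
    return records


def write_edge_list(records: Iterable[InteractionRecord], path) -> None:
    rows = [{"gene_a": r.gene_a, "gene_b": r.gene_b,
             "evidence_count": r.evidence_count} for r in records]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "evidence_count"]).to_csv(
        path, sep="\t", index=False)


def write_network(net: MolecularNetwork, path, graphml: bool = True) -> None:
    """Write the network as a TSV edge list plus node-list sidecar and GraphML."""
    path = Path(path)
    rows = [{"gene_a": a, "gene_b": b,
             "sources": ",".join(net.graph.edges[a, b].get("sources", []))}
            for a, b in sorted(net.edges)]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "sources"]).to_csv(
        path, sep="\t", index=False)
    path.with_suffix(".nodes.txt").write_text(
        "\n".join(sorted(net.nodes)) + "\n")
    if graphml:
        g = nx.Graph()
        g.add_nodes_from(sorted(net.nodes))
        for a, b in sorted(net.edges):
            g.add_edge(a, b, sources=",".join(net.graph.edges[a, b].get("sources", [])))
        nx.write_graphml(g, path.with_suffix(".graphml"))


def read_network(path) -> MolecularNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str)
    net = MolecularNetwork.from_edges(zip(df["gene_a"], df["gene_b"]))
    if "sources" in df.columns:
        for _, row in df.iterrows():
            a, b = sorted((row["gene_a"].upper(), row["gene_b"].upper()))
            if pd.notna(row["sources"]) and row["sources"]:
                net.graph.edges[a, b]["sources"] = row["sources"].split(",")
    return net


# -- expression ----------------------------------------------------------
def read_probe_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_probe_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_probe_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe", "symbol_string"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns probe, symbol_string")
    return df.set_index("probe")["symbol_string"]


def write_probe_map(mapping: pd.Series, path) -> None:
    mapping.rename("symbol_string").rename_axis("probe").to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch_id": str},
                     keep_default_na=False, na_values=[])
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out["control_ids"] = out["control_ids"].map(
        lambda v: ";".join(v) if isinstance(v, (list, tuple)) else (v or ""))
    out[META_COLUMNS].to_csv(path, sep="\t", index=False)


def write_profile(profile: ExpressionProfile | ComboPrediction, path) -> None:
    if isinstance(profile, ComboPrediction):
        df = pd.DataFrame({"gene": profile.combo_ratios.index,
                           "ratio": profile.combo_ratios.values,
                           "weight": profile.weights.values,
                           "mode_used": profile.mode_used_per_gene.values})
    else:
        df = pd.DataFrame({"gene": profile.ratios.index,
                           "ratio": profile.ratios.values,
                           "weight": profile.weights.values})
    df.to_csv(path, sep="\t", index=False)


def read_profile(path, label: str | None = None) -> ExpressionProfile:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "ratio"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns gene, ratio")
    label = label or Path(path).stem
    weights = df.set_index("gene")["weight"] if "weight" in df.columns else None
    return ExpressionProfile(label, df.set_index("gene")["ratio"], weights=weights)


# -- gene sets -----------------------------------------------------------
def read_gene_set(path, gmt_set: str | None = None) -> set[str]:
    """Plain one-symbol-per-line file, or a named set from a GMT file."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        sets = read_gmt(path)
        if gmt_set is None:
            if len(sets) != 1:
                raise ValueError(f"{path}: specify which of {sorted(sets)} to use")
            return next(iter(sets.values()))
        return sets[gmt_set]
    return {line.strip().upper() for line in path.read_text().splitlines()
            if line.strip() and not line.startswith("#")}


def read_gmt(path) -> dict[str, set[str]]:
    sets = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3:
            sets[parts[0]] = {g.strip().upper() for g in parts[2:] if g.strip()}
    return sets


def write_gene_set(genes: Iterable[str], path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_targets(path) -> dict[str, tuple[str, ...]]:
    """`drug<TAB>comma-separated targets` with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"drug", "targets"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns drug, targets")
    return {row["drug"]: tuple(sorted(t.strip().upper() for t in row["targets"].split(",")))
            for _, row in df.iterrows()}


def write_targets(targets_map: Mapping[str, Iterable[str]], path) -> None:
    rows = [{"drug": d, "targets": ",".join(sorted(t))}
            for d, t in sorted(targets_map.items())]
    pd.DataFrame(rows, columns=["drug", "targets"]).to_csv(path, sep="\t", index=False)


# -- subnetworks ---------------------------------------------------------
def write_subnetwork(result: SubnetworkResult, path_base) -> None:
    """Export one subnetwork as JSON + SIF + GraphML next to each other."""
    base = Path(path_base)
    payload = {
        "genes": list(result.genes),
        "edges": [list(e) for e in result.edges],
        "targets": list(result.targets),
        "r_requested": result.r_requested,
        "objective": result.objective,
        "normalized_score": result.normalized_score,
        "lp_integral": result.lp_integral,
    }
    base.with_suffix(".json").write_text(json.dumps(payload, indent=2) + "\n")
    with open(base.with_suffix(".sif"), "w") as fh:
        seen = set()
        for a, b in result.edges:
            fh.write(f"{a}\tinteracts\t{b}\n")
            seen.update((a, b))
        for g in result.genes:
            if g not in seen:
                fh.write(f"{g}\n")
    g = nx.Graph()
    g.add_nodes_from(result.genes)
    g.add_edges_from(result.edges)
    nx.write_graphml(g, base.with_suffix(".graphml"))


def read_subnetwork(path) -> SubnetworkResult:
    payload = json.loads(Path(path).read_text())
    return SubnetworkResult(
        genes=tuple(payload["genes"]),
        edges=tuple(tuple(e) for e in payload["edges"]),
        r_requested=payload["r_requested"],
        objective=payload["objective"],
        normalized_score=payload["normalized_score"],
        lp_integral=payload["lp_integral"],
        targets=tuple(payload.get("targets", ())),
    )


# -- provenance ----------------------------------------------------------
def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path, config: dict, inputs: Mapping[str, str]) -> None:
    import networkx, numpy, pandas, scipy

    payload = {
        "config": config,
        "inputs": {k: {"path": str(v), "sha256": file_sha256(v)}
                   for k, v in inputs.items()},
        "versions": {"numpy": numpy.__version__, "scipy": scipy.__version__,
                     "pandas": pandas.__version__, "networkx": networkx.__version__},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
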