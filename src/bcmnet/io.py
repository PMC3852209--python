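"""Readers and writers for the pipeline's text formats.

Formats: expression TSV (first column gene id, header = sample ids), edge
list TSV with vertex lists in ``#``-prefixed header lines, BiNet JSON and
GMT gene sets, survival CSV (sample_id, time, event), evaluation CSV, and
Newick dendrograms.  Writers are deterministic (fixed field order, no
timestamps) so identical runs give byte-identical artifacts; readers
reject malformed input with the offending location rather than coercing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import WeightedBipartiteGraph
from .merging import DendrogramNode, MacroNetwork, dendrogram_to_newick
from .mining import BCMParams, BiNet, MiningResult
from .survival import SurvivalCohort

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_edges_tsv",
    "write_edges_tsv",
    "read_binets_json",
    "write_binets_json",
    "write_binets_gmt",
    "read_survival_csv",
    "write_survival_csv",
    "write_macros_json",
    "write_newick",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV, validating as it goes."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        pos = int(np.nonzero(df.index.duplicated())[0][0])
        raise ValueError(  # header is line 1
            f"{path}:{pos + 2}: duplicate gene id {df.index[pos]!r}"
        )
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            line = list(df.index).index(bad) + 2
            raise ValueError(f"{path}:{line}: non-numeric value in column {col!r}")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        line = list(df.index).index(gene) + 2
        raise ValueError(f"{path}:{line}: missing value")
    return df


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def write_edges_tsv(graph: WeightedBipartiteGraph, path) -> None:
    """Edge list TSV; vertex lists preserved in '#'-prefixed header lines."""
    with open(path, "w") as fh:
        fh.write("#x_vertices\t" + "\t".join(graph.x_ids) + "\n")
        fh.write("#y_vertices\t" + "\t".join(graph.y_ids) + "\n")
        fh.write("tumor_gene\tstroma_gene\tweight\n")
        for x, y, w in graph.edges():
            fh.write(f"{x}\t{y}\t{w:.17g}\n")


def read_edges_tsv(path) -> WeightedBipartiteGraph:
    path = Path(path)
    x_ids: list[str] | None = None
    y_ids: list[str] | None = None
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#x_vertices\t"):
                x_ids = line.split("\t")[1:]
                continue
            if line.startswith("#y_vertices\t"):
                y_ids = line.split("\t")[1:]
                continue
            if line.startswith("tumor_gene\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                w = float(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric weight {parts[2]!r}")
            edges.append((parts[0], parts[1], w))
    if x_ids is None or y_ids is None:
        raise ValueError(f"{path}: missing #x_vertices/#y_vertices header lines")
    return WeightedBipartiteGraph.from_edges(x_ids, y_ids, edges)


def _binet_to_dict(b: BiNet) -> dict:
    return {
        "x_members": b.x_members,
        "y_members": b.y_members,
        "seed_edge": list(b.seed_edge),
        "density": b.density,
        "growth_trace": [list(t) for t in b.growth_trace],
    }


def write_binets_json(result: MiningResult, path) -> None:
    params = {
        "C": result.params.C,
        "tau": result.params.tau,
        "beta": result.params.beta,
        "min_seed_weight": result.params.min_seed_weight,
    }
    payload = {
        "params": params,
        "config_hash": config_hash(params),
        "w_max": result.w_max,
        "selected_edge_count": result.selected_edge_count,
        "binets": [_binet_to_dict(b) for b in result.binets],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_binets_json(path) -> MiningResult:
    with open(path) as fh:
        payload = json.load(fh)
    params = BCMParams(**payload["params"])
    binets = [
        BiNet(
            x_members=d["x_members"],
            y_members=d["y_members"],
            seed_edge=tuple(d["seed_edge"]),
            density=d["density"],
            growth_trace=[tuple(t) for t in d["growth_trace"]],
        )
        for d in payload["binets"]
    ]
    return MiningResult(binets, payload["selected_edge_count"], params, payload["w_max"])


def write_binets_gmt(binets: list[BiNet], path, prefix: str = "binet") -> None:
    """GMT gene sets: one line per BiNet, union of both sides.

    Description field records the per-side composition so tumor/stroma
    membership survives the union.
    """
    with open(path, "w") as fh:
        for i, b in enumerate(binets):
            desc = (
                f"density={b.density:.6g};"
                f"x={','.join(b.x_members)};y={','.join(b.y_members)}"
            )
            genes = "\t".join(sorted(b.genes))
            fh.write(f"{prefix}{i}\t{desc}\t{genes}\n")


def write_survival_csv(cohort: SurvivalCohort, path) -> None:
    pd.DataFrame(
        {"sample_id": cohort.sample_ids, "time": cohort.time, "event": cohort.event}
    ).to_csv(path, index=False, float_format="%.17g")


def read_survival_csv(path, features: pd.DataFrame | None = None) -> SurvivalCohort:
    """Read a survival table; optional expression matrices supply features.

    ``features`` is a samples x genes DataFrame aligned by sample id (rows
    for unknown sample ids are dropped with an error if any survival
    sample has no feature row).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    ids = [str(s) for s in df["sample_id"]]
    if features is None:
        feats = pd.DataFrame(index=ids)
    else:
        missing = [s for s in ids if s not in features.index]
        if missing:
            raise ValueError(f"{path}: no feature row for sample {missing[0]!r}")
        feats = features.loc[ids]
    return SurvivalCohort(
        sample_ids=ids,
        time=df["time"].to_numpy(float),
        event=df["event"].to_numpy(int),
        features=feats,
    )


def write_macros_json(macros: list[MacroNetwork], path) -> None:
    payload = [
        {
            "member_binet_ids": m.member_binet_ids,
            "x_union": sorted(m.x_union),
            "y_union": sorted(m.y_union),
            "density": m.density,
        }
        for m in macros
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_newick(root: DendrogramNode, path, labels: list[str] | None = None) -> None:
    Path(path).write_text(dendrogram_to_newick(root, labels) + "\n")
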