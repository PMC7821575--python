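"""Readers and writers for the pipeline's delimited-text formats.

Conventions: tables are comma-separated UTF-8 with a mandatory header and
"." decimals; square matrices are whitespace-delimited (compatible with
BrainNet Viewer ``.edge`` files); node coordinates are MNI millimeters kept
to 2 decimals; node indices are 1-based in files and 0-based in memory.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import ConnectivityStack, build_stack
from .exceptions import InvalidParameterError
from .mfa import MFAResult, MultiBlockTable, partial_scores_frame, variance_table
from .nbs import NBSRun
from .simulate import GroundTruth

ITEM_COLUMNS = [f"item_{i + 1:02d}" for i in range(12)]
NODE_COLUMNS = ["label", "hemisphere", "x", "y", "z"]


# ---------------------------------------------------------------------------
# questionnaire


def read_questionnaire(path) -> MultiBlockTable:
    """Load a long-format questionnaire CSV into a MultiBlockTable.

    Expected header: subject_id, day, run, item_01..item_12.  Subjects with
    incomplete blocks are dropped (warning); duplicated (subject, day, run)
    rows and non-numeric item values are errors.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ["subject_id", "day", "run", *ITEM_COLUMNS]
               if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"{path}: missing column(s) {missing}")
    for col in ITEM_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() and not df[col].isna().any():
            row = int(df.index[vals.isna()][0])
            raise InvalidParameterError(
                f"{path}: non-numeric value in column {col!r} at row {row}"
            )
        df[col] = vals
    return MultiBlockTable.from_long(df, item_names=ITEM_COLUMNS)


def write_questionnaire(table: MultiBlockTable, path) -> None:
    table.to_long().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# matrices, node tables, ground truth


def write_matrix(matrix: np.ndarray, path, fmt: str = "%.10g") -> None:
    """Whitespace-delimited square matrix (BrainNet .edge compatible)."""
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt=fmt)


def read_matrix(path) -> np.ndarray:
    m = np.loadtxt(path, ndmin=2)
    if m.shape[0] != m.shape[1]:
        raise InvalidParameterError(f"{path}: matrix is not square {m.shape}")
    return m


def write_node_table(node_table: pd.DataFrame, path) -> None:
    out = node_table[NODE_COLUMNS].copy()
    for c in ("x", "y", "z"):
        out[c] = out[c].round(2)
    out.to_csv(path, index=False)


def read_node_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in NODE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"{path}: missing column(s) {missing}")
    return df[NODE_COLUMNS]


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def write_connectivity_dir(stack: ConnectivityStack, outdir) -> None:
    """One whitespace matrix file per scan plus metadata and node tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = stack.meta.copy()
    files = []
    for s in range(stack.n_scans):
        row = meta.iloc[s]
        name = f"{row.subject_id}_day{row.day}_run{row.run}.txt"
        write_matrix(stack.matrix(s), outdir / name)
        files.append(name)
    meta["file"] = files
    meta.to_csv(outdir / "scans.csv", index=False)
    write_node_table(stack.node_table, outdir / "nodes.csv")


def read_connectivity_dir(path, questionnaire=None) -> ConnectivityStack:
    path = Path(path)
    meta = pd.read_csv(path / "scans.csv")
    node_table = read_node_table(path / "nodes.csv")
    matrices = [read_matrix(path / f) for f in meta["file"]]
    return build_stack(
        matrices, meta.drop(columns="file"), node_table, questionnaire=questionnaire
    )


# ---------------------------------------------------------------------------
# factor-analysis outputs


def write_mfa_tables(result: MFAResult, subject_ids, outdir, summaries=()) -> list:
    """Write loadings, scores, contributions and scree tables; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    k = len(result.block_labels)
    j = result.n_items
    cols = [f"component_{l + 1}" for l in range(result.n_components)]

    idx = pd.MultiIndex.from_tuples(
        [
            (d, r, item)
            for (d, r) in result.block_labels
            for item in result.item_names
        ],
        names=["day", "run", "item"],
    )
    loadings = pd.DataFrame(result.loadings, index=idx, columns=cols).reset_index()
    written.append(_save(loadings, outdir / "loadings.csv"))

    scores = pd.DataFrame(result.compromise_scores, columns=cols)
    scores.insert(0, "subject_id", list(subject_ids))
    written.append(_save(scores, outdir / "compromise_scores.csv"))
    written.append(
        _save(partial_scores_frame(result, subject_ids), outdir / "partial_scores.csv")
    )

    ctr = result.contributions.transpose(1, 0, 2).reshape(k * j, -1)
    contrib = pd.DataFrame(ctr, index=idx, columns=cols).reset_index()
    written.append(_save(contrib, outdir / "contributions.csv"))
    written.append(_save(variance_table(result), outdir / "variance.csv"))

    for summary in summaries:
        p = outdir / f"bootstrap_component_{summary.component}.csv"
        written.append(_save(summary.table, p))
    return written


def _save(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# network outputs


def write_network_tables(
    run: NBSRun, node_table: pd.DataFrame, outdir, prefix: str = "network"
) -> list:
    """Tables and BrainNet files for every component of a run.

    Per component k (1-based, extent-sorted): ``{prefix}{k}_nodes.csv``
    (atlas label, hemisphere, MNI x/y/z), ``{prefix}{k}_edges.csv``
    (pairwise connections, 1-based node indices), ``{prefix}{k}.node`` and
    ``{prefix}{k}.edge`` (BrainNet Viewer).  Empty runs still produce a
    header-only summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    n_nodes = len(node_table)
    summary_rows = []
    for k, comp in enumerate(run.components, start=1):
        for node in comp.nodes:
            if not 0 <= node < n_nodes:
                raise InvalidParameterError(
                    f"component references node {node} absent from node table"
                )
        nodes = node_table.iloc[comp.nodes][NODE_COLUMNS].copy()
        nodes.insert(0, "node", np.asarray(comp.nodes) + 1)  # 1-based in files
        written.append(_save(nodes, outdir / f"{prefix}{k}_nodes.csv"))

        lab = node_table["label"]
        hemi = node_table["hemisphere"]
        edges = pd.DataFrame(
            {
                "node_i": [i + 1 for i, _ in comp.edges],
                "node_j": [j + 1 for _, j in comp.edges],
                "label_i": [f"{hemi[i]} {lab[i]}" for i, _ in comp.edges],
                "label_j": [f"{hemi[j]} {lab[j]}" for _, j in comp.edges],
            }
        )
        written.append(_save(edges, outdir / f"{prefix}{k}_edges.csv"))
        written.extend(
            write_brainnet(comp, node_table, outdir / f"{prefix}{k}")
        )
        summary_rows.append(
            {
                "network": k,
                "extent": comp.size_extent,
                "n_nodes": len(comp.nodes),
                "p_fwe": comp.p_fwe,
                "cohens_d": comp.cohens_d,
                "mean_abs_t": comp.mean_abs_t,
            }
        )
    summary = pd.DataFrame(
        summary_rows,
        columns=["network", "extent", "n_nodes", "p_fwe", "cohens_d", "mean_abs_t"],
    )
    written.append(_save(summary, outdir / f"{prefix}_summary.csv"))
    return written


def write_brainnet(component, node_table: pd.DataFrame, stem) -> list:
    """BrainNet Viewer .node (x y z color size label) and .edge files.

    The .edge matrix is the symmetric 0/1 adjacency over the component's
    nodes (in ascending node order, matching the .node rows).
    """
    stem = Path(stem)
    nodes = list(component.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    degree = np.zeros(len(nodes))
    adj = np.zeros((len(nodes), len(nodes)))
    for i, j in component.edges:
        adj[pos[i], pos[j]] = adj[pos[j], pos[i]] = 1.0
        degree[pos[i]] += 1
        degree[pos[j]] += 1
    node_path = stem.with_suffix(".node")
    with open(node_path, "w") as fh:
        for n, deg in zip(nodes, degree):
            row = node_table.iloc[n]
            label = str(row["label"]).replace(" ", "_")
            fh.write(
                f"{row['x']:.2f}\t{row['y']:.2f}\t{row['z']:.2f}\t"
                f"1\t{deg:.0f}\t{row['hemisphere']}_{label}\n"
            )
    edge_path = stem.with_suffix(".edge")
    write_matrix(adj, edge_path, fmt="%.0f")
    return [node_path, edge_path]


def read_edge_pairs(path) -> list:
    """Canonical 0-based edge pairs from a ``*_edges.csv`` file."""
    df = pd.read_csv(path)
    return sorted(
        tuple(sorted((int(i) - 1, int(j) - 1)))
        for i, j in zip(df["node_i"], df["node_j"])
    )


def write_null_distribution(run: NBSRun, path) -> None:
    pd.DataFrame({"max_size": run.null_max_sizes}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run report


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_report(path, config: dict, stages: dict) -> None:
    """Provenance record: version, config echo, per-stage logs + checksums.

    ``stages`` maps stage name -> {"seconds": float, "seed": ...,
    "outputs": [paths], ...}; checksums are added here.
    """
    report = {"software": {"name": "wandernet", "version": __version__},
              "config": config, "stages": {}}
    for name, info in stages.items():
        entry = {k: v for k, v in info.items() if k != "outputs"}
        entry["outputs"] = {
            str(Path(p).name): file_checksum(p) for p in info.get("outputs", [])
        }
        report["stages"][name] = entry
    Path(path).write_text(json.dumps(report, indent=1, default=str))
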