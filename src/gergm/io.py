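"""Readers and writers for networks, covariates, and fit artifacts.

Conventions: comma-delimited CSV for matrices ('.' decimal, UTF-8, '#'
comment lines), TSV for tables, JSON (schema-versioned) for fit records.
Adjacency files are read as source-row -> target-column.  Vertices are
0-based internally and label-based externally.  All floats are written at 10
significant digits so identical runs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .marginals import EdgeDesign
from .networks import ValuedNetwork, edge_pairs

SCHEMA_VERSION = "1.0"
FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def _read_table(path, **kwargs) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, comment="#", **kwargs)


def read_network(path, format: str = "matrix", directed: bool = True) -> ValuedNetwork:
    """Read a network from a CSV/TSV adjacency matrix or a 3-column edge list.

    Matrix files may carry a header row / first column of vertex labels.
    Edge lists must contain every ordered pair exactly once (the continuous
    model requires all dyads observed).
    """
    path = Path(path)
    if format == "matrix":
        frame = _read_table(path, header=None, dtype=str)
        values = frame.values
        labels = None
        # header row of labels <=> top-left cell is not numeric
        def _numeric(s) -> bool:
            if s is None or (isinstance(s, float) and np.isnan(s)):
                return False  # empty top-left corner of a labeled matrix
            try:
                float(s)
                return True
            except (TypeError, ValueError):
                return False

        if not _numeric(values[0, 0]) and values.shape[0] > 1:
            if not _numeric(values[0, 1]):  # full header row
                labels = [str(v) for v in values[0, 1:]]
                values = values[1:, 1:]
            else:
                labels = [str(v) for v in values[1:, 0]]
                values = values[1:, 1:]
        try:
            mat = values.astype(float)
        except ValueError as err:
            raise ValueError(f"{path}: non-numeric entry in adjacency matrix") from err
        if mat.shape[0] != mat.shape[1]:
            raise ValueError(f"{path}: ragged or non-square matrix {mat.shape}")
        return ValuedNetwork(mat, directed=directed, vertex_labels=labels)
    if format == "edgelist":
        frame = _read_table(path, header=None, dtype=str)
        # optional header row: value column not numeric
        try:
            float(frame.iloc[0, 2])
        except (TypeError, ValueError):
            frame = frame.iloc[1:].reset_index(drop=True)
        frame[2] = frame[2].astype(float)
        if frame.shape[1] != 3:
            raise ValueError(f"{path}: edge list must have 3 columns (source, target, value)")
        frame.columns = ["source", "target", "value"]
        labels = sorted(set(frame["source"].astype(str)) | set(frame["target"].astype(str)))
        index = {lab: k for k, lab in enumerate(labels)}
        n = len(labels)
        mat = np.full((n, n), np.nan)
        for _, row in frame.iterrows():
            i, j = index[str(row["source"])], index[str(row["target"])]
            if i == j:
                continue
            if not np.isnan(mat[i, j]):
                raise ValueError(f"{path}: duplicate edge {row['source']}->{row['target']}")
            mat[i, j] = float(row["value"])
        if not directed:
            miss = np.isnan(mat) & np.isnan(mat.T)
            mat = np.where(np.isnan(mat), mat.T, mat)
            mat[np.eye(n, dtype=bool)] = 0.0
            if np.any(miss & ~np.eye(n, dtype=bool)):
                i, j = np.argwhere(miss & ~np.eye(n, dtype=bool))[0]
                raise ValueError(f"{path}: missing dyad {labels[i]}-{labels[j]}")
        else:
            np.fill_diagonal(mat, 0.0)
            if np.any(np.isnan(mat)):
                i, j = np.argwhere(np.isnan(mat))[0]
                raise ValueError(f"{path}: missing ordered pair {labels[i]}->{labels[j]}")
        return ValuedNetwork(mat, directed=directed, vertex_labels=labels)
    raise ValueError(f"unknown network format {format!r}")


def write_network(net: ValuedNetwork, path, format: str = "matrix") -> None:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    labels = net.vertex_labels or [str(k) for k in range(net.n)]
    if format == "matrix":
        frame = pd.DataFrame(net.values, index=labels, columns=labels)
        frame.to_csv(path, sep=sep, float_format=FLOAT_FMT)
    elif format == "edgelist":
        pairs = edge_pairs(net.n, net.directed)
        frame = pd.DataFrame(
            {
                "source": [labels[i] for i in pairs[:, 0]],
                "target": [labels[j] for j in pairs[:, 1]],
                "value": net.values[pairs[:, 0], pairs[:, 1]],
            }
        )
        frame.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)
    else:
        raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

EXPANSION_MODES = ("sender", "receiver", "absdiff")


def expand_node_attribute(
    attr: np.ndarray, n: int, mode: str, directed: bool = True
) -> np.ndarray:
    """Expand one per-node attribute to a per-edge column.

    sender: z_ij = u_i; receiver: z_ij = u_j; absdiff: z_ij = |u_i - u_j|.
    """
    if mode not in EXPANSION_MODES:
        raise ValueError(f"unknown expansion mode {mode!r}; choose from {EXPANSION_MODES}")
    attr = np.asarray(attr, dtype=float)
    pairs = edge_pairs(n, directed)
    if mode == "sender":
        return attr[pairs[:, 0]]
    if mode == "receiver":
        return attr[pairs[:, 1]]
    return np.abs(attr[pairs[:, 0]] - attr[pairs[:, 1]])


def read_covariates(
    network: ValuedNetwork,
    node_table_path=None,
    expansions: list[tuple[str, str]] | None = None,
    edge_matrix_paths: list | None = None,
) -> EdgeDesign:
    """Build an EdgeDesign from a node-attribute table and/or edge matrices.

    ``expansions`` pairs (attribute_name, mode) with mode in sender /
    receiver / absdiff; node labels must match the network's.  Each entry of
    ``edge_matrix_paths`` is an (n, n) CSV used directly as an edge covariate.
    """
    cols = [np.ones(network.m)]
    names = ["intercept"]
    if node_table_path is not None:
        table = _read_table(node_table_path)
        label_col = table.columns[0]
        table[label_col] = table[label_col].astype(str)
        table = table.set_index(label_col)
        net_labels = network.vertex_labels or [str(k) for k in range(network.n)]
        missing = [lab for lab in net_labels if lab not in table.index]
        if missing:
            raise ValueError(f"node table is missing labels {missing}")
        table = table.loc[net_labels]
        for attr, mode in expansions or []:
            if attr not in table.columns:
                raise ValueError(f"attribute {attr!r} not in node table")
            values = pd.to_numeric(table[attr], errors="coerce").to_numpy()
            if np.any(np.isnan(values)):
                raise ValueError(f"non-numeric values in attribute {attr!r}")
            cols.append(expand_node_attribute(values, network.n, mode, network.directed))
            names.append(f"{attr}_{mode}")
    for path in edge_matrix_paths or []:
        mat = _read_table(path, header=None).to_numpy(dtype=float)
        if mat.shape != (network.n, network.n):
            raise ValueError(f"{path}: edge covariate matrix must be {network.n}x{network.n}")
        pairs = edge_pairs(network.n, network.directed)
        cols.append(mat[pairs[:, 0], pairs[:, 1]])
        names.append(Path(path).stem)
    return EdgeDesign(np.column_stack(cols), names)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


def _fmt(x: float) -> float:
    return float(FLOAT_FMT % x)


def write_results(result, outdir, seed: int | None = None) -> dict[str, Path]:
    """Write a fitted model as coefficients.tsv + fit.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coef_path = outdir / "coefficients.tsv"
    frame = pd.DataFrame(
        {
            "name": result.param_names,
            "estimate": result.params,
            "se": result.bse,
            "z": result.zvalues,
            "p": result.pvalues,
        }
    )
    frame.to_csv(coef_path, sep="\t", index=False, float_format=FLOAT_FMT)
    record = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed if seed is not None else result.config.seed,
        "family": result.model.family,
        "bounds": list(result.model.bounds) if result.model.bounds else None,
        "statistics": list(result.model.spec.names),
        "config": {
            k: (v if not isinstance(v, np.ndarray) else v.tolist())
            for k, v in dataclasses.asdict(result.config).items()
        },
        "theta": [_fmt(v) for v in result.theta],
        "beta": [_fmt(v) for v in result.beta],
        "bse": [_fmt(v) for v in result.bse],
        "vcov": [[_fmt(v) for v in row] for row in result.vcov],
        "loglik_trace": [_fmt(v) for v in result.loglik_trace],
        "converged": bool(result.converged),
        "n_outer": int(result.n_outer),
        "M_used": int(result.M_used),
    }
    json_path = outdir / "fit.json"
    json_path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return {"coefficients": coef_path, "fit": json_path}


def write_simulation(sim, outdir, seed: int | None = None, prefix: str = "net") -> None:
    """Write simulated networks as CSV matrices plus a per-sweep summary TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for k, net in enumerate(sim.networks):
        frame = pd.DataFrame(net.values)
        frame.to_csv(outdir / f"{prefix}_{k:05d}.csv", header=False, index=False,
                     float_format=FLOAT_FMT)
    summary = pd.DataFrame({"sweep": np.arange(len(sim.mean_trace)),
                            "mean_edge_value": sim.mean_trace})
    summary.to_csv(outdir / "trace.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    meta = {"schema_version": SCHEMA_VERSION, "seed": seed,
            "n_networks": len(sim.networks)}
    (outdir / "simulation.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def write_diagnostics(report, outdir) -> None:
    """Write a degeneracy/convergence report as JSON + per-edge TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {
        "schema_version": SCHEMA_VERSION,
        "degenerate": bool(report.degenerate),
        "grand_mean": _fmt(report.grand_mean),
        "observed_mean": _fmt(report.observed_mean),
        "share_abs_geweke_z_gt_2": None
        if report.share_abs_z_gt_2 is None
        else _fmt(report.share_abs_z_gt_2),
        "n_rhat_ge_1.1": report.n_rhat_ge_1_1,
        "gelman_rubin_available": report.gelman_rubin_available,
    }
    (outdir / "diagnostics.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    if report.geweke_z is not None:
        cols = {"geweke_z": report.geweke_z}
        if report.rhat is not None:
            cols["rhat"] = report.rhat
        n = min(len(v) for v in cols.values())
        pd.DataFrame({k: v[:n] for k, v in cols.items()}).to_csv(
            outdir / "per_edge.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
    (outdir / "verdict.txt").write_text(report.verdict() + "\n")
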