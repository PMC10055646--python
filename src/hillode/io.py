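"""Plain-text readers and writers for the package's on-disk formats.

All files are TSV (or GMT / flat YAML) and use gene names, never indices.
Matrix orientation everywhere: ``A[i, j]`` = effect of gene j (source) on
gene i (target). Readers and writers round-trip bit-exactly on their own
output.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grn import GRNEstimate
from .prior import PriorModel
from .types import Trajectory, check_gene_index

logger = logging.getLogger(__name__)

__all__ = [
    "write_trajectories",
    "read_trajectories",
    "write_prior",
    "read_prior",
    "read_gmt",
    "write_grn",
    "write_adjacency",
    "write_eval_report",
    "read_config",
    "write_manifest",
]


def write_trajectories(path, trajs: list[Trajectory], genes: list[str] | None = None) -> None:
    """Long-format TSV with columns trajectory_id, time, gene, value."""
    rows = []
    for tid, tr in enumerate(trajs):
        g = genes or tr.genes or [f"G{i}" for i in range(tr.n_genes)]
        for k, t in enumerate(tr.times):
            for j, name in enumerate(g):
                rows.append((tid, t, name, tr.values[k, j]))
    df = pd.DataFrame(rows, columns=["trajectory_id", "time", "gene", "value"])
    df.to_csv(path, sep="\t", index=False)


def read_trajectories(path) -> tuple[list[Trajectory], list[str]]:
    """Parse long-format trajectory TSV; order of rows is irrelevant.

    Every trajectory must observe the same gene set at every time; missing
    (gene, time) cells or ragged gene sets raise with the offenders listed.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"trajectory_id", "time", "gene", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory TSV needs columns {sorted(required)}")
    genes = check_gene_index(sorted(df["gene"].unique()))
    trajs = []
    for tid, sub in df.groupby("trajectory_id", sort=True):
        wide = sub.pivot_table(index="time", columns="gene", values="value", aggfunc="first")
        missing = wide.isna()
        if missing.to_numpy().any():
            offenders = [
                (t, g) for t, g in zip(*np.nonzero(missing.to_numpy()))
            ][:5]
            cells = [(wide.index[t], wide.columns[g]) for t, g in offenders]
            raise ValueError(f"trajectory {tid} missing (time, gene) cells: {cells}")
        if set(wide.columns) != set(genes):
            raise ValueError(f"trajectory {tid} has a ragged gene set")
        wide = wide[genes].sort_index()
        trajs.append(Trajectory(wide.index.to_numpy(float), wide.to_numpy(float), genes=genes))
    return trajs, genes


def write_prior(path, prior: PriorModel) -> None:
    """Edge-list TSV with columns source, target, sign."""
    genes = prior.genes or [f"G{i}" for i in range(prior.n)]
    ti, sj = np.nonzero(prior.A)
    df = pd.DataFrame(
        {
            "source": [genes[j] for j in sj],
            "target": [genes[i] for i in ti],
            "sign": [int(prior.A[i, j]) for i, j in zip(ti, sj)],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_prior(path, genes: list[str], seed=0) -> PriorModel:
    """Edge-list TSV (source, target, sign in {+1, -1, NA}) to a PriorModel.

    Unknown signs are assigned +1 or -1 with equal probability under
    ``seed``; edges naming genes outside the index are dropped (count
    logged); duplicate edges with conflicting signs raise.
    """
    genes = check_gene_index(genes)
    pos = {g: i for i, g in enumerate(genes)}
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    n = len(genes)
    A = np.zeros((n, n))
    if df.empty:
        return PriorModel(A, genes=genes)
    if not {"source", "target", "sign"}.issubset(df.columns):
        raise ValueError("prior TSV needs columns source, target, sign")
    rng = np.random.default_rng(seed)
    dropped = 0
    seen: dict[tuple[int, int], float] = {}
    for _, row in df.iterrows():
        s, t = row["source"], row["target"]
        if s not in pos or t not in pos:
            dropped += 1
            continue
        sign = row["sign"]
        if pd.isna(sign):
            sign = 1.0 if rng.random() < 0.5 else -1.0
        else:
            sign = float(sign)
            if sign not in (-1.0, 1.0):
                raise ValueError(f"invalid sign {sign} on edge {s}->{t}")
        key = (pos[t], pos[s])
        if key in seen and seen[key] != sign:
            raise ValueError(f"conflicting duplicate edge {s}->{t}")
        seen[key] = sign
        A[key] = sign
    if dropped:
        logger.info("dropped %d prior edges naming unknown genes", dropped)
    return PriorModel(A, genes=genes)


def read_gmt(path) -> dict[str, set]:
    """Standard GMT gene-set file: name, description, then member genes.

    Duplicate pathway names and malformed lines raise (with the line
    number); pathways with no genes are dropped with a warning.
    """
    pathways: dict[str, set] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed GMT line {ln}: need name and description")
        name = parts[0]
        if name in pathways:
            raise ValueError(f"duplicate pathway name {name!r} at line {ln}")
        members = {g for g in parts[2:] if g}
        if not members:
            logger.warning("pathway %s (line %d) has no genes; dropped", name, ln)
            continue
        pathways[name] = members
    return pathways


def write_grn(path, est: GRNEstimate, genes: list[str] | None = None) -> None:
    """Edge-score TSV with columns source, target, score, sign (full matrix)."""
    genes = genes or est.genes or [f"G{i}" for i in range(est.n)]
    rows = []
    for i in range(est.n):
        for j in range(est.n):
            if i == j:
                continue
            sc = est.scores[i, j]
            rows.append((genes[j], genes[i], sc, int(np.sign(sc))))
    pd.DataFrame(rows, columns=["source", "target", "score", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_adjacency(path, matrix: np.ndarray, genes: list[str]) -> None:
    """n x n table with gene names on both axes (rows = targets)."""
    pd.DataFrame(matrix, index=genes, columns=genes).to_csv(path, sep="\t")


def read_adjacency(path) -> tuple[np.ndarray, list[str]]:
    """Read an n x n table written by :func:`write_adjacency`."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ValueError("adjacency table must have identical row and column gene names")
    return df.to_numpy(float), check_gene_index(df.columns)


def write_influence(path, infl) -> None:
    genes = infl.genes or [f"G{i}" for i in range(infl.n)]
    pd.DataFrame({"gene": genes, "influence": infl.scores}).to_csv(
        path, sep="\t", index=False
    )


def read_influence(path):
    from .perturbation import InfluenceScores

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return InfluenceScores(df["influence"].to_numpy(float), genes=list(df["gene"]))


def write_eval_report(path, report) -> None:
    """Flat key-value text file for an evaluation report."""
    d = report.as_dict() if hasattr(report, "as_dict") else dict(report)
    Path(path).write_text("".join(f"{k}\t{v:.6g}\n" for k, v in d.items()))


def read_config(path) -> dict:
    """Flat key-value configuration file (YAML syntax)."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must be a flat key-value mapping")
    return cfg


def write_manifest(out_dir, payload: dict) -> None:
    """Record config, seed and software version for a run."""
    from . import __version__

    payload = {"hillode_version": __version__, **payload}
    Path(out_dir, "manifest.json").write_text(json.dumps(payload, indent=2, default=str))
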