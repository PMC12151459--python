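"""Plain-text file formats: labelled TSV matrices, edge lists, configs.

All matrices travel as tab-separated files with a header row and a first
label column; values are written with round-trippable precision (shortest
decimal representation that restores the exact float). Gold-standard
networks use a DREAM-style ``regulator<TAB>target<TAB>weight`` edge list;
the in-memory convention everywhere is entry (target row, regulator
column).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulator import GRNMatrix, PerturbationDesign, ExpressionDataset, SimulationConfig

__all__ = [
    "ParseError",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "infer_replicates",
    "read_edge_list",
    "write_edge_list",
    "read_config",
    "write_config",
    "write_benchmark_bundle",
    "read_benchmark_bundle",
]

_REPLICATE_SUFFIX = re.compile(r"_r(\d+)$")


class ParseError(ValueError):
    """Malformed input file; message carries the offending line or label."""


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a labelled TSV matrix, validating shape and labels."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    ncol = len(header) - 1
    row_labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != ncol + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {ncol + 1} columns, found {len(cells)}"
            )
        row_labels.append(cells[0])
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    for labels, kind in ((row_labels, "row"), (header[1:], "column")):
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                raise ParseError(f"{path}: duplicate {kind} label {lab!r}")
            seen.add(lab)
    return pd.DataFrame(rows, index=row_labels, columns=header[1:], dtype=float)


def write_matrix_tsv(matrix, path, row_labels=None, col_labels=None) -> None:
    """Write a matrix (ndarray or DataFrame) as a labelled TSV."""
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
        row_labels = list(matrix.index)
        col_labels = list(matrix.columns)
    else:
        values = np.asarray(matrix, dtype=float)
        if row_labels is None:
            row_labels = [f"G{i + 1}" for i in range(values.shape[0])]
        if col_labels is None:
            col_labels = [f"C{j + 1}" for j in range(values.shape[1])]
    with open(path, "w") as fh:
        fh.write("\t".join(["gene", *map(str, col_labels)]) + "\n")
        for lab, row in zip(row_labels, values):
            fh.write("\t".join([str(lab), *(repr(float(v)) for v in row)]) + "\n")


def infer_replicates(columns) -> int:
    """Number of technical replicates from ``_r1/_r2/...`` column suffixes."""
    reps = [int(m.group(1)) for c in columns if (m := _REPLICATE_SUFFIX.search(str(c)))]
    return max(reps) if reps else 1


def read_edge_list(path, gene_names: list[str]) -> GRNMatrix:
    """Read a regulator<TAB>target<TAB>weight edge list into an adjacency matrix.

    Unlisted pairs are zero; the edge regulator -> target lands at
    (row target, column regulator).
    """
    index = {g: i for i, g in enumerate(gene_names)}
    weights = np.zeros((len(gene_names), len(gene_names)))
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
        regulator, target, weight = cells
        for lab in (regulator, target):
            if lab not in index:
                raise ParseError(f"{path}:{lineno}: unknown gene label {lab!r}")
        try:
            weights[index[target], index[regulator]] = float(weight)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric weight {weight!r}") from None
    return GRNMatrix(weights, gene_names=list(gene_names))


def write_edge_list(network: GRNMatrix, path) -> None:
    """Write the nonzero entries as regulator<TAB>target<TAB>weight lines."""
    names = network.gene_names
    with open(path, "w") as fh:
        for i, j in zip(*np.nonzero(network.weights)):
            fh.write(f"{names[j]}\t{names[i]}\t{float(network.weights[i, j])!r}\n")


_CONFIG_FIELDS = (
    "n_genes",
    "avg_links_per_gene",
    "snr",
    "replicates",
    "seed",
    "weight_low",
    "weight_high",
    "confidence_level",
)


def read_config(path) -> SimulationConfig:
    """Load a simulation config from a YAML key-value file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(_CONFIG_FIELDS)
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return SimulationConfig(**raw)


def write_config(config: SimulationConfig, path) -> None:
    payload = {k: getattr(config, k) for k in _CONFIG_FIELDS}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _experiment_labels(gene_names: list[str], replicates: int) -> list[str]:
    return [f"{g}_r{r + 1}" for r in range(replicates) for g in gene_names]


def write_benchmark_bundle(
    directory,
    network: GRNMatrix,
    design: PerturbationDesign,
    data: ExpressionDataset,
) -> None:
    """Write network.tsv, perturbation.tsv, expression.tsv, goldstandard.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = network.gene_names
    cols = _experiment_labels(names, design.replicates)
    write_matrix_tsv(network.weights, directory / "network.tsv", names, names)
    write_matrix_tsv(design.values, directory / "perturbation.tsv", names, cols)
    write_matrix_tsv(data.Y, directory / "expression.tsv", names, cols)
    write_edge_list(network, directory / "goldstandard.tsv")


def read_benchmark_bundle(directory) -> tuple[GRNMatrix, np.ndarray, np.ndarray]:
    """Load (network, P, Y) back from a bundle directory."""
    directory = Path(directory)
    net_df = read_matrix_tsv(directory / "network.tsv")
    P = read_matrix_tsv(directory / "perturbation.tsv")
    Y = read_matrix_tsv(directory / "expression.tsv")
    network = GRNMatrix(net_df.to_numpy(), gene_names=list(net_df.index))
    return network, P.to_numpy(), Y.to_numpy()
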