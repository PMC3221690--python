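"""Tab-delimited I/O for expression matrices, designs, and result tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .anova import ExperimentDesign

__all__ = ["read_dataset", "write_dataset", "write_results", "bh_adjust"]

DESIGN_COLUMNS = ["observation_id", "group", "probe", "replicate"]


def read_dataset(matrix_path: str | Path, design_path: str | Path
                 ) -> tuple[np.ndarray, ExperimentDesign, list[str]]:
    """Read a gene x observation TSV matrix and its design table.

    The matrix's first column holds gene identifiers; remaining column
    headers are observation ids that must match the design table 1:1.
    Returns ``(Y, design, gene_ids)``.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    des = pd.read_csv(design_path, sep="\t", dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in des.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    obs = list(mat.columns)
    if sorted(obs) != sorted(des["observation_id"]):
        raise ValueError("observation ids in matrix and design do not match 1:1")
    des = des.set_index("observation_id").loc[obs].reset_index()
    if not np.issubdtype(mat.to_numpy().dtype, np.number):
        raise ValueError("non-numeric cells in expression matrix")
    design = ExperimentDesign(
        observation_ids=tuple(obs),
        probe_level=tuple(des["probe"]),
        group_level=tuple(des["group"]),
        replicate_level=tuple(des["replicate"]),
    )
    return mat.to_numpy(dtype=float), design, list(mat.index.astype(str))


def write_dataset(path_matrix: str | Path, path_design: str | Path,
                  Y: np.ndarray, design: ExperimentDesign,
                  gene_ids: list[str] | None = None) -> None:
    """Write a dataset as the TSV pair that :func:`read_dataset` accepts."""
    if gene_ids is None:
        gene_ids = [f"gene{i + 1}" for i in range(Y.shape[0])]
    mat = pd.DataFrame(Y, index=pd.Index(gene_ids, name="gene"),
                       columns=list(design.observation_ids))
    mat.to_csv(path_matrix, sep="\t")
    des = pd.DataFrame({
        "observation_id": design.observation_ids,
        "group": design.group_level,
        "probe": design.probe_level,
        "replicate": design.replicate_level,
    })
    des.to_csv(path_design, sep="\t", index=False)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a per-gene results table (gene, statistic, value, p, reject)."""
    results.to_csv(path, sep="\t", index=False)
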