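"""Transcriptome-side computations: transcribed-gene counting, DEG
filtering, the co-expression pre-filter, and classical MDS of expression
profiles.

The expression matrix is a DataFrame of non-negative RPKM values, genes as
the index and sample-replicate labels of the form ``[<type>_]S<stage>_R<rep>``
as columns.  Differential-expression testing itself is upstream: a DE table
(gene, fold_change, q_value) is taken as input and only filtered here.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .dmr import venn_counts

SAMPLE_LABEL = re.compile(r"^(?:(?P<prefix>.+)_)?S(?P<stage>\d+)_R(?P<rep>\d+)$")


def validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if (matrix < 0).any().any():
        raise ValueError("RPKM values must be non-negative")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample labels")


def sample_groups(columns) -> dict[str, list[str]]:
    """Group replicate columns by sample (stage) label, preserving order."""
    groups: dict[str, list[str]] = {}
    for col in columns:
        m = SAMPLE_LABEL.match(col)
        key = col if m is None else (
            (m.group("prefix") + "_" if m.group("prefix") else "") + "S" + m.group("stage")
        )
        groups.setdefault(key, []).append(col)
    return groups


def stage_means(matrix: pd.DataFrame) -> pd.DataFrame:
    """Average replicates per stage, one column per sample."""
    validate_matrix(matrix)
    groups = sample_groups(matrix.columns)
    return pd.DataFrame({key: matrix[cols].mean(axis=1) for key, cols in groups.items()})


def count_transcribed(
    matrix: pd.DataFrame, threshold: float = 1.0, mode: str = "mean"
) -> pd.Series:
    """Number of transcribed genes (RPKM > threshold, strict) per sample.

    ``mode="mean"`` averages replicates per stage before thresholding;
    ``mode="all"`` requires every replicate of a stage to clear it.
    """
    validate_matrix(matrix)
    groups = sample_groups(matrix.columns)
    out = {}
    for key, cols in groups.items():
        if mode == "mean":
            out[key] = int((matrix[cols].mean(axis=1) > threshold).sum())
        elif mode == "all":
            out[key] = int((matrix[cols] > threshold).all(axis=1).sum())
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(out, name="transcribed")


def filter_degs(
    table: pd.DataFrame, min_fold: float = 4.0, max_q: float = 0.01
) -> pd.DataFrame:
    """Strict DEG filter: fold change > min_fold (or < 1/min_fold) and
    q < max_q; both inequalities strict.  Adds a direction column (up/down,
    later stage over earlier)."""
    if (table["fold_change"] <= 0).any():
        raise ValueError("fold changes must be positive ratios")
    up = (table["fold_change"] > min_fold) & (table["q_value"] < max_q)
    down = (table["fold_change"] < 1.0 / min_fold) & (table["q_value"] < max_q)
    out = table.loc[up | down].copy()
    out["direction"] = np.where(out["fold_change"] > 1.0, "up", "down")
    return out


def variation_filter(
    matrix: pd.DataFrame, min_max_rpkm: float = 2.0, min_cv: float = 1.0
) -> pd.Index:
    """Co-expression pre-filter: keep genes with max RPKM > min_max_rpkm and
    coefficient of variation (sample sd / mean) > min_cv.

    Genes with zero mean have undefined CV and are excluded.
    """
    validate_matrix(matrix)
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    keep = (matrix.max(axis=1) > min_max_rpkm) & (mean > 0) & (cv > min_cv)
    return matrix.index[keep]


def mds_embedding(
    matrix: pd.DataFrame, dimensions: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Classical (metric) MDS of samples on Euclidean expression distances.

    Returns (distance matrix, coordinates, stress).  Coordinates come from
    the top eigenpairs of the double-centred squared-distance matrix; stress
    is the relative residual sqrt(Σ(d_emb − d)² / Σd²).
    """
    validate_matrix(matrix)
    X = matrix.to_numpy(dtype=float).T  # samples × genes
    n = X.shape[0]
    if n < dimensions + 1:
        raise ValueError(f"need at least {dimensions + 1} samples for {dimensions}-D MDS")
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dimensions]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    emb_diff = coords[:, None, :] - coords[None, :, :]
    D_emb = np.sqrt((emb_diff**2).sum(axis=2))
    denom = (D**2).sum()
    stress = float(np.sqrt(((D_emb - D) ** 2).sum() / denom)) if denom > 0 else 0.0
    labels = matrix.columns
    dist_df = pd.DataFrame(D, index=labels, columns=labels)
    coord_df = pd.DataFrame(
        coords, index=labels, columns=[f"dim{i + 1}" for i in range(dimensions)]
    )
    return dist_df, coord_df, stress


def summarize_deg_direction(
    deg_tables: dict[str, pd.DataFrame]
) -> tuple[pd.DataFrame, dict[str, dict[frozenset, int]]]:
    """Up/down DEG counts per comparison plus Venn overlaps across
    comparisons (computed separately for up and down sets)."""
    rows = []
    up_sets: dict[str, set] = {}
    down_sets: dict[str, set] = {}
    for name, table in deg_tables.items():
        up = set(table.loc[table["direction"] == "up", "gene"])
        down = set(table.loc[table["direction"] == "down", "gene"])
        up_sets[name] = up
        down_sets[name] = down
        rows.append((name, len(up), len(down)))
    counts = pd.DataFrame(rows, columns=["comparison", "up", "down"])
    overlaps = {"up": venn_counts(up_sets), "down": venn_counts(down_sets)}
    return counts, overlaps
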