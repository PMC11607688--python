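"""Single-cell QC, marker gating, and label-transfer quality statistics.

Implements the per-dataset QC filters (unique feature count, mitochondrial
percentage, total RNA count, all strict inequalities), T/Sox2 expression
gating on log-normalized values, closest-cell label transfer in a shared
50-dimensional PC embedding, the three per-cluster transfer-QC statistics
(mean k-NN distance, labelling agreement, unique-mapping fraction), Pearson
correlation between cluster-averaged PC vectors, and the +-1
cluster-average differential-expression rule with top-10 reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "QC_PRESETS",
    "GATE_PRESETS",
    "ExpressionMatrix",
    "Embedding",
    "filter_cells",
    "lognormalize",
    "gate_by_expression",
    "transfer_labels",
    "transfer_qc",
    "cluster_correlation",
    "cluster_de",
]

# Per-dataset QC threshold presets; all comparisons are strict:
# UFC > ufc_min, MC < mc_max (and MC > mc_min where present), TRC < trc_max.
QC_PRESETS: Dict[str, Dict[str, float]] = {
    "0h": {"ufc_min": 2500, "mc_max": 10, "trc_max": 150_000},
    "24h_r1": {"ufc_min": 2750, "mc_max": 15, "mc_min": 1, "trc_max": 100_000},
    "24h_r2": {"ufc_min": 3750, "mc_max": 15, "mc_min": 1, "trc_max": 150_000},
    "48h_r1": {"ufc_min": 2750, "mc_max": 15, "mc_min": 1, "trc_max": 100_000},
    "48h_r2": {"ufc_min": 3500, "mc_max": 15, "mc_min": 1, "trc_max": 120_000},
    "72h": {"ufc_min": 2500, "mc_max": 20, "mc_min": 1, "trc_max": 135_000},
}

# Marker gates on log-normalized expression: value > pos -> positive,
# value <= neg -> negative, otherwise excluded.
GATE_PRESETS: Dict[str, Tuple[float, float]] = {
    "T": (1.5, 0.05),
    "Sox2": (1.0, 0.05),
}

UFC_COL = "unique_feature_count"
MC_COL = "mito_percent"
TRC_COL = "total_rna_count"


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with normalization metadata."""

    values: np.ndarray
    genes: List[str]
    cell_ids: Optional[List[str]] = None
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.genes):
            raise ValueError("values must be (n_cells, n_genes)")

    def gene(self, name: str) -> np.ndarray:
        if name not in self.genes:
            raise ValueError(f"gene {name!r} not in matrix")
        return self.values[:, self.genes.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.genes, index=self.cell_ids)


@dataclass
class Embedding:
    """Cells x D low-dimensional coordinates with per-cell labels."""

    coords: np.ndarray
    labels: np.ndarray
    source: str = "query"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2D (cells x D)")
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding coordinates must be finite")
        if len(self.labels) != len(self.coords):
            raise ValueError("labels must cover all rows")

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def _resolve_thresholds(thresholds: Union[str, Dict[str, float]]) -> Dict[str, float]:
    if isinstance(thresholds, str):
        if thresholds not in QC_PRESETS:
            raise ValueError(
                f"unknown preset {thresholds!r}; available: {sorted(QC_PRESETS)}")
        return QC_PRESETS[thresholds]
    return dict(thresholds)


def qc_pass(table: pd.DataFrame, thresholds: Union[str, Dict[str, float]]) -> pd.Series:
    """Boolean per-cell pass flag under a threshold set (strict inequalities)."""
    th = _resolve_thresholds(thresholds)
    ok = pd.Series(True, index=table.index)
    if "ufc_min" in th:
        ok &= table[UFC_COL] > th["ufc_min"]
    if "mc_max" in th:
        ok &= table[MC_COL] < th["mc_max"]
    if "mc_min" in th:
        ok &= table[MC_COL] > th["mc_min"]
    if "trc_max" in th:
        ok &= table[TRC_COL] < th["trc_max"]
    return ok


def filter_cells(
    table: pd.DataFrame, thresholds: Union[str, Dict[str, float]]
) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Remove low-quality cells; keep rows satisfying ALL conditions.

    ``thresholds`` is a preset name (e.g. ``"0h"``) or a dict with keys
    among {ufc_min, mc_max, mc_min, trc_max}.  Returns the filtered table
    and a report with kept/removed counts, per condition and overall.
    """
    th = _resolve_thresholds(thresholds)
    conds = {}
    if "ufc_min" in th:
        conds[f"{UFC_COL}>{th['ufc_min']:g}"] = table[UFC_COL] > th["ufc_min"]
    if "mc_max" in th:
        conds[f"{MC_COL}<{th['mc_max']:g}"] = table[MC_COL] < th["mc_max"]
    if "mc_min" in th:
        conds[f"{MC_COL}>{th['mc_min']:g}"] = table[MC_COL] > th["mc_min"]
    if "trc_max" in th:
        conds[f"{TRC_COL}<{th['trc_max']:g}"] = table[TRC_COL] < th["trc_max"]
    keep = pd.Series(True, index=table.index)
    for c in conds.values():
        keep &= c
    report = {
        "n_input": int(len(table)),
        "n_kept": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "removed_by_condition": {name: int((~c).sum()) for name, c in conds.items()},
        "thresholds": th,
    }
    return table[keep].copy(), report


# ---------------------------------------------------------------------------
# normalization and gating
# ---------------------------------------------------------------------------

def lognormalize(matrix: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Log-normalize counts: ln(1 + scale * count / cell_total) per cell.

    A cell with zero total counts becomes an all-zero row, with a warning.
    """
    counts = np.asarray(matrix.values, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells have zero total counts; "
                      "their normalized rows are all zero", stacklevel=2)
    safe = np.where(totals == 0, 1.0, totals)
    out = np.log1p(scale * counts / safe)
    out[zero] = 0.0
    return ExpressionMatrix(out, list(matrix.genes), matrix.cell_ids,
                            normalization=f"lognorm({scale:g})")


def gate_by_expression(
    matrix: ExpressionMatrix,
    gene: str,
    pos_cutoff: Optional[float] = None,
    neg_cutoff: Optional[float] = None,
) -> np.ndarray:
    """Trichotomize cells on one gene's normalized expression.

    value > pos_cutoff -> "positive"; value <= neg_cutoff -> "negative";
    in between -> "excluded".  Defaults follow the marker presets
    (T: 1.5/0.05, Sox2: 1.0/0.05).
    """
    if pos_cutoff is None or neg_cutoff is None:
        if gene not in GATE_PRESETS:
            raise ValueError(f"no gate preset for {gene!r}; give explicit cutoffs")
        pos_cutoff, neg_cutoff = GATE_PRESETS[gene]
    if not pos_cutoff > neg_cutoff:
        raise ValueError("pos_cutoff must exceed neg_cutoff")
    vals = matrix.gene(gene)
    labels = np.full(len(vals), "excluded", dtype=object)
    labels[vals > pos_cutoff] = "positive"
    labels[vals <= neg_cutoff] = "negative"
    return labels


# ---------------------------------------------------------------------------
# label transfer and its QC
# ---------------------------------------------------------------------------

def _check_dims(query: Embedding, reference: Embedding) -> None:
    if query.n_dims != reference.n_dims:
        raise ValueError(
            f"dimension mismatch: query D={query.n_dims}, "
            f"reference D={reference.n_dims}")


def transfer_labels(
    query: Embedding, reference: Embedding
) -> Tuple[np.ndarray, np.ndarray]:
    """Assign each query cell the label of its Euclidean-nearest reference
    cell; exact distance ties resolve to the lowest reference index.

    Returns (assigned_labels, assigned_reference_indices).
    """
    _check_dims(query, reference)
    if len(reference.coords) == 0:
        raise ValueError("reference embedding is empty")
    k = min(5, len(reference.coords))
    nn = NearestNeighbors(n_neighbors=k).fit(reference.coords)
    dist, idx = nn.kneighbors(query.coords)
    # resolve near-exact ties deterministically: lowest reference index wins
    tied = dist <= dist[:, :1] * (1 + 1e-12) + 1e-12 * (dist[:, :1] == 0)
    assigned = np.array([row[t].min() for row, t in zip(idx, tied)])
    return reference.labels[assigned], assigned


def transfer_qc(
    query: Embedding,
    reference: Embedding,
    assigned_labels: np.ndarray,
    assigned_indices: np.ndarray,
    k: int = 30,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster transfer-QC statistics.

    (1) mean_knn_distance: cluster mean over cells of the mean Euclidean
        distance to the cell's k closest reference cells;
    (2) agreement_score: cluster mean over cells of the fraction of those k
        reference cells whose label equals the cell's assigned label;
    (3) unique_fraction: number of unique reference cells the cluster's
        cells mapped to, divided by the cluster size (close to 1 for
        well-mixed integration).

    Returns (per-cluster DataFrame, per-cell DataFrame).
    """
    _check_dims(query, reference)
    if k > len(reference.coords):
        raise ValueError(f"k={k} exceeds reference size {len(reference.coords)}")
    nn = NearestNeighbors(n_neighbors=k).fit(reference.coords)
    dist, idx = nn.kneighbors(query.coords)
    knn_labels = reference.labels[idx]
    per_cell = pd.DataFrame({
        "cluster": query.labels,
        "mean_knn_distance": dist.mean(axis=1),
        "agreement": (knn_labels == np.asarray(assigned_labels)[:, None]).mean(axis=1),
        "assigned_index": np.asarray(assigned_indices),
    })
    rows = []
    for cluster, grp in per_cell.groupby("cluster", sort=True):
        rows.append({
            "cluster": cluster,
            "mean_knn_distance": float(grp["mean_knn_distance"].mean()),
            "agreement_score": float(grp["agreement"].mean()),
            "unique_fraction": grp["assigned_index"].nunique() / len(grp),
            "n_cells": int(len(grp)),
        })
    return pd.DataFrame(rows).set_index("cluster"), per_cell


# ---------------------------------------------------------------------------
# cluster correlation and differential expression
# ---------------------------------------------------------------------------

def _cluster_means(emb: Embedding) -> pd.DataFrame:
    df = pd.DataFrame(emb.coords)
    df["__cluster"] = emb.labels
    return df.groupby("__cluster", sort=True).mean()


def cluster_correlation(
    emb_a: Embedding, emb_b: Embedding
) -> Tuple[pd.DataFrame, List[str]]:
    """Pearson correlation between cluster-averaged embedding-component
    vectors for every cluster pair.

    Returns the clusters_a x clusters_b correlation matrix and a list of
    clusters whose averaged vector has zero variance across components
    (their correlations are undefined and set to NaN).
    """
    _check_dims(emb_a, emb_b)
    ma = _cluster_means(emb_a)
    mb = _cluster_means(emb_b)
    flagged = []
    for name, m in (("a", ma), ("b", mb)):
        for cl in m.index:
            if np.std(m.loc[cl].to_numpy()) == 0:
                flagged.append(f"{name}:{cl}")
    out = pd.DataFrame(index=ma.index, columns=mb.index, dtype=float)
    for ca in ma.index:
        va = ma.loc[ca].to_numpy()
        for cb in mb.index:
            vb = mb.loc[cb].to_numpy()
            if va.std() == 0 or vb.std() == 0:
                out.loc[ca, cb] = np.nan
            else:
                out.loc[ca, cb] = float(np.corrcoef(va, vb)[0, 1])
    out.index.name = "cluster_a"
    out.columns.name = "cluster_b"
    return out, flagged


def cluster_de(
    matrix: ExpressionMatrix,
    clusters: Sequence,
    pair: Tuple[object, object],
    cutoff: float = 1.0,
    top_n: int = 10,
) -> pd.DataFrame:
    """Cluster-average differential expression between a pair of clusters.

    Per gene the difference of cluster-mean normalized expression is
    computed; genes with |difference| >= ``cutoff`` are kept, ranked by
    |difference|, and truncated to the ``top_n`` largest per direction.
    """
    clusters = np.asarray(clusters)
    ca, cb = pair
    for c in pair:
        if not (clusters == c).any():
            raise ValueError(f"unknown cluster id {c!r}")
    mean_a = matrix.values[clusters == ca].mean(axis=0)
    mean_b = matrix.values[clusters == cb].mean(axis=0)
    diff = mean_a - mean_b
    df = pd.DataFrame({
        "gene": matrix.genes,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "difference": diff,
    })
    df = df[np.abs(df["difference"]) >= cutoff]
    df = df.reindex(df["difference"].abs().sort_values(ascending=False).index)
    up = df[df["difference"] > 0].head(top_n)
    down = df[df["difference"] < 0].head(top_n)
    out = pd.concat([up, down]).reset_index(drop=True)
    out["direction"] = np.where(out["difference"] > 0, f"up_in_{ca}", f"up_in_{cb}")
    return out
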