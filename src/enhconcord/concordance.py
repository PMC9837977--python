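"""Found-vector correlation analysis.

Each query enhancer is scored 1 ("found") or 0 ("not found") against every
reference set, giving one binary vector per reference. Pairwise Pearson
correlation of these vectors — on 0/1 data, the phi coefficient — reveals
whether different references recover the *same* query enhancers. Grouping
references by experiment series (batch) and comparing within-batch to
between-batch mean correlation quantifies batch effects: high within / low
between means experiment series, not assay type, drives which enhancers
are detected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .overlap import ReferenceIndex, found_mask

__all__ = [
    "FoundVector",
    "ConcordanceMatrix",
    "found_vector",
    "correlation_matrix",
    "group_summary",
    "export_matrix",
    "read_matrix",
]


@dataclass
class FoundVector:
    """0/1 detection indicators for one reference set over a fixed query set."""

    reference_label: str
    batch_label: str
    values: np.ndarray
    query_names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            raise ValueError("found-vector values must be 0 or 1")

    @property
    def n_found(self) -> int:
        return int(self.values.sum())


@dataclass
class ConcordanceMatrix:
    """Symmetric matrix of pairwise phi correlations between found-vectors.

    Entries involving a constant vector are NaN (undefined), never coerced
    to 0; summaries exclude them.
    """

    labels: List[str]
    batches: List[str]
    r: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.labels, columns=self.labels)


def found_vector(
    query: IntervalSet,
    reference: IntervalSet | ReferenceIndex,
    batch_label: str = "",
) -> FoundVector:
    """Score each query interval 1 iff it overlaps >= 1 reference interval.

    Entry order follows the query set's deterministic ordering, so vectors
    built against the same query are directly comparable. The vector sum
    equals the ``-wa -u`` overlap count.
    """
    if len(query) == 0:
        raise ValueError("empty query set")
    mask = found_mask(query, reference)
    label = reference.label
    return FoundVector(
        reference_label=label,
        batch_label=batch_label,
        values=mask.astype(np.int8),
        query_names=query.names,
    )


def correlation_matrix(vectors: Sequence[FoundVector]) -> ConcordanceMatrix:
    """Pairwise Pearson (phi) correlations between found-vectors.

    Requires >= 2 vectors of equal length. Pairs involving a constant
    vector are marked NaN; the diagonal is exactly 1 for non-constant
    vectors.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors")
    lengths = {len(v.values) for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"found-vector length mismatch: {sorted(lengths)}")
    x = np.array([v.values for v in vectors], dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    n = len(vectors)
    r = np.full((n, n), np.nan)
    ok = norms > 0
    if ok.any():
        sub = centered[ok]
        block = (sub @ sub.T) / np.outer(norms[ok], norms[ok])
        r[np.ix_(ok, ok)] = np.clip(block, -1.0, 1.0)
        r[np.diag_indices(n)] = np.where(ok, 1.0, np.nan)
    return ConcordanceMatrix(
        labels=[v.reference_label for v in vectors],
        batches=[v.batch_label for v in vectors],
        r=r,
    )


def group_summary(
    matrix: ConcordanceMatrix,
    group_a: str,
    group_b: Optional[str] = None,
) -> Tuple[float, float, int]:
    """Mean, sample sd, and pair count of r within or between batches.

    Within-group (``group_b`` omitted or equal): off-diagonal pairs only.
    Between-group: every (a, b) cross pair. NaN (undefined) entries are
    excluded; zero eligible pairs is an error.
    """
    if group_b is None:
        group_b = group_a
    idx_a = [i for i, b in enumerate(matrix.batches) if b == group_a]
    idx_b = [i for i, b in enumerate(matrix.batches) if b == group_b]
    if not idx_a or not idx_b:
        raise ValueError(f"unknown batch label {group_a!r} or {group_b!r}")
    vals: List[float] = []
    if group_a == group_b:
        for ii, i in enumerate(idx_a):
            for j in idx_a[ii + 1:]:
                vals.append(matrix.r[i, j])
    else:
        for i in idx_a:
            for j in idx_b:
                vals.append(matrix.r[i, j])
    arr = np.array([v for v in vals if not math.isnan(v)])
    if arr.size == 0:
        raise ValueError(
            f"no eligible pairs for batches {group_a!r} / {group_b!r}"
        )
    sd = 0.0 if arr.size == 1 else float(arr.std(ddof=1))
    return float(arr.mean()), sd, int(arr.size)


def export_matrix(
    matrix: ConcordanceMatrix,
    path,
    batch_path=None,
    heatmap_path=None,
) -> None:
    """Write the correlation matrix as a square TSV (NaN rendered "NA").

    A sidecar TSV maps each label to its batch; an optional heatmap PNG
    orders rows/columns by batch then label (cosmetic output).
    """
    frame = matrix.to_frame()
    frame.to_csv(path, sep="\t", na_rep="NA", float_format="%.6f",
                 index_label="label")
    if batch_path is not None:
        with open(batch_path, "wt", encoding="utf-8") as fh:
            fh.write("label\tbatch\n")
            for label, batch in zip(matrix.labels, matrix.batches):
                fh.write(f"{label}\t{batch}\n")
    if heatmap_path is not None:
        _render_heatmap(matrix, heatmap_path)


def _render_heatmap(matrix: ConcordanceMatrix, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = sorted(range(len(matrix.labels)),
                   key=lambda i: (matrix.batches[i], matrix.labels[i]))
    r = matrix.r[np.ix_(order, order)]
    labels = [matrix.labels[i] for i in order]
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(labels)),) * 2)
    im = ax.imshow(r, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labels)), labels, fontsize=6)
    fig.colorbar(im, ax=ax, label="phi")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def read_matrix(path, batch_path=None) -> ConcordanceMatrix:
    """Re-load an exported matrix TSV (and optional batch sidecar)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    labels = list(frame.index.astype(str))
    batches = [""] * len(labels)
    if batch_path is not None:
        side = pd.read_csv(batch_path, sep="\t", dtype=str)
        lookup: Dict[str, str] = dict(zip(side["label"], side["batch"]))
        batches = [lookup.get(lab, "") for lab in labels]
    return ConcordanceMatrix(labels=labels, batches=batches,
                             r=frame.to_numpy(dtype=float))
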