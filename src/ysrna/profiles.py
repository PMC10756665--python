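"""Multi-sample YsRNA profile matrices and summary comparisons."""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .inference import INSUFFICIENT_DATA
from .quantify import CountTable
from .reference import Side

__all__ = [
    "build_matrix",
    "homolog_ratio",
    "compare_profiles",
    "matrix_to_long",
    "plot_matrix",
]


def build_matrix(
    tables: Iterable[CountTable],
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Sample x (homolog, half) matrix of aggregate RPM.

    Rows are samples (index = sample_id, with an optional ``tissue`` label
    column taken from ``labels``); columns are a (parent_id, side)
    MultiIndex; classes without hits are 0.  All tables must have been built
    against the same reference.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no count tables given")
    parent_ids = tables[0].parent_ids
    if any(t.parent_ids != parent_ids for t in tables):
        raise ValueError("count tables were built against different references")
    cols = pd.MultiIndex.from_product(
        [parent_ids, [Side.FIVE_PRIME.value, Side.THREE_PRIME.value]],
        names=["parent_id", "side"],
    )
    rows = {}
    for t in tables:
        agg = t.aggregate().set_index(["parent_id", "side"])["rpm"]
        rows[t.sample_id] = agg.reindex(cols, fill_value=0.0)
    mat = pd.DataFrame.from_dict(rows, orient="index")
    mat.columns = cols
    mat.index.name = "sample"
    if labels:
        mat.attrs["tissue"] = {s: labels.get(s, "") for s in mat.index}
    return mat


def homolog_ratio(
    row: pd.Series,
    numerator_parent: str,
    denominator_parent: str,
    side: Side | str = Side.FIVE_PRIME,
):
    """RPM ratio of two homologs on one half (e.g. the Ys1:Ys3 ratio that
    separates sperm heads from seminal exosomes).  Returns the
    INSUFFICIENT_DATA sentinel when the denominator class has zero RPM."""
    side_val = side.value if isinstance(side, Side) else str(side)
    num = float(row[(numerator_parent, side_val)])
    den = float(row[(denominator_parent, side_val)])
    if den == 0.0:
        return INSUFFICIENT_DATA
    return num / den


def compare_profiles(row_a: Sequence[float], row_b: Sequence[float]) -> dict:
    """Cosine similarity and Spearman rank correlation of two profile rows."""
    a = np.asarray(row_a, dtype=float)
    b = np.asarray(row_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cannot compare an all-zero profile")
    cosine = float(np.dot(a, b) / (na * nb))
    rho = stats.spearmanr(a, b).statistic
    return {"cosine": cosine, "spearman": float(rho)}


def matrix_to_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """Tidy long-format export (sample, tissue, parent_id, side, rpm) for
    downstream statistics packages."""
    tissue = matrix.attrs.get("tissue", {})
    long = (
        matrix.stack(["parent_id", "side"], future_stack=True)
        .rename("rpm")
        .reset_index()
    )
    long.insert(1, "tissue", long["sample"].map(lambda s: tissue.get(s, "")))
    return long


def plot_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Grouped bar chart of aggregate RPM per (homolog, half) and sample."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    n_samples = len(matrix)
    width = 0.8 / max(n_samples, 1)
    x = np.arange(matrix.shape[1])
    for k, (sample, row) in enumerate(matrix.iterrows()):
        ax.bar(x + k * width, row.values, width=width, label=str(sample))
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels([f"{p} {s}" for p, s in matrix.columns], rotation=45,
                       ha="right")
    ax.set_ylabel("RPM (alignable reads)")
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
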