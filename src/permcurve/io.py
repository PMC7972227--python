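"""Reading and writing feature tables, metadata and results.

Feature tables are plain TSV/CSV with a header row and an ID column; the
canonical in-memory orientation is samples-as-rows (a pandas DataFrame with
sample IDs as the index and feature IDs as columns).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import GroupLabels

__all__ = [
    "load_feature_table",
    "write_feature_table",
    "load_metadata",
    "write_results",
]


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def load_feature_table(path, orientation: str = "samples_as_rows") -> pd.DataFrame:
    """Load and validate an abundance table.

    ``orientation`` says how the file is laid out; the returned DataFrame
    is always samples x features.  Negative values, missing cells and
    duplicate IDs are rejected with the offending coordinates.
    """
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path)
    if orientation == "features_as_rows":
        df = df.T
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample IDs: {dupes}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature IDs: {dupes}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as err:
        raise ValueError(f"non-numeric entry in {path}: {err}") from None
    bad = np.argwhere(np.isnan(values))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"missing value at sample {df.index[i]!r}, feature {df.columns[j]!r}"
        )
    bad = np.argwhere(values < 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"negative abundance {values[i, j]} at sample {df.index[i]!r}, "
            f"feature {df.columns[j]!r}"
        )
    return df.astype(float)


def write_feature_table(table: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.to_csv(path, sep=sep)


def load_metadata(
    path,
    sample_ids,
    group_column: str | None = None,
    outcome_column: str | None = None,
    level_order: tuple | None = None,
):
    """Load sample metadata aligned to a feature table's sample order.

    Exactly one of ``group_column`` (binary factor, mapped to {1, 2} by
    sorted level order unless ``level_order`` overrides it) or
    ``outcome_column`` (numeric) must be given.
    """
    if (group_column is None) == (outcome_column is None):
        raise ValueError("give exactly one of group_column or outcome_column")
    meta = _read_delimited(path)
    sample_ids = list(sample_ids)
    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    meta = meta.loc[sample_ids]
    if group_column is not None:
        if group_column not in meta.columns:
            raise ValueError(f"metadata has no column {group_column!r}")
        col = meta[group_column]
        levels = sorted(col.unique()) if level_order is None else list(level_order)
        if len(levels) != 2 or set(col.unique()) != set(levels):
            raise ValueError(
                f"group column {group_column!r} must have exactly 2 levels, "
                f"got {sorted(col.unique())}"
            )
        labels = np.where(col.to_numpy() == levels[0], 1, 2)
        return GroupLabels(tuple(sample_ids), labels)
    if outcome_column not in meta.columns:
        raise ValueError(f"metadata has no column {outcome_column!r}")
    col = pd.to_numeric(meta[outcome_column], errors="coerce")
    if col.isna().any():
        bad = meta.index[col.isna()].tolist()
        raise ValueError(f"non-numeric outcome for samples: {bad}")
    return pd.Series(col.to_numpy(dtype=float), index=sample_ids, name=outcome_column)


def write_results(fitted, outdir) -> dict:
    """Serialize a fitted ProgressivePermutation to ``outdir``.

    Writes traces.tsv (long format), curve.tsv, fragility.tsv,
    selection.tsv and summary.json; returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traces = fitted.traces_
    long = []
    for i, k in enumerate(traces.ks):
        for j, feat in enumerate(traces.feature_ids):
            long.append(
                (feat, int(k), traces.p_median[i, j], traces.p_q025[i, j],
                 traces.p_q975[i, j])
            )
    pd.DataFrame(
        long, columns=["feature", "k", "p_median", "p_q025", "p_q975"]
    ).to_csv(outdir / "traces.tsv", sep="\t", index=False, float_format="%.6g")

    curve = fitted.curve_
    pd.DataFrame(
        {
            "k": curve.ks,
            "mixing": curve.mixing,
            "nsig": curve.nsig,
            "nsig_prop": curve.nsig / curve.n_features,
            "nsig_q025": curve.nsig_q025,
            "nsig_q975": curve.nsig_q975,
        }
    ).to_csv(outdir / "curve.tsv", sep="\t", index=False, float_format="%.6g")

    fitted.fragility_.to_frame().to_csv(
        outdir / "fragility.tsv", sep="\t", index=False, float_format="%.6g"
    )
    fitted.selection_.to_frame().to_csv(
        outdir / "selection.tsv", sep="\t", index=False, float_format="%.6g"
    )
    summary = fitted.summary()
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
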