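"""Long-format CSV input/output and result serialization.

The on-disk format is tidy long format: one row per (subject, time) with
columns ``id, time, y, e1..eq, x1..xp``. Column names are configurable
through a mapping. Loading validates balance (equal k per subject),
binary dummies, and numeric completeness, with row-level diagnostics.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import LongitudinalDataset, GroupMap
from .solver import FitResult
from .tuning import CVResult

__all__ = ["read_long_csv", "write_long_csv", "write_results", "coefficient_table"]


def _resolve_columns(df: pd.DataFrame, column_map: dict | None):
    cmap = {"id": "id", "time": "time", "y": "y", "e_prefix": "e", "x_prefix": "x"}
    if column_map:
        cmap.update(column_map)
    e_cols = sorted(
        (c for c in df.columns if c.startswith(cmap["e_prefix"]) and c[len(cmap["e_prefix"]):].isdigit()),
        key=lambda c: int(c[len(cmap["e_prefix"]):]),
    )
    x_cols = sorted(
        (c for c in df.columns if c.startswith(cmap["x_prefix"]) and c[len(cmap["x_prefix"]):].isdigit()),
        key=lambda c: int(c[len(cmap["x_prefix"]):]),
    )
    for key in ("id", "time", "y"):
        if cmap[key] not in df.columns:
            raise ValueError(f"missing required column {cmap[key]!r}")
    if not e_cols:
        raise ValueError(f"no environment dummy columns matching prefix {cmap['e_prefix']!r}")
    return cmap, e_cols, x_cols


def read_long_csv(path, column_map: dict | None = None) -> LongitudinalDataset:
    """Load a balanced long-format table into a LongitudinalDataset.

    Subjects keep their order of first appearance; rows within a subject
    are sorted by time. Missing cells, duplicate (id, time) pairs,
    non-binary dummies, and unbalanced subjects are rejected with the
    offending rows named.
    """
    df = pd.read_csv(path)
    cmap, e_cols, x_cols = _resolve_columns(df, column_map)
    value_cols = [cmap["y"]] + e_cols + x_cols
    na_rows = df.index[df[value_cols].isna().any(axis=1)]
    if len(na_rows):
        raise ValueError(f"missing values in rows (0-based) {list(na_rows[:10])}")
    dup = df.duplicated(subset=[cmap["id"], cmap["time"]])
    if dup.any():
        raise ValueError(
            f"duplicated (id, time) pairs in rows (0-based) {list(df.index[dup][:10])}"
        )
    ids = df[cmap["id"]].to_numpy()
    order = pd.unique(ids)
    counts = df.groupby(cmap["id"], sort=False).size()
    if counts.nunique() != 1:
        bad = counts[counts != counts.iloc[0]]
        raise ValueError(f"unbalanced subjects (unequal time counts): {dict(bad.head(10))}")
    k = int(counts.iloc[0])
    df = df.sort_values(by=[cmap["time"]], kind="stable")
    df["_subj_order"] = pd.Categorical(df[cmap["id"]], categories=order, ordered=True)
    df = df.sort_values(by=["_subj_order"], kind="stable")
    n = len(order)
    y = df[cmap["y"]].to_numpy(float).reshape(n, k)
    E = df[e_cols].to_numpy(float).reshape(n, k, len(e_cols))
    X = (df[x_cols].to_numpy(float).reshape(n, k, len(x_cols))
         if x_cols else np.zeros((n, k, 0)))
    return LongitudinalDataset(y=y, X=X, E=E, subject_ids=order)


def write_long_csv(data: LongitudinalDataset, path) -> None:
    """Write a dataset in the long format accepted by :func:`read_long_csv`."""
    n, k, p, q = data.n, data.k, data.p, data.q
    rows = {
        "id": np.repeat(data.subject_ids, k),
        "time": np.tile(np.arange(1, k + 1), n),
        "y": data.y.reshape(-1),
    }
    for j in range(q):
        rows[f"e{j + 1}"] = data.E[:, :, j].reshape(-1)
    for j in range(p):
        rows[f"x{j + 1}"] = data.X[:, :, j].reshape(-1)
    pd.DataFrame(rows).to_csv(path, index=False)


def column_names(groups: GroupMap) -> list[str]:
    names = ["intercept"] + [f"e{j + 1}" for j in range(groups.q)]
    names += [f"x{h + 1}" for h in range(groups.p)]
    names += [f"x{h + 1}:e{l + 1}" for h in range(groups.p) for l in range(groups.q)]
    return names


def coefficient_table(fit: FitResult, groups: GroupMap) -> pd.DataFrame:
    """Tidy coefficient table: column name, block, estimate, selected flag."""
    blocks = (["intercept"] + ["environment"] * groups.q
              + ["main"] * groups.p + ["interaction"] * groups.p * groups.q)
    return pd.DataFrame({
        "column": column_names(groups),
        "block": blocks,
        "estimate": fit.beta,
        "selected": fit.selected_mask,
    })


def write_results(
    outdir,
    groups: GroupMap | None = None,
    fit: FitResult | None = None,
    cv: CVResult | None = None,
    metrics: pd.DataFrame | None = None,
    manifest: dict | None = None,
) -> None:
    """Write whichever artifacts are present under ``outdir``:
    coefficients.csv, cv_surface.csv, metrics.csv, and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fit is not None:
        if groups is None:
            raise ValueError("writing a fit requires its GroupMap")
        coefficient_table(fit, groups).to_csv(outdir / "coefficients.csv", index=False)
    if cv is not None:
        surf = pd.DataFrame(
            cv.errors,
            index=pd.Index(cv.grid.lambda1_values, name="lambda1"),
            columns=pd.Index(cv.grid.lambda2_values, name="lambda2"),
        )
        surf.to_csv(outdir / "cv_surface.csv")
    if metrics is not None:
        metrics.to_csv(outdir / "metrics.csv", index=False)
    if manifest is not None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
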