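"""Two-colour array preprocessing.

Turns spot-level two-channel intensity tables into a normalized, imputed,
standardized expression matrix, in the fixed order

    MA transform -> print-tip loess -> scale normalization
                 -> kNN imputation -> per-array standardization.

* MA transform: M = log2 of the background-subtracted red/green ratio,
  A = mean log2 intensity; spots with a non-positive corrected intensity in
  either channel (or a bad flag) are masked.
* Print-tip loess: within each print-tip block a robust locally linear fit
  of M on A is subtracted, removing intensity-dependent dye bias separately
  per pin (statsmodels lowess, 3 robustness iterations).  Blocks with too
  few usable spots fall back to the whole-array fit.
* Scale normalization: every array's median absolute deviation of M is
  matched to the geometric mean of the per-array MADs.
* kNN imputation: a missing entry is replaced by the mean of the k nearest
  feature rows (plain Euclidean distance over jointly observed samples),
  skipping neighbours that are themselves missing in the target sample.
* Standardization: each array (column) to mean 0, sd 1 (sample sd).

The in-memory ExpressionMatrix is a pandas DataFrame, features x samples,
with NaN marking missing entries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

_log = logging.getLogger(__name__)

__all__ = [
    "compute_ma",
    "printtip_loess",
    "spots_to_matrix",
    "scale_normalize",
    "knn_impute",
    "standardize_arrays",
    "preprocess_spot_tables",
]

SPOT_COLUMNS = ["Block", "Row", "Column", "ID", "F635", "B635", "F532", "B532", "Flags"]


def compute_ma(spot: pd.DataFrame) -> pd.DataFrame:
    """MA transform of one sample's spot table.

    Returns a per-spot frame with feature_id, block, M and A; masked spots
    (bad flag or non-positive background-subtracted intensity) carry NaN.
    Raises if no spot is usable.
    """
    missing_cols = [c for c in SPOT_COLUMNS if c not in spot.columns]
    if missing_cols:
        raise ValueError(f"spot table lacks columns {missing_cols}")
    red = spot["F635"].to_numpy(dtype=float) - spot["B635"].to_numpy(dtype=float)
    green = spot["F532"].to_numpy(dtype=float) - spot["B532"].to_numpy(dtype=float)
    ok = (spot["Flags"].to_numpy() >= 0) & (red > 0) & (green > 0)
    if not ok.any():
        raise ValueError("no usable spots")
    m = np.full(len(spot), np.nan)
    a = np.full(len(spot), np.nan)
    m[ok] = np.log2(red[ok] / green[ok])
    a[ok] = 0.5 * np.log2(red[ok] * green[ok])
    out = pd.DataFrame({
        "feature_id": spot["ID"].astype(str).to_numpy(),
        "block": spot["Block"].to_numpy(),
        "M": m,
        "A": a,
    })
    out.attrs["sample_id"] = spot.attrs.get("sample_id")
    return out


def printtip_loess(ma: pd.DataFrame, span: float = 0.4,
                   min_spots_per_block: int = 8, iterations: int = 3
                   ) -> pd.DataFrame:
    """Subtract a per-print-tip-block loess fit of M on A.

    A is unchanged and masked spots are untouched.  Blocks with fewer than
    `min_spots_per_block` usable spots are normalized against the
    whole-array fit instead (with a warning in the log).
    """
    out = ma.copy()
    m = out["M"].to_numpy(dtype=float).copy()
    a = out["A"].to_numpy(dtype=float)
    usable = np.isfinite(m) & np.isfinite(a)
    if usable.sum() < 2:
        raise ValueError("too few usable spots for loess normalization")
    global_fit = None

    def _fit(mask: np.ndarray) -> np.ndarray:
        return lowess(m[mask], a[mask], frac=span, it=iterations,
                      return_sorted=False)

    blocks = out["block"].to_numpy()
    for b in np.unique(blocks):
        in_block = (blocks == b) & usable
        n_b = int(in_block.sum())
        if n_b == 0:
            continue
        if n_b < min_spots_per_block:
            _log.warning("block %s has %d usable spots (< %d); "
                         "falling back to whole-array loess", b, n_b,
                         min_spots_per_block)
            if global_fit is None:
                global_fit = np.full(m.size, np.nan)
                global_fit[usable] = _fit(usable)
            m[in_block] = m[in_block] - global_fit[in_block]
        else:
            m[in_block] = m[in_block] - _fit(in_block)
    out["M"] = m
    return out


def spots_to_matrix(ma_tables: list[pd.DataFrame],
                    sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Assemble per-sample MA frames into a features x samples matrix of M."""
    if sample_ids is None:
        sample_ids = [t.attrs.get("sample_id") or f"S{i + 1:03d}"
                      for i, t in enumerate(ma_tables)]
    cols = {}
    for sid, t in zip(sample_ids, ma_tables):
        s = pd.Series(t["M"].to_numpy(), index=t["feature_id"].to_numpy())
        if s.index.has_duplicates:
            s = s.groupby(level=0).mean()
        cols[sid] = s
    return pd.DataFrame(cols)


def _mad(col: np.ndarray) -> float:
    col = col[np.isfinite(col)]
    return float(np.median(np.abs(col - np.median(col))))


def scale_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Match each array's MAD of M to the geometric mean of all arrays' MADs."""
    if mat.shape[1] < 2:
        raise ValueError("scale normalization requires at least 2 samples")
    values = mat.to_numpy(dtype=float)
    mads = np.array([_mad(values[:, j]) for j in range(values.shape[1])])
    zero = np.flatnonzero(mads == 0)
    if zero.size:
        raise ValueError("zero MAD in sample(s): %s"
                         % [str(mat.columns[j]) for j in zero])
    gmean = float(np.exp(np.mean(np.log(mads))))
    return mat * (gmean / mads)


def knn_impute(mat: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing entries from the k nearest feature rows.

    Nearness is plain Euclidean distance over the samples both rows observe;
    neighbours missing the target sample are skipped in favour of the next
    nearest.  A missing entry with no usable neighbour falls back to the
    feature-row mean (logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = mat.to_numpy(dtype=float)
    p, n = values.shape
    obs = np.isfinite(values)
    if np.any(obs.sum(axis=1) == 0):
        raise ValueError("feature row(s) with no observed values; filter first")
    miss_rows = np.flatnonzero(~obs.all(axis=1))
    if miss_rows.size == 0:
        return mat.copy()
    z = np.where(obs, values, 0.0)
    j = obs.astype(float)
    sq = z * z
    # squared distance over jointly observed columns, all row pairs at once
    d2 = sq @ j.T + j @ sq.T - 2.0 * (z @ z.T)
    np.maximum(d2, 0.0, out=d2)
    joint = j @ j.T
    d2[joint == 0] = np.inf
    np.fill_diagonal(d2, np.inf)
    row_mean = np.nanmean(np.where(obs, values, np.nan), axis=1)

    out = values.copy()
    n_fallback = 0
    for f in miss_rows:
        neighbours = np.argsort(d2[f], kind="stable")
        for s in np.flatnonzero(~obs[f]):
            donors = neighbours[obs[neighbours, s] & np.isfinite(d2[f, neighbours])]
            if donors.size == 0:
                out[f, s] = row_mean[f]
                n_fallback += 1
            else:
                out[f, s] = values[donors[:k], s].mean()
    if n_fallback:
        _log.warning("knn_impute: %d entr(ies) fell back to the row mean",
                     n_fallback)
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)


def standardize_arrays(mat: pd.DataFrame) -> pd.DataFrame:
    """Transform every array (column) to mean 0 and sample sd 1."""
    values = mat.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("standardize_arrays requires a complete matrix; "
                         "impute first")
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError("zero variance in sample(s): %s"
                         % [str(mat.columns[j]) for j in zero])
    return (mat - mu) / sd


def preprocess_spot_tables(spot_tables: list[pd.DataFrame],
                           span: float = 0.4, k: int = 10,
                           min_spots_per_block: int = 8,
                           max_row_missing: float = 0.5,
                           sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Full preprocessing chain from spot tables to an analysis-ready matrix.

    Feature rows missing in more than `max_row_missing` of the samples are
    dropped before imputation (kNN is unreliable for them).
    """
    ma_tables = [printtip_loess(compute_ma(t), span=span,
                                min_spots_per_block=min_spots_per_block)
                 for t in spot_tables]
    mat = spots_to_matrix(ma_tables, sample_ids=sample_ids)
    frac_missing = mat.isna().mean(axis=1)
    keep = frac_missing <= max_row_missing
    dropped = int((~keep).sum())
    if dropped:
        _log.warning("dropping %d feature row(s) with > %.0f%% missing",
                     dropped, 100 * max_row_missing)
    mat = mat.loc[keep]
    mat = scale_normalize(mat)
    mat = knn_impute(mat, k=k)
    return standardize_arrays(mat)
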