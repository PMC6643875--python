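"""Colony sizes -> per-strain log growth ratios (LGRs).

Stages: plate normalization (plate median or GFP-free reference strains),
ratio computation against one or two control conditions, spatial smoothing
on the plate grid, duplicate aggregation by averaging, and Z-transformation.

LGR convention: ln(control / experimental), so growth defects are positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from screenmix.screen_io import ValidationError

CONTROL_CONDITIONS = ("control_a", "control_b")

#: per-strain status flags propagated to the hit table
FLAG_DEAD = "dead"
FLAG_SICK = "sick"
FLAG_CONTROL_FAILURE = "control_failure"
FLAG_UNSMOOTHED = "unsmoothed"


@dataclass(frozen=True)
class NormalizationConfig:
    """Knobs for plate normalization and spatial smoothing (natural log throughout)."""

    plate_norm: str = "plate_median"  # or "reference_strains"
    smoothing_window: int = 7
    smoothing_min_neighbors: int = 8
    replicate_summary: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        if self.plate_norm not in ("plate_median", "reference_strains"):
            raise ValueError(f"unknown plate_norm {self.plate_norm!r}")
        w = self.smoothing_window
        if w < 3 or w % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 3")
        if not (1 <= self.smoothing_min_neighbors <= w * w - 1):
            raise ValueError("smoothing_min_neighbors must be in [1, window^2 - 1]")
        if self.replicate_summary not in ("mean", "median"):
            raise ValueError(f"unknown replicate_summary {self.replicate_summary!r}")


def plate_normalize(colonies: pd.DataFrame,
                    config: NormalizationConfig | None = None) -> pd.DataFrame:
    """Rescale colony sizes so each physical plate has a reference median of 1.

    A physical plate is one (plate_id, condition, replicate) layer.  In
    ``plate_median`` mode each layer is divided by the median of its nonzero
    sizes.  In ``reference_strains`` mode the scale for every layer of a
    (plate_id, replicate) pair is the median size of that pair's ``gfp_free``
    observations (GFP-free controls grown in the same batch), so the GFP-free
    median becomes 1.  Idempotent in both modes.
    """
    config = config or NormalizationConfig()
    df = colonies.copy()

    if config.plate_norm == "plate_median":
        def scale_of(group: pd.DataFrame) -> float:
            nz = group.loc[group["size"] > 0, "size"]
            if nz.empty:
                key = group.name
                raise ValidationError(f"plate {key}: all colonies are zero")
            return float(nz.median())

        scales = df.groupby(["plate_id", "condition", "replicate"], sort=False,
                            group_keys=False).apply(scale_of, include_groups=False)
        idx = pd.MultiIndex.from_frame(df[["plate_id", "condition", "replicate"]])
        df["size"] = df["size"].to_numpy() / scales.reindex(idx).to_numpy()
    else:
        gfp = df[df["condition"] == "gfp_free"]
        if gfp.empty:
            raise ValidationError("reference_strains normalization requires gfp_free records")
        counts = gfp.groupby(["plate_id", "replicate"]).size()
        short = counts[counts < 3]
        if len(short):
            raise ValidationError(
                f"plate {short.index[0]}: fewer than 3 gfp_free observations"
            )
        scales = gfp.groupby(["plate_id", "replicate"])["size"].median()
        idx = pd.MultiIndex.from_frame(df[["plate_id", "replicate"]])
        missing = ~idx.isin(scales.index)
        if missing.any():
            bad = df.loc[missing, "plate_id"].iloc[0]
            raise ValidationError(f"plate {bad}: no gfp_free records for normalization")
        df["size"] = df["size"].to_numpy() / scales.reindex(idx).to_numpy()
    return df


def _summarize_replicates(sizes: np.ndarray, how: str) -> tuple[float, str]:
    """Mean (or median) of nonzero normalized sizes, with dead/sick flagging."""
    sizes = np.asarray(sizes, dtype=float)
    nonzero = sizes[sizes > 0]
    if nonzero.size == 0:
        return math.nan, FLAG_DEAD
    flag = FLAG_SICK if nonzero.size <= sizes.size / 2 else ""
    value = float(np.median(nonzero)) if how == "median" else float(nonzero.mean())
    return value, flag


def compute_lgr(experimental: float, controls: dict[str, float]) -> float:
    """LGR for one strain: mean over control conditions c of ln(size_c / size_exp)."""
    if not controls:
        raise ValidationError("at least one control condition required")
    if not experimental > 0:
        raise ValidationError("experimental size must be positive")
    per_control = [math.log(size / experimental) for size in controls.values()]
    return float(np.mean(per_control))


def position_lgrs(colonies: pd.DataFrame,
                  config: NormalizationConfig | None = None) -> pd.DataFrame:
    """Per-position LGR table from plate-normalized colonies.

    Returns one row per (plate_id, row, col) of the experimental layout with
    columns strain_id, lgr and flags.  Replicates are summarized within each
    condition by the mean of nonzero sizes; strains with all experimental
    replicates dead get flag 'dead' (LGR NaN, never +inf), strains with all
    control replicates dead get 'control_failure', and strains with at least
    half of their experimental replicates dead are flagged 'sick' but scored.
    """
    config = config or NormalizationConfig()
    exp = colonies[colonies["condition"] == "experimental"]
    if exp.empty:
        raise ValidationError("no experimental observations")
    present_controls = [c for c in CONTROL_CONDITIONS
                        if (colonies["condition"] == c).any()]
    if not present_controls:
        raise ValidationError("no control observations")

    key = ["plate_id", "row", "col"]
    by_cond: dict[str, pd.DataFrame] = {}
    for cond in ("experimental", *present_controls):
        sub = colonies[colonies["condition"] == cond]
        agg = sub.groupby(key).agg(
            strain_id=("strain_id", "first"),
            sizes=("size", lambda s: _summarize_replicates(s.to_numpy(),
                                                           config.replicate_summary)),
        )
        by_cond[cond] = agg

    out = by_cond["experimental"].copy()
    out[["exp_mean", "exp_flag"]] = pd.DataFrame(out.pop("sizes").tolist(), index=out.index)

    records = []
    for pos, rec in out.iterrows():
        flags = set()
        if rec["exp_flag"]:
            flags.add(rec["exp_flag"])
        ctrl_means = []
        for cond in present_controls:
            try:
                c_mean, c_flag = by_cond[cond].loc[pos, "sizes"]
            except KeyError:
                c_mean, c_flag = math.nan, FLAG_DEAD
            if c_flag == FLAG_DEAD or not np.isfinite(c_mean):
                flags.add(FLAG_CONTROL_FAILURE)
            else:
                ctrl_means.append(c_mean)
        if FLAG_DEAD in flags or not ctrl_means:
            lgr = math.nan
            if not ctrl_means:
                flags.add(FLAG_CONTROL_FAILURE)
        else:
            lgr = float(np.mean([math.log(c / rec["exp_mean"]) for c in ctrl_means]))
        records.append((*pos, rec["strain_id"], lgr, ";".join(sorted(flags))))
    return pd.DataFrame(records, columns=[*key, "strain_id", "lgr", "flags"])


def aggregate_duplicates(lgrs: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated strains to one row each by arithmetic-mean LGR.

    Input needs columns strain_id and lgr (flags optional).  Records the copy
    count in an ``n_copies`` column; flags are unioned.
    """
    def _merge(group: pd.DataFrame) -> pd.Series:
        vals = group["lgr"].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        flags: set[str] = set()
        if "flags" in group.columns:
            for f in group["flags"]:
                if f:
                    flags.update(str(f).split(";"))
        return pd.Series({
            "lgr": float(finite.mean()) if finite.size else math.nan,
            "n_copies": len(group),
            "flags": ";".join(sorted(flags)),
        })

    out = (lgrs.groupby("strain_id", sort=False, group_keys=False)
           .apply(_merge, include_groups=False).reset_index())
    out["n_copies"] = out["n_copies"].astype(int)
    return out


def _windowed_median_grid(grid: np.ndarray, window: int,
                          min_neighbors: int) -> tuple[np.ndarray, np.ndarray]:
    """Self-excluding windowed median per cell; NaN where too few neighbors."""
    n_rows, n_cols = grid.shape
    half = window // 2
    med = np.full_like(grid, np.nan)
    ok = np.zeros(grid.shape, dtype=bool)
    for i in range(n_rows):
        r0, r1 = max(0, i - half), min(n_rows, i + half + 1)
        for j in range(n_cols):
            c0, c1 = max(0, j - half), min(n_cols, j + half + 1)
            block = grid[r0:r1, c0:c1].ravel().copy()
            # exclude self once (it may be NaN already)
            self_idx = (i - r0) * (c1 - c0) + (j - c0)
            block[self_idx] = np.nan
            neighbors = block[np.isfinite(block)]
            if neighbors.size >= min_neighbors:
                med[i, j] = np.median(neighbors)
                ok[i, j] = True
    return med, ok


def spatial_smooth(lgrs: pd.DataFrame, geometry,
                   config: NormalizationConfig | None = None) -> pd.DataFrame:
    """Remove smooth spatial artifacts from per-position LGRs, plate by plate.

    adjusted = raw - (median of raw LGRs in the centered window, excluding
    self) + plate-wide median, then a final plate-level recentering so the
    plate-wide median of adjusted values equals that of the raw values.
    Positions with fewer than ``smoothing_min_neighbors`` finite neighbors
    keep their raw value (no local correction) and are flagged 'unsmoothed'.

    Input needs columns plate_id, row, col, lgr (flags optional); output adds
    ``lgr_smoothed`` and updates flags.
    """
    config = config or NormalizationConfig()
    w = config.smoothing_window
    if w > geometry.n_rows or w > geometry.n_cols:
        raise ValidationError(
            f"smoothing window {w} larger than plate {geometry}"
        )
    out = lgrs.copy()
    if "flags" not in out.columns:
        out["flags"] = ""
    out["lgr_smoothed"] = np.nan

    for plate_id, sub in out.groupby("plate_id", sort=False):
        grid = np.full((geometry.n_rows, geometry.n_cols), np.nan)
        rows = sub["row"].to_numpy() - 1
        cols = sub["col"].to_numpy() - 1
        grid[rows, cols] = sub["lgr"].to_numpy(dtype=float)
        plate_median = np.nanmedian(grid) if np.isfinite(grid).any() else np.nan

        med, ok = _windowed_median_grid(grid, w, config.smoothing_min_neighbors)
        adjusted = np.where(ok, grid - med + plate_median, grid)
        # recenter so the plate-wide median is exactly preserved
        vals = adjusted[rows, cols]
        finite = vals[np.isfinite(vals)]
        if finite.size:
            adjusted = adjusted + (plate_median - np.median(finite))
        out.loc[sub.index, "lgr_smoothed"] = adjusted[rows, cols]
        unsmoothed = ~ok[rows, cols] & np.isfinite(grid[rows, cols])
        if unsmoothed.any():
            idx = sub.index[unsmoothed]
            prev = out.loc[idx, "flags"].astype(str)
            out.loc[idx, "flags"] = np.where(
                prev == "", FLAG_UNSMOOTHED, prev + ";" + FLAG_UNSMOOTHED
            )
    return out


def z_transform(lgrs: np.ndarray | pd.Series) -> np.ndarray:
    """Standardize to sample mean 0 and sample sd 1 (denominator n-1)."""
    x = np.asarray(lgrs, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise ValidationError("z_transform requires at least 2 finite values")
    sd = finite.std(ddof=1)
    if sd == 0:
        raise ValidationError("z_transform undefined for zero-variance data")
    return (x - finite.mean()) / sd
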