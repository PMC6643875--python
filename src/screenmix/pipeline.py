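"""End-to-end composition of the analysis stages, plus the run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np
import pandas as pd

import screenmix
from screenmix.hitcalling import CutoffSet, compute_cutoffs, call_hits
from screenmix.mixture import HIT_PEAK, FitConfig, MixtureFit, fit_mixture
from screenmix.normalize import (
    NormalizationConfig,
    aggregate_duplicates,
    plate_normalize,
    position_lgrs,
    spatial_smooth,
    z_transform,
)
from screenmix.screen_io import PlateGeometry, ScreenTable

log = logging.getLogger("screenmix")


@dataclass
class PipelineResult:
    screen: ScreenTable
    fit: MixtureFit
    cutoffs: CutoffSet
    hits: pd.DataFrame
    method: str  # "q" or "z", the authoritative hit list


def build_screen_table(colonies: pd.DataFrame, geometry: PlateGeometry,
                       norm_config: NormalizationConfig | None = None,
                       screen_name: str = "screen",
                       n_replicates: int | None = None) -> ScreenTable:
    """Colony sizes -> per-strain ScreenTable.

    Stage order: plate_normalize -> per-position LGRs -> spatial_smooth ->
    aggregate_duplicates -> z_transform.  GFP-free control strains are kept
    out of the strain table (they are normalization references, not queries)
    but their LGRs are available via :func:`gfp_free_lgrs`.
    """
    norm_config = norm_config or NormalizationConfig()
    normalized = plate_normalize(colonies, norm_config)
    queries = normalized[normalized["condition"] != "gfp_free"]
    positions = position_lgrs(queries, norm_config)
    smoothed = spatial_smooth(positions, geometry, norm_config)

    raw = aggregate_duplicates(positions[["strain_id", "lgr", "flags"]])
    smooth = aggregate_duplicates(
        smoothed[["strain_id", "lgr_smoothed", "flags"]]
        .rename(columns={"lgr_smoothed": "lgr"}))
    data = raw.rename(columns={"lgr": "lgr_raw"}).merge(
        smooth[["strain_id", "lgr"]].rename(columns={"lgr": "lgr_smoothed"}),
        on="strain_id")
    z = np.full(len(data), np.nan)
    finite = np.isfinite(data["lgr_smoothed"].to_numpy(dtype=float))
    z_vals = z_transform(data.loc[finite, "lgr_smoothed"].to_numpy(dtype=float))
    z[finite] = z_vals
    data["z_score"] = z
    if n_replicates is None:
        n_replicates = int(colonies["replicate"].max())
    return ScreenTable(screen_name=screen_name,
                       data=data[["strain_id", "lgr_raw", "lgr_smoothed", "z_score",
                                  "n_copies", "flags"]],
                       n_replicates=n_replicates)


def gfp_free_lgrs(colonies: pd.DataFrame, geometry: PlateGeometry,
                  norm_config: NormalizationConfig | None = None) -> np.ndarray:
    """LGR-scale values for GFP-free control strains.

    GFP-free controls carry no experimental/control pairing of their own, so
    their raw value is the log-ratio of the normalized reference level (1
    after reference normalization) to the strain's mean normalized size.
    That ratio only carries experimental-side replicate noise, whereas a
    query LGR also carries control-side noise (variance (C+1)/C times larger
    for C control conditions), so the values are rescaled by sqrt((C+1)/C)
    to sit on the query-LGR noise scale before thresholding.
    """
    norm_config = norm_config or NormalizationConfig(plate_norm="reference_strains")
    normalized = plate_normalize(colonies, norm_config)
    gfp = normalized[normalized["condition"] == "gfp_free"]
    if gfp.empty:
        return np.empty(0)
    n_controls = colonies.loc[
        colonies["condition"].isin(["control_a", "control_b"]), "condition"].nunique()
    scale = math.sqrt((n_controls + 1) / n_controls) if n_controls else 1.0
    values = []
    for _, plate in gfp.groupby("plate_id"):
        nz = plate[plate["size"] > 0]
        grand_mean = nz["size"].mean()  # mean-based reference cancels the
        means = nz.groupby(["row", "col"])["size"].mean()  # lognormal Jensen bias
        values.append(np.log(grand_mean / means.to_numpy(dtype=float)))
    return scale * np.concatenate(values)


def run_pipeline(colonies: pd.DataFrame, geometry: PlateGeometry,
                 norm_config: NormalizationConfig | None = None,
                 fit_config: FitConfig | None = None,
                 screen_name: str = "screen",
                 z_threshold: float = 2.0, q_threshold: float = 0.5,
                 method: str = "auto") -> PipelineResult:
    """Full pipeline: normalize -> LGRs -> smooth -> aggregate -> z ->
    fit mixture -> classify -> cutoffs -> call hits.

    ``method`` selects the authoritative hit list: 'q', 'z', or 'auto'
    (q for hit_peak fits, z otherwise — the empirical-Bayes result decides).
    """
    screen = build_screen_table(colonies, geometry, norm_config, screen_name)
    lgrs = screen.data["lgr_smoothed"].to_numpy(dtype=float)
    fit = fit_mixture(lgrs, fit_config)
    log.info("screen %s: fit classification=%s rho2=%.4f mu2=%.4f",
             screen_name, fit.classification, fit.rho2, fit.mu2)
    cutoffs = compute_cutoffs(lgrs, fit, z_threshold, q_threshold)
    hits = call_hits(screen, fit, cutoffs)
    if method == "auto":
        chosen = "q" if fit.classification == HIT_PEAK else "z"
    elif method in ("q", "z"):
        chosen = method
        if chosen == "q" and fit.classification != HIT_PEAK:
            log.warning("q-based hit list requested but fit is %s; "
                        "falling back to z", fit.classification)
            chosen = "z"
    else:
        raise ValueError(f"unknown method {method!r}")
    log.info("screen %s: hit-calling method=%s", screen_name, chosen)
    return PipelineResult(screen=screen, fit=fit, cutoffs=cutoffs,
                          hits=hits, method=chosen)


def write_manifest(out_dir: str, subcommand: str, params: dict,
                   inputs: list[str] | None = None,
                   seed: int | None = None) -> str:
    """Write the run manifest (one per output directory)."""
    manifest = {
        "tool": "screenmix",
        "version": screenmix.__version__,
        "subcommand": subcommand,
        "params": params,
        "seed": seed,
        "inputs": {},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    for path in inputs or []:
        with open(path, "rb") as fh:
            manifest["inputs"][os.path.basename(path)] = hashlib.sha256(
                fh.read()).hexdigest()
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return path
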