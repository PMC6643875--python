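"""Synthetic colony-array screens with planted ground truth.

Generative model (log scale, natural log): for a colony of gene g on plate p
at grid position (r, c),

    log size = log(base_size) + plate_offset(p, replicate)
               + gradient(r, c) - theta_g * [condition == experimental]
               + Normal(0, sigma_noise^2)

so colony sizes are lognormal.  Gene effects theta are mixture-structured:
a fraction rho2_true of genes are hits with theta drawn from
N(mu2_true, sigma2_true^2) truncated at 0 (growth defects only); null genes
have theta = 0.  Control conditions share each plate's offset and spatial
gradient (paired layout), and GFP-free control strains (theta = 0) occupy
reserved positions.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from screenmix.screen_io import ColonyObservation, PlateGeometry, ValidationError

BASE_SIZE = 500.0  # arbitrary pixel-area units

#: sub-seed offsets so each stochastic stage has its own stream
_SEED_EFFECTS = 1
_SEED_LAYOUT = 2
_SEED_NOISE = 3
_SEED_PLATES = 4
_SEED_VALIDATION = 5


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated screen; ``seed`` is mandatory."""

    n_genes: int
    seed: int
    geometry: PlateGeometry = PlateGeometry(16, 24)
    n_replicates_primary: int = 4
    n_replicates_validation: int = 16
    rho2_true: float = 0.15
    mu2_true: float = 1.0
    sigma2_true: float = 0.4
    sigma_noise: float = 0.3
    plate_offset_sd: float = 0.2
    plate_offsets: tuple[float, ...] | None = None  # explicit per-plate log offsets
    gradient_amplitude: float = 0.0
    duplicate_fraction: float = 0.0
    n_gfp_free: int = 8  # controls per plate (primary screens)
    n_gfp_free_validation: int = 48  # denser controls for thresholding re-screens
    n_controls: int = 2  # control conditions beside experimental

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho2_true <= 1.0):
            raise ValueError("rho2_true must be in [0, 1]")
        for name in ("sigma2_true", "sigma_noise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_controls not in (1, 2):
            raise ValueError("n_controls must be 1 or 2")

    @classmethod
    def for_target_lgr(cls, n_genes: int, seed: int, rho2: float,
                       mu2: float, sigma1: float, sigma2: float,
                       n_replicates: int = 4, n_controls: int = 2,
                       **kwargs) -> "SimConfig":
        """Config whose *downstream LGR distribution* approximates the mixture
        (1-rho2) N(0, sigma1^2) + rho2 N(mu2, sigma2^2).

        With R replicates and C control conditions, Var(null LGR) =
        sigma_noise^2 (C+1)/(C R), so sigma_noise is back-computed from the
        requested sigma1; the planted effect sd is sqrt(sigma2^2 - sigma1^2)
        so that effect spread plus measurement spread gives sigma2.
        """
        if sigma2 <= sigma1:
            raise ValueError("sigma2 must exceed sigma1 (hit peak is noisier)")
        sigma_noise = sigma1 * math.sqrt(n_controls * n_replicates / (n_controls + 1))
        sigma_effect = math.sqrt(sigma2 ** 2 - sigma1 ** 2)
        return cls(n_genes=n_genes, seed=seed, rho2_true=rho2, mu2_true=mu2,
                   sigma2_true=sigma_effect, sigma_noise=sigma_noise,
                   n_replicates_primary=n_replicates, n_controls=n_controls,
                   **kwargs)


def _condition_names(n_controls: int) -> list[str]:
    return ["experimental"] + ["control_a", "control_b"][:n_controls]


def draw_truth(config: SimConfig) -> pd.DataFrame:
    """Ground-truth table: gene_id, component (1 null / 2 hit), theta."""
    rng = np.random.default_rng(config.seed + _SEED_EFFECTS)
    is_hit = rng.random(config.n_genes) < config.rho2_true
    theta = np.zeros(config.n_genes)
    n_hits = int(is_hit.sum())
    if n_hits:
        # truncated-at-0 normal via rejection (fast: truncation is far-tail here)
        draws = rng.normal(config.mu2_true, config.sigma2_true, size=4 * n_hits + 64)
        draws = draws[draws > 0]
        while draws.size < n_hits:
            extra = rng.normal(config.mu2_true, config.sigma2_true, size=4 * n_hits + 64)
            draws = np.concatenate([draws, extra[extra > 0]])
        theta[is_hit] = draws[:n_hits]
    return pd.DataFrame({
        "gene_id": [f"gene{idx:05d}" for idx in range(config.n_genes)],
        "component": np.where(is_hit, 2, 1),
        "theta": theta,
    })


def _layout(config: SimConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Assign genes (plus duplicates and GFP-free controls) to plate positions."""
    rng = np.random.default_rng(config.seed + _SEED_LAYOUT)
    genes = truth["gene_id"].tolist()
    n_dup = int(round(config.duplicate_fraction * len(genes)))
    duplicated = list(rng.choice(genes, size=n_dup, replace=False)) if n_dup else []
    entries = genes + duplicated  # strain entries to place (gfp_free added per plate)

    per_plate = config.geometry.n_positions - config.n_gfp_free
    if per_plate < 1:
        raise ValidationError("plate geometry too small for the GFP-free controls")
    n_plates = math.ceil(len(entries) / per_plate)
    capacity = n_plates * per_plate
    if capacity < len(entries):
        raise ValidationError(
            f"geometry too small: need {math.ceil(len(entries) / per_plate)} plates"
        )

    all_positions = [(r, c) for r in range(1, config.geometry.n_rows + 1)
                     for c in range(1, config.geometry.n_cols + 1)]
    order = rng.permutation(len(entries))
    rows = []
    cursor = 0
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        pos_order = rng.permutation(config.geometry.n_positions)
        positions = [all_positions[k] for k in pos_order]
        # reserve the first n_gfp_free shuffled positions for controls
        for g in range(config.n_gfp_free):
            r, c = positions[g]
            rows.append((plate_id, r, c, f"GFPfree{p + 1:02d}_{g:02d}", True))
        for k in range(per_plate):
            if cursor >= len(entries):
                break
            r, c = positions[config.n_gfp_free + k]
            rows.append((plate_id, r, c, entries[order[cursor]], False))
            cursor += 1
    return pd.DataFrame(rows, columns=["plate_id", "row", "col", "strain_id", "is_gfp_free"])


def _gradient(config: SimConfig, rng: np.random.Generator, n_plates: int,
              conditions: list[str]) -> dict[tuple[str, str], np.ndarray]:
    """Additive log-size tilt per physical plate, keyed by (plate_id, condition).

    Each condition layer is a separate agar plate and gets its own random
    linear gradient (shared across replicates), so spatial artifacts survive
    into LGRs — which is what the smoothing stage exists to remove."""
    grids = {}
    geom = config.geometry
    rr = (np.arange(geom.n_rows)[:, None]) / max(geom.n_rows - 1, 1)
    cc = (np.arange(geom.n_cols)[None, :]) / max(geom.n_cols - 1, 1)
    for p in range(n_plates):
        for cond in conditions:
            key = (f"P{p + 1:02d}", cond)
            if config.gradient_amplitude == 0:
                grids[key] = np.zeros((geom.n_rows, geom.n_cols))
                continue
            angle = rng.uniform(0, 2 * math.pi)
            tilt = math.cos(angle) * rr + math.sin(angle) * cc
            tilt = tilt - tilt.min()
            span = tilt.max() or 1.0
            grids[key] = config.gradient_amplitude * (tilt / span - 0.5)
    return grids


def _generate(config: SimConfig, truth: pd.DataFrame, layout: pd.DataFrame,
              n_replicates: int, noise_seed: int) -> list[ColonyObservation]:
    theta_map = dict(zip(truth["gene_id"], truth["theta"]))
    n_plates = layout["plate_id"].nunique()
    rng_plates = np.random.default_rng(config.seed + _SEED_PLATES)
    if config.plate_offsets is not None:
        if len(config.plate_offsets) < n_plates * n_replicates:
            raise ValidationError("not enough plate_offsets for plates x replicates")
        offsets = np.asarray(config.plate_offsets, dtype=float)[:n_plates * n_replicates]
        offsets = offsets.reshape(n_plates, n_replicates)
    else:
        offsets = rng_plates.normal(0.0, config.plate_offset_sd,
                                    size=(n_plates, n_replicates))
    conditions = _condition_names(config.n_controls)
    gradients = _gradient(config, rng_plates, n_plates, conditions)

    rng = np.random.default_rng(noise_seed)
    plate_index = {pid: i for i, pid in enumerate(sorted(layout["plate_id"].unique()))}
    obs: list[ColonyObservation] = []
    base = math.log(BASE_SIZE)
    for rec in layout.itertuples(index=False):
        theta = 0.0 if rec.is_gfp_free else theta_map[rec.strain_id]
        p_idx = plate_index[rec.plate_id]
        for rep in range(1, n_replicates + 1):
            # offset shared across conditions: paired plates grown in one batch
            off = offsets[p_idx, rep - 1]
            for cond in conditions:
                grad = gradients[rec.plate_id, cond][rec.row - 1, rec.col - 1]
                effect = -theta if cond == "experimental" else 0.0
                log_size = base + off + grad + effect + rng.normal(0.0, config.sigma_noise)
                out_cond = "gfp_free" if rec.is_gfp_free else cond
                if rec.is_gfp_free and cond != "experimental":
                    continue  # one gfp_free layer per (plate, replicate)
                obs.append(ColonyObservation(
                    rec.plate_id, rec.row, rec.col, rec.strain_id, out_cond,
                    rep, round(math.exp(log_size), 3),
                ))
    return obs


def simulate_screen(config: SimConfig) -> tuple[list[ColonyObservation], pd.DataFrame]:
    """Simulate a primary screen.

    Returns colony observations for the experimental condition, the control
    condition(s) and the per-plate GFP-free controls, plus the ground-truth
    table (gene_id, component, theta) with plate/position assignments merged
    in.  Byte-identical output for a fixed seed.
    """
    truth = draw_truth(config)
    layout = _layout(config, truth)
    obs = _generate(config, truth, layout, config.n_replicates_primary,
                    config.seed + _SEED_NOISE)
    placed = layout[~layout["is_gfp_free"]].rename(columns={"strain_id": "gene_id"})
    truth = truth.merge(placed[["gene_id", "plate_id", "row", "col"]]
                        .drop_duplicates("gene_id"), on="gene_id", how="left")
    return obs, truth


def simulate_validation(truth: pd.DataFrame, selected: list[str],
                        config: SimConfig) -> list[ColonyObservation]:
    """Re-screen selected strains at validation depth (default 16 replicates).

    Same generative model with fresh noise; GFP-free controls are included
    for thresholding.  Unknown strains raise.
    """
    known = set(truth["gene_id"])
    unknown = [s for s in selected if s not in known]
    if unknown:
        raise ValidationError(f"unknown strain {unknown[0]!r} in validation selection")
    sub_truth = truth[truth["gene_id"].isin(selected)].reset_index(drop=True)
    val_config = replace(config, n_genes=len(sub_truth),
                         seed=config.seed + _SEED_VALIDATION,
                         n_gfp_free=config.n_gfp_free_validation,
                         plate_offsets=None)
    layout = _layout(val_config, sub_truth)
    return _generate(val_config, sub_truth, layout,
                     config.n_replicates_validation,
                     val_config.seed + _SEED_NOISE)


# ---------------------------------------------------------------------------
# fixture suite

def make_fixture_suite(out_dir: str) -> dict[str, str]:
    """Write a small fixed-seed fixture set for tests and demos.

    Emits one screen with a strong hit peak ('spb_like'), one few-hit screen
    ('few_hit', rho2 = 0.02), one gradient-heavy plate set, and an 8-screen
    LGR matrix (5 screens sharing a planted hit set + 3 unrelated) for
    clustering, plus ground-truth tables.  Deterministic.
    """
    import os

    from screenmix.screen_io import write_colony_table

    os.makedirs(out_dir, exist_ok=True)
    written: dict[str, str] = {}

    def emit(name: str, config: SimConfig) -> pd.DataFrame:
        obs, truth = simulate_screen(config)
        path = os.path.join(out_dir, f"{name}_colonies.tsv")
        write_colony_table(obs, path, meta={"fixture": name, "seed": config.seed})
        tpath = os.path.join(out_dir, f"{name}_truth.tsv")
        truth.to_csv(tpath, sep="\t", index=False)
        written[name] = path
        written[f"{name}_truth"] = tpath
        return truth

    emit("spb_like", SimConfig.for_target_lgr(
        n_genes=2000, seed=101, rho2=0.20, mu2=1.2, sigma1=0.2, sigma2=0.4))
    emit("few_hit", SimConfig.for_target_lgr(
        n_genes=2000, seed=202, rho2=0.02, mu2=0.3, sigma1=0.2, sigma2=0.3))
    emit("gradient", SimConfig.for_target_lgr(
        n_genes=1000, seed=303, rho2=0.10, mu2=1.0, sigma1=0.2, sigma2=0.4,
        gradient_amplitude=0.5))
    return written


def shared_hit_matrix(seed: int = 404, n_strains: int = 400,
                      n_shared_screens: int = 5, n_other_screens: int = 3,
                      rho2: float = 0.15, mu2: float = 1.0,
                      sigma1: float = 0.2, sigma2: float = 0.4) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LGR matrix where the first n_shared_screens share one planted hit set
    and the remaining screens each have independent hits.  Returns (matrix,
    truth) with truth holding the shared-hit indicator per strain."""
    rng = np.random.default_rng(seed)
    strains = [f"gene{i:05d}" for i in range(n_strains)]
    shared_hits = rng.random(n_strains) < rho2
    cols = {}
    for s in range(n_shared_screens + n_other_screens):
        if s < n_shared_screens:
            hits = shared_hits
        else:
            hits = rng.random(n_strains) < rho2
        effect = np.where(hits, rng.normal(mu2, math.sqrt(max(sigma2 ** 2 - sigma1 ** 2,
                                                              1e-12)), n_strains), 0.0)
        noise = rng.normal(0.0, sigma1, n_strains)
        name = f"shared{s + 1}" if s < n_shared_screens else f"other{s - n_shared_screens + 1}"
        cols[name] = effect + noise
    matrix = pd.DataFrame(cols, index=strains)
    truth = pd.DataFrame({"strain_id": strains, "shared_hit": shared_hits})
    return matrix, truth
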