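"""Posterior hit probabilities, cutoffs, hit calling and validation prediction.

q(x) is the posterior probability that a strain with measured LGR x belongs
to the hit peak (Component 2).  The q-based cutoff L_q is the LGR where
q(x) crosses q_threshold (default 0.5); the classical cutoff L_Z is the LGR
where the screen's Z-transformation equals z_threshold (default 2).
pV(x) predicts the probability that a strain validates in a high-replicate
re-screen; predicted FPR = 1 - pV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from screenmix.mixture import HIT_PEAK, MixtureFit
from screenmix.screen_io import ScreenTable, ValidationError


class CutoffError(ValueError):
    pass


@dataclass(frozen=True)
class CutoffSet:
    """Hit-calling cutoffs in LGR units.  l_q is None for non-hit_peak fits."""

    l_z: float
    l_q: float | None
    z_threshold: float = 2.0
    q_threshold: float = 0.5


def q_posterior(x, fit: MixtureFit):
    """Posterior probability of Component 2 membership given LGR x.

    q(x) = rho2 N(x; mu2, s2^2) / [(1-rho2) N(x; mu1, s1^2) + rho2 N(x; mu2, s2^2)],
    evaluated in log space so tails far from both means neither overflow nor
    round to 0/1 prematurely.
    """
    x_arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x_arr)):
        raise ValidationError("q_posterior requires finite x")
    if fit.rho2 <= 0.0:
        return np.zeros_like(x_arr) if x_arr.ndim else 0.0
    if fit.rho2 >= 1.0:
        return np.ones_like(x_arr) if x_arr.ndim else 1.0
    log1 = math.log1p(-fit.rho2) + norm.logpdf(x_arr, fit.mu1, fit.sigma1)
    log2 = math.log(fit.rho2) + norm.logpdf(x_arr, fit.mu2, fit.sigma2)
    # q = 1 / (1 + exp(log1 - log2)), stable at both ends
    with np.errstate(over="ignore"):
        q = 1.0 / (1.0 + np.exp(log1 - log2))
    return float(q) if x_arr.ndim == 0 else q


def lq_cutoff(fit: MixtureFit, q_threshold: float = 0.5) -> float:
    """Smallest LGR in [mu1, mu2] where q(x) = q_threshold.

    Only the between-means crossing is used; q may be non-monotone outside
    [mu1, mu2] when sigma1 != sigma2.  Root located by bisection to 1e-9.
    """
    if fit.classification != HIT_PEAK:
        raise CutoffError(
            f"L_q cutoff only defined for hit_peak fits (got {fit.classification!r})"
        )
    lo, hi = fit.mu1, fit.mu2

    def g(x: float) -> float:
        return q_posterior(x, fit) - q_threshold

    if g(lo) >= 0.0:
        raise CutoffError("components indistinguishable: q(mu1) already above threshold")
    if g(hi) <= 0.0:
        raise CutoffError("components indistinguishable: q(mu2) below threshold")
    # pre-scan for the first sign change so the smallest root is returned
    grid = np.linspace(lo, hi, 513)
    vals = np.array([g(t) for t in grid])
    idx = int(np.argmax(vals >= 0.0))
    a, b = grid[idx - 1], grid[idx]
    return float(brentq(g, a, b, xtol=1e-12))


def lz_cutoff(lgrs, z_threshold: float = 2.0) -> float:
    """LGR where the Z-transformation of the data equals z_threshold:
    mean + z_threshold * sd (sample sd, denominator n-1)."""
    x = np.asarray(lgrs, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValidationError("lz_cutoff requires >= 2 finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("lz_cutoff undefined for zero-variance data")
    return float(x.mean() + z_threshold * sd)


def compute_cutoffs(lgrs, fit: MixtureFit, z_threshold: float = 2.0,
                    q_threshold: float = 0.5) -> CutoffSet:
    """Both cutoffs for a screen; L_q is None unless the fit has a hit peak."""
    l_q = lq_cutoff(fit, q_threshold) if fit.classification == HIT_PEAK else None
    return CutoffSet(l_z=lz_cutoff(lgrs, z_threshold), l_q=l_q,
                     z_threshold=z_threshold, q_threshold=q_threshold)


def call_hits(screen: ScreenTable, fit: MixtureFit, cutoffs: CutoffSet) -> pd.DataFrame:
    """Per-strain hit table with q, pV and hit flags (closed cutoffs, >=).

    For fits without a hit peak the q/pv/hit_q columns are NA and the
    Z-based list is authoritative.  Strains with Z <= -z_threshold are
    annotated as growth enhancers in a separate column, never as hits —
    they rarely reproduce in validation screens.
    """
    df = screen.data.copy()
    lgr = df["lgr_smoothed"].to_numpy(dtype=float)
    z = df["z_score"].to_numpy(dtype=float)
    out = pd.DataFrame({
        "strain_id": df["strain_id"],
        "lgr": lgr,
        "z_score": z,
    })
    if fit.classification == HIT_PEAK and cutoffs.l_q is not None:
        finite = np.isfinite(lgr)
        q = np.full(lgr.shape, np.nan)
        q[finite] = q_posterior(lgr[finite], fit)
        out["q"] = q
        out["pv"] = q
        out["hit_q"] = pd.array(lgr >= cutoffs.l_q, dtype="boolean")
        out.loc[~finite, "hit_q"] = pd.NA
    else:
        out["q"] = np.nan
        out["pv"] = np.nan
        out["hit_q"] = pd.array([pd.NA] * len(out), dtype="boolean")
    out["hit_z"] = pd.array(z >= cutoffs.z_threshold, dtype="boolean")
    out["enhancer"] = pd.array(z <= -cutoffs.z_threshold, dtype="boolean")
    if "flags" in df.columns:
        out["flags"] = df["flags"]
    return out


def pv_validation(x, fit: MixtureFit, noise_aware: bool = False,
                  validation_threshold_lgr: float | None = None,
                  n_replicates_primary: int = 4,
                  n_replicates_validation: int = 16):
    """Predicted probability of validation for a strain with primary LGR x.

    Baseline (default): pV(x) = q(x), the posterior true-hit probability;
    predicted FPR at x is 1 - pV(x).  The optional noise-aware variant
    multiplies q(x) by the probability that a true hit re-measured with
    n_replicates_validation replicates exceeds the validation threshold,
    taking the per-measurement noise sd as sigma1 * sqrt(n_replicates_primary)
    (Component 1 spread attributed to primary-screen replicate noise).
    """
    q = q_posterior(x, fit)
    if not noise_aware:
        return q
    if validation_threshold_lgr is None:
        raise ValidationError("noise-aware pV requires a validation threshold")
    sigma_m = fit.sigma1 * math.sqrt(n_replicates_primary)
    sd_val = sigma_m / math.sqrt(n_replicates_validation)
    p_exceed = norm.sf(validation_threshold_lgr, loc=np.asarray(x, dtype=float),
                       scale=sd_val)
    return q * p_exceed


def predicted_fpr(x, fit: MixtureFit, **pv_kwargs):
    """Predicted false-positive rate at LGR x: 1 - pV(x)."""
    return 1.0 - pv_validation(x, fit, **pv_kwargs)


def validation_threshold(gfp_free_lgrs, method: str = "mean_2sd") -> float:
    """Validation cutoff from GFP-free control LGRs.

    'mean_2sd' (default): mean + 2 * sample sd; 'p95': 95th percentile.
    Requires >= 20 controls.
    """
    x = np.asarray(gfp_free_lgrs, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValidationError(
            f"validation_threshold requires >= 20 GFP-free control LGRs, got {x.size}"
        )
    if method == "mean_2sd":
        sd = x.std(ddof=1)
        return float(x.mean() + 2.0 * sd)
    if method == "p95":
        return float(np.quantile(x, 0.95))
    raise ValueError(f"unknown method {method!r}")


def empirical_fpr_binned(lgrs: pd.Series, validated: pd.Series,
                         bins) -> pd.DataFrame:
    """Bin strains by primary-screen LGR and estimate FPR per bin.

    ``lgrs`` and ``validated`` are aligned by strain_id index; every
    validation record must match a screened strain.  ``bins`` is a bin width
    (scalar) or explicit edges.  Per-bin empirical FPR = fraction not
    validated; bins with fewer than 10 strains are flagged low-confidence.
    """
    if len(validated) == 0:
        raise ValidationError("empty validation set")
    unknown = validated.index.difference(lgrs.index)
    if len(unknown):
        raise ValidationError(f"validation record for unscreened strain {unknown[0]!r}")
    x = lgrs.loc[validated.index].to_numpy(dtype=float)
    v = validated.to_numpy(dtype=bool)
    if np.isscalar(bins):
        width = float(bins)
        lo = math.floor(x.min() / width) * width
        hi = math.ceil(x.max() / width) * width
        edges = np.arange(lo, hi + width / 2, width)
        if len(edges) < 2:
            edges = np.array([lo, lo + width])
    else:
        edges = np.asarray(bins, dtype=float)
    which = np.digitize(x, edges) - 1
    which = np.clip(which, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = which == b
        count = int(mask.sum())
        if count == 0:
            continue
        n_val = int(v[mask].sum())
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1],
            "count": count, "validated": n_val,
            "fpr": 1.0 - n_val / count,
            "low_confidence": count < 10,
        })
    return pd.DataFrame(rows)
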