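"""Tabular I/O for colony tables, screen tables, hit tables and fit summaries.

All artifacts are TSV files with '#'-prefixed comment lines, a mandatory
header row, and "NA" as the sole missing-value token.  Grid coordinates are
1-based integers.  Strain identifiers are opaque, case-sensitive tokens.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

NA_TOKEN = "NA"

CONDITIONS = ("experimental", "control_a", "control_b", "gfp_free")

COLONY_COLUMNS = ["plate_id", "row", "col", "strain_id", "condition", "replicate", "size"]
SCREEN_COLUMNS = ["strain_id", "lgr_raw", "lgr_smoothed", "z_score"]
HIT_COLUMNS = ["strain_id", "lgr", "z_score", "q", "pv", "hit_z", "hit_q", "enhancer", "flags"]
FIT_COLUMNS = [
    "screen_name", "rho2", "mu1", "sigma1", "mu2", "sigma2",
    "loglik", "n", "converged", "classification",
]


class FormatError(ValueError):
    """Header or structural problem in a TSV artifact."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class PlateGeometry:
    """Colony-array grid dimensions, e.g. 16x24 (384) or 32x48 (1536)."""

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("plate geometry must have at least one cell")

    @property
    def n_positions(self) -> int:
        return self.n_rows * self.n_cols

    @classmethod
    def parse(cls, text: str) -> "PlateGeometry":
        """Parse a 'ROWSxCOLS' string such as '16x24'."""
        try:
            r, c = text.lower().split("x")
            return cls(int(r), int(c))
        except (ValueError, AttributeError) as exc:
            raise FormatError(f"cannot parse plate geometry {text!r}; expected e.g. '16x24'") from exc

    def __str__(self) -> str:
        return f"{self.n_rows}x{self.n_cols}"


class ColonyObservation(NamedTuple):
    """One colony-size measurement with its grid coordinates and identity.

    size == 0 encodes a dead/absent colony; missingness is an absent record.
    """

    plate_id: str
    row: int
    col: int
    strain_id: str
    condition: str
    replicate: int
    size: float


@dataclass
class ScreenTable:
    """Per-strain LGRs (raw, smoothed) and Z-scores for one screen."""

    screen_name: str
    data: pd.DataFrame  # columns: strain_id, lgr_raw, lgr_smoothed, z_score
    n_replicates: int = 4
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in SCREEN_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"screen table missing columns: {missing}")
        dup = self.data["strain_id"][self.data["strain_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate strain_id in screen table: {dup.iloc[0]!r}")
        z = self.data["z_score"].to_numpy(dtype=float)
        z = z[np.isfinite(z)]  # dead/flagged strains carry NaN, not a z-score
        if len(z) >= 2:
            if abs(z.mean()) > 1e-9 or abs(z.std(ddof=1) - 1.0) > 1e-9:
                raise ValidationError(
                    "z_score column must have sample mean 0 and sd 1 (ddof=1) within 1e-9"
                )

    @property
    def strain_ids(self) -> list[str]:
        return self.data["strain_id"].tolist()

    def lgrs(self, smoothed: bool = True) -> pd.Series:
        col = "lgr_smoothed" if smoothed else "lgr_raw"
        return self.data.set_index("strain_id")[col]


def _fmt(x: object) -> str:
    if x is None:
        return NA_TOKEN
    if isinstance(x, (bool, np.bool_)):
        return "true" if x else "false"
    if isinstance(x, (float, np.floating)):
        if not np.isfinite(x):
            return NA_TOKEN
        # shortest exact representation: byte-stable and round-trips exactly
        return repr(float(x))
    return str(x)


def _read_tsv(path: str, required: list[str]) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a commented TSV; returns (frame, metadata from '# key=value' lines)."""
    meta: dict[str, str] = {}
    lines: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            if raw.startswith("#"):
                body = raw[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            lines.append(raw)
    if not lines:
        raise FormatError(f"{path}: no header row found")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: malformed header, missing column(s) {missing}")
    df = pd.read_csv(
        io.StringIO("".join(lines)), sep="\t", dtype=str,
        keep_default_na=False, na_values=[NA_TOKEN],
    )
    return df, meta


def _write_tsv(path: str, columns: list[str], rows: Iterable[Iterable[object]],
               meta: dict[str, object] | None = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# colony tables

def read_colony_table(path: str, geometry: PlateGeometry) -> list[ColonyObservation]:
    """Read and validate a colony-size table.

    Raises :class:`FormatError` for a malformed header and
    :class:`ValidationError` (with the offending 1-based data line number)
    for out-of-contract records.
    """
    df, _ = _read_tsv(path, COLONY_COLUMNS)
    obs: list[ColonyObservation] = []
    seen: set[tuple[str, int, int, str, int]] = set()
    for lineno, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            row, col = int(rec.row), int(rec.col)
            replicate = int(rec.replicate)
            size = float(rec.size)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: line {lineno}: non-numeric field ({exc})") from exc
        if not (1 <= row <= geometry.n_rows) or not (1 <= col <= geometry.n_cols):
            raise ValidationError(
                f"{path}: line {lineno}: position ({row},{col}) outside {geometry} plate"
            )
        if rec.condition not in CONDITIONS:
            raise ValidationError(
                f"{path}: line {lineno}: unknown condition {rec.condition!r}"
            )
        if replicate < 1:
            raise ValidationError(f"{path}: line {lineno}: replicate must be >= 1")
        if not np.isfinite(size) or size < 0:
            raise ValidationError(f"{path}: line {lineno}: negative or non-finite size {rec.size}")
        key = (str(rec.plate_id), row, col, str(rec.condition), replicate)
        if key in seen:
            raise ValidationError(
                f"{path}: line {lineno}: duplicate position {key[:3]} within "
                f"condition={rec.condition} replicate={replicate}"
            )
        seen.add(key)
        obs.append(ColonyObservation(
            str(rec.plate_id), row, col, str(rec.strain_id), str(rec.condition),
            replicate, size,
        ))
    return obs


def write_colony_table(observations: Iterable[ColonyObservation], path: str,
                       meta: dict[str, object] | None = None) -> None:
    _write_tsv(path, COLONY_COLUMNS, observations, meta)


def colony_frame(observations: Iterable[ColonyObservation]) -> pd.DataFrame:
    """Pack observations into a DataFrame for the normalization pipeline."""
    df = pd.DataFrame(observations, columns=COLONY_COLUMNS)
    return df.astype({"row": int, "col": int, "replicate": int, "size": float})


def frame_to_observations(df: pd.DataFrame) -> list[ColonyObservation]:
    return [ColonyObservation(str(r.plate_id), int(r.row), int(r.col), str(r.strain_id),
                              str(r.condition), int(r.replicate), float(r.size))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# screen tables

def write_screen_table(screen: ScreenTable, path: str,
                       extra_meta: dict[str, object] | None = None) -> None:
    meta: dict[str, object] = {
        "screen_name": screen.screen_name,
        "n_replicates": screen.n_replicates,
    }
    if screen.provenance:
        meta["provenance"] = screen.provenance
    meta.update(extra_meta or {})
    rows = (
        (r.strain_id, r.lgr_raw, r.lgr_smoothed, r.z_score)
        for r in screen.data[SCREEN_COLUMNS].itertuples(index=False)
    )
    _write_tsv(path, SCREEN_COLUMNS, rows, meta)


def read_screen_table(path: str) -> ScreenTable:
    df, meta = _read_tsv(path, SCREEN_COLUMNS)
    if len(df):
        data = pd.DataFrame({
            "strain_id": df["strain_id"].astype(str),
            "lgr_raw": pd.to_numeric(df["lgr_raw"]),
            "lgr_smoothed": pd.to_numeric(df["lgr_smoothed"]),
            "z_score": pd.to_numeric(df["z_score"]),
        })
    else:
        data = pd.DataFrame({c: pd.Series(dtype=float if c != "strain_id" else str)
                             for c in SCREEN_COLUMNS})
    return ScreenTable(
        screen_name=meta.get("screen_name", ""),
        data=data,
        n_replicates=int(meta.get("n_replicates", 4)),
        provenance=meta.get("provenance", ""),
    )


# ---------------------------------------------------------------------------
# hit tables and fit summaries

def write_hit_table(hits: pd.DataFrame, path: str,
                    meta: dict[str, object] | None = None) -> None:
    cols = [c for c in HIT_COLUMNS if c in hits.columns]
    rows = (tuple(rec) for rec in hits[cols].itertuples(index=False))
    _write_tsv(path, cols, rows, meta)


def read_hit_table(path: str) -> pd.DataFrame:
    df, _ = _read_tsv(path, ["strain_id", "lgr", "z_score"])
    out = pd.DataFrame({"strain_id": df["strain_id"].astype(str)})
    for c in ("lgr", "z_score", "q", "pv"):
        if c in df.columns:
            out[c] = pd.to_numeric(df[c])
    for c in ("hit_z", "hit_q", "enhancer"):
        if c in df.columns:
            out[c] = df[c].map({"true": True, "false": False})
    if "flags" in df.columns:
        out["flags"] = df["flags"].fillna("")
    return out


def write_fit_summary(rows: pd.DataFrame, path: str,
                      meta: dict[str, object] | None = None) -> None:
    recs = (tuple(rec) for rec in rows[FIT_COLUMNS].itertuples(index=False))
    _write_tsv(path, FIT_COLUMNS, recs, meta)


def read_fit_summary(path: str) -> pd.DataFrame:
    df, _ = _read_tsv(path, FIT_COLUMNS)
    for c in ("rho2", "mu1", "sigma1", "mu2", "sigma2", "loglik"):
        df[c] = pd.to_numeric(df[c])
    df["n"] = df["n"].astype(int)
    df["converged"] = df["converged"].map({"true": True, "false": False})
    return df
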