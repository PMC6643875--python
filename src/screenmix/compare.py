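"""Cross-screen analysis: screen-parameter summaries and hierarchical
clustering of multi-screen LGR matrices by correlation distance with
average linkage (UPGMA)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from screenmix.mixture import HIT_PEAK, MixtureFit
from screenmix.screen_io import ValidationError

MIN_PAIRWISE_OVERLAP = 10


def screen_param_table(fits: dict[str, MixtureFit],
                       sort_by_rho2: bool = False) -> pd.DataFrame:
    """One row per screen with (rho2, mu2, sigma2, classification).

    Screens whose fit lacks a well-defined hit peak are flagged; plotting
    rho2 against mu2 separates screens where many strains are affected from
    screens where effects are strong.
    """
    if not fits:
        raise ValidationError("at least one fit required")
    rows = [{
        "screen_name": name,
        "rho2": fit.rho2,
        "mu2": fit.mu2,
        "sigma2": fit.sigma2,
        "classification": fit.classification,
        "flagged": fit.classification != HIT_PEAK,
    } for name, fit in fits.items()]
    df = pd.DataFrame(rows)
    if sort_by_rho2:
        df = df.sort_values("rho2", ascending=False, kind="stable").reset_index(drop=True)
    return df


def correlation_distance(matrix: pd.DataFrame, axis: str = "screens",
                         centered: bool = True) -> pd.DataFrame:
    """Pairwise distance d = 1 - Pearson correlation over pairwise-complete
    entries.

    ``matrix`` is strains (rows) x screens (columns); ``axis`` selects which
    is compared.  Uncentered correlation (cosine of the raw vectors) is
    available behind ``centered=False``.  Pairs sharing fewer than 10
    entries, or zero-variance vectors, raise rather than silently impute.
    """
    if axis not in ("screens", "strains"):
        raise ValueError("axis must be 'screens' or 'strains'")
    data = matrix if axis == "screens" else matrix.T
    labels = list(data.columns)
    if len(labels) < 2:
        raise ValidationError("need >= 2 vectors to compare")
    arr = data.to_numpy(dtype=float)
    k = len(labels)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            both = np.isfinite(arr[:, i]) & np.isfinite(arr[:, j])
            if both.sum() < MIN_PAIRWISE_OVERLAP:
                raise ValidationError(
                    f"screens {labels[i]!r} and {labels[j]!r} share only "
                    f"{int(both.sum())} strains (< {MIN_PAIRWISE_OVERLAP})"
                )
            u, v = arr[both, i], arr[both, j]
            if centered:
                u = u - u.mean()
                v = v - v.mean()
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu == 0:
                raise ValidationError(f"zero-variance vector {labels[i]!r}")
            if nv == 0:
                raise ValidationError(f"zero-variance vector {labels[j]!r}")
            r = float(np.dot(u, v) / (nu * nv))
            dist[i, j] = dist[j, i] = 1.0 - r
    return pd.DataFrame(dist, index=labels, columns=labels)


@dataclass
class LinkageTree:
    """UPGMA merge list: (node_a, node_b, height, size) per merge.

    Leaves are numbered 0..n-1 in label order; internal node i (>= n) is
    created by merge i - n.  Heights are non-decreasing along merges.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_newick(self) -> str:
        """Newick string with branch lengths = height/2 differences
        (ultrametric: leaf-to-node distance is half the merge height)."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        text = {i: self.labels[i] for i in range(n)}
        for m, (a, b, h, _size) in enumerate(self.merges):
            node = n + m
            height[node] = h / 2.0
            la = height[node] - height[a]
            lb = height[node] - height[b]
            text[node] = f"({text[a]}:{la:.10g},{text[b]}:{lb:.10g})"
        return text[n + len(self.merges) - 1] + ";"

    def leaves_under(self, node: int) -> set[int]:
        n = self.n_leaves
        if node < n:
            return {node}
        a, b, _, _ = self.merges[node - n]
        return self.leaves_under(a) | self.leaves_under(b)

    def clades(self) -> list[frozenset[str]]:
        """Label sets of every internal node."""
        return [frozenset(self.labels[i] for i in self.leaves_under(self.n_leaves + m))
                for m in range(len(self.merges))]


def average_linkage_cluster(distances: pd.DataFrame) -> LinkageTree:
    """UPGMA clustering of a symmetric distance matrix.

    At each step the pair of clusters with minimal average inter-cluster
    distance is merged; ties are broken toward the lowest-index pair, making
    the merge order deterministic.  Average linkage guarantees heights are
    non-decreasing for any valid distance matrix.
    """
    labels = list(distances.index)
    n = len(labels)
    if n < 2:
        raise ValidationError("need >= 2 leaves to cluster")
    d = distances.to_numpy(dtype=float)
    if not np.allclose(d, d.T, equal_nan=False) or not np.allclose(np.diag(d), 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")

    # active clusters: node id -> (index into dist rows, size)
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                dd = dist[(a, b) if a < b else (b, a)]
                if best is None or dd < best[0] - 1e-15:
                    best = (dd, a, b)
        _, a, b = best
        h = dist[(a, b) if a < b else (b, a)]
        new_size = size[a] + size[b]
        merges.append((a, b, h, new_size))
        # UPGMA update: weighted average of distances to the merged pair
        for c in active:
            if c in (a, b):
                continue
            dac = dist[(a, c) if a < c else (c, a)]
            dbc = dist[(b, c) if b < c else (c, b)]
            dist[(c, next_id)] = (size[a] * dac + size[b] * dbc) / new_size
        size[next_id] = new_size
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return LinkageTree(merges=merges, labels=labels)


def frequent_flyers(hit_tables: dict[str, pd.DataFrame],
                    min_fraction: float = 0.75,
                    hit_column: str = "hit_z") -> pd.DataFrame:
    """Strains that are hits in >= min_fraction of the screens assaying them.

    ``hit_tables`` maps screen name to a hit table (strain_id + boolean hit
    column).  Returns per-strain assay counts, hit counts and hit fractions
    for the qualifying strains, sorted by fraction then strain_id.
    """
    if len(hit_tables) < 2:
        raise ValidationError("need >= 2 screens to find frequent flyers")
    assayed: dict[str, int] = {}
    hits: dict[str, int] = {}
    for table in hit_tables.values():
        flags = table.set_index("strain_id")[hit_column]
        for strain, flag in flags.items():
            if pd.isna(flag):
                continue
            assayed[strain] = assayed.get(strain, 0) + 1
            if bool(flag):
                hits[strain] = hits.get(strain, 0) + 1
    rows = []
    for strain, n_assayed in assayed.items():
        n_hit = hits.get(strain, 0)
        frac = n_hit / n_assayed
        if frac >= min_fraction:
            rows.append({"strain_id": strain, "n_assayed": n_assayed,
                         "n_hit": n_hit, "hit_fraction": frac})
    df = pd.DataFrame(rows, columns=["strain_id", "n_assayed", "n_hit", "hit_fraction"])
    return df.sort_values(["hit_fraction", "strain_id"],
                          ascending=[False, True]).reset_index(drop=True)
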