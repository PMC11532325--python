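"""Phytosociological relevé processing and landscape typing.

Relevé tables record species cover on the Braun-Blanquet ordinal scale
(``r, +, 1..5``).  Codes are converted to percent cover by the conventional
class midpoints, aggregated per relevé to growth-form abundances (the
maximum converted cover over the member species of each growth form), and
averaged per alliance.  The alliance x growth-form matrix is then
consolidated into vegetation types by k-means, with the number of clusters
chosen by the elbow rule — the maximizer of the discrete second difference
of the within-cluster sum of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .params import GROUPS

__all__ = [
    "BB_CODES",
    "bb_to_percent",
    "percent_to_bb",
    "read_releves",
    "validate_releves",
    "aggregate_growth_forms",
    "releve_matrix",
    "alliance_matrix",
    "ClusterResult",
    "cluster_alliances",
]

#: Braun-Blanquet code -> percent cover (class midpoints; 'r' and '+' use the
#: conventional token values for rare / sparse occurrences).
BB_CODES: Mapping[str, float] = {
    "r": 0.1, "+": 0.5, "1": 2.5, "2": 15.0, "3": 37.5, "4": 62.5, "5": 87.5,
}

#: Upper class edges used to map a percent cover back to a code.
_BB_EDGES = [(0.3, "r"), (1.0, "+"), (5.0, "1"), (25.0, "2"),
             (50.0, "3"), (75.0, "4"), (100.0, "5")]

RELEVE_COLUMNS = ["releve_id", "alliance_id", "species", "growth_form", "bb_code"]


def bb_to_percent(code: str) -> float:
    """Percent cover of one Braun-Blanquet code."""
    key = str(code).strip()
    if key not in BB_CODES:
        raise ValueError(f"unknown Braun-Blanquet code {code!r}; "
                         f"expected one of {sorted(BB_CODES)}")
    return BB_CODES[key]


def percent_to_bb(pct: float) -> str | None:
    """Braun-Blanquet code whose cover class contains ``pct`` (None if 0)."""
    if pct < 0 or pct > 100:
        raise ValueError(f"percent cover {pct} outside [0, 100]")
    if pct == 0:
        return None
    for edge, code in _BB_EDGES:
        if pct <= edge:
            return code
    return "5"


def validate_releves(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RELEVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"relevé table missing columns {missing}")
    df = df.copy()
    df["bb_code"] = df["bb_code"].astype(str).str.strip()
    bad = ~df["bb_code"].isin(BB_CODES)
    if bad.any():
        raise ValueError(f"invalid Braun-Blanquet codes: "
                         f"{sorted(df.loc[bad, 'bb_code'].unique())}")
    badg = ~df["growth_form"].isin(GROUPS)
    if badg.any():
        raise ValueError(f"invalid growth-form labels: "
                         f"{sorted(df.loc[badg, 'growth_form'].unique())}")
    return df


def read_releves(path) -> pd.DataFrame:
    """Read and validate a headered delimited relevé table (CSV or TSV)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    return validate_releves(df)


def aggregate_growth_forms(records: pd.DataFrame) -> pd.Series:
    """Growth-form abundance row of a single relevé.

    Per growth form, the maximum converted percent cover over its member
    species; growth forms without records score 0.  Order-invariant and
    idempotent under record duplication.
    """
    records = validate_releves(records)
    if records["releve_id"].nunique() > 1:
        raise ValueError("records span more than one relevé")
    pct = records["bb_code"].map(BB_CODES)
    out = pct.groupby(records["growth_form"]).max()
    return out.reindex(GROUPS, fill_value=0.0).astype(float)


def releve_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Relevé x growth-form percent-cover matrix (per-relevé maxima)."""
    df = validate_releves(df)
    pct = df["bb_code"].map(BB_CODES)
    mat = (pct.groupby([df["releve_id"], df["growth_form"]]).max()
           .unstack(fill_value=0.0))
    return mat.reindex(columns=GROUPS, fill_value=0.0).astype(float)


def alliance_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Alliance x growth-form matrix: alliance means of the relevé maxima."""
    df = validate_releves(df)
    per_releve = releve_matrix(df)
    alliance_of = (df.drop_duplicates("releve_id")
                   .set_index("releve_id")["alliance_id"])
    return per_releve.groupby(alliance_of.reindex(per_releve.index)).mean()


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series
    centroids: pd.DataFrame
    wss: np.ndarray  # within-cluster sum of squares for k = 1..k_max


def cluster_alliances(matrix: pd.DataFrame, k_max: int = 10,
                      seed: int = 0) -> ClusterResult:
    """Consolidate alliances into vegetation types via elbow/k-means.

    Runs k-means for k = 1..k_max (10 restarts, fixed seed) and picks the
    elbow as the k maximizing the second difference of the within-cluster
    sum of squares on the log scale — the point of strongest relative
    flattening of the WSS curve, which is robust to one dominant split
    (e.g. woodland vs treeless types) dwarfing the absolute differences.
    A degenerate matrix (all rows identical) yields k = 1.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if len(matrix) < k_max:
        raise ValueError(f"need at least k_max={k_max} rows, got {len(matrix)}")
    X = matrix.to_numpy(dtype=float)
    fits = []
    wss = np.empty(k_max)
    with warnings.catch_warnings():
        # duplicate rows legitimately yield fewer distinct clusters than k
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        for k in range(1, k_max + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
            fits.append(km)
            wss[k - 1] = km.inertia_
    if wss[0] <= 1e-9:  # all rows identical
        best_k = 1
    else:
        # second difference of log WSS over interior k; +2 maps back to k
        lw = np.log(np.maximum(wss, 1e-9))
        d2 = lw[:-2] - 2.0 * lw[1:-1] + lw[2:]
        best_k = int(np.argmax(d2)) + 2
    km = fits[best_k - 1]
    assignments = pd.Series(km.labels_, index=matrix.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, columns=matrix.columns)
    return ClusterResult(best_k, assignments, centroids, wss)
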