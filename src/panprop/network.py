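"""Co-occurrence networks from normalized abundance tables.

Association is Spearman's rank correlation (midranks for ties). Significance
defaults to a seeded permutation test (appropriate for short reactor series),
with the t approximation available as a documented option; Benjamini-Hochberg
correction is applied once across all tested pairs, and edges require both
|rho| >= rho_min and q <= q_max. Partners of a focal taxon are ranked by
descending rho, and taxa can be correlated against environmental covariates
(e.g. propionate concentration) the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceTable",
    "NetworkEdge",
    "normalize_counts",
    "spearman_matrix",
    "build_network",
    "focal_partners",
    "covariate_correlation",
    "edges_frame",
    "to_networkx",
]

_ROW_SUM_TOL = 1e-9


@dataclass
class AbundanceTable:
    """Samples-by-taxa abundances (counts or relative); nonnegative."""

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("abundances must be nonnegative")
        if self.normalized:
            sums = self.data.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=_ROW_SUM_TOL):
                raise ValueError("normalized table rows must each sum to 1")


@dataclass(frozen=True)
class NetworkEdge:
    taxon_a: str
    taxon_b: str
    rho: float
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.taxon_a == self.taxon_b:
            raise ValueError("self-edges are not allowed")


def normalize_counts(table: AbundanceTable | pd.DataFrame) -> AbundanceTable:
    """Total-sum scaling to relative abundance; all-zero samples are dropped.

    Idempotent: an already-normalized table is returned unchanged.
    """
    df = table.data if isinstance(table, AbundanceTable) else table
    if (df.values < 0).any():
        raise ValueError("abundances must be nonnegative")
    sums = df.sum(axis=1)
    zero = sums == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} all-zero sample(s): "
            f"{df.index[zero].tolist()}"
        )
        df = df.loc[~zero]
        sums = sums[~zero]
    return AbundanceTable(data=df.div(sums, axis=0), normalized=True)


def _midranks(x: np.ndarray) -> np.ndarray:
    """Column-wise average ranks (midranks for ties)."""
    return np.apply_along_axis(stats.rankdata, 0, x)


def _standardize(r: np.ndarray) -> np.ndarray:
    r = r - r.mean(axis=0)
    sd = np.sqrt((r ** 2).sum(axis=0))
    return r / sd


def _permutation_pvalues(
    ranks: np.ndarray,
    rho_obs: np.ndarray,
    n_permutations: int,
    seed: int,
    block: int = 500,
) -> np.ndarray:
    """Two-sided permutation p-values for every pair, batched.

    Each permutation shuffles every taxon's sample order independently, giving a
    valid draw from the pairwise null for all pairs at once; null correlations
    are computed by batched matrix products over standardized ranks.
    """
    n, t = ranks.shape
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31]))
    exceed = np.zeros((t, t), dtype=np.int64)
    done = 0
    while done < n_permutations:
        b = min(block, n_permutations - done)
        idx = np.argsort(rng.random((b, n, t)), axis=1)
        perm = np.take_along_axis(np.broadcast_to(ranks, (b, n, t)), idx, axis=1)
        z = perm - perm.mean(axis=1, keepdims=True)
        z /= np.sqrt((z ** 2).sum(axis=1, keepdims=True))
        null = np.einsum("bni,bnj->bij", z, z)
        exceed += (np.abs(null) >= np.abs(rho_obs)[None] - 1e-12).sum(axis=0)
        done += b
    return (1.0 + exceed) / (n_permutations + 1.0)


def _t_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), n - 2)


def spearman_matrix(
    table: AbundanceTable | pd.DataFrame,
    prevalence_min: float = 0.2,
    method: str = "permutation",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p-values.

    Taxa present (nonzero) in fewer than ``prevalence_min`` of samples are
    excluded before testing, as are constant taxa (warned, not NaN-filled).
    ``method`` is ``"permutation"`` (default, seeded) or ``"t"``.
    """
    df = table.data if isinstance(table, AbundanceTable) else table
    n = len(df)
    if n < 4:
        raise ValueError("need >= 4 samples for Spearman correlation")

    prev = (df > 0).mean(axis=0)
    keep = prev >= prevalence_min
    dropped = df.columns[~keep].tolist()
    if dropped:
        warnings.warn(f"excluding {len(dropped)} low-prevalence taxa: {dropped}")
    df = df.loc[:, keep]
    const = df.nunique(axis=0) <= 1
    if const.any():
        warnings.warn(
            f"excluding constant taxa (rho undefined): {df.columns[const].tolist()}"
        )
        df = df.loc[:, ~const]
    if df.shape[1] < 2:
        raise ValueError("fewer than two testable taxa after filtering")

    ranks = _midranks(df.to_numpy(dtype=float))
    z = _standardize(ranks)
    rho = z.T @ z
    np.fill_diagonal(rho, 1.0)

    if method == "permutation":
        p = _permutation_pvalues(ranks, rho, n_permutations, seed)
    elif method == "t":
        p = _t_pvalues(rho, n)
    else:
        raise ValueError("method must be 'permutation' or 't'")
    np.fill_diagonal(p, 0.0)

    cols = df.columns
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    rho_min: float = 0.6,
    q_max: float = 0.05,
) -> list[NetworkEdge]:
    """Threshold correlations into edges after a single BH pass over all pairs."""
    if not (rho.shape == p.shape and rho.index.equals(p.index)
            and rho.columns.equals(p.columns)):
        raise ValueError("rho and p matrices must be aligned")
    from statsmodels.stats.multitest import multipletests

    taxa = rho.columns.to_list()
    iu = np.triu_indices(len(taxa), k=1)
    pvals = p.to_numpy()[iu]
    rhos = rho.to_numpy()[iu]
    if pvals.size == 0:
        return []
    q = multipletests(pvals, method="fdr_bh")[1]
    edges = [
        NetworkEdge(taxon_a=taxa[i], taxon_b=taxa[j], rho=float(r),
                    p_value=float(pv), q_value=float(qv))
        for i, j, r, pv, qv in zip(iu[0], iu[1], rhos, pvals, q)
        if abs(r) >= rho_min and qv <= q_max
    ]
    return edges


def focal_partners(
    edges: Sequence[NetworkEdge],
    focal_taxon: str,
    top_k: int | None = None,
    tested_taxa: Sequence[str] | None = None,
) -> list[tuple[str, float]]:
    """Partners of the focal taxon ranked by descending rho (ties by id)."""
    if tested_taxa is not None and focal_taxon not in tested_taxa:
        raise ValueError(f"focal taxon {focal_taxon!r} not in the tested set")
    partners = []
    seen_focal = tested_taxa is not None
    for e in edges:
        if focal_taxon in (e.taxon_a, e.taxon_b):
            seen_focal = True
            other = e.taxon_b if e.taxon_a == focal_taxon else e.taxon_a
            partners.append((other, e.rho))
    if not seen_focal:
        raise ValueError(f"focal taxon {focal_taxon!r} not present in the edge set")
    partners.sort(key=lambda pr: (-pr[1], pr[0]))
    if top_k is not None:
        partners = partners[: max(top_k, 0)]
    return partners


def covariate_correlation(
    table: AbundanceTable | pd.DataFrame,
    taxon: str,
    covariate: Sequence[float] | pd.Series,
    method: str = "permutation",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rho and p between one taxon and an environmental covariate."""
    df = table.data if isinstance(table, AbundanceTable) else table
    if taxon not in df.columns:
        raise ValueError(f"unknown taxon {taxon!r}")
    y = np.asarray(covariate, dtype=float)
    x = df[taxon].to_numpy(dtype=float)
    if len(y) != len(x):
        raise ValueError("covariate length does not match the sample count")
    if len(x) < 4:
        raise ValueError("need >= 4 paired observations")

    rx, ry = stats.rankdata(x), stats.rankdata(y)
    zx = (rx - rx.mean()) / np.sqrt(((rx - rx.mean()) ** 2).sum())
    zy = (ry - ry.mean()) / np.sqrt(((ry - ry.mean()) ** 2).sum())
    rho = float(zx @ zy)

    if method == "t":
        p = float(_t_pvalues(np.array([rho]), len(x))[0])
    elif method == "permutation":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 32]))
        perm = np.array([zx @ zy[rng.permutation(len(y))] for _ in range(n_permutations)])
        p = float((1 + np.sum(np.abs(perm) >= abs(rho) - 1e-12)) / (n_permutations + 1))
    else:
        raise ValueError("method must be 'permutation' or 't'")
    return rho, p


def edges_frame(edges: Sequence[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"taxon_a": e.taxon_a, "taxon_b": e.taxon_b, "rho": e.rho,
             "p_value": e.p_value, "q_value": e.q_value}
            for e in edges
        ],
        columns=["taxon_a", "taxon_b", "rho", "p_value", "q_value"],
    )


def to_networkx(edges: Sequence[NetworkEdge]):
    """Edge list as a networkx graph (for GraphML export)."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_edge(e.taxon_a, e.taxon_b, rho=e.rho, p=e.p_value, q=e.q_value)
    return g


def write_edges_tsv(edges: Sequence[NetworkEdge], path: str | Path,
                    header: str = "") -> None:
    with Path(path).open("w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        edges_frame(edges).to_csv(fh, sep="\t", index=False)
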