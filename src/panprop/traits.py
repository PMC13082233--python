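"""KO incidence/count matrices, group prevalence, habitat enrichment and the
phylum-marker criterion.

The marker rule classifies a gene family (KO) as a phylum marker when it is
present in at least ``p_in`` of the focal-phylum genomes and absent from at
least ``p_out`` of the other genomes (both inclusive; defaults 75%/75%, i.e.
present in at most 25% of the others). Habitat enrichment mirrors a
linear-model design on raw KO counts with Benjamini-Hochberg correction and no
normalization or transformation: per KO, an ordinary least-squares fit of the
count on a two-level habitat indicator, with the second habitat coded 1 so that
enrichment in the first habitat yields a negative coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KoMatrix",
    "EnrichmentResult",
    "MarkerCriteria",
    "build_ko_matrix",
    "prevalence",
    "phylum_markers",
    "habitat_enrichment",
    "enrichment_frame",
]


@dataclass
class KoMatrix:
    """Genomes-by-KO count matrix with per-genome group labels.

    ``counts`` rows are genome ids, columns KO ids, values integer counts >= 0
    (incidence is ``counts > 0``). ``meta`` is indexed by genome id and carries
    the grouping columns used downstream (``habitat``, ``focal``, ``clade``).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            missing = self.counts.index.difference(self.meta.index).tolist()
            extra = self.meta.index.difference(self.counts.index).tolist()
            raise ValueError(
                f"counts and meta must index the same genomes "
                f"(missing from meta: {missing}; extra in meta: {extra})"
            )
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise ValueError("duplicate genome or KO ids")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def incidence(self) -> pd.DataFrame:
        return (self.counts > 0).astype(np.int8)


@dataclass(frozen=True)
class MarkerCriteria:
    """Inclusive prevalence bounds of the phylum-marker rule."""

    p_in: float = 0.75
    p_out: float = 0.75

    def __post_init__(self) -> None:
        for v in (self.p_in, self.p_out):
            if not (0.0 < v <= 1.0):
                raise ValueError("marker criteria must lie in (0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    ko_id: str
    coef: float
    p_value: float
    q_value: float
    enriched_in: str


def build_ko_matrix(
    annotations: pd.DataFrame | str | Path,
    metadata: pd.DataFrame | str | Path,
) -> KoMatrix:
    """Pivot a long annotation table (genome_id, ko_id[, count]) into a KoMatrix.

    Duplicate (genome, KO) rows are summed; genomes present in the metadata but
    absent from the annotations get all-zero rows; annotations referencing
    genomes unknown to the metadata raise an error listing the offenders.
    """
    if not isinstance(annotations, pd.DataFrame):
        annotations = pd.read_csv(annotations, sep="\t", comment="#")
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, sep="\t", comment="#")
    if "genome_id" in metadata.columns:
        metadata = metadata.set_index("genome_id")

    needed = {"genome_id", "ko_id"}
    if not needed.issubset(annotations.columns):
        raise ValueError(f"annotations must have columns {sorted(needed)}")
    ann = annotations.copy()
    if "count" not in ann.columns:
        ann["count"] = 1
    if not np.issubdtype(np.asarray(ann["count"]).dtype, np.number):
        raise ValueError("annotation counts must be numeric")

    unknown = sorted(set(ann["genome_id"]) - set(metadata.index))
    if unknown:
        raise ValueError(f"annotations reference genomes absent from metadata: {unknown}")

    if ann.empty:
        warnings.warn("empty annotation table; building an all-zero KO matrix")
        counts = pd.DataFrame(
            np.zeros((len(metadata), 0), dtype=np.int64), index=metadata.index
        )
    else:
        counts = (
            ann.pivot_table(index="genome_id", columns="ko_id", values="count",
                            aggfunc="sum", fill_value=0)
            .reindex(metadata.index, fill_value=0)
            .astype(np.int64)
        )
        counts.columns.name = None
    counts.index.name = "genome_id"
    return KoMatrix(counts=counts, meta=metadata)


def prevalence(matrix: KoMatrix, group: str, by: str = "habitat") -> pd.Series:
    """Per-KO fraction of the group's genomes carrying the KO.

    The denominator is the number of genomes in the group, not the number with
    any annotation.
    """
    if by not in matrix.meta.columns:
        raise ValueError(f"metadata has no column {by!r}")
    mask = matrix.meta[by] == group
    if not mask.any():
        raise ValueError(f"unknown or empty group {group!r} in column {by!r}")
    return matrix.incidence.loc[mask.values].mean(axis=0).rename(f"prevalence_{group}")


def _focal_mask(matrix: KoMatrix, focal_flag: str | pd.Series) -> pd.Series:
    if isinstance(focal_flag, str):
        if focal_flag not in matrix.meta.columns:
            raise ValueError(f"metadata has no column {focal_flag!r}")
        mask = matrix.meta[focal_flag].astype(bool)
    else:
        mask = focal_flag.reindex(matrix.meta.index).astype(bool)
    return mask


def phylum_markers(
    matrix: KoMatrix,
    focal_flag: str | pd.Series = "focal",
    criteria: MarkerCriteria = MarkerCriteria(),
) -> pd.DataFrame:
    """KOs present in >= p_in of focal genomes and absent in >= p_out of others.

    Inclusive inequalities: a KO at exactly 75% focal prevalence and exactly 25%
    background prevalence qualifies at the defaults. Returns a table indexed by
    ko_id with columns ``prev_focal`` and ``prev_other``.
    """
    mask = _focal_mask(matrix, focal_flag)
    if not mask.any():
        raise ValueError("empty focal set")
    if mask.all():
        raise ValueError("empty background set")
    inc = matrix.incidence
    prev_in = inc.loc[mask.values].mean(axis=0)
    prev_out = inc.loc[~mask.values].mean(axis=0)
    # float-tolerant inclusive bounds so exact-boundary prevalences qualify
    eps = 1e-12
    hit = (prev_in >= criteria.p_in - eps) & ((1.0 - prev_out) >= criteria.p_out - eps)
    out = pd.DataFrame({"prev_focal": prev_in[hit], "prev_other": prev_out[hit]})
    out.index.name = "ko_id"
    return out.sort_index()


def habitat_enrichment(
    matrix: KoMatrix,
    habitats: Sequence[str] = ("AD", "aquatic"),
    q_threshold: float = 0.05,
    use_incidence: bool = False,
) -> list[EnrichmentResult]:
    """Per-KO linear-model enrichment between two habitats with BH correction.

    For each KO, the raw count (or 0/1 incidence with ``use_incidence``) is
    regressed on a habitat indicator coding ``habitats[1]`` as 1 and
    ``habitats[0]`` as 0, so enrichment in the first habitat yields coef < 0
    (with the default pair, AD-enrichment is coef < 0 and aquatic coef > 0).
    Two-sided p-values come from the coefficient's t statistic (the closed-form
    OLS slope test; identical to the pooled-variance two-group comparison).
    KOs with zero variance across both groups are reported with coef 0, p 1.
    """
    if len(habitats) != 2 or habitats[0] == habitats[1]:
        raise ValueError("exactly two distinct habitats are required")
    g0 = matrix.meta["habitat"] == habitats[0]
    g1 = matrix.meta["habitat"] == habitats[1]
    n0, n1 = int(g0.sum()), int(g1.sum())
    for label, n in ((habitats[0], n0), (habitats[1], n1)):
        if n < 3:
            raise ValueError(f"habitat group {label!r} has {n} genomes; need >= 3")

    data = matrix.incidence if use_incidence else matrix.counts
    if not all(np.issubdtype(dt, np.number) for dt in data.dtypes):
        raise ValueError("KO counts must be numeric")
    x0 = data.loc[g0.values].to_numpy(dtype=float)
    x1 = data.loc[g1.values].to_numpy(dtype=float)

    mean0, mean1 = x0.mean(axis=0), x1.mean(axis=0)
    coef = mean1 - mean0  # OLS slope on the 0/1 indicator
    ss = ((x0 - mean0) ** 2).sum(axis=0) + ((x1 - mean1) ** 2).sum(axis=0)
    df = n0 + n1 - 2
    se = np.sqrt(ss / df * (1.0 / n0 + 1.0 / n1))

    p = np.ones_like(coef)
    degenerate = (ss == 0) & (coef == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / np.where(se > 0, se, 1.0), np.inf * np.sign(coef))
    testable = ~degenerate
    p[testable] = 2.0 * stats.t.sf(np.abs(t[testable]), df)
    p[degenerate] = 1.0
    coef = np.where(degenerate, 0.0, coef)

    q = multipletests(p, method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            ko_id=str(ko),
            coef=float(c),
            p_value=float(pv),
            q_value=float(qv),
            enriched_in=habitats[1] if c > 0 else (habitats[0] if c < 0 else ""),
        )
        for ko, c, pv, qv in zip(data.columns, coef, p, q)
    ]
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Enrichment results as a tidy table (ko_id, coef, p, q, enriched_in)."""
    return pd.DataFrame(
        [
            {"ko_id": r.ko_id, "coef": r.coef, "p_value": r.p_value,
             "q_value": r.q_value, "enriched_in": r.enriched_in}
            for r in results
        ]
    )
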