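"""Genome quality filtering, sketch-based ANI estimation and species clustering.

The species-level dereplication follows the operational criterion that two
genomes below 96.5% average nucleotide identity (ANI) over at least 60% of the
aligned genome represent distinct species. ANI is estimated alignment-free from
canonical k-mer bottom sketches via the sketch-distance identity

    ANI = 1 + (1/k) * ln(2j / (1 + j)),

where ``j`` is the bottom-sketch Jaccard estimate, and the aligned-fraction
criterion is proxied by the containment of the smaller genome's distinct k-mers
in the larger genome's full k-mer set. Clustering is greedy and quality-ranked
(leader clustering): genomes are processed in decreasing quality-score order and
join the first cluster whose representative they match at both thresholds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeRecord",
    "AniEstimate",
    "GenomeCluster",
    "quality_filter",
    "estimate_ani",
    "estimate_ani_matrix",
    "cluster_genomes",
    "select_representative",
    "quality_score",
    "read_genomes_fasta",
    "read_ani_table",
    "write_ani_table",
    "write_cluster_table",
]


@dataclass(frozen=True)
class GenomeRecord:
    """A genome with quality metrics and habitat/clade labels."""

    genome_id: str
    sequence: str | None = None
    path: str | None = None
    completeness: float | None = None
    contamination: float | None = None
    habitat: str = ""
    clade: str = ""

    def get_sequence(self) -> str:
        if self.sequence is not None:
            return self.sequence
        if self.path is not None:
            from Bio import SeqIO

            return "".join(str(rec.seq) for rec in SeqIO.parse(self.path, "fasta"))
        raise ValueError(f"genome {self.genome_id!r} has neither sequence nor path")


@dataclass(frozen=True)
class AniEstimate:
    """Pairwise ANI with an aligned-fraction (coverage) proxy; unordered pair."""

    genome_a: str
    genome_b: str
    ani: float
    aligned_fraction: float
    below_detection: bool = False

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.genome_a, self.genome_b))


@dataclass(frozen=True)
class GenomeCluster:
    cluster_id: str
    representative_id: str
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a cluster member")


def quality_score(completeness: float, contamination: float) -> float:
    """dRep-style winner score: completeness - 5 * contamination."""
    return completeness - 5.0 * contamination


def quality_filter(
    genomes: Sequence[GenomeRecord],
    min_completeness: float = 0.50,
    max_contamination: float = 0.10,
) -> list[GenomeRecord]:
    """Keep genomes with completeness strictly above and contamination strictly
    below the thresholds (medium-to-high-quality MAG criterion)."""
    kept = []
    for g in genomes:
        for metric, name in ((g.completeness, "completeness"),
                             (g.contamination, "contamination")):
            if metric is None or not math.isfinite(metric):
                raise ValueError(f"genome {g.genome_id!r} is missing {name}")
        if g.completeness > min_completeness and g.contamination < max_contamination:
            kept.append(g)
    return kept


# --------------------------------------------------------------------------- #
# k-mer machinery

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[ord(chr(_b).lower())] = _i


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Stable 64-bit mixer (splitmix64 finalizer); deterministic across runs."""
    z = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def canonical_kmer_hashes(seq: str, k: int = 21) -> np.ndarray:
    """Sorted distinct hashes of canonical (strand-minimum) k-mers.

    Windows containing non-ACGT characters are dropped. 2k bits must fit a
    64-bit word (k <= 31).
    """
    if k < 1 or k > 31:
        raise ValueError("k must lie in [1, 31]")
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    codes = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    valid = codes != 255
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    w = windows[ok].astype(np.uint64)
    if w.size == 0:
        return np.empty(0, dtype=np.uint64)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = w @ powers
    rev = (np.uint64(3) - w) @ powers[::-1]
    canon = np.minimum(fwd, rev)
    return np.unique(_splitmix64(canon))


def estimate_ani(
    seq_a: str,
    seq_b: str,
    k: int = 21,
    sketch_size: int = 1000,
    genome_a: str = "a",
    genome_b: str = "b",
) -> AniEstimate:
    """Sketch-based ANI between two sequences.

    The Jaccard index of the two canonical k-mer sets is estimated from the
    bottom-``sketch_size`` hashes of their union; disjoint sketches yield an ANI
    of 0 flagged ``below_detection`` rather than an exception. The aligned
    fraction is the containment of the smaller genome's distinct k-mers in the
    larger genome's full k-mer set.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    ha = canonical_kmer_hashes(seq_a, k)
    hb = canonical_kmer_hashes(seq_b, k)
    if ha.size == 0 or hb.size == 0:
        raise ValueError("no valid k-mers (sequence shorter than k or all ambiguous)")

    union = np.union1d(ha, hb)
    s = min(sketch_size, union.size)
    bottom = union[:s]  # union1d returns sorted hashes
    shared = int(np.isin(bottom, ha, assume_unique=True).sum()
                 + np.isin(bottom, hb, assume_unique=True).sum()) - s
    j = shared / s

    small, large = (ha, hb) if ha.size <= hb.size else (hb, ha)
    aligned_fraction = float(np.isin(small, large, assume_unique=True).mean())

    if j <= 0:
        return AniEstimate(genome_a, genome_b, 0.0, aligned_fraction, below_detection=True)
    ani = 1.0 + math.log(2.0 * j / (1.0 + j)) / k
    return AniEstimate(genome_a, genome_b, min(max(ani, 0.0), 1.0), aligned_fraction)


def estimate_ani_matrix(
    genomes: Sequence[GenomeRecord], k: int = 21, sketch_size: int = 1000
) -> list[AniEstimate]:
    """All-pairs sketch ANI (hashes computed once per genome)."""
    hashes = {g.genome_id: canonical_kmer_hashes(g.get_sequence(), k) for g in genomes}
    out: list[AniEstimate] = []
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1:]:
            ha, hb = hashes[ga.genome_id], hashes[gb.genome_id]
            union = np.union1d(ha, hb)
            s = min(sketch_size, union.size)
            bottom = union[:s]
            shared = int(np.isin(bottom, ha, assume_unique=True).sum()
                         + np.isin(bottom, hb, assume_unique=True).sum()) - s
            j = shared / s
            small, large = (ha, hb) if ha.size <= hb.size else (hb, ha)
            af = float(np.isin(small, large, assume_unique=True).mean())
            if j <= 0:
                out.append(AniEstimate(ga.genome_id, gb.genome_id, 0.0, af, True))
            else:
                ani = 1.0 + math.log(2.0 * j / (1.0 + j)) / k
                out.append(AniEstimate(ga.genome_id, gb.genome_id,
                                       min(max(ani, 0.0), 1.0), af))
    return out


# --------------------------------------------------------------------------- #
# clustering


def _pair_lookup(ani: Iterable[AniEstimate]) -> dict[frozenset[str], AniEstimate]:
    table: dict[frozenset[str], AniEstimate] = {}
    for est in ani:
        table[est.pair] = est
    return table


def cluster_genomes(
    ani: Sequence[AniEstimate],
    genomes: Sequence[GenomeRecord],
    ani_threshold: float = 0.965,
    min_aligned_fraction: float = 0.60,
) -> list[GenomeCluster]:
    """Greedy quality-ranked leader clustering into species-level clusters.

    Genomes are sorted by quality score (completeness - 5*contamination)
    descending, ties broken lexicographically by id. Each genome joins the first
    existing cluster whose representative it matches at ``ani >= ani_threshold``
    and ``aligned_fraction >= min_aligned_fraction``; otherwise it founds a new
    cluster and becomes its representative. Pairs absent from ``ani`` (including
    below-detection sketch pairs) are treated as non-matching. Deterministic.
    """
    if not (0.0 < ani_threshold <= 1.0):
        raise ValueError("ani_threshold must lie in (0, 1]")
    if not (0.0 <= min_aligned_fraction <= 1.0):
        raise ValueError("min_aligned_fraction must lie in [0, 1]")
    lookup = _pair_lookup(ani)

    def sort_key(g: GenomeRecord):
        score = quality_score(g.completeness or 0.0, g.contamination or 0.0)
        return (-score, g.genome_id)

    ordered = sorted(genomes, key=sort_key)
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for g in ordered:
        placed = False
        for rep in reps:
            est = lookup.get(frozenset((g.genome_id, rep)))
            if est is None or est.below_detection:
                continue
            if est.ani >= ani_threshold and est.aligned_fraction >= min_aligned_fraction:
                members[rep].append(g.genome_id)
                placed = True
                break
        if not placed:
            reps.append(g.genome_id)
            members[g.genome_id] = [g.genome_id]
    return [
        GenomeCluster(
            cluster_id=f"GC{i + 1}",
            representative_id=rep,
            member_ids=tuple(members[rep]),
        )
        for i, rep in enumerate(reps)
    ]


def select_representative(
    cluster: GenomeCluster | Sequence[str],
    genome_meta: Mapping[str, tuple[float, float]] | Sequence[GenomeRecord],
) -> str:
    """Best-quality member: argmax of completeness - 5*contamination, ties by id."""
    member_ids = (
        list(cluster.member_ids) if isinstance(cluster, GenomeCluster) else list(cluster)
    )
    if not member_ids:
        raise ValueError("empty cluster")
    if not isinstance(genome_meta, Mapping):
        genome_meta = {
            g.genome_id: (g.completeness or 0.0, g.contamination or 0.0)
            for g in genome_meta
        }
    scored = sorted(
        member_ids, key=lambda m: (-quality_score(*genome_meta[m]), m)
    )
    return scored[0]


# --------------------------------------------------------------------------- #
# IO


def read_genomes_fasta(paths: Mapping[str, str | Path],
                       metadata: pd.DataFrame | None = None) -> list[GenomeRecord]:
    """Load genomes from FASTA files keyed by genome id; optional metadata table
    (indexed by genome_id, columns completeness/contamination/habitat/clade)."""
    from Bio import SeqIO

    records = []
    for gid, path in paths.items():
        seq = "".join(str(rec.seq) for rec in SeqIO.parse(str(path), "fasta"))
        kwargs = {}
        if metadata is not None and gid in metadata.index:
            row = metadata.loc[gid]
            kwargs = {
                "completeness": float(row.get("completeness", np.nan)),
                "contamination": float(row.get("contamination", np.nan)),
                "habitat": str(row.get("habitat", "")),
                "clade": str(row.get("clade", "")),
            }
        records.append(GenomeRecord(genome_id=gid, sequence=seq, path=str(path), **kwargs))
    return records


def read_ani_table(path: str | Path) -> list[AniEstimate]:
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"genome_a", "genome_b", "ani", "aligned_fraction"}
    if not needed.issubset(df.columns):
        raise ValueError(f"ANI table must have columns {sorted(needed)}")
    return [
        AniEstimate(r.genome_a, r.genome_b, float(r.ani), float(r.aligned_fraction))
        for r in df.itertuples()
    ]


def write_ani_table(ani: Sequence[AniEstimate], path: str | Path, header: str = "") -> None:
    df = pd.DataFrame(
        [
            {
                "genome_a": e.genome_a,
                "genome_b": e.genome_b,
                "ani": e.ani,
                "aligned_fraction": e.aligned_fraction,
                "below_detection": e.below_detection,
            }
            for e in ani
        ]
    )
    with Path(path).open("w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_cluster_table(clusters: Sequence[GenomeCluster], path: str | Path,
                        header: str = "") -> None:
    rows = [
        {"cluster_id": c.cluster_id, "representative_id": c.representative_id,
         "member_id": m}
        for c in clusters
        for m in c.member_ids
    ]
    with Path(path).open("w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    summary = {"n_genomes": sum(len(c.member_ids) for c in clusters),
               "n_clusters": len(clusters)}
    Path(str(path) + ".summary.json").write_text(json.dumps(summary, indent=2) + "\n")
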