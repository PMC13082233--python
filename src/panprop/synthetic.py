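"""Ground-truthed synthetic inputs for every downstream analysis stage.

Three generators emulate the statistical structure the analyses assume:

* :func:`simulate_pangenome` — a focal phylum versus background genomes with
  shared/core/accessory gene-family (KO) structure, planted phylum markers,
  completeness-driven binomial gene dropout and contamination false-presences.
* :func:`simulate_sequence_pair` — nucleotide sequence pairs at a controlled
  divergence (uniform substitutions over the three alternative bases, no indels),
  the fixture for the sketch ANI estimator.
* :func:`simulate_abundance_series` — compositional abundance series with planted
  monotone taxon-taxon and taxon-covariate associations.

All randomness flows from one explicit integer seed per config through
``numpy.random.SeedSequence([seed, stream])`` with fixed per-purpose stream tags,
so outputs are bit-identical across runs and platforms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PangenomeConfig",
    "PangenomeTruth",
    "AbundanceSeriesConfig",
    "AbundanceSeries",
    "SequencePair",
    "simulate_pangenome",
    "simulate_sequence_pair",
    "simulate_abundance_series",
    "write_pangenome",
    "write_abundance_series",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Invalid generator configuration."""


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Child generator for one purpose; stream tags keep draws independent."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


# --------------------------------------------------------------------------- #
# pangenome


@dataclass(frozen=True)
class PangenomeConfig:
    """Study conditions for one synthetic pangenome.

    Defaults emulate a modest focal-phylum collection against an AD background:
    60 focal and 40 background genomes, medium-to-high completeness, a small
    planted marker set, and habitat labels split between anaerobic-digester and
    aquatic origins.
    """

    n_focal: int = 60
    n_background: int = 40
    n_core_focal: int = 100
    n_markers: int = 10
    n_shared: int = 200
    n_accessory: int = 200
    completeness_range: tuple[float, float] = (0.9, 1.0)
    contamination_rate: float = 0.01
    habitats: Sequence[tuple[str, int, int]] | None = None  # (label, n_focal, n_background)
    core_focal_prevalence: float = 0.95
    core_background_prevalence: float = 0.5
    accessory_prevalence_range: tuple[float, float] = (0.1, 0.9)
    marker_focal_fraction: float = 1.0
    marker_background_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_focal", "n_background", "n_core_focal", "n_markers",
                     "n_shared", "n_accessory"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.completeness_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("completeness_range must be ordered and within [0, 1]")
        if not (0.0 <= self.contamination_rate <= 0.1):
            raise ConfigError("contamination_rate must lie in [0, 0.1]")
        if self.n_focal + self.n_background == 0:
            raise ConfigError("need at least one genome")
        if self.n_core_focal + self.n_markers + self.n_shared + self.n_accessory == 0:
            raise ConfigError("need at least one KO")
        if not (0.0 <= self.marker_focal_fraction <= 1.0):
            raise ConfigError("marker_focal_fraction must lie in [0, 1]")
        if not (0.0 <= self.marker_background_fraction <= 1.0):
            raise ConfigError("marker_background_fraction must lie in [0, 1]")


@dataclass
class PangenomeTruth:
    """A simulated pangenome with its generating ground truth."""

    true_matrix: pd.DataFrame  # genomes x KOs, 0/1 before dropout
    observed_matrix: pd.DataFrame  # genomes x KOs, 0/1 after dropout + contamination
    marker_kos: set[str]
    genome_meta: pd.DataFrame  # genome_id-indexed: focal, habitat, clade, completeness, contamination
    config: PangenomeConfig | None = None


def _habitat_assignment(cfg: PangenomeConfig) -> tuple[list[str], list[str]]:
    if cfg.habitats is None:
        plan = [
            ("AD", (cfg.n_focal + 1) // 2, (cfg.n_background + 1) // 2),
            ("aquatic", cfg.n_focal // 2, cfg.n_background // 2),
        ]
    else:
        plan = list(cfg.habitats)
        if sum(p[1] for p in plan) != cfg.n_focal:
            raise ConfigError("habitat focal counts must sum to n_focal")
        if sum(p[2] for p in plan) != cfg.n_background:
            raise ConfigError("habitat background counts must sum to n_background")
    focal = [label for label, nf, _ in plan for _ in range(nf)]
    background = [label for label, _, nb in plan for _ in range(nb)]
    return focal, background


_CLADE_BY_HABITAT = {"AD": "I", "aquatic": "II", "landfill": "IV"}


def simulate_pangenome(config: PangenomeConfig) -> PangenomeTruth:
    """Simulate a genomes-by-KO incidence matrix with known planted structure.

    The true matrix plants four KO classes: shared (present everywhere), focal
    core (high prevalence in the focal phylum, intermediate in the background),
    markers (present in ``marker_focal_fraction`` of focal genomes and
    ``marker_background_fraction`` of background genomes), and accessory KOs at
    a per-KO random intermediate prevalence common to both groups. The observed
    matrix retains each true gene independently with probability equal to the
    genome's completeness and adds each absent KO with probability
    ``contamination_rate`` (checkM-style completeness/contamination semantics).
    """
    cfg = config
    n_g = cfg.n_focal + cfg.n_background
    focal_hab, bg_hab = _habitat_assignment(cfg)

    genome_ids = [f"G{i + 1:04d}" for i in range(n_g)]
    focal_mask = np.zeros(n_g, dtype=bool)
    focal_mask[: cfg.n_focal] = True
    habitats = focal_hab + bg_hab

    ko_classes = (
        [("shared", i) for i in range(cfg.n_shared)]
        + [("core", i) for i in range(cfg.n_core_focal)]
        + [("marker", i) for i in range(cfg.n_markers)]
        + [("accessory", i) for i in range(cfg.n_accessory)]
    )
    ko_ids = [f"K{i + 1:05d}" for i in range(len(ko_classes))]
    marker_cols = [k for k, (cls, _) in zip(ko_ids, ko_classes) if cls == "marker"]

    rng_true = _rng(cfg.seed, 1)
    true = np.zeros((n_g, len(ko_ids)), dtype=np.int8)
    for j, (cls, _) in enumerate(ko_classes):
        if cls == "shared":
            true[:, j] = 1
        elif cls == "core":
            true[focal_mask, j] = rng_true.random(cfg.n_focal) < cfg.core_focal_prevalence
            true[~focal_mask, j] = (
                rng_true.random(cfg.n_background) < cfg.core_background_prevalence
            )
        elif cls == "marker":
            k_in = int(round(cfg.marker_focal_fraction * cfg.n_focal))
            k_out = int(round(cfg.marker_background_fraction * cfg.n_background))
            rows_in = rng_true.choice(cfg.n_focal, size=k_in, replace=False)
            rows_out = rng_true.choice(cfg.n_background, size=k_out, replace=False)
            true[rows_in, j] = 1
            true[cfg.n_focal + rows_out, j] = 1
        else:  # accessory: one prevalence per KO, common to both groups
            lo, hi = cfg.accessory_prevalence_range
            p = rng_true.uniform(lo, hi)
            true[:, j] = rng_true.random(n_g) < p

    rng_qc = _rng(cfg.seed, 2)
    lo, hi = cfg.completeness_range
    completeness = rng_qc.uniform(lo, hi, size=n_g)
    contamination = np.full(n_g, cfg.contamination_rate)

    rng_obs = _rng(cfg.seed, 3)
    retain = rng_obs.random(true.shape) < completeness[:, None]
    spurious = rng_obs.random(true.shape) < contamination[:, None]
    observed = ((true == 1) & retain) | ((true == 0) & spurious)

    meta = pd.DataFrame(
        {
            "focal": focal_mask,
            "habitat": habitats,
            "clade": [
                _CLADE_BY_HABITAT.get(h, "III") if f else "other"
                for h, f in zip(habitats, focal_mask)
            ],
            "completeness": completeness,
            "contamination": contamination,
        },
        index=pd.Index(genome_ids, name="genome_id"),
    )
    return PangenomeTruth(
        true_matrix=pd.DataFrame(true, index=meta.index, columns=ko_ids),
        observed_matrix=pd.DataFrame(
            observed.astype(np.int8), index=meta.index, columns=ko_ids
        ),
        marker_kos=set(marker_cols),
        genome_meta=meta,
        config=cfg,
    )


def write_pangenome(truth: PangenomeTruth, outdir: str | Path, header: str = "") -> dict:
    """Write observed matrix (long TSV), metadata TSV and a JSON truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obs = truth.observed_matrix
    long = obs.stack()
    long = long[long > 0].rename("count").reset_index()
    long.columns = ["genome_id", "ko_id", "count"]

    def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
        with path.open("w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=index)

    _write(long, outdir / "annotations.tsv")
    _write(truth.genome_meta.reset_index(), outdir / "genome_metadata.tsv")
    sidecar = {
        "marker_kos": sorted(truth.marker_kos),
        "n_genomes": int(obs.shape[0]),
        "n_kos": int(obs.shape[1]),
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return sidecar


# --------------------------------------------------------------------------- #
# sequence pairs


@dataclass(frozen=True)
class SequencePair:
    seq_a: str
    seq_b: str
    realized_identity: float


def random_sequence(length: int, seed: int | np.random.Generator) -> str:
    """Uniform random nucleotide sequence of the given length."""
    if length <= 0:
        raise ConfigError("length must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, 10)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate_sequence(seq: str, divergence: float,
                    rng: np.random.Generator) -> tuple[str, float]:
    """Substitute each site independently with probability ``divergence``.

    Substitutions pick uniformly among the three alternative bases (Jukes-Cantor
    style, no indels). Returns the mutant and the realized identity.
    """
    if not (0.0 <= divergence < 0.75):
        raise ConfigError("divergence must lie in [0, 0.75)")
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    lut[_BASES] = np.arange(4)
    two_bit = lut[codes]
    hit = rng.random(codes.size) < divergence
    # shift by 1..3 mod 4 guarantees a different base at every substituted site
    shift = rng.integers(1, 4, size=int(hit.sum()))
    two_bit[hit] = (two_bit[hit] + shift) % 4
    mutant = _BASES[two_bit].tobytes().decode()
    identity = 1.0 - hit.mean() if codes.size else 1.0
    return mutant, float(identity)


def simulate_sequence_pair(length: int, divergence: float, seed: int = 0) -> SequencePair:
    """A random sequence and a mutant at the requested nucleotide divergence."""
    rng = _rng(seed, 11)
    seq_a = random_sequence(length, rng)
    seq_b, identity = mutate_sequence(seq_a, divergence, rng)
    return SequencePair(seq_a=seq_a, seq_b=seq_b, realized_identity=identity)


# --------------------------------------------------------------------------- #
# abundance series


@dataclass(frozen=True)
class AbundanceSeriesConfig:
    """Compositional abundance series with planted monotone associations.

    Defaults emulate a reactor amplicon series: a few dozen taxa, weekly-scale
    sampling, one planted partner pair and one covariate-tracking taxon.
    """

    n_taxa: int = 20
    n_samples: int = 50
    planted_pairs: Sequence[tuple[int, int, int]] = ()  # (taxon_i, taxon_j, sign)
    covariate_link: Sequence[tuple[int, int]] = ()  # (taxon, sign)
    noise_sd: float = 0.3
    signal_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ConfigError("n_samples must be >= 4 (Spearman needs >= 4 points)")
        if self.n_taxa < 1:
            raise ConfigError("n_taxa must be >= 1")
        seen: dict[frozenset[int], int] = {}
        for i, j, sign in self.planted_pairs:
            if i == j:
                raise ConfigError("planted pair indices must be distinct")
            for idx in (i, j):
                if not (0 <= idx < self.n_taxa):
                    raise ConfigError(f"planted taxon index {idx} out of range")
            if sign not in (-1, 1):
                raise ConfigError("planted sign must be -1 or +1")
            key = frozenset((i, j))
            if seen.get(key, sign) != sign:
                raise ConfigError(f"conflicting planted signs for pair {tuple(sorted(key))}")
            seen[key] = sign
        for idx, sign in self.covariate_link:
            if not (0 <= idx < self.n_taxa):
                raise ConfigError(f"covariate-linked taxon index {idx} out of range")
            if sign not in (-1, 1):
                raise ConfigError("covariate link sign must be -1 or +1")


@dataclass
class AbundanceSeries:
    table: pd.DataFrame  # samples x taxa, nonnegative
    covariate: pd.Series
    config: AbundanceSeriesConfig


def simulate_abundance_series(config: AbundanceSeriesConfig) -> AbundanceSeries:
    """Generate nonnegative abundances with planted monotone structure.

    Each planted pair shares a latent Gaussian signal; each member's
    log-abundance is ``sign * signal + noise``, so with ``noise_sd = 0`` the pair
    is exactly monotone (Spearman rho = +/-1) and under noise the association
    attenuates smoothly. A covariate-linked taxon tracks the environmental
    covariate the same way.
    """
    cfg = config
    rng = _rng(cfg.seed, 20)
    log_abund = rng.normal(0.0, 1.0, size=(cfg.n_samples, cfg.n_taxa))

    linked = {i for i, j, _ in cfg.planted_pairs for i in (i, j)}
    linked |= {i for i, _ in cfg.covariate_link}
    log_abund[:, sorted(linked)] = 0.0

    for i, j, sign in cfg.planted_pairs:
        z = rng.normal(0.0, 1.0, size=cfg.n_samples)
        log_abund[:, i] += cfg.signal_scale * z
        log_abund[:, j] += sign * cfg.signal_scale * z

    covariate = rng.normal(0.0, 1.0, size=cfg.n_samples)
    for idx, sign in cfg.covariate_link:
        log_abund[:, idx] += sign * cfg.signal_scale * covariate

    if cfg.noise_sd > 0:
        log_abund[:, sorted(linked)] += rng.normal(
            0.0, cfg.noise_sd, size=(cfg.n_samples, len(linked))
        )

    table = pd.DataFrame(
        np.exp(log_abund),
        index=pd.Index([f"S{i + 1:03d}" for i in range(cfg.n_samples)], name="sample_id"),
        columns=[f"OTU_{j + 1}" for j in range(cfg.n_taxa)],
    )
    cov = pd.Series(covariate, index=table.index, name="covariate")
    return AbundanceSeries(table=table, covariate=cov, config=cfg)


def write_abundance_series(series: AbundanceSeries, outdir: str | Path,
                           header: str = "") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, obj in (("abundance.tsv", series.table.reset_index()),
                      ("covariate.tsv", series.covariate.reset_index())):
        with (outdir / name).open("w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            obj.to_csv(fh, sep="\t", index=False)


def write_fasta(records: dict[str, str], path: str | Path, width: int = 80) -> None:
    """Write sequences as FASTA (plain writer keeps line width deterministic)."""
    with Path(path).open("w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def gc_content(seq: str) -> float:
    """GC fraction of a nucleotide sequence (ambiguous bases excluded)."""
    if not seq:
        warnings.warn("empty sequence; GC content undefined, returning 0.0")
        return 0.0
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    acgt = np.isin(arr, _BASES)
    gc = np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8))
    denom = int(acgt.sum())
    return float(gc.sum() / denom) if denom else 0.0
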