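"""End-to-end orchestration: simulate -> dereplicate -> traits -> markers ->
thermodynamics -> network, from one flat YAML config with per-stage sections.

Every output file carries a header comment echoing the seed and the stage
parameters, so a run is reproducible from its own outputs; the run report is a
JSON summary sufficient to re-run the pipeline identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import derep, network, synthetic, thermo, traits

__all__ = ["RunConfig", "run_pipeline", "validate_config", "load_config", "DEFAULTS"]

DEFAULTS: dict[str, dict[str, Any]] = {
    "simulate": {
        "enabled": False,
        "n_focal": 30, "n_background": 20, "n_core_focal": 40, "n_markers": 5,
        "n_shared": 80, "n_accessory": 80,
        "completeness_range": [0.9, 1.0], "contamination_rate": 0.01,
    },
    "derep": {
        "enabled": False,
        "n_species": 3, "members_per_species": 2, "genome_length": 20000,
        "within_divergence": 0.005, "between_divergence": 0.08,
        "k": 21, "sketch_size": 1000,
        "ani_threshold": 0.965, "min_aligned_fraction": 0.60,
        "min_completeness": 0.50, "max_contamination": 0.10,
        "ani_table": None,
    },
    "traits": {"enabled": False, "habitats": ["AD", "aquatic"], "q_threshold": 0.05},
    "markers": {"enabled": False, "p_in": 0.75, "p_out": 0.75},
    "thermo": {
        "enabled": False, "pathways": ["alternative_mmc", "classical_mmc"],
        "compound_table": None, "temperature_K": 298.15, "threshold_kJ": 0.0,
    },
    "network": {
        "enabled": False,
        "n_taxa": 12, "n_samples": 50, "noise_sd": 0.3,
        "planted_pairs": [[0, 1, 1]], "covariate_link": [[2, -1]],
        "prevalence_min": 0.2, "rho_min": 0.6, "q_max": 0.05,
        "method": "permutation", "n_permutations": 2000,
    },
}

_RANGES = {
    ("derep", "ani_threshold"): (0.0, 1.0, "open-left"),
    ("derep", "min_aligned_fraction"): (0.0, 1.0, "closed"),
    ("derep", "min_completeness"): (0.0, 1.0, "closed"),
    ("derep", "max_contamination"): (0.0, 1.0, "closed"),
    ("markers", "p_in"): (0.0, 1.0, "open-left"),
    ("markers", "p_out"): (0.0, 1.0, "open-left"),
    ("traits", "q_threshold"): (0.0, 1.0, "open-left"),
    ("network", "rho_min"): (0.0, 1.0, "closed"),
    ("network", "q_max"): (0.0, 1.0, "open-left"),
    ("network", "prevalence_min"): (0.0, 1.0, "closed"),
}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "panprop_out"
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def stage(self, name: str) -> dict[str, Any]:
        merged = dict(DEFAULTS[name])
        merged.update(self.stages.get(name, {}))
        return merged


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    stages = {k: v or {} for k, v in raw.items() if k in DEFAULTS}
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "panprop_out")),
        stages=stages,
    )


def validate_config(path: str | Path) -> list[str]:
    """Return a list of problems (empty iff the config is valid)."""
    problems: list[str] = []
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        return [f"unreadable config: {exc}"]
    if not isinstance(raw, dict):
        return ["config must be a mapping"]
    known = set(DEFAULTS) | {"seed", "outdir"}
    for key in raw:
        if key not in known:
            problems.append(f"unknown section {key!r}")
    if "seed" in raw and not isinstance(raw["seed"], int):
        problems.append("seed: must be an integer")
    for (section, key), (lo, hi, kind) in _RANGES.items():
        block = raw.get(section) or {}
        if key in block:
            v = block[key]
            if not isinstance(v, (int, float)):
                problems.append(f"{section}.{key}: must be numeric")
            elif (kind == "open-left" and not (lo < v <= hi)) or (
                kind == "closed" and not (lo <= v <= hi)
            ):
                bounds = f"({lo}, {hi}]" if kind == "open-left" else f"[{lo}, {hi}]"
                problems.append(f"{section}.{key}: {v} outside {bounds}")
    thermo_block = raw.get("thermo") or {}
    if thermo_block.get("enabled"):
        ct = thermo_block.get("compound_table")
        if ct is not None and not Path(ct).exists():
            problems.append(f"thermo.compound_table: path {ct!r} does not exist")
    for section in DEFAULTS:
        block = raw.get(section) or {}
        for key in block:
            if key not in DEFAULTS[section] and key != "enabled":
                problems.append(f"{section}.{key}: unknown key")
    return problems


def _header(stage: str, cfg: RunConfig, params: dict[str, Any]) -> str:
    clean = {k: v for k, v in sorted(params.items()) if k != "enabled"}
    return f"panprop stage={stage} seed={cfg.seed} params={json.dumps(clean, sort_keys=True)}"


def _run_simulate(cfg: RunConfig, outdir: Path, report: dict) -> synthetic.PangenomeTruth:
    p = cfg.stage("simulate")
    pg_cfg = synthetic.PangenomeConfig(
        n_focal=p["n_focal"], n_background=p["n_background"],
        n_core_focal=p["n_core_focal"], n_markers=p["n_markers"],
        n_shared=p["n_shared"], n_accessory=p["n_accessory"],
        completeness_range=tuple(p["completeness_range"]),
        contamination_rate=p["contamination_rate"], seed=cfg.seed,
    )
    truth = synthetic.simulate_pangenome(pg_cfg)
    synthetic.write_pangenome(truth, outdir / "simulate", header=_header("simulate", cfg, p))
    report["simulate"] = {
        "n_genomes": int(truth.observed_matrix.shape[0]),
        "n_kos": int(truth.observed_matrix.shape[1]),
        "n_planted_markers": len(truth.marker_kos),
        "params": p,
    }
    return truth


def _run_derep(cfg: RunConfig, outdir: Path, report: dict) -> None:
    p = cfg.stage("derep")
    stage_dir = outdir / "derep"
    stage_dir.mkdir(parents=True, exist_ok=True)
    if p.get("ani_table"):
        ani = derep.read_ani_table(p["ani_table"])
        ids = sorted({g for e in ani for g in (e.genome_a, e.genome_b)})
        genomes = [derep.GenomeRecord(genome_id=g, completeness=1.0, contamination=0.0)
                   for g in ids]
    else:
        rng_seed = cfg.seed
        root = synthetic.random_sequence(p["genome_length"], rng_seed)
        genomes = []
        fasta: dict[str, str] = {}
        import numpy as np

        rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 40]))
        half = p["between_divergence"] / 2
        for s in range(p["n_species"]):
            ancestor, _ = synthetic.mutate_sequence(root, half, rng)
            for m in range(p["members_per_species"]):
                seq, _ = synthetic.mutate_sequence(
                    ancestor, p["within_divergence"] / 2, rng
                )
                gid = f"sp{s + 1}_m{m + 1}"
                genomes.append(derep.GenomeRecord(
                    genome_id=gid, sequence=seq, completeness=1.0, contamination=0.0
                ))
                fasta[gid] = seq
        synthetic.write_fasta(fasta, stage_dir / "genomes.fasta")
        ani = derep.estimate_ani_matrix(genomes, k=p["k"], sketch_size=p["sketch_size"])
        derep.write_ani_table(ani, stage_dir / "ani.tsv", header=_header("derep", cfg, p))
    kept = derep.quality_filter(genomes, p["min_completeness"], p["max_contamination"])
    clusters = derep.cluster_genomes(
        ani, kept, p["ani_threshold"], p["min_aligned_fraction"]
    )
    derep.write_cluster_table(clusters, stage_dir / "clusters.tsv",
                              header=_header("derep", cfg, p))
    report["derep"] = {
        "n_genomes": len(kept),
        "n_clusters": len(clusters),
        "params": {k: v for k, v in p.items() if k != "ani_table"},
    }


def _run_traits(cfg: RunConfig, outdir: Path, report: dict,
                truth: synthetic.PangenomeTruth) -> traits.KoMatrix:
    p = cfg.stage("traits")
    stage_dir = outdir / "traits"
    stage_dir.mkdir(parents=True, exist_ok=True)
    matrix = traits.build_ko_matrix(
        outdir / "simulate" / "annotations.tsv",
        outdir / "simulate" / "genome_metadata.tsv",
    )
    results = traits.habitat_enrichment(
        matrix, habitats=tuple(p["habitats"]), q_threshold=p["q_threshold"]
    )
    frame = traits.enrichment_frame(results)
    with (stage_dir / "enrichment.tsv").open("w") as fh:
        fh.write(f"# {_header('traits', cfg, p)}\n")
        frame.to_csv(fh, sep="\t", index=False)
    prev_frames = []
    for habitat in p["habitats"]:
        prev = traits.prevalence(matrix, habitat).rename("prevalence").reset_index()
        prev.insert(1, "group", habitat)
        prev.columns = ["ko_id", "group", "prevalence"]
        prev_frames.append(prev)
    import pandas as pd

    with (stage_dir / "prevalence.tsv").open("w") as fh:
        fh.write(f"# {_header('traits', cfg, p)}\n")
        pd.concat(prev_frames).to_csv(fh, sep="\t", index=False)
    n_sig = int((frame["q_value"] < p["q_threshold"]).sum())
    report["traits"] = {"n_kos_tested": len(frame), "n_significant": n_sig, "params": p}
    return matrix


def _run_markers(cfg: RunConfig, outdir: Path, report: dict,
                 matrix: traits.KoMatrix) -> None:
    p = cfg.stage("markers")
    stage_dir = outdir / "markers"
    stage_dir.mkdir(parents=True, exist_ok=True)
    crit = traits.MarkerCriteria(p_in=p["p_in"], p_out=p["p_out"])
    markers = traits.phylum_markers(matrix, "focal", crit)
    with (stage_dir / "markers.tsv").open("w") as fh:
        fh.write(f"# {_header('markers', cfg, p)}\n")
        markers.reset_index().to_csv(fh, sep="\t", index=False)
    report["markers"] = {"n_markers": len(markers), "params": p}


def _run_thermo(cfg: RunConfig, outdir: Path, report: dict) -> None:
    p = cfg.stage("thermo")
    stage_dir = outdir / "thermo"
    stage_dir.mkdir(parents=True, exist_ok=True)
    compounds = thermo.load_compound_table(p.get("compound_table"))
    summary = {}
    for name in p["pathways"]:
        pw = thermo.load_pathway(bundled=name)
        ledger = thermo.pathway_ledger(pw, compounds, temperature_K=p["temperature_K"])
        thermo.write_ledger_tsv(ledger, stage_dir / f"{name}_ledger.tsv",
                                header=_header("thermo", cfg, p))
        feas = thermo.coupling_feasibility(ledger, threshold_kJ=p["threshold_kJ"])
        thermo.write_feasibility_json(feas, stage_dir / f"{name}_feasibility.json")
        summary[name] = {
            "overall_dg0_kJ": ledger.overall_dg0,
            "reference_net_dg0_kJ": ledger.reference_net_dg0,
        }
    report["thermo"] = {"pathways": summary, "params": p}


def _run_network(cfg: RunConfig, outdir: Path, report: dict) -> None:
    p = cfg.stage("network")
    stage_dir = outdir / "network"
    stage_dir.mkdir(parents=True, exist_ok=True)
    series_cfg = synthetic.AbundanceSeriesConfig(
        n_taxa=p["n_taxa"], n_samples=p["n_samples"], noise_sd=p["noise_sd"],
        planted_pairs=tuple(tuple(x) for x in p["planted_pairs"]),
        covariate_link=tuple(tuple(x) for x in p["covariate_link"]),
        seed=cfg.seed,
    )
    series = synthetic.simulate_abundance_series(series_cfg)
    synthetic.write_abundance_series(series, stage_dir,
                                     header=_header("network", cfg, p))
    norm = network.normalize_counts(series.table)
    rho, pmat = network.spearman_matrix(
        norm, prevalence_min=p["prevalence_min"], method=p["method"],
        n_permutations=p["n_permutations"], seed=cfg.seed,
    )
    edges = network.build_network(rho, pmat, rho_min=p["rho_min"], q_max=p["q_max"])
    network.write_edges_tsv(edges, stage_dir / "edges.tsv",
                            header=_header("network", cfg, p))
    report["network"] = {
        "n_taxa_tested": rho.shape[0], "n_edges": len(edges), "params": p,
    }


def run_pipeline(config: RunConfig | str | Path) -> dict:
    """Run enabled stages in dependency order; returns the run report."""
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": cfg.seed, "outdir": str(outdir), "stages_run": []}

    truth = matrix = None
    order = ["simulate", "derep", "traits", "markers", "thermo", "network"]
    for stage in order:
        if not cfg.stage(stage).get("enabled"):
            continue
        try:
            if stage == "simulate":
                truth = _run_simulate(cfg, outdir, report)
            elif stage == "derep":
                _run_derep(cfg, outdir, report)
            elif stage == "traits":
                if truth is None:
                    truth = _run_simulate(cfg, outdir, report)
                matrix = _run_traits(cfg, outdir, report, truth)
            elif stage == "markers":
                if matrix is None:
                    if truth is None:
                        truth = _run_simulate(cfg, outdir, report)
                    matrix = _run_traits(cfg, outdir, report, truth)
                _run_markers(cfg, outdir, report, matrix)
            elif stage == "thermo":
                _run_thermo(cfg, outdir, report)
            elif stage == "network":
                _run_network(cfg, outdir, report)
        except Exception as exc:
            report["failed_stage"] = stage
            report["error"] = str(exc)
            (outdir / "run_report.json").write_text(
                json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
            )
            raise
        report["stages_run"].append(stage)
    (outdir / "run_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
    )
    return report
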