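"""Reaction and pathway Gibbs free-energy ledgers for propionate oxidation routes.

Standard transformed free energies (pH 7, 25 degC) are computed from per-compound
formation energies by signed stoichiometric summation, concentration corrections
follow the mass-action term RT*ln(Q), and pathways are evaluated step by step with
an explicit account of thermodynamically coupled step pairs (endergonic steps paid
for by exergonic partners, e.g. propionate activation by acetate-kinase ATP yield).

Conventions
-----------
* ``dgf0_prime`` values are transformed standard formation energies in kJ/mol at
  pH 7, 25 degC; protons never appear in stoichiometries and water activity is 1.
* Stoichiometric coefficients are signed: products positive, substrates negative.
* A pathway may declare an explicit ``net_reaction``; the ledger then verifies that
  the formal sum of its steps cancels to exactly that stoichiometry (Hess's law).
* A pathway may additionally declare a ``reference_net``: the overall transformation
  the route effects once catalytic carrier pools (adenylates, CoA, the
  aspartate/glutamate amino couple) are regenerated by the rest of metabolism.
  Its free energy is evaluated from the same compound table and reported alongside
  the literal step sum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

R_KJ = 8.314e-3  # gas constant, kJ mol^-1 K^-1
DEFAULT_T = 298.15  # K

_HESS_TOL = 1e-9


class MissingCompoundError(KeyError):
    """A reaction references a compound absent from the formation-energy table."""


@dataclass(frozen=True)
class Compound:
    """A compound with a transformed standard formation energy (kJ/mol, pH 7)."""

    name: str
    dgf0_prime: float
    source: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.dgf0_prime):
            raise ValueError(f"non-finite formation energy for {self.name!r}")


@dataclass(frozen=True)
class Reaction:
    """A reaction as a signed stoichiometry (products +, substrates -)."""

    reaction_id: str
    stoichiometry: Mapping[str, float]
    step_label: str = ""
    enzyme_label: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.reaction_id!r} has empty stoichiometry")
        for name, coef in self.stoichiometry.items():
            if coef == 0:
                raise ValueError(
                    f"reaction {self.reaction_id!r} has zero coefficient for {name!r}"
                )

    def reversed(self) -> "Reaction":
        return Reaction(
            reaction_id=f"{self.reaction_id}_rev",
            stoichiometry={c: -v for c, v in self.stoichiometry.items()},
            step_label=self.step_label,
            enzyme_label=self.enzyme_label,
        )


@dataclass(frozen=True)
class Pathway:
    """An ordered chain of reactions with optional coupled step pairs."""

    pathway_id: str
    reactions: Sequence[Reaction]
    couplings: Sequence[tuple[str, str]] = ()
    net_reaction: Reaction | None = None
    reference_net: Reaction | None = None
    description: str = ""

    def __post_init__(self) -> None:
        labels = [r.step_label for r in self.reactions]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate step labels in pathway")
        seen: set[str] = set()
        for a, b in self.couplings:
            for lab in (a, b):
                if lab not in labels:
                    raise ValueError(f"coupling references unknown step {lab!r}")
                if lab in seen:
                    raise ValueError(f"step {lab!r} appears in more than one coupling")
                seen.add(lab)

    def step(self, label: str) -> Reaction:
        for r in self.reactions:
            if r.step_label == label:
                return r
        raise KeyError(label)


@dataclass
class ThermoLedger:
    """Per-step, per-coupling and overall free energies for one pathway."""

    pathway_id: str
    step_dg0: dict[str, float]
    coupling_dg0: dict[tuple[str, str], float]
    overall_dg0: float
    net_dg0: float | None = None
    reference_net_dg0: float | None = None
    step_dg_prime: dict[str, float] | None = None
    coupling_dg_prime: dict[tuple[str, str], float] | None = None
    overall_dg_prime: float | None = None
    temperature_K: float = DEFAULT_T
    concentrations: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Ledger as a tidy per-step table (kJ/mol)."""
        rows = []
        for label, dg in self.step_dg0.items():
            row = {"step": label, "dg0_prime_kJ": dg}
            if self.step_dg_prime is not None:
                row["dg_prime_kJ"] = self.step_dg_prime[label]
            rows.append(row)
        return pd.DataFrame(rows)


def load_compound_table(path: str | Path | None = None) -> dict[str, Compound]:
    """Read a TSV of (name, dgf0_prime_kJ_mol, source) into a compound table.

    With no argument, the bundled table is used: small-molecule anchors transcribed
    from the Thauer/Jungermann/Decker 1977 compilation, thioester/acyl-phosphate/
    adenylate entries back-calculated from standard hydrolysis free energies
    (each row carries its provenance).
    """
    if path is None:
        ref = resources.files("panprop.data").joinpath("compounds_dgf0.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"name", "dgf0_prime_kJ_mol"}
    if not required.issubset(df.columns):
        raise ValueError(f"compound table must have columns {sorted(required)}")
    if df["name"].duplicated().any():
        dups = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate compound names: {dups}")
    table: dict[str, Compound] = {}
    for _, row in df.iterrows():
        table[row["name"]] = Compound(
            name=row["name"],
            dgf0_prime=float(row["dgf0_prime_kJ_mol"]),
            source=str(row.get("source", "")),
        )
    return table


def _reaction_from_mapping(reaction_id: str, stoich: Mapping[str, float],
                           step_label: str = "", enzyme_label: str = "") -> Reaction:
    return Reaction(
        reaction_id=reaction_id,
        stoichiometry={str(k): float(v) for k, v in stoich.items()},
        step_label=step_label or reaction_id,
        enzyme_label=enzyme_label,
    )


def load_pathway(path: str | Path | None = None, *, bundled: str | None = None) -> Pathway:
    """Load a pathway definition from YAML.

    ``bundled`` may be ``"alternative_mmc"`` or ``"classical_mmc"`` to load the
    transcribed propionate-oxidation routes shipped with the package.
    """
    if (path is None) == (bundled is None):
        raise ValueError("pass exactly one of path= or bundled=")
    if bundled is not None:
        ref = resources.files("panprop.data").joinpath(f"pathway_{bundled}.yaml")
        with resources.as_file(ref) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    reactions = [
        _reaction_from_mapping(
            reaction_id=f"{raw['pathway_id']}_{s['step']}",
            stoich=s["stoichiometry"],
            step_label=str(s["step"]),
            enzyme_label=s.get("enzyme", ""),
        )
        for s in raw["steps"]
    ]
    net = raw.get("net_reaction")
    ref_net = raw.get("reference_net")
    return Pathway(
        pathway_id=raw["pathway_id"],
        reactions=reactions,
        couplings=tuple((str(a), str(b)) for a, b in raw.get("couplings", [])),
        net_reaction=_reaction_from_mapping(f"{raw['pathway_id']}_net", net) if net else None,
        reference_net=(
            _reaction_from_mapping(f"{raw['pathway_id']}_refnet", ref_net) if ref_net else None
        ),
        description=raw.get("description", ""),
    )


def reaction_dg0(reaction: Reaction, compounds: Mapping[str, Compound]) -> float:
    """Standard transformed reaction free energy: sum of nu * dGf0' (kJ/mol)."""
    missing = [c for c in reaction.stoichiometry if c not in compounds]
    if missing:
        raise MissingCompoundError(
            f"reaction {reaction.reaction_id!r}: no formation energy for {missing}"
        )
    return sum(
        coef * compounds[name].dgf0_prime for name, coef in reaction.stoichiometry.items()
    )


def reaction_dg_prime(
    reaction: Reaction,
    compounds: Mapping[str, Compound],
    concentrations: Mapping[str, float],
    temperature_K: float = DEFAULT_T,
) -> float:
    """Concentration-adjusted free energy: dG' = dG0' + RT * sum(nu * ln c).

    Water is held at unit activity (protons are already folded into the primed
    formation energies and never appear in stoichiometries). Compounds without an
    entry in ``concentrations`` stay at 1 M.
    """
    dg = reaction_dg0(reaction, compounds)
    rt = R_KJ * temperature_K
    for name, coef in reaction.stoichiometry.items():
        if name == "water":
            continue
        c = concentrations.get(name, 1.0)
        if c <= 0:
            raise ValueError(f"nonpositive concentration for {name!r}: {c}")
        dg += rt * coef * math.log(c)
    return dg


def _formal_sum(reactions: Sequence[Reaction]) -> dict[str, float]:
    total: dict[str, float] = {}
    for r in reactions:
        for name, coef in r.stoichiometry.items():
            total[name] = total.get(name, 0.0) + coef
    return {k: v for k, v in total.items() if abs(v) > _HESS_TOL}


def pathway_ledger(
    pathway: Pathway,
    compounds: Mapping[str, Compound],
    concentrations: Mapping[str, float] | None = None,
    temperature_K: float = DEFAULT_T,
) -> ThermoLedger:
    """Evaluate a pathway: per-step dG0', coupling nets, overall sum (Hess's law).

    If the pathway declares a ``net_reaction``, the formal sum of the steps must
    cancel to exactly that stoichiometry; a residual raises ``ValueError`` naming
    the non-cancelling compounds. If concentrations are given, a parallel dG'
    column is computed (additive over steps the same way dG0' is).
    """
    step_dg0 = {r.step_label: reaction_dg0(r, compounds) for r in pathway.reactions}
    overall = sum(step_dg0.values())

    net_dg0 = None
    if pathway.net_reaction is not None:
        residual = _formal_sum(list(pathway.reactions) + [pathway.net_reaction.reversed()])
        if residual:
            raise ValueError(
                f"pathway {pathway.pathway_id!r}: step sum does not cancel to the "
                f"declared net reaction; residual stoichiometry {residual}"
            )
        net_dg0 = reaction_dg0(pathway.net_reaction, compounds)

    coupling_dg0 = {
        (a, b): step_dg0[a] + step_dg0[b] for a, b in pathway.couplings
    }

    ref_dg0 = None
    if pathway.reference_net is not None:
        ref_dg0 = reaction_dg0(pathway.reference_net, compounds)

    ledger = ThermoLedger(
        pathway_id=pathway.pathway_id,
        step_dg0=step_dg0,
        coupling_dg0=coupling_dg0,
        overall_dg0=overall,
        net_dg0=net_dg0,
        reference_net_dg0=ref_dg0,
        temperature_K=temperature_K,
        concentrations=dict(concentrations or {}),
    )

    if concentrations is not None:
        ledger.step_dg_prime = {
            r.step_label: reaction_dg_prime(r, compounds, concentrations, temperature_K)
            for r in pathway.reactions
        }
        ledger.coupling_dg_prime = {
            (a, b): ledger.step_dg_prime[a] + ledger.step_dg_prime[b]
            for a, b in pathway.couplings
        }
        ledger.overall_dg_prime = sum(ledger.step_dg_prime.values())
    return ledger


def coupling_feasibility(
    ledger: ThermoLedger, threshold_kJ: float = 0.0, use_prime: bool = False
) -> dict:
    """Per-coupling feasibility (net dG <= threshold) plus uncoupled endergonic steps.

    Returns a report dict with one boolean per coupling and, for every step not in
    any coupling, its free energy and sign.
    """
    per_step = ledger.step_dg_prime if (use_prime and ledger.step_dg_prime) else ledger.step_dg0
    per_coupling = (
        ledger.coupling_dg_prime
        if (use_prime and ledger.coupling_dg_prime)
        else ledger.coupling_dg0
    )
    coupled_steps = {lab for pair in per_coupling for lab in pair}
    report = {
        "pathway_id": ledger.pathway_id,
        "threshold_kJ": threshold_kJ,
        "couplings": {
            f"{a}+{b}": {"net_dg_kJ": dg, "feasible": dg <= threshold_kJ}
            for (a, b), dg in per_coupling.items()
        },
        "uncoupled_steps": {
            lab: {"dg_kJ": dg, "endergonic": dg > 0}
            for lab, dg in per_step.items()
            if lab not in coupled_steps
        },
    }
    return report


def write_ledger_tsv(ledger: ThermoLedger, path: str | Path, header: str = "") -> None:
    """Write the per-step ledger as TSV with an optional provenance header."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        ledger.to_frame().to_csv(fh, sep="\t", index=False)


def write_feasibility_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
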