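"""Pathway-completeness prediction and species-level summaries.

A strain is predicted to produce a metabolite iff some directed path from
tryptophan to that metabolite has every reaction requirement satisfied by the
strain's detected enzyme families (breadth-first reachability over satisfied
edges).  Species-level summaries report, per metabolite, the percentage of
strains in the species predicted to produce it, rounded half-away-from-zero to
one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .homology import StrainAnnotation
from .network import MetabolicNetwork

__all__ = [
    "PredictionProfile",
    "SpeciesSummary",
    "enzymes_present",
    "predict_metabolites",
    "summarize_by_species",
    "round_percent",
    "format_percent",
]


def round_percent(x: float) -> float:
    """Round to one decimal, half away from zero."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_percent(x: float) -> str:
    """Table-style percent: one decimal with a trailing '.0' dropped (e.g. '6.7', '100')."""
    r = round_percent(x)
    return str(int(r)) if r == int(r) else f"{r:.1f}"


@dataclass
class PredictionProfile:
    strain_id: str
    enzymes_present: frozenset[str]
    predicted: frozenset[str]


def enzymes_present(
    annotation: StrainAnnotation, hdhd_as_fldh: bool = True
) -> frozenset[str]:
    """Enzyme families with at least one passing hit in the strain.

    With ``hdhd_as_fldh`` (the default), HdhD hits are folded into the fldH
    family: HdhD shares fldH's EC number and acts as an ILA dehydrogenase.
    """
    present = {e for e, c in annotation.count.items() if c >= 1}
    if hdhd_as_fldh and "HdhD" in present:
        present.discard("HdhD")
        present.add("fldH")
    return frozenset(present)


def predict_metabolites(
    present: frozenset[str] | set[str], network: MetabolicNetwork
) -> frozenset[str]:
    """Metabolites reachable from Trp through satisfied reactions.

    Returns reached metabolites intersected with ``network.predictable``
    (Trp itself excluded; metabolites behind an unknown-enzyme reaction are
    never returned).
    """
    unknown = set(present) - set(network.registry)
    if unknown:
        raise ValueError(f"unknown enzyme abbrev(s): {sorted(unknown)}")
    present = frozenset(present)
    reached = {network.root}
    changed = True
    while changed:
        changed = False
        for e in network.edges:
            if (
                e.substrate in reached
                and e.product not in reached
                and e.requirement.satisfied_by(present)
            ):
                reached.add(e.product)
                changed = True
    return frozenset(reached & network.predictable)


def profile_strain(
    annotation: StrainAnnotation,
    network: MetabolicNetwork,
    hdhd_as_fldh: bool = True,
) -> PredictionProfile:
    present = enzymes_present(annotation, hdhd_as_fldh=hdhd_as_fldh)
    return PredictionProfile(
        strain_id=annotation.strain_id,
        enzymes_present=present,
        predicted=predict_metabolites(present, network),
    )


@dataclass
class SpeciesSummary:
    """Per-species percentage of strains predicted to produce each metabolite."""

    table: pd.DataFrame  # index: species; columns: metabolites; rounded percents
    n_strains: dict[str, int] = field(default_factory=dict)

    def formatted(self) -> pd.DataFrame:
        out = self.table.map(format_percent)
        out.insert(0, "n_strains", [self.n_strains[s] for s in out.index])
        return out


def summarize_by_species(
    profiles: list[PredictionProfile],
    species_map: dict[str, str],
    network: MetabolicNetwork,
) -> SpeciesSummary:
    """Percent of strains per species predicted to produce each metabolite.

    Percentages are 100 * k / n rounded half-away-from-zero to one decimal.
    Every strain must appear in ``species_map``; species with zero strains are
    not representable (they simply do not occur).
    """
    missing = sorted({p.strain_id for p in profiles} - set(species_map))
    if missing:
        raise ValueError(f"strains missing from species map: {missing}")
    # stable, pathway-oriented column order
    order = [m for m in ("IPYA", "ILA", "IA", "IPA", "IAM", "TA", "IAAld", "IAA")
             if m in network.predictable]
    metabolites = order + sorted(network.predictable - set(order))
    by_species: dict[str, list[PredictionProfile]] = {}
    for p in profiles:
        by_species.setdefault(species_map[p.strain_id], []).append(p)
    rows = {}
    n_strains = {}
    for sp in sorted(by_species):
        ps = by_species[sp]
        n = len(ps)
        n_strains[sp] = n
        rows[sp] = [
            round_percent(100.0 * sum(m in p.predicted for p in ps) / n)
            for m in metabolites
        ]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=metabolites)
    table.index.name = "species"
    return SpeciesSummary(table=table, n_strains=n_strains)
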