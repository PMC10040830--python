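"""Genotype-phenotype concordance scoring.

Concentrations (ng/mL) are converted to a presence/absence phenotype by a
detection threshold.  Indole-3-pyruvic acid (IPYA) is never observed directly
in fermentation supernatants — it is consumed as fast as it forms — so its
phenotype is inferred from its only downstream product: observed ILA implies
IPYA occurred.  Each evaluable strain x metabolite cell is then classified by
crossing gene presence (GE/GA, from the pathway prediction) with phenotype
presence (PE/PA); prediction accuracy is the fraction of concordant cells
(GE_PE + GA_PA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .network import MetabolicNetwork
from .predict import PredictionProfile, round_percent

__all__ = [
    "Presence",
    "ConcordanceCell",
    "PhenotypeTable",
    "ConcordanceReport",
    "phenotype_from_concentrations",
    "classify",
    "accuracy_report",
]


class Presence(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNMEASURED = "unmeasured"


class ConcordanceCell(str, Enum):
    GE_PE = "GE_PE"
    GE_PA = "GE_PA"
    GA_PE = "GA_PE"
    GA_PA = "GA_PA"

    @property
    def concordant(self) -> bool:
        return self in (ConcordanceCell.GE_PE, ConcordanceCell.GA_PA)


@dataclass
class PhenotypeTable:
    """Observed presence per strain x metabolite, after IPYA inference."""

    presence: pd.DataFrame  # values from Presence; index strains, columns metabolites
    detection_threshold: float = 0.0

    def get(self, strain: str, metabolite: str) -> Presence:
        if metabolite not in self.presence.columns or strain not in self.presence.index:
            return Presence.UNMEASURED
        return Presence(self.presence.at[strain, metabolite])


def phenotype_from_concentrations(
    concentrations: pd.DataFrame, threshold: float = 0.0
) -> PhenotypeTable:
    """Threshold a strain x metabolite concentration table (ng/mL).

    A metabolite is present iff its concentration strictly exceeds
    ``threshold`` (default 0: any positive quantified amount counts).  NaN
    cells are unmeasured.  The IPYA column is then overwritten by the ILA
    column (measured-by-inference); if ILA is not measured, IPYA stays
    unmeasured.
    """
    if threshold < 0:
        raise ValueError("detection threshold must be >= 0")
    vals = concentrations.astype(float)
    if (vals.to_numpy() < 0).any():
        bad = vals[(vals < 0).any(axis=1)].index.tolist()
        raise ValueError(f"negative concentrations for strain(s) {bad}")
    presence = vals.map(
        lambda v: Presence.UNMEASURED.value
        if pd.isna(v)
        else (Presence.PRESENT.value if v > threshold else Presence.ABSENT.value)
    )
    if "ILA" in presence.columns:
        presence["IPYA"] = presence["ILA"]
    return PhenotypeTable(presence=presence, detection_threshold=threshold)


def classify(
    profile: PredictionProfile,
    phenotype: PhenotypeTable,
    strain: str,
    metabolite: str,
    network: MetabolicNetwork,
) -> ConcordanceCell | None:
    """GE/GA x PE/PA for one cell; None when the phenotype is unmeasured."""
    if metabolite not in network.predictable:
        raise ValueError(f"{metabolite!r} is not a predictable metabolite")
    obs = phenotype.get(strain, metabolite)
    if obs is Presence.UNMEASURED:
        return None
    ge = metabolite in profile.predicted
    pe = obs is Presence.PRESENT
    return {
        (True, True): ConcordanceCell.GE_PE,
        (True, False): ConcordanceCell.GE_PA,
        (False, True): ConcordanceCell.GA_PE,
        (False, False): ConcordanceCell.GA_PA,
    }[(ge, pe)]


@dataclass
class ConcordanceReport:
    cells: pd.DataFrame  # long format: strain, species, metabolite, gene, phenotype, cell
    per_metabolite_accuracy: dict[str, float]
    per_species_accuracy: dict[tuple[str, str], float]
    overall_accuracy_by_metabolite_mean: float
    overall_accuracy_pooled: float
    skipped: int = 0
    not_applicable: list[str] = field(default_factory=list)

    def stacked_counts(self) -> pd.DataFrame:
        """Per-metabolite counts of the four concordance cells."""
        return (
            self.cells.groupby(["metabolite", "cell"]).size().unstack(fill_value=0)
            .reindex(columns=[c.value for c in ConcordanceCell], fill_value=0)
        )


def _acc(cells: pd.Series) -> float:
    ok = cells.isin([ConcordanceCell.GE_PE.value, ConcordanceCell.GA_PA.value]).sum()
    return round_percent(100.0 * ok / len(cells))


def accuracy_report(
    profiles: list[PredictionProfile],
    phenotypes: PhenotypeTable,
    species_map: dict[str, str],
    network: MetabolicNetwork,
    include_ipya: bool = True,
) -> ConcordanceReport:
    """Classify every evaluable strain x metabolite cell and summarise accuracy.

    Unmeasured metabolites are excluded from denominators.  Two overall
    figures are reported: the unweighted mean of per-metabolite accuracies
    (the headline figure) and the pooled accuracy over all evaluated cells.
    ``include_ipya`` controls whether the inferred IPYA phenotype participates.
    """
    missing = sorted({p.strain_id for p in profiles} - set(species_map))
    if missing:
        raise ValueError(f"strains missing from species map: {missing}")
    scope = sorted(network.predictable)
    if not include_ipya:
        scope = [m for m in scope if m != "IPYA"]
    rows = []
    skipped = 0
    for p in profiles:
        for m in scope:
            cell = classify(p, phenotypes, p.strain_id, m, network)
            if cell is None:
                skipped += 1
                continue
            rows.append(
                {
                    "strain": p.strain_id,
                    "species": species_map[p.strain_id],
                    "metabolite": m,
                    "gene": "GE" if m in p.predicted else "GA",
                    "phenotype": "PE" if cell in (ConcordanceCell.GE_PE, ConcordanceCell.GA_PE) else "PA",
                    "cell": cell.value,
                }
            )
    cells = pd.DataFrame(rows, columns=["strain", "species", "metabolite", "gene", "phenotype", "cell"])
    if cells.empty:
        raise ValueError("no evaluable strain x metabolite cells")
    per_met = {m: _acc(g["cell"]) for m, g in cells.groupby("metabolite")}
    per_sp = {
        (sp, m): _acc(g["cell"]) for (sp, m), g in cells.groupby(["species", "metabolite"])
    }
    not_applicable = [m for m in scope if m not in per_met]
    mean_acc = round_percent(float(np.mean([per_met[m] for m in per_met])))
    pooled = _acc(cells["cell"])
    return ConcordanceReport(
        cells=cells,
        per_metabolite_accuracy=per_met,
        per_species_accuracy=per_sp,
        overall_accuracy_by_metabolite_mean=mean_acc,
        overall_accuracy_pooled=pooled,
        skipped=skipped,
        not_applicable=not_applicable,
    )
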