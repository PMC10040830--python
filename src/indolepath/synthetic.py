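"""Seeded synthetic inputs: proteomes with planted homologs, and metabolomics.

The generator emulates the statistical structure the analysis assumes:

* per-strain proteomes containing diverged homologs (30-90% identity) of the
  pathway's reference enzymes among unrelated random decoy proteins;
* a strain x metabolite concentration table with species-level lognormal
  means, strain-level noise, a detection limit, optional false negatives, and
  optional genotype-discordant phenotype injections (the tryptamine /
  indoleacrylate anomaly pattern seen in real cohorts).

All randomness flows from explicit integer seeds through independent
``numpy.random.Generator`` streams, so outputs are reproducible per seed.
The bundled reference enzyme database is synthetic: random proteins generated
from a fixed internal seed, one or two per enzyme family, standing in for a
curated set of real reference sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import ProteinRecord
from .network import ReferenceDB, default_registry
from .phylo import global_identity
from .predict import PredictionProfile

__all__ = [
    "BACKGROUND_AA_FREQS",
    "SpeciesSpec",
    "CohortSpec",
    "MetabolomicsSpec",
    "Cohort",
    "random_protein",
    "mutate_to_identity",
    "synthetic_reference_db",
    "generate_cohort",
    "generate_metabolomics",
    "default_cohort_spec",
    "paper_like_metabolomics_spec",
]

# Robinson-Robinson background amino-acid frequencies
BACKGROUND_AA_FREQS = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.065,
}

_AAS = np.array(list(BACKGROUND_AA_FREQS))
_FREQS = np.array(list(BACKGROUND_AA_FREQS.values()))
_FREQS = _FREQS / _FREQS.sum()

#: Internal seed for the synthetic reference enzyme database (a fixed input,
#: like a curated database, not part of a run's randomness).
_REFDB_SEED = 20230313

#: Reference protein lengths per enzyme family (typical bacterial sizes).
_REF_LENGTHS = {
    "ArAT": 390, "TDC": 470, "TMO": 550, "amiE": 340, "fldH": 330,
    "LDH": 320, "HdhD": 310, "fldA": 420, "fldBC": 640, "fldI": 250,
    "acdA": 360, "ALD": 480, "IPD": 550, "PPD": 560,
}


def random_protein(length: int, seed: int, prefix: str = "rand") -> ProteinRecord:
    """I.i.d. protein from the background amino-acid frequency table."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(_AAS, size=length, p=_FREQS))
    return ProteinRecord(id=f"{prefix}_{seed}", sequence=seq)


def mutate_to_identity(
    seq: str,
    target_identity_pct: float,
    indel_rate: float = 0.0,
    seed: int = 0,
    tolerance: float = 2.0,
    max_attempts: int = 40,
) -> tuple[ProteinRecord, float]:
    """Mutate ``seq`` until its global identity to the original is near target.

    Random substitutions (and, at ``indel_rate``, single-residue indels) are
    applied; the achieved identity is measured with the global aligner and
    must land within ``tolerance`` percentage points of
    ``target_identity_pct``.  Returns the mutant and the achieved identity.
    """
    if not 15.0 < target_identity_pct <= 100.0:
        raise ValueError("target identity must be in (15, 100]")
    if target_identity_pct == 100.0:
        return ProteinRecord(id="mut", sequence=seq), 100.0
    rng = np.random.default_rng(seed)
    L = len(seq)
    frac = 1.0 - target_identity_pct / 100.0
    scale = 1.0
    for _ in range(max_attempts):
        n_sub = min(L - 1, max(1, round(frac * scale * L)))
        pos = rng.choice(L, size=n_sub, replace=False)
        chars = list(seq)
        for p in pos:
            choices = [c for c in _AAS if c != chars[p]]
            chars[p] = choices[rng.integers(len(choices))]
        if indel_rate > 0:
            keep = rng.random(len(chars)) >= indel_rate
            inserted = []
            for c, k in zip(chars, keep):
                if k:
                    inserted.append(c)
                if rng.random() < indel_rate:
                    inserted.append(str(rng.choice(_AAS)))
            chars = inserted or chars
        mutant = "".join(chars)
        achieved = global_identity(seq, mutant)
        if abs(achieved - target_identity_pct) <= tolerance:
            return ProteinRecord(id="mut", sequence=mutant), achieved
        # realignment recovers some identity; push harder or ease off
        scale *= 1.15 if achieved > target_identity_pct else 0.9
    raise RuntimeError(
        f"could not reach {target_identity_pct}% identity within "
        f"{max_attempts} attempts (last achieved {achieved:.1f}%)"
    )


def synthetic_reference_db(seed: int = _REFDB_SEED, registry=None) -> ReferenceDB:
    """Synthetic reference enzyme database (stand-in for a curated set).

    One reference protein per enzyme family, plus a second diverged reference
    (~55% identity) for ArAT and LDH so multi-reference indexing paths are
    exercised.  Deterministic for a given seed.
    """
    registry = registry or default_registry()
    records: dict[str, tuple[str, str]] = {}
    for i, abbrev in enumerate(sorted(_REF_LENGTHS)):
        rec = random_protein(_REF_LENGTHS[abbrev], seed + 7919 * i, prefix=abbrev)
        records[f"{abbrev}_ref1"] = (abbrev, rec.sequence)
    for abbrev in ("ArAT", "LDH"):
        base = records[f"{abbrev}_ref1"][1]
        mut, _ = mutate_to_identity(base, 55.0, seed=seed + sum(ord(c) for c in abbrev))
        records[f"{abbrev}_ref2"] = (abbrev, mut.sequence)
    return ReferenceDB(records=records, registry=registry)


@dataclass(frozen=True)
class SpeciesSpec:
    """One species of the cohort: size, planted enzymes, and extras.

    ``enzymes`` are planted in every strain; ``extra_enzymes`` maps an enzyme
    to the number of strains (taken in order) that additionally carry it.
    """

    name: str
    n_strains: int
    enzymes: tuple[str, ...]
    extra_enzymes: dict[str, int] = field(default_factory=dict)
    target_identity_pct: float = 60.0
    source: str = "Human feces"

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        if not 15.0 < self.target_identity_pct <= 100.0:
            raise ValueError("target identity must be in (15, 100]")


@dataclass(frozen=True)
class CohortSpec:
    species: tuple[SpeciesSpec, ...]
    decoys_per_proteome: int = 20
    decoy_length_range: tuple[int, int] = (150, 450)
    seed: int = 0


@dataclass
class Cohort:
    """Generated cohort: proteomes, metadata, and the ground-truth manifest."""

    proteomes: dict[str, list[ProteinRecord]]
    metadata: pd.DataFrame  # index strain; columns species, source
    truth: dict[str, frozenset[str]]  # strain -> planted enzyme families

    @property
    def species_map(self) -> dict[str, str]:
        return self.metadata["species"].to_dict()


def generate_cohort(spec: CohortSpec, refdb: ReferenceDB | None = None) -> Cohort:
    """Plant mutated enzyme homologs plus decoys into per-strain proteomes."""
    refdb = refdb or synthetic_reference_db()
    known = {abbrev for abbrev, _ in refdb.records.values()}
    proteomes: dict[str, list[ProteinRecord]] = {}
    truth: dict[str, frozenset[str]] = {}
    meta_rows = []
    strain_counter = 0
    for sp_i, sp in enumerate(spec.species):
        for e in set(sp.enzymes) | set(sp.extra_enzymes):
            if e not in known:
                raise ValueError(f"species {sp.name!r} plants unknown enzyme {e!r}")
        for k in range(sp.n_strains):
            strain_counter += 1
            strain = f"{sp.name.replace(' ', '_')}_S{k + 1:02d}"
            plants = list(sp.enzymes) + [
                e for e, n_extra in sorted(sp.extra_enzymes.items()) if k < n_extra
            ]
            rng_base = spec.seed * 1_000_003 + sp_i * 10_007 + k * 101
            proteome: list[ProteinRecord] = []
            for pi, abbrev in enumerate(plants):
                ref_id = refdb.index[abbrev][0]
                mut, _ = mutate_to_identity(
                    refdb.sequence(ref_id),
                    sp.target_identity_pct,
                    seed=(rng_base + pi) % (2**31),
                )
                proteome.append(
                    ProteinRecord(id=f"{strain}_p{pi + 1:03d}_{abbrev}", sequence=mut.sequence)
                )
            rng = np.random.default_rng((rng_base + 7777) % (2**31))
            lo, hi = spec.decoy_length_range
            for di in range(spec.decoys_per_proteome):
                ln = int(rng.integers(lo, hi + 1))
                seq = "".join(rng.choice(_AAS, size=ln, p=_FREQS))
                proteome.append(
                    ProteinRecord(id=f"{strain}_d{di + 1:03d}", sequence=seq)
                )
            proteomes[strain] = proteome
            truth[strain] = frozenset(plants)
            meta_rows.append({"strain": strain, "species": sp.name, "source": sp.source})
    metadata = pd.DataFrame(meta_rows).set_index("strain")
    return Cohort(proteomes=proteomes, metadata=metadata, truth=truth)


@dataclass(frozen=True)
class MetabolomicsSpec:
    """Concentration-table generator settings.

    ``means`` maps (species, metabolite) -> lognormal mean ng/mL, with
    ``default_mean`` used for genotype-positive cells without an entry.  ``cv``
    is the coefficient of variation of strain-level noise.  Genotype-positive
    cells are zeroed with probability ``false_negative_rate``;
    ``phenotype_injections`` force (species, metabolite) pairs to be present
    regardless of genotype.  Values below ``detection_limit`` are floored to 0.
    """

    measured_metabolites: tuple[str, ...] = ("ILA", "IA", "IPA", "TA", "IAM", "IAA", "IAld")
    means: dict[tuple[str, str], float] = field(default_factory=dict)
    default_mean: float = 100.0
    cv: float = 0.8
    false_negative_rate: float = 0.0
    phenotype_injections: tuple[tuple[str, str], ...] = ()
    injection_mean: float = 30.0
    always_absent: tuple[str, ...] = ()
    detection_limit: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.false_negative_rate <= 1.0:
            raise ValueError("false_negative_rate must be in [0,1]")
        if any(m < 0 for m in self.means.values()) or self.default_mean < 0:
            raise ValueError("means must be >= 0")


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def generate_metabolomics(
    profiles: list[PredictionProfile],
    spec: MetabolomicsSpec,
    species_map: dict[str, str],
) -> pd.DataFrame:
    """Strain x metabolite concentration table (ng/mL) from genotype profiles.

    Genotype-positive cells draw lognormal concentrations; genotype-negative
    cells are 0 except for injected (species, metabolite) anomalies.  IPYA is
    deliberately never measured (it is inferred downstream from ILA), matching
    how such tables are produced in practice.
    """
    rng = np.random.default_rng(spec.seed)
    rows = {}
    for p in sorted(profiles, key=lambda p: p.strain_id):
        sp = species_map[p.strain_id]
        row = {}
        for m in spec.measured_metabolites:
            if m in spec.always_absent:
                row[m] = 0.0
                continue
            injected = (sp, m) in spec.phenotype_injections
            positive = m in p.predicted
            if injected:
                val = _lognormal(rng, spec.means.get((sp, m), spec.injection_mean), spec.cv)
            elif positive:
                if rng.random() < spec.false_negative_rate:
                    val = 0.0
                else:
                    val = _lognormal(rng, spec.means.get((sp, m), spec.default_mean), spec.cv)
            else:
                val = 0.0
            if val < spec.detection_limit:
                val = 0.0
            row[m] = val
        rows[p.strain_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "strain"
    return table


# ---------------------------------------------------------------------------
# Default study-condition cohort: 13 species, 148 strains, enzyme profiles
# chosen so the predicted species-level percentages match the reference
# prediction table the pipeline is validated against.

def default_cohort_spec(seed: int = 0, decoys_per_proteome: int = 20) -> CohortSpec:
    base = ("ArAT", "LDH", "amiE", "ALD")
    with_ipd = base + ("IPD",)
    sp = [
        SpeciesSpec("L. acidophilus", 8, base, {"TMO": 1}),
        SpeciesSpec("L. crispatus", 14, base + ("TMO",)),
        SpeciesSpec("L. curvatus", 4, ("amiE", "ALD")),
        SpeciesSpec("L. fermentum", 11, with_ipd),
        SpeciesSpec("L. gasseri", 8, base),
        SpeciesSpec("L. helveticus", 9, base, {"TMO": 8},
                    source="Fermented yak milk"),
        SpeciesSpec("L. mucosae", 15, with_ipd, {"TMO": 2}),
        SpeciesSpec("L. paracasei", 10, with_ipd, {"TMO": 4},
                    source="Chinese pickle"),
        SpeciesSpec("L. plantarum", 10, with_ipd, {"TMO": 8}),
        SpeciesSpec("L. reuteri", 30, with_ipd, {"TMO": 2},
                    source="Fermented rice milk"),
        SpeciesSpec("L. rhamnosus", 9, with_ipd),
        SpeciesSpec("L. salivarius", 12, with_ipd + ("fldH",), {"TMO": 8}),
        SpeciesSpec("L. pentosus", 8, with_ipd + ("TMO",)),
    ]
    return CohortSpec(species=tuple(sp), seed=seed,
                      decoys_per_proteome=decoys_per_proteome)


def paper_like_metabolomics_spec(seed: int = 0) -> MetabolomicsSpec:
    """Concentration-table conditions emulating the real cohort's anomalies.

    Tryptamine appears in every L. helveticus strain and indoleacrylate in
    every L. mucosae strain despite absent genotypes; indoleacetamide is
    never observed despite present genotypes (consumed as an intermediate);
    L. salivarius has a roughly 20-fold elevated ILA mean; IAA means sit in
    the tens of ng/mL.
    """
    means = {
        ("L. salivarius", "ILA"): 1900.0,
        ("L. helveticus", "TA"): 35.0,
        ("L. mucosae", "IA"): 20.0,
        ("L. pentosus", "IAA"): 22.5,
    }
    return MetabolomicsSpec(
        means=means,
        default_mean=100.0,
        phenotype_injections=(("L. helveticus", "TA"), ("L. mucosae", "IA")),
        always_absent=("IAM",),
        seed=seed,
    )
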