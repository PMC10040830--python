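"""Tryptophan indole-derivative metabolic network and enzyme registry.

The microbial indole branch of tryptophan catabolism converts Trp into nine
downstream metabolites (IPYA, ILA, IA, IPA, TA, IAM, IAAld, IAA, IAld).  Each
conversion is carried out by one or more enzyme families; a strain is predicted
to produce a metabolite iff every reaction on some Trp-path to it has at least
one required enzyme alternative fully present in the strain's genome.

This module holds the fixed network topology, the enzyme-family registry, and
the reference protein database used for homology searches.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from Bio import SeqIO

__all__ = [
    "EnzymeFamily",
    "Requirement",
    "UNKNOWN_REQUIREMENT",
    "ReactionEdge",
    "MetabolicNetwork",
    "ReferenceDB",
    "NetworkValidationError",
    "default_registry",
    "build_default_network",
    "load_network",
    "save_network",
    "load_reference_db",
    "METABOLITES",
    "METABOLITE_NAMES",
    "ENZYME_ABBREVS",
]

#: Fixed uppercase metabolite tokens; display names live in METABOLITE_NAMES.
METABOLITES = ("Trp", "IPYA", "ILA", "IA", "IPA", "TA", "IAM", "IAAld", "IAA", "IAld")

METABOLITE_NAMES = {
    "Trp": "tryptophan",
    "IPYA": "indole-3-pyruvic acid",
    "ILA": "indole-3-lactic acid",
    "IA": "3-indoleacrylic acid",
    "IPA": "indole-3-propionic acid",
    "TA": "tryptamine",
    "IAM": "indole-3-acetamide",
    "IAAld": "indole-3-acetaldehyde",
    "IAA": "indole-3-acetic acid",
    "IAld": "3-indolealdehyde",
}

_EC_RE = re.compile(r"^(\d+|-)(\.(\d+|-)){3}$")


class NetworkValidationError(ValueError):
    """Raised when a network document violates the schema or graph invariants."""


@dataclass(frozen=True)
class EnzymeFamily:
    """One enzyme family of the pathway (e.g. ArAT, fldH, amiE)."""

    abbrev: str
    full_name: str
    ec_number: str
    role_note: str = ""

    def __post_init__(self) -> None:
        if not _EC_RE.match(self.ec_number):
            raise ValueError(f"malformed EC number {self.ec_number!r} for {self.abbrev}")


@dataclass(frozen=True)
class Requirement:
    """Disjunction of conjunctions of enzyme families.

    ``alternatives`` is a frozenset of frozensets of enzyme abbrevs; the
    requirement is satisfied by an available-enzyme set S iff at least one
    alternative is fully contained in S.  The empty disjunction is the
    never-satisfiable "unknown enzyme" requirement.
    """

    alternatives: frozenset[frozenset[str]]

    @classmethod
    def of(cls, *alternatives) -> "Requirement":
        return cls(frozenset(frozenset(alt) for alt in alternatives))

    @property
    def known(self) -> bool:
        return bool(self.alternatives)

    def satisfied_by(self, present: set[str] | frozenset[str]) -> bool:
        present = frozenset(present)
        return any(alt <= present for alt in self.alternatives)

    def enzymes(self) -> frozenset[str]:
        out: set[str] = set()
        for alt in self.alternatives:
            out |= alt
        return frozenset(out)


#: Never-satisfiable requirement for reactions whose enzyme is unidentified.
UNKNOWN_REQUIREMENT = Requirement(frozenset())


@dataclass(frozen=True)
class ReactionEdge:
    substrate: str
    product: str
    requirement: Requirement

    def __post_init__(self) -> None:
        if self.substrate == self.product:
            raise NetworkValidationError(
                f"self-loop edge {self.substrate}->{self.product}"
            )


def default_registry() -> dict[str, EnzymeFamily]:
    """The 14-family enzyme registry of the indole pathway.

    HdhD (D-2-hydroxyacid dehydrogenase) is registered as its own family with
    its own reference sequences, but by default its homology hits are counted
    under fldH (see the ``hdhd_as_fldh`` flag): it shares fldH's EC number and
    acts as an indolelactate dehydrogenase.
    """
    fams = [
        EnzymeFamily("ArAT", "aromatic amino acid aminotransferase", "2.6.1.-",
                     "Trp -> IPYA, first-step transaminase"),
        EnzymeFamily("TDC", "tryptophan decarboxylase", "4.1.1.105",
                     "Trp -> TA"),
        EnzymeFamily("TMO", "tryptophan 2-monooxygenase", "1.13.12.3",
                     "Trp -> IAM"),
        EnzymeFamily("amiE", "amidase", "3.5.1.4", "IAM -> IAA"),
        EnzymeFamily("fldH", "indolelactate dehydrogenase", "1.1.1.-",
                     "IPYA -> ILA"),
        EnzymeFamily("LDH", "lactate dehydrogenase", "1.1.1.-",
                     "IPYA -> ILA (alternative to fldH)"),
        EnzymeFamily("HdhD", "D-2-hydroxyacid dehydrogenase", "1.1.1.-",
                     "counted as fldH-equivalent ILA dehydrogenase"),
        EnzymeFamily("fldA", "cinnamoyl-CoA:phenyllactate CoA-transferase", "2.8.3.17",
                     "ILA -> IA cluster member"),
        EnzymeFamily("fldBC", "phenyllactoyl-CoA dehydratase alpha/beta", "4.2.1.-",
                     "ILA -> IA cluster member (alpha/beta treated as one unit)"),
        EnzymeFamily("fldI", "R-phenyllactate dehydratase activator", "-.-.-.-",
                     "ILA -> IA cluster member"),
        EnzymeFamily("acdA", "phenylacrylate reductase", "1.3.1.-", "IA -> IPA"),
        EnzymeFamily("ALD", "aldehyde dehydrogenase", "1.2.1.3", "IAAld -> IAA"),
        EnzymeFamily("IPD", "indolepyruvate decarboxylase", "4.1.1.74",
                     "IPYA -> IAAld"),
        EnzymeFamily("PPD", "phenylpyruvate decarboxylase", "4.1.1.43",
                     "IPYA -> IAAld (alternative to IPD)"),
    ]
    return {f.abbrev: f for f in fams}


ENZYME_ABBREVS = tuple(default_registry())


@dataclass
class MetabolicNetwork:
    """Directed acyclic metabolite network rooted at Trp."""

    metabolites: frozenset[str]
    edges: list[ReactionEdge]
    registry: dict[str, EnzymeFamily] = field(default_factory=default_registry)
    root: str = "Trp"

    def __post_init__(self) -> None:
        self._validate()

    # -- validation -------------------------------------------------------
    def _graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.metabolites)
        g.add_edges_from((e.substrate, e.product) for e in self.edges)
        return g

    def _validate(self) -> None:
        for e in self.edges:
            for m in (e.substrate, e.product):
                if m not in self.metabolites:
                    raise NetworkValidationError(
                        f"edge {e.substrate}->{e.product} references unknown metabolite {m!r}"
                    )
            unknown = e.requirement.enzymes() - set(self.registry)
            if unknown:
                raise NetworkValidationError(
                    f"edge {e.substrate}->{e.product} references enzymes absent "
                    f"from the registry: {sorted(unknown)}"
                )
        g = self._graph()
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise NetworkValidationError(f"network contains a cycle: {cycle}")
        unreachable = self.metabolites - {self.root} - nx.descendants(g, self.root)
        if unreachable:
            raise NetworkValidationError(
                f"metabolites unreachable from {self.root}: {sorted(unreachable)}"
            )

    # -- queries ----------------------------------------------------------
    @property
    def predictable(self) -> frozenset[str]:
        """Metabolites for which every edge on some Trp-path has a known requirement."""
        reached = {self.root}
        frontier = [self.root]
        while frontier:
            nxt: list[str] = []
            for e in self.edges:
                if e.substrate in reached and e.requirement.known and e.product not in reached:
                    reached.add(e.product)
                    nxt.append(e.product)
            frontier = nxt
        return frozenset(reached - {self.root})

    def out_edges(self, metabolite: str) -> list[ReactionEdge]:
        return [e for e in self.edges if e.substrate == metabolite]

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and set(self.edges) == set(other.edges)
            and self.root == other.root
        )


def build_default_network() -> MetabolicNetwork:
    """The fixed microbial indole-derivative network.

    Ten metabolites, ten reactions; nine with known enzyme requirements.  The
    IAA -> IAld conversion is represented but its enzyme is unidentified, so
    IAld is never predictable.
    """
    R = Requirement.of
    edges = [
        ReactionEdge("Trp", "IPYA", R({"ArAT"})),
        ReactionEdge("Trp", "TA", R({"TDC"})),
        ReactionEdge("Trp", "IAM", R({"TMO"})),
        ReactionEdge("IPYA", "ILA", R({"fldH"}, {"LDH"})),
        ReactionEdge("ILA", "IA", R({"fldA", "fldBC", "fldI"})),
        ReactionEdge("IA", "IPA", R({"acdA"})),
        ReactionEdge("IPYA", "IAAld", R({"IPD"}, {"PPD"})),
        ReactionEdge("IAAld", "IAA", R({"ALD"})),
        ReactionEdge("IAM", "IAA", R({"amiE"})),
        ReactionEdge("IAA", "IAld", UNKNOWN_REQUIREMENT),
    ]
    return MetabolicNetwork(metabolites=frozenset(METABOLITES), edges=edges)


# ---------------------------------------------------------------------------
# JSON (de)serialization


def save_network(network: MetabolicNetwork, path: str | Path | None = None) -> str:
    doc = {
        "metabolites": sorted(network.metabolites),
        "root": network.root,
        "edges": [
            {
                "substrate": e.substrate,
                "product": e.product,
                "alternatives": sorted(
                    sorted(alt) for alt in e.requirement.alternatives
                ),
            }
            for e in network.edges
        ],
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_network(document: str | dict | Path) -> MetabolicNetwork:
    """Build a validated network from a JSON document (text, dict or path)."""
    if isinstance(document, Path):
        document = document.read_text()
    if isinstance(document, str):
        if document == "default":
            return build_default_network()
        p = Path(document)
        if document.lstrip()[:1] not in "{[" and p.is_file():
            document = p.read_text()
        doc = json.loads(document)
    else:
        doc = document
    try:
        metabolites = frozenset(doc["metabolites"])
        raw_edges = doc["edges"]
    except (KeyError, TypeError) as exc:
        raise NetworkValidationError(f"malformed network document: missing {exc}") from exc
    edges = []
    for i, re_ in enumerate(raw_edges):
        try:
            req = Requirement.of(*re_["alternatives"]) if re_["alternatives"] is not None \
                else UNKNOWN_REQUIREMENT
            if not re_["alternatives"]:
                req = UNKNOWN_REQUIREMENT
            edges.append(ReactionEdge(re_["substrate"], re_["product"], req))
        except KeyError as exc:
            raise NetworkValidationError(f"edge #{i} missing key {exc}") from exc
    return MetabolicNetwork(
        metabolites=metabolites, edges=edges, root=doc.get("root", "Trp")
    )


# ---------------------------------------------------------------------------
# Reference protein database

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ReferenceDB:
    """Curated reference proteins for each enzyme family.

    ``records`` maps sequence id -> (enzyme abbrev, amino-acid sequence);
    ``index`` maps enzyme abbrev -> list of sequence ids.
    """

    records: dict[str, tuple[str, str]]
    registry: dict[str, EnzymeFamily] = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("reference database is empty")
        for sid, (abbrev, seq) in self.records.items():
            if abbrev not in self.registry:
                raise ValueError(f"record {sid!r} maps to unknown enzyme {abbrev!r}")
            if not seq:
                raise ValueError(f"record {sid!r} has an empty sequence")
            bad = set(seq) - _AA_ALPHABET
            if bad:
                raise ValueError(f"record {sid!r} has illegal residues {sorted(bad)}")

    @property
    def index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for sid, (abbrev, _) in self.records.items():
            idx.setdefault(abbrev, []).append(sid)
        return {k: sorted(v) for k, v in idx.items()}

    def sequence(self, sid: str) -> str:
        return self.records[sid][1]

    def enzyme_of(self, sid: str) -> str:
        return self.records[sid][0]

    def __len__(self) -> int:
        return len(self.records)


def load_reference_db(
    fasta_path: str | Path,
    mapping_table_path: str | Path,
    registry: dict[str, EnzymeFamily] | None = None,
) -> ReferenceDB:
    """Load reference proteins (multi-FASTA) plus a ``seq_id<TAB>abbrev`` table.

    FASTA records without a mapping are skipped with a warning; mapping rows
    that reference a missing FASTA id raise.
    """
    registry = registry or default_registry()
    mapping: dict[str, str] = {}
    for ln, line in enumerate(Path(mapping_table_path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"mapping table line {ln}: expected 2 columns, got {len(parts)}")
        mapping[parts[0]] = parts[1]
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ValueError(f"empty reference FASTA: {fasta_path}")
    missing = sorted(set(mapping) - set(seqs))
    if missing:
        raise ValueError(f"mapping references ids absent from FASTA: {missing}")
    unmapped = sorted(set(seqs) - set(mapping))
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} reference record(s) without an enzyme mapping "
            f"were skipped: {unmapped[:5]}{'...' if len(unmapped) > 5 else ''}"
        )
    records = {sid: (mapping[sid], seqs[sid]) for sid in mapping}
    return ReferenceDB(records=records, registry=registry)
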