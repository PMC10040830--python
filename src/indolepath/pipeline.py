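"""End-to-end pipeline: annotate -> predict -> summarize -> concordance -> stats."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .align import KarlinParams, ProteinRecord
from .concordance import ConcordanceReport, accuracy_report, phenotype_from_concentrations
from .homology import StrainAnnotation, search_homologs
from .io import RunConfig, annotation_summary_table, hit_table, read_fasta, write_tsv
from .network import MetabolicNetwork, ReferenceDB, load_network
from .predict import PredictionProfile, SpeciesSummary, profile_strain, summarize_by_species
from .stats import gene_metabolite_correlations

log = logging.getLogger("indolepath")

__all__ = ["PipelineResult", "annotate_cohort", "run_pipeline"]


@dataclass
class PipelineResult:
    annotations: list[StrainAnnotation]
    profiles: list[PredictionProfile]
    summary: SpeciesSummary
    concordance: ConcordanceReport | None
    correlations: pd.DataFrame | None


def annotate_cohort(
    proteomes: dict[str, list[ProteinRecord]],
    refdb: ReferenceDB,
    config: RunConfig,
) -> list[StrainAnnotation]:
    karlin = KarlinParams(config.karlin_lambda, config.karlin_k)
    log.info(
        "homology search: identity>=%s%%, E<=%s, qcov>=%s%%, scov>=%s%%, %s open %s extend %s",
        config.thresholds.min_identity, config.thresholds.max_evalue,
        config.thresholds.min_query_cover, config.thresholds.min_subject_cover,
        config.matrix, config.gap_open, config.gap_extend,
    )
    anns = []
    for strain in sorted(proteomes):
        anns.append(
            search_homologs(
                proteomes[strain],
                refdb,
                config.thresholds,
                strain_id=strain,
                matrix=config.matrix,
                gap_open=config.gap_open,
                gap_extend=config.gap_extend,
                karlin=karlin,
                unique_best_family=config.unique_best_family,
            )
        )
    return anns


def run_pipeline(
    proteomes: dict[str, list[ProteinRecord]],
    refdb: ReferenceDB,
    species_map: dict[str, str],
    config: RunConfig | None = None,
    concentrations: pd.DataFrame | None = None,
    counts_for_stats: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    network: MetabolicNetwork | None = None,
) -> PipelineResult:
    """Run every stage and optionally write all module outputs to ``out_dir``.

    Concordance and association stages run only when ``concentrations`` is
    given.  Outputs are deterministic for fixed inputs and config.
    """
    config = config or RunConfig()
    network = network or load_network(config.network)
    annotations = annotate_cohort(proteomes, refdb, config)
    profiles = [
        profile_strain(a, network, hdhd_as_fldh=config.hdhd_as_fldh) for a in annotations
    ]
    summary = summarize_by_species(profiles, species_map, network)
    concord = None
    corr_df = None
    if concentrations is not None:
        phen = phenotype_from_concentrations(concentrations, config.detection_threshold)
        concord = accuracy_report(
            profiles, phen, species_map, network,
            include_ipya=config.include_ipya_in_accuracy,
        )
        counts = counts_for_stats
        if counts is None:
            counts = pd.DataFrame(
                [
                    {e: a.count.get(e, 0) for e in network.registry}
                    for a in annotations
                ],
                index=[a.strain_id for a in annotations],
            )
        corr = gene_metabolite_correlations(counts, concentrations, alpha=config.alpha)
        corr_df = pd.DataFrame([vars(r) for r in corr])
    result = PipelineResult(annotations, profiles, summary, concord, corr_df)
    if out_dir is not None:
        _write_artifacts(result, config, Path(out_dir))
    return result


def _write_artifacts(res: PipelineResult, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(annotation_summary_table(res.annotations), out / "annotation.tsv")
    write_tsv(hit_table(res.annotations), out / "hits.tsv")
    long_rows = [
        {"strain": p.strain_id, "metabolite": m, "predicted": int(m in p.predicted)}
        for p in res.profiles
        for m in sorted(res.summary.table.columns)
    ]
    write_tsv(pd.DataFrame(long_rows), out / "predictions.tsv")
    write_tsv(res.summary.formatted(), out / "species_summary.tsv", index=True)
    if res.concordance is not None:
        write_tsv(res.concordance.cells, out / "concordance.tsv")
        acc = pd.DataFrame(
            [{"metabolite": m, "accuracy": a}
             for m, a in sorted(res.concordance.per_metabolite_accuracy.items())]
            + [
                {"metabolite": "_mean_over_metabolites",
                 "accuracy": res.concordance.overall_accuracy_by_metabolite_mean},
                {"metabolite": "_pooled",
                 "accuracy": res.concordance.overall_accuracy_pooled},
            ]
        )
        write_tsv(acc, out / "accuracy.tsv")
    if res.correlations is not None:
        write_tsv(res.correlations, out / "correlations.tsv")
    cfg_text = config.to_json()
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": config.seed,
        "n_strains": len(res.profiles),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "config.json").write_text(cfg_text)


def load_proteome_dir(proteome_dir: str | Path) -> dict[str, list[ProteinRecord]]:
    """Strain id = FASTA file stem; one proteome FASTA per strain."""
    proteomes = {}
    for path in sorted(Path(proteome_dir).glob("*.fa*")):
        proteomes[path.stem] = read_fasta(path)
    if not proteomes:
        raise ValueError(f"no proteome FASTA files in {proteome_dir}")
    return proteomes
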