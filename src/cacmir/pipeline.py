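"""End-to-end orchestration: screen -> hairpin -> targets -> annotate -> network.

``run_pipeline`` executes every configured stage in order, writes each
stage's table under the output directory, and returns a ``FunnelReport``
of the counts at every filter.  The run is fully deterministic given the
master seed (per-stage seeds derive from it by fixed offsets).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate as _annotate
from . import netanalysis as _net
from .errors import CacmirError, ParameterError
from .hairpin import (
    HairpinThresholds,
    PutativeMiRNA,
    assign_name,
    evaluate_hairpin,
    extract_precursor,
    fold,
)
from .homolog_screen import (
    ScreenParams,
    ScreenStats,
    filter_coding,
    find_homologs,
    remove_redundant,
)
from .io_formats import SequenceRecord, read_fasta, write_report
from .target_scan import TargetParams, compute_upe, count_unique_targets, find_sites

# fixed per-stage seed offsets derived from the master seed
_SEED_RANDOMIZATION = 7001


@dataclass
class PipelineConfig:
    refs: str | None = None
    ests: str | None = None
    transcripts: str | None = None
    annotations: str | None = None
    associations: str | None = None
    interactions_binary: str | None = None
    interactions_complexes: str | None = None
    outdir: str = "pipeline_out"
    screen: ScreenParams = field(default_factory=ScreenParams)
    hairpin: HairpinThresholds = field(default_factory=HairpinThresholds)
    flank: int = 100
    target: TargetParams = field(default_factory=TargetParams)
    alpha: float = 0.05
    disease_keyword: str | None = "cancer"
    n_randomization_reps: int = 200
    run_randomization: bool = True
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (("screen", ScreenParams), ("hairpin", HairpinThresholds), ("target", TargetParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ParameterError(f"invalid config: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class FunnelReport:
    """Counts at every stage of the screening funnel."""

    input_ests: int = 0
    word_seed_hits: int = 0
    homolog_hits: int = 0
    after_redundancy: int = 0
    after_coding_filter: int = 0
    hairpin_pass: int = 0
    named_mirnas: int = 0
    target_pairs: int = 0
    unique_target_genes: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> FunnelReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    funnel = FunnelReport()

    stage = "screen"
    try:
        refs = read_fasta(config.refs) if config.refs else []
        ests = read_fasta(config.ests) if config.ests else []
        funnel.input_ests = len(ests)

        stats = ScreenStats()
        hits = find_homologs(refs, ests, config.screen, stats=stats)
        funnel.word_seed_hits = stats.n_word_seed_placements
        funnel.homolog_hits = len(hits)
        est_by_id = {e.id: e for e in ests}

        # candidate mature sequence for each hit, on the hit strand
        def mature_of(hit) -> str:
            seq = est_by_id[hit.est_id].sequence[hit.est_start : hit.est_end]
            if hit.strand == "-":
                from .io_formats import revcomp

                seq = revcomp(seq)
            return seq

        unique_hits, _ = remove_redundant(hits, key=mature_of)
        funnel.after_redundancy = len(unique_hits)

        noncoding, _ = filter_coding(
            [est_by_id[h.est_id] for h in unique_hits], config.screen
        )
        noncoding_ids = {e.id for e in noncoding}
        candidates = [h for h in unique_hits if h.est_id in noncoding_ids]
        funnel.after_coding_filter = len(candidates)
        write_report(
            [dataclasses.asdict(h) for h in hits],
            outdir / "homolog_hits.tsv",
            columns=["est_id", "ref_mirna_id", "est_start", "est_end", "strand", "mismatches", "identity"],
        )

        stage = "hairpin"
        putative: list[PutativeMiRNA] = []
        hairpin_rows = []
        for hit in candidates:
            est = est_by_id[hit.est_id]
            cand = extract_precursor(est, hit, flank=config.flank)
            result = fold(cand.sequence)
            ev = evaluate_hairpin(cand, result, hit, config.hairpin)
            row = {
                "est_id": hit.est_id,
                "homolog": hit.ref_mirna_id,
                "mature": mature_of(hit),
                "msl": hit.est_end - hit.est_start,
                "psl": len(cand.sequence),
                "mfe_dg": ev.mfe_dg,
                "gc_percent": ev.gc_percent,
                "mfei": ev.mfei,
                "arm": cand.arm,
                "verdict": ev.verdict,
            }
            hairpin_rows.append(row)
            if ev.verdict:
                name = assign_name(hit.ref_mirna_id)
                putative.append(
                    PutativeMiRNA(
                        name=name,
                        homolog_name=hit.ref_mirna_id,
                        mature_seq=mature_of(hit),
                        precursor=cand,
                        evaluation=ev,
                    )
                )
        funnel.hairpin_pass = len(putative)
        named, _ = remove_redundant(putative, key=lambda p: p.name)
        funnel.named_mirnas = len(named)
        write_report(
            hairpin_rows,
            outdir / "hairpin_evaluation.tsv",
            columns=["est_id", "homolog", "mature", "msl", "psl", "mfe_dg", "gc_percent", "mfei", "arm", "verdict"],
        )

        stage = "targets"
        pairs = []
        site_rows = []
        if config.transcripts and named:
            transcripts = read_fasta(config.transcripts)
            for mir in named:
                query = SequenceRecord(id=mir.name, sequence=mir.mature_seq)
                for tx in transcripts:
                    for site in find_sites(query, tx, config.target):
                        site.upe = compute_upe(tx, site, params=config.target)
                        pairs.append((mir.name, tx.id))
                        site_rows.append(
                            {
                                "mirna": mir.name,
                                "gene": tx.id,
                                "start": site.site_start,
                                "end": site.site_end,
                                "expectation": site.expectation,
                                "mismatches": site.n_mismatches,
                                "gu": site.n_gu,
                                "inhibition": site.inhibition,
                                "upe": site.upe,
                            }
                        )
        n_genes, n_pairs = count_unique_targets(pairs)
        funnel.target_pairs = n_pairs
        funnel.unique_target_genes = n_genes
        write_report(
            site_rows,
            outdir / "target_sites.tsv",
            columns=["mirna", "gene", "start", "end", "expectation", "mismatches", "gu", "inhibition", "upe"],
        )

        stage = "annotate"
        if config.annotations and site_rows:
            sets = _annotate.read_annotation_table(config.annotations)
            query = sorted({r["gene"] for r in site_rows})
            results = _annotate.enrich(query, sets, alpha=config.alpha)
            write_report(
                [
                    {
                        "term_id": r.term_id,
                        "term_name": r.term_name,
                        "category": r.category,
                        "k": r.k,
                        "K": r.K,
                        "p_value": r.p_value,
                        "p_adjusted": r.p_adjusted,
                        "significant": r.significant,
                    }
                    for r in results
                ],
                outdir / "enrichment.tsv",
                columns=["term_id", "term_name", "category", "k", "K", "p_value", "p_adjusted", "significant"],
            )
        if config.associations and site_rows:
            assocs = _annotate.read_associations(config.associations)
            query = sorted({r["gene"] for r in site_rows})
            dmap = _annotate.map_diseases(query, assocs, keyword=config.disease_keyword)
            write_report(dmap.by_disease, outdir / "disease_map.json", format="json")

        stage = "network"
        if config.interactions_binary:
            data = _net.read_interactions(config.interactions_binary, config.interactions_complexes)
            network = _net.build_network(data)
            report = _net.centrality_report(network)
            report.table.to_csv(outdir / "centralities.tsv", sep="\t", float_format="%.6g")
            hubs = {
                method: [
                    {"rank": r, "protein": str(node), "score": float(score)}
                    for (r, node, score) in _net.rank_hubs(report, method=method)
                ]
                for method in ("degree", "bottleneck")
            }
            write_report(hubs, outdir / "hubs.json", format="json")
            if config.run_randomization and network.graph.number_of_nodes() >= 2:
                rand = _net.randomize_and_test(
                    network,
                    n_reps=config.n_randomization_reps,
                    seed=(config.master_seed + _SEED_RANDOMIZATION) % (2**31),
                    alpha=config.alpha,
                )
                write_report(
                    {
                        "ks_statistic": rand.ks_statistic,
                        "p_value": rand.p_value,
                        "n_replicates": rand.n_replicates,
                        "model": list(rand.model),
                        "significant": rand.significant,
                    },
                    outdir / "randomization.json",
                    format="json",
                )
    except CacmirError as exc:
        raise CacmirError(f"pipeline stage {stage!r} failed: {exc}") from exc

    write_report(funnel.as_dict(), outdir / "funnel.json", format="json")
    return funnel
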