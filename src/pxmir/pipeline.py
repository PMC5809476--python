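"""End-to-end orchestration: simulate -> clean -> collapse -> map ->
annotate -> known/novel miRNAs -> differential expression -> targets ->
enrichment -> qPCR, with one seed, a run manifest and regenerable reports.

All stage thresholds live in :class:`PipelineConfig` with the pipeline's
canonical defaults: insert length 18-30 nt, known-miRNA raw count >= 10 in
at least one library, TPM zero substitution 0.01 and minimum 1, novel
criteria (score > 1, shuffle p < 0.05, MFE < -19 kcal/mol), DE alpha 0.05
with |log2FC| >= 1 after Bonferroni, enrichment corrected p <= 0.05.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog as cat
from . import diffexpr, enrich, qpcr, targets
from . import reads as rd
from . import simulate as sim

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_reports"]


@dataclass
class PipelineConfig:
    seed: int = 0
    # cleaning
    min_insert_len: int = 18
    max_insert_len: int = 30
    # known miRNAs
    known_min_count: int = 10
    # expression / DE
    tpm_zero_sub: float = 0.01
    tpm_min: float = 1.0
    de_alpha: float = 0.05
    de_fc_min: float = 1.0
    # novel miRNAs
    novel_score_min: float = 1.0
    novel_randfold_alpha: float = 0.05
    novel_mfe_max: float = -19.0
    novel_min_count: int = 10
    novel_n_shuffles: int = 99
    # targets
    align_threshold: float = 80.0
    duplex_threshold: float = -20.0
    seed_min_type: str = "7mer"
    # enrichment
    enrich_alpha: float = 0.05
    enrich_correction: str = "bonferroni"
    # simulation scale (the synthetic study's conditions)
    simulation: sim.SimulationConfig | None = None

    def __post_init__(self):
        if self.simulation is None:
            self.simulation = sim.SimulationConfig(seed=self.seed)
        self.validate()

    def validate(self) -> None:
        if self.min_insert_len < 1 or self.max_insert_len < self.min_insert_len:
            raise ValueError("bad insert length bounds")
        for name in ("de_alpha", "novel_randfold_alpha", "enrich_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1)")
        if self.enrich_correction not in ("bonferroni", "benjamini_hochberg"):
            raise ValueError("unknown enrichment correction")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    study: sim.SyntheticStudy
    stats: dict[str, rd.LibraryStats]
    tags: list[rd.CleanTag]
    hits: dict
    annotation: dict[str, str]
    known_records: list[cat.ExpressionRecord]
    counts: pd.DataFrame
    tpm: pd.DataFrame
    novel_candidates: list[cat.HairpinCandidate]
    novel_accepted: list[cat.HairpinCandidate]
    de_results: dict[str, list[diffexpr.ACTestResult]]
    consensus_sites: list[targets.TargetSite]
    venn: dict[str, int]
    enrichment: list[enrich.EnrichmentResult]
    classification: pd.DataFrame
    qpcr_records: list[qpcr.QpcrRecord]
    qpcr_stats: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage on a synthetic study; deterministic per seed."""
    scfg = config.simulation
    manifest: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                      "stages": {}}

    study = sim.generate_all(scfg)
    manifest["stages"]["simulate"] = {
        "libraries": len(study.libraries),
        "reads_per_library": scfg.reads_per_library}

    inserts: dict[str, list[str]] = {}
    stats: dict[str, rd.LibraryStats] = {}
    for lib, lib_reads in study.libraries.items():
        stream = (rd.RawRead(i, s, q, lib) for i, s, q in lib_reads)
        inserts[lib], stats[lib] = rd.clean_reads(
            stream, scfg.adapter3, scfg.adapter5, library=lib,
            min_len=config.min_insert_len, max_len=config.max_insert_len)
    manifest["stages"]["clean"] = {
        lib: st.clean_total for lib, st in stats.items()}

    tags = rd.collapse_tags(inserts)
    manifest["stages"]["collapse"] = {"unique_tags": len(tags)}

    hits = rd.map_tags(tags, study.genome)
    for lib, st in stats.items():
        st.mapped_total = rd.mapped_read_total(tags, hits, lib)
    manifest["stages"]["map"] = {
        "mapped_tags": sum(1 for h in hits.values() if h)}

    features = [(c, s, e, rd.GFF_TYPE_MAP[t])
                for c, s, e, t, _n in study.gff_records
                if t in rd.GFF_TYPE_MAP]
    annotation = rd.annotate_tags(tags, hits, features)
    manifest["stages"]["annotate"] = {
        cls: sum(1 for v in annotation.values() if v == cls)
        for cls in set(annotation.values())}

    mature_catalog = [cat.MatureMiRNA(e["name"], e["mature"])
                      for e in study.known_catalog]
    known_records = cat.filter_low_count(
        cat.match_known(tags, mature_catalog),
        min_count=config.known_min_count)
    counts = pd.DataFrame(
        {lib: {r.mirna: r.raw_counts.get(lib, 0) for r in known_records}
         for lib in scfg.libraries}).fillna(0).astype(int)
    clean_totals = {lib: stats[lib].clean_total for lib in scfg.libraries}
    tpm = diffexpr.normalize_tpm(counts, clean_totals,
                                 zero_sub=config.tpm_zero_sub)
    for r in known_records:
        r.tpm = {lib: float(tpm.at[r.mirna, lib]) for lib in scfg.libraries}
    manifest["stages"]["known"] = {"retained": len(known_records)}

    unannotated = [t for t in tags if annotation[t.sequence] == "unannotated"]
    novel_candidates = cat.discover_novel(
        unannotated, hits, study.genome,
        n_shuffles=config.novel_n_shuffles, seed=config.seed,
        min_count=config.novel_min_count, lazy_shuffle=True)
    novel_accepted = cat.filter_novel(
        novel_candidates, score_min=config.novel_score_min,
        alpha=config.novel_randfold_alpha, mfe_max=config.novel_mfe_max)
    manifest["stages"]["novel"] = {"candidates": len(novel_candidates),
                                   "accepted": len(novel_accepted)}

    de_results = diffexpr.test_all(
        counts, clean_totals, scfg.control, scfg.treatments,
        alpha=config.de_alpha, fc_threshold=config.de_fc_min,
        min_tpm=config.tpm_min)
    manifest["stages"]["de"] = {
        trt: {"up": sum(r.regulation == "up" for r in res),
              "down": sum(r.regulation == "down" for r in res),
              "tested": len(res)}
        for trt, res in de_results.items()}

    de_mirnas = sorted({r.mirna for res in de_results.values() for r in res
                        if r.regulation != "ns"})
    by_name = {e["name"]: e["mature"] for e in study.known_catalog}
    consensus_sites, venn = targets.predict_targets(
        {m: by_name[m] for m in de_mirnas if m in by_name}, study.utrs,
        align_threshold=config.align_threshold,
        duplex_threshold=config.duplex_threshold,
        seed_min_type=config.seed_min_type)
    manifest["stages"]["targets"] = {"consensus": len(consensus_sites),
                                     **venn}

    term_map = pd.DataFrame(study.term_rows,
                            columns=["gene_id", "term_id", "term_name",
                                     "category"])
    target_genes = sorted({s.transcript for s in consensus_sites})
    background = sorted(study.utrs)
    enrichment = enrich.correct_terms(
        enrich.hypergeom_enrich(target_genes, background, term_map),
        method=config.enrich_correction)
    classification = enrich.classification_table(target_genes, term_map)
    manifest["stages"]["enrich"] = {
        "tested_terms": len(enrichment),
        "significant": sum(r.p_corrected <= config.enrich_alpha
                           for r in enrichment)}

    ct = pd.DataFrame(study.qpcr_rows)
    qpcr_records = qpcr.delta_delta_ct(ct, scfg.control)
    qpcr_stats = qpcr.group_stats(qpcr_records)
    manifest["stages"]["qpcr"] = {"targets": ct["target"].nunique()}

    return PipelineResult(
        config=config, study=study, stats=stats, tags=tags, hits=hits,
        annotation=annotation, known_records=known_records, counts=counts,
        tpm=tpm, novel_candidates=novel_candidates,
        novel_accepted=novel_accepted, de_results=de_results,
        consensus_sites=consensus_sites, venn=venn, enrichment=enrichment,
        classification=classification, qpcr_records=qpcr_records,
        qpcr_stats=qpcr_stats, manifest=manifest)


def _hdr(config: PipelineConfig) -> str:
    return f"# config_hash={config.config_hash()}\n"


def write_reports(result: PipelineResult, outdir) -> list[str]:
    """Write the TSV/JSON report set; returns the file names written."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    scfg = cfg.simulation
    written = []

    def save(name: str, df: pd.DataFrame, **kw):
        path = out / name
        with open(path, "w") as fh:
            fh.write(_hdr(cfg))
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g", **kw)
        written.append(name)

    # library stats (cleaning cascade + mapping)
    rows = []
    for lib, st in result.stats.items():
        rows.append({
            "library": lib, "raw_total": st.raw_total,
            "removed_low_quality": st.removed_low_quality,
            "removed_5prime_contaminant": st.removed_5prime_contaminant,
            "removed_no_3adapter_or_insert": st.removed_no_3adapter_or_insert,
            "removed_short": st.removed_short,
            "clean_total": st.clean_total, "mapped_total": st.mapped_total})
    save("library_stats.tsv", pd.DataFrame(rows))

    hist = rd.length_distribution(result.tags)
    rows = [{"library": lib, "length": L, "frequency": f}
            for lib in scfg.libraries for L, f in hist.get(lib, {}).items()]
    save("length_histogram.tsv", pd.DataFrame(rows))

    # abundance: mean TPM across the four libraries, top 10
    mean_tpm = result.tpm.mean(axis=1).sort_values(ascending=False)
    ab = mean_tpm.rename("mean_tpm").reset_index().rename(
        columns={"index": "mirna"})
    save("abundance.tsv", ab)
    save("abundance_top10.tsv", ab.head(10))

    for trt, res in result.de_results.items():
        rows = [{"mirna": r.mirna, "x": r.x, "y": r.y, "N1": r.N1, "N2": r.N2,
                 "tpm_control": r.tpm_control, "tpm_treatment": r.tpm_treatment,
                 "log2fc": r.log2fc, "C": r.C, "D": r.D,
                 "p_value": r.p_value, "p_corrected": r.p_corrected,
                 "regulation": r.regulation} for r in res]
        save(f"de_{trt}.tsv", pd.DataFrame(rows))
        volcano = diffexpr.classify_de(
            list(res), m=len(res), alpha=cfg.de_alpha,
            fc_threshold=cfg.de_fc_min)
        save(f"volcano_{trt}.tsv", volcano)

    rows = [{"candidate": c.name, "locus": "{}:{}-{}({})".format(*c.locus),
             "mfe": c.mfe, "simplified_score": c.simplified_score,
             "randfold_p": c.randfold_p,
             "accepted": c in result.novel_accepted}
            for c in result.novel_candidates]
    save("novel_candidates.tsv", pd.DataFrame(rows))

    rows = [{"mirna": s.mirna, "transcript": s.transcript,
             "start": s.interval[0], "end": s.interval[1],
             "site_type": s.site_type, "align_score": s.align_score,
             "duplex_energy": s.duplex_energy}
            for s in result.consensus_sites]
    save("consensus_sites.tsv", pd.DataFrame(rows))
    save("venn_counts.tsv", pd.DataFrame(
        [{"set": k, "count": v} for k, v in result.venn.items()]))

    rows = [{"term": r.term, "name": r.name, "category": r.category,
             "k": r.k, "K": r.K, "n": r.n, "N": r.N,
             "p_value": r.p_value, "p_corrected": r.p_corrected}
            for r in result.enrichment]
    save("enrichment.tsv", pd.DataFrame(rows))
    save("classification.tsv", result.classification)
    save("qpcr_rq.tsv", result.qpcr_stats)

    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
    written.append("manifest.json")
    result.study.truth.to_json(out / "ground_truth.json")
    written.append("ground_truth.json")
    return written
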