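"""End-to-end orchestration: simulate -> preprocess -> collapse/align ->
quantify -> differential expression -> network, with a run manifest.

Every stage's outputs land under a run directory with fixed names; the
manifest records the configuration snapshot, the root seed, per-stage
record counts and SHA-256 checksums of every output file, so a rerun
with identical configuration and seed is verifiably identical.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import align as _align
from . import collapse as _collapse
from . import diffexp as _diffexp
from . import network as _network
from . import preprocess as _preprocess
from . import quantify as _quantify
from . import synthetic as _synthetic
from .config import RunConfig
from .io import read_fastq, write_annotation_gff3, write_genome_fasta, write_network

log = logging.getLogger("srnakit")

STAGES = ("synthesize", "preprocess", "collapse_align", "quantify", "diffexp", "network")


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, counts: dict, outputs: dict[str, Path]) -> None:
        self.stages.append(
            {
                "stage": name,
                "counts": counts,
                "outputs": {k: _sha256(p) for k, p in outputs.items()},
                "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
            }
        )

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "seed": self.seed, "stages": self.stages},
                      fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_all(
    config: RunConfig,
    outdir: str | Path,
    genome_design: _synthetic.GenomeDesign | None = None,
    library_design: _synthetic.LibraryDesign | None = None,
    n_spiked: int = 20,
    outlier_library: str | None = None,
) -> RunManifest:
    """Run the full synthetic pipeline; returns the manifest.

    Intermediate and final tables are written under ``outdir`` with fixed
    names (counts.tsv, nev.tsv, de_results.tsv, network.sif, ...).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest = RunManifest(config.to_dict(), seed)
    gdesign = genome_design or _synthetic.GenomeDesign()
    ldesign = library_design or _synthetic.LibraryDesign()

    # --- synthesize -------------------------------------------------------
    log.info("stage synthesize")
    genome, annotation = _synthetic.make_genome_and_annotation(gdesign, seed)
    truth = _synthetic.build_truth(annotation, ldesign, n_spiked=n_spiked, seed=seed,
                                   outlier_library=outlier_library)
    sim = _synthetic.simulate_libraries(genome, annotation, truth, ldesign, seed,
                                        outdir / "reads")
    interactions, pair_info = _synthetic.make_interaction_databases(
        truth, seed=seed, min_db_support=config.min_db_support
    )
    tables = _synthetic.make_gene_tables(truth, seed=seed)
    genome_path = outdir / "genome.fa"
    ann_path = outdir / "annotation.gff3"
    write_genome_fasta(genome, genome_path)
    write_annotation_gff3(annotation, ann_path)
    truth.to_files(outdir / "truth")
    interactions.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    tables.to_files(outdir)
    manifest.add_stage(
        "synthesize",
        {"features": len(annotation), "libraries": len(ldesign.libraries),
         "reads": int(sim.library_totals.sum())},
        {"genome": genome_path, "annotation": ann_path,
         "interactions": outdir / "interactions.tsv"},
    )

    # --- preprocess -------------------------------------------------------
    log.info("stage preprocess")
    clipper = _preprocess.AdapterClipper(
        config.adapter, config.adapter_error_rate, config.adapter_min_overlap
    )
    processed: dict[str, list] = {}
    reports = []
    for lib, path in sim.fastq_paths.items():
        kept, rep = _preprocess.preprocess_reads(
            read_fastq(path), config, library=lib, clipper=clipper
        )
        processed[lib] = kept
        reports.append(rep)
    report_df = pd.DataFrame(
        {
            "library": [r.library for r in reports],
            "raw_reads": [r.raw_reads for r in reports],
            "kept_reads": [r.kept_reads for r in reports],
            "discarded_pct": [r.discarded_pct for r in reports],
            "length_mode": [r.length_mode for r in reports],
        }
    )
    pre_path = outdir / "preprocess_report.tsv"
    report_df.to_csv(pre_path, sep="\t", index=False)
    manifest.add_stage(
        "preprocess",
        {"raw": int(report_df["raw_reads"].sum()), "kept": int(report_df["kept_reads"].sum())},
        {"report": pre_path},
    )

    # --- collapse + align -------------------------------------------------
    log.info("stage collapse_align")
    tags, singletons = _collapse.collapse(processed)
    policy = _align.AlignPolicy(config.max_mismatches, True, config.max_loci,
                                config.loci_cap_post_stratum)
    hits = _align.align_tags(tags, genome, policy)
    aln_path = outdir / "alignments.tsv"
    _align.write_alignments_tsv(hits, aln_path)
    manifest.add_stage(
        "collapse_align",
        {"tags": len(tags), "singleton_reads": singletons,
         "mapped_tags": sum(1 for h in hits.values() if h)},
        {"alignments": aln_path},
    )

    # --- quantify ---------------------------------------------------------
    log.info("stage quantify")
    if not Path(ann_path).exists():  # defensive: quantify needs the annotation
        raise StageError("quantify", f"missing annotation file {ann_path}")
    libraries = list(sim.fastq_paths)
    assignments = _quantify.assign_tags(hits, annotation, config.overlap_fraction)
    counts, stats = _quantify.fractional_count(assignments, tags, libraries, annotation)
    nev = _quantify.normalize(counts, config.nev_mode,
                              library_totals=stats.table["mapped"])
    counts_path, nev_path, stats_path = (
        outdir / "counts.tsv", outdir / "nev.tsv", outdir / "annotation_stats.tsv",
    )
    counts.to_csv(counts_path, sep="\t", index_label="feature")
    nev.to_csv(nev_path, sep="\t", index_label="feature")
    stats.table.to_csv(stats_path, sep="\t", index_label="library")
    manifest.add_stage(
        "quantify",
        {"features_quantified": int((counts.sum(axis=1) > 0).sum())},
        {"counts": counts_path, "nev": nev_path, "stats": stats_path},
    )

    # --- diffexp ----------------------------------------------------------
    log.info("stage diffexp")
    model = _diffexp.SmallRNADEModel(
        counts, ldesign.groups, control="N", case="C", pairs=ldesign.pairs, nev=nev
    )
    outrep = model.remove_outliers(config.outlier_sd, config.pca_log_transform)
    results = model.fit(de_fdr=config.de_fdr)
    de_path = outdir / "de_results.tsv"
    results.table.to_csv(de_path, sep="\t")
    out_path = outdir / "outliers.tsv"
    outrep.scores.assign(
        flagged=[s in outrep.flagged for s in outrep.scores.index],
        removed=[s in outrep.removed for s in outrep.scores.index],
    ).to_csv(out_path, sep="\t", index_label="library")
    results.ma_table().to_csv(outdir / "ma.tsv", sep="\t")
    newick = results.cluster_newick()
    if newick:
        (outdir / "clustering.nwk").write_text(newick + "\n")
    results.boxplot_table().to_csv(outdir / "boxplot.tsv", sep="\t", index=False)
    manifest.add_stage(
        "diffexp",
        {"significant": int(len(results.significant)),
         "outliers_removed": len(outrep.removed)},
        {"de_results": de_path, "outliers": out_path, "ma": outdir / "ma.tsv"},
    )

    # --- network ----------------------------------------------------------
    log.info("stage network")
    sig = results.significant
    de_mirnas = {
        f: d for f, d in sig["direction"].items() if f.startswith("mir")
    }
    edges = _network.build_network(
        de_mirnas, tables.up_genes, tables.down_genes, interactions,
        config.min_db_support,
    )
    sif_path, gml_path = outdir / "network.sif", outdir / "network.graphml"
    write_network(edges, sif_path, "sif")
    write_network(edges, gml_path, "graphml")
    per_mirna, per_gene = _network.target_counts(edges)
    per_mirna.rename("n_targets").to_csv(outdir / "target_counts.tsv", sep="\t",
                                         index_label="mirna")
    manifest.add_stage(
        "network",
        {"edges": len(edges), "mirnas": int(per_mirna.size), "genes": int(per_gene.size)},
        {"sif": sif_path, "graphml": gml_path},
    )

    manifest.write(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def add_average_row(table: pd.DataFrame, label: str = "Average") -> pd.DataFrame:
    """Append a row of full-precision column means (display rounds later)."""
    avg = table.mean(axis=0, numeric_only=True)
    out = table.copy()
    out.loc[label] = avg
    return out


def read_accounting_table(
    preprocess_report: pd.DataFrame, annotation_stats: pd.DataFrame
) -> pd.DataFrame:
    """Per-library read accounting (raw, trimmed, sncRNA, miRNA) with an
    Average row, mirroring the classic overview table layout."""
    t = pd.DataFrame(
        {
            "raw_reads": preprocess_report.set_index("library")["raw_reads"],
            "trimmed_reads": preprocess_report.set_index("library")["kept_reads"],
            "sncRNA": annotation_stats["sncRNA"],
            "miRNA": annotation_stats["miRNA"],
        }
    )
    return add_average_row(t)


def top_de_table(de_table: pd.DataFrame, k: int = 15) -> dict[str, pd.DataFrame]:
    """Top-k down- and upregulated features sorted by FDR."""
    out = {}
    for direction in ("down", "up"):
        sub = de_table[de_table["direction"] == direction].sort_values("fdr").head(k)
        out[direction] = sub[["control_nev", "cancer_nev", "log2_fold_change", "fdr"]]
    return out
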