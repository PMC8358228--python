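"""Orchestration of the full analysis: distances → ScrollSaw filtering →
annotation → intron mapping → Dollo loss mapping → motif/PTM screens.

External ML tree inference is a deliberate gap in the chain: the pipeline
exports the retained subset for tree building and ingests resulting Newick
files (with dual supports) for rooting and tree-based assignment; it never
shells out to external binaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .introns import GeneStructure, map_gene_to_alignment, shared_intron_clusters
from .io import (dedup_alignment, parse_fasta_alignment,
                 parse_newick_dual_support, parse_table, write_fasta)
from .minpairs import run_scrollsaw, write_pair_table
from .motifs import (MYRISTOYLATION_MIN_TOOLS, PALMITOYLATION_MIN_TOOLS,
                     consensus_from_table, group_feature_summary,
                     scan_nterm_motifs)
from .profiles import annotate_sequence, build_profile
from .treeops import dollo_map, mad_root

__all__ = ["RunReport", "run_full"]

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Stage outputs plus a manifest sufficient to re-run bit-identically."""

    manifest: dict
    scrollsaw: object = None
    annotations: pd.DataFrame | None = None
    intron_sites: pd.DataFrame | None = None
    intron_clusters: dict | None = None
    gain_loss: list = field(default_factory=list)
    rooting: object = None
    feature_summary: pd.DataFrame | None = None
    timings: dict = field(default_factory=dict)


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _manifest_header(manifest: dict) -> str:
    digest = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return f"# manifest {digest}\n"


def _write_tsv(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    with open(path, "w") as fh:
        fh.write(_manifest_header(manifest))
        df.to_csv(fh, sep="\t", index=False)


def run_full(
    inputs: dict,
    config: AnalysisConfig,
    outdir,
    *,
    mode: str = "pan_eukaryotic",
) -> RunReport:
    """Run every stage for which the required inputs are present.

    ``inputs`` maps input kinds to paths: ``alignment`` (required),
    ``taxon_map`` (required), and optionally ``reference_labels`` (TSV id,
    label — the annotated retained set used to build profiles), ``tree``
    (Newick with dual supports, used for MAD rooting), ``species_tree``
    (rooted Newick for Dollo mapping), ``gene_structures``,
    ``presence_absence`` and ``predictor_calls`` TSVs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "mode": mode,
        "inputs": {k: _digest(v) for k, v in inputs.items()},
        "version": __version__,
    }
    report = RunReport(manifest=manifest)
    model = config.build_model()

    def stage(name):
        logger.info("stage %s", name)
        return time.monotonic()

    t0 = stage("parse")
    aln = parse_fasta_alignment(inputs["alignment"], aligned=True)
    taxon_map = parse_table(inputs["taxon_map"], "taxon_map", groups=config.groups)
    taxon_map.check_covers(aln.ids)
    n_in = len(aln)
    aln = dedup_alignment(aln)
    logger.info("parsed %d sequences, %d nonidentical", n_in, len(aln))
    report.timings["parse"] = time.monotonic() - t0

    t0 = stage("scrollsaw")
    min_pairs = (config.min_pair_count_pan if mode == "pan_eukaryotic"
                 else config.min_pair_count_taxon)
    ss = run_scrollsaw(aln, taxon_map, model, mode=mode, min_pairs=min_pairs,
                       min_overlap=config.min_overlap, d_max=config.d_max)
    report.scrollsaw = ss
    write_pair_table(ss, outdir / "minimal_pairs.tsv")
    retained_rows = aln.subset(ss.retained_set)
    write_fasta(retained_rows, outdir / "retained.fasta")
    (outdir / "retained_ids.txt").write_text(
        "".join(f"{i}\n" for i in sorted(ss.retained_set)))
    report.timings["scrollsaw"] = time.monotonic() - t0

    ref_labels: dict[str, str] = {}
    if "reference_labels" in inputs:
        df = pd.read_csv(inputs["reference_labels"], sep="\t", dtype=str, comment="#")
        ref_labels = dict(zip(df["id"], df["label"]))

    tree = None
    if "tree" in inputs:
        t0 = stage("mad")
        tree = parse_newick_dual_support(inputs["tree"])
        rooted, best, _ = mad_root(tree)
        report.rooting = best
        from .io import write_newick_dual_support

        write_newick_dual_support(rooted, outdir / "rooted.nwk")
        report.timings["mad"] = time.monotonic() - t0

    annotations: dict[str, object] = {}
    if ref_labels:
        t0 = stage("annotate")
        by_label: dict[str, list[str]] = {}
        for seq_id, label in ref_labels.items():
            if seq_id in aln:
                by_label.setdefault(label, []).append(seq_id)
        profiles = [build_profile(aln.subset(ids), label)
                    for label, ids in sorted(by_label.items()) if len(ids) >= 2]
        rows = []
        for r in aln.rows:
            if r.id in ref_labels:
                continue
            decision = annotate_sequence(
                r, profiles, tree=tree, refs=ref_labels,
                sh_min=config.sh_alrt_min, ufboot_min=config.ufboot_min,
                margin_threshold=config.hmm_margin_bits)
            annotations[r.id] = decision
            rows.append({"seq_id": r.id, "label": decision.label,
                         "method": decision.method})
        report.annotations = pd.DataFrame(rows)
        _write_tsv(report.annotations, outdir / "annotations.tsv", manifest)
        report.timings["annotate"] = time.monotonic() - t0

    if "gene_structures" in inputs:
        t0 = stage("introns")
        genes = [GeneStructure(g, s, tuple(o))
                 for g, s, o in parse_table(inputs["gene_structures"], "gene_structure")
                 if s in aln]
        rows = []
        for gene in genes:
            for site in map_gene_to_alignment(gene, aln):
                rows.append({"gene_id": gene.gene_id, "seq_id": gene.seq_id,
                             "residue": site.residue_index, "phase": site.phase,
                             "column": site.column})
        report.intron_sites = pd.DataFrame(
            rows, columns=["gene_id", "seq_id", "residue", "phase", "column"])
        labels = {**{s: l for s, l in ref_labels.items()},
                  **{s: d.label for s, d in annotations.items()}}
        report.intron_clusters = shared_intron_clusters(genes, aln, labels=labels)
        _write_tsv(report.intron_sites, outdir / "intron_sites.tsv", manifest)
        report.timings["introns"] = time.monotonic() - t0

    if "presence_absence" in inputs and "species_tree" in inputs:
        t0 = stage("dollo")
        pa = parse_table(inputs["presence_absence"], "presence_absence")
        sp_tree = parse_newick_dual_support(inputs["species_tree"])
        maps = []
        for paralog in pa.columns:
            col = pa[paralog]
            present = set(col[col == 1].index)
            absent = set(col[col == 0].index)
            if not present:
                logger.warning("paralog %s present nowhere; skipped", paralog)
                continue
            maps.append(dollo_map(sp_tree, present, absent, gain="root",
                                  paralog=paralog))
        report.gain_loss = maps
        df = pd.DataFrame([{
            "paralog": m.paralog, "n_losses": m.n_losses,
            "loss_edges": "|".join(",".join(sorted(e)) for e in m.loss_edges),
        } for m in maps])
        _write_tsv(df, outdir / "gain_loss.tsv", manifest)
        report.timings["dollo"] = time.monotonic() - t0

    if "predictor_calls" in inputs:
        t0 = stage("ptm")
        calls = parse_table(inputs["predictor_calls"], "predictor_calls")
        reports = {r.id: scan_nterm_motifs(r) for r in aln.rows
                   if len(r.ungapped) >= 3}
        myr = consensus_from_table(calls, "myristoylation", MYRISTOYLATION_MIN_TOOLS)
        palm = consensus_from_table(calls, "palmitoylation", PALMITOYLATION_MIN_TOOLS) \
            if (calls["modification"] == "palmitoylation").any() else pd.DataFrame(columns=["seq_id", "verdict"])
        tm = calls[calls["modification"] == "tm"]
        tm_pos = set(tm[tm["call"]]["seq_id"]) if len(tm) else set()
        labels = {**ref_labels, **{s: d.label for s, d in annotations.items()}}
        labels = {s: l for s, l in labels.items() if s in reports and l != "unclassified"}
        if labels:
            report.feature_summary = group_feature_summary(
                labels, reports,
                myr_positive=set(myr[myr["verdict"]]["seq_id"]),
                palm_positive=set(palm[palm["verdict"]]["seq_id"]) if len(palm) else set(),
                tm_positive=tm_pos)
            _write_tsv(report.feature_summary, outdir / "feature_summary.tsv", manifest)
        report.timings["ptm"] = time.monotonic() - t0

    with open(outdir / "manifest.json", "w") as fh:
        json.dump({**manifest, "timings": report.timings}, fh, indent=2, default=str)
    return report
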