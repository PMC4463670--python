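"""End-to-end pipeline: simulate? -> clean -> annotate -> identify -> isomiR
-> differential expression -> qPCR? -> target scan?, with a run manifest.

Each stage writes its table under the output directory so stages are
individually re-runnable from intermediate files; the manifest records the
package version, parameters and SHA-256 digests of every input consumed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import catalog_table, detect_duplexes, group_families, identify_conserved
from .expression import DEConfig, build_table, call_de, scatter_table
from .isomir import isomir_table, nta_profile, substitution_spectrum
from .mapping import annotate_tags, annotation_summary, map_tags, retain_for_mirna
from .qpcr import cluster_heatmap, read_ct_table, relative_expression
from .reads import (
    clean_fastq,
    collapse_unique,
    common_specific,
    length_distribution,
    write_collapsed_fasta,
    write_summary_tsv,
)
from .seedscan import scan_targets, sites_table
from .seqs import read_fasta, to_rna
from .simulate import ArmAnnotation, ReferenceBundle, SimulationConfig, generate_references, simulate_libraries, write_libraries


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_arms_tsv(path) -> dict[str, ArmAnnotation]:
    arms = {}
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples():
        star = None if row.star_name in (".", "", None) else row.star_name
        arms[row.hairpin_id] = ArmAnnotation(
            row.hairpin_id,
            row.mature_name,
            int(row.mature_start),
            int(row.mature_end),
            star,
            int(row.star_start),
            int(row.star_end),
        )
    return arms


def load_references(paths: dict) -> tuple[ReferenceBundle, dict[str, dict[str, str]]]:
    """Load references from FASTA/TSV paths into a bundle plus annotation refs."""
    genome = read_fasta(paths["genome"])
    hairpins = read_fasta(paths["hairpin"])
    mature = read_fasta(paths["mature"])
    arms = read_arms_tsv(paths["arms"])
    ncrna: dict[str, list[tuple[str, str]]] = {}
    from Bio import SeqIO

    if paths.get("ncrna"):
        for rec in SeqIO.parse(str(paths["ncrna"]), "fasta"):
            cat = "unknown"
            for token in rec.description.split():
                if token.startswith("category="):
                    cat = token.split("=", 1)[1]
            ncrna.setdefault(cat, []).append((rec.id, str(rec.seq).upper().replace("U", "T")))
    if paths.get("transcripts"):
        tx = read_fasta(paths["transcripts"])
        ncrna["mRNA_fragment"] = list(tx.items())
    bundle = ReferenceBundle(genome, hairpins, mature, arms, ncrna)
    category_refs = {cat: dict(entries) for cat, entries in ncrna.items()}
    return bundle, category_refs


def run_pipeline(config: dict, outdir) -> dict:
    """Run the configured stages; returns a result dict and writes tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": _jsonable(config), "inputs": {}, "outputs": []}
    results: dict = {}

    def _record(path: Path):
        manifest["outputs"].append(str(path.relative_to(outdir)))

    # --- stage: simulate (optional) ---------------------------------------
    try:
        if "simulate" in config:
            sim = SimulationConfig(**config["simulate"])
            refs = generate_references(sim)
            ref_paths = refs.write(outdir / "refs")
            reads_a, reads_b, truth = simulate_libraries(sim, refs)
            fq_a, fq_b = write_libraries(reads_a, reads_b, outdir / "reads")
            truth.write(outdir / "truth")
            category_refs = {
                cat: dict(entries) for cat, entries in refs.ncrna.items()
            }
            adapter3 = sim.adapter3
            results["truth"] = truth
        else:
            refs, category_refs = load_references(config["inputs"])
            fq_a = Path(config["inputs"]["fastq_a"])
            fq_b = Path(config["inputs"]["fastq_b"])
            adapter3 = config.get("adapter3", SimulationConfig().adapter3)
            for key, p in config["inputs"].items():
                manifest["inputs"][key] = _sha256(Path(p))
        results["refs"] = refs
    except StageError:
        raise
    except Exception as err:
        raise StageError("simulate/load", err) from err

    # --- stage: clean ------------------------------------------------------
    try:
        clean_cfg = config.get("clean", {})
        inserts_a, summary_a = clean_fastq(fq_a, adapter3, **clean_cfg)
        inserts_b, summary_b = clean_fastq(fq_b, adapter3, **clean_cfg)
        tags_a = collapse_unique(inserts_a)
        tags_b = collapse_unique(inserts_b)
        write_summary_tsv({"A": summary_a, "B": summary_b}, outdir / "clean_summary.tsv")
        write_collapsed_fasta(tags_a, outdir / "tags_A.fa")
        write_collapsed_fasta(tags_b, outdir / "tags_B.fa")
        _record(outdir / "clean_summary.tsv")
        results.update(
            tags_a=tags_a,
            tags_b=tags_b,
            summary_a=summary_a,
            summary_b=summary_b,
            common_specific=common_specific(tags_a, tags_b),
            length_distribution={
                "A": length_distribution(tags_a),
                "B": length_distribution(tags_b),
            },
        )
    except Exception as err:
        raise StageError("clean", err) from err

    # --- stage: annotate ---------------------------------------------------
    try:
        max_mm = int(config.get("max_mismatch", 1))
        annot: dict = {}
        retained: dict = {}
        for lib, tags in (("A", tags_a), ("B", tags_b)):
            hits, map_summary = map_tags(tags, refs.genome, max_mm)
            records = annotate_tags(tags, category_refs, max_mm)
            annot[lib] = {
                "mapping": map_summary,
                "records": records,
                "categories": annotation_summary(records, tags),
            }
            retained[lib] = retain_for_mirna(records, tags)
        results["annotation"] = annot
        results["retained"] = retained
        pd.DataFrame(
            [
                {"library": lib, "category": cat, **row}
                for lib in annot
                for cat, row in annot[lib]["categories"].items()
            ]
        ).to_csv(outdir / "annotation_categories.tsv", sep="\t", index=False)
        _record(outdir / "annotation_categories.tsv")
    except Exception as err:
        raise StageError("annotate", err) from err

    # --- stage: identify ---------------------------------------------------
    try:
        cat, assignments = identify_conserved(
            retained["A"], retained["B"], refs.mature, refs.hairpins, refs.arms,
            max_mismatch=max_mm,
        )
        catalog_table(cat).to_csv(outdir / "catalog.tsv", sep="\t", index=False)
        _record(outdir / "catalog.tsv")
        duplexes = detect_duplexes(cat, refs.arms, refs.hairpins)
        pd.DataFrame(
            [
                {
                    "hairpin": d.hairpin,
                    "mature": d.mature.name,
                    "star": d.star.name,
                    "overhang_mature3": d.overhang_mature3,
                    "overhang_star3": d.overhang_star3,
                }
                for d in duplexes
            ]
        ).to_csv(outdir / "duplexes.tsv", sep="\t", index=False)
        _record(outdir / "duplexes.tsv")
        results.update(catalog=cat, assignments=assignments,
                       families=group_families(cat), duplexes=duplexes)
    except Exception as err:
        raise StageError("identify", err) from err

    # --- stage: isomiR -----------------------------------------------------
    try:
        records = [rec for recs in assignments.values() for rec in recs]
        spectrum = substitution_spectrum(records)
        spectrum.to_csv(outdir / "substitution_spectrum.tsv", sep="\t", index=False)
        _record(outdir / "substitution_spectrum.tsv")
        counts = {
            seq: (
                next((t.count for t in retained["A"] if t.sequence == seq), 0),
                next((t.count for t in retained["B"] if t.sequence == seq), 0),
            )
            for seq in assignments
        }
        results.update(
            isomir_records=records,
            spectrum=spectrum,
            nta_profile=nta_profile(records),
            isomir_counts=counts,
        )
    except Exception as err:
        raise StageError("isomir", err) from err

    # --- stage: differential expression -----------------------------------
    try:
        de_cfg = DEConfig(**config.get("de", {}))
        counts_by_name = {
            name: (entry.count_a, entry.count_b) for name, entry in cat.items()
        }
        table = build_table(
            counts_by_name, summary_a.clean_reads, summary_b.clean_reads
        )
        table, de_summary = call_de(table, de_cfg)
        table.to_csv(outdir / "differential_expression.tsv", sep="\t", index=False)
        scatter_table(table).to_csv(outdir / "de_scatter.tsv", sep="\t", index=False)
        _record(outdir / "differential_expression.tsv")
        _record(outdir / "de_scatter.tsv")
        results.update(de_table=table, de_summary=de_summary)
    except Exception as err:
        raise StageError("de", err) from err

    # --- stage: qPCR (optional) -------------------------------------------
    if config.get("qpcr", {}).get("ct_table"):
        try:
            qcfg = config["qpcr"]
            ct = read_ct_table(qcfg["ct_table"])
            rel = relative_expression(ct, qcfg.get("reference_tissue", "muscle"))
            rel.to_csv(outdir / "qpcr_relative_expression.tsv", sep="\t")
            _record(outdir / "qpcr_relative_expression.tsv")
            clusters = cluster_heatmap(rel)
            for key in ("row_newick", "col_newick"):
                path = outdir / f"qpcr_{key}.nwk"
                path.write_text(str(clusters[key]) + "\n")
                _record(path)
            results.update(qpcr_matrix=rel, qpcr_clusters=clusters)
        except Exception as err:
            raise StageError("qpcr", err) from err

    # --- stage: target scan (optional) ------------------------------------
    if config.get("targets", {}).get("enabled"):
        try:
            mirnas = {
                name: entry.sequence
                for name, entry in cat.items()
                if results["de_table"].set_index("name")["status"]
                .get(name, "")
                .startswith("significant")
            }
            tx = {
                name: seq
                for name, seq in category_refs.get("mRNA_fragment", {}).items()
            }
            sites = scan_targets(mirnas, tx)
            sites_table(sites).to_csv(outdir / "target_sites.tsv", sep="\t", index=False)
            _record(outdir / "target_sites.tsv")
            results["target_sites"] = sites
        except Exception as err:
            raise StageError("targets", err) from err

    summarize(results, outdir)
    for name in ("length_histogram.tsv",):
        _record(outdir / name)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results


def summarize(results: dict, outdir) -> None:
    """Figure-style data tables derived from stage outputs."""
    outdir = Path(outdir)
    rows = []
    for lib, dist in results["length_distribution"].items():
        for length, (n, frac) in dist.items():
            rows.append({"library": lib, "length": length, "reads": n, "fraction": frac})
    pd.DataFrame(rows).to_csv(outdir / "length_histogram.tsv", sep="\t", index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
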