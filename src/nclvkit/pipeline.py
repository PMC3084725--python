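"""Pipeline orchestration: run the full analysis from a single config.

A :class:`PipelineConfig` (built in code or loaded from YAML/JSON) names the
requested stages, the input files, the e-value thresholds and the terminal
window.  :func:`run_pipeline` validates the config, runs the stages in
dependency order (``simulate`` first, so downstream stages can consume its
outputs), writes every stage output under ``out_dir`` and records a
reproducibility manifest (package version, seed, thresholds, SHA-256 checksum
of every output).  Re-running an identical config reproduces identical
checksums.

Exit-code convention for the CLI built on top: 0 success, 2 validation error,
1 runtime error.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import codon_usage, genome_architecture as ga, homology, phyletics, synteny
from . import io_formats as iof
from . import synthetic_data as synth

STAGES = (
    "simulate",
    "rbh",
    "orfans",
    "duplicates",
    "families",
    "architecture",
    "synteny",
    "phyletics",
    "rscu",
)

# inputs each stage needs (keys into PipelineConfig.inputs)
_REQUIRED_INPUTS: dict[str, tuple[str, ...]] = {
    "rbh": ("hits_ab", "hits_ba"),
    "orfans": ("proteins", "hits_refdb", "hits_envdb"),
    "duplicates": ("self_hits",),
    "families": ("hits_family_db", "family_map"),
    "architecture": ("genome", "category"),
    "synteny": ("hits_ab", "hits_ba", "genome", "genome_b"),
    "phyletics": ("family_tables",),
    "rscu": ("cds",),
}

_SIMULATE_PROVIDES = (
    "hits_ab",
    "hits_ba",
    "self_hits",
    "proteins",
    "hits_refdb",
    "hits_envdb",
    "genome",
    "genome_b",
    "category",
    "family_tables",
    "cds",
    "hits_family_db",
    "family_map",
)


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults equal the analysis' standard thresholds."""

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    inputs: dict[str, Any] = field(default_factory=dict)
    thresholds: homology.ThresholdConfig = field(default_factory=homology.ThresholdConfig)
    window: int = 50_000
    linkage: str = "complete"
    seed: int = 0
    out_dir: Path = Path("nclvkit_out")
    simulate: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        thr = homology.ThresholdConfig(**d.pop("thresholds", {}))
        out_dir = Path(d.pop("out_dir", "nclvkit_out"))
        return cls(thresholds=thr, out_dir=out_dir, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of violations; empty iff the config is runnable."""
    v: list[str] = []
    for s in config.stages:
        if s not in STAGES:
            v.append(f"stages: unknown stage {s!r}")
    try:
        homology.ThresholdConfig(**asdict(config.thresholds))
    except (ValueError, TypeError) as exc:
        v.append(f"thresholds: {exc}")
    if config.window <= 0:
        v.append("window: must be positive")
    if config.linkage not in phyletics.LINKAGES:
        v.append(f"linkage: must be one of {phyletics.LINKAGES}")
    simulated = "simulate" in config.stages
    for stage in config.stages:
        for key in _REQUIRED_INPUTS.get(stage, ()):
            if simulated and key in _SIMULATE_PROVIDES:
                continue
            val = config.inputs.get(key)
            if val is None:
                v.append(f"{stage}: missing input {key!r}")
                continue
            paths = val if isinstance(val, (list, tuple)) else [val]
            for p in paths:
                if not Path(p).exists():
                    v.append(f"{stage}: input file {p} does not exist")
    if "architecture" in config.stages and not simulated:
        genome_path = config.inputs.get("genome")
        if genome_path and Path(genome_path).exists():
            g = iof.read_genome_tsv_with_length(genome_path)
            if 2 * config.window >= g.length:
                v.append(
                    f"RegionSpec: 2*window ({2 * config.window}) must be < genome "
                    f"length ({g.length})"
                )
    return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(msg: str, quiet: bool) -> None:
    if not quiet:
        print(msg, file=sys.stderr)


def _run_simulate(config: PipelineConfig, out: Path) -> dict[str, Path]:
    p = {
        "length": 618_000,
        "n_genes": 500,
        "window": config.window,
        "p_cat_terminal": 0.5,
        "p_cat_central": 0.1,
        "orth_frac": 0.5,
        "fp_rate": 0.05,
        "fn_rate": 0.05,
        "n_groups": 4,
        "taxa_per_group": 10,
        "n_families": 200,
        "core_frac": 0.15,
        "flip_rate": 0.02,
        "n_cds": 50,
        "cds_codons": 300,
        "codon_weights": {"AAA": 3.0, "AAG": 1.0},
        "p_homolog": 0.5,
        "p_env_given_orfan": 0.2,
    }
    p.update(config.simulate)
    seed = config.seed
    produced: dict[str, Path] = {}

    genome_a, truth_a = synth.gen_annotated_genome(
        p["length"], p["n_genes"], p["window"], p["p_cat_terminal"],
        p["p_cat_central"], seed=seed, genome_id="synthA",
    )
    genome_b, _ = synth.gen_annotated_genome(
        p["length"], p["n_genes"], p["window"], 0.0, 0.0,
        seed=seed + 1, genome_id="synthB",
    )
    produced["genome"] = out / "genome_a.tsv"
    iof.write_genome(genome_a, produced["genome"])
    produced["genome_b"] = out / "genome_b.tsv"
    iof.write_genome(genome_b, produced["genome_b"])
    produced["category"] = out / "category.tsv"
    with open(produced["category"], "wt", encoding="utf-8") as fh:
        for gid in sorted(truth_a.positives()):
            fh.write(gid + "\n")

    # planted orthologs: a deterministic subset of rank-matched genes
    rng_pairs = np.random.default_rng(seed + 2)
    ids_a, ids_b = genome_a.gene_ids(), genome_b.gene_ids()
    n_orth = int(p["orth_frac"] * min(len(ids_a), len(ids_b)))
    chosen = sorted(rng_pairs.choice(min(len(ids_a), len(ids_b)), size=n_orth, replace=False))
    planted = {(f"a_{ids_a[i]}", f"b_{ids_b[i]}") for i in chosen}
    decoys_a = {f"a_{g}" for g in ids_a} - {a for a, _ in planted}
    decoys_b = {f"b_{g}" for g in ids_b} - {b for _, b in planted}
    hits_ab, hits_ba = synth.gen_hit_table(
        planted, (decoys_a, decoys_b), p["fp_rate"], p["fn_rate"], seed=seed + 3
    )
    produced["hits_ab"] = out / "hits_ab.tsv"
    produced["hits_ba"] = out / "hits_ba.tsv"
    iof.write_hits(hits_ab, produced["hits_ab"])
    iof.write_hits(hits_ba, produced["hits_ba"])
    with open(out / "planted_pairs.tsv", "wt", encoding="utf-8") as fh:
        for a, b in sorted(planted):
            fh.write(f"{a}\t{b}\n")

    # self hits: plant duplicate clusters among genome A genes
    rng_dup = np.random.default_rng(seed + 4)
    dup_candidates = [g for g in ids_a]
    self_hits: list[iof.HitRecord] = []
    n_dup_pairs = max(1, len(dup_candidates) // 20)
    idx = rng_dup.choice(len(dup_candidates), size=2 * n_dup_pairs, replace=False)
    for k in range(n_dup_pairs):
        g1, g2 = dup_candidates[idx[2 * k]], dup_candidates[idx[2 * k + 1]]
        e = synth._log_uniform(rng_dup, 1e-80, 1e-12)
        self_hits.append(synth._mk_hit(rng_dup, g1, g2, e))
        self_hits.append(synth._mk_hit(rng_dup, g2, g1, e))
    produced["self_hits"] = out / "self_hits.tsv"
    iof.write_hits(self_hits, produced["self_hits"])

    # reference / environmental database hits for ORFan classification
    rng_orf = np.random.default_rng(seed + 5)
    ref_hits, env_hits = [], []
    for g in ids_a:
        if rng_orf.random() < p["p_homolog"]:
            ref_hits.append(synth._mk_hit(rng_orf, g, f"ref_{g}", synth._log_uniform(rng_orf, 1e-60, 1e-6)))
        elif rng_orf.random() < p["p_env_given_orfan"]:
            env_hits.append(synth._mk_hit(rng_orf, g, f"env_{g}", synth._log_uniform(rng_orf, 1e-40, 1e-6)))
    produced["hits_refdb"] = out / "hits_refdb.tsv"
    produced["hits_envdb"] = out / "hits_envdb.tsv"
    iof.write_hits(ref_hits, produced["hits_refdb"])
    iof.write_hits(env_hits, produced["hits_envdb"])
    produced["proteins"] = out / "proteins.txt"
    with open(produced["proteins"], "wt", encoding="utf-8") as fh:
        for g in ids_a:
            fh.write(g + "\n")

    # hits against a small family database, plus the subject -> family map
    rng_fam = np.random.default_rng(seed + 8)
    n_db_families = 20
    fam_hits = []
    fam_map_rows = [(f"db{j:02d}", f"COG{j:04d}") for j in range(n_db_families)]
    for g in ids_a:
        if rng_fam.random() < 0.4:
            j = int(rng_fam.integers(0, n_db_families))
            fam_hits.append(
                synth._mk_hit(rng_fam, g, f"db{j:02d}", synth._log_uniform(rng_fam, 1e-40, 1e-4))
            )
    produced["hits_family_db"] = out / "hits_family_db.tsv"
    iof.write_hits(fam_hits, produced["hits_family_db"])
    produced["family_map"] = out / "family_map.tsv"
    with open(produced["family_map"], "wt", encoding="utf-8") as fh:
        for subj, fam in fam_map_rows:
            fh.write(f"{subj}\t{fam}\n")

    # per-taxon family tables from a planted phyletic matrix
    matrix, ptruth = synth.gen_phyletic_profiles(
        p["n_groups"], p["taxa_per_group"], p["n_families"],
        p["core_frac"], p["flip_rate"], seed=seed + 6,
    )
    fam_dir = out / "family_tables"
    fam_dir.mkdir(exist_ok=True)
    fam_paths = []
    for taxon in matrix.index:
        fams = matrix.columns[matrix.loc[taxon] == 1]
        table = pd.DataFrame(
            {"protein_id": [f"{taxon}_p{i}" for i in range(len(fams))],
             "family_id": list(fams),
             "evalue": [1e-10] * len(fams)}
        )
        path = fam_dir / f"{taxon}.tsv"
        iof.write_family_table(table, path)
        fam_paths.append(path)
    produced["family_tables"] = fam_dir
    with open(out / "planted_groups.tsv", "wt", encoding="utf-8") as fh:
        for taxon in sorted(ptruth.group_of):
            fh.write(f"{taxon}\t{ptruth.group_of[taxon]}\n")

    # coding sequences with a known codon bias
    cds = synth.gen_coding_sequences(
        p["n_cds"], p["codon_weights"], p["cds_codons"], seed=seed + 7
    )
    produced["cds"] = out / "cds.fasta"
    iof.write_fasta(cds, produced["cds"])
    return produced


def run_pipeline(config: PipelineConfig, quiet: bool = True) -> dict[str, Any]:
    """Run the requested stages in dependency order; return the manifest."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    inputs: dict[str, Any] = dict(config.inputs)
    outputs: dict[str, str] = {}
    ordered = [s for s in STAGES if s in config.stages]

    for stage in ordered:
        t0 = time.monotonic()
        if stage == "simulate":
            produced = _run_simulate(config, out)
            inputs.update({k: str(v) for k, v in produced.items()})
            for k, v in produced.items():
                if Path(v).is_file():
                    outputs[f"simulate:{Path(v).name}"] = _sha256(Path(v))
        elif stage == "rbh":
            hits_ab = iof.read_hits(inputs["hits_ab"])
            hits_ba = iof.read_hits(inputs["hits_ba"])
            pairs = homology.rbh_pairs(hits_ab, hits_ba, thr.e_rbh)
            path = out / "rbh_pairs.tsv"
            with open(path, "wt", encoding="utf-8") as fh:
                fh.write("a_id\tb_id\tevalue_ab\tevalue_ba\tmin_bitscore\n")
                for pr in sorted(pairs, key=lambda x: (x.a_id, x.b_id)):
                    fh.write(
                        f"{pr.a_id}\t{pr.b_id}\t{pr.evalue_ab:.6g}\t"
                        f"{pr.evalue_ba:.6g}\t{pr.min_bitscore:.1f}\n"
                    )
            outputs["rbh_pairs.tsv"] = _sha256(path)
        elif stage == "orfans":
            proteins = [l.strip() for l in open(inputs["proteins"]) if l.strip()]
            labels, fractions = homology.classify_orfans(
                proteins,
                iof.read_hits(inputs["hits_refdb"]),
                iof.read_hits(inputs["hits_envdb"]),
                thr.e_rbh,
            )
            path = out / "orfan_labels.tsv"
            with open(path, "wt", encoding="utf-8") as fh:
                fh.write("protein_id\tlabel\n")
                for lab in labels:
                    fh.write(f"{lab.protein_id}\t{lab.label}\n")
            with open(out / "orfan_fractions.json", "wt", encoding="utf-8") as fh:
                json.dump(fractions, fh, indent=2, sort_keys=True)
            outputs["orfan_labels.tsv"] = _sha256(path)
            outputs["orfan_fractions.json"] = _sha256(out / "orfan_fractions.json")
        elif stage == "duplicates":
            clusters = homology.find_duplicates(iof.read_hits(inputs["self_hits"]), thr.e_dup)
            path = out / "duplicate_clusters.tsv"
            with open(path, "wt", encoding="utf-8") as fh:
                fh.write("cluster\tgene_id\n")
                for i, cl in enumerate(sorted(clusters, key=min)):
                    for g in sorted(cl):
                        fh.write(f"{i}\t{g}\n")
            outputs["duplicate_clusters.tsv"] = _sha256(path)
        elif stage == "families":
            import csv

            fam_map: dict[str, str] = {}
            with open(inputs["family_map"], "rt", encoding="utf-8") as fh:
                for row in csv.reader(fh, delimiter="\t"):
                    if len(row) >= 2:
                        fam_map[row[0]] = row[1]
            table = homology.assign_families(
                iof.read_hits(inputs["hits_family_db"]), fam_map, thr.e_family
            )
            path = out / "family_assignments.tsv"
            iof.write_family_table(table, path)
            outputs["family_assignments.tsv"] = _sha256(path)
        elif stage == "architecture":
            genome = iof.read_genome_tsv_with_length(inputs["genome"])
            category = {
                l.strip() for l in open(inputs["category"], "rt", encoding="utf-8") if l.strip()
            }
            spec = ga.RegionSpec(genome.length, config.window)
            res = ga.enrichment(genome, category, spec)
            path = out / "enrichment.tsv"
            with open(path, "wt", encoding="utf-8") as fh:
                fh.write(
                    "rate_terminal_pct\trate_central_pct\todds_ratio\tp_two_sided\t"
                    "a\tb\tc\td\n"
                )
                fh.write(
                    f"{res.rate_terminal:.6g}\t{res.rate_central:.6g}\t"
                    f"{res.odds_ratio:.6g}\t{res.p_two_sided:.6g}\t"
                    f"{res.table.a}\t{res.table.b}\t{res.table.c}\t{res.table.d}\n"
                )
            tracks = ga.genome_tracks(
                genome, {g: {"DUPLICATED"} for g in category}
            )
            tracks_path = out / "tracks.tsv"
            tracks.to_csv(tracks_path, sep="\t", index=False)
            outputs["enrichment.tsv"] = _sha256(path)
            outputs["tracks.tsv"] = _sha256(tracks_path)
        elif stage == "synteny":
            genome_a = iof.read_genome_tsv_with_length(inputs["genome"])
            genome_b = iof.read_genome_tsv_with_length(inputs["genome_b"])
            hits_ab = iof.read_hits(inputs["hits_ab"])
            hits_ba = iof.read_hits(inputs["hits_ba"])
            pairs = homology.rbh_pairs(hits_ab, hits_ba, thr.e_rbh)
            # hit-table protein ids may be prefixed relative to genome gene ids
            pairs = {_strip_pair(pr, genome_a, genome_b) for pr in pairs}
            pairs.discard(None)
            blocks = synteny.synteny_blocks(
                pairs, genome_a, genome_b, e_max=thr.e_synteny_grade, gap=0
            )
            bl_path = out / "synteny_blocks.tsv"
            synteny.blocks_to_frame(blocks).to_csv(bl_path, sep="\t", index=False)
            dp_path = out / "dotplot.tsv"
            synteny.dotplot_points(pairs, genome_a, genome_b, score="evalue").to_csv(
                dp_path, sep="\t", index=False
            )
            outputs["synteny_blocks.tsv"] = _sha256(bl_path)
            outputs["dotplot.tsv"] = _sha256(dp_path)
        elif stage == "phyletics":
            fam_dir = Path(inputs["family_tables"])
            files = sorted(fam_dir.glob("*.tsv")) if fam_dir.is_dir() else [
                Path(f) for f in inputs["family_tables"]
            ]
            assignments = {f.stem: iof.read_family_table(f) for f in files}
            matrix = phyletics.build_matrix(assignments)
            dist = phyletics.euclidean_distances(matrix)
            tree = phyletics.hierarchical_cluster(dist, config.linkage)
            iof.write_matrix(matrix, out / "phyletic_matrix.tsv")
            iof.write_matrix(dist, out / "distance_matrix.tsv")
            (out / "dendrogram.nwk").write_text(phyletics.to_newick(tree) + "\n")
            heat = phyletics.order_by_clustering(matrix, config.linkage)
            iof.write_matrix(heat, out / "heatmap_matrix.tsv")
            for name in ("phyletic_matrix.tsv", "distance_matrix.tsv",
                         "dendrogram.nwk", "heatmap_matrix.tsv"):
                outputs[name] = _sha256(out / name)
        elif stage == "rscu":
            records = iof.read_fasta(inputs["cds"])
            values = codon_usage.genome_rscu([str(r.seq) for r in records])
            table = codon_usage.rscu_table(values)
            path = out / "rscu.tsv"
            table.to_csv(path, sep="\t", index=False, float_format="%.6g")
            outputs["rscu.tsv"] = _sha256(path)
        _log(f"[{stage}] done in {time.monotonic() - t0:.2f}s", quiet)

    manifest = {
        "package": "nclvkit",
        "version": __version__,
        "seed": config.seed,
        "stages": ordered,
        "thresholds": asdict(thr),
        "window": config.window,
        "linkage": config.linkage,
        "outputs": dict(sorted(outputs.items())),
    }
    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _strip_pair(pr, genome_a: iof.Genome, genome_b: iof.Genome):
    """Map hit-table protein ids (possibly 'a_'/'b_'-prefixed) onto gene ids."""
    a, b = pr.a_id, pr.b_id
    ids_a, ids_b = set(genome_a.gene_ids()), set(genome_b.gene_ids())
    if a not in ids_a and a.startswith("a_") and a[2:] in ids_a:
        a = a[2:]
    if b not in ids_b and b.startswith("b_") and b[2:] in ids_b:
        b = b[2:]
    if a not in ids_a or b not in ids_b:
        return None
    return homology.OrthologPair(a, b, pr.evalue_ab, pr.evalue_ba, pr.min_bitscore)
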