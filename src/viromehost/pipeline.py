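"""End-to-end orchestration: synth → screen → cluster → spacers → hosts →
ecology → hic, with one config, deterministic seeding and a run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import fields
from pathlib import Path

import pandas as pd
import yaml

from . import crisprdb, ecol, genus_net, hicval, hostlink, synthio, vscreen

STAGES = ("synth", "screen", "cluster", "spacers", "hosts", "ecology", "hic")


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise StageError("config", "E_SCHEMA", "config must be a mapping")
    known = set(STAGES) | {"seed", "out"}
    for key in cfg:
        if key not in known:
            raise StageError("config", "E_SCHEMA", f"unknown config block {key!r}")
    for stage in STAGES:
        block = cfg.get(stage, {})
        if block is None:
            block = {}
        if not isinstance(block, dict):
            raise StageError("config", "E_SCHEMA", f"block {stage!r} must be a mapping")
        cfg[stage] = block
    cfg.setdefault("seed", 0)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: dict, outdir) -> dict:
    """Execute every enabled stage in dependency order; return the manifest."""
    cfg = validate_config(dict(cfg))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"seed": seed, "stages": [], "outputs": {}}

    def record(stage: str, paths: dict[str, str]):
        manifest["stages"].append(stage)
        manifest["outputs"][stage] = {
            name: {"path": p, "sha256": _sha256(Path(p))} for name, p in paths.items()}

    def enabled(stage: str) -> bool:
        return cfg[stage].get("enabled", True)

    # ---- synth -----------------------------------------------------------
    synth_params = {k: v for k, v in cfg["synth"].items() if k != "enabled"}
    for key in ("virus_len_range", "spacer_len_range"):
        if key in synth_params:
            synth_params[key] = tuple(synth_params[key])
    valid = {f.name for f in fields(synthio.SynthConfig)}
    bad = set(synth_params) - valid
    if bad:
        raise StageError("synth", "E_PARAM", f"unknown synth parameters {sorted(bad)}")
    scfg = synthio.SynthConfig(seed=seed, **synth_params)
    try:
        comm = synthio.gen_community(scfg)
    except ValueError as e:
        raise StageError("synth", "E_GEN", str(e)) from e
    sdir = out / "synth"
    paths = synthio.write_community(comm, sdir)
    record("synth", paths)

    # ---- screen ----------------------------------------------------------
    if enabled("screen"):
        mode = cfg["screen"].get("criteria_mode", "any")
        table = vscreen.screen_table(comm.annotations, comm.contig_lengths, mode)
        viral_ids = sorted(table.loc[table["viral"], "contig_id"])
        p1 = out / "screen_decisions.tsv"
        table.to_csv(p1, sep="\t", index=False)
        p2 = out / "viral_contigs.tsv"
        pd.DataFrame({"contig_id": viral_ids}).to_csv(p2, sep="\t", index=False)
        record("screen", {"decisions": str(p1), "viral_contigs": str(p2)})
    else:
        viral_ids = sorted(comm.viruses)

    # ---- cluster ---------------------------------------------------------
    if enabled("cluster"):
        blk = cfg["cluster"]
        prots = [(g, s) for g, s in sorted(comm.proteins.items())
                 if comm.gene_to_contig[g] in comm.viruses]
        pcs = genus_net.cluster_proteins(prots, comm.gene_to_contig,
                                         blk.get("id_threshold", 0.9))
        genera = genus_net.assign_genera(sorted(comm.viruses), pcs,
                                         blk.get("score_threshold", 3.0))
        p = out / "genus_assignments.tsv"
        pd.DataFrame(sorted(genera.items()),
                     columns=["contig_id", "genus"]).to_csv(p, sep="\t", index=False)
        record("cluster", {"genus_assignments": str(p)})
        genus_map = genera
    else:
        genus_map = comm.truth.true_genus_of

    # ---- spacers ---------------------------------------------------------
    lineages = dict(zip(comm.host_lineages["genome_id"], comm.host_lineages["lineage"]))
    if enabled("spacers"):
        try:
            db = crisprdb.build_spacer_db(comm.hosts, lineages)
        except ValueError as e:
            raise StageError("spacers", "E_LINEAGE", str(e)) from e
        p = out / "spacers.tsv"
        pd.DataFrame(
            [dict(spacer_id=r.spacer_id, genome_id=r.genome_id,
                  sequence=r.sequence, lineage=r.lineage) for r in db]
        ).to_csv(p, sep="\t", index=False)
        record("spacers", {"spacers": str(p)})
    else:
        db = []

    # ---- hosts -----------------------------------------------------------
    links = []
    if enabled("hosts") and db:
        blk = cfg["hosts"]
        thr = hostlink.MatchThresholds(
            min_identity=blk.get("min_identity", 0.97),
            min_coverage=blk.get("min_coverage", 0.90),
            max_mismatches=blk.get("max_mismatches", 1))
        links = hostlink.predict_hosts(comm.viruses, db, thr)
        p = out / "virus_host_links.tsv"
        hostlink.links_table(links).to_csv(p, sep="\t", index=False)
        ranges = hostlink.host_range_counts(links)
        p2 = out / "host_range_summary.tsv"
        pd.DataFrame(sorted(ranges.items()),
                     columns=["host_range", "n_contigs"]).to_csv(p2, sep="\t", index=False)
        record("hosts", {"links": str(p), "host_range": str(p2)})

    # ---- ecology ---------------------------------------------------------
    if enabled("ecology"):
        ab = ecol.relative_abundance(comm.coverage, comm.contig_lengths, genus_map)
        p = out / "abundance.tsv"
        ab.to_csv(p, sep="\t")
        div_rows = []
        for s in ab.columns:
            div_rows.append(dict(sample_id=s, shannon=ecol.shannon(ab[s]),
                                 pielou=ecol.pielou(ab[s]),
                                 richness=int((ab[s] > 0).sum())))
        p2 = out / "diversity.tsv"
        pd.DataFrame(div_rows).to_csv(p2, sep="\t", index=False)
        D = ecol.bray_curtis_matrix(ab)
        coords, eig = ecol.pcoa(D.to_numpy(), k=2)
        p3 = out / "pcoa.tsv"
        pd.DataFrame(coords, index=D.index,
                     columns=[f"PC{i+1}" for i in range(coords.shape[1])]
                     ).to_csv(p3, sep="\t")
        counts, core = ecol.core_shared_genera(ab > 0)
        p4 = out / "upset_counts.tsv"
        pd.DataFrame(
            [dict(samples="|".join(sorted(k)), n_genera=v)
             for k, v in sorted(counts.items(), key=lambda kv: sorted(kv[0]))]
        ).to_csv(p4, sep="\t", index=False)
        p5 = out / "core_genera.tsv"
        pd.DataFrame({"genus": core}).to_csv(p5, sep="\t", index=False)
        record("ecology", {"abundance": str(p), "diversity": str(p2),
                           "pcoa": str(p3), "upset": str(p4), "core": str(p5)})

    # ---- hic -------------------------------------------------------------
    if enabled("hic"):
        blk = cfg["hic"]
        hic_links = hicval.deconvolve(comm.hic, blk.get("min_count", 5),
                                      blk.get("dominance_ratio", 2.0))
        crispr_pairs = hicval.crispr_links_to_bins(links, comm.bin_membership)
        summary = hicval.compare_with_crispr(crispr_pairs, hic_links)
        p = out / "hic_links.tsv"
        pd.DataFrame(
            [dict(virus_id=v, bin_id=b) for v, bins in sorted(hic_links.items())
             for b in bins]).to_csv(p, sep="\t", index=False)
        p2 = out / "hic_summary.tsv"
        pd.DataFrame([summary.__dict__]).to_csv(p2, sep="\t", index=False)
        record("hic", {"links": str(p), "summary": str(p2)})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
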