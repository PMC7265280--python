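"""Config-driven pipeline driver: simulate -> assign -> ecology ->
heatmap -> consensus -> phylo, with shared seeding and a provenance
manifest.

Stages communicate only through files in the run directory, so each
stage can be re-run or toggled independently; the manifest records the
configuration, seeds and output checksums, and a rerun with the same
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd

from . import __version__, bbh, consensus, ecology, heatmap, io, phylo, synth
from .primers import PrimerSet

logger = logging.getLogger("operonscope")

STAGES = ("simulate", "assign", "ecology", "heatmap", "consensus", "phylo")


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study's stated values
    wherever one is printed (size window 3700-5700, alignment filter
    >1000, primer identity 85%, top 15 reads, 97% species threshold,
    100 bootstraps)."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # simulate
    n_species: int = 3
    copies_per_species: int = 4
    target_identity: float = 0.94
    n_reads: int = 150
    group_sizes: tuple[int, int, int, int] = (3, 4, 4, 6)
    sub_rate: float = 0.05
    ins_rate: float = 0.015
    del_rate: float = 0.015
    strand_bias: tuple[float, float] = (1.0, 1.0)
    strand_profile: float = 0.0
    exercise_enriched: str | None = None
    wt_sed_species: str | None = None
    # assign
    min_len: int = 3700
    max_len: int = 5700
    min_aln: int = 1000
    # ecology
    n_perm: int = 999
    top_k: int = 10
    # heatmap
    heatmap_taxon: str | None = None  # default: most abundant taxon
    top_n: int = 15
    primer_identity: float = 0.85
    # consensus
    min_reads: int = 5
    its_bin_width: int = 25
    consensus_max_iter: int = 10
    make_plots: bool = False
    # phylo
    region: str = "16S"
    window_start: int = 280
    window_length: int = 275
    n_bootstrap: int = 100
    species_threshold: float = 0.97

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


_TUPLE_FIELDS = {"stages": str, "group_sizes": int, "strand_bias": float}


def load_config(path: str | os.PathLike, **overrides) -> RunConfig:
    """Parse a plain key = value config file; unknown keys are rejected."""
    valid = {f.name: f for f in fields(RunConfig)}
    kwargs: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in valid:
                raise ValueError(f"unknown config key: {key!r}")
            kwargs[key] = _parse_value(key, value)
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def _parse_value(key: str, value: str):
    if key in _TUPLE_FIELDS:
        cast = _TUPLE_FIELDS[key]
        return tuple(cast(v.strip()) for v in value.split(","))
    if value.lower() in ("none", ""):
        return None
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: str, stage: str, produced_by: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"stage '{stage}' needs {os.path.basename(path)}; run stage "
            f"'{produced_by}' first (or provide the file)")
    return path


def run(config: RunConfig, out_dir: str | os.PathLike) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written to manifest.json in *out_dir*).
    """
    out = str(out_dir)
    os.makedirs(out, exist_ok=True)
    t_start = time.time()
    written: list[str] = []
    timings: dict[str, float] = {}

    def path(name: str) -> str:
        return os.path.join(out, name)

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        logger.info("stage %s: starting", stage)
        written += _STAGE_FUNCS[stage](config, path)
        timings[stage] = round(time.time() - t0, 3)
        logger.info("stage %s: done in %.2fs", stage, timings[stage])

    cfg = asdict(config)
    manifest = {
        "version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": config.seed,
        "stage_timings_s": timings,
        "outputs": {os.path.basename(p): _sha256(p) for p in sorted(set(written))},
        "elapsed_s": round(time.time() - t_start, 3),
    }
    with open(path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_simulate(cfg: RunConfig, path) -> list[str]:
    panel = synth.make_reference_panel(
        cfg.n_species, cfg.copies_per_species,
        synth.DivergenceSpec(cfg.target_identity), seed=cfg.seed)
    designs = synth.default_cohort(
        panel, n_reads=cfg.n_reads, group_sizes=cfg.group_sizes,
        exercise_enriched=cfg.exercise_enriched, wt_sed_species=cfg.wt_sed_species)
    em = synth.ErrorModel(cfg.sub_rate, cfg.ins_rate, cfg.del_rate,
                          cfg.strand_bias, cfg.strand_profile, seed=cfg.seed + 1)
    reads = synth.simulate_reads(panel, designs, em)
    paths = synth.write_fixture(reads, panel, designs, os.path.dirname(path("x")))
    with open(path("anchors.json"), "w") as fh:
        json.dump(panel.anchors, fh, indent=2, sort_keys=True)
    return [*paths.values(), path("anchors.json")]


def _load_reads(path) -> list[synth.ReadRecord]:
    seqs = io.read_sequences(_require(path("reads.fasta"), "assign", "simulate"))
    truth = None
    if os.path.exists(path("truth.tsv")):
        truth = io.read_truth(path("truth.tsv")).set_index("read_id")
    meta = io.read_metadata(path("metadata.tsv"))
    sample_ids = sorted(meta["sample_id"], key=len, reverse=True)
    out = []
    for rid, seq in seqs:
        sample = next((s for s in sample_ids if rid.startswith(s)), rid.rsplit("_r", 1)[0])
        tr = None
        if truth is not None and rid in truth.index:
            row = truth.loc[rid]
            tr = (row["species_id"], int(row["copy_id"]), row["direction"])
        out.append(synth.ReadRecord(rid, sample, seq, "unknown", tr))
    return out


def _stage_assign(cfg: RunConfig, path) -> list[str]:
    reads = _load_reads(path)
    refs = io.read_fasta(_require(path("refs_16s.fasta"), "assign", "simulate"))
    meta = io.read_metadata(path("metadata.tsv"))
    kept = bbh.size_filter(reads, cfg.min_len, cfg.max_len)
    records = bbh.assign_reads(kept, refs)
    records = bbh.filter_alignments(records, cfg.min_aln)
    records.to_csv(path("bbh.tsv"), sep="\t", index=False)
    table = bbh.build_count_table(records, meta)
    io.write_table(table.counts, path("counts_raw.tsv"))
    io.write_table(table.normalize().counts, path("counts_norm.tsv"))
    return [path("bbh.tsv"), path("counts_raw.tsv"), path("counts_norm.tsv")]


def _stage_ecology(cfg: RunConfig, path) -> list[str]:
    counts = io.read_table(_require(path("counts_norm.tsv"), "ecology", "assign"))
    meta = io.read_metadata(path("metadata.tsv"))
    table = bbh.CountTable(counts, normalized=True)
    dm = ecology.bray_curtis(ecology.fourth_root(table))
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path("braycurtis.tsv"), sep="\t")
    ord_res = ecology.nmds(dm, seed=cfg.seed + 2)
    coords = ord_res.coordinates.copy()
    coords["stress"] = ord_res.stress
    coords.to_csv(path("nmds_coords.tsv"), sep="\t")
    extra = []
    if cfg.make_plots:
        from .plots import plot_nmds
        plot_nmds(ord_res.coordinates, meta, ord_res.stress, path("nmds.svg"))
        extra.append(path("nmds.svg"))
    term_sets = (("activity", "genotype", "activity:genotype"),
                 ("activity", "genotype"), ("activity",))
    per = None
    for terms in term_sets:
        try:
            per = ecology.permanova(dm, meta, terms=terms,
                                    n_perm=cfg.n_perm, seed=cfg.seed + 3)
            break
        except ValueError as exc:
            logger.warning("permanova with terms %s not estimable (%s)", terms, exc)
    if per is None:
        raise ValueError("design too small for any PERMANOVA term set")
    per.table.to_csv(path("permanova.tsv"), sep="\t")
    ecology.alpha_diversity(table).to_csv(path("alpha.tsv"), sep="\t")
    depths = [int(d) for d in np.linspace(1, counts.sum(axis=1).min(), 12)]
    rows = []
    for s in table.samples:
        rc = ecology.rarefaction_curve(table.counts.loc[s], depths)
        rc.insert(0, "sample_id", s)
        rows.append(rc)
    pd.concat(rows).to_csv(path("rarefaction.tsv"), sep="\t", index=False)
    outs = [path("braycurtis.tsv"), path("nmds_coords.tsv"), path("permanova.tsv"),
            path("alpha.tsv"), path("rarefaction.tsv"), *extra]
    for by in ("genotype", "activity"):
        ecology.enrichment(table, meta, by, cfg.top_k).to_csv(
            path(f"enrichment_{by}.tsv"), sep="\t", index=False)
        outs.append(path(f"enrichment_{by}.tsv"))
    return outs


def _heatmap_inputs(cfg: RunConfig, path):
    records = pd.read_csv(_require(path("bbh.tsv"), "heatmap", "assign"), sep="\t")
    reads = _load_reads(path)
    taxon = cfg.heatmap_taxon
    if taxon is None:
        taxon = records["ref_id"].value_counts().idxmax()
    return records, reads, taxon


def _stage_heatmap(cfg: RunConfig, path) -> list[str]:
    records, reads, taxon = _heatmap_inputs(cfg, path)
    meta = io.read_metadata(path("metadata.tsv"))
    top = heatmap.select_top_reads(records, reads, taxon, cfg.top_n)
    primers = PrimerSet(min_identity=cfg.primer_identity)
    oriented, _ = heatmap.orient_reads(top, primers)
    d = heatmap.pairwise_identity_matrix(oriented)
    res = heatmap.seriate_and_cluster(d)
    order = res.ordering
    mat = pd.DataFrame(d.data, index=list(d.ids), columns=list(d.ids)).loc[order, order]
    mat.to_csv(path(f"ordered_matrix_{taxon}.tsv"), sep="\t")
    truth = io.read_truth(path("truth.tsv")) if os.path.exists(path("truth.tsv")) else None
    report = heatmap.source_composition(res, oriented, meta, truth)
    payload = {"taxon": taxon, "ordering": order, "cut_height": res.cut_height,
               "silhouette": res.silhouette,
               "clusters": report}
    with open(path(f"clusters_{taxon}.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    outs = [path(f"ordered_matrix_{taxon}.tsv"), path(f"clusters_{taxon}.json")]
    if cfg.make_plots:
        from .plots import plot_heatmap
        plot_heatmap(mat, path(f"heatmap_{taxon}.svg"))
        outs.append(path(f"heatmap_{taxon}.svg"))
    return outs


def _panel_anchors(path) -> dict[str, str]:
    with open(_require(path("anchors.json"), "consensus", "simulate")) as fh:
        return json.load(fh)


class _AnchorPanel:
    """Minimal panel stand-in carrying only the anchor motifs."""

    def __init__(self, anchors):
        self.anchors = anchors


def _stage_consensus(cfg: RunConfig, path) -> list[str]:
    records, reads, taxon = _heatmap_inputs(cfg, path)
    meta = io.read_metadata(path("metadata.tsv"))
    anchors = _panel_anchors(path)
    wanted = set(records.loc[records["ref_id"] == taxon, "read_id"])
    taxon_reads = [r for r in reads if r.read_id in wanted]
    oriented, _ = heatmap.orient_reads(taxon_reads, PrimerSet(min_identity=cfg.primer_identity))
    ops = consensus.reconstruct_taxon(
        oriented, taxon, _AnchorPanel(anchors), meta,
        its_bin_width=cfg.its_bin_width, min_reads=cfg.min_reads,
        max_iter=cfg.consensus_max_iter)
    io.write_fasta([(c.name.replace("|", "_").replace(" ", ""), c.sequence) for c in ops],
                   path("consensus.fasta"))
    cov = pd.DataFrame([{"name": c.name, "n_reads": c.n_reads,
                         "iterations": c.iterations_used, "converged": c.converged,
                         "mean_coverage": float(np.mean(c.coverage))} for c in ops])
    cov.to_csv(path("coverage.tsv"), sep="\t", index=False)
    with open(path("groups.json"), "w") as fh:
        json.dump([{"name": c.name, "n_reads": c.n_reads} for c in ops],
                  fh, indent=2, sort_keys=True)
    return [path("consensus.fasta"), path("coverage.tsv"), path("groups.json")]


def _stage_phylo(cfg: RunConfig, path) -> list[str]:
    anchors = _panel_anchors(path)
    cons = io.read_fasta(_require(path("consensus.fasta"), "phylo", "consensus"))
    refs = io.read_fasta(_require(path("refs_operon.fasta"), "phylo", "simulate"))
    seqs: dict[str, str] = {}
    for name, seq in cons + [(n.replace("|", "_"), s) for n, s in refs]:
        try:
            seqs[name] = phylo.extract_region(seq, anchors, cfg.region)
        except ValueError as exc:
            logger.warning("phylo: %s skipped (%s)", name, exc)
    aln = phylo.align_and_mask(seqs, cfg.region)
    full = phylo.identity_matrix(aln)
    full.to_csv(path("identity_full.tsv"), sep="\t")
    win = phylo.identity_matrix(aln, (cfg.window_start, cfg.window_length))
    win.to_csv(path("identity_window.tsv"), sep="\t")
    phylo.call_species(full, cfg.species_threshold).to_csv(
        path("species_calls.tsv"), sep="\t", index=False)
    io.write_fasta(zip(aln.names, aln.rows), path("alignment.fasta"))
    outs = [path("identity_full.tsv"), path("identity_window.tsv"),
            path("species_calls.tsv"), path("alignment.fasta")]
    if len(aln.names) >= 4:
        tree = phylo.nj_bootstrap_tree(aln, cfg.n_bootstrap, seed=cfg.seed + 4)
        with open(path("tree.nwk"), "w") as fh:
            fh.write(tree.newick + "\n")
        outs.append(path("tree.nwk"))
    else:
        logger.warning("phylo: fewer than 4 sequences; tree skipped")
    return outs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "assign": _stage_assign,
    "ecology": _stage_ecology,
    "heatmap": _stage_heatmap,
    "consensus": _stage_consensus,
    "phylo": _stage_phylo,
}
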