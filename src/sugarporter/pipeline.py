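"""End-to-end workflow: screen -> tree -> clades -> motifs -> DE -> regulons.

Each stage reads the files named in the :class:`~sugarporter.config.RunConfig`
and writes plain TSV/JSON/Newick into the run directory.  Every table starts
with comment lines recording the tool version, the seed and the SHA-256 of
the inputs it was computed from, and a resolved copy of the configuration is
written next to the outputs, so a run can be reproduced from its directory
alone.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .expression import (
    affected_set,
    apply_st_filters,
    average_replicates,
    cluster_genes,
    export_heatmap_table,
    moderated_de,
    regulon_overlap,
)
from .motifs import clade_conservation, default_motifs, read_motif_table, scan_sequence, write_hits_tsv
from .phylo import (
    CladeAssignment,
    Clade,
    bootstrap_supports,
    extract_supported_clades,
    propagate_substrate_labels,
    read_tree,
    root_on_outgroup,
    trim_gap_columns,
    write_clades_tsv,
    write_tree,
    write_unplaced_tsv,
)
from .profile_screen import (
    build_profile,
    calibrate_cutoff,
    parse_search_table,
    score_protein,
    screen_proteome,
    write_candidates_tsv,
)
from .seqio import apply_labels, read_alignment, read_fasta, read_label_table

log = logging.getLogger("sugarporter")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _header(seed: int, inputs: dict[str, str]) -> str:
    lines = [f"# sugarporter {__version__} seed={seed}"]
    for name, path in inputs.items():
        lines.append(f"# input {name}={Path(path).name} sha256={_sha256(path)}")
    return "\n".join(lines) + "\n"


def _prepend_header(path: Path, header: str) -> None:
    body = path.read_text()
    path.write_text(header + body)


def read_clades_tsv(path: str | Path) -> CladeAssignment:
    """Read a clades table written by :func:`~sugarporter.phylo.write_clades_tsv`."""
    clades = []
    with open(path) as fh:
        rows = [line for line in fh if not line.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    for row in reader:
        clades.append(
            Clade(
                clade_id=row["clade_id"],
                members=row["members"].split(";") if row["members"] else [],
                support=int(row["support"]),
                substrate_labels=set(
                    s for s in row["substrate_labels"].split(";") if s
                ),
            )
        )
    return CladeAssignment(clades=clades, unplaced=[])


def run_all(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.resolved.yaml")
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        candidates: list[str] | None = None
        if config.stages.get("screen"):
            candidates = _stage_screen(config, out)
        tree = None
        if config.stages.get("tree"):
            tree = _stage_tree(config, out)
        assignment = None
        if config.stages.get("clades"):
            assignment = _stage_clades(config, out, tree, candidates)
        if config.stages.get("motifs"):
            _stage_motifs(config, out, assignment)
        filtered = None
        if config.stages.get("de"):
            filtered = _stage_de(config, out)
        if config.stages.get("regulons"):
            _stage_regulons(config, out, filtered)
    finally:
        log.removeHandler(fh)
        fh.close()
    return out


def _require(config: RunConfig, stage: str, *names: str) -> list[str]:
    paths = []
    for name in names:
        value = getattr(config, name)
        if value is None or not Path(value).exists():
            raise StageError(stage, f"missing input {name!r}: {value}")
        paths.append(value)
    return paths


def _load_references(config: RunConfig, stage: str):
    (labels_path,) = _require(config, stage, "reference_labels")
    return read_label_table(labels_path)


def _stage_screen(config: RunConfig, out: Path) -> list[str]:
    proteome_path, align_path = _require(config, "screen", "proteome", "reference_alignment")
    labels = _load_references(config, "screen")
    proteome = apply_labels(read_fasta(proteome_path), labels)
    profile = build_profile(read_alignment(align_path))
    if config.hmmer_table:
        known_scores = parse_search_table(config.hmmer_table)
        known_scores = {k: v for k, v in known_scores.items() if k in labels}
        scores = None
    else:
        scores = {rec.id: score_protein(profile, rec) for rec in proteome}
        known_scores = {rid: scores[rid].score for rid in labels if rid in scores}
    if not known_scores:
        raise StageError("screen", "no reference transporter was scored")
    if config.cutoff is not None:
        cutoff, calibration = float(config.cutoff), None
    else:
        calibration = calibrate_cutoff(known_scores)
        cutoff = calibration.cutoff
    hits = screen_proteome(proteome, profile, cutoff)
    header = _header(config.seed, {"proteome": proteome_path, "reference_alignment": align_path})
    write_candidates_tsv(hits, out / "candidates.tsv")
    _prepend_header(out / "candidates.tsv", header)
    report = {
        "cutoff": cutoff,
        "calibrated": calibration is not None,
        "argmin_id": calibration.argmin_id if calibration else None,
        "n_candidates": len(hits),
        "known_scores": dict(sorted(known_scores.items())),
    }
    (out / "calibration.json").write_text(json.dumps(report, indent=2) + "\n")
    log.info("screen: %d candidates at cutoff %.2f", len(hits), cutoff)
    return [h.protein_id for h in hits]


def _read_outgroup_ids(path: str) -> list[str]:
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        return [r.id for r in read_fasta(path)]
    return [line.strip() for line in text.splitlines() if line.strip()]


def _stage_tree(config: RunConfig, out: Path):
    if config.tree:
        tree = read_tree(config.tree)
        write_tree(tree, out / "tree.nwk")
        return tree
    align_path, outgroup_path = _require(config, "tree", "alignment", "outgroup")
    msa = trim_gap_columns(read_alignment(align_path), config.max_gap_fraction)
    tree = bootstrap_supports(msa, replicates=config.bootstrap, seed=config.seed)
    tree = root_on_outgroup(tree, _read_outgroup_ids(outgroup_path))
    write_tree(tree, out / "tree.nwk")
    log.info("tree: %d leaves, %d bootstrap replicates", len(msa.ids), config.bootstrap)
    return tree


def _stage_clades(config: RunConfig, out: Path, tree, candidates):
    if tree is None:
        tree_path = config.tree or str(out / "tree.nwk")
        if not Path(tree_path).exists():
            raise StageError("clades", f"no tree available: {tree_path}")
        tree = read_tree(tree_path)
    labels = _load_references(config, "clades")
    if candidates is None:
        cand_path = config.st_list or str(out / "candidates.tsv")
        if not Path(cand_path).exists():
            raise StageError("clades", f"no candidate list available: {cand_path}")
        candidates = _read_id_column(cand_path)
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    candidates = [c for c in candidates if c in leaf_labels and c not in labels]
    assignment = extract_supported_clades(
        tree,
        candidates=candidates,
        references=[r for r in labels if r in leaf_labels],
        min_support=config.min_support,
        min_branch_length=config.min_branch_length,
    )
    refs = [
        _label_record(rid, info) for rid, info in labels.items()
    ]
    assignment = propagate_substrate_labels(assignment, refs)
    write_clades_tsv(assignment, out / "clades.tsv")
    write_unplaced_tsv(assignment, out / "unplaced.tsv")
    log.info(
        "clades: %d clades, %d unplaced", len(assignment.clades), len(assignment.unplaced)
    )
    return assignment


def _label_record(rid: str, info: dict):
    from .seqio import ProteinRecord

    return ProteinRecord(
        id=rid,
        sequence="X",  # only the labels matter for propagation
        species=info.get("species", ""),
        is_reference=True,
        substrate_labels=info.get("substrate_labels", frozenset()),
    )


def _read_id_column(path: str) -> list[str]:
    ids = []
    with open(path) as fh:
        rows = [line for line in fh if not line.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    if reader.fieldnames and "id" in reader.fieldnames:
        for row in reader:
            ids.append(row["id"])
        return ids
    return [line.strip().split("\t")[0] for line in rows if line.strip()]


def _stage_motifs(config: RunConfig, out: Path, assignment):
    (proteome_path,) = _require(config, "motifs", "proteome")
    proteins = read_fasta(proteome_path)
    patterns = (
        read_motif_table(config.motif_table) if config.motif_table else default_motifs()
    )
    if assignment is None:
        clades_path = out / "clades.tsv"
        if not clades_path.exists():
            raise StageError("motifs", f"no clade table available: {clades_path}")
        assignment = read_clades_tsv(clades_path)
    hits = []
    for rec in proteins:
        for pat in patterns:
            hits.extend(scan_sequence(pat, rec))
    write_hits_tsv(hits, out / "motif_hits.tsv")
    table = clade_conservation(
        assignment, proteins, patterns, threshold=config.conservation_threshold,
        warn=log.warning,
    )
    table.to_tsv(out / "conservation.tsv")
    _prepend_header(out / "conservation.tsv", _header(config.seed, {"proteome": proteome_path}))
    variants_rows = []
    for (clade_id, motif), counter in sorted(table.variants.items()):
        for variant, count in sorted(counter.items()):
            variants_rows.append((clade_id, motif, variant, count))
    with open(out / "motif_variants.tsv", "w") as fh:
        fh.write("clade_id\tmotif\tvariant\tcount\n")
        for row in variants_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    log.info("motifs: %d patterns, %d hits", len(patterns), len(hits))


def _stage_de(config: RunConfig, out: Path):
    expr_path, samples_path = _require(config, "de", "expression", "samples")
    expr = pd.read_csv(expr_path, sep="\t", index_col=0, comment="#")
    samples = pd.read_csv(samples_path, sep="\t", comment="#")
    st_genes = set(_read_id_column(config.st_list)) if config.st_list else None
    header = _header(config.seed, {"expression": expr_path, "samples": samples_path})
    filtered = {}
    for comp in config.comparisons:
        wt = samples.loc[
            (samples.strain == comp.wt_strain)
            & (samples.carbon_source == comp.carbon_source),
            "sample",
        ].tolist()
        mut = samples.loc[
            (samples.strain == comp.mutant_strain)
            & (samples.carbon_source == comp.carbon_source),
            "sample",
        ].tolist()
        if not wt or not mut:
            raise StageError(
                "de",
                f"comparison {comp.tf}: no samples for "
                f"{comp.wt_strain}/{comp.mutant_strain} on {comp.carbon_source}",
            )
        de = moderated_de(expr, wt, mut)
        table = apply_st_filters(
            de,
            fc_cutoff=config.fc,
            adj_p_cutoff=config.adj_p,
            floor=config.floor,
            st_genes=st_genes,
        )
        path = out / f"de_{comp.tf}.tsv"
        table.to_csv(path, sep="\t", float_format="%.6g")
        _prepend_header(path, header)
        filtered[comp.tf] = table
        log.info("de %s: %d affected", comp.tf, int(table["affected"].sum()))
    # condition means + clustering for the heatmap export
    means = average_replicates(expr, samples)
    if means.shape[1] >= 2 and expr.shape[0] >= 2:
        cl = cluster_genes(means)
        heat = export_heatmap_table(means, cl["order"], filtered)
        heat.to_csv(out / "heatmap.tsv", sep="\t", float_format="%.4f")
    return filtered


def _stage_regulons(config: RunConfig, out: Path, filtered):
    if filtered is None:
        filtered = {}
        for path in sorted(out.glob("de_*.tsv")):
            tf = path.stem[3:]
            filtered[tf] = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if not filtered:
        raise StageError("regulons", "no differential-expression tables available")
    regulons = {tf: affected_set(tbl) for tf, tbl in filtered.items()}
    with open(out / "regulons.tsv", "w") as fh:
        fh.write("tf\tn_affected\tgenes\n")
        for tf in sorted(regulons):
            fh.write(f"{tf}\t{len(regulons[tf])}\t{';'.join(sorted(regulons[tf]))}\n")
    summary = regulon_overlap(regulons)
    summary.pairwise.to_csv(out / "regulon_overlap.tsv", sep="\t")
    with open(out / "regulon_overlap.tsv", "a") as fh:
        fh.write(f"# genes affected by >=2 TFs: {summary.multi_tf_count}\n")
    counts = summary.per_gene_tf_count
    counts.rename("n_tfs").to_csv(out / "gene_tf_counts.tsv", sep="\t")
    log.info(
        "regulons: %d TFs, %d genes affected by >=2 TFs",
        len(regulons),
        summary.multi_tf_count,
    )
    return regulons
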