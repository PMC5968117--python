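"""Seeded synthetic inputs with machine-readable ground truth.

Two generators back the test suite and the worked examples:

* :func:`simulate_family` emits a clade-structured protein family with a
  planted transporter domain, planted signature motifs, characterized
  (reference) members carrying substrate labels, unrelated decoy proteins,
  and a diverged outgroup clade.  Clade-defining substitutions follow an
  infinite-sites scheme (each site mutates on at most one lineage of the
  clade backbone) and member-level noise an infinite-alleles rule (every
  substitution introduces a residue unseen at that site), so clades are
  exact star lineages with no spurious shared derived signal; within a
  clade the domain is under strict purifying constraint (members differ
  only outside it), which makes the screening, clade-partition and
  motif-conservation truth exact.  Motif realizations are planted once in
  the family ancestor; clades designed to lack a motif get it degraded,
  and accidental matches are scrubbed, so presence/absence equals the
  design exactly.

* :func:`simulate_expression` emits a genes x samples matrix with
  log-normal baselines, condition-specific induction (a gene induced on a
  carbon source is multiplied by the induction effect in every strain),
  TF-knockout regulons (in the TF's deletion strain the induced level is
  divided by the knockdown factor on the inducing source), and
  multiplicative log-normal replicate noise.

Identical (config, seed) always reproduces identical output bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .motifs import MotifPattern, parse_motif, scan_sequence
from .profile_screen import ROBINSON_ROBINSON
from .seqio import AMINO_ACIDS, MSA, ProteinRecord, write_alignment, write_fasta

DEFAULT_SUBSTRATES = (
    "D-glucose",
    "D-xylose",
    "L-arabinose",
    "D-galactose",
    "L-rhamnose",
    "D-galacturonic acid",
)

# (pattern, offset inside the domain, clades carrying it)
DEFAULT_MOTIF_PLAN = (
    ("GGxxxGxD", 10, (0, 1)),
    ("QQLxG", 40, (0, 1, 2, 3)),
    ("YYxP/T", 70, (0, 3)),
)


@dataclass
class FamilyConfig:
    """Design of the synthetic transporter family.

    Substitution probabilities are per site: ``between_sub`` separates the
    clade ancestors from the family ancestor (domain included, planted
    motifs excluded), ``within_sub`` separates members from their clade
    ancestor (outside the domain only -- the domain is treated as being
    under purifying selection within a clade).
    """

    seed: int
    n_clades: int = 4
    members_per_clade: int = 8
    decoys: int = 30
    sequence_length: int = 400
    domain_length: int = 120
    domain_start: int = 140
    within_sub: float = 0.05
    between_sub: float = 0.15
    outgroup_size: int = 3
    outgroup_sub: float = 0.25
    reference_fraction: float = 0.5
    substrate_labels: tuple[str, ...] = DEFAULT_SUBSTRATES
    motif_plan: tuple[tuple[str, int, tuple[int, ...]], ...] = DEFAULT_MOTIF_PLAN

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p, nm in ((self.within_sub, "within_sub"), (self.between_sub, "between_sub"), (self.outgroup_sub, "outgroup_sub")):
            if not 0 <= p <= 0.5:
                raise ValueError(f"{nm} must be in [0, 0.5]")
        if self.n_clades * self.between_sub + self.outgroup_sub > 1.0:
            raise ValueError(
                "infinite-sites budget exceeded: n_clades*between_sub + "
                "outgroup_sub must be <= 1"
            )
        if self.domain_start + self.domain_length > self.sequence_length:
            raise ValueError("domain does not fit in the sequence")
        if not 0 < self.reference_fraction <= 1:
            raise ValueError("reference_fraction must be in (0, 1]")
        if self.n_clades < 1 or self.members_per_clade < 1:
            raise ValueError("need at least one clade with one member")
        spans = []
        for text, offset, clades in self.motif_plan:
            pat = parse_motif(text)
            if offset < 0 or offset + len(pat) > self.domain_length:
                raise ValueError(f"motif {text!r} does not fit in the domain")
            if any(c < 0 or c >= self.n_clades for c in clades):
                raise ValueError(f"motif {text!r}: clade index out of range")
            spans.append((offset, offset + len(pat), text))
        spans.sort()
        for (s1, e1, t1), (s2, e2, t2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"motifs {t1!r} and {t2!r} overlap in the domain")


@dataclass
class FamilyTruth:
    clade_of: dict[str, int]          # member id -> clade index
    references: dict[str, str]        # reference id -> substrate label
    decoys: list[str]
    outgroup: list[str]
    motif_positions: dict[str, dict[str, int]]  # id -> pattern -> start
    motif_design: dict[str, list[int]]          # pattern -> carrying clades
    domain_span: tuple[int, int]
    clade_substrate: dict[int, str]

    def candidate_ids(self) -> list[str]:
        return [i for i in self.clade_of if i not in self.references]

    def clade_partition(self) -> dict[str, int]:
        """Planted clade index for every candidate (non-reference member)."""
        return {i: c for i, c in self.clade_of.items() if i not in self.references}


@dataclass
class SyntheticFamily:
    records: list[ProteinRecord]        # members + decoys + outgroup
    reference_alignment: MSA            # reference domain segments
    truth: FamilyTruth
    config: FamilyConfig

    @property
    def proteome(self) -> list[ProteinRecord]:
        """What the screen sees: family members and decoys, no outgroup."""
        og = set(self.truth.outgroup)
        return [r for r in self.records if r.id not in og]

    @property
    def references(self) -> list[ProteinRecord]:
        return [r for r in self.records if r.is_reference]

    @property
    def outgroup_records(self) -> list[ProteinRecord]:
        og = set(self.truth.outgroup)
        return [r for r in self.records if r.id in og]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteome, outdir / "proteome.fasta")
        write_fasta(self.outgroup_records, outdir / "outgroup.fasta")
        write_alignment(self.reference_alignment, outdir / "reference_domain_alignment.fasta")
        with open(outdir / "references.tsv", "w") as fh:
            fh.write("id\tspecies\tsubstrate_labels\n")
            for rec in self.references:
                fh.write(f"{rec.id}\tsynthetic\t{';'.join(sorted(rec.substrate_labels))}\n")
        truth = asdict(self.truth)
        truth["config"] = asdict(self.config)
        with open(outdir / "family_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _draw_background(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(np.array(list(AMINO_ACIDS)), size=length, p=ROBINSON_ROBINSON)


def _mutate(
    rng: np.random.Generator,
    seq: np.ndarray,
    prob: float,
    protected: np.ndarray,
) -> np.ndarray:
    """Substitute each unprotected site with probability ``prob``.

    Replacement residues are drawn from the background excluding the
    current residue, so a substitution always changes the site.
    """
    seq = seq.copy()
    hit = (rng.random(len(seq)) < prob) & ~protected
    for pos in np.flatnonzero(hit):
        choices = [aa for aa in AMINO_ACIDS if aa != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
    return seq


def _realize(pattern: MotifPattern, rng: np.random.Generator) -> str:
    out = []
    for tok in pattern.tokens:
        if tok is None:
            out.append(AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))])
        else:
            out.append(tok[rng.integers(len(tok))])
    return "".join(out)


def _break_match(
    seq: np.ndarray,
    pattern: MotifPattern,
    start: int,
    mutable: np.ndarray,
    rng: np.random.Generator,
) -> bool:
    """Mutate one constrained, mutable position inside a match so the
    window no longer satisfies the pattern.  The position is chosen at
    random among the eligible ones so that independently degraded copies
    rarely coincide.  Returns False when the match has no constrained
    mutable position."""
    eligible = [
        (start + k, tok)
        for k, tok in enumerate(pattern.tokens)
        if tok is not None and mutable[start + k]
    ]
    if not eligible:
        return False
    pos, tok = eligible[rng.integers(len(eligible))]
    choices = [aa for aa in AMINO_ACIDS if aa not in tok]
    seq[pos] = choices[rng.integers(len(choices))]
    return True


def _scrub(
    seq: np.ndarray,
    patterns: list[MotifPattern],
    keep_at: dict[str, int],
    mutable: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Remove accidental motif matches, in place.

    Matches of a pattern at its planted offset (``keep_at``) are preserved;
    every other match is broken.  If a straddling match has no constrained
    mutable position, the constraint is relaxed to any constrained
    position outside planted motif spans (vanishingly rare)."""
    for _ in range(20):
        dirty = False
        text = "".join(seq)
        for pat in patterns:
            for hit in scan_sequence(pat, text):
                if keep_at.get(pat.name) == hit.start:
                    continue
                if not _break_match(seq, pat, hit.start, mutable, rng):
                    relaxed = mutable.copy()
                    relaxed[:] = True
                    for name, at in keep_at.items():
                        plen = next(len(p) for p in patterns if p.name == name)
                        relaxed[at : at + plen] = False
                    _break_match(seq, pat, hit.start, relaxed, rng)
                dirty = True
        if not dirty:
            return
    raise RuntimeError("could not scrub accidental motif matches")  # pragma: no cover


def simulate_family(config: FamilyConfig) -> SyntheticFamily:
    rng = np.random.default_rng(config.seed)
    L = config.sequence_length
    dstart, dlen = config.domain_start, config.domain_length
    dend = dstart + dlen
    patterns = [parse_motif(text) for text, _, _ in config.motif_plan]
    plan = {
        text: (dstart + offset, set(clades))
        for text, offset, clades in config.motif_plan
    }
    ancestor = _draw_background(rng, L)
    # plant one family-level realization of every motif in the ancestor;
    # carrying clades inherit it unchanged, the others degrade it.  Shared
    # motif residues are therefore ancestral, never derived, and carry no
    # clade-grouping signal.
    for pat in patterns:
        at = plan[pat.name][0]
        ancestor[at : at + len(pat)] = list(_realize(pat, rng))
    motif_mask = np.zeros(L, dtype=bool)
    for pat in patterns:
        at = plan[pat.name][0]
        motif_mask[at : at + len(pat)] = True

    # infinite-sites backbone: every non-motif site mutates on at most one
    # branch (one clade or the outgroup), so the clade backbone is an exact
    # star with zero shared derived signal between clades.
    n_branches = config.n_clades + 1  # clades + outgroup lineage
    probs = [config.between_sub] * config.n_clades + [config.outgroup_sub]
    probs.append(1.0 - sum(probs))  # no mutation
    branch_of_site = rng.choice(n_branches + 1, size=L, p=probs)
    branch_of_site[motif_mask] = n_branches  # motif spans handled separately

    def _derive(branch: int) -> np.ndarray:
        seq = ancestor.copy()
        for pos in np.flatnonzero(branch_of_site == branch):
            choices = [aa for aa in AMINO_ACIDS if aa != seq[pos]]
            seq[pos] = choices[rng.integers(len(choices))]
        return seq

    records: list[ProteinRecord] = []
    clade_of: dict[str, int] = {}
    references: dict[str, str] = {}
    motif_positions: dict[str, dict[str, int]] = {}
    n_ref = max(1, int(np.ceil(config.reference_fraction * config.members_per_clade)))

    domain_mask = np.zeros(L, dtype=bool)
    domain_mask[dstart:dend] = True

    # infinite-alleles member noise: a within-clade substitution introduces
    # a residue not present in any other lineage at that site, so member
    # noise never creates shared derived states between clades (which would
    # otherwise leak spurious bootstrap signal into the star backbone).
    used_residues: dict[int, set[str]] = {pos: {ancestor[pos]} for pos in range(L)}

    def _member_noise(seq: np.ndarray, mutable: np.ndarray) -> np.ndarray:
        seq = seq.copy()
        hit = (rng.random(L) < config.within_sub) & mutable
        for pos in np.flatnonzero(hit):
            banned = used_residues[pos] | {seq[pos]}
            choices = [aa for aa in AMINO_ACIDS if aa not in banned]
            if not choices:  # pragma: no cover - needs >19 lineages at a site
                choices = [aa for aa in AMINO_ACIDS if aa != seq[pos]]
            seq[pos] = choices[rng.integers(len(choices))]
            used_residues[pos].add(seq[pos])
        return seq

    for ci in range(config.n_clades):
        carried = {
            pat.name: plan[pat.name][0]
            for pat in patterns
            if ci in plan[pat.name][1]
        }
        protected = np.zeros(L, dtype=bool)
        for name, at in carried.items():
            plen = next(len(p) for p in patterns if p.name == name)
            protected[at : at + plen] = True
        clade_seq = _derive(ci)
        for pat in patterns:
            at, clades = plan[pat.name]
            if ci not in clades:
                # guarantee absence at the planted offset
                _break_match(clade_seq, pat, at, np.ones(L, dtype=bool), rng)
        _scrub(clade_seq, patterns, carried, ~protected, rng)
        for pos in range(L):
            used_residues[pos].add(clade_seq[pos])
        label = config.substrate_labels[ci % len(config.substrate_labels)]
        for mi in range(config.members_per_clade):
            member = _member_noise(clade_seq, ~domain_mask)
            _scrub(member, patterns, carried, ~domain_mask, rng)
            pid = f"c{ci + 1}m{mi + 1:02d}"
            is_ref = mi < n_ref
            records.append(
                ProteinRecord(
                    id=pid,
                    sequence="".join(member),
                    species="synthetic",
                    is_reference=is_ref,
                    substrate_labels=frozenset({label}) if is_ref else frozenset(),
                )
            )
            clade_of[pid] = ci
            if is_ref:
                references[pid] = label
            motif_positions[pid] = dict(carried)

    decoys: list[str] = []
    for di in range(config.decoys):
        seq = _draw_background(rng, L)
        _scrub(seq, patterns, {}, np.ones(L, dtype=bool), rng)
        pid = f"decoy{di + 1:02d}"
        decoys.append(pid)
        records.append(ProteinRecord(id=pid, sequence="".join(seq), species="synthetic"))

    # the outgroup is its own (deeply diverged) clade, as a real outgroup
    # lineage would be; members then vary within it like any other clade
    outgroup: list[str] = []
    og_ancestor = _derive(config.n_clades)
    for pat in patterns:
        _break_match(og_ancestor, pat, plan[pat.name][0], np.ones(L, dtype=bool), rng)
    _scrub(og_ancestor, patterns, {}, np.ones(L, dtype=bool), rng)
    for pos in range(L):
        used_residues[pos].add(og_ancestor[pos])
    for oi in range(config.outgroup_size):
        seq = _member_noise(og_ancestor, ~domain_mask)
        _scrub(seq, patterns, {}, ~domain_mask, rng)
        pid = f"outg{oi + 1}"
        outgroup.append(pid)
        records.append(ProteinRecord(id=pid, sequence="".join(seq), species="outgroup"))

    ref_ids = sorted(references)
    ref_alignment = MSA(
        ref_ids,
        [next(r.sequence[dstart:dend] for r in records if r.id == i) for i in ref_ids],
    )
    truth = FamilyTruth(
        clade_of=clade_of,
        references=references,
        decoys=decoys,
        outgroup=outgroup,
        motif_positions=motif_positions,
        motif_design={text: sorted(clades) for text, _, clades in config.motif_plan},
        domain_span=(dstart, dend),
        clade_substrate={
            ci: config.substrate_labels[ci % len(config.substrate_labels)]
            for ci in range(config.n_clades)
        },
    )
    return SyntheticFamily(
        records=records, reference_alignment=ref_alignment, truth=truth, config=config
    )


# ---------------------------------------------------------------------------
# expression


DEFAULT_TF_PLAN = {
    "XlnR": "D-xylose",
    "AraR": "L-arabinose",
    "AmyR": "maltose",
    "GalX": "D-galactose",
    "RhaR": "L-rhamnose",
    "GaaR": "D-galacturonic acid",
}

DEFAULT_CONDITIONS = (
    "D-glucose",
    "D-xylose",
    "L-arabinose",
    "maltose",
    "D-galactose",
    "L-rhamnose",
    "D-galacturonic acid",
    "sucrose",
)


@dataclass
class ExpressionConfig:
    """Design of the synthetic expression study.

    The layout mirrors a wild type profiled on every carbon source plus one
    deletion strain per transcription factor profiled on its inducing
    source, all in biological duplicate.  ``regulon_plan`` maps TF ->
    affected ST genes; a regulon gene must be induced on its TF's source
    (``induction_plan`` is completed accordingly when it omits the gene).
    """

    seed: int
    n_genes: int = 2000
    n_st_genes: int = 30
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    tf_plan: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TF_PLAN))
    replicates: int = 2
    wild_type: str = "WT"
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    st_baseline_log2_mean: float = 9.0
    st_baseline_log2_sd: float = 1.0
    induction_effect: float = 8.0
    knockdown: float = 4.0
    noise_sd: float = 0.25
    regulon_plan: dict[str, list[str]] | None = None
    induction_plan: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.induction_effect <= 1 or self.knockdown <= 1:
            raise ValueError("induction effect and knockdown factor must be > 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for tf, cond in self.tf_plan.items():
            if cond not in self.conditions:
                raise ValueError(f"TF {tf}: inducing source {cond!r} not a condition")
        if self.regulon_plan is None:
            self.regulon_plan = self._default_regulons()
        st = set(self.st_gene_ids())
        for tf, genes in self.regulon_plan.items():
            if tf not in self.tf_plan:
                raise ValueError(f"regulon for unknown TF {tf}")
            unknown = [g for g in genes if g not in st]
            if unknown:
                raise ValueError(f"regulon of {tf} references unknown genes {unknown}")
        if self.induction_plan is None:
            self.induction_plan = {}
        induction = {g: set(c) for g, c in self.induction_plan.items()}
        for tf, genes in self.regulon_plan.items():
            for g in genes:
                induction.setdefault(g, set()).add(self.tf_plan[tf])
        all_ids = set(self.gene_ids())
        for g, conds in induction.items():
            if g not in all_ids:
                raise ValueError(f"induction plan references unknown gene {g}")
            bad = [c for c in conds if c not in self.conditions]
            if bad:
                raise ValueError(f"gene {g}: unknown conditions {bad}")
        self.induction_plan = {g: sorted(c) for g, c in sorted(induction.items())}

    def st_gene_ids(self) -> list[str]:
        return [f"st{i + 1:03d}" for i in range(self.n_st_genes)]

    def gene_ids(self) -> list[str]:
        background = [f"g{i + 1:04d}" for i in range(self.n_genes - self.n_st_genes)]
        return self.st_gene_ids() + background

    def _default_regulons(self) -> dict[str, list[str]]:
        """Four exclusive targets per TF plus three designed overlap genes."""
        st = self.st_gene_ids()
        tfs = list(self.tf_plan)
        per_tf = 4
        need = per_tf * len(tfs) + 3
        if len(st) < need:
            raise ValueError(
                f"default regulon plan needs >= {need} ST genes, have {len(st)}"
            )
        plan: dict[str, list[str]] = {}
        k = 0
        for tf in tfs:
            plan[tf] = st[k : k + per_tf]
            k += per_tf
        overlaps = st[k : k + 3]
        pairs = [(tfs[0], tfs[1]), (tfs[1], tfs[-1]), (tfs[-2], tfs[-1])]
        for gene, (a, b) in zip(overlaps, pairs):
            plan[a].append(gene)
            plan[b].append(gene)
        return {tf: sorted(genes) for tf, genes in plan.items()}


@dataclass
class ExpressionTruth:
    regulons: dict[str, list[str]]
    induced_conditions: dict[str, list[str]]
    st_genes: list[str]
    tf_plan: dict[str, str]
    wild_type: str


@dataclass
class SyntheticExpression:
    expr: pd.DataFrame      # genes x samples, linear scale
    samples: pd.DataFrame   # sample, strain, carbon_source, replicate
    truth: ExpressionTruth
    config: ExpressionConfig

    def comparison_samples(self, tf: str) -> tuple[list[str], list[str]]:
        """(wild-type, mutant) sample ids on the TF's inducing source."""
        cond = self.config.tf_plan[tf]
        sheet = self.samples
        wt = sheet.loc[
            (sheet.strain == self.config.wild_type) & (sheet.carbon_source == cond),
            "sample",
        ].tolist()
        mut = sheet.loc[
            (sheet.strain == f"d{tf}") & (sheet.carbon_source == cond), "sample"
        ].tolist()
        return wt, mut

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expr.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6f")
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        truth = asdict(self.truth)
        with open(outdir / "expression_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_expression(config: ExpressionConfig) -> SyntheticExpression:
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    st = set(config.st_gene_ids())
    n = len(genes)
    base = np.empty(n)
    for i, g in enumerate(genes):
        if g in st:
            base[i] = 2.0 ** rng.normal(config.st_baseline_log2_mean, config.st_baseline_log2_sd)
        else:
            base[i] = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd)

    rows = []
    for cond in config.conditions:
        for r in range(1, config.replicates + 1):
            rows.append((f"{config.wild_type}.{cond}.r{r}", config.wild_type, cond, r))
    for tf in config.tf_plan:
        cond = config.tf_plan[tf]
        for r in range(1, config.replicates + 1):
            rows.append((f"d{tf}.{cond}.r{r}", f"d{tf}", cond, r))
    samples = pd.DataFrame(rows, columns=["sample", "strain", "carbon_source", "replicate"])

    induced = {g: set(c) for g, c in config.induction_plan.items()}
    regulon = {tf: set(g) for tf, g in config.regulon_plan.items()}
    level = np.empty((n, len(samples)))
    for j, (_, strain, cond, _) in samples.iterrows():
        col = base.copy()
        for i, g in enumerate(genes):
            if cond in induced.get(g, ()):  # condition-specific induction
                col[i] *= config.induction_effect
            if strain.startswith("d"):
                tf = strain[1:]
                if g in regulon.get(tf, ()) and cond == config.tf_plan[tf]:
                    col[i] /= config.knockdown
        level[:, j] = col
    noise = 2.0 ** rng.normal(0.0, config.noise_sd, size=level.shape) if config.noise_sd > 0 else 1.0
    expr = pd.DataFrame(level * noise, index=genes, columns=samples["sample"].tolist())
    expr.index.name = "gene"
    truth = ExpressionTruth(
        regulons={tf: sorted(g) for tf, g in config.regulon_plan.items()},
        induced_conditions=config.induction_plan,
        st_genes=config.st_gene_ids(),
        tf_plan=dict(config.tf_plan),
        wild_type=config.wild_type,
    )
    return SyntheticExpression(expr=expr, samples=samples, truth=truth, config=config)
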