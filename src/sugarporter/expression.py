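"""Expression averaging, clustering, moderated differential expression and
TF-regulon tables.

The workflow mirrors a wild-type-versus-TF-deletion microarray comparison:
replicate arrays are averaged per (strain, carbon source) condition on the
linear normalized scale, genes are hierarchically clustered on correlation
distance of their log2 profiles, and each mutant is compared to the wild
type with a two-group moderated t-test (empirical-Bayes variance shrinkage,
the two-sample special case of the limma linear model).  Genes pass the
regulon filter when their linear fold change exceeds 1.5 in the reduced
direction with Benjamini-Hochberg adjusted p below 0.01, unless both
condition means sit under the expression floor of 50, in which case the
gene is not assessable ("na").  An RNA-seq variant of the filter
(FPKM > 10, FC > 1.5, t-test p < 0.05) is provided for comparisons whose
published analysis used those thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

DEFAULT_FC_CUTOFF = 1.5
DEFAULT_ADJ_P_CUTOFF = 0.01
DEFAULT_EXPRESSION_FLOOR = 50.0
DEFAULT_FPKM_FLOOR = 10.0
DEFAULT_RNASEQ_P = 0.05


def average_replicates(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    group_by: Sequence[str] = ("strain", "carbon_source"),
) -> pd.DataFrame:
    """Arithmetic mean per gene per condition group on the linear scale.

    ``expr`` is genes x samples; ``samples`` must have a ``sample`` column
    matching ``expr``'s columns plus the grouping columns.  Output columns
    are a MultiIndex over the grouping keys.
    """
    samples = samples.set_index("sample") if "sample" in samples.columns else samples
    missing = [c for c in expr.columns if c not in samples.index]
    if missing:
        raise ValueError(f"samples sheet missing entries for {missing}")
    keys = samples.loc[expr.columns, list(group_by)]
    groups = keys.groupby(list(group_by), sort=True).groups
    cols = {}
    for key, sample_ids in groups.items():
        key = key if isinstance(key, tuple) else (key,)
        cols[key] = expr[list(sample_ids)].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(cols.keys(), names=list(group_by))
    return out


def cluster_genes(
    mean_matrix: pd.DataFrame,
    n_clusters: int | None = None,
    height: float | None = None,
) -> dict:
    """Average-linkage hierarchical clustering on 1 - Pearson correlation.

    Profiles are log2(mean + 1) transformed.  Genes with zero variance
    across conditions cannot be correlated; they are assigned distance 1 to
    everything and reported under ``flagged``.  Returns the scipy linkage,
    the dendrogram leaf order (gene ids), and flat cluster labels when a
    cut is requested.
    """
    if mean_matrix.shape[1] < 2:
        raise ValueError("correlation is undefined on a single condition")
    if mean_matrix.shape[0] < 2:
        raise ValueError("need at least two genes to cluster")
    X = np.log2(mean_matrix.to_numpy(dtype=float) + 1.0)
    sd = X.std(axis=1)
    flagged = [g for g, s in zip(mean_matrix.index, sd) if s == 0]
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc**2).sum(axis=1))
    norm[norm == 0] = 1.0
    U = Xc / norm[:, None]
    corr = U @ U.T
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    Z = hierarchy.average(squareform(dist, checks=False))
    order = [mean_matrix.index[i] for i in hierarchy.leaves_list(Z)]
    flat = None
    if n_clusters is not None:
        flat = pd.Series(
            hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust"),
            index=mean_matrix.index,
        )
    elif height is not None:
        flat = pd.Series(
            hierarchy.fcluster(Z, t=height, criterion="distance"),
            index=mean_matrix.index,
        )
    return {"linkage": Z, "order": order, "clusters": flat, "flagged": flagged}


def _fit_f_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior for gene variances.

    Under the hierarchical model the sample variances are distributed as
    s0^2 * F(df, d0).  Matching the first two moments of the observed
    variances gives d0 and s0^2; when the observed dispersion is no larger
    than the chi-square sampling noise alone, the prior is effectively
    infinitely informative (d0 = inf, s0^2 = mean variance).
    """
    s2 = s2[np.isfinite(s2)]
    if len(s2) == 0 or np.all(s2 == 0):
        raise ValueError("no residual variance information: all-constant matrix")
    m1 = s2.mean()
    v = s2.var(ddof=1) if len(s2) > 1 else 0.0
    if m1 <= 0:
        raise ValueError("no residual variance information: all-constant matrix")
    r = v / (m1 * m1)
    # Var/E^2 of F(df, d0) scaled: r = 2 (df + d0 - 2) / (df (d0 - 4))
    if r * df <= 2.0 + 1e-12:
        return float(m1), np.inf
    d0 = (4.0 * r * df + 2.0 * df - 4.0) / (r * df - 2.0)
    if d0 <= 4.0:
        d0 = 4.0 + 1e-6  # moment solution only valid for d0 > 4
    s0_sq = m1 * (d0 - 2.0) / d0
    return float(s0_sq), float(d0)


def moderated_de(
    expr: pd.DataFrame,
    wt_samples: Sequence[str],
    mut_samples: Sequence[str],
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t-test per gene (mutant vs wild type).

    Statistics are computed on log2(value + 1).  Gene-wise pooled variances
    are shrunk toward a common prior (s0^2, d0) estimated across genes by
    method of moments on the scaled-F distribution of sample variances;
    ``prior_df`` overrides the estimated d0 (0 gives the ordinary
    two-sample t).  Two-sided p-values use d0 + df degrees of freedom and
    are Benjamini-Hochberg adjusted across all genes in ``expr``.

    Returns a frame indexed by gene with columns ``log2_fc`` (mutant minus
    wild type), ``mean_wt``/``mean_mut`` (linear scale), ``t_mod``, ``p``,
    ``adj_p``, ``s2``, ``s2_post``, ``df_prior``, ``df_total``.
    """
    wt_samples = list(wt_samples)
    mut_samples = list(mut_samples)
    if not wt_samples or not mut_samples:
        raise ValueError("both groups need at least one sample")
    n1, n2 = len(wt_samples), len(mut_samples)
    df = n1 + n2 - 2
    if df < 1:
        raise ValueError("need at least 3 samples in total for a t-test")
    W = expr[wt_samples].to_numpy(dtype=float)
    M = expr[mut_samples].to_numpy(dtype=float)
    if np.any(W < 0) or np.any(M < 0):
        raise ValueError("expression values must be nonnegative")
    lw, lm = np.log2(W + 1.0), np.log2(M + 1.0)
    fc = lm.mean(axis=1) - lw.mean(axis=1)
    ss = ((lw - lw.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (lm - lm.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df
    if prior_df is None:
        s0_sq, d0 = _fit_f_prior(s2, df)
    elif prior_df == 0:
        s0_sq, d0 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        s0_sq = float(np.mean(s2))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fc / np.where(se > 0, se, 1.0), np.where(fc == 0, 0.0, np.inf * np.sign(fc)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    adj_p = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2_fc": fc,
            "mean_wt": W.mean(axis=1),
            "mean_mut": M.mean(axis=1),
            "t_mod": t,
            "p": p,
            "adj_p": adj_p,
            "s2": s2,
            "s2_post": s2_post,
            "df_prior": d0,
            "df_total": df_total,
        },
        index=expr.index,
    )


def apply_st_filters(
    de: pd.DataFrame,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    adj_p_cutoff: float = DEFAULT_ADJ_P_CUTOFF,
    floor: float = DEFAULT_EXPRESSION_FLOOR,
    direction: str = "reduced",
    st_genes: Iterable[str] | None = None,
    adjust_within_st: bool = False,
) -> pd.DataFrame:
    """Apply the microarray regulon filters to a moderated-DE table.

    Genes whose wild-type AND mutant condition means are both below the
    expression floor are flagged ``na`` (not assessable) and never called
    affected.  The remaining genes are affected when the linear fold change
    is strictly greater than ``fc_cutoff`` in the requested direction
    (``reduced`` in the mutant by default, ``both`` for either) and the
    BH-adjusted p is strictly below ``adj_p_cutoff``.

    With ``st_genes`` the table is restricted to the candidate transporter
    set after filtering; ``adjust_within_st=True`` instead re-runs the BH
    adjustment inside the candidate set before thresholding.
    """
    if direction not in {"reduced", "increased", "both"}:
        raise ValueError(f"unknown direction {direction!r}")
    out = de.copy()
    if st_genes is not None and adjust_within_st:
        out = out.loc[[g for g in out.index if g in set(st_genes)]].copy()
        out["adj_p"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    wt, mut = out["mean_wt"].to_numpy(), out["mean_mut"].to_numpy()
    na = (wt < floor) & (mut < floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc_reduced = np.where(mut > 0, wt / np.where(mut > 0, mut, 1.0), np.inf)
        fc_increased = np.where(wt > 0, mut / np.where(wt > 0, wt, 1.0), np.inf)
    fc_reduced = np.where((wt == 0) & (mut == 0), 1.0, fc_reduced)
    fc_increased = np.where((wt == 0) & (mut == 0), 1.0, fc_increased)
    if direction == "reduced":
        passes_fc = fc_reduced > fc_cutoff
    elif direction == "increased":
        passes_fc = fc_increased > fc_cutoff
    else:
        passes_fc = (fc_reduced > fc_cutoff) | (fc_increased > fc_cutoff)
    affected = ~na & passes_fc & (out["adj_p"].to_numpy() < adj_p_cutoff)
    out["na"] = na
    out["fold_change"] = np.where(fc_reduced >= fc_increased, fc_reduced, fc_increased)
    out["affected"] = affected
    if st_genes is not None and not adjust_within_st:
        out = out.loc[[g for g in out.index if g in set(st_genes)]]
    return out


def affected_set(filtered: pd.DataFrame) -> set[str]:
    return set(filtered.index[filtered["affected"]])


def rnaseq_filter(
    table: pd.DataFrame,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    p_cutoff: float = DEFAULT_RNASEQ_P,
    fpkm_floor: float = DEFAULT_FPKM_FLOOR,
) -> set[str]:
    """RNA-seq regulon filter: FPKM > floor in at least one condition,
    fold change > cutoff reduced in the mutant, t-test p < cutoff.

    ``table`` is indexed by gene with columns ``fpkm_wt``, ``fpkm_mut``,
    ``p``.
    """
    required = {"fpkm_wt", "fpkm_mut", "p"}
    if not required.issubset(table.columns):
        raise ValueError(f"rnaseq table needs columns {sorted(required)}")
    wt = table["fpkm_wt"].to_numpy(dtype=float)
    mut = table["fpkm_mut"].to_numpy(dtype=float)
    p = table["p"].to_numpy(dtype=float)
    expressed = (wt > fpkm_floor) | (mut > fpkm_floor)
    with np.errstate(divide="ignore"):
        fc = np.where(mut > 0, wt / np.where(mut > 0, mut, 1.0), np.inf)
    keep = expressed & (fc > fc_cutoff) & (p < p_cutoff)
    return set(table.index[keep])


@dataclass
class OverlapSummary:
    per_gene_tf_count: pd.Series
    multi_tf_count: int
    pairwise: pd.DataFrame  # TF x TF intersection sizes


def regulon_overlap(regulons: Mapping[str, set[str]]) -> OverlapSummary:
    """How many genes answer to more than one transcription factor.

    Returns per-gene TF counts, the number of genes in >= 2 regulons, and
    all pairwise regulon intersection sizes.
    """
    tfs = sorted(regulons)
    universe = sorted(set().union(*regulons.values())) if regulons else []
    counts = pd.Series(
        {g: sum(g in regulons[tf] for tf in tfs) for g in universe}, dtype=int
    )
    pairwise = pd.DataFrame(
        [[len(regulons[a] & regulons[b]) for b in tfs] for a in tfs],
        index=tfs,
        columns=tfs,
    )
    multi = int((counts >= 2).sum()) if len(counts) else 0
    return OverlapSummary(per_gene_tf_count=counts, multi_tf_count=multi, pairwise=pairwise)


def export_heatmap_table(
    mean_matrix: pd.DataFrame,
    order: Sequence[str],
    fc_tables: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Genes ordered by the dendrogram, with per-TF log2 fold changes.

    ``fc_tables`` maps TF name -> filtered DE table (from
    :func:`apply_st_filters`); its log2 fold change is appended per TF with
    "na" where the gene was below the expression floor in both strains.
    """
    out = mean_matrix.loc[list(order)].copy()
    out.columns = ["|".join(map(str, c)) if isinstance(c, tuple) else str(c) for c in out.columns]
    if fc_tables:
        for tf, table in fc_tables.items():
            col = []
            for g in order:
                if g in table.index and not table.loc[g, "na"]:
                    col.append(f"{table.loc[g, 'log2_fc']:.3f}")
                else:
                    col.append("na")
            out[f"log2fc_{tf}"] = col
    return out
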