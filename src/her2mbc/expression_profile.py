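"""HER2-driven expression profile, clustering and downstream classification.

Samples are split into four groups by HER2 status crossed with prior
anti-HER2 therapy; genes differing across the groups (Kruskal-Wallis
p < 0.001, unadjusted) define the HER2-driven profile, with chromosome 17
genes excluded regardless of p because they may be passengers co-amplified
with ERBB2. Expression of the selected genes is median centred per gene,
samples are correlated against each other (Pearson) and the correlation
matrix drives agglomerative clustering (distance 1 - r, average linkage by
default, dendrogram cut into k = 4 groups). Cluster composition is tested
with Fisher/chi-square enrichment.

Downstream classifiers: ESR1 low/high from a two-component mixture on log2
ESR1 expression (reusing the HER2-calling machinery); meta-ER status from
primary ER label crossed with the metastatic ESR1 class; gene-set signature
scores (mean of gene-wise median-centred log2 expression) with MAPK-high
defined as strictly above the cohort median score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .her2_calling import DegenerateInputError, fit_expression_mixture
from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

GROUP_LABELS = ("HER2+/prior", "HER2+/naive", "HER2-/prior", "HER2-/naive")

KW_SELECTION_P = 0.001  # strict, unadjusted
EXCLUDED_CHROMOSOME = "17"


def _log2(values: np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(values, dtype=float) + 1.0)


def make_four_groups(
    her2_calls: dict[str, str], prior_anti_her2: dict[str, bool]
) -> pd.Series:
    """Cross HER2 status with prior anti-HER2 therapy into four groups.

    Samples missing either label are excluded with a log entry.
    """
    labels = {}
    skipped = []
    for s, call in her2_calls.items():
        if call not in ("positive", "negative") or s not in prior_anti_her2:
            skipped.append(s)
            continue
        her2 = "HER2+" if call == "positive" else "HER2-"
        prior = "prior" if prior_anti_her2[s] else "naive"
        labels[s] = f"{her2}/{prior}"
    if skipped:
        logger.warning("four-group assignment: %d samples excluded (missing label)",
                       len(skipped))
    return pd.Series(labels, name="group")


@dataclass
class GeneSelectionResult:
    frame: pd.DataFrame  # index gene; columns p, selected, exclusion_reason

    @property
    def selected_genes(self) -> list[str]:
        return self.frame.index[self.frame["selected"]].tolist()


def select_her2_genes(
    expr: ExpressionMatrix,
    groups: pd.Series,
    *,
    p_threshold: float = KW_SELECTION_P,
) -> GeneSelectionResult:
    """Kruskal-Wallis screen of every gene across the sample groups.

    A gene is selected iff its unadjusted KW p is strictly below the
    threshold and it does not lie on chromosome 17. Fewer than four groups
    (a cohort missing a combination) is tolerated with a warning; constant
    genes have undefined p and are never selected.
    """
    samples = [s for s in expr.samples if s in groups.index]
    if len(samples) < len(expr.samples):
        logger.warning("gene selection: %d samples lack a group label",
                       len(expr.samples) - len(samples))
    grp = groups.loc[samples]
    levels = sorted(grp.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups for gene selection")
    if len(levels) < 4:
        logger.warning("only %d of 4 groups present; KW runs on those", len(levels))
    counts = grp.value_counts()
    if (counts < 2).any():
        raise ValueError(f"need >= 2 samples per group, got {counts.to_dict()}")

    col_idx = [expr.samples.index(s) for s in samples]
    masks = [(grp == g).to_numpy() for g in levels]
    rows = []
    for gi, gene in enumerate(expr.genes):
        vals = expr.values[gi, col_idx]
        reason = "none"
        try:
            p = float(stats.kruskal(*[vals[m] for m in masks]).pvalue)
        except ValueError:  # all values identical
            logger.info("gene %s constant across samples; p undefined", gene)
            p, reason = np.nan, "p_above_threshold"
        selected = bool(p < p_threshold) if np.isfinite(p) else False
        if expr.chromosome(gene) == EXCLUDED_CHROMOSOME:
            selected, reason = False, "chr17"
        elif not selected and reason == "none":
            reason = "p_above_threshold"
        rows.append({"gene": gene, "p": p, "selected": selected,
                     "exclusion_reason": reason})
    frame = pd.DataFrame(rows).set_index("gene")
    logger.info("gene selection: %d of %d genes selected",
                int(frame["selected"].sum()), len(frame))
    return GeneSelectionResult(frame)


@dataclass
class ClusterResult:
    samples: list[str]
    correlation: pd.DataFrame  # sample x sample Pearson r
    linkage_matrix: np.ndarray
    labels: pd.Series  # sample -> cluster id (1..k)
    linkage_method: str
    k: int


def cluster_on_profile(
    expr: ExpressionMatrix,
    selected_genes: list[str],
    *,
    k: int = 4,
    linkage: str = "average",
) -> ClusterResult:
    """Median-centre the selected genes, correlate samples, cluster.

    Distance is 1 - Pearson r on the per-gene median-centred log2 profile;
    the dendrogram is cut into ``k`` flat clusters.
    """
    if len(selected_genes) < 2:
        raise ValueError("need at least 2 selected genes to cluster")
    if len(expr.samples) < k:
        raise ValueError(f"need at least k={k} samples")
    sub = expr.subset_genes(selected_genes)
    centred = _log2(sub.values)
    centred = centred - np.median(centred, axis=1, keepdims=True)
    corr = np.corrcoef(centred.T)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=sub.samples, name="cluster")
    logger.info("clustering: %d samples into %d clusters (%s linkage)",
                len(labels), labels.nunique(), linkage)
    return ClusterResult(
        samples=list(sub.samples),
        correlation=pd.DataFrame(corr, index=sub.samples, columns=sub.samples),
        linkage_matrix=Z,
        labels=labels,
        linkage_method=linkage,
        k=k,
    )


def cluster_enrichment(labels: pd.Series, annotation: pd.Series) -> pd.DataFrame:
    """Per-cluster enrichment of a categorical annotation.

    Binary annotations use a two-sided Fisher exact test on the 2x2
    in-cluster/out-of-cluster table; annotations with more than two levels
    use a chi-square test. A constant annotation yields p = 1 with a
    warning.
    """
    common = labels.index.intersection(annotation.index)
    lab = labels.loc[common]
    ann = annotation.loc[common]
    levels = pd.unique(ann)
    rows = []
    for cluster in sorted(lab.unique()):
        inside = ann[lab == cluster]
        outside = ann[lab != cluster]
        if len(inside) == 0:
            logger.warning("cluster %s empty; skipped", cluster)
            continue
        if len(levels) <= 1:
            logger.warning("annotation constant; enrichment p = 1")
            rows.append({"cluster": cluster, "p": 1.0, "test": "none",
                         "n_in": len(inside), "positives_in": len(inside)})
            continue
        if len(levels) == 2:
            pos = levels[0] if str(levels[0]).lower() in ("true", "1", "positive", "yes") \
                else sorted(map(str, levels))[-1]
            table = [
                [int((inside.astype(str) == str(pos)).sum()),
                 int((inside.astype(str) != str(pos)).sum())],
                [int((outside.astype(str) == str(pos)).sum()),
                 int((outside.astype(str) != str(pos)).sum())],
            ]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
            rows.append({"cluster": cluster, "p": p, "test": "fisher",
                         "n_in": len(inside), "positives_in": table[0][0]})
        else:
            contingency = pd.crosstab(lab == cluster, ann)
            p = float(stats.chi2_contingency(contingency)[1])
            rows.append({"cluster": cluster, "p": p, "test": "chi2",
                         "n_in": len(inside), "positives_in": np.nan})
    return pd.DataFrame(rows).set_index("cluster")


def score_signature(
    expr: ExpressionMatrix, gene_set: list[str], *, name: str = "signature"
) -> pd.Series:
    """Per-sample mean of gene-wise median-centred log2 expression.

    Only genes present in the matrix contribute; coverage is logged and a
    zero intersection is an error naming the missing genes.
    """
    present = [g for g in gene_set if g in expr.genes]
    if not present:
        raise KeyError(
            f"signature {name!r}: none of the genes are in the matrix "
            f"(missing: {sorted(gene_set)[:10]}...)"
        )
    if len(present) < len(gene_set):
        logger.warning("signature %s: %d of %d genes present", name,
                       len(present), len(gene_set))
    sub = expr.subset_genes(present)
    centred = _log2(sub.values)
    centred = centred - np.median(centred, axis=1, keepdims=True)
    return pd.Series(centred.mean(axis=0), index=sub.samples, name=name)


def classify_esr1(
    expr: ExpressionMatrix, *, gene: str = "ESR1", random_state: int = 0
) -> pd.Series:
    """Low/high ESR1 class from a two-component mixture on log2 expression.

    A sample is low iff its value is at or below the density cross-point
    (the mirror of the strict-above rule used for HER2 calling). Degenerate
    or effectively unimodal input is refused.
    """
    values = _log2(expr.row(gene))
    if values.size < 20:
        raise DegenerateInputError("need >= 20 samples to classify ESR1")
    fit = fit_expression_mixture(values, random_state=random_state)
    if fit.cross_point is None or fit.cross_point_fallback:
        raise DegenerateInputError(
            f"{gene} expression looks unimodal; refusing a low/high split"
        )
    return pd.Series(
        np.where(values <= fit.cross_point, "low", "high"),
        index=expr.samples, name=f"{gene.lower()}_class",
    )


META_ER_MAP = {
    ("positive", "low"): "pos_to_low",
    ("positive", "high"): "concordant_pos",
    ("negative", "high"): "neg_to_high",
    ("negative", "low"): "concordant_neg",
}


def meta_er_status(primary_er: pd.Series, esr1_class: pd.Series) -> pd.Series:
    """Combine primary ER label with the metastatic ESR1 class.

    Samples with unknown primary ER are omitted with a log entry.
    """
    common = primary_er.index.intersection(esr1_class.index)
    out = {}
    omitted = 0
    for s in common:
        key = (primary_er[s], esr1_class[s])
        if key not in META_ER_MAP:
            omitted += 1
            continue
        out[s] = META_ER_MAP[key]
    if omitted:
        logger.info("meta-ER status omitted for %d samples with unknown ER", omitted)
    return pd.Series(out, name="meta_er")


def mapk_high(scores: pd.Series) -> pd.Series:
    """High iff the signature score is strictly above the cohort median."""
    if len(scores) < 2:
        raise ValueError("need >= 2 samples")
    return scores > scores.median()
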