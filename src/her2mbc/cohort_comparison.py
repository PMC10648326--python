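"""Descriptive and comparative statistics between cohorts.

Covers tumor mutational burden (TMB, somatic SNV/MNV/indel count per
megabase, with TMB-high defined as strictly more than 10/Mb), the
mutational-signature inclusion filter (keep signatures with at least 10%
contribution in at least 10% of samples), two-group/k-group nonparametric
location tests, per-gene mutation-frequency comparisons between cohorts
with TMB as a covariate, and Hochberg step-up multiple-testing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

#: default genome size in Mb for the TMB denominator (non-N autosomal + sex, hg19)
DEFAULT_GENOME_SIZE_MB = 2859.0

TMB_HIGH_CUTOFF = 10.0  # mutations per Mb, strictly above


@dataclass(frozen=True)
class TmbRecord:
    sample_id: str
    n_variants: int
    genome_size_mb: float
    tmb: float
    tmb_high: bool


def compute_tmb(
    sample_id: str, n_variants: int, genome_size_mb: float = DEFAULT_GENOME_SIZE_MB
) -> TmbRecord:
    """Variants per megabase; TMB-high iff strictly above 10/Mb."""
    if genome_size_mb <= 0:
        raise ValueError(f"genome_size_mb must be > 0, got {genome_size_mb}")
    if n_variants < 0:
        raise ValueError(f"n_variants must be >= 0, got {n_variants}")
    tmb = n_variants / genome_size_mb
    return TmbRecord(sample_id, int(n_variants), float(genome_size_mb), tmb,
                     tmb > TMB_HIGH_CUTOFF)


def signature_inclusion_filter(
    contributions: pd.DataFrame,
    *,
    min_contribution: float = 0.10,
    min_sample_fraction: float = 0.10,
) -> list[str]:
    """Signatures with >= ``min_contribution`` in >= ``min_sample_fraction``
    of samples; both comparisons inclusive.

    ``contributions`` is samples x signatures with fractions in [0, 1].
    """
    if contributions.size == 0:
        raise ValueError("empty contribution matrix")
    vals = contributions.to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("contributions must be fractions in [0, 1]")
    n = len(contributions)
    needed = min_sample_fraction * n
    counts = (vals >= min_contribution).sum(axis=0)
    kept = [s for s, c in zip(contributions.columns, counts) if c + 1e-9 >= needed]
    logger.info("signature filter: kept %d of %d signatures", len(kept),
                contributions.shape[1])
    return kept


def compare_groups_continuous(values, groups) -> tuple[float, float]:
    """Mann-Whitney U for two groups, Kruskal-Wallis for more.

    Returns (statistic, two-sided p). Ties are handled by midranks.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    arrays = [values[groups == g] for g in levels]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    if len(arrays) == 2:
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
    else:
        res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def hochberg_correct(pvalues) -> np.ndarray:
    """Hochberg step-up adjusted p values, returned in input order.

    For sorted p(1) <= ... <= p(n), adj(i) = min over j >= i of
    (n - j + 1) * p(j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    factors = n - np.arange(n)  # (n - j + 1) for 1-based rank j
    scaled = factors * p[order]
    adj_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    adj = np.empty(n)
    adj[order] = adj_sorted
    return adj


def benjamini_hochberg_correct(pvalues) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment (selectable alternative)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GeneFrequencyTest:
    gene: str
    count_a: int
    total_a: int
    count_b: int
    total_b: int
    fisher_p: float
    cohort_coef: float
    coef_ci_low: float
    coef_ci_high: float
    coef_p: float
    fisher_p_adj: float = np.nan
    coef_p_adj: float = np.nan


def gene_frequency_tests(
    mutations: pd.DataFrame,
    cohort_labels: pd.Series,
    tmb: pd.Series,
    *,
    family: str = "linear",
    correction: str = "hochberg",
) -> pd.DataFrame:
    """Per-gene mutation-frequency comparison between two cohorts.

    For each gene: a two-sided Fisher exact test on the 2x2 table, and a
    regression of the 0/1 mutation indicator on cohort membership plus TMB.
    The default family is a linear-probability model (OLS on the indicator,
    so the cohort coefficient is a risk difference); logistic is available.
    The chosen multiple-testing correction is applied across genes to both
    p-value columns and recorded in the output metadata (``df.attrs``).
    """
    if family not in ("linear", "logistic"):
        raise ValueError(f"unknown family {family!r}")
    labels = pd.Series(cohort_labels).astype(str)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two cohorts, got {levels}")
    a, b = levels
    if (labels == a).sum() == 0 or (labels == b).sum() == 0:
        raise ValueError("both cohorts must be non-empty")
    indicator = (labels == b).astype(float)  # effect of cohort b vs a
    tmb = pd.Series(tmb).astype(float).loc[labels.index]

    results: list[GeneFrequencyTest] = []
    for gene in mutations.columns:
        y = mutations[gene].astype(float).loc[labels.index]
        if y.sum() == 0:
            logger.info("gene %s mutated in no sample; skipped", gene)
            continue
        in_a, in_b = y[labels == a], y[labels == b]
        table = [
            [int(in_a.sum()), int(len(in_a) - in_a.sum())],
            [int(in_b.sum()), int(len(in_b) - in_b.sum())],
        ]
        fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])

        X = sm.add_constant(pd.DataFrame({"cohort": indicator, "tmb": tmb}))
        try:
            if family == "linear":
                fit = sm.OLS(y, X).fit()
            else:
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            coef = float(fit.params["cohort"])
            ci = fit.conf_int().loc["cohort"]
            coef_p = float(fit.pvalues["cohort"])
            ci_lo, ci_hi = float(ci[0]), float(ci[1])
        except Exception as exc:  # separation / singular design
            logger.warning("gene %s: regression failed (%s)", gene, exc)
            coef = ci_lo = ci_hi = coef_p = np.nan
        results.append(
            GeneFrequencyTest(
                gene=gene,
                count_a=int(in_a.sum()), total_a=len(in_a),
                count_b=int(in_b.sum()), total_b=len(in_b),
                fisher_p=fisher_p,
                cohort_coef=coef, coef_ci_low=ci_lo, coef_ci_high=ci_hi,
                coef_p=coef_p,
            )
        )
    if not results:
        raise ValueError("no testable genes (none mutated in any sample)")

    df = pd.DataFrame([r.__dict__ for r in results]).set_index("gene")
    correct = {"hochberg": hochberg_correct, "bh": benjamini_hochberg_correct}[correction]
    df["fisher_p_adj"] = correct(df["fisher_p"].to_numpy())
    ok = df["coef_p"].notna()
    df.loc[ok, "coef_p_adj"] = correct(df.loc[ok, "coef_p"].to_numpy())
    df.attrs["correction"] = correction
    df.attrs["family"] = family
    df.attrs["cohort_effect"] = f"{b} vs {a}"
    return df
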