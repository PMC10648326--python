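"""Composite genomic risk score for progression on anti-HER2 therapy.

The predictive core: genomic and clinical items are encoded as categorical
variables, screened one at a time with Cox proportional-hazards regression,
combined by strict forward selection, and the five retained features
(PIK3CA mutation, CDK12 mutation, Amp-peak-6 gain on chr8p11.23, a DBS3
signature contribution above the cohort median, and number of prior therapy
lines) are summed into a single risk score. The binary features each score
1 when present; prior lines score 0.25 / 0.5 / 0.75 / 1 for 0 / 1 / 2-3 /
>= 4 lines. A patient is high risk when the total is at least 2.25.

A three-feature validation mode reproduces the scoring used on targeted
panel data where DBS3 and prior lines are unavailable: a sample is high
risk when any of PIK3CA, CDK12 or Amp-peak-6 is present, with Amp-peak-6
derived from SEG segments overlapping chr8:32280146-47560553 at copy
number strictly greater than 1.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test

from .io_formats import ClinicalRecord, GenomicFeatures, SegmentTable

logger = logging.getLogger(__name__)

RISK_CUTOFF = 2.25  # high risk iff total >= 2.25

#: prior-lines category -> score contribution
PRIOR_LINES_SCORE = {0: 0.25, 1: 0.5, 2: 0.75, 3: 1.0}

AMP_PEAK6_REGION = ("8", 32280146, 47560553)  # GISTIC region limits, chr8p11.23
AMP_PEAK6_CN_THRESHOLD = 1.5  # segment positive iff CN strictly > 1.5


def prior_lines_category(prior_lines: int) -> int:
    """Map a raw prior-line count to the 4-level ordinal: 0, 1, 2-3, >=4."""
    if prior_lines < 0:
        raise ValueError(f"prior_lines must be >= 0, got {prior_lines}")
    if prior_lines == 0:
        return 0
    if prior_lines == 1:
        return 1
    if prior_lines <= 3:
        return 2
    return 3


# ---------------------------------------------------------------------------
# item encoding
# ---------------------------------------------------------------------------

def encode_items(
    features: dict[str, GenomicFeatures],
    clinical: list[ClinicalRecord],
    *,
    signatures: list[str] | None = None,
    her2_calls: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Encode screening items as categorical covariates, one column each.

    Mutated genes and CN-region flags become yes/no indicators; signature
    contributions (restricted to ``signatures``, typically those passing
    the 10%-in-10% inclusion filter) become above/below cohort-median
    indicators with strictly-above counting as 1; continuous counts
    (mutation count, SV count, ploidy) are likewise dichotomised at the
    cohort median; prior therapy lines become the 4-level ordinal; ER and
    HER2 status become binary. Zero-variance items are dropped with a log
    entry.
    """
    clin = {c.sample_id: c for c in clinical}
    samples = [s for s in features if s in clin]
    if not samples:
        raise ValueError("no samples shared between features and clinical tables")

    cols: dict[str, pd.Series] = {}
    all_genes = sorted({g for s in samples for g in features[s].mutated_genes})
    for gene in all_genes:
        cols[f"mut_{gene}"] = pd.Series(
            {s: int(gene in features[s].mutated_genes) for s in samples}
        )
    all_regions = sorted({r for s in samples for r in features[s].cn_region_flags})
    for region in all_regions:
        cols[f"region_{region}"] = pd.Series(
            {s: int(features[s].cn_region_flags.get(region, False)) for s in samples}
        )
    if signatures:
        for sig in signatures:
            vals = pd.Series(
                {s: features[s].signature_contributions.get(sig, np.nan) for s in samples}
            )
            med = vals.median()
            cols[f"sig_{sig}"] = (vals > med).astype(int)  # strict >: at-median is below
    for name, getter in (
        ("n_variants", lambda f: f.n_variants),
        ("n_sv", lambda f: f.n_sv),
        ("ploidy", lambda f: f.ploidy),
    ):
        vals = pd.Series({s: getter(features[s]) for s in samples}, dtype=float)
        cols[f"{name}_above_median"] = (vals > vals.median()).astype(int)
    cols["wgd"] = pd.Series({s: int(features[s].wgd) for s in samples})
    cols["chromothripsis"] = pd.Series(
        {s: int(features[s].chromothripsis) for s in samples}
    )
    cols["er_positive"] = pd.Series(
        {s: int(clin[s].primary_er == "positive") for s in samples}
    )
    if her2_calls is not None:
        cols["her2_positive"] = pd.Series(
            {s: int(her2_calls.get(s) == "positive") for s in samples}
        )
    cols["prior_lines_cat"] = pd.Series(
        {s: prior_lines_category(clin[s].prior_lines) for s in samples}
    )

    df = pd.DataFrame(cols).loc[samples]
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        logger.info("dropping %d zero-variance items: %s", len(constant), constant)
        df = df.drop(columns=constant)
    return df


# ---------------------------------------------------------------------------
# Cox screening and forward selection
# ---------------------------------------------------------------------------

@dataclass
class CoxScreenResult:
    item: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    selected_univariate: bool
    flagged: bool = False
    in_final_model: bool = False


def _fit_cox(df: pd.DataFrame, duration_col: str = "time", event_col: str = "event"):
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph


def univariate_cox_screen(
    items: pd.DataFrame,
    pfs_time: pd.Series,
    pfs_event: pd.Series,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One Cox proportional-hazards fit per item (Efron tie handling).

    Items producing monotone likelihood (complete separation) are flagged
    and excluded from selection. Requires at least 10 events.
    """
    time = pd.Series(pfs_time, dtype=float).loc[items.index]
    event = pd.Series(pfs_event).astype(bool).loc[items.index]
    if event.sum() < 10:
        raise ValueError(f"need >= 10 events for screening, got {int(event.sum())}")

    results: list[CoxScreenResult] = []
    for item in items.columns:
        df = pd.DataFrame({item: items[item].astype(float),
                           "time": time, "event": event.astype(int)})
        try:
            cph = _fit_cox(df)
            hr = float(np.exp(cph.params_[item]))
            ci = np.exp(cph.confidence_intervals_).loc[item]
            p = float(cph.summary.loc[item, "p"])
            results.append(CoxScreenResult(
                item=item, hazard_ratio=hr,
                ci_low=float(ci.iloc[0]), ci_high=float(ci.iloc[1]),
                p=p, selected_univariate=p < alpha,
            ))
        except Exception as exc:  # monotone likelihood / singular design
            logger.warning("item %s: Cox fit failed (%s); flagged", item, exc)
            results.append(CoxScreenResult(
                item=item, hazard_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                p=np.nan, selected_univariate=False, flagged=True,
            ))
    return pd.DataFrame([r.__dict__ for r in results]).set_index("item")


def forward_select(
    screen: pd.DataFrame,
    items: pd.DataFrame,
    pfs_time: pd.Series,
    pfs_event: pd.Series,
    *,
    alpha: float = 0.05,
) -> tuple[list[str], CoxPHFitter | None]:
    """Strict forward selection seeded with the most significant item.

    Remaining univariately significant items are tried in ascending
    univariate-p order; a candidate is kept only if its multivariable Wald
    p stays below ``alpha``. Accepted items are never removed.
    """
    time = pd.Series(pfs_time, dtype=float).loc[items.index]
    event = pd.Series(pfs_event).astype(bool).loc[items.index].astype(int)
    candidates = (
        screen[screen["selected_univariate"] & ~screen["flagged"]]
        .sort_values("p").index.tolist()
    )
    if not candidates:
        raise ValueError("no univariately significant items to select from")

    selected = [candidates[0]]
    model = None
    for cand in candidates[1:]:
        trial = selected + [cand]
        df = items[trial].astype(float).assign(time=time, event=event)
        try:
            cph = _fit_cox(df)
        except (ConvergenceError, ConvergenceWarning) as exc:
            logger.warning("candidate %s: joint fit failed (%s); skipped", cand, exc)
            continue
        if float(cph.summary.loc[cand, "p"]) < alpha:
            selected.append(cand)
            model = cph
    if model is None or list(model.params_.index) != selected:
        df = items[selected].astype(float).assign(time=time, event=event)
        model = _fit_cox(df)
    logger.info("forward selection retained %d items: %s", len(selected), selected)
    return selected, model


# ---------------------------------------------------------------------------
# the composite risk score
# ---------------------------------------------------------------------------

@dataclass
class RiskScoreResult:
    sample_id: str
    components: dict[str, float] = field(default_factory=dict)
    total: float = 0.0
    label: str = "low"  # "high" | "low"
    mode: str = "full_5feature"  # | "validation_3feature"


def compute_risk_score(
    sample_id: str,
    pik3ca: bool,
    cdk12: bool,
    amp_peak6: bool,
    dbs3_above_median: bool,
    prior_lines: int,
) -> RiskScoreResult:
    """Full five-feature score: binary features score 1 when present,
    prior lines score 0.25/0.5/0.75/1, high risk iff total >= 2.25."""
    components = {
        "pik3ca": float(bool(pik3ca)),
        "cdk12": float(bool(cdk12)),
        "amp_peak6": float(bool(amp_peak6)),
        "dbs3": float(bool(dbs3_above_median)),
        "prior_lines": PRIOR_LINES_SCORE[prior_lines_category(prior_lines)],
    }
    total = sum(components.values())
    return RiskScoreResult(
        sample_id=sample_id,
        components=components,
        total=total,
        label="high" if total >= RISK_CUTOFF else "low",
        mode="full_5feature",
    )


def validation_mode_score(
    sample_id: str, pik3ca: bool, cdk12: bool, amp_peak6: bool
) -> RiskScoreResult:
    """Three-feature validation scorer: high risk iff any feature present.

    The three events were mutually exclusive in the validation cohort this
    rule was designed for; co-occurrence is allowed but logged.
    """
    present = [bool(pik3ca), bool(cdk12), bool(amp_peak6)]
    if sum(present) > 1:
        logger.warning(
            "sample %s: multiple validation features present; the 3-feature "
            "rule assumes mutual exclusivity", sample_id,
        )
    return RiskScoreResult(
        sample_id=sample_id,
        components={"pik3ca": float(present[0]), "cdk12": float(present[1]),
                    "amp_peak6": float(present[2])},
        total=float(sum(present)),
        label="high" if any(present) else "low",
        mode="validation_3feature",
    )


def amp_peak6_validation(
    segments: SegmentTable,
    *,
    region: tuple[str, int, int] = AMP_PEAK6_REGION,
    threshold: float = AMP_PEAK6_CN_THRESHOLD,
    samples: list[str] | None = None,
) -> dict[str, bool]:
    """Amp-peak-6 positivity from SEG input.

    A sample is positive iff it has at least one segment overlapping the
    region (closed intervals, >= 1 bp overlap) with value strictly greater
    than the threshold. Samples with no qualifying segment — including
    samples with no chr8 segments at all — are negative.
    """
    chrom, start, end = region
    df = segments.frame
    hit = df[
        (df["chrom"] == str(chrom))
        & (df["start"] <= end)
        & (df["end"] >= start)
        & (df["value"] > threshold)
    ]
    positives = set(hit["sample_id"])
    universe = samples if samples is not None else list(pd.unique(df["sample_id"]))
    return {s: s in positives for s in universe}


def score_cohort(
    features: dict[str, GenomicFeatures],
    clinical: list[ClinicalRecord],
    *,
    dbs3_signature: str = "DBS3",
    amp_peak6_region_name: str = "Amp-peak-6",
    dbs3_reference: pd.Series | None = None,
) -> pd.DataFrame:
    """Apply the full five-feature score to a cohort.

    The DBS3 median is computed over the cohort being scored unless an
    explicit reference distribution of contributions is supplied.
    """
    clin = {c.sample_id: c for c in clinical}
    samples = [s for s in features if s in clin]
    contrib = pd.Series(
        {s: features[s].signature_contributions.get(dbs3_signature, np.nan)
         for s in samples}
    )
    median = (dbs3_reference.median() if dbs3_reference is not None
              else contrib.median())
    rows = []
    for s in samples:
        res = compute_risk_score(
            s,
            pik3ca="PIK3CA" in features[s].mutated_genes,
            cdk12="CDK12" in features[s].mutated_genes,
            amp_peak6=features[s].cn_region_flags.get(amp_peak6_region_name, False),
            dbs3_above_median=bool(contrib[s] > median),
            prior_lines=clin[s].prior_lines,
        )
        rows.append({"sample_id": s, **res.components,
                     "total": res.total, "label": res.label, "mode": res.mode})
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# survival evaluation
# ---------------------------------------------------------------------------

@dataclass
class KmResult:
    curves: dict[str, pd.DataFrame]  # group -> survival table
    statistic: float
    p: float


def product_limit(pfs_time, pfs_event) -> pd.Series:
    """Kaplan-Meier product-limit survival estimate for one group."""
    kmf = KaplanMeierFitter()
    kmf.fit(pd.Series(pfs_time, dtype=float), event_observed=pd.Series(pfs_event).astype(bool))
    return kmf.survival_function_.iloc[:, 0].rename("survival")


def km_logrank(groups, pfs_time, pfs_event) -> KmResult:
    """Product-limit curves per group plus the two-sided log-rank test."""
    groups = pd.Series(groups).astype(str)
    time = pd.Series(pfs_time, dtype=float)
    event = pd.Series(pfs_event).astype(bool)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("log-rank comparison needs at least two groups")
    if event.sum() < 1:
        raise ValueError("need at least one event")

    curves: dict[str, pd.DataFrame] = {}
    for g in levels:
        mask = (groups == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask], label=g)
        curves[g] = kmf.survival_function_.rename(columns={g: "survival"})
    test = multivariate_logrank_test(time, groups, event)
    return KmResult(curves=curves, statistic=float(test.test_statistic),
                    p=float(test.p_value))
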