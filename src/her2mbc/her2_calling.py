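"""Two-stage HER2 status assignment.

ERBB2 amplification is called in two stages. First, log2 ERBB2 expression of
the samples with RNA-seq is fit with a two-component Gaussian mixture; the
cross-point of the weighted component densities (the expression value where
the two curves intersect between the component means) yields an intermediate
high/low call. Second, that intermediate call is used as the reference label
in an ROC analysis against the absolute ERBB2 copy number of the same
samples, and the copy-number threshold maximising Youden's J is transferred
to the whole cohort — including samples without RNA-seq. A sample is HER2+
iff its copy number is strictly above the threshold.

The ROC optimum criterion is Youden's J (sensitivity + specificity - 1) by
default; distance to the (0, 1) corner is available as an alternative and
the choice is recorded on the result.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .io_formats import ExpressionMatrix, GenomicFeatures

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Input has no usable structure (constant values, too few points)."""


class OrientationError(ValueError):
    """The marker is anti-informative for the given labels."""


@dataclass
class MixtureFit:
    """Two-component 1-D Gaussian mixture, components ordered by mean."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    cross_point: float | None
    converged: bool
    log_likelihood: float
    cross_point_fallback: bool = False

    def __post_init__(self) -> None:
        w1, w2 = self.weights
        if not (0 < w1 < 1 and 0 < w2 < 1 and abs(w1 + w2 - 1) < 1e-9):
            raise ValueError(f"weights must be in (0,1) and sum to 1, got {self.weights}")


@dataclass
class RocResult:
    """Full candidate-threshold grid with the chosen operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    threshold: float
    chosen_sensitivity: float
    chosen_specificity: float
    criterion: str = "youden"

    @property
    def youden(self) -> float:
        return self.chosen_sensitivity + self.chosen_specificity - 1.0


@dataclass
class Her2Call:
    sample_id: str
    erbb2_cn: float
    call: str  # "positive" | "negative"
    provenance: str  # "roc_threshold" | "user_threshold"


def fit_expression_mixture(
    values: np.ndarray,
    *,
    n_init: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    random_state: int = 0,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture to log2 expression values by EM.

    Requires at least 20 finite values with non-zero variance. The
    cross-point is the root of ``w1 N(x; m1, s1) = w2 N(x; m2, s2)`` between
    the ordered means, found by bisection; when no root exists between the
    means (extreme weights) the midpoint of the means is used instead and
    the fit is flagged ``cross_point_fallback``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise DegenerateInputError(
            f"need >= 20 finite values for a mixture fit, got {x.size}"
        )
    if np.ptp(x) == 0 or np.std(x) == 0:
        raise DegenerateInputError("constant input; no mixture structure to fit")

    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_init,
        tol=tol,
        max_iter=max_iter,
        random_state=random_state,
    ).fit(x.reshape(-1, 1))

    order = np.argsort(gm.means_.ravel())
    means = tuple(float(m) for m in gm.means_.ravel()[order])
    sds = tuple(float(math.sqrt(c)) for c in gm.covariances_.ravel()[order])
    weights = tuple(float(w) for w in gm.weights_[order])
    ll = float(gm.score(x.reshape(-1, 1)) * x.size)

    if not gm.converged_:
        logger.warning("mixture EM did not converge after %d restarts", n_init)
        return MixtureFit(means, sds, weights, None, False, ll)

    cross, fallback = _cross_point(means, sds, weights)
    return MixtureFit(means, sds, weights, cross, True, ll, cross_point_fallback=fallback)


def _cross_point(means, sds, weights) -> tuple[float, bool]:
    m1, m2 = means
    s1, s2 = sds
    w1, w2 = weights

    def diff(x: float) -> float:
        return w1 * norm.pdf(x, m1, s1) - w2 * norm.pdf(x, m2, s2)

    lo, hi = m1, m2
    if diff(lo) * diff(hi) > 0:
        logger.warning(
            "no density crossing between component means; using midpoint fallback"
        )
        return 0.5 * (m1 + m2), True
    return float(brentq(diff, lo, hi, xtol=1e-12)), False


def intermediate_call(values: np.ndarray, fit: MixtureFit) -> np.ndarray:
    """Boolean high/low call per value: high iff strictly above cross-point."""
    if not fit.converged or fit.cross_point is None:
        raise ValueError("refusing intermediate call from an unconverged mixture fit")
    return np.asarray(values, dtype=float) > fit.cross_point


def _scan(labels: np.ndarray, cn: np.ndarray):
    """Sensitivity/specificity of 'cn > t' over candidate thresholds t."""
    uniq = np.unique(cn)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    pos, neg = cn[labels], cn[~labels]
    sens = np.array([np.mean(pos > t) for t in thresholds])
    spec = np.array([np.mean(neg <= t) for t in thresholds])
    return thresholds, sens, spec


def derive_cn_threshold(
    labels: np.ndarray, cn: np.ndarray, *, criterion: str = "youden"
) -> RocResult:
    """Transfer the intermediate high/low labels to a copy-number threshold.

    Candidate thresholds are the midpoints between consecutive sorted unique
    copy-number values plus -inf/+inf sentinels. The chosen threshold
    maximises Youden's J (default) or minimises distance to the (0, 1) ROC
    corner; ties are broken toward the larger threshold so positive calls
    are conservative. Anti-informative orientation (high-labelled samples
    with *lower* copy number) is detected and refused.
    """
    labels = np.asarray(labels, dtype=bool)
    cn = np.asarray(cn, dtype=float)
    if labels.shape != cn.shape:
        raise ValueError("labels and cn must be aligned")
    if labels.all() or (~labels).all():
        raise ValueError("both label classes must be non-empty")
    if criterion not in ("youden", "corner"):
        raise ValueError(f"unknown criterion {criterion!r}")

    thresholds, sens, spec = _scan(labels, cn)
    j = sens + spec - 1.0
    if j.max() <= (-j).max():
        raise OrientationError(
            "marker is anti-informative for these labels (high class has "
            "lower copy number); refusing to derive a threshold"
        )
    if criterion == "youden":
        score = j
    else:
        score = -np.hypot(1.0 - sens, 1.0 - spec)
    # argmax with ties broken toward the larger threshold
    best = np.flatnonzero(score >= score.max() - 1e-12)[-1]
    logger.info(
        "ROC threshold %.6g (criterion=%s, sens=%.4f, spec=%.4f)",
        thresholds[best], criterion, sens[best], spec[best],
    )
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        threshold=float(thresholds[best]),
        chosen_sensitivity=float(sens[best]),
        chosen_specificity=float(spec[best]),
        criterion=criterion,
    )


def call_her2(
    sample_id: str, cn: float, threshold: float, *, provenance: str = "roc_threshold"
) -> Her2Call:
    """HER2+ iff copy number strictly exceeds the threshold."""
    if not (np.isfinite(cn) and np.isfinite(threshold)):
        raise ValueError(f"non-finite copy number or threshold for {sample_id}")
    call = "positive" if cn > threshold else "negative"
    return Her2Call(sample_id=sample_id, erbb2_cn=float(cn), call=call,
                    provenance=provenance)


@dataclass
class CohortHer2Result:
    calls: dict[str, Her2Call]
    mixture: MixtureFit | None
    roc: RocResult | None
    threshold: float
    expression_gene: str = "ERBB2"
    intermediate_high: dict[str, bool] = field(default_factory=dict)

    def positive_samples(self) -> list[str]:
        return [s for s, c in self.calls.items() if c.call == "positive"]


def assign_cohort_her2(
    expr: ExpressionMatrix | None,
    features: dict[str, GenomicFeatures],
    *,
    gene: str = "ERBB2",
    threshold: float | None = None,
    criterion: str = "youden",
    mixture_random_state: int = 0,
) -> CohortHer2Result:
    """Run the full two-stage assignment over a cohort.

    Samples lacking expression still receive a copy-number call once the
    threshold is derived from the overlap samples. A user-supplied
    ``threshold`` bypasses both the mixture and ROC stages; calls are then
    marked ``user_threshold``.
    """
    if threshold is not None:
        calls = {
            s: call_her2(s, f.erbb2_cn, threshold, provenance="user_threshold")
            for s, f in features.items()
        }
        return CohortHer2Result(calls=calls, mixture=None, roc=None,
                                threshold=float(threshold))

    if expr is None:
        raise ValueError("threshold underivable: no expression matrix supplied")
    try:
        log2_expr = np.log2(expr.row(gene) + 1.0)
    except KeyError:
        raise ValueError(f"threshold underivable: gene {gene!r} absent from expression")

    overlap = [s for s in expr.samples if s in features]
    if len(overlap) < 20:
        raise ValueError(
            f"need >= 20 samples with both expression and copy number, got {len(overlap)}"
        )
    idx = [expr.samples.index(s) for s in overlap]
    values = log2_expr[idx]
    cn = np.array([features[s].erbb2_cn for s in overlap])

    fit = fit_expression_mixture(values, random_state=mixture_random_state)
    high = intermediate_call(values, fit)
    if high.all() or (~high).all():
        raise ValueError("intermediate call produced a single class; cannot run ROC")
    roc = derive_cn_threshold(high, cn, criterion=criterion)

    calls = {
        s: call_her2(s, f.erbb2_cn, roc.threshold) for s, f in features.items()
    }
    return CohortHer2Result(
        calls=calls,
        mixture=fit,
        roc=roc,
        threshold=roc.threshold,
        expression_gene=gene,
        intermediate_high=dict(zip(overlap, (bool(h) for h in high))),
    )
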