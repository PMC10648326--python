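"""Synthetic metastatic breast cancer cohorts with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so that every stage of the pipeline can be exercised end to end
without access-restricted patient data:

* ERBB2 copy number is a two-component log-normal mixture (amplified vs
  non-amplified) and log2 ERBB2 expression is bimodal conditional on the
  amplification truth;
* per-gene mutation flags are Bernoulli at published cohort prevalences
  (PIK3CA 39%, CDK12 13%), signature contributions are Dirichlet within
  each class with the DBS3 concentration elevated in a designated high
  fraction (12%), and Amp-peak-6 is present in 35% of samples;
* progression-free survival is exponential under a proportional-hazards
  model driven by the five risk features with hazard ratios 5.53 (PIK3CA),
  3.47 (CDK12), 18.07 (DBS3-high), 3.91 (Amp-peak-6) and 1.43 per
  prior-lines category, with independent exponential censoring;
* the expression matrix plants four-group (HER2 x prior anti-HER2) effects
  on a subset of genes, chromosome 17 passenger effects in amplified
  samples only, and MAPK / ESR1-module gene-set structure tied to an ER
  pos-to-low switching fraction (11.5% of primary-ER+ samples).

All randomness flows from one integer seed through a single NumPy
Generator, so identical parameters give bit-identical cohorts.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ClinicalRecord,
    ExpressionMatrix,
    GenomicFeatures,
    SegmentTable,
    features_frame,
    write_clinical,
    write_expression,
    write_seg,
)
from .risk_model import PRIOR_LINES_SCORE, compute_risk_score

AMP_PEAK6_REGION = ("8", 32280146, 47560553)

#: signatures simulated per class (Dirichlet within class)
SIGNATURE_SETS = {
    "SBS": ["SBS1", "SBS2", "SBS3", "SBS5", "SBS13", "SBS18"],
    "DBS": ["DBS2", "DBS3", "DBS11"],
    "ID": ["ID1", "ID2", "ID8"],
    "SV": ["SV3", "SV5", "SV6"],
}

_DIRICHLET_ALPHA = {
    "SBS": np.array([2.0, 1.0, 1.0, 2.0, 0.8, 0.6]),
    "DBS": np.array([1.5, 0.4, 1.1]),  # DBS3 second; low baseline concentration
    "ID": np.array([1.5, 1.0, 0.8]),
    "SV": np.array([1.0, 1.0, 1.0]),
}
_DBS3_HIGH_ALPHA = 8.0  # DBS3 concentration for designated high samples


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults are the published study conditions
    where stated, otherwise values typical for WGS-profiled MBC cohorts."""

    n_samples: int = 700
    frac_amplified: float = 0.10
    cn_background: tuple[float, float] = (1.10, 0.25)  # mean, sd of log2 CN
    cn_amplified: tuple[float, float] = (4.50, 0.55)
    expr_mixture: tuple[float, float, float] = (5.0, 10.0, 1.0)  # low, high, sd (log2)
    mutation_prevalence: dict[str, float] = field(
        default_factory=lambda: {"PIK3CA": 0.39, "CDK12": 0.13, "TP53": 0.63}
    )
    dbs3_high_frac: float = 0.12
    amp_peak6_frac: float = 0.35
    prior_lines_probs: tuple[float, ...] = (0.26, 0.36, 0.19, 0.19)
    log_hazard_ratios: dict[str, float] = field(
        default_factory=lambda: {
            "PIK3CA": math.log(5.53),
            "CDK12": math.log(3.47),
            "DBS3": math.log(18.07),
            "amp_peak6": math.log(3.91),
            "prior_lines": math.log(1.43),  # per ordinal category step
        }
    )
    baseline_hazard: float = math.log(2) / 300.0  # events/day; median 300 d at baseline
    # events/day, solved so E[c/(c+h)] = 0.20 at the default feature mix
    censoring_rate: float = 2.7765e-3
    n_profile_genes: int = 1000  # null background genes
    effect_genes: int = 100  # planted 4-group effect genes (25 per group)
    chr17_passenger_genes: int = 30
    n_signature_genes: int = 25  # per planted MAPK / ESR1-module set
    effect_size: float = 3.0  # group shift in units of the noise sd
    noise_sd: float = 1.0
    pos_to_low_frac: float = 0.115
    er_positive_frac: float = 0.81
    prior_anti_her2_probs: tuple[float, float] = (0.60, 0.15)  # P(prior | HER2+/-)
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = [self.frac_amplified, self.dbs3_high_frac, self.amp_peak6_frac,
                     self.pos_to_low_frac, self.er_positive_frac,
                     *self.prior_anti_her2_probs, *self.mutation_prevalence.values()]
        if any(not 0.0 <= f <= 1.0 for f in fractions):
            raise ValueError("all fractions must lie in [0, 1]")
        if abs(sum(self.prior_lines_probs) - 1.0) > 1e-9:
            raise ValueError("prior_lines_probs must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth per sample plus the planted gene structure."""

    table: pd.DataFrame  # indexed by sample_id
    effect_genes: dict[str, list[str]]  # group label -> planted genes
    chr17_passengers: list[str]
    mapk_genes: list[str]
    esr1_module_genes: list[str]
    cn_boundary: tuple[float, float]  # background 99th / amplified 1st pct (CN units)


@dataclass
class CohortBundle:
    clinical: list[ClinicalRecord]
    features: dict[str, GenomicFeatures]
    expression: ExpressionMatrix
    segments: SegmentTable
    truth: SyntheticTruth
    params: SimulationParams


GROUP_OF = {
    (True, True): "HER2+/prior",
    (True, False): "HER2+/naive",
    (False, True): "HER2-/prior",
    (False, False): "HER2-/naive",
}


def simulate_risk_cohort(
    n_samples: int,
    seed: int,
    *,
    params: SimulationParams | None = None,
) -> pd.DataFrame:
    """Feature-level survival cohort for risk-score studies.

    Draws only the five risk features and the exponential PFS/censoring
    times under the proportional-hazards model — the minimal cohort needed
    to study the score's Kaplan-Meier separation.
    """
    p = params or SimulationParams()
    rng = np.random.default_rng(seed)
    pik3ca = rng.random(n_samples) < p.mutation_prevalence.get("PIK3CA", 0.39)
    cdk12 = rng.random(n_samples) < p.mutation_prevalence.get("CDK12", 0.13)
    dbs3 = rng.random(n_samples) < p.dbs3_high_frac
    amp6 = rng.random(n_samples) < p.amp_peak6_frac
    lines_cat = rng.choice(len(p.prior_lines_probs), size=n_samples,
                           p=p.prior_lines_probs)
    time, event = _simulate_survival(rng, p, pik3ca, cdk12, dbs3, amp6, lines_cat)
    return pd.DataFrame({
        "pik3ca": pik3ca, "cdk12": cdk12, "dbs3": dbs3, "amp_peak6": amp6,
        "prior_lines_cat": lines_cat, "time": time, "event": event,
    })


def _hazard(p: SimulationParams, pik3ca, cdk12, dbs3, amp6, lines_cat) -> np.ndarray:
    lhr = p.log_hazard_ratios
    eta = (
        lhr["PIK3CA"] * pik3ca.astype(float)
        + lhr["CDK12"] * cdk12.astype(float)
        + lhr["DBS3"] * dbs3.astype(float)
        + lhr["amp_peak6"] * amp6.astype(float)
        + lhr["prior_lines"] * lines_cat.astype(float)
    )
    return p.baseline_hazard * np.exp(eta)


def _simulate_survival(rng, p, pik3ca, cdk12, dbs3, amp6, lines_cat):
    hazard = _hazard(p, pik3ca, cdk12, dbs3, amp6, lines_cat)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.exponential(1.0 / p.censoring_rate, size=hazard.size)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    time = np.maximum(np.ceil(time), 1.0)  # whole days, at least one
    return time, event


def expected_censoring_fraction(params: SimulationParams | None = None) -> float:
    """Analytic P(censored) = E[c / (c + h)] over the feature distribution.

    Exact enumeration of the 2^4 x 4 lattice of feature combinations with
    their Bernoulli/categorical probabilities.
    """
    p = params or SimulationParams()
    prev = [
        p.mutation_prevalence.get("PIK3CA", 0.39),
        p.mutation_prevalence.get("CDK12", 0.13),
        p.dbs3_high_frac,
        p.amp_peak6_frac,
    ]
    total = 0.0
    for combo in itertools.product([0, 1], repeat=4):
        prob = math.prod(q if on else 1 - q for on, q in zip(combo, prev))
        for cat, cat_p in enumerate(p.prior_lines_probs):
            h = _hazard(
                p,
                np.array([combo[0]]), np.array([combo[1]]),
                np.array([combo[2]]), np.array([combo[3]]),
                np.array([cat]),
            )[0]
            total += prob * cat_p * p.censoring_rate / (p.censoring_rate + h)
    return total


def simulate_cohort(params: SimulationParams | None = None) -> CohortBundle:
    """Generate a complete cohort: clinical, genomic features, expression,
    SEG segments and the ground-truth table. Deterministic given the seed."""
    p = params or SimulationParams()
    n = p.n_samples
    if n < 10:
        raise ValueError(f"n_samples must be >= 10, got {n}")
    rng = np.random.default_rng(p.seed)
    samples = [f"S{i + 1:04d}" for i in range(n)]

    # --- HER2 truth, copy number, ERBB2 expression -------------------------
    amplified = rng.random(n) < p.frac_amplified
    log2_cn = np.where(
        amplified,
        rng.normal(p.cn_amplified[0], p.cn_amplified[1], size=n),
        rng.normal(p.cn_background[0], p.cn_background[1], size=n),
    )
    erbb2_cn = 2.0 ** log2_cn
    lo_mean, hi_mean, expr_sd = p.expr_mixture
    erbb2_log2 = np.where(
        amplified,
        rng.normal(hi_mean, expr_sd, size=n),
        rng.normal(lo_mean, expr_sd, size=n),
    )
    z_bg = 2.326347874  # 99th percentile of the standard normal
    cn_boundary = (
        2.0 ** (p.cn_background[0] + z_bg * p.cn_background[1]),
        2.0 ** (p.cn_amplified[0] - z_bg * p.cn_amplified[1]),
    )

    # --- therapy history and clinical table --------------------------------
    prior_probs = np.where(amplified, *p.prior_anti_her2_probs)
    prior_aht = rng.random(n) < prior_probs
    lines_cat = rng.choice(len(p.prior_lines_probs), size=n, p=p.prior_lines_probs)
    lines_actual = np.select(
        [lines_cat == 0, lines_cat == 1, lines_cat == 2],
        [0, 1, rng.integers(2, 4, size=n)],
        default=rng.integers(4, 7, size=n),
    )
    er_positive = rng.random(n) < p.er_positive_frac

    # --- mutations, signatures, regions ------------------------------------
    mutations = pd.DataFrame(
        {g: rng.random(n) < q for g, q in p.mutation_prevalence.items()},
        index=samples,
    )
    dbs3_high = rng.random(n) < p.dbs3_high_frac
    amp6 = rng.random(n) < p.amp_peak6_frac
    sig_columns: dict[str, np.ndarray] = {}
    for cls, names in SIGNATURE_SETS.items():
        alpha = _DIRICHLET_ALPHA[cls]
        draws = rng.dirichlet(alpha, size=n)
        if cls == "DBS":
            hi_alpha = alpha.copy()
            hi_alpha[names.index("DBS3")] = _DBS3_HIGH_ALPHA
            hi_draws = rng.dirichlet(hi_alpha, size=n)
            draws = np.where(dbs3_high[:, None], hi_draws, draws)
        for j, name in enumerate(names):
            sig_columns[name] = draws[:, j]
    signatures = pd.DataFrame(sig_columns, index=samples)

    n_variants = np.rint(rng.lognormal(math.log(9000), 0.7, size=n)).astype(int)
    n_sv = np.rint(rng.lognormal(math.log(550), 0.8, size=n)).astype(int)
    ploidy = np.clip(rng.normal(3.1, 0.6, size=n), 1.2, None)
    wgd = ploidy > 3.4
    chromothripsis = rng.random(n) < 0.30

    # --- survival ------------------------------------------------------------
    time, event = _simulate_survival(
        rng, p, mutations["PIK3CA"].to_numpy(), mutations["CDK12"].to_numpy(),
        dbs3_high, amp6, lines_cat,
    )

    # --- ER / ESR1 / MAPK truth ---------------------------------------------
    # primary-ER+ samples switch to low metastatic ESR1 with pos_to_low_frac;
    # primary-ER- samples are mostly concordant low, a small tail re-expresses.
    esr1_high = np.where(
        er_positive,
        rng.random(n) >= p.pos_to_low_frac,
        rng.random(n) < 0.10,
    )
    meta_er = np.select(
        [er_positive & ~esr1_high, er_positive & esr1_high,
         ~er_positive & esr1_high],
        ["pos_to_low", "concordant_pos", "neg_to_high"],
        default="concordant_neg",
    )
    mapk_shifted = er_positive & ~esr1_high  # pos-to-low cases upregulate MAPK

    # --- expression matrix ----------------------------------------------------
    autosomes = [str(c) for c in range(1, 23) if c != 17] + ["X"]
    gene_names: list[str] = []
    gene_chrom: dict[str, str] = {}
    blocks: list[np.ndarray] = []

    def add_gene(name: str, chrom: str, values: np.ndarray) -> None:
        gene_names.append(name)
        gene_chrom[name] = chrom
        blocks.append(values)

    noise = lambda: rng.normal(0.0, p.noise_sd, size=n)  # noqa: E731
    baseline = lambda: rng.uniform(4.0, 9.0)  # noqa: E731

    for i in range(p.n_profile_genes):
        add_gene(f"GENE{i + 1:05d}", autosomes[i % len(autosomes)],
                 baseline() + noise())

    group_idx = np.array(
        [list(GROUP_OF.values()).index(GROUP_OF[(bool(a), bool(t))])
         for a, t in zip(amplified, prior_aht)]
    )
    effect_genes: dict[str, list[str]] = {g: [] for g in GROUP_OF.values()}
    per_group = max(1, p.effect_genes // 4)
    for gi, group in enumerate(GROUP_OF.values()):
        for j in range(per_group):
            name = f"EFF{gi + 1}_{j + 1:03d}"
            shift = np.where(group_idx == gi, p.effect_size * p.noise_sd, 0.0)
            add_gene(name, autosomes[(gi * per_group + j) % len(autosomes)],
                     baseline() + shift + noise())
            effect_genes[group].append(name)

    chr17_passengers = []
    for j in range(p.chr17_passenger_genes):
        name = f"CH17_{j + 1:03d}"
        shift = np.where(amplified, p.effect_size * p.noise_sd, 0.0)
        add_gene(name, "17", baseline() + shift + noise())
        chr17_passengers.append(name)

    mapk_genes, esr1_module = [], []
    for j in range(p.n_signature_genes):
        name = f"MAPKG{j + 1:03d}"
        add_gene(name, autosomes[j % len(autosomes)],
                 baseline() + np.where(mapk_shifted, 1.5 * p.noise_sd, 0.0) + noise())
        mapk_genes.append(name)
    for j in range(p.n_signature_genes):
        name = f"ESR1M{j + 1:03d}"
        add_gene(name, autosomes[(j + 7) % len(autosomes)],
                 baseline() + np.where(esr1_high, 1.5 * p.noise_sd, 0.0) + noise())
        esr1_module.append(name)

    add_gene("ESR1", "6", np.where(esr1_high,
                                   rng.normal(8.0, 0.8, size=n),
                                   rng.normal(3.0, 0.8, size=n)))
    add_gene("ERBB2", "17", erbb2_log2)

    log2_matrix = np.vstack(blocks)
    expression = ExpressionMatrix(
        genes=gene_names,
        samples=list(samples),
        values=np.maximum(2.0 ** log2_matrix - 1.0, 0.0),
        gene_chrom=gene_chrom,
    )

    # --- SEG segments ----------------------------------------------------------
    chrom8_start, chrom8_end = AMP_PEAK6_REGION[1], AMP_PEAK6_REGION[2]
    seg_rows = []
    for i, s in enumerate(samples):
        # background segments: chr8 outside the peak region, one other chrom
        seg_rows.append((s, "8", 10_000_000, 20_000_000,
                         round(float(rng.normal(1.0, 0.15)), 4)))
        seg_rows.append((s, "5", 1_000_000, 50_000_000,
                         round(float(rng.normal(1.0, 0.15)), 4)))
        if amp6[i]:
            start = int(rng.integers(chrom8_start, chrom8_end - 2_000_000))
            seg_rows.append((s, "8", start, start + 2_000_000,
                             round(1.6 + float(rng.exponential(1.0)), 4)))
        elif rng.random() < 0.3:  # neutral segment inside the region
            start = int(rng.integers(chrom8_start, chrom8_end - 1_000_000))
            seg_rows.append((s, "8", start, start + 1_000_000,
                             round(float(rng.uniform(0.7, 1.4)), 4)))
    segments = SegmentTable(pd.DataFrame(
        seg_rows, columns=list(SegmentTable.COLUMNS)
    ))

    # --- assemble objects -------------------------------------------------------
    clinical = [
        ClinicalRecord(
            sample_id=s,
            primary_er="positive" if er_positive[i] else "negative",
            biopsy_site=str(rng.choice(["liver", "lymph_node", "bone", "other"],
                                       p=[0.45, 0.20, 0.12, 0.23])),
            prior_anti_her2=bool(prior_aht[i]),
            prior_lines=int(lines_actual[i]),
            post_biopsy_anti_her2=True,
            pfs_time=float(time[i]),
            pfs_event=bool(event[i]),
        )
        for i, s in enumerate(samples)
    ]
    features = {
        s: GenomicFeatures(
            sample_id=s,
            mutated_genes=set(mutations.columns[mutations.loc[s]]),
            signature_contributions=signatures.loc[s].to_dict(),
            n_variants=int(n_variants[i]),
            n_sv=int(n_sv[i]),
            erbb2_cn=float(erbb2_cn[i]),
            ploidy=float(ploidy[i]),
            wgd=bool(wgd[i]),
            chromothripsis=bool(chromothripsis[i]),
            cn_region_flags={"Amp-peak-6": bool(amp6[i])},
        )
        for i, s in enumerate(samples)
    }

    risk = [
        compute_risk_score(
            s,
            pik3ca=bool(mutations.loc[s, "PIK3CA"]),
            cdk12=bool(mutations.loc[s, "CDK12"]),
            amp_peak6=bool(amp6[i]),
            dbs3_above_median=bool(dbs3_high[i]),
            prior_lines=int(lines_actual[i]),
        )
        for i, s in enumerate(samples)
    ]
    truth_table = pd.DataFrame({
        "her2_amplified": amplified,
        "group": [GROUP_OF[(bool(a), bool(t))] for a, t in zip(amplified, prior_aht)],
        "dbs3_high": dbs3_high,
        "amp_peak6": amp6,
        "prior_lines_cat": lines_cat,
        "risk_total": [r.total for r in risk],
        "risk_group": [r.label for r in risk],
        "esr1_high": esr1_high,
        "meta_er": meta_er,
        "mapk_shifted": mapk_shifted,
    }, index=pd.Index(samples, name="sample_id"))

    truth = SyntheticTruth(
        table=truth_table,
        effect_genes=effect_genes,
        chr17_passengers=chr17_passengers,
        mapk_genes=mapk_genes,
        esr1_module_genes=esr1_module,
        cn_boundary=cn_boundary,
    )
    return CohortBundle(clinical=clinical, features=features, expression=expression,
                        segments=segments, truth=truth, params=p)


def write_cohort(bundle: CohortBundle, directory: str | Path) -> dict[str, Path]:
    """Write the analysis inputs under ``<dir>/inputs`` and the ground truth
    beside them, so the input set can be consumed blind to the truth."""
    directory = Path(directory)
    inputs = directory / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    paths = {
        "clinical": inputs / "clinical.tsv",
        "features": inputs / "features.tsv",
        "mutations": inputs / "mutations.tsv",
        "signatures": inputs / "signatures.tsv",
        "expression": inputs / "expression.tsv",
        "annotation": inputs / "gene_annotation.tsv",
        "segments": inputs / "segments.seg",
        "truth": directory / "truth.tsv",
        "truth_genes": directory / "truth_genes.json",
        "params": directory / "params.json",
    }
    write_clinical(bundle.clinical, paths["clinical"])
    features_frame(bundle.features).to_csv(paths["features"], sep="\t")
    muts = pd.DataFrame(
        {g: [int(g in bundle.features[s].mutated_genes) for s in bundle.features]
         for g in sorted({m for f in bundle.features.values() for m in f.mutated_genes})},
        index=pd.Index(list(bundle.features), name="sample_id"),
    )
    muts.to_csv(paths["mutations"], sep="\t")
    sigs = pd.DataFrame(
        {s: f.signature_contributions for s, f in bundle.features.items()}
    ).T
    sigs.index.name = "sample_id"
    sigs.to_csv(paths["signatures"], sep="\t")
    write_expression(bundle.expression, paths["expression"], paths["annotation"])
    write_seg(bundle.segments, paths["segments"])

    bundle.truth.table.to_csv(paths["truth"], sep="\t")
    with open(paths["truth_genes"], "w") as fh:
        json.dump({
            "effect_genes": bundle.truth.effect_genes,
            "chr17_passengers": bundle.truth.chr17_passengers,
            "mapk_genes": bundle.truth.mapk_genes,
            "esr1_module_genes": bundle.truth.esr1_module_genes,
            "cn_boundary": list(bundle.truth.cn_boundary),
        }, fh, indent=1)
    with open(paths["params"], "w") as fh:
        json.dump(asdict(bundle.params), fh, indent=1, default=list)
    return paths
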