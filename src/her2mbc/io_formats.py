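"""Readers and writers for the tabular formats the pipeline consumes.

Every table is plain TSV with a header row, except copy-number segments
which use the SEG convention (whitespace-delimited, 1-based fully-closed
intervals as produced by CBS/IGV). Readers normalise foreign dialects into
one canonical in-memory representation and log row counts; silent data loss
is forbidden, so anything dropped or flagged is reported through the module
logger.

Chromosome names are stored without a ``chr`` prefix; both ``chr8`` and
``8`` are accepted on read.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ER_STATES = ("positive", "negative", "unknown")

#: classes of mutational signatures, inferred from the signature name prefix
SIGNATURE_CLASSES = ("SBS", "DBS", "ID", "SV")

_SIG_CLASS_RE = re.compile(r"^(SBS|DBS|ID|SV)")


class SchemaError(ValueError):
    """A required column is missing or a value cannot be interpreted."""


class IntegrityError(ValueError):
    """The file parses but violates a cross-row invariant."""


class FormatError(ValueError):
    """A malformed line; carries the offending line number in the message."""


def normalize_chromosome(name: object) -> str:
    """Strip any ``chr`` prefix and return the bare chromosome name."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


# ---------------------------------------------------------------------------
# clinical records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClinicalRecord:
    """One patient: primary-tumour ER status, therapy history and outcome.

    ``pfs_time`` is days from start of post-biopsy therapy; ``pfs_event``
    is True for progressive disease and False for censoring (CR/PR/SD at
    last assessment). Both are optional but must be present together.
    """

    sample_id: str
    primary_er: str = "unknown"
    biopsy_site: str = ""
    prior_anti_her2: bool = False
    prior_lines: int = 0
    post_biopsy_anti_her2: bool = False
    pfs_time: float | None = None
    pfs_event: bool | None = None

    def __post_init__(self) -> None:
        if self.primary_er not in ER_STATES:
            raise SchemaError(
                f"primary_er must be one of {ER_STATES}, got {self.primary_er!r}"
            )
        if self.prior_lines < 0:
            raise IntegrityError(f"prior_lines must be >= 0, got {self.prior_lines}")
        if (self.pfs_time is None) != (self.pfs_event is None):
            raise IntegrityError(
                f"sample {self.sample_id}: pfs_time and pfs_event must be "
                "present together"
            )
        if self.pfs_time is not None and self.pfs_time <= 0:
            raise IntegrityError(
                f"sample {self.sample_id}: pfs_time must be positive"
            )


_CLINICAL_REQUIRED = (
    "sample_id",
    "primary_er",
    "prior_anti_her2",
    "prior_lines",
    "post_biopsy_anti_her2",
)
_CLINICAL_OPTIONAL = ("biopsy_site", "pfs_time", "pfs_event")

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def _parse_bool(value: object, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise SchemaError(f"column {column!r}: cannot interpret {value!r} as boolean")


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return str(value).strip() in ("", "NA", "nan", "None", ".")


def read_clinical(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[ClinicalRecord]:
    """Read a clinical TSV into :class:`ClinicalRecord` objects.

    ``dialect`` maps canonical column names to the names used in the file,
    so foreign tables can be adapted without code changes. Unknown extra
    columns are ignored with a logged warning; unknown ER status is kept
    as ``"unknown"``, never dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    rename = {v: k for k, v in (dialect or {}).items()}
    df = df.rename(columns=rename)
    for col in _CLINICAL_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"clinical table {path}: missing required column {col!r}")
    extras = [c for c in df.columns if c not in _CLINICAL_REQUIRED + _CLINICAL_OPTIONAL]
    if extras:
        logger.warning("clinical table %s: ignoring extra columns %s", path, extras)

    records: list[ClinicalRecord] = []
    for _, row in df.iterrows():
        er = str(row["primary_er"]).strip().lower()
        if _is_missing(row["primary_er"]) or er not in ER_STATES:
            er = "unknown"
        time_missing = "pfs_time" not in df.columns or _is_missing(row.get("pfs_time"))
        event_missing = "pfs_event" not in df.columns or _is_missing(row.get("pfs_event"))
        records.append(
            ClinicalRecord(
                sample_id=str(row["sample_id"]).strip(),
                primary_er=er,
                biopsy_site="" if _is_missing(row.get("biopsy_site")) else str(row["biopsy_site"]),
                prior_anti_her2=_parse_bool(row["prior_anti_her2"], "prior_anti_her2"),
                prior_lines=int(row["prior_lines"]),
                post_biopsy_anti_her2=_parse_bool(
                    row["post_biopsy_anti_her2"], "post_biopsy_anti_her2"
                ),
                pfs_time=None if time_missing else float(row["pfs_time"]),
                pfs_event=None if event_missing else _parse_bool(row["pfs_event"], "pfs_event"),
            )
        )
    ids = [r.sample_id for r in records]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise IntegrityError(f"clinical table {path}: duplicate sample_id {sorted(dupes)}")
    logger.info("clinical table %s: %d records", path, len(records))
    return records


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        if d["pfs_time"] is None:
            d["pfs_time"] = ""
            d["pfs_event"] = ""
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# per-sample genomic features
# ---------------------------------------------------------------------------

@dataclass
class GenomicFeatures:
    """Somatic features of one sample as produced by upstream WGS pipelines.

    ``signature_contributions`` maps signature name (e.g. ``DBS3``) to its
    relative contribution in [0, 1]; within each class (SBS/DBS/ID/SV) the
    contributions sum to at most 1. ``cn_region_flags`` marks recurrently
    altered copy-number regions (e.g. ``Amp-peak-6``).
    """

    sample_id: str
    mutated_genes: set[str] = field(default_factory=set)
    signature_contributions: dict[str, float] = field(default_factory=dict)
    n_variants: int = 0
    n_sv: int = 0
    erbb2_cn: float = 2.0
    ploidy: float = 2.0
    wgd: bool = False
    chromothripsis: bool = False
    cn_region_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_variants < 0 or self.n_sv < 0:
            raise IntegrityError(f"sample {self.sample_id}: negative event count")
        if self.erbb2_cn <= 0 or self.ploidy <= 0:
            raise IntegrityError(
                f"sample {self.sample_id}: copy number and ploidy must be > 0"
            )
        sums: dict[str, float] = {}
        for name, frac in self.signature_contributions.items():
            if not 0.0 <= frac <= 1.0:
                raise IntegrityError(
                    f"sample {self.sample_id}: contribution of {name} = {frac} "
                    "outside [0, 1]"
                )
            sums[signature_class(name)] = sums.get(signature_class(name), 0.0) + frac
        for cls, total in sums.items():
            if total > 1.0 + 1e-6:
                raise IntegrityError(
                    f"sample {self.sample_id}: {cls} contributions sum to {total} > 1"
                )


def signature_class(name: str) -> str:
    """Return the signature class (SBS/DBS/ID/SV) encoded in a name."""
    m = _SIG_CLASS_RE.match(name)
    if not m:
        raise SchemaError(f"cannot infer signature class from name {name!r}")
    return m.group(1)


def read_mutation_flags(path: str | Path) -> pd.DataFrame:
    """Samples x genes 0/1 matrix; first column is the sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise IntegrityError(f"mutation table {path}: duplicate sample ids {dup}")
    logger.info("mutation table %s: %d samples x %d genes", path, *df.shape)
    return df.astype(bool)


def read_signature_contributions(path: str | Path) -> pd.DataFrame:
    """Samples x signatures fraction matrix; class encoded in column names."""
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    for col in df.columns:
        signature_class(col)  # raises on unparseable names
    if ((df < 0) | (df > 1)).any().any():
        raise IntegrityError(f"signature table {path}: contribution outside [0, 1]")
    classes = pd.Series({c: signature_class(c) for c in df.columns})
    for cls in classes.unique():
        sums = df.loc[:, classes[classes == cls].index].sum(axis=1)
        if (sums > 1.0 + 1e-6).any():
            bad = sums[sums > 1.0 + 1e-6].index.tolist()
            raise IntegrityError(
                f"signature table {path}: {cls} contributions exceed 1 for {bad}"
            )
    logger.info("signature table %s: %d samples x %d signatures", path, *df.shape)
    return df


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Per-sample scalar features (counts, CN, ploidy, flags, CN regions)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise IntegrityError(f"feature table {path}: duplicate sample ids")
    logger.info("feature table %s: %d samples", path, len(df))
    return df


def assemble_features(
    feature_table: pd.DataFrame,
    mutations: pd.DataFrame | None = None,
    signatures: pd.DataFrame | None = None,
) -> dict[str, GenomicFeatures]:
    """Combine the scalar/mutation/signature tables into per-sample objects.

    Region flags are the feature-table columns prefixed ``region_``.
    """
    out: dict[str, GenomicFeatures] = {}
    region_cols = [c for c in feature_table.columns if c.startswith("region_")]
    for sid, row in feature_table.iterrows():
        sid = str(sid)
        muts: set[str] = set()
        if mutations is not None and sid in mutations.index:
            muts = set(mutations.columns[mutations.loc[sid].astype(bool)])
        sigs: dict[str, float] = {}
        if signatures is not None and sid in signatures.index:
            sigs = signatures.loc[sid].to_dict()
        out[sid] = GenomicFeatures(
            sample_id=sid,
            mutated_genes=muts,
            signature_contributions=sigs,
            n_variants=int(row["n_variants"]),
            n_sv=int(row["n_sv"]),
            erbb2_cn=float(row["erbb2_cn"]),
            ploidy=float(row["ploidy"]),
            wgd=_parse_bool(row["wgd"], "wgd"),
            chromothripsis=_parse_bool(row["chromothripsis"], "chromothripsis"),
            cn_region_flags={
                c[len("region_"):]: _parse_bool(row[c], c) for c in region_cols
            },
        )
    return out


def features_frame(features: Mapping[str, GenomicFeatures]) -> pd.DataFrame:
    """Flatten per-sample features back to the scalar table layout."""
    rows = {}
    for sid, f in features.items():
        row: dict[str, object] = {
            "n_variants": f.n_variants,
            "n_sv": f.n_sv,
            "erbb2_cn": f.erbb2_cn,
            "ploidy": f.ploidy,
            "wgd": f.wgd,
            "chromothripsis": f.chromothripsis,
        }
        for region, flag in f.cn_region_flags.items():
            row[f"region_{region}"] = flag
        rows[sid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


# ---------------------------------------------------------------------------
# SEG copy-number segments
# ---------------------------------------------------------------------------

@dataclass
class SegmentTable:
    """Copy-number segments; coordinates are 1-based, fully closed."""

    frame: pd.DataFrame  # columns: sample_id, chrom, start, end, value

    COLUMNS = ("sample_id", "chrom", "start", "end", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"segment table missing columns {missing}")
        if len(self.frame) and (self.frame["start"] > self.frame["end"]).any():
            raise IntegrityError("segment with start > end")

    def __len__(self) -> int:
        return len(self.frame)

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.frame[self.frame["sample_id"] == sample_id]


def read_seg(path: str | Path) -> SegmentTable:
    """Parse a SEG file (5 or 6 whitespace-delimited columns with header).

    Six columns are interpreted as (sample, chrom, start, end, num_mark,
    value); five as (sample, chrom, start, end, value). Chromosome names
    are normalised; coordinates are kept as written.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            return SegmentTable(pd.DataFrame(columns=list(SegmentTable.COLUMNS)))
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) == 6:
                sid, chrom, start, end, _nmark, value = parts
            elif len(parts) == 5:
                sid, chrom, start, end, value = parts
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 or 6 columns, got {len(parts)}"
                )
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise FormatError(f"{path}:{lineno}: start {start_i} > end {end_i}")
            rows.append(
                (str(sid), normalize_chromosome(chrom), start_i, end_i, float(value))
            )
    frame = pd.DataFrame(rows, columns=list(SegmentTable.COLUMNS))
    logger.info("segment file %s: %d segments", path, len(frame))
    return SegmentTable(frame)


def write_seg(table: SegmentTable, path: str | Path) -> None:
    df = table.frame.copy()
    df.insert(4, "num_mark", 0)
    df.to_csv(path, sep="\t", index=False,
              header=["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"])


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Normalised (GeTMM-scale) gene x sample expression with annotation.

    Values are consumed as given and must be non-negative; analyses that
    need a log scale apply ``log2(x + 1)`` themselves. Genes without a
    chromosome annotation are retained and flagged in ``unannotated``.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    gene_chrom: dict[str, str]
    unannotated: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise SchemaError(
                f"expression values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise IntegrityError("duplicate gene symbols in expression matrix")
        if np.any(self.values < 0):
            raise IntegrityError("negative expression value; normalized input must be >= 0")
        self.unannotated = {g for g in self.genes if g not in self.gene_chrom} | set(
            self.unannotated
        )

    def row(self, gene: str) -> np.ndarray:
        try:
            i = self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None
        return self.values[i]

    def chromosome(self, gene: str) -> str | None:
        return self.gene_chrom.get(gene)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.genes if g in set(genes)]
        idx = [self.genes.index(g) for g in keep]
        return ExpressionMatrix(
            genes=keep,
            samples=list(self.samples),
            values=self.values[idx],
            gene_chrom={g: c for g, c in self.gene_chrom.items() if g in set(keep)},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


def read_gene_annotation(path: str | Path) -> dict[str, str]:
    """Two-column gene -> chromosome map (TSV with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "chromosome"}.issubset(df.columns):
        raise SchemaError(f"annotation {path}: needs columns 'gene' and 'chromosome'")
    return {
        str(g): normalize_chromosome(c) for g, c in zip(df["gene"], df["chromosome"])
    }


def read_expression(path: str | Path, annotation: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise IntegrityError(f"expression matrix {path}: duplicate gene rows {dup}")
    gene_chrom = read_gene_annotation(annotation)
    matrix = ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        gene_chrom=gene_chrom,
    )
    if matrix.unannotated:
        logger.warning(
            "expression matrix %s: %d genes without chromosome annotation",
            path, len(matrix.unannotated),
        )
    logger.info("expression matrix %s: %d genes x %d samples", path, *matrix.values.shape)
    return matrix


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     annotation_path: str | Path | None = None) -> None:
    matrix.to_frame().rename_axis("gene").to_csv(path, sep="\t")
    if annotation_path is not None:
        pd.DataFrame(
            {"gene": matrix.genes,
             "chromosome": [matrix.gene_chrom.get(g, "NA") for g in matrix.genes]}
        ).to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML (or flat key: value) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"config {path}: expected a mapping at top level")
    return cfg
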