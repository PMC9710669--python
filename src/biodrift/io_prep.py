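"""Expression-matrix IO and cohort preparation.

Mirrors the preparation applied to paired breast-cancer cohorts before
streaming: per-cohort Z-scoring of log-scale expression, restriction of both
cohorts to their shared gene set, surrogate intrinsic-subtype labeling from
clinical markers (ER, PgR, HER2, Ki-67), and concatenation of the labeled
cohorts into a single ordered stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .stream import ExpressionStream

SUBTYPES = ["LuminalA", "LuminalB", "HER2", "Basal"]


@dataclass
class ExpressionMatrix:
    """A samples x genes numeric matrix with a cohort tag.

    ``values`` is a pandas DataFrame indexed by sample id with gene-id
    columns; missing measurements are NaN.
    """

    values: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        genes = list(self.values.columns)
        if len(set(genes)) != len(genes):
            dups = sorted({g for g in genes if genes.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers: {dups}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.columns]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def __len__(self) -> int:
        return len(self.values)


def read_expression_matrix(path: str | Path, orientation: str = "samples_in_rows",
                           source: str = "") -> ExpressionMatrix:
    """Read a TSV/CSV expression matrix (gzip transparently handled).

    ``orientation`` declares whether rows are samples or genes; genes-in-rows
    input is transposed so the in-memory matrix is always samples x genes.
    Non-numeric cells other than the usual NA spellings are an error naming
    the offending cell.
    """
    if orientation not in ("samples_in_rows", "genes_in_rows"):
        raise ValueError(f"unknown orientation: {orientation}")
    path = Path(path)
    sep = "," if ".csv" in path.name else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"parse error in {path.name}: {exc}") from exc
    if orientation == "genes_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna() & ~df.astype(str).isin(["NA", "NaN", "nan"])
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at sample {df.index[r]!r}, "
            f"gene {df.columns[c]!r}")
    return ExpressionMatrix(values=coerced, source=source)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path,
                            orientation: str = "samples_in_rows") -> None:
    df = m.values if orientation == "samples_in_rows" else m.values.T
    sep = "," if ".csv" in Path(path).name else "\t"
    df.to_csv(path, sep=sep)


def zscore_standardize(m: ExpressionMatrix, ddof: int = 1,
                       tol: float = 1e-12) -> ExpressionMatrix:
    """Per-gene Z-scores within one cohort (mean 0, SD 1, n-1 denominator).

    Zero-variance genes carry no information and are dropped with a warning.
    Standardization is per cohort, before concatenation; streams are not
    re-standardized online.
    """
    vals = m.values
    sd = vals.std(axis=0, ddof=ddof)
    constant = [g for g in vals.columns if not sd[g] > tol]
    if constant:
        warnings.warn(f"dropping {len(constant)} zero-variance gene(s): "
                      f"{constant[:10]}", stacklevel=2)
        vals = vals.drop(columns=constant)
        sd = sd.drop(constant)
    out = (vals - vals.mean(axis=0)) / sd
    return ExpressionMatrix(values=out, source=m.source)


def intersect_genes(a: ExpressionMatrix,
                    b: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both cohorts to their shared genes, in one canonical order."""
    shared = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not shared:
        raise ValueError("cohorts share no genes")
    return (ExpressionMatrix(a.values[shared], source=a.source),
            ExpressionMatrix(b.values[shared], source=b.source))


class Marker(str, Enum):
    POS = "pos"
    NEG = "neg"
    MISSING = "missing"


@dataclass
class ClinicalMarkers:
    """ER / PgR / HER2 receptor status and the Ki-67 proliferation index."""

    er_status: Marker = Marker.MISSING
    pgr_status: Marker = Marker.MISSING
    her2_status: Marker = Marker.MISSING
    ki67: float | None = None

    def __post_init__(self) -> None:
        self.er_status = Marker(self.er_status)
        self.pgr_status = Marker(self.pgr_status)
        self.her2_status = Marker(self.her2_status)
        if self.ki67 is not None and not 0 <= self.ki67 <= 100:
            raise ValueError("ki67 must be a percentage in [0, 100]")


def assign_stgallen_subtype(cm: ClinicalMarkers,
                            ki67_high_threshold: float = 20.0) -> str | None:
    """Surrogate intrinsic subtype from clinical markers (St. Gallen 2013).

    LuminalA: hormone-receptor positive, HER2-, Ki-67 below threshold.
    LuminalB: hormone-receptor positive and (HER2+ or Ki-67 high).
    HER2: ER-, PgR-, HER2+.  Basal: triple negative.
    Returns ``None`` (unlabeled) when a marker needed to decide is missing;
    such profiles are discarded upstream.
    """
    if not 0 < ki67_high_threshold < 100:
        raise ValueError("ki67_high_threshold must be in (0, 100)")
    er, pgr, her2 = cm.er_status, cm.pgr_status, cm.her2_status

    if er == Marker.POS or pgr == Marker.POS:
        if her2 == Marker.POS:
            return "LuminalB"
        ki67_high = None if cm.ki67 is None else cm.ki67 >= ki67_high_threshold
        if her2 == Marker.NEG:
            if ki67_high is None:
                return None
            return "LuminalB" if ki67_high else "LuminalA"
        # HER2 missing: Ki-67 high forces LuminalB either way
        return "LuminalB" if ki67_high else None
    if er == Marker.NEG and pgr == Marker.NEG:
        if her2 == Marker.POS:
            return "HER2"
        if her2 == Marker.NEG:
            return "Basal"
        return None
    return None  # hormone status undecidable


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV with columns sample_id, er, pgr, her2, ki67."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "er", "pgr", "her2", "ki67"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df.set_index("sample_id")


def label_cohort(m: ExpressionMatrix, phenotype: pd.DataFrame,
                 ki67_high_threshold: float = 20.0) -> tuple[ExpressionMatrix, list[str]]:
    """Assign subtypes to a cohort and drop unlabeled samples."""
    labels, keep = [], []
    for sid in m.sample_ids:
        if sid not in phenotype.index:
            continue
        row = phenotype.loc[sid]
        ki67 = None if pd.isna(row["ki67"]) else float(row["ki67"])
        cm = ClinicalMarkers(
            er_status=_parse_marker(row["er"]), pgr_status=_parse_marker(row["pgr"]),
            her2_status=_parse_marker(row["her2"]), ki67=ki67)
        lab = assign_stgallen_subtype(cm, ki67_high_threshold)
        if lab is not None:
            keep.append(sid)
            labels.append(lab)
    return ExpressionMatrix(m.values.loc[keep], source=m.source), labels


def _parse_marker(v) -> Marker:
    if pd.isna(v):
        return Marker.MISSING
    s = str(v).strip().lower()
    if s in ("pos", "positive", "1", "+"):
        return Marker.POS
    if s in ("neg", "negative", "0", "-"):
        return Marker.NEG
    return Marker.MISSING


def concatenate_streams(a: ExpressionMatrix, a_labels: list[str],
                        b: ExpressionMatrix, b_labels: list[str],
                        order: str = "ab",
                        class_names: list[str] | None = None) -> ExpressionStream:
    """Concatenate two labeled, gene-aligned cohorts into one stream.

    Sample order within each cohort is preserved (no shuffling): the stream
    is consumed exactly in acquisition order.
    """
    if order not in ("ab", "ba"):
        raise ValueError("order must be 'ab' or 'ba'")
    if len(a) and len(b) and a.gene_ids != b.gene_ids:
        raise ValueError("gene order mismatch; intersect_genes first")
    if len(a_labels) != len(a.values) or len(b_labels) != len(b.values):
        raise ValueError("label length mismatch")
    parts = [(a, a_labels), (b, b_labels)]
    if order == "ba":
        parts.reverse()
    genes = a.gene_ids if len(a.values) else b.gene_ids
    if class_names is None:
        class_names = [s for s in SUBTYPES if s in set(a_labels) | set(b_labels)]
        if not class_names:
            class_names = sorted(set(a_labels) | set(b_labels))
    code = {c: i for i, c in enumerate(class_names)}
    X = np.vstack([p.values.to_numpy(dtype=float) for p, _ in parts
                   if len(p.values)]) if (len(a.values) or len(b.values)) \
        else np.empty((0, len(genes)))
    y, sources, sample_ids = [], [], []
    for mat, labs in parts:
        y.extend(code[v] for v in labs)
        sources.extend([mat.source or "cohort"] * len(labs))
        sample_ids.extend(mat.sample_ids)
    return ExpressionStream(feature_names=list(genes), X=X,
                            y=np.array(y, dtype=int),
                            sources=np.array(sources, dtype=object),
                            class_names=list(class_names),
                            sample_ids=sample_ids)
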