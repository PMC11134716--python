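"""Data containers and plain-text readers/writers.

Expression matrices travel as genes x samples TSVs (first column gene ids,
header row sample ids, integer counts).  Clinical tables are flat TSVs keyed
by sample id.  Trained score models are serialized as a TSV body preceded by
a ``# key=value`` comment header carrying provenance, so model files are
diffable and platform-neutral.

All validation happens at construction time: a malformed object is rejected
before any downstream computation can consume it.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sahr")

#: the four prognosis categories, in the order gene panels are assembled
CATEGORIES = (
    "oncogene_like",
    "suppressor_like",
    "up_regulated_saver",
    "down_regulated_saver",
)

#: categories whose planted/annotated direction is "up" in tumors
UP_CATEGORIES = ("oncogene_like", "up_regulated_saver")

STAGES = ("I", "II", "III", "IV")

#: hazard ratios above this are considered unreliable and rejected on read
HR_MAX = 20.0


class ValidationError(ValueError):
    """An object violates a domain invariant."""


class ParseError(ValueError):
    """A file could not be interpreted in the declared format."""


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples expression container.

    ``counts`` holds raw non-negative integers.  After normalization,
    ``normalized`` holds counts divided by per-sample ``size_factors``;
    the three pieces are kept consistent by construction.
    """

    counts: pd.DataFrame
    normalized: pd.DataFrame | None = None
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if not isinstance(c, pd.DataFrame):
            raise ValidationError("counts must be a DataFrame (genes x samples)")
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if c.size and (c.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.normalized is not None:
            n = self.normalized
            if n.shape != c.shape:
                raise ValidationError("normalized and counts dimensions differ")
            if not (n.index.equals(c.index) and n.columns.equals(c.columns)):
                raise ValidationError("normalized and counts ids differ")
            if (n.to_numpy() < 0).any():
                raise ValidationError("normalized values must be non-negative")
        if self.size_factors is not None:
            s = self.size_factors
            if not s.index.equals(c.columns):
                raise ValidationError("size factor index must match sample ids")
            if (s.to_numpy() <= 0).any():
                raise ValidationError("size factors must be positive")

    # -- convenience -------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(
            counts=self.counts.loc[:, ids],
            normalized=None if self.normalized is None else self.normalized.loc[:, ids],
            size_factors=None if self.size_factors is None else self.size_factors.loc[ids],
        )

    def drop_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        drop = [g for g in gene_ids if g in self.counts.index]
        return ExpressionMatrix(
            counts=self.counts.drop(index=drop),
            normalized=None if self.normalized is None else self.normalized.drop(index=drop),
            size_factors=self.size_factors,
        )


def read_expression(path: str | Path, format: str = "counts_tsv") -> ExpressionMatrix:
    """Read a genes x samples raw-count TSV.

    The first column holds gene ids, the header row sample ids, and every
    cell a non-negative integer.  Orientation is part of the format
    contract; a transposed file is not detected.
    """
    if format != "counts_tsv":
        raise ValueError(f"unknown expression format: {format!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty expression file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: expression file has no data cells")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: malformed numeric cell at gene {row!r}, sample {col!r}"
            )
        arr = parsed.to_numpy(dtype=float)
        if not np.all(arr == np.floor(arr)):
            row = df.index[(arr != np.floor(arr)).nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-integer count at gene {row!r}, sample {col!r}"
            )
        values[:, j] = arr.astype(np.int64)
    counts = pd.DataFrame(values, index=df.index, columns=df.columns)
    counts.index.name = "gene_id"
    em = ExpressionMatrix(counts=counts)
    logger.info("read_expression: %d genes x %d samples from %s", em.n_genes, em.n_samples, path)
    return em


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples table as TSV (first column ``gene_id``)."""
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

_STAGE_RE = re.compile(r"^(IV|III|II|I)([ABC][0-9]?)?$")

CONDITIONS = ("tumor", "normal")
SPLITS = ("train", "test", "unassigned")


def normalize_stage(raw: object) -> str:
    """Collapse a free-text stage annotation onto I/II/III/IV.

    Strips a leading ``Stage`` token and any trailing sub-stage letter
    (A/B/C), so ``"Stage IIIA"`` becomes ``"III"``.  Anything unparseable,
    including missing values, maps to ``"unknown"``.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return "unknown"
    s = str(raw).strip()
    if not s or s.lower() in {"na", "nan", "none", "unknown", "[not available]"}:
        return "unknown"
    s = re.sub(r"^stage\s*", "", s, flags=re.IGNORECASE).strip().upper()
    m = _STAGE_RE.match(s)
    return m.group(1) if m else "unknown"


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates, indexed by sample id.

    Columns: ``condition`` (tumor/normal), ``os_time`` (non-negative,
    unit-agnostic), ``os_event`` (1 event, 0 censored), ``stage``
    (I-IV/unknown) and ``split`` (train/test/unassigned).  ``os_time`` and
    ``os_event`` may be missing for normal samples, which carry no
    survival follow-up; survival operations validate completeness on the
    tumor samples they actually consume.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"condition", "os_time", "os_event", "stage", "split"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        bad_cond = set(df["condition"].unique()) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown condition values: {sorted(bad_cond)}")
        t = pd.to_numeric(df["os_time"], errors="coerce")
        if ((t < 0) & t.notna()).any():
            sid = df.index[(t < 0).fillna(False)][0]
            raise ValidationError(f"negative os_time for sample {sid!r}")
        e = df["os_event"]
        bad_e = e.dropna()[~e.dropna().isin([0, 1])]
        if len(bad_e):
            raise ValidationError(
                f"os_event outside {{0,1}} for sample {bad_e.index[0]!r}"
            )
        bad_stage = set(df["stage"].unique()) - set(STAGES) - {"unknown"}
        if bad_stage:
            raise ValidationError(f"unknown stage values: {sorted(bad_stage)}")
        bad_split = set(df["split"].unique()) - set(SPLITS)
        if bad_split:
            raise ValidationError(f"unknown split values: {sorted(bad_split)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def tumors(self) -> pd.DataFrame:
        return self.data[self.data["condition"] == "tumor"]

    def normals(self) -> pd.DataFrame:
        return self.data[self.data["condition"] == "normal"]

    def survival_frame(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        """Times and events for the given tumor samples; missing data rejected."""
        sub = self.data.loc[list(sample_ids)]
        if (sub["condition"] != "tumor").any():
            sid = sub.index[sub["condition"] != "tumor"][0]
            raise ValidationError(f"survival requested for non-tumor sample {sid!r}")
        if sub["os_time"].isna().any() or sub["os_event"].isna().any():
            sid = sub.index[sub["os_time"].isna() | sub["os_event"].isna()][0]
            raise ValidationError(f"missing survival data for tumor sample {sid!r}")
        return pd.DataFrame(
            {
                "time": sub["os_time"].astype(float),
                "event": sub["os_event"].astype(int),
            }
        )


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV.

    Required columns: ``sample_id``, ``condition``, ``os_time``,
    ``os_event``.  Optional: ``stage`` (normalized onto I-IV, missing ->
    unknown) and ``split`` (missing -> unassigned).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty clinical file") from exc
    required = ["sample_id", "condition", "os_time", "os_event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    out = pd.DataFrame(index=pd.Index(df["sample_id"], name="sample_id"))
    out["condition"] = df["condition"].str.strip().str.lower().to_numpy()
    out["os_time"] = pd.to_numeric(df["os_time"], errors="coerce").to_numpy()
    raw_ev = pd.to_numeric(df["os_event"], errors="coerce")
    has_ev = df["os_event"].notna() & (df["os_event"].str.strip() != "")
    if (raw_ev.isna() & has_ev).any():
        sid = df["sample_id"][raw_ev.isna() & has_ev].iloc[0]
        raise ParseError(f"{path}: malformed os_event for sample {sid!r}")
    out["os_event"] = raw_ev.to_numpy()
    stage_col = df["stage"] if "stage" in df.columns else pd.Series(index=df.index, dtype=object)
    out["stage"] = [normalize_stage(v) for v in stage_col]
    if "split" in df.columns:
        out["split"] = (
            df["split"].fillna("unassigned").replace("", "unassigned").str.strip().to_numpy()
        )
    else:
        out["split"] = "unassigned"
    table = ClinicalTable(out)
    logger.info(
        "read_clinical: %d samples (%d tumor / %d normal) from %s",
        len(out), len(table.tumors()), len(table.normals()), path,
    )
    return table


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SAHR model serialization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SAHREntry:
    """One gene of a trained panel: category, dichotomization cutoff, HR."""

    gene_id: str
    category: str
    cutoff: float
    hr: float


#: per-category panel size limits, keyed like CATEGORIES
DEFAULT_LIMITS = {
    "oncogene_like": 20,
    "suppressor_like": 20,
    "up_regulated_saver": 10,
    "down_regulated_saver": 10,
}


@dataclass
class SAHRModel:
    """A frozen, orderable gene panel for one cancer type.

    Each entry carries the training-cohort expression cutoff and the
    worse-vs-better oriented hazard ratio (hence 1 <= hr <= 20).  The panel
    holds at most 20 oncogene-like, 20 suppressor-like, 10 up-regulated-saver
    and 10 down-regulated-saver genes.
    """

    cancer_type_label: str
    entries: list[SAHREntry]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        counts = {c: 0 for c in CATEGORIES}
        for e in self.entries:
            if e.category not in CATEGORIES:
                raise ValidationError(f"unknown category {e.category!r} for {e.gene_id!r}")
            if e.gene_id in seen:
                raise ValidationError(f"duplicate gene id in model: {e.gene_id!r}")
            seen.add(e.gene_id)
            counts[e.category] += 1
            if not (1.0 <= e.hr <= HR_MAX):
                raise ValidationError(
                    f"hazard ratio {e.hr} for {e.gene_id!r} outside [1, {HR_MAX:g}]"
                )
            if not np.isfinite(e.cutoff):
                raise ValidationError(f"non-finite cutoff for {e.gene_id!r}")
        for cat, limit in DEFAULT_LIMITS.items():
            if counts[cat] > limit:
                raise ValidationError(
                    f"{counts[cat]} {cat} entries exceed the limit of {limit}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(e) for e in self.entries],
            columns=["gene_id", "category", "cutoff", "hr"],
        )


def write_model(model: SAHRModel, path: str | Path) -> None:
    """Serialize a model as a commented-header TSV; full float precision."""
    path = Path(path)
    lines = [f"# cancer_type_label={model.cancer_type_label}"]
    for key in sorted(model.provenance):
        lines.append(f"# {key}={model.provenance[key]}")
    lines.append("gene_id\tcategory\tcutoff\thr")
    for e in model.entries:
        lines.append(f"{e.gene_id}\t{e.category}\t{e.cutoff!r}\t{e.hr!r}")
    path.write_text("\n".join(lines) + "\n")


def read_model(path: str | Path) -> SAHRModel:
    """Read a model written by :func:`write_model`; invariants re-checked."""
    path = Path(path)
    label = ""
    provenance: dict = {}
    entries: list[SAHREntry] = []
    header_seen = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise ParseError(f"{path}:{lineno}: malformed provenance line")
            key, _, value = body.partition("=")
            if key.strip() == "cancer_type_label":
                label = value.strip()
            else:
                provenance[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if not header_seen:
            if fields != ["gene_id", "category", "cutoff", "hr"]:
                raise ParseError(f"{path}:{lineno}: unexpected model header {fields}")
            header_seen = True
            continue
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 fields, found {len(fields)}")
        try:
            entry = SAHREntry(fields[0], fields[1], float(fields[2]), float(fields[3]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed numeric field") from exc
        entries.append(entry)
    if not header_seen:
        raise ParseError(f"{path}: no model table found")
    return SAHRModel(cancer_type_label=label, entries=entries, provenance=provenance)


def configure_logging(level: int = logging.INFO) -> None:
    """Log per-stage record counts to stderr (idempotent)."""
    root = logging.getLogger("sahr")
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
        root.addHandler(handler)
    root.setLevel(level)
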