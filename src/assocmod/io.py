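"""Core containers and file I/O for multi-omic cohort data.

All matrices use a single TSV dialect: the first row holds sample ids, the
first column holds feature (probe/gene) ids, cells are numeric, "NA" denotes
a missing value, encoding is UTF-8.  Features with more than 20% missing
entries are dropped; remaining missing entries are imputed with the feature
median (rank-neutral under the downstream empirical-CDF transform).

The in-memory convention throughout the package is a pandas DataFrame with
features as rows and samples as columns.  :class:`OmicsMatrix` tags such a
frame with its biological role; :class:`CohortBundle` groups the matrices of
one cohort with its clinical table and gene annotation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: biological roles a matrix may carry
ROLES = ("expression", "cnv_probe", "methylation")

#: fraction of missing entries above which a feature is dropped
MAX_MISSING_FRACTION = 0.20


class DataError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class OmicsMatrix:
    """A role-tagged numeric matrix, features x samples.

    Parameters
    ----------
    role : str
        One of ``expression``, ``cnv_probe``, ``methylation``.
    data : pandas.DataFrame
        Numeric values; index = feature ids, columns = sample ids.
    """

    role: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DataError(f"unknown matrix role {self.role!r}; expected one of {ROLES}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DataError(f"duplicate feature id {dup!r} in {self.role} matrix")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise DataError(f"duplicate sample id {dup!r} in {self.role} matrix")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns


@dataclass
class CohortBundle:
    """All data of one cohort: matrices, optional clinical table, annotation.

    ``matrices`` is keyed by a free label (e.g. ``expression_tumor``) so that
    paired tumor/adjacent-normal matrices of the same role can coexist.
    When a clinical table is present, every matrix column is a clinical
    sample (enforced by :func:`load_cohort` / :meth:`validate`).
    """

    name: str
    matrices: dict[str, OmicsMatrix] = field(default_factory=dict)
    clinical: pd.DataFrame | None = None
    annotation: pd.DataFrame | None = None

    def validate(self) -> None:
        if self.clinical is not None:
            known = set(self.clinical.index)
            for label, m in self.matrices.items():
                extra = set(m.sample_ids) - known
                if extra:
                    raise DataError(
                        f"cohort {self.name!r}: matrix {label!r} has samples absent "
                        f"from the clinical table: {sorted(extra)[:5]}"
                    )


# ---------------------------------------------------------------------------
# matrix TSV
# ---------------------------------------------------------------------------

def read_matrix_tsv(path, role: str) -> OmicsMatrix:
    """Read a feature-by-sample TSV matrix.

    Non-numeric cells raise :class:`DataError` naming the offending row and
    column.  Features exceeding the missing-value budget are dropped;
    remaining missing entries are median-imputed.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise DataError(f"matrix file not found: {path}") from None
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    values = raw.mask(raw == "NA")
    try:
        values = values.astype(float)
    except ValueError:
        # locate the first bad cell for the error message
        for col in values.columns:
            coerced = pd.to_numeric(values[col], errors="coerce")
            bad = coerced.isna() & (raw[col] != "NA")
            if bad.any():
                row = values.index[bad.argmax()]
                raise DataError(
                    f"non-numeric cell at feature {row!r}, sample {col!r} in {path}"
                ) from None
        raise
    values = _handle_missing(values, str(path))
    if role == "methylation":
        v = values.to_numpy()
        if np.nanmin(v) < 0.0 or np.nanmax(v) > 1.0:
            raise DataError(f"methylation beta values outside [0, 1] in {path}")
    return OmicsMatrix(role=role, data=values)


def _handle_missing(values: pd.DataFrame, origin: str) -> pd.DataFrame:
    frac = values.isna().mean(axis=1)
    drop = frac > MAX_MISSING_FRACTION
    if drop.any():
        logger.warning(
            "%s: dropping %d features with >%.0f%% missing values",
            origin, int(drop.sum()), 100 * MAX_MISSING_FRACTION,
        )
        values = values.loc[~drop]
    if values.isna().to_numpy().any():
        med = values.median(axis=1)
        values = values.T.fillna(med).T
    return values


def write_matrix_tsv(matrix: OmicsMatrix | pd.DataFrame, path) -> None:
    data = matrix.data if isinstance(matrix, OmicsMatrix) else matrix
    data.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# annotation / clinical
# ---------------------------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation table (gene_id, chromosome, arm, position)."""
    try:
        ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str, "arm": str})
    except FileNotFoundError:
        raise DataError(f"annotation file not found: {path}") from None
    return validate_annotation(ann)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "chromosome", "arm", "position"}
    missing = required - set(ann.columns)
    if missing:
        raise DataError(f"annotation missing columns: {sorted(missing)}")
    if ann["gene_id"].duplicated().any():
        dup = ann.loc[ann["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise DataError(f"duplicate gene id in annotation: {dup!r}")
    bad_arm = ~ann["arm"].isin(["p", "q"])
    if bad_arm.any():
        raise DataError(f"annotation arm must be 'p' or 'q'; got {ann.loc[bad_arm, 'arm'].iloc[0]!r}")
    if (ann["position"] < 0).any():
        raise DataError("annotation positions must be non-negative")
    return ann.set_index("gene_id", drop=False)


def arm_labels(annotation: pd.DataFrame) -> pd.Series:
    """Map each gene to its chromosome-arm segment id, e.g. ``chr7p``."""
    return "chr" + annotation["chromosome"].astype(str) + annotation["arm"]


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical table (sample_id, time, event, gender, cohort)."""
    try:
        clin = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except FileNotFoundError:
        raise DataError(f"clinical file not found: {path}") from None
    return validate_clinical(clin)


def validate_clinical(clin: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "time", "event"}
    missing = required - set(clin.columns)
    if missing:
        raise DataError(f"clinical table missing columns: {sorted(missing)}")
    if clin["sample_id"].duplicated().any():
        raise DataError("duplicate sample_id in clinical table")
    if (clin["time"] <= 0).any():
        raise DataError("clinical times must be strictly positive")
    if not clin["event"].isin([0, 1, True, False]).all():
        raise DataError("clinical event indicator must be 0/1")
    clin = clin.copy()
    clin["event"] = clin["event"].astype(bool)
    if "gender" not in clin.columns:
        clin["gender"] = "unknown"
    if "cohort" not in clin.columns:
        clin["cohort"] = ""
    return clin.set_index("sample_id", drop=False)


def write_clinical(clin: pd.DataFrame, path) -> None:
    out = clin.copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort loading
# ---------------------------------------------------------------------------

def load_cohort(entry: dict) -> CohortBundle:
    """Assemble a :class:`CohortBundle` from a config entry.

    ``entry`` maps ``name``, ``annotation`` (path), optional ``clinical``
    (path) and ``matrices``: a mapping label -> {"path": ..., "role": ...}.
    Samples are aligned to the intersection of all matrix columns (and the
    clinical table when present), preserving the clinical table's order;
    dropped samples are logged.
    """
    name = entry.get("name", "cohort")
    annotation = read_annotation(entry["annotation"]) if entry.get("annotation") else None
    clinical = read_clinical(entry["clinical"]) if entry.get("clinical") else None

    matrices: dict[str, OmicsMatrix] = {}
    for label, spec in entry.get("matrices", {}).items():
        matrices[label] = read_matrix_tsv(spec["path"], spec["role"])
    if not matrices:
        raise DataError(f"cohort {name!r} declares no matrices")

    shared: pd.Index | None = None
    for m in matrices.values():
        shared = m.sample_ids if shared is None else shared.intersection(m.sample_ids)
    if clinical is not None:
        ordered = [s for s in clinical.index if s in set(shared)]
    else:
        ordered = [s for s in matrices[next(iter(matrices))].sample_ids if s in set(shared)]
    if not ordered:
        raise DataError(f"cohort {name!r}: no samples shared across matrices and clinical table")

    for label, m in matrices.items():
        dropped = set(m.sample_ids) - set(ordered)
        if dropped:
            logger.warning(
                "cohort %s: dropping %d unaligned samples from %s (e.g. %s)",
                name, len(dropped), label, sorted(dropped)[:3],
            )
        matrices[label] = OmicsMatrix(role=m.role, data=m.data.loc[:, ordered])
    if clinical is not None:
        clinical = clinical.loc[ordered]

    bundle = CohortBundle(name=name, matrices=matrices, clinical=clinical, annotation=annotation)
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# gene sets and citation counts
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: set name, description, member genes per line."""
    sets: dict[str, list[str]] = {}
    try:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    continue
                sets[fields[0]] = [g for g in fields[2:] if g]
    except FileNotFoundError:
        raise DataError(f"GMT file not found: {path}") from None
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for nm, genes in sets.items():
            fh.write("\t".join([nm, description, *genes]) + "\n")


def read_citation_counts(path) -> pd.Series:
    """Read a two-column TSV (gene_id, count) of literature co-citation counts."""
    try:
        tab = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    except FileNotFoundError:
        raise DataError(f"citation count file not found: {path}") from None
    if not {"gene_id", "count"} <= set(tab.columns):
        raise DataError("citation table needs columns gene_id, count")
    return tab.set_index("gene_id")["count"].astype(float)


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

def write_validation_report(results, path) -> None:
    """Write one TSV row per (module, cohort) of validation statistics.

    ``results`` is a sequence of objects exposing ``to_rows()`` (see
    ``assocmod.validation.ModuleValidationResult``).  Floats are printed
    with 12 significant digits so the companion reader round-trips them.
    """
    rows = []
    for res in results:
        rows.extend(res.to_rows())
    if not rows:
        raise DataError("refusing to write an empty validation report")
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_validation_report(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except FileNotFoundError:
        raise DataError(f"validation report not found: {path}") from None


# ---------------------------------------------------------------------------
# module serialization
# ---------------------------------------------------------------------------

def write_modules_tsv(modules, path) -> None:
    rows = [
        {
            "module_id": m.module_id,
            "type": m.kind,
            "effector": ";".join(m.effectors),
            "regulators": ";".join(m.regulators),
            "targets": ";".join(m.targets),
        }
        for m in modules
    ]
    pd.DataFrame(rows, columns=["module_id", "type", "effector", "regulators", "targets"]).to_csv(
        path, sep="\t", index=False
    )


def write_modules_json(modules, path) -> None:
    payload = [
        {
            "module_id": m.module_id,
            "type": m.kind,
            "effectors": list(m.effectors),
            "regulators": list(m.regulators),
            "targets": list(m.targets),
        }
        for m in modules
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_modules_json(path):
    from .discovery import AssociationModule

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return [
        AssociationModule(
            module_id=m["module_id"],
            kind=m["type"],
            effectors=list(m["effectors"]),
            regulators=list(m["regulators"]),
            targets=list(m["targets"]),
        )
        for m in payload
    ]
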