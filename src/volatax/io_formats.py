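"""Reading and writing of peak tables, sample metadata and dichotomous keys.

Canonical interchange formats (all plain text, UTF-8):

* Peak table — wide CSV/TSV: one row per compound, first column
  ``compound_id``, optional annotation columns ``rt_min``, ``name``,
  ``class``, then one numeric column per sample.
* Sample metadata — CSV with columns ``sample_id``, ``replicate_group``,
  ``group_label`` and optional ``is_outgroup``, ``host_plant``, ``location``.
* Dichotomous key — versioned JSON (``schema_version`` field).

Missing abundance cells are read as zeros (not-detected semantics) and the
number of imputed cells is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    ConsistencyError,
    FormatError,
    SchemaVersionError,
)

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("rt_min", "name", "class")

KEY_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakTable:
    """Nonnegative compound × sample abundance matrix with annotations.

    Parameters
    ----------
    compound_ids : sequence of str
        Ordered, unique compound labels (matrix rows).
    sample_ids : sequence of str
        Ordered, unique sample labels (matrix columns).
    abundances : ndarray of shape (n_compounds, n_samples)
        Nonnegative intensities in arbitrary units.
    annotations : pandas.DataFrame, optional
        Indexed by compound id; any of the columns ``rt_min`` (minutes,
        nonnegative), ``name``, ``class``.
    """

    compound_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    abundances: np.ndarray
    annotations: pd.DataFrame | None = None

    def __post_init__(self):
        compounds = tuple(str(c) for c in self.compound_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "compound_ids", compounds)
        object.__setattr__(self, "sample_ids", samples)
        values = np.asarray(self.abundances, dtype=float)
        if values.shape != (len(compounds), len(samples)):
            raise FormatError(
                f"abundance matrix shape {values.shape} does not match "
                f"{len(compounds)} compounds x {len(samples)} samples"
            )
        dup = _duplicates(compounds)
        if dup:
            raise FormatError(f"duplicate compound ids: {sorted(dup)}")
        dup = _duplicates(samples)
        if dup:
            raise FormatError(f"duplicate sample ids: {sorted(dup)}")
        if not np.all(np.isfinite(values)):
            raise FormatError("abundances contain non-finite values")
        if (values < 0).any():
            rows, cols = np.nonzero(values < 0)
            raise FormatError(
                f"negative abundance at compound {compounds[rows[0]]!r}, "
                f"sample {samples[cols[0]]!r}"
            )
        values.setflags(write=False)
        object.__setattr__(self, "abundances", values)
        if self.annotations is not None:
            ann = self.annotations
            if "rt_min" in ann.columns:
                rt = pd.to_numeric(ann["rt_min"], errors="coerce")
                if (rt.dropna() < 0).any():
                    raise FormatError("negative retention time in annotations")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundances, index=list(self.compound_ids),
            columns=list(self.sample_ids),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "PeakTable":
        keep = [self.sample_ids.index(s) for s in sample_ids]
        return replace(
            self,
            sample_ids=tuple(sample_ids),
            abundances=self.abundances[:, keep].copy(),
        )

    def subset_compounds(self, compound_ids: Sequence[str]) -> "PeakTable":
        keep = [self.compound_ids.index(c) for c in compound_ids]
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[
                [c for c in compound_ids if c in self.annotations.index]
            ]
        return replace(
            self,
            compound_ids=tuple(compound_ids),
            abundances=self.abundances[keep, :].copy(),
            annotations=ann,
        )

    def equals(self, other: "PeakTable", atol: float = 0.0) -> bool:
        return (
            self.compound_ids == other.compound_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.abundances, other.abundances, atol=atol, rtol=0)
        )


@dataclass(frozen=True)
class SampleTable:
    """Per-sample metadata: replicate structure and a-priori grouping."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "replicate_group", "group_label")
    OPTIONAL = ("is_outgroup", "host_plant", "location")

    def __post_init__(self):
        df = self.table.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"sample metadata is missing columns: {missing}")
        for col in self.REQUIRED:
            df[col] = df[col].astype(str)
        if "is_outgroup" not in df.columns:
            df["is_outgroup"] = False
        df["is_outgroup"] = df["is_outgroup"].map(_to_bool)
        for col in ("host_plant", "location"):
            if col not in df.columns:
                df[col] = None
        dup = _duplicates(df["sample_id"].tolist())
        if dup:
            raise FormatError(f"duplicate sample ids in metadata: {sorted(dup)}")
        spans = df.groupby("replicate_group")["group_label"].nunique()
        bad = spans[spans > 1].index.tolist()
        if bad:
            raise ConsistencyError(
                f"replicate groups spanning multiple group labels: {bad}"
            )
        df = df.reset_index(drop=True)
        object.__setattr__(self, "table", df)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.table["sample_id"])

    def group_of_sample(self, variable: str = "group_label") -> dict[str, str]:
        """Map sample id -> grouping value (``group_label`` or ``host_plant``)."""
        if variable not in self.table.columns:
            raise ConsistencyError(f"unknown grouping variable {variable!r}")
        col = self.table[variable]
        if col.isna().any():
            bad = self.table.loc[col.isna(), "sample_id"].tolist()
            raise ConsistencyError(
                f"samples without a value for {variable!r}: {bad}"
            )
        return dict(zip(self.table["sample_id"], col.astype(str)))

    def replicate_group_of_sample(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["replicate_group"]))

    def outgroup_labels(self) -> set[str]:
        mask = self.table["is_outgroup"]
        return set(self.table.loc[mask, "group_label"])

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        df = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleTable(df)


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _to_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"1", "true", "yes", "t"}:
        return True
    if text in {"0", "false", "no", "f", "", "nan", "none"}:
        return False
    raise FormatError(f"cannot interpret {value!r} as a boolean")


# ---------------------------------------------------------------------------
# Peak table I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_peak_table(path, layout: str = "wide") -> PeakTable:
    """Read a wide-format peak table (compounds as rows, samples as columns).

    Blank cells become 0; the count of imputed cells is logged at WARNING
    level. Annotation columns ``rt_min``/``name``/``class``, when present,
    must directly follow ``compound_id``.
    """
    if layout != "wide":
        raise ConfigurationError(
            f"unsupported peak-table layout {layout!r}; use 'wide'"
        )
    path = Path(path)
    if not path.exists():
        raise FormatError(f"peak table not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 1 or df.columns[0] in ("", None):
        raise FormatError(f"{path}: first column must be compound_id")
    first = df.columns[0]
    df = df.rename(columns={first: "compound_id"})
    ann_cols = []
    for col in df.columns[1:]:
        if col in ANNOTATION_COLUMNS:
            ann_cols.append(col)
        else:
            break
    sample_cols = [c for c in df.columns[1 + len(ann_cols):]]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns found")
    compounds = df["compound_id"].astype(str).tolist()
    dup = _duplicates(compounds)
    if dup:
        raise FormatError(f"{path}: duplicate compound ids: {sorted(dup)}")
    raw = df[sample_cols]
    n_missing = int(raw.isna().sum().sum())
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.any().any():
        r, c = np.nonzero(bad.to_numpy())
        raise FormatError(
            f"{path}: non-numeric abundance at compound {compounds[r[0]]!r}, "
            f"sample {sample_cols[c[0]]!r}"
        )
    if n_missing:
        logger.warning("%s: %d missing abundance cells set to 0", path, n_missing)
    matrix = values.fillna(0.0).to_numpy(dtype=float)
    neg = matrix < 0
    if neg.any():
        r, c = np.nonzero(neg)
        raise FormatError(
            f"{path}: negative abundance at compound {compounds[r[0]]!r}, "
            f"sample {sample_cols[c[0]]!r}"
        )
    annotations = None
    if ann_cols:
        annotations = df[["compound_id", *ann_cols]].set_index("compound_id")
        if "rt_min" in annotations.columns:
            annotations["rt_min"] = pd.to_numeric(annotations["rt_min"])
    return PeakTable(
        compound_ids=tuple(compounds),
        sample_ids=tuple(sample_cols),
        abundances=matrix,
        annotations=annotations,
    )


def write_peak_table(pt: PeakTable, path) -> None:
    path = Path(path)
    df = pt.to_dataframe()
    if pt.annotations is not None:
        ann = pt.annotations.reindex(list(pt.compound_ids))
        df = pd.concat([ann, df], axis=1)
    df.index.name = "compound_id"
    df.to_csv(path, sep=_sep_for(path))


def read_sample_metadata(path) -> SampleTable:
    """Read and validate sample metadata CSV; ``is_outgroup`` defaults false."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"sample metadata not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    return SampleTable(df)


def write_sample_metadata(st: SampleTable, path) -> None:
    st.table.to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Dichotomous key I/O (JSON, versioned)
# ---------------------------------------------------------------------------

def write_key(key, path) -> None:
    """Serialize a :class:`~volatax.biomarkers.DichotomousKey` to JSON."""
    payload = {
        "schema_version": KEY_SCHEMA_VERSION,
        "taxa": [
            {
                "taxon": t.taxon,
                "eb": [[c, float(l)] for c, l in t.eb],
                "seb": [[c, float(l)] for c, l in t.seb],
                "provenance": list(t.provenance),
            }
            for t in key.taxa
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_key(path):
    """Read a dichotomous key written by :func:`write_key` (lossless)."""
    from .biomarkers import DichotomousKey, KeyTaxon

    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    version = payload.get("schema_version")
    if version != KEY_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{path}: key schema_version {version!r} is not supported "
            f"(expected {KEY_SCHEMA_VERSION})"
        )
    taxa = [
        KeyTaxon(
            taxon=entry["taxon"],
            eb=tuple((c, float(l)) for c, l in entry["eb"]),
            seb=tuple((c, float(l)) for c, l in entry["seb"]),
            provenance=tuple(entry.get("provenance", ())),
        )
        for entry in payload["taxa"]
    ]
    return DichotomousKey(taxa=tuple(taxa))
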