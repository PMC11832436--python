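"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices travel as TSV (genes in rows, first column the gene id),
sample metadata as CSV, gene sets as GMT, and evidence/target panels as
two-column TSV.  Gene identifiers are opaque, case-sensitive strings; an
optional alias map may be applied explicitly at load time, never implicitly.
Missing metadata is encoded as an empty field and never imputed.

All writers emit ``#``-prefixed comment header lines (timestamp / seed) that
the paired readers skip, and every reader validates the invariants of its
in-memory type (non-negative expression, unique identifiers, score ranges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from fgf21cohort.errors import ParseError

logger = logging.getLogger("fgf21cohort")

#: allowed metadata score ranges (inclusive); NAS is the sum of the first three
SCORE_RANGES = {
    "steatosis": (0, 3),
    "lobular_inflammation": (0, 3),
    "ballooning": (0, 2),
    "nas": (0, 8),
    "fibrosis": (0, 4),
}

METADATA_COLUMNS = [
    "sample_id",
    "group",
    "sex",
    "steatosis",
    "lobular_inflammation",
    "ballooning",
    "nas",
    "fibrosis",
    "study_id",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional description and a category tag.

    Categories mirror how the sets are used downstream: ``pathway`` sets are
    filtered on \\|NES\\| > 1, ``immune_marker`` sets (LM22-style) on the signed
    NES > 1 rule, ``matrisome`` and ``target_panel`` sets are used for
    annotation and overlap arithmetic.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    category: str = "pathway"

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def _comment_header(seed: int | None = None) -> str:
    import datetime

    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    line = f"# fgf21cohort output; written {stamp}"
    if seed is not None:
        line += f"; seed={seed}"
    return line + "\n"


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, alias_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a genes x samples expression TSV into a validated DataFrame.

    The first column holds gene ids, the header row sample ids.  Values must
    be non-negative, finite, and complete; duplicate gene or sample ids and
    ragged rows are errors.  ``alias_map`` (old id -> new id), when given, is
    applied before the duplicate check.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: malformed expression TSV: {exc}") from exc
    if alias_map:
        frame.index = [alias_map.get(g, g) for g in frame.index]
    frame.index = frame.index.astype(str)
    frame.index.name = "gene_id"
    dupes = frame.index[frame.index.duplicated()].unique()
    if len(dupes):
        raise ParseError(f"{path}: duplicated gene id(s): {', '.join(map(str, dupes))}")
    if frame.columns.duplicated().any():
        raise ParseError(f"{path}: duplicated sample id(s)")
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = frame.index[np.isnan(values).any(axis=1)][0]
        raise ParseError(f"{path}: missing value(s), first at gene {bad!r}")
    if (values < 0).any():
        bad = frame.index[(values < 0).any(axis=1)][0]
        raise ParseError(f"{path}: negative value(s), first at gene {bad!r}")
    return frame.astype(float)


def write_expression(frame: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a genes x samples matrix as TSV with a comment header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment_header(seed))
        frame.to_csv(fh, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def _validate_metadata(meta: pd.DataFrame, origin: str) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"{origin}: missing metadata column(s): {', '.join(missing)}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{origin}: duplicated sample id {dupes!r}")
    bad_group = set(meta["group"].dropna()) - {"control", "patient"}
    if bad_group:
        raise ParseError(f"{origin}: unknown group value(s): {sorted(bad_group)}")
    bad_sex = set(meta["sex"].dropna()) - {"F", "M", "unknown"}
    if bad_sex:
        raise ParseError(f"{origin}: unknown sex value(s): {sorted(bad_sex)}")
    for col, (lo, hi) in SCORE_RANGES.items():
        vals = pd.to_numeric(meta[col], errors="coerce")
        out = vals.dropna()[(vals.dropna() < lo) | (vals.dropna() > hi)]
        if len(out):
            raise ParseError(
                f"{origin}: {col} value {out.iloc[0]} outside [{lo}, {hi}]"
            )
        meta[col] = vals
    comp = meta[["steatosis", "lobular_inflammation", "ballooning", "nas"]]
    complete = comp.notna().all(axis=1)
    if complete.any():
        mismatch = complete & (
            comp.loc[:, ["steatosis", "lobular_inflammation", "ballooning"]].sum(axis=1)
            != comp["nas"]
        )
        if mismatch.any():
            sid = meta.loc[mismatch, "sample_id"].iloc[0]
            raise ParseError(f"{origin}: NAS != component sum for sample {sid!r}")
    return meta.set_index("sample_id", drop=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-sample clinical covariate table (CSV)."""
    path = Path(path)
    meta = pd.read_csv(path, comment="#", dtype={"sample_id": str, "study_id": str})
    return _validate_metadata(meta, str(path))


def write_metadata(meta: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment_header(seed))
        meta.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, category: str = "pathway") -> GeneSetCollection:
    """Read a GMT file: per line, tab-separated name, description, members.

    Duplicate members within a set are deduplicated with a logged warning;
    lines with fewer than three fields are a parse error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has <3 fields")
            name, description, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning("%s:%d: set %r lists duplicate members; deduplicated",
                               path, lineno, name)
            sets[name] = deduped
            descriptions[name] = description
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return GeneSetCollection(sets=sets, descriptions=descriptions, category=category)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# evidence / target panels (two-column TSV)
# ---------------------------------------------------------------------------

def read_evidence_table(path: str | Path) -> pd.DataFrame:
    """Read a two-column TSV of (gene id, source tag) evidence entries."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", header=None,
                        names=["gene_id", "source"], dtype=str)
    if frame["gene_id"].isna().any() or frame["source"].isna().any():
        raise ParseError(f"{path}: evidence table requires two fields per line")
    return frame


def write_evidence_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame[["gene_id", "source"]].to_csv(path, sep="\t", index=False, header=False)


def write_table(frame: pd.DataFrame, path: str | Path, seed: int | None = None,
                index: bool = False) -> None:
    """Write a generic result table as TSV with a comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment_header(seed))
        frame.to_csv(fh, sep="\t", index=index)


def setup_logging(level: str = "INFO") -> None:
    """Timestamped logging to standard error."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        force=True,
    )


def genes_from_iterable(genes: Iterable[str]) -> list[str]:
    """Deduplicate while preserving order (helper for master-list unions)."""
    return list(dict.fromkeys(genes))
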