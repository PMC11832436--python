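"""Regulator recurrence filtering and cross-species target validation.

A candidate transcriptional regulator is retained only when the same
direction of regulation (per-patient signed-FC call at the 1.5 threshold)
recurs in at least ``min_patients`` (default 10) patients of a stratum; the
rule is evaluated per direction per stratum by default, with an option to
pool the up/down strata.  Regulator proportions between the FGF21-up and
FGF21-down strata are compared with a 2x2 Williams-corrected independence
G-test at the two-way corrected alpha (.025).

The target ledger holds a de-duplicated master list of experimentally
validated index-gene targets with per-evidence-set membership (synthetic
FGF21-analog treatment, transgenic and knockout models, patient-regulated
DEGs); overlap percentages are reported as 100 * |master AND evidence| /
|master| to 1 decimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fgf21cohort.io import genes_from_iterable
from fgf21cohort.stats import AlphaPolicy, GTestResult, g_test_independence

logger = logging.getLogger("fgf21cohort")

MIN_PATIENTS_DEFAULT = 10


def recurrence_filter(calls: pd.DataFrame, strata: pd.Series, candidates,
                      min_patients: int = MIN_PATIENTS_DEFAULT,
                      pooled: bool = False) -> pd.DataFrame:
    """Per-candidate, per-stratum counts of up/down direction calls and the
    >= ``min_patients`` recurrence pass flags.

    ``calls`` is the genes x patients {-1, 0, +1} matrix, ``strata`` the
    per-patient index-gene status.  Only the up and down strata are
    evaluated (the unchanged stratum is not a contrast of interest).  With
    ``pooled=True`` the up and down strata are merged before counting.

    Returns a long table: gene_id, stratum, n_stratum, n_up_calls,
    n_down_calls, pass_up, pass_down.
    """
    candidates = list(candidates)
    if not candidates:
        logger.warning("recurrence_filter: empty candidate list")
        return pd.DataFrame(columns=["gene_id", "stratum", "n_stratum",
                                     "n_up_calls", "n_down_calls",
                                     "pass_up", "pass_down"])
    missing = [g for g in candidates if g not in calls.index]
    if missing:
        raise KeyError(f"candidate(s) not in call matrix: {missing[:5]}")
    if pooled:
        groups = {"up+down": strata.index[strata.isin(["up", "down"])]}
    else:
        groups = {s: strata.index[strata == s] for s in ("up", "down")}
    rows = []
    for stratum, patients in groups.items():
        patients = [p for p in patients if p in calls.columns]
        sub = calls.loc[candidates, patients].to_numpy()
        n_up = (sub == 1).sum(axis=1)
        n_down = (sub == -1).sum(axis=1)
        for g, u, d in zip(candidates, n_up, n_down):
            rows.append((g, stratum, len(patients), int(u), int(d),
                         bool(u >= min_patients), bool(d >= min_patients)))
    return pd.DataFrame(rows, columns=["gene_id", "stratum", "n_stratum",
                                       "n_up_calls", "n_down_calls",
                                       "pass_up", "pass_down"])


@dataclass
class ProportionComparison:
    gene_id: str
    direction: str
    table: np.ndarray            # 2x2 (regulated, not) x (up-stratum, down-stratum)
    result: GTestResult
    alpha: float
    significant: bool


def proportion_compare(record: pd.DataFrame, gene_id: str, direction: str = "up",
                       policy: AlphaPolicy | None = None) -> ProportionComparison:
    """Compare a regulator's regulated-patient proportion between the up and
    down strata (2x2 Williams-corrected independence G-test, alpha .05/2).

    ``record`` is the long table from :func:`recurrence_filter` run
    un-pooled; ``direction`` selects which call direction is counted as
    "regulated".
    """
    if policy is None:
        policy = AlphaPolicy(n_way=2)
    col = "n_up_calls" if direction == "up" else "n_down_calls"
    sub = record[record["gene_id"] == gene_id].set_index("stratum")
    if not {"up", "down"}.issubset(sub.index):
        raise ValueError("record must contain both 'up' and 'down' strata "
                         "(run recurrence_filter with pooled=False)")
    reg = np.array([sub.loc["up", col], sub.loc["down", col]], dtype=float)
    sizes = np.array([sub.loc["up", "n_stratum"], sub.loc["down", "n_stratum"]],
                     dtype=float)
    if np.any(sizes == 0):
        raise ValueError("a stratum has size 0; proportions undefined")
    table = np.vstack([reg, sizes - reg])
    res = g_test_independence(table)
    return ProportionComparison(
        gene_id=gene_id, direction=direction, table=table, result=res,
        alpha=policy.corrected, significant=bool(res.p < policy.corrected),
    )


@dataclass
class TargetLedger:
    """Master target list plus named evidence sets.

    ``master`` is de-duplicated preserving order; ``source_tags`` maps each
    master gene to its provenance tag(s) (analog-treated, transgenic,
    knockout, ...).  ``evidence`` holds the comparison sets, e.g. the
    cross-species animal-model DEGs and the patient-regulated DEG set.
    """

    master: list[str]
    source_tags: dict[str, list[str]] = field(default_factory=dict)
    evidence: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.master:
            raise ValueError("master target list is empty")
        deduped = genes_from_iterable(self.master)
        if len(deduped) < len(self.master):
            logger.info("target ledger: removed %d duplicate master entries",
                        len(self.master) - len(deduped))
        self.master = deduped

    @classmethod
    def from_tables(cls, master_table: pd.DataFrame,
                    evidence_tables: dict[str, pd.DataFrame]) -> "TargetLedger":
        """Build from two-column (gene_id, source) tables; the master list is
        the de-duplicated union of the master table's genes."""
        tags: dict[str, list[str]] = {}
        for _, row in master_table.iterrows():
            tags.setdefault(row["gene_id"], []).append(row["source"])
        return cls(
            master=list(master_table["gene_id"]),
            source_tags=tags,
            evidence={name: set(tbl["gene_id"]) for name, tbl in evidence_tables.items()},
        )


def overlap_percentage(master, other) -> tuple[int, float]:
    """(count, percentage to 1 dp) of master genes present in ``other``;
    percentage = 100 * |A AND B| / |A| with A the master list."""
    master = genes_from_iterable(master)
    inter = sum(1 for g in master if g in set(other))
    return inter, round(100.0 * inter / len(master), 1)


def validate_targets(ledger: TargetLedger) -> pd.DataFrame:
    """Overlap report: master vs each evidence set and vs their union.

    Columns: evidence, n_master, n_evidence, n_overlap, pct_of_master.
    """
    rows = []
    union: set[str] = set()
    for name, members in ledger.evidence.items():
        union |= members
        n, pct = overlap_percentage(ledger.master, members)
        rows.append((name, len(ledger.master), len(members), n, pct))
    if len(ledger.evidence) > 1:
        n, pct = overlap_percentage(ledger.master, union)
        rows.append(("union", len(ledger.master), len(union), n, pct))
    return pd.DataFrame(rows, columns=["evidence", "n_master", "n_evidence",
                                       "n_overlap", "pct_of_master"])


def make_synthetic_ledger(n_master: int = 188,
                          overlaps: dict[str, tuple[int, int]] | None = None
                          ) -> TargetLedger:
    """Synthetic stand-in ledger built from set sizes alone.

    The study's published counts serve as inputs: a master list of
    ``n_master`` validated targets and, per evidence set, ``(n_overlap,
    n_total)`` pairs -- by default the cross-species animal-model evidence
    (87 of 188 shared, 120 genes total) and the patient-regulated DEG set
    (146 of 188 shared, 400 genes total).  Gene identifiers are synthetic
    placeholders; only the set arithmetic is meaningful.
    """
    if overlaps is None:
        overlaps = {"animal_models": (87, 120), "patients_regulated": (146, 400)}
    master = [f"T{i:04d}" for i in range(1, n_master + 1)]
    evidence: dict[str, set[str]] = {}
    extra = 0
    for name, (n_overlap, n_total) in overlaps.items():
        if n_overlap > n_master or n_overlap > n_total:
            raise ValueError(f"overlap for {name!r} exceeds set sizes")
        members = set(master[:n_overlap])
        fillers = [f"X{extra + i:04d}" for i in range(n_total - n_overlap)]
        extra += len(fillers)
        evidence[name] = members | set(fillers)
    return TargetLedger(master=master,
                        source_tags={g: ["synthetic"] for g in master},
                        evidence=evidence)
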