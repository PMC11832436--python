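"""Per-patient signed fold changes and index-gene stratification.

Fold changes are expressed in the signed convention used throughout: a ratio
r >= 1 is reported as +r, a ratio r < 1 as -1/r, so that "-1.5" means
1.5-fold down and |FC| >= 1 always.  Each patient is compared against a
pooled control reference (per-gene mean of the control samples on the linear
scale); patients whose index-gene signed FC reaches +-threshold (inclusive,
default 1.5) are classified up / down, the remainder unchanged.

The same machinery yields the full gene x patient direction-call matrix of
{-1, 0, +1} used by the regulator recurrence filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default signed-FC magnitude assigned when a patient value is exactly 0
ZERO_VALUE_CAP = 64.0


@dataclass
class ControlReference:
    """Per-gene central value of the control samples (linear scale).

    Genes whose reference is 0 (all-zero controls) are excluded from FC
    computation and listed in ``excluded_genes``.
    """

    values: pd.Series
    n_controls: int
    excluded_genes: list[str]
    method: str = "mean"


def control_reference(expression: pd.DataFrame, meta: pd.DataFrame,
                      method: str = "mean") -> ControlReference:
    """Compute the per-gene control central value.

    ``method`` is the arithmetic ``"mean"`` on the linear scale by default;
    ``"geometric"`` is offered for log-symmetric data.
    """
    controls = meta.index[meta["group"] == "control"]
    controls = [s for s in controls if s in expression.columns]
    if len(controls) == 0:
        raise ValueError("no control samples in metadata/expression overlap")
    if len(controls) < 2:
        raise ValueError("need >= 2 control samples for a reference")
    sub = expression[controls]
    if method == "mean":
        ref = sub.mean(axis=1)
    elif method == "geometric":
        with np.errstate(divide="ignore"):
            ref = np.exp(np.log(sub.where(sub > 0)).mean(axis=1)).fillna(0.0)
    else:
        raise ValueError(f"unknown reference method {method!r}")
    excluded = list(ref.index[ref <= 0])
    ref = ref[ref > 0]
    return ControlReference(values=ref, n_controls=len(controls),
                            excluded_genes=excluded, method=method)


def signed_fc(patient_value, reference_value, zero_cap: float = ZERO_VALUE_CAP):
    """Signed fold change of ``patient_value`` against ``reference_value``.

    r = patient/reference; returns +r when r >= 1 else -1/r.  A patient value
    of exactly 0 maps to the capped sentinel -``zero_cap`` rather than -inf.
    Accepts scalars or arrays.
    """
    patient = np.asarray(patient_value, dtype=float)
    reference = np.asarray(reference_value, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference value(s) must be > 0")
    if np.any(patient < 0):
        raise ValueError("patient value(s) must be >= 0")
    with np.errstate(divide="ignore"):
        r = patient / reference
        out = np.where(r >= 1.0, r, -1.0 / r)
    out = np.where(patient == 0, -abs(zero_cap), out)
    if np.isscalar(patient_value) and np.isscalar(reference_value):
        return float(out)
    return out


def fc_matrix(expression: pd.DataFrame, reference: ControlReference,
              samples=None, zero_cap: float = ZERO_VALUE_CAP) -> pd.DataFrame:
    """Signed-FC matrix (genes x samples) against the control reference;
    reference-excluded genes are absent from the result."""
    genes = reference.values.index.intersection(expression.index)
    cols = expression.columns if samples is None else list(samples)
    values = signed_fc(
        expression.loc[genes, cols].to_numpy(),
        reference.values[genes].to_numpy()[:, None],
        zero_cap=zero_cap,
    )
    return pd.DataFrame(values, index=genes, columns=cols)


def classify_index_status(fc, threshold: float = 1.5):
    """Map signed FC(s) to 'up' / 'down' / 'unchanged'; boundaries inclusive
    (the observed up-range starts exactly at +1.5)."""
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    arr = np.asarray(fc, dtype=float)
    labels = np.where(arr >= threshold, "up",
                      np.where(arr <= -threshold, "down", "unchanged"))
    if np.isscalar(fc):
        return str(labels)
    return labels


@dataclass
class StratificationResult:
    """Per-patient index-gene status plus the stratum count triple."""

    status: pd.Series                 # patient id -> label
    fc: pd.Series                     # patient id -> index-gene signed FC
    threshold: float
    index_gene: str

    @property
    def counts(self) -> dict[str, int]:
        vc = self.status.value_counts()
        return {k: int(vc.get(k, 0)) for k in ("up", "down", "unchanged")}


def stratify(expression: pd.DataFrame, meta: pd.DataFrame, index_gene: str = "FGF21",
             threshold: float = 1.5, reference: ControlReference | None = None
             ) -> StratificationResult:
    """Classify every patient by index-gene signed FC against the pooled
    control reference."""
    if index_gene not in expression.index:
        raise KeyError(f"index gene {index_gene!r} not in expression matrix")
    if reference is None:
        reference = control_reference(expression, meta)
    if index_gene not in reference.values.index:
        raise ValueError(f"index gene {index_gene!r} excluded (zero control reference)")
    patients = [s for s in meta.index[meta["group"] == "patient"]
                if s in expression.columns]
    fc = pd.Series(
        signed_fc(expression.loc[index_gene, patients].to_numpy(),
                  reference.values[index_gene]),
        index=patients, name="index_fc",
    )
    status = pd.Series(classify_index_status(fc.to_numpy(), threshold),
                       index=patients, name="status")
    return StratificationResult(status=status, fc=fc, threshold=threshold,
                                index_gene=index_gene)


def direction_calls(expression: pd.DataFrame, reference: ControlReference,
                    meta: pd.DataFrame, threshold: float = 1.5) -> pd.DataFrame:
    """Genes x patients matrix of direction calls in {-1, 0, +1}.

    +1 iff signed FC >= +threshold, -1 iff <= -threshold, else 0.  Genes
    excluded from the reference are absent.
    """
    patients = [s for s in meta.index[meta["group"] == "patient"]
                if s in expression.columns]
    fcs = fc_matrix(expression, reference, samples=patients)
    calls = np.zeros(fcs.shape, dtype=np.int8)
    calls[fcs.to_numpy() >= threshold] = 1
    calls[fcs.to_numpy() <= -threshold] = -1
    return pd.DataFrame(calls, index=fcs.index, columns=fcs.columns)
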