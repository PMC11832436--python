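"""Weighted Kolmogorov-Smirnov gene-set enrichment with permutation NES.

Genes are ranked by a real-valued score (signed fold change or test
statistic), descending, with ties broken deterministically by gene id.  The
running sum increments at set members ("hits") by |score|^weight normalised
over the set's hit scores and decrements at non-members by 1/(N - N_h); the
enrichment score ES is the signed maximum deviation of this walk.  NES is
calibrated against gene-label permutations: obs ES divided by the mean |ES|
of same-sign permutations, with an add-one-smoothed permutation p value.

Two pass rules are computed per set: |NES| > 1 with p < .05 (used for
pathway collections) and signed NES > 1 with p < .05 (used for immune-cell
marker panels); the applicable one is selected by the collection's category
tag.  Matrisome-style categorical panels are handled by simple membership
annotation rather than enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fgf21cohort.errors import EmptyOverlapError, FullCoverageError
from fgf21cohort.io import GeneSetCollection

P_THRESHOLD = 0.05
NES_THRESHOLD = 1.0


def rank_genes(scores: pd.Series) -> pd.Series:
    """Order genes by score descending, ties broken by gene id ascending.

    Returns the reordered score Series (strictly ordered ranking).
    """
    if scores.index.duplicated().any():
        raise ValueError("duplicate genes in ranking scores")
    frame = scores.rename("score").rename_axis("gene_id").reset_index()
    frame = frame.sort_values(["score", "gene_id"], ascending=[False, True],
                              kind="stable")
    return frame.set_index("gene_id")["score"]


def enrichment_score(ranked: pd.Series, gene_set, weight: float = 1.0
                     ) -> tuple[float, np.ndarray]:
    """ES and the full running sum for one gene set against a ranked list.

    ``ranked`` is a descending score Series as produced by
    :func:`rank_genes`.  The set must overlap the ranked universe and must
    not cover it entirely.
    """
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    hit = np.isin(genes, list(gene_set))
    n = len(genes)
    n_h = int(hit.sum())
    if n_h == 0:
        raise EmptyOverlapError("gene set has no overlap with the ranked list")
    if n_h == n:
        raise FullCoverageError("gene set covers the entire ranked list")

    weights = np.abs(scores[hit]) ** weight
    total = weights.sum()
    steps = np.full(n, -1.0 / (n - n_h))
    if total > 0:
        steps[hit] = weights / total
    else:  # all hit scores zero: fall back to equal hit increments
        steps[hit] = 1.0 / n_h
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


@dataclass
class EnrichmentResult:
    """Per-set enrichment outcome and the two NES pass rules."""

    name: str
    size: int                    # overlap with the ranked universe
    es: float
    nes: float
    p: float
    n_perm: int
    pass_abs: bool               # p < .05 and |NES| > 1
    pass_signed: bool            # p < .05 and NES > 1
    note: str = ""


def nes_and_p(obs_es: float, ranked: pd.Series, gene_set, n_perm: int = 1000,
              seed: int | np.random.Generator = 0, weight: float = 1.0,
              name: str = "") -> EnrichmentResult:
    """Permutation-calibrated NES and p for an observed enrichment score.

    Gene-label permutation null: each permutation assigns the set to a
    uniformly random subset of ranked positions of the same overlap size.
    NES = obs ES / mean(|permutation ES| of the same sign); p uses add-one
    smoothing over same-sign permutations.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    n = len(genes)
    k = int(np.isin(genes, list(gene_set)).sum())
    if k == 0:
        raise EmptyOverlapError("gene set has no overlap with the ranked list")
    if k == n:
        raise FullCoverageError("gene set covers the entire ranked list")

    # vectorised permutation walks
    positions = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
    abs_w = np.abs(scores) ** weight
    hit_w = abs_w[positions]
    totals = hit_w.sum(axis=1, keepdims=True)
    steps = np.full((n_perm, n), -1.0 / (n - k))
    rows = np.repeat(np.arange(n_perm), k)
    flat_pos = positions.ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        inc = np.where(totals > 0, hit_w / totals, 1.0 / k)
    steps[rows, flat_pos] = inc.ravel()
    walks = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(walks), axis=1)
    perm_es = walks[np.arange(n_perm), idx]

    obs_sign = 1.0 if obs_es >= 0 else -1.0
    same = perm_es * obs_sign > 0
    n_same = int(same.sum())
    if n_same == 0 or obs_es == 0:
        return EnrichmentResult(
            name=name, size=k, es=obs_es, nes=float("nan"), p=1.0,
            n_perm=n_perm, pass_abs=False, pass_signed=False,
            note="no same-sign permutation ES; NES undefined",
        )
    mean_abs = np.abs(perm_es[same]).mean()
    nes = obs_es / mean_abs
    p = (1 + int((np.abs(perm_es[same]) >= abs(obs_es)).sum())) / (1 + n_same)
    return EnrichmentResult(
        name=name, size=k, es=obs_es, nes=float(nes), p=float(p), n_perm=n_perm,
        pass_abs=bool(p < P_THRESHOLD and abs(nes) > NES_THRESHOLD),
        pass_signed=bool(p < P_THRESHOLD and nes > NES_THRESHOLD),
    )


def enrich_collection(scores: pd.Series, collection: GeneSetCollection,
                      weight: float = 1.0, n_perm: int = 1000, seed: int = 0
                      ) -> pd.DataFrame:
    """Run ES/NES/p for every set in a collection against one ranking.

    Sets with no overlap are reported with a diagnostic note rather than
    raising, so one stray panel does not abort a batch run.  The ``applicable``
    pass flag follows the collection category: signed NES > 1 for
    ``immune_marker`` panels, |NES| > 1 otherwise.
    """
    ranked = rank_genes(scores)
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in collection.items():
        try:
            es, _ = enrichment_score(ranked, members, weight=weight)
            res = nes_and_p(es, ranked, members, n_perm=n_perm, seed=rng,
                            weight=weight, name=name)
        except EmptyOverlapError:
            res = EnrichmentResult(name=name, size=0, es=float("nan"),
                                   nes=float("nan"), p=float("nan"),
                                   n_perm=n_perm, pass_abs=False,
                                   pass_signed=False, note="empty overlap")
        rows.append(res)
    frame = pd.DataFrame([r.__dict__ for r in rows])
    signed = collection.category == "immune_marker"
    frame["applicable_pass"] = frame["pass_signed"] if signed else frame["pass_abs"]
    return frame.set_index("name", drop=False)


def marker_enrichment(deg_ranking: pd.Series, marker_sets: GeneSetCollection,
                      weight: float = 1.0, n_perm: int = 1000, seed: int = 0
                      ) -> pd.DataFrame:
    """Immune-cell marker enrichment (LM22-style): signed NES > 1 rule.

    Both flags are reported; ``applicable_pass`` is the signed rule.
    """
    if marker_sets.category != "immune_marker":
        raise ValueError("marker_sets must be tagged category='immune_marker'")
    return enrich_collection(deg_ranking, marker_sets, weight=weight,
                             n_perm=n_perm, seed=seed)


def annotate_panels(genes, panels: GeneSetCollection) -> tuple[pd.DataFrame, pd.Series]:
    """Map each gene to the categorical panel(s) containing it.

    Returns (per-gene annotation table with a semicolon-joined ``panels``
    column, 'unannotated' when in none; per-panel membership counts over the
    queried genes).  Counts sum to the number of (gene, panel) memberships.
    """
    genes = list(genes)
    membership = {name: set(members) for name, members in panels.items()}
    labels = []
    counts = {name: 0 for name in membership}
    for g in genes:
        hits = [name for name, members in membership.items() if g in members]
        for h in hits:
            counts[h] += 1
        labels.append(";".join(hits) if hits else "unannotated")
    annotation = pd.DataFrame({"gene_id": genes, "panels": labels}).set_index(
        "gene_id", drop=False
    )
    return annotation, pd.Series(counts, name="n_genes")
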