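"""Seeded synthetic MASLD-cohort generator with ground-truth labels.

The generator emulates the statistical structure the downstream analysis
assumes: a pool of healthy controls plus patients carrying a planted index-gene
stratum (FGF21 up / down / unchanged), planted differentially expressed gene
programs with per-stratum directions and effect sizes, covariate-linked
histology scores (NAS components and fibrosis), and multiplicative log-normal
noise.  Defaults mirror the study conditions: 66 controls against 396 patients
split (117, 159, 120), index-gene signed fold changes spanning 1.5 to 21.3
(up) and -1.5 to -7.5 (down).

Expression is generated on the log2 scale -- per-gene control baselines drawn
uniformly on log2 [3, 10], additive Gaussian noise, planted log2 shifts -- and
exponentiated to linear intensities, so fold-change semantics are exact in the
noise-free limit.  A single integer seed fixes every random draw; identical
configurations produce bitwise-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fgf21cohort.errors import ConfigurationError
from fgf21cohort.io import (
    GeneSetCollection,
    write_expression,
    write_gmt,
    write_metadata,
    write_table,
)

STRATA = ("up", "down", "unchanged")

#: ordinal-score supports
SCORE_LEVELS = {
    "steatosis": 4,             # 0-3
    "lobular_inflammation": 4,  # 0-3
    "ballooning": 3,            # 0-2
    "fibrosis": 5,              # 0-4
}


@dataclass(frozen=True)
class ProgramSpec:
    """A planted DEG program: ``n_genes`` genes shifted by ``direction`` *
    log2(``effect_fc``) in patients of ``stratum`` only."""

    name: str
    stratum: str
    direction: int
    effect_fc: float
    n_genes: int

    def __post_init__(self):
        if self.stratum not in STRATA:
            raise ConfigurationError(f"unknown stratum {self.stratum!r}")
        if self.direction not in (-1, 1):
            raise ConfigurationError("program direction must be -1 or +1")
        if self.effect_fc < 1:
            raise ConfigurationError("effect_fc is a ratio >= 1")
        if self.n_genes < 1:
            raise ConfigurationError("program needs >= 1 gene")


def default_programs() -> tuple[ProgramSpec, ...]:
    """Planted programs loosely shaped after the biology under study:
    autophagy and OXPHOS induced, complement repressed with high FGF21;
    fibrosis/ECM induced, lipid transport repressed with low FGF21."""
    return (
        ProgramSpec("autophagy", "up", +1, 2.5, 30),
        ProgramSpec("oxphos", "up", +1, 2.0, 40),
        ProgramSpec("complement", "up", -1, 2.0, 25),
        ProgramSpec("matrisome_fibrosis", "down", +1, 2.5, 35),
        ProgramSpec("lipid_transport", "down", -1, 2.0, 30),
    )


def default_covariate_model() -> dict[str, dict[str, list[float]]]:
    """Stratum-specific categorical score distributions.

    Chosen so the down-stratum carries higher fibrosis and inflammation and
    the up-stratum is depleted for inflammation score 3 -- the direction of
    the clinical table, without matching its values.
    """
    return {
        "up": {
            "steatosis": [0.05, 0.30, 0.38, 0.27],
            "lobular_inflammation": [0.12, 0.60, 0.22, 0.06],
            "ballooning": [0.33, 0.32, 0.35],
            "fibrosis": [0.28, 0.32, 0.22, 0.12, 0.06],
        },
        "down": {
            "steatosis": [0.05, 0.37, 0.22, 0.36],
            "lobular_inflammation": [0.30, 0.25, 0.20, 0.25],
            "ballooning": [0.45, 0.15, 0.40],
            "fibrosis": [0.15, 0.20, 0.25, 0.22, 0.18],
        },
        "unchanged": {
            "steatosis": [0.05, 0.52, 0.21, 0.22],
            "lobular_inflammation": [0.24, 0.50, 0.17, 0.09],
            "ballooning": [0.39, 0.41, 0.20],
            "fibrosis": [0.24, 0.33, 0.23, 0.12, 0.08],
        },
    }


def null_covariate_model() -> dict[str, dict[str, list[float]]]:
    """Identical score distributions in every stratum (association = 0)."""
    shared = {
        "steatosis": [0.10, 0.40, 0.28, 0.22],
        "lobular_inflammation": [0.22, 0.48, 0.19, 0.11],
        "ballooning": [0.38, 0.32, 0.30],
        "fibrosis": [0.23, 0.27, 0.23, 0.16, 0.11],
    }
    return {s: {k: list(v) for k, v in shared.items()} for s in STRATA}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic cohort.

    Signed fold-change intervals follow the +r / -1/r convention: the up
    interval must sit inside [1.5, inf), the down interval inside
    (-inf, -1.5], and the unchanged interval strictly inside (-1.5, 1.5).
    """

    n_controls: int = 66
    n_up: int = 117
    n_down: int = 159
    n_unchanged: int = 120
    n_genes: int = 2000
    index_gene: str = "FGF21"
    fc_up_range: tuple[float, float] = (1.5, 21.3)
    fc_down_range: tuple[float, float] = (-7.5, -1.5)
    fc_unchanged_range: tuple[float, float] = (-1.45, 1.45)
    program_specs: tuple[ProgramSpec, ...] = field(default_factory=default_programs)
    noise_sd: float = 0.4
    covariate_model: Mapping[str, Mapping[str, Sequence[float]]] = field(
        default_factory=default_covariate_model
    )
    sex_known_frac: float = 175 / 396
    sex_female_prob: Mapping[str, float] = field(
        default_factory=lambda: {"up": 0.59, "down": 0.23, "unchanged": 0.43}
    )
    component_known_frac: float = 162 / 396
    score_known_frac: float = 328 / 396
    seed: int = 0

    def __post_init__(self):
        for name in ("n_controls", "n_up", "n_down", "n_unchanged", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        lo, hi = self.fc_up_range
        if not (1.5 <= lo <= hi):
            raise ConfigurationError("fc_up_range must lie within [1.5, inf)")
        lo, hi = self.fc_down_range
        if not (lo <= hi <= -1.5):
            raise ConfigurationError("fc_down_range must lie within (-inf, -1.5]")
        lo, hi = self.fc_unchanged_range
        if not (-1.5 < lo <= hi < 1.5) or abs(lo) < 1 or abs(hi) < 1:
            raise ConfigurationError(
                "fc_unchanged_range must be signed FCs strictly inside (-1.5, 1.5)"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        planted = sum(p.n_genes for p in self.program_specs)
        if planted + 1 > self.n_genes:
            raise ConfigurationError(
                f"index gene + {planted} program genes exceed n_genes={self.n_genes}"
            )
        names = [p.name for p in self.program_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("program names must be unique")

    @property
    def n_patients(self) -> int:
        return self.n_up + self.n_down + self.n_unchanged

    def with_strong_effects(self) -> "SimConfig":
        """The label-recovery regime: effects pulled away from the +-1.5
        boundary and low noise, so planted strata are essentially separable."""
        return replace(
            self,
            fc_up_range=(2.5, 21.3),
            fc_down_range=(-7.5, -2.5),
            fc_unchanged_range=(-1.15, 1.15),
            noise_sd=0.15,
        )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    patient_strata: pd.Series        # patient id -> stratum label
    index_fc: pd.Series              # patient id -> planted signed FC of index gene
    gene_programs: pd.DataFrame      # gene_id, program, stratum, direction, effect_fc
    covariate_means: pd.DataFrame    # planted mean score per (stratum, covariate)

    @property
    def planted_genes(self) -> list[str]:
        return list(self.gene_programs["gene_id"])


def _signed_fc_to_log2(fc: np.ndarray) -> np.ndarray:
    """+r / -1/r signed FC -> log2 ratio."""
    fc = np.asarray(fc, dtype=float)
    return np.where(fc >= 0, np.log2(np.abs(fc)), -np.log2(np.abs(fc)))


def _draw_signed_fc(rng: np.random.Generator, fc_range: tuple[float, float],
                    n: int) -> np.ndarray:
    """Draw signed FCs log-uniformly within a signed interval."""
    lo, hi = fc_range
    llo, lhi = sorted(_signed_fc_to_log2(np.array([lo, hi])))
    lr = rng.uniform(llo, lhi, size=n)
    return np.where(lr >= 0, 2.0 ** lr, -(2.0 ** -lr))


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (expression matrix, sample metadata, truth) for one cohort.

    Control samples scatter around per-gene baselines; patient samples
    multiply the baseline by the planted signed FC (index gene, per patient)
    and by each planted program effect (program genes, per stratum), all with
    additive Gaussian noise on the log2 scale.
    """
    rng_expr = np.random.default_rng([config.seed, 0])
    rng_cov = np.random.default_rng([config.seed, 1])

    n_other = config.n_genes - 1
    gene_ids = [config.index_gene] + [f"G{i:05d}" for i in range(1, n_other + 1)]
    sample_ids = (
        [f"CTRL{i:04d}" for i in range(1, config.n_controls + 1)]
        + [f"PAT{i:04d}" for i in range(1, config.n_patients + 1)]
    )
    patient_ids = sample_ids[config.n_controls:]

    strata = np.repeat(
        np.array(STRATA, dtype=object),
        [config.n_up, config.n_down, config.n_unchanged],
    )

    # planted index-gene signed FCs per patient
    index_fc = np.empty(config.n_patients)
    for stratum, fc_range in (("up", config.fc_up_range),
                              ("down", config.fc_down_range),
                              ("unchanged", config.fc_unchanged_range)):
        mask = strata == stratum
        index_fc[mask] = _draw_signed_fc(rng_expr, fc_range, int(mask.sum()))

    # planted programs occupy disjoint gene blocks right after the index gene
    records = []
    cursor = 1
    for spec in config.program_specs:
        block = gene_ids[cursor:cursor + spec.n_genes]
        cursor += spec.n_genes
        for g in block:
            records.append((g, spec.name, spec.stratum, spec.direction, spec.effect_fc))
    gene_programs = pd.DataFrame(
        records, columns=["gene_id", "program", "stratum", "direction", "effect_fc"]
    )

    # log2 expression = baseline + planted shift + noise
    baselines = rng_expr.uniform(3.0, 10.0, size=config.n_genes)
    shifts = np.zeros((config.n_genes, config.n_patients))
    shifts[0, :] = _signed_fc_to_log2(index_fc)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for _, row in gene_programs.iterrows():
        gi = gene_index[row.gene_id]
        shifts[gi, strata == row.stratum] = row.direction * np.log2(row.effect_fc)

    n_samples = config.n_controls + config.n_patients
    log2_expr = np.tile(baselines[:, None], (1, n_samples))
    log2_expr[:, config.n_controls:] += shifts
    if config.noise_sd > 0:
        log2_expr = log2_expr + rng_expr.normal(
            0.0, config.noise_sd, size=log2_expr.shape
        )
    expression = pd.DataFrame(2.0 ** log2_expr, index=gene_ids, columns=sample_ids)
    expression.index.name = "gene_id"

    # --- metadata -----------------------------------------------------------
    meta = _draw_metadata(config, rng_cov, sample_ids, strata)

    cov_means = (
        pd.DataFrame(
            {
                cov: {
                    s: float(np.dot(np.arange(len(p)), p))
                    for s, p in ((s, config.covariate_model[s][cov]) for s in STRATA)
                }
                for cov in SCORE_LEVELS
            }
        )
        .rename_axis(index="stratum")
    )

    truth = SyntheticTruth(
        patient_strata=pd.Series(strata, index=patient_ids, name="stratum"),
        index_fc=pd.Series(index_fc, index=patient_ids, name="index_fc"),
        gene_programs=gene_programs,
        covariate_means=cov_means,
    )
    return expression, meta, truth


def _draw_metadata(config: SimConfig, rng: np.random.Generator,
                   sample_ids: list[str], strata: np.ndarray) -> pd.DataFrame:
    n_ctrl, n_pat = config.n_controls, config.n_patients
    group = ["control"] * n_ctrl + ["patient"] * n_pat

    # ordinal scores per patient from stratum-specific categorical draws
    scores = {c: np.full(n_pat, np.nan) for c in SCORE_LEVELS}
    for stratum in STRATA:
        mask = strata == stratum
        n = int(mask.sum())
        for cov, k in SCORE_LEVELS.items():
            probs = np.asarray(config.covariate_model[stratum][cov], dtype=float)
            if len(probs) != k or not np.isclose(probs.sum(), 1.0):
                raise ConfigurationError(
                    f"covariate_model[{stratum!r}][{cov!r}] must be {k} probs summing to 1"
                )
            scores[cov][mask] = rng.choice(k, size=n, p=probs)
    nas = (scores["steatosis"] + scores["lobular_inflammation"]
           + scores["ballooning"])

    # sex: known for a fraction of patients, stratum-linked female share
    sex = np.full(n_pat, "unknown", dtype=object)
    known = rng.random(n_pat) < config.sex_known_frac
    for stratum in STRATA:
        mask = known & (strata == stratum)
        p_f = config.sex_female_prob[stratum]
        sex[mask] = np.where(rng.random(int(mask.sum())) < p_f, "F", "M")
    ctrl_sex = np.where(rng.random(n_ctrl) < 0.5, "F", "M")

    # missingness: components known for a subset; NAS/fibrosis for a larger one
    comp_known = rng.random(n_pat) < config.component_known_frac
    score_known = comp_known | (rng.random(n_pat) < config.score_known_frac)
    for cov in ("steatosis", "lobular_inflammation", "ballooning"):
        scores[cov][~comp_known] = np.nan
    nas = np.where(score_known, nas, np.nan)
    scores["fibrosis"][~score_known] = np.nan

    study = np.array([f"STUDY{1 + i % 9}" for i in range(n_pat)], dtype=object)

    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group,
            "sex": np.concatenate([ctrl_sex, sex]),
            "steatosis": np.concatenate([np.full(n_ctrl, np.nan), scores["steatosis"]]),
            "lobular_inflammation": np.concatenate(
                [np.full(n_ctrl, np.nan), scores["lobular_inflammation"]]
            ),
            "ballooning": np.concatenate([np.full(n_ctrl, np.nan), scores["ballooning"]]),
            "nas": np.concatenate([np.full(n_ctrl, np.nan), nas]),
            "fibrosis": np.concatenate([np.full(n_ctrl, np.nan), scores["fibrosis"]]),
            "study_id": np.concatenate([np.full(n_ctrl, "CONTROLS", dtype=object), study]),
        }
    )
    return meta.set_index("sample_id", drop=False)


def generate_gene_sets(config: SimConfig, decoys_per_program: int = 1) -> GeneSetCollection:
    """GMT-style collection of the planted program sets plus size-matched
    decoy sets drawn from unplanted genes (guaranteed zero overlap with any
    planted DE gene or the index gene).

    Seeded from ``config.seed`` on an independent substream, so the
    collection is identical across runs and independent of whether
    :func:`generate_cohort` was called first.
    """
    if not config.program_specs:
        raise ConfigurationError("program_specs is empty; nothing to emit")
    rng = np.random.default_rng([config.seed, 2])
    n_other = config.n_genes - 1
    gene_ids = [f"G{i:05d}" for i in range(1, n_other + 1)]

    cursor = 0
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    planted_end = sum(p.n_genes for p in config.program_specs)
    unplanted = gene_ids[planted_end:]
    for spec in config.program_specs:
        block = gene_ids[cursor:cursor + spec.n_genes]
        cursor += spec.n_genes
        sets[spec.name] = block
        descriptions[spec.name] = (
            f"planted {spec.stratum}-stratum program, direction {spec.direction:+d}, "
            f"effect {spec.effect_fc}x"
        )
        for d in range(decoys_per_program):
            if spec.n_genes > len(unplanted):
                raise ConfigurationError(
                    f"decoy for {spec.name!r} needs {spec.n_genes} genes; "
                    f"only {len(unplanted)} unplanted genes available"
                )
            name = f"decoy_{spec.name}" if decoys_per_program == 1 else f"decoy_{spec.name}_{d + 1}"
            picked = rng.choice(len(unplanted), size=spec.n_genes, replace=False)
            sets[name] = [unplanted[i] for i in sorted(picked)]
            descriptions[name] = f"decoy matched to {spec.name} (no planted genes)"
    return GeneSetCollection(sets=sets, descriptions=descriptions, category="pathway")


def write_cohort(outdir: str | Path, expression: pd.DataFrame, meta: pd.DataFrame,
                 truth: SyntheticTruth, gene_sets: GeneSetCollection | None = None,
                 seed: int | None = None) -> None:
    """Write a generated cohort as expression TSV, metadata CSV, truth TSV
    and (optionally) the gene sets as GMT."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(expression, outdir / "expression.tsv", seed=seed)
    write_metadata(meta, outdir / "metadata.csv", seed=seed)
    truth_table = pd.DataFrame(
        {"stratum": truth.patient_strata, "index_fc": truth.index_fc}
    ).rename_axis("sample_id")
    write_table(truth_table, outdir / "truth_patients.tsv", seed=seed, index=True)
    write_table(truth.gene_programs, outdir / "truth_genes.tsv", seed=seed)
    if gene_sets is not None:
        write_gmt(gene_sets, outdir / "gene_sets.gmt")
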