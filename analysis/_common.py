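"""Shared setup for the numbered analysis drivers.

Every driver regenerates the same seeded synthetic cohort through the
library, so the scripts can be run independently and still agree; outputs
land under results/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from fgf21cohort.simulate import SimConfig, generate_cohort, generate_gene_sets

RESULTS = Path(__file__).resolve().parents[1] / "results"


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--out", type=Path, default=RESULTS)
    return parser.parse_args()


def study_cohort(seed: int):
    """Default study conditions: 66 controls, (117, 159, 120) patients,
    index FC ranges 1.5..21.3 / -7.5..-1.5, log2 noise 0.4."""
    config = SimConfig(seed=seed)
    return config, *generate_cohort(config)


def strong_cohort(seed: int):
    """Same sizes in the strong-effects regime (separable strata)."""
    config = SimConfig(seed=seed).with_strong_effects()
    return config, *generate_cohort(config)


def cohort_gene_sets(config):
    return generate_gene_sets(config)
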