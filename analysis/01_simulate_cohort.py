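"""Generate the synthetic study cohorts and write them to disk.

Two seeded cohorts are produced: the default-conditions cohort (66 healthy
controls, 396 patients split 117 up / 159 down / 120 unchanged for the index
gene FGF21, planted DEG programs, log2 noise 0.4) and a strong-effects
variant used for recovery analyses.  Expression, metadata, ground truth and
the planted/decoy gene sets are written under results/cohort[_strong]/.
"""

from _common import cohort_gene_sets, parse_args, strong_cohort, study_cohort

from fgf21cohort.simulate import write_cohort


def main() -> None:
    args = parse_args(__doc__)
    for label, maker in (("cohort", study_cohort), ("cohort_strong", strong_cohort)):
        config, expr, meta, truth = maker(args.seed)
        sets = cohort_gene_sets(config)
        outdir = args.out / label
        write_cohort(outdir, expr, meta, truth, gene_sets=sets, seed=args.seed)
        n_pat = config.n_patients
        print(f"{label}: {expr.shape[0]} genes x {expr.shape[1]} samples "
              f"({config.n_controls} controls, {n_pat} patients) -> {outdir}")
        print(f"  planted programs: "
              f"{', '.join(p.name for p in config.program_specs)}")


if __name__ == "__main__":
    main()
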