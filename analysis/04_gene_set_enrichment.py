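"""Weighted-KS enrichment of the stratum DEG rankings.

The up-stratum signed-FC ranking is tested against the planted program sets
and their size-matched decoys (|NES| > 1, p < .05 rule) and, re-tagged as
immune-marker style panels, under the signed NES > 1 rule.  Planted sets
should pass, decoys should not.  A small matrisome-style annotation of the
planted fibrosis program is also reported.
"""

from _common import cohort_gene_sets, parse_args, strong_cohort

from fgf21cohort.dge import call_degs
from fgf21cohort.enrichment import annotate_panels, enrich_collection
from fgf21cohort.io import GeneSetCollection, write_table
from fgf21cohort.stratify import control_reference, stratify


def main() -> None:
    args = parse_args(__doc__)
    config, expr, meta, truth = strong_cohort(args.seed)
    ref = control_reference(expr, meta)
    result = stratify(expr, meta, reference=ref)
    outdir = args.out / "enrichment"
    outdir.mkdir(parents=True, exist_ok=True)

    up = result.status.index[result.status == "up"]
    table = call_degs(expr, meta, up, ref, cohort_id="up")
    sets = cohort_gene_sets(config)
    frame = enrich_collection(table["signed_fc"], sets, n_perm=1000,
                              seed=args.seed)
    write_table(frame.drop(columns=["name"]), outdir / "pathway_enrichment.tsv",
                seed=args.seed, index=True)
    passed = list(frame.index[frame["applicable_pass"]])
    print(f"pathway rule (|NES|>1, p<.05): passing sets: {passed}")

    markers = GeneSetCollection(sets=dict(sets.sets),
                                descriptions=dict(sets.descriptions),
                                category="immune_marker")
    mframe = enrich_collection(table["signed_fc"], markers, n_perm=1000,
                               seed=args.seed)
    write_table(mframe.drop(columns=["name"]), outdir / "marker_enrichment.tsv",
                seed=args.seed, index=True)
    print(f"marker rule (NES>1, p<.05): passing sets: "
          f"{list(mframe.index[mframe['applicable_pass']])}")

    fibro = truth.gene_programs.loc[
        truth.gene_programs["program"] == "matrisome_fibrosis", "gene_id"
    ]
    panels = GeneSetCollection(
        sets={"core_matrisome": list(fibro[:20]),
              "matrisome_associated": list(fibro[20:])},
        category="matrisome",
    )
    query = list(fibro) + [g for g in expr.index if g.startswith("G")][-50:]
    annotation, counts = annotate_panels(query, panels)
    write_table(annotation, outdir / "matrisome_annotation.tsv", seed=args.seed)
    print(f"matrisome annotation counts: {counts.to_dict()}")


if __name__ == "__main__":
    main()
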