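"""Apply the >=10-patient recurrence rule to candidate regulators and
compare regulated proportions between the up and down strata.

Candidates are the planted program genes plus a tail of null genes.  A
candidate passes when the same direction call recurs in >= 10 patients of a
stratum; for each passing candidate the regulated proportion in the
FGF21-up vs FGF21-down strata is compared with the 2x2 Williams-corrected
G-test at the two-way corrected alpha (.025).
"""

import pandas as pd
from _common import parse_args, strong_cohort

from fgf21cohort.io import write_table
from fgf21cohort.stats import AlphaPolicy, round_p
from fgf21cohort.stratify import control_reference, direction_calls, stratify
from fgf21cohort.targets import proportion_compare, recurrence_filter


def main() -> None:
    args = parse_args(__doc__)
    _, expr, meta, truth = strong_cohort(args.seed)
    ref = control_reference(expr, meta)
    result = stratify(expr, meta, reference=ref)
    calls = direction_calls(expr, ref, meta)
    outdir = args.out / "regulators"
    outdir.mkdir(parents=True, exist_ok=True)

    null_tail = [g for g in expr.index if g.startswith("G")][-40:]
    candidates = list(truth.gene_programs["gene_id"]) + null_tail
    record = recurrence_filter(calls, result.status, candidates, min_patients=10)
    write_table(record, outdir / "recurrence.tsv", seed=args.seed)
    passing = record.loc[record["pass_up"] | record["pass_down"], "gene_id"].unique()
    planted = set(truth.gene_programs["gene_id"])
    print(f"{len(passing)} of {len(candidates)} candidates pass the >=10 rule "
          f"({len(set(passing) & planted)} planted, "
          f"{len(set(passing) - planted)} null)")

    policy = AlphaPolicy(n_way=2)
    rows = []
    pairs = sorted(
        {(row["gene_id"], direction)
         for _, row in record.iterrows()
         for direction, flag in (("up", "pass_up"), ("down", "pass_down"))
         if row[flag]}
    )
    for gene, direction in pairs:
        try:
            comp = proportion_compare(record, gene, direction=direction,
                                      policy=policy)
        except ValueError:  # zero margin: regulated in no/all patients
            rows.append({"gene_id": gene, "direction": direction,
                         "p": float("nan"),
                         "alpha": policy.corrected_rounded,
                         "significant": False})
            continue
        rows.append({"gene_id": gene, "direction": direction,
                     "p": round_p(comp.result.p),
                     "alpha": policy.corrected_rounded,
                     "significant": comp.significant})
    frame = pd.DataFrame(rows)
    write_table(frame, outdir / "proportion_tests.tsv", seed=args.seed)
    n_sig = int(frame["significant"].sum())
    print(f"{n_sig} (gene, direction) proportions differ between strata at "
          f"alpha = {policy.corrected_rounded}")


if __name__ == "__main__":
    main()
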