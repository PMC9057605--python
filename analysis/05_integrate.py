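#!/usr/bin/env python
"""Cross promoter methylation with differential expression (tet2kit vs kit).

Averages CpG methylation in TSS +/- 1 kb per gene and condition, bins the
tet2kit promoter means into quartiles and the tet2kit-kit difference into
hyper / hypo / stable (20-point rule), cross-tabulates both against DE
status, and associates HMRs to their nearest TSS within 50 kb. Requires
02_call_dmrs.py and 04_differential_expression.py first.
"""

import argparse

from epimast.pipeline import RunConfig, stage_integrate


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", default="results/pipeline")
    args = parser.parse_args()

    cfg = RunConfig(seed=args.seed, outdir=args.outdir)
    rep = stage_integrate(cfg)
    print(f"promoters with methylation signal: {rep['n_promoters']}")
    print("DE status x methylation delta (tet2kit - kit):")
    for status, row in rep["crosstab_delta"].items():
        print(f"  {status:5s} " + "  ".join(f"{k}={v}" for k, v in row.items()))
    if "n_hmr_associated" in rep:
        print(f"HMRs associated to a gene: {rep['n_hmr_associated']} "
              f"(promoter-overlapping: {rep['n_hmr_promoter']})")


if __name__ == "__main__":
    main()
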