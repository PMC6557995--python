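"""Cohort-subtraction burden analysis.

Derives the latent cancer cohort by subtracting the non-cancer cohort from
the general cohort, then Fisher-tests every gene's aggregate allele counts
against the control cohort (BH FDR across genes).

Writes results/burden.tsv sorted by raw p.
"""

from _common import RESULTS, require_bundle

from pedvar import cohort_burden
from pedvar.pipeline import RunConfig, _run_burden
from pedvar.variant_model import read_annotation


def main() -> None:
    bundle = require_bundle()
    cfg = RunConfig.from_yaml(bundle / "run.yaml")
    annotation = read_annotation(cfg.annotation)
    table = cohort_burden.quality_filter(cohort_burden.read_cohort_table(cfg.cohort))
    burden = _run_burden(cfg, annotation, table)
    RESULTS.mkdir(exist_ok=True)
    burden.to_csv(RESULTS / "burden.tsv", sep="\t", index=False)
    top = burden.head(5)
    print(f"{len(burden)} genes tested "
          f"({cfg.burden_cohort_a} vs {cfg.burden_cohort_b})")
    print("top hits:")
    print(top.to_string(index=False))
    n_sig = int((burden["q"] < 0.05).sum())
    print(f"\n{n_sig} gene(s) at FDR < 0.05; "
          f"top gene {burden.iloc[0]['gene']} with p = {burden.iloc[0]['p']:.3g}")
    print(f"table -> {RESULTS / 'burden.tsv'}")


if __name__ == "__main__":
    main()
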