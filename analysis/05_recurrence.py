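"""Somatic recurrence statistics for the candidate gene.

Builds the per-residue mutation spectrum from the MAF-like somatic table,
runs the windowed binomial hotspot scan (Bonferroni over residues), applies
the 20/20 oncogene/TSG rule, and tests per-cancer-type enrichment against
the pooled mutation rate (BH across types).

Writes results/hotspots.tsv, results/enrichment.tsv and
results/gene_classification.json.
"""

import json

from _common import RESULTS, require_bundle

from pedvar.pipeline import RunConfig, _run_recurrence


def main() -> None:
    bundle = require_bundle()
    cfg = RunConfig.from_yaml(bundle / "run.yaml")
    hotspots, gene_class, enrichment = _run_recurrence(cfg)
    RESULTS.mkdir(exist_ok=True)
    hotspots.to_csv(RESULTS / "hotspots.tsv", sep="\t", index=False)
    enrichment.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)
    (RESULTS / "gene_classification.json").write_text(
        json.dumps(gene_class, indent=2, sort_keys=True)
    )
    flagged = hotspots[hotspots["is_hotspot"]]
    print(f"hotspot scan over {len(hotspots)} residues "
          f"(window +/-{cfg.window_halfwidth}, alpha {cfg.hotspot_alpha}):")
    print(flagged.to_string(index=False) if len(flagged) else "  none flagged")
    print(f"\n20/20 classification: {gene_class['label']} "
          f"(oncogene fraction {gene_class['oncogene_fraction']:.3f}, "
          f"tsg fraction {gene_class['tsg_fraction']:.3f})")
    print("\nper-cancer-type enrichment:")
    print(enrichment.to_string(index=False))
    print(f"\ntables -> {RESULTS}/hotspots.tsv, enrichment.tsv, gene_classification.json")


if __name__ == "__main__":
    main()
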