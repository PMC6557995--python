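"""Generate the synthetic familial study: ten two-patient pedigrees with
planted shared rare non-silent variants, population cohort tables with an
enriched candidate gene, a conserved-profile PSSM, and a somatic spectrum
with a planted hotspot at residue 42.

Writes the input bundle to scratch/demo and a truth summary to
results/simulation_truth.json.
"""

import json

from _common import BUNDLE, RESULTS, SEED

from pedvar.pipeline import make_demo


def main() -> None:
    paths = make_demo(BUNDLE, seed=SEED)
    truth = json.loads((BUNDLE / "truth.json").read_text())
    planted = [v for ids in truth["planted_by_pedigree"].values() for v in ids]
    print(f"bundle written to {BUNDLE}")
    print(f"  pedigrees: {len(truth['planted_by_pedigree'])}")
    print(f"  planted shared variants: {len(planted)}")
    print(f"  enriched gene: {truth['planted_enriched_gene']}")
    print(f"  planted somatic hotspots: {truth['planted_hotspots']}")
    print(f"  chance background collisions: {truth['background_collisions'] or 'none'}")
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "simulation_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    print(f"truth summary -> {RESULTS / 'simulation_truth.json'}")
    del paths


if __name__ == "__main__":
    main()
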