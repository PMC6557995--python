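"""Substitution-tolerance scoring of the candidate gene's mutations.

Scores each candidate missense substitution in the top burden gene against
the PSSM (dS = mutant score minus wild-type score), compares the observed
mean to 10,000 Monte Carlo sets of three random mutations, and reports the
lower-tail empirical p.

Writes results/tolerance.tsv.
"""

import pandas as pd

from _common import RESULTS, SEED, require_bundle

from pedvar import tolerance
from pedvar.synthetic_data import child_seed
from pedvar.tolerance import parse_hgvs_p, read_pssm


def main() -> None:
    bundle = require_bundle()
    candidates = pd.read_csv(RESULTS / "candidates.tsv", sep="\t")
    burden = pd.read_csv(RESULTS / "burden.tsv", sep="\t")
    gene = burden.iloc[0]["gene"]
    pssm = read_pssm(bundle / "gene.pssm")
    rows = candidates[(candidates["gene"] == gene) & (candidates["type"] == "missense")]
    mutations = [parse_hgvs_p(h) for h in rows["hgvs_p"]]
    scores = [tolerance.delta_s(pssm, *m) for m in mutations]
    observed = sum(s.delta_s for s in scores) / len(scores)
    null = tolerance.sample_null(pssm, set_size=3, n_sets=10_000,
                                 seed=child_seed(SEED, "null"))
    p = tolerance.empirical_p(observed, null)
    out = pd.DataFrame(
        {
            "mutation": [f"p.{s.wt}{s.position}{s.mut}" for s in scores],
            "delta_s": [s.delta_s for s in scores],
            "set_mean": observed,
            "empirical_p": p,
        }
    )
    RESULTS.mkdir(exist_ok=True)
    out.to_csv(RESULTS / "tolerance.tsv", sep="\t", index=False)
    negative = sum(s.delta_s < 0 for s in scores)
    print(f"{len(scores)} candidate missense substitutions in {gene}")
    print(out.to_string(index=False))
    print(f"\n{negative}/{len(scores)} substitutions have negative dS "
          f"(less tolerated than wild type)")
    print(f"observed mean dS {observed:.2f}; null mean "
          f"{null.samples.mean():.2f}; lower-tail empirical p = {p:.4f}")
    print(f"table -> {RESULTS / 'tolerance.tsv'}")


if __name__ == "__main__":
    main()
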