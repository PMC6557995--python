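import numpy as np
import pytest

from pedvar.synthetic_data import SimConfig
from pedvar.tolerance import PSSM, ALPHABET


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down study layout: three two-sample pedigrees, 300 background
    variants — enough structure for every stage, fast enough for many runs."""
    return SimConfig(
        seed=11,
        n_background_variants=300,
        n_planted_shared=3,
        pedigree_layout=(
            ("F001", 2, 0.25),
            ("F002", 2, 0.0625),
            ("F003", 2, 0.03),
        ),
        pssm_length=120,
        n_somatic=60,
        n_somatic_truncating=4,
    )


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory, small_config):
    """One shared demo bundle on disk (seed 42, scaled-down layout)."""
    from pedvar.pipeline import make_demo

    outdir = tmp_path_factory.mktemp("demo") / "bundle"
    overrides = {
        f.name: getattr(small_config, f.name)
        for f in small_config.__dataclass_fields__.values()
        if f.name != "seed"
    }
    make_demo(outdir, seed=42, **overrides)
    return outdir


@pytest.fixture()
def tiny_pssm() -> PSSM:
    """An 8-position matrix with hand-planted rows used for arithmetic checks.

    Position 7 is D with score(D) = 6 and score(H) = -3, so the D->H
    substitution scores -9; position 2 is R with score(R) = 4, score(Q) = 3,
    so R->Q scores -1.
    """
    rng = np.random.default_rng(0)
    scores = rng.integers(-4, 5, size=(8, 20))
    wild_type = "MRAKLCDE"
    for i, wt in enumerate(wild_type):
        scores[i, ALPHABET.index(wt)] = 5  # wt favoured everywhere
    scores[6, ALPHABET.index("D")] = 6
    scores[6, ALPHABET.index("H")] = -3
    scores[1, ALPHABET.index("R")] = 4
    scores[1, ALPHABET.index("Q")] = 3
    return PSSM(wild_type, scores)
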