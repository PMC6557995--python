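"""Shared paths and loaders for the numbered analysis drivers.

Run the scripts from the repository root in order; `01_simulate.py` writes
the synthetic study bundle under scratch/demo and the later steps read it.
Result tables land under results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "scratch" / "demo"
RESULTS = ROOT / "results"

SEED = 2019  # one global analysis seed; generators derive child streams


def require_bundle() -> Path:
    if not (BUNDLE / "run.yaml").exists():
        raise SystemExit("no synthetic bundle found - run analysis/01_simulate.py first")
    return BUNDLE
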