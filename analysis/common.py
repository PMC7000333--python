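"""Shared configuration for the numbered analysis scripts.

Every script re-derives the same synthetic study from SEED, so each can be
run independently; outputs land under results/.
"""

from pathlib import Path

from pkdrx.simulate import SimulationConfig

SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"


def study_config() -> SimulationConfig:
    """The default synthetic study: NB noise, log2FC 2 planted archetypes."""
    return SimulationConfig(seed=SEED)


def outdir(sub: str = "") -> Path:
    d = DATA if sub == "data" else (RESULTS / sub if sub else RESULTS)
    d.mkdir(parents=True, exist_ok=True)
    return d
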