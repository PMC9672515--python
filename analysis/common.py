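"""Shared run configuration for the numbered analysis scripts.

All scripts operate on the same run directory (results/run) with one
fixed seed, so each can be run alone or in sequence; re-running any
script reproduces its outputs exactly.
"""

from pathlib import Path

from cernapipe.datagen import SimulationConfig
from cernapipe.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "results" / "run"
SEED = 1


def make_config() -> PipelineConfig:
    return PipelineConfig(
        outdir=str(RUN_DIR),
        rng_seed=SEED,
        trend_n_perm=999,
        sim=SimulationConfig(
            n_mirna=60, n_mrna=240, n_circ=100,
            lfc_magnitude=2.0, frac_mirna_down=0.8, frac_circ_up=0.8,
        ),
    )
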