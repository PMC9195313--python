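"""Shared configuration for the numbered analysis drivers.

One moderate-size synthetic study (3 patients per group, 12 stimuli per
category) reused by every step; each driver runs the pipeline up to its
stage into results/study and summarizes what that stage found.
"""
from pathlib import Path

from facegamma.pipeline import ALL_STAGES, RunConfig, run_pipeline
from facegamma.simulate import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 7


def study_config() -> RunConfig:
    sim = SimConfig(n_patients_per_group=3, n_per_category=12, seed=SEED)
    return RunConfig(sim=sim, seed=SEED, n_perm=500, n_surrogates=100,
                     coupling_pairs=(("fusiform", "amygdala"),
                                     ("parahippocampal", "hippocampus")))


def run_through(stage: str) -> Path:
    cfg = study_config()
    cfg.stages = ALL_STAGES[:ALL_STAGES.index(stage) + 1]
    return run_pipeline(cfg, RESULTS)
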