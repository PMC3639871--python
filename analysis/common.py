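"""Shared scale and paths for the numbered analysis scripts.

The demo cohort is a scaled-down version of the full study conditions
(six subjects per group instead of 17/15, 20 of 102 channels, 8 s of
80 s records) so the whole analysis chain runs in minutes on one CPU.
Every script regenerates what it needs deterministically from the seed.
"""

from pathlib import Path

from clgfnet.cohort import CohortSpec, MotifAbundance

RESULTS = Path(__file__).resolve().parent.parent / "results"

SEED = 7


def demo_spec() -> CohortSpec:
    return CohortSpec(
        n_subjects_per_group=(6, 6),
        n_channels=20,
        duration=8.0,
        archetypes={
            "control": MotifAbundance(local_mean=4, global_mean=3,
                                      clgf_mean=2, count_sd=1.0, n_negative=1),
            "patient": MotifAbundance(local_mean=2, global_mean=2,
                                      clgf_mean=0.5, count_sd=0.8, n_negative=1),
        },
        seed=SEED,
    )
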