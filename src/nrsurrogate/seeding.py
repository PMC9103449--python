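"""Deterministic per-stage seed derivation.

One global integer seed is split into independent substreams, one per
pipeline stage, via :class:`numpy.random.SeedSequence`. Re-running a single
stage with the same global seed therefore reproduces it exactly regardless of
which other stages ran before.
"""

from __future__ import annotations

import numpy as np

STAGES = (
    "generate",
    "nni",
    "cluster",
    "smote",
    "fit",
    "tune",
    "evaluate",
    "explain",
    "surface",
)


def _stage_index(stage: str) -> int:
    try:
        return STAGES.index(stage)
    except ValueError as exc:
        raise ValueError(f"unknown stage {stage!r}; one of {STAGES}") from exc


def stage_seed(seed: int, stage: str) -> int:
    """A 31-bit integer seed for *stage*, derived from the global *seed*."""
    ss = np.random.SeedSequence([int(seed), _stage_index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """A Generator on the stage's substream."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _stage_index(stage)])
    )


def child_seed(seed: int, index: int) -> int:
    """31-bit child seed for repeated sub-tasks (e.g. split s of 999)."""
    ss = np.random.SeedSequence([int(seed), 10_000 + int(index)])
    return int(ss.generate_state(1)[0] % (2**31))
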