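"""Deterministic, named RNG substreams.

A master seed plus a named path (stream kind, trial index) maps to an
independent :class:`numpy.random.Generator` via ``SeedSequence`` spawn keys,
so any trial or noise source can be regenerated in isolation and a batch is
invariant to its size: trial i uses the same streams whether simulated alone
or inside a 100-trial batch.
"""

from __future__ import annotations

import numpy as np

# stream kinds
INIT_WEIGHTS = 0
SC_NOISE = 1
TA_NOISE = 2
PERMUTATION = 3
GENERIC = 4


def substream(master_seed: int, stream: int, trial_index: int = 0,
              extra: int = 0) -> np.random.Generator:
    """Generator for the (stream, trial, extra) substream of a master seed."""
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(int(stream), int(trial_index),
                                           int(extra)))
    return np.random.default_rng(ss)
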