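"""Named random substreams.

All randomness in the package flows from a single root seed through named,
independent substreams, so that e.g. re-drawing PSM scores (a new MS run of the
same sample) never perturbs which peptides were sampled, and the synthetic
proteome can be rebuilt independently of the experiment drawn on top of it.
"""

from __future__ import annotations

import numpy as np

#: Stable stream identifiers. Never reorder or renumber: output reproducibility
#: across package versions depends on these values.
STREAMS = {
    "proteome": 0,
    "peptides": 1,
    "scores": 2,
    "noise": 3,
    "profiles": 4,
    "scramble": 5,
    "chance": 6,
}


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return the generator for substream *name* (optionally sub-indexed) of *seed*."""
    if name not in STREAMS:
        raise KeyError(f"unknown substream {name!r}; one of {sorted(STREAMS)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(STREAMS[name], int(index)))
    return np.random.default_rng(ss)
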