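"""Named random-number streams derived from one master seed.

Every stochastic step draws from its own child stream of a single master
seed, so stages are reproducible independently of each other (adding
variants does not perturb the pedigree, and so on). Stream names are
registered here; the (name -> index) map is stable across releases.
"""

from __future__ import annotations

import numpy as np

# Stable registry: never reorder, only append.
_STREAMS = {
    "pedigree": 0,
    "genedrop": 1,
    "traits": 2,
    "batch": 3,
    "pipette": 4,
    "array": 5,
    "fixture": 6,
    "misc": 7,
}


def stream(master_seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of ``master_seed``."""
    try:
        idx = _STREAMS[name]
    except KeyError:  # pragma: no cover - programming error
        raise KeyError(f"unregistered RNG stream {name!r}") from None
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=(idx,)))


def stream_names() -> tuple[str, ...]:
    return tuple(_STREAMS)
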