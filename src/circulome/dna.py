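"""Small DNA-string helpers shared across the package."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int, p=None) -> str:
    """Random DNA string; `p` optionally gives per-base probabilities over ACGT."""
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


def draw_base(rng: np.random.Generator, composition: dict[str, float]) -> str:
    bases = sorted(composition)
    probs = np.array([composition[b] for b in bases], dtype=float)
    probs = probs / probs.sum()
    return bases[rng.choice(len(bases), p=probs)]
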