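"""Small DNA-string helpers shared across modules.

Sequences are plain uppercase Python strings over {A,C,G,T,N}; numpy uint8
views are used where per-site vector work pays off.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans(
    "ACGTRYSWKMBDHVN-",
    "TGCAYRSWMKVHDBN-",
)

# IUPAC complement also used for consensus letters (N <-> N).
IUPAC_COMPLEMENT = {a: b for a, b in zip("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")}


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware; gaps preserved)."""
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.40) -> str:
    """i.i.d. background sequence with the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


def seq_to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def mutate_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution at probability `rate`; a hit always changes the base."""
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        old = arr[i]
        choices = [b for b in BASES if b != old]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def substitute_exact(seq: str, n_sub: int, rng: np.random.Generator,
                     positions: np.ndarray | None = None) -> tuple[str, np.ndarray]:
    """Substitute exactly `n_sub` distinct sites (each changed to a different base).

    Returns (mutated sequence, positions chosen). Used where a realized
    p-distance must land on target rather than fluctuate binomially.
    """
    if positions is None:
        positions = rng.choice(len(seq), size=n_sub, replace=False)
    arr = list(seq)
    for i in positions:
        old = arr[i]
        choices = [b for b in BASES if b != old]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr), np.asarray(positions)


def mutate_indels(seq: str, rate: float, rng: np.random.Generator,
                  max_len: int = 10, p_geom: float = 0.5) -> str:
    """Per-site indel events; lengths 1..max_len, geometric. 50/50 ins/del."""
    if rate <= 0:
        return seq
    out = []
    i = 0
    n = len(seq)
    events = rng.random(n) < rate
    while i < n:
        if events[i]:
            length = min(int(rng.geometric(p_geom)), max_len)
            if rng.random() < 0.5:  # deletion
                i += length
                continue
            out.append(seq[i])
            out.append(random_dna(rng, length, gc=0.5))
            i += 1
        else:
            out.append(seq[i])
            i += 1
    return "".join(out)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("A") + seq.count("T")) / len(seq)
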