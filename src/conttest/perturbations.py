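"""Deliberately degraded alignments for benchmark validation.

Two corruption models: shifting a random subset of rows one column out
of register (prepend a gap, truncate the last character), and mutating
a random subset of non-gap residues to different amino acids.  A
benchmark that tracks alignment quality must score these progressively
worse as the corrupted fraction grows.
"""

from __future__ import annotations

import math

import numpy as np

from .dca_predictor import AMINO_ACIDS
from .formats_io import GAP, Msa


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def shift_misalign(msa: Msa, fraction: float, seed: int) -> Msa:
    """Shift a random subset of rows one column out of alignment.

    ``round(fraction * N)`` rows (half-up) are chosen uniformly without
    replacement; each chosen row r becomes ``'-' + r[:-1]``.  Width,
    row ids and row order are unchanged.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    if msa.width < 2:
        raise ValueError("alignment width must be >= 2 to shift")
    rng = np.random.default_rng(seed)
    m = _round_half_up(fraction * msa.n_rows)
    # prefix of a seeded permutation: uniform without replacement, and a
    # larger fraction at the same seed perturbs a superset of rows, so
    # dose-response series share their randomness
    chosen = set(rng.permutation(msa.n_rows)[:m].tolist())
    rows = [
        (rid, GAP + seq[:-1] if k in chosen else seq)
        for k, (rid, seq) in enumerate(msa.rows)
    ]
    return Msa(tuple(rows))


def mutate_residues(msa: Msa, fraction: float, seed: int) -> Msa:
    """Mutate a random subset of non-gap cells to different amino acids.

    ``round(fraction * n_residues)`` cells (half-up) are chosen
    uniformly among all non-gap cells; each is replaced by a uniformly
    chosen standard amino acid different from the original.  Gaps are
    never created or destroyed; shape and row ids are unchanged.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    grid = np.array([list(seq) for _, seq in msa.rows])
    nongap = np.argwhere(grid != GAP)
    if len(nongap) == 0:
        raise ValueError("alignment contains no residues to mutate")
    rng = np.random.default_rng(seed)
    m = _round_half_up(fraction * len(nongap))
    # permutation prefix, see shift_misalign
    picked = nongap[rng.permutation(len(nongap))[:m]]
    for r, c in picked:
        original = grid[r, c]
        choices = [a for a in AMINO_ACIDS if a != original]
        grid[r, c] = choices[rng.integers(len(choices))]
    rows = [
        (rid, "".join(grid[k]))
        for k, (rid, _) in enumerate(msa.rows)
    ]
    return Msa(tuple(rows))
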