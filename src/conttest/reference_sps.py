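"""Sum-of-pairs scoring against a reference alignment of an embedded
sequence subset.

The SPS of a test alignment is the fraction of residue pairs placed in
the same column by the reference alignment that the test alignment also
places in the same column (reference-pair recall, the BAliBASE
convention).  Residues are identified by their ordinal within the
de-gapped row, so the score is independent of gap placement elsewhere.
"""

from __future__ import annotations

from typing import FrozenSet, Sequence

from .errors import ConsistencyError, DegenerateInputError, LookupError_
from .formats_io import GAP, Msa

#: ((row_a, res_ordinal_a), (row_b, res_ordinal_b)) with row_a < row_b.
AlignedPairSet = FrozenSet[tuple[tuple[str, int], tuple[str, int]]]


def aligned_pairs(msa: Msa, subset_ids: Sequence[str]) -> AlignedPairSet:
    """All residue pairs the alignment places in a common column.

    For every column and every unordered pair of subset rows where both
    rows carry a residue, emit the pair keyed by each residue's 1-based
    ordinal within its de-gapped row.  Canonical ordering: row_a < row_b
    by id.
    """
    ids = list(subset_ids)
    if len(set(ids)) != len(ids):
        raise LookupError_("duplicate ids in subset")
    if len(ids) < 2:
        raise DegenerateInputError("need at least 2 subset rows")
    seqs = {rid: msa.row(rid) for rid in ids}  # raises for unknown ids
    ids.sort()
    # per-row residue ordinal at each column (0 where gapped)
    ordinals: dict[str, list[int]] = {}
    for rid in ids:
        count = 0
        col_ord = []
        for ch in seqs[rid]:
            if ch != GAP:
                count += 1
                col_ord.append(count)
            else:
                col_ord.append(0)
        ordinals[rid] = col_ord
    pairs = set()
    for col in range(msa.width):
        present = [(rid, ordinals[rid][col]) for rid in ids if ordinals[rid][col]]
        for a in range(len(present)):
            for b in range(a + 1, len(present)):
                pairs.add((present[a], present[b]))
    return frozenset(pairs)


def sps(test_msa: Msa, ref_msa: Msa, subset_ids: Sequence[str]) -> float:
    """Fraction of reference-aligned residue pairs reproduced by the test
    alignment.

    Subset rows must carry identical de-gapped sequences in both
    alignments; a mismatch raises :class:`ConsistencyError`.
    """
    for rid in subset_ids:
        t = test_msa.row(rid).replace(GAP, "")
        r = ref_msa.row(rid).replace(GAP, "")
        if t != r:
            raise ConsistencyError(
                f"row {rid!r}: de-gapped sequence differs between test and reference"
            )
    ref_pairs = aligned_pairs(ref_msa, subset_ids)
    if not ref_pairs:
        raise DegenerateInputError("reference alignment aligns no residue pairs")
    test_pairs = aligned_pairs(test_msa, subset_ids)
    return len(test_pairs & ref_pairs) / len(ref_pairs)
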