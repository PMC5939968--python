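"""True contact sets from 3D coordinates, and MSA-column -> structure
residue mapping.

A contact is a pair of residues whose representative atoms (Cbeta;
Calpha for glycine) lie within a distance threshold, default 8 A.  Only
long-range pairs are kept: sequence separation j - i >= 24, i.e. at
least 23 intervening residues.  Columns of the alignment are mapped to
structure residue indices through the target row, with a global
pairwise alignment bridging any differences between the aligned
sequence and the crystallized construct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateInputError, LookupError_, MappingQualityError
from .formats_io import GAP, Msa, ResidueCoords

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 8.0
DEFAULT_MIN_SEP = 24


@dataclass(frozen=True)
class ContactSet:
    """Set of long-range residue index pairs for a protein of length L.

    Pairs are canonical ``(i, j)`` with ``1 <= i < j <= L`` and
    ``j - i >= min_sep`` (default 24, i.e. > 23 intervening positions).
    """

    L: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self):
        for i, j in self.pairs:
            if not (1 <= i < j <= self.L):
                raise ValueError(f"pair ({i},{j}) outside 1..{self.L} or i >= j")
        object.__setattr__(self, "pairs", frozenset(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return pair in self.pairs


@dataclass(frozen=True)
class ColumnMap:
    """Partial injective map from alignment column to structure residue.

    ``col_to_res`` maps 1-based alignment columns to 1-based residue
    indices in structure coordinates; it is strictly increasing over the
    mapped columns.  Columns where the target row is gapped, and
    residues unresolved in the structure, are unmapped.
    """

    target_row_id: str
    col_to_res: dict[int, int]

    def __post_init__(self):
        cols = sorted(self.col_to_res)
        vals = [self.col_to_res[c] for c in cols]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("column map is not strictly increasing")
        object.__setattr__(self, "col_to_res", dict(self.col_to_res))

    @property
    def res_to_col(self) -> dict[int, int]:
        return {r: c for c, r in self.col_to_res.items()}


def extract_contacts(
    coords: ResidueCoords,
    threshold_angstrom: float = DEFAULT_THRESHOLD,
    min_sep: int = DEFAULT_MIN_SEP,
) -> ContactSet:
    """Compute the long-range contact set of a structure.

    Returns all residue pairs ``(i, j)`` with ``j - i >= min_sep`` whose
    representative atoms are within ``threshold_angstrom`` (inclusive
    boundary).  Residues absent from ``coords`` (unresolved) never
    appear.  An empty set is a legal result.
    """
    if not coords.residues:
        raise DegenerateInputError("no residues in coordinate set")
    if threshold_angstrom <= 0:
        raise ValueError("threshold must be positive")
    if min_sep < 1:
        raise ValueError("min_sep must be >= 1")
    idx = coords.indices
    n = len(idx)
    pairs: set[tuple[int, int]] = set()
    if n >= 2:
        dmat = squareform(pdist(coords.xyz))
        sep = np.abs(idx[None, :] - idx[:, None])
        a, b = np.nonzero((dmat <= threshold_angstrom) & (sep >= min_sep))
        for u, v in zip(a, b):
            if u < v:
                pairs.add((int(idx[u]), int(idx[v])))
    return ContactSet(L=coords.length, pairs=frozenset(pairs))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # free end gaps (semi-global): tolerates expression tags / constructs
    aligner.end_gap_score = 0.0
    return aligner


def _sanitize_for_blosum(seq: str) -> str:
    """Replace letters outside the BLOSUM62 alphabet with 'X'."""
    alphabet = set("ARNDCQEGHILKMFPSTWYVBZX")
    return "".join(c if c in alphabet else "X" for c in seq)


def map_columns(
    msa: Msa,
    target_row_id: str,
    structure_seq: str,
    min_identity: float = 0.30,
    force: bool = False,
) -> ColumnMap:
    """Map alignment columns to structure residue indices.

    The de-gapped target MSA row is globally aligned (Needleman-Wunsch,
    BLOSUM62, gap open -11 / extend -1, free end gaps) to
    ``structure_seq``.  Substituted positions are mapped; positions
    aligned to a gap in either sequence are unmapped.  If the pairwise
    identity over aligned positions is below ``min_identity`` the
    mapping is refused (guards against wrong-chain input) unless
    ``force`` is set.
    """
    if target_row_id not in msa:
        raise LookupError_(f"target row {target_row_id!r} not in MSA")
    row = msa.row(target_row_id)
    degapped_cols = [c for c, ch in enumerate(row, start=1) if ch != GAP]
    target_seq = "".join(row[c - 1] for c in degapped_cols)
    if not target_seq:
        raise DegenerateInputError("target row contains only gaps")
    if not structure_seq:
        raise DegenerateInputError("empty structure sequence")

    aligner = _make_aligner()
    aln = aligner.align(
        _sanitize_for_blosum(target_seq), _sanitize_for_blosum(structure_seq)
    )[0]
    # aligned blocks include substitutions; gapped positions fall
    # between blocks and stay unmapped
    n_aligned = 0
    n_ident = 0
    ord_to_struct: dict[int, int] = {}
    for (ts, te), (ss, se) in zip(*aln.aligned):
        for k in range(te - ts):
            t_ord = ts + k  # 0-based ordinal in de-gapped target row
            s_idx = ss + k  # 0-based structure index
            ord_to_struct[t_ord] = s_idx + 1
            n_aligned += 1
            if target_seq[t_ord] == structure_seq[s_idx]:
                n_ident += 1
    if n_aligned == 0:
        raise MappingQualityError("no aligned positions between target and structure")
    identity = n_ident / n_aligned
    if identity < min_identity and not force:
        raise MappingQualityError(
            f"target/structure identity {identity:.2f} below {min_identity:.2f}; "
            "wrong chain? (use force=True to override)"
        )
    col_to_res = {
        degapped_cols[t_ord]: s_idx
        for t_ord, s_idx in sorted(ord_to_struct.items())
    }
    return ColumnMap(target_row_id=target_row_id, col_to_res=col_to_res)


def restrict_to_resolved(cmap: ColumnMap, coords: ResidueCoords) -> ColumnMap:
    """Drop mapped columns whose structure residue is unresolved."""
    resolved = set(int(i) for i in coords.indices)
    return ColumnMap(
        target_row_id=cmap.target_row_id,
        col_to_res={c: r for c, r in cmap.col_to_res.items() if r in resolved},
    )


def read_contacts(path: str, L: int) -> ContactSet:
    """Read a 2-column whitespace-delimited contact list (1-based, i < j)."""
    pairs = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected two columns")
            i, j = int(fields[0]), int(fields[1])
            if i > j:
                i, j = j, i
            pairs.add((i, j))
    return ContactSet(L=L, pairs=frozenset(pairs))


def write_contacts(contacts: ContactSet, path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, j in sorted(contacts.pairs):
            fh.write(f"{i} {j}\n")
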