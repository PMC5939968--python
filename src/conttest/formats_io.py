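"""Readers and writers for the formats the benchmark touches.

Aligned FASTA (the alignments being scored), minimal PDB ATOM records
(the target structure), Newick (guide trees), plus deterministic
row-order shuffling of alignments.

Normalization rules for alignments: sequences are uppercased on read
and '.' gap characters are converted to '-', so downstream code sees a
single canonical gap character.
"""

from __future__ import annotations

import gzip
import io
import logging
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import (
    AlignmentShapeError,
    FormatError,
    LookupError_,
    UnsupportedTopologyError,
)

logger = logging.getLogger(__name__)

GAP = "-"

_ALLOWED_CHARS = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ-")

#: Three-letter -> one-letter residue codes, including common modified
#: residues mapped to their parent amino acid.  Unknown codes become 'X'.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified residues mapped to parent codes
    "MSE": "M", "SEC": "U", "PYL": "O", "SEP": "S", "TPO": "T",
    "PTR": "Y", "CSO": "C", "HYP": "P", "MLY": "K", "M3L": "K",
    "KCX": "K", "CME": "C", "CSD": "C", "OCS": "C", "FME": "M",
}


@dataclass(frozen=True)
class Msa:
    """A rectangular protein multiple sequence alignment.

    ``rows`` is an ordered list of ``(id, sequence)`` pairs.  All
    sequences have equal length, use '-' as the only gap character and
    contain only uppercase letters.  Row ids are unique and non-empty.
    """

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.rows:
            raise FormatError("alignment has no rows")
        width = len(self.rows[0][1])
        if width < 1:
            raise AlignmentShapeError("alignment width must be >= 1")
        seen: set[str] = set()
        for rid, seq in self.rows:
            if not rid:
                raise FormatError("empty row id")
            if rid in seen:
                raise FormatError(f"duplicate row id: {rid!r}")
            seen.add(rid)
            if len(seq) != width:
                raise AlignmentShapeError(
                    f"row {rid!r} has length {len(seq)}, expected {width}"
                )
            bad = set(seq) - _ALLOWED_CHARS
            if bad:
                raise FormatError(
                    f"row {rid!r} contains invalid characters: {sorted(bad)}"
                )
        object.__setattr__(self, "rows", tuple(self.rows))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def row(self, rid: str) -> str:
        for r, seq in self.rows:
            if r == rid:
                return seq
        raise LookupError_(f"row id {rid!r} not in alignment")

    def __contains__(self, rid: str) -> bool:
        return any(r == rid for r, _ in self.rows)


@dataclass(frozen=True)
class ResidueCoords:
    """Representative-atom coordinates for the residues of one chain.

    One entry per residue that has a usable representative atom:
    ``(seq_index, aa, xyz, atom_used)`` where ``seq_index`` is 1-based
    and strictly increasing (unresolved residues are simply absent),
    ``xyz`` is in Angstrom and ``atom_used`` is "CB" except "CA" for
    glycine or as a fallback when CB is missing.
    """

    target_id: str
    residues: tuple[tuple[int, str, tuple[float, float, float], str], ...]

    def __post_init__(self):
        prev = 0
        for idx, aa, xyz, atom in self.residues:
            if idx <= prev:
                raise FormatError("residue seq_index not strictly increasing")
            prev = idx
            if atom not in ("CB", "CA"):
                raise FormatError(f"unknown representative atom {atom!r}")
        object.__setattr__(self, "residues", tuple(self.residues))

    @property
    def length(self) -> int:
        """Target protein length L (index of the last resolved residue)."""
        return self.residues[-1][0] if self.residues else 0

    @property
    def indices(self) -> np.ndarray:
        return np.array([r[0] for r in self.residues], dtype=int)

    @property
    def xyz(self) -> np.ndarray:
        return np.array([r[2] for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        """One-letter sequence of the resolved residues, in order."""
        return "".join(r[1] for r in self.residues)


def _open_text(path_or_text: str):
    """Accept a filesystem path (optionally gzipped) or raw text."""
    text = str(path_or_text)
    if not text:
        raise FormatError("empty input")
    if "\n" in text or text.startswith((">", "ATOM", "HETATM")):
        return io.StringIO(text)
    if text.endswith(".gz"):
        return gzip.open(text, "rt", encoding="utf-8")
    return open(text, "r", encoding="utf-8")


def read_msa(path_or_text: str) -> Msa:
    """Read an aligned FASTA file (or literal FASTA text) into an Msa.

    Lowercase letters are uppercased and '.' gaps become '-'.  Raises
    :class:`AlignmentShapeError` for ragged rows and
    :class:`FormatError` for duplicate ids or an empty file.
    """
    rows: list[tuple[str, str]] = []
    rid = None
    chunks: list[str] = []
    with _open_text(path_or_text) as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                if rid is not None:
                    rows.append((rid, "".join(chunks)))
                rid = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            else:
                if rid is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line.strip().upper().replace(".", GAP))
    if rid is not None:
        rows.append((rid, "".join(chunks)))
    if not rows:
        raise FormatError("empty FASTA input")
    return Msa(tuple(rows))


def write_msa(msa: Msa, path: str, wrap: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rid, seq in msa.rows:
            fh.write(f">{rid}\n")
            for start in range(0, len(seq), wrap):
                fh.write(seq[start : start + wrap] + "\n")


def shuffle_rows(msa: Msa, seed: int) -> Msa:
    """Return a copy of ``msa`` with row order permuted by a seeded RNG.

    Deterministic for a fixed seed; the row multiset is preserved
    exactly.  Mirrors the benchmark's practice of randomizing input
    sequence order before each alignment replicate.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(msa.n_rows)
    return Msa(tuple(msa.rows[i] for i in perm))


def read_pdb_chain(path_or_text: str, chain_id: str) -> ResidueCoords:
    """Extract representative-atom coordinates for one chain of a PDB file.

    Fixed-column ATOM-record parsing.  The representative atom is CB,
    except CA for glycine; non-glycine residues missing CB fall back to
    CA with a warning (keeps index continuity).  Residues lacking both
    are omitted with a warning.  Altloc: the first of 'A' or blank is
    kept, others skipped.  Residues are renumbered 1..L in order of
    appearance so that sequence-separation filters see consecutive
    indices regardless of author numbering.
    """
    per_residue: dict[tuple, dict] = {}
    order: list[tuple] = []
    found_chain = False
    with _open_text(path_or_text) as fh:
        for line in fh:
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if line[21] != chain_id:
                continue
            # HETATM accepted only for mapped modified residues (e.g. MSE)
            resname = line[17:20].strip()
            if line.startswith("HETATM") and resname not in THREE_TO_ONE:
                continue
            found_chain = True
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            atom_name = line[12:16].strip()
            if atom_name not in ("CA", "CB"):
                continue
            key = (line[22:26], line[26])  # resSeq + iCode
            rec = per_residue.get(key)
            if rec is None:
                rec = {"resname": resname}
                per_residue[key] = rec
                order.append(key)
            if atom_name not in rec:  # first altloc wins
                rec[atom_name] = (
                    float(line[30:38]),
                    float(line[38:46]),
                    float(line[46:54]),
                )
    if not found_chain:
        raise LookupError_(f"chain {chain_id!r} not found in PDB input")
    residues = []
    idx = 0
    for key in order:
        rec = per_residue[key]
        aa = THREE_TO_ONE.get(rec["resname"], "X")
        idx += 1
        if aa == "G":
            if "CA" in rec:
                residues.append((idx, aa, rec["CA"], "CA"))
            else:
                warnings.warn(f"glycine at {key} lacks CA; residue omitted")
                idx -= 1
        elif "CB" in rec:
            residues.append((idx, aa, rec["CB"], "CB"))
        elif "CA" in rec:
            warnings.warn(
                f"residue {rec['resname']} at {key} lacks CB; using CA"
            )
            residues.append((idx, aa, rec["CA"], "CA"))
        else:
            warnings.warn(
                f"residue {rec['resname']} at {key} lacks CB and CA; omitted"
            )
            idx -= 1
    if not residues:
        raise FormatError(f"no usable residues in chain {chain_id!r}")
    return ResidueCoords(target_id=chain_id, residues=tuple(residues))


# ---------------------------------------------------------------------------
# Trees


def _check_binary(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        n_children = len(node.child_nodes())
        if n_children not in (0, 2):
            raise UnsupportedTopologyError(
                f"tree is not strictly binary: node with {n_children} children"
            )


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted binary tree.

    Polytomies (including an unrooted trifurcating root) raise
    :class:`UnsupportedTopologyError`: the imbalance statistics assume
    strictly binary topologies.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise FormatError(f"could not parse Newick: {exc}") from exc
    tree.is_rooted = True
    _check_binary(tree)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf labels in tree")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to canonical single-line Newick (with branch
    lengths if present)."""
    return (
        tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()
    )
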