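"""Self-contained synthetic test cases: a toy 3D structure, its true
contact set, and an MSA whose planted covariation sits exactly at the
structure's contacts.

The generator emulates the shape of a single-domain protein-family
alignment: a compact chain whose long-range contacts are known by
construction, and hundreds-to-thousands of rows in which contacting
column pairs covary.  Covariation is modelled by a per-pair random
bijection applied to a shared latent letter — a deliberate
simplification of compensatory substitution that gives exact control of
per-pair signal strength without a full Potts sampler.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .contact_truth import ColumnMap, ContactSet, extract_contacts
from .dca_predictor import AMINO_ACIDS
from .errors import GenerationError
from .formats_io import GAP, Msa, ResidueCoords, write_msa

TARGET_ID = "TARGET"

#: Self-avoidance floor for the random walk, in Angstrom.  The internal
#: rejection threshold is slightly above it so that coordinates rounded
#: to PDB precision (3 decimals) still satisfy the floor.
MIN_PAIR_DIST = 2.0
_REJECT_DIST = 2.01

DEFAULT_BOND_LENGTH = 3.8
DEFAULT_GAP_RATE = 0.05


@dataclass(frozen=True)
class SyntheticCase:
    """A generated benchmark case, fully reproducible from its params."""

    coords: ResidueCoords
    truth: ContactSet
    msa: Msa
    planted_pairs: frozenset[tuple[int, int]]
    params: dict

    @property
    def column_map(self) -> ColumnMap:
        """Identity map: the target row is ungapped and fully resolved,
        so alignment column k is structure residue k."""
        return ColumnMap(
            target_row_id=TARGET_ID,
            col_to_res={c: c for c in range(1, self.coords.length + 1)},
        )


def _toy_sequence(L: int) -> str:
    """All alanine except every 7th residue glycine (exercises the
    Calpha-for-glycine contact rule)."""
    return "".join("G" if (k + 1) % 7 == 0 else "A" for k in range(L))


def sample_structure(
    L: int,
    seed: int,
    bond_length: float = DEFAULT_BOND_LENGTH,
    confinement_radius: float | None = None,
    max_attempts: int = 100,
) -> ResidueCoords:
    """Random compact chain with fixed step length inside a sphere.

    A self-avoidance-biased random walk: consecutive residues are
    ``bond_length`` apart, every step is rejected if it leaves the
    confinement sphere (radius 3.0 * L^(1/3) by default, mimicking
    globular-protein density) or comes within 2 A of an existing
    residue.  Chains are resampled until the default contact extraction
    finds at least one long-range pair (up to ``max_attempts``).
    Coordinates are rounded to 0.001 A so PDB round-trips are exact.
    """
    if L < 30:
        raise ValueError("need L >= 30 so long-range pairs are possible")
    radius = confinement_radius if confinement_radius is not None else 3.0 * L ** (1 / 3)
    rng = np.random.default_rng(seed)
    seq = _toy_sequence(L)
    for _ in range(max_attempts):
        pts = _sample_walk(L, rng, bond_length, radius)
        if pts is None:
            continue
        pts = np.round(pts, 3)
        residues = tuple(
            (
                k + 1,
                seq[k],
                (float(x), float(y), float(z)),
                "CA" if seq[k] == "G" else "CB",
            )
            for k, (x, y, z) in enumerate(pts)
        )
        coords = ResidueCoords(target_id=TARGET_ID, residues=residues)
        if len(extract_contacts(coords)) >= 1:
            return coords
    raise GenerationError(
        f"no long-range contact after {max_attempts} attempts (L={L})"
    )


def _sample_walk(
    L: int, rng: np.random.Generator, bond: float, radius: float
) -> np.ndarray | None:
    pts = np.empty((L, 3))
    pts[0] = 0.0
    for k in range(1, L):
        for _ in range(200):
            v = rng.normal(size=3)
            v *= bond / np.linalg.norm(v)
            cand = pts[k - 1] + v
            if np.linalg.norm(cand) > radius:
                continue
            if k >= 2 and np.min(np.linalg.norm(pts[: k - 1] - cand, axis=1)) < _REJECT_DIST:
                continue
            pts[k] = cand
            break
        else:
            return None  # stuck; restart the chain
    return pts


def _maximal_disjoint_pairs(
    pairs: frozenset[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Greedy maximal subset of pairs sharing no residue (avoids
    confounded three-way couplings)."""
    used: set[int] = set()
    planted = []
    for i, j in sorted(pairs):
        if i not in used and j not in used:
            planted.append((i, j))
            used.update((i, j))
    return planted


def sample_msa(
    coords: ResidueCoords,
    truth: ContactSet,
    N: int,
    rho: float,
    gap_rate: float,
    seed: int,
) -> tuple[Msa, frozenset[tuple[int, int]]]:
    """Generate an alignment with covariation planted at true contacts.

    A maximal residue-disjoint subset of ``truth.pairs`` is planted.
    Unplanted columns are i.i.d. uniform over the 20 amino acids.  For
    each planted pair, each row independently undergoes a perfect
    covariation event with probability ``rho``: both letters derive from
    one latent letter through a pair-specific random bijection;
    otherwise both are independent background draws.  Finally each
    non-target cell is gapped with probability ``gap_rate``.  Row 1 is
    the ungapped target sequence (id "TARGET") matching ``coords``.
    """
    if N < 50:
        raise ValueError("need N >= 50 rows")
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must be in [0, 1]")
    if not truth.pairs:
        raise ValueError("truth contact set is empty")
    rng = np.random.default_rng(seed)
    L = coords.length
    planted = _maximal_disjoint_pairs(truth.pairs)
    n_bg = N - 1  # all rows except the target
    grid = rng.integers(0, 20, size=(n_bg, L))
    for i, j in planted:
        bijection = rng.permutation(20)
        covary = rng.random(n_bg) < rho
        latent = rng.integers(0, 20, size=n_bg)
        grid[covary, i - 1] = latent[covary]
        grid[covary, j - 1] = bijection[latent[covary]]
    letters = np.array(list(AMINO_ACIDS))
    chars = letters[grid]
    if gap_rate > 0:
        gaps = rng.random((n_bg, L)) < gap_rate
        chars[gaps] = GAP
    rows = [(TARGET_ID, coords.sequence)]
    width = len("%d" % n_bg)
    for k in range(n_bg):
        rows.append((f"seq{k + 1:0{width}d}", "".join(chars[k])))
    return Msa(tuple(rows)), frozenset(planted)


def make_case(
    L: int = 60,
    N: int = 1000,
    rho: float = 0.9,
    gap_rate: float = DEFAULT_GAP_RATE,
    seed: int = 0,
) -> SyntheticCase:
    """Generate a full synthetic test case from one seed.

    The structure and MSA stages draw sub-seeds from a seeded RNG, so
    the whole case is reproducible from ``(L, N, rho, gap_rate, seed)``.
    """
    master = np.random.default_rng(seed)
    s_struct, s_msa = (int(x) for x in master.integers(0, 2**31 - 1, size=2))
    coords = sample_structure(L, s_struct)
    truth = extract_contacts(coords)
    msa, planted = sample_msa(coords, truth, N, rho, gap_rate, s_msa)
    return SyntheticCase(
        coords=coords,
        truth=truth,
        msa=msa,
        planted_pairs=planted,
        params={
            "L": L,
            "N": N,
            "rho": rho,
            "gap_rate": gap_rate,
            "seed": seed,
        },
    )


_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:^4s}{alt:1s}{res:>3s} {chain:1s}{resseq:>4d}"
    "{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2s}\n"
)

_ONE_TO_THREE = {"A": "ALA", "G": "GLY"}


def write_pdb(coords: ResidueCoords, path: str, chain_id: str = "A") -> None:
    """Write minimal ATOM records (representative atom per residue)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        serial = 0
        for idx, aa, (x, y, z), atom in coords.residues:
            serial += 1
            fh.write(
                _PDB_ATOM.format(
                    serial=serial,
                    name=atom,
                    alt=" ",
                    res=_ONE_TO_THREE.get(aa, "UNK"),
                    chain=chain_id,
                    resseq=idx,
                    icode=" ",
                    x=x,
                    y=y,
                    z=z,
                    occ=1.0,
                    b=0.0,
                    element="C",
                )
            )
        fh.write("TER\nEND\n")


def write_case(case: SyntheticCase, out_dir: str) -> dict[str, str]:
    """Write msa.fasta, structure.pdb, contacts.txt and params.json.

    The files round-trip through the readers to reproduce the in-memory
    case exactly.  Returns the paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "msa": os.path.join(out_dir, "msa.fasta"),
        "pdb": os.path.join(out_dir, "structure.pdb"),
        "contacts": os.path.join(out_dir, "contacts.txt"),
        "params": os.path.join(out_dir, "params.json"),
    }
    write_msa(case.msa, paths["msa"])
    write_pdb(case.coords, paths["pdb"])
    with open(paths["contacts"], "w", encoding="utf-8", newline="\n") as fh:
        for i, j in sorted(case.truth.pairs):
            fh.write(f"{i} {j}\n")
    with open(paths["params"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(
            {**case.params, "planted_pairs": sorted(case.planted_pairs)},
            fh,
            indent=2,
        )
        fh.write("\n")
    return paths
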