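"""Mean-field direct coupling analysis (mfDCA) contact prediction.

Infers direct residue-residue couplings from the columns of a large
protein MSA: sequences are reweighted by identity clustering, single-
and pair-column frequencies are regularized with a pseudocount, the
(q-1)-state covariance matrix is inverted to obtain pair couplings, and
each column pair is scored by the Direct Information (DI) of a two-site
model with self-consistent fields.  High-DI pairs are predicted
contacts.

An adapter parses ranked contact lists produced by external predictors
(PSICOV, FreeContact dialects).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .contact_truth import ColumnMap
from .errors import DegenerateInputError, FormatError, NumericalError
from .formats_io import GAP, Msa

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino acid alphabet used for state encoding.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: q = 21 states: 20 amino acids plus gap.  Ambiguity codes (B, Z, X,
#: and rare letters such as U/O/J) carry no usable frequency information
#: and are counted as the gap state.
Q = 21
_GAP_STATE = 20

_CHAR_TO_STATE = np.full(256, _GAP_STATE, dtype=np.int8)
for _k, _aa in enumerate(AMINO_ACIDS):
    _CHAR_TO_STATE[ord(_aa)] = _k


@dataclass(frozen=True)
class DcaParams:
    """Tunable parameters of the mean-field DCA predictor.

    reweight_identity: sequences at least this fraction identical are
        downweighted as one effective observation (default 0.8).
    pseudocount_weight: lambda in the frequency blend
        f~ = (1-lambda) f_data + lambda f_uniform (default 0.5).
    max_gap_col_fraction: columns gappier than this are dropped before
        the covariance step (default 0.9).
    apc: apply average-product correction to DI scores (off by default;
        raw DI is the conventional mfDCA ranking score).
    di_tol / di_max_iter: convergence of the self-consistent two-site
        fields used for DI; the tight default makes DI symmetric under
        column exchange to ~1e-9, so ranked lists are reproducible.
    """

    reweight_identity: float = 0.8
    pseudocount_weight: float = 0.5
    max_gap_col_fraction: float = 0.9
    apc: bool = False
    di_tol: float = 1e-6
    di_max_iter: int = 200

    def __post_init__(self):
        if not (0 < self.reweight_identity <= 1):
            raise ValueError("reweight_identity must be in (0, 1]")
        if not (0 < self.pseudocount_weight < 1):
            raise ValueError("pseudocount_weight must be in (0, 1)")
        if not (0 < self.max_gap_col_fraction <= 1):
            raise ValueError("max_gap_col_fraction must be in (0, 1]")


@dataclass(frozen=True)
class PredictionList:
    """Ranked contact predictions: (i, j, score), score descending.

    Indices are 1-based target-structure residue indices with i < j and
    no duplicates.  Ties are broken lexicographically by (i, j) so the
    ranking is deterministic.
    """

    predictor_name: str
    entries: tuple[tuple[int, int, float], ...]

    def __post_init__(self):
        seen = set()
        for i, j, _ in self.entries:
            if i >= j:
                raise ValueError(f"entry ({i},{j}) must have i < j")
            if (i, j) in seen:
                raise ValueError(f"duplicate prediction ({i},{j})")
            seen.add((i, j))
        ordered = tuple(
            sorted(self.entries, key=lambda e: (-e[2], e[0], e[1]))
        )
        object.__setattr__(self, "entries", ordered)

    def __len__(self) -> int:
        return len(self.entries)


def encode_msa(msa: Msa, columns: list[int] | None = None) -> np.ndarray:
    """Encode MSA rows as an (N, L) int8 state matrix over q = 21 states.

    ``columns`` is an optional list of 1-based alignment columns to keep
    (in order); by default all columns are used.
    """
    arr = np.frombuffer(
        "".join(seq for _, seq in msa.rows).encode("ascii"), dtype=np.uint8
    ).reshape(msa.n_rows, msa.width)
    states = _CHAR_TO_STATE[arr]
    if columns is not None:
        states = states[:, [c - 1 for c in columns]]
    return np.ascontiguousarray(states)


def effective_weights(states: np.ndarray, reweight_identity: float = 0.8) -> np.ndarray:
    """Identity-based sequence weights.

    The weight of sequence s is 1 / |{t : identity(s, t) >= theta}|,
    self included; identity is the fraction of positions with equal
    states (gap counted as a state).  The sum of weights is Meff, the
    effective number of sequences.
    """
    n = states.shape[0]
    if n < 2:
        return np.ones(n)
    # pdist hamming gives the fraction of differing positions
    diff = squareform(pdist(states, metric="hamming"))
    similar = (1.0 - diff) >= reweight_identity
    return 1.0 / similar.sum(axis=1)


def _frequencies(
    states: np.ndarray, weights: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Reweighted, pseudocount-regularized single and pair frequencies.

    Returns (fi, fij): fi is (L, q); fij is (L*q, L*q) in site-major
    block layout.  Diagonal blocks carry the single-site frequencies on
    their diagonal, as required for the covariance construction.
    """
    n, L = states.shape
    meff = weights.sum()
    onehot = np.zeros((n, L * Q))
    cols = np.arange(L) * Q + states
    onehot[np.arange(n)[:, None], cols] = 1.0

    fi = (weights[:, None] * onehot).sum(axis=0).reshape(L, Q) / meff
    fij = (onehot * weights[:, None]).T @ onehot / meff

    fi_t = (1 - lam) * fi + lam / Q
    fij_t = (1 - lam) * fij + lam / (Q * Q)
    # same-site blocks: f~ii(a,b) = (1-lam) fi(a) delta_ab + (lam/q) delta_ab
    for s in range(L):
        blk = slice(s * Q, (s + 1) * Q)
        fij_t[blk, blk] = np.diag((1 - lam) * fi[s] + lam / Q)
    return fi_t, fij_t


def _couplings(fi: np.ndarray, fij: np.ndarray) -> np.ndarray:
    """Invert the (q-1)-state covariance matrix to get pair couplings.

    Returns e of shape (L, L, q, q) in the gauge where the last state
    (gap) has zero couplings.
    """
    L = fi.shape[0]
    qm = Q - 1
    keep = np.concatenate([np.arange(s * Q, s * Q + qm) for s in range(L)])
    fi_flat = fi[:, :qm].reshape(-1)
    C = fij[np.ix_(keep, keep)] - np.outer(fi_flat, fi_flat)
    try:
        invC = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "covariance matrix singular despite pseudocount regularization"
        ) from exc
    e = np.zeros((L, L, Q, Q))
    e[:, :, :qm, :qm] = -invC.reshape(L, qm, L, qm).transpose(0, 2, 1, 3)
    return e


def _direct_information(
    eij: np.ndarray, fi: np.ndarray, fj: np.ndarray, tol: float, max_iter: int
) -> float:
    """DI of one pair from its coupling block and single-site marginals.

    Finds fields mu_i, mu_j such that the two-site model
    P(a,b) ~ exp(-e(a,b)) mu_i(a) mu_j(b) reproduces the single-site
    marginals, then returns the mutual information of P against the
    product of marginals.
    """
    W = np.exp(-eij)
    mu_i = np.full(Q, 1.0 / Q)
    mu_j = np.full(Q, 1.0 / Q)
    for _ in range(max_iter):
        new_i = fi / (W @ mu_j)
        new_i /= new_i.sum()
        new_j = fj / (W.T @ new_i)
        new_j /= new_j.sum()
        delta = max(
            np.abs(new_i - mu_i).max(), np.abs(new_j - mu_j).max()
        )
        mu_i, mu_j = new_i, new_j
        if delta < tol:
            break
    P = W * np.outer(mu_i, mu_j)
    P /= P.sum()
    prod = np.outer(fi, fj)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P / prod), 0.0)
    return float(terms.sum())


def _direct_information_batch(
    W: np.ndarray, fa: np.ndarray, fb: np.ndarray, tol: float, max_iter: int
) -> np.ndarray:
    """Vectorized DI over P pairs.

    ``W`` is (P, q, q); ``fa``/``fb`` are the (P, q) single-site
    marginals of each pair's first/second column.  Same fixed-point
    iteration as :func:`_direct_information`, run for all pairs at once.
    """
    P = W.shape[0]
    mu_a = np.full((P, Q), 1.0 / Q)
    mu_b = np.full((P, Q), 1.0 / Q)
    for _ in range(max_iter):
        new_a = fa / np.einsum("pab,pb->pa", W, mu_b)
        new_a /= new_a.sum(axis=1, keepdims=True)
        new_b = fb / np.einsum("pab,pa->pb", W, new_a)
        new_b /= new_b.sum(axis=1, keepdims=True)
        delta = max(
            np.abs(new_a - mu_a).max(), np.abs(new_b - mu_b).max()
        )
        mu_a, mu_b = new_a, new_b
        if delta < tol:
            break
    Pdir = W * mu_a[:, :, None] * mu_b[:, None, :]
    Pdir /= Pdir.sum(axis=(1, 2), keepdims=True)
    prod = fa[:, :, None] * fb[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(Pdir > 0, Pdir * np.log(Pdir / prod), 0.0)
    return terms.sum(axis=(1, 2))


def _apc(scores: dict[tuple[int, int], float]) -> dict[tuple[int, int], float]:
    """Average-product correction of a symmetric pair-score table."""
    sites = sorted({s for pair in scores for s in pair})
    row_mean = {
        s: np.mean([scores[tuple(sorted((s, t)))] for t in sites if t != s])
        for s in sites
    }
    total = np.mean(list(scores.values()))
    return {
        (i, j): v - row_mean[i] * row_mean[j] / total
        for (i, j), v in scores.items()
    }


def predict_contacts_mfdca(
    msa: Msa, column_map: ColumnMap, params: DcaParams = DcaParams()
) -> PredictionList:
    """Predict ranked contacts for the target structure from an MSA.

    Restricts to the columns mapped by ``column_map`` (target-ungapped,
    structure-resolved), drops columns gappier than
    ``params.max_gap_col_fraction``, runs mean-field DCA and emits all
    column pairs as (i, j, DI) in structure residue indices, sorted by
    DI descending with (i, j)-lexicographic tie-break.
    """
    cols = sorted(column_map.col_to_res)
    if len(cols) < 2:
        raise DegenerateInputError("need at least 2 mapped columns")
    states = encode_msa(msa, columns=cols)
    gap_frac = (states == _GAP_STATE).mean(axis=0)
    usable = gap_frac <= params.max_gap_col_fraction
    if usable.sum() < 2:
        raise DegenerateInputError(
            "fewer than 2 columns pass the gap-fraction filter"
        )
    cols = [c for c, u in zip(cols, usable) if u]
    states = states[:, usable]

    weights = effective_weights(states, params.reweight_identity)
    fi, fij = _frequencies(states, weights, params.pseudocount_weight)
    e = _couplings(fi, fij)

    L = len(cols)
    res = [column_map.col_to_res[c] for c in cols]
    ia, ib = np.triu_indices(L, k=1)
    W = np.exp(-e[ia, ib])
    di = _direct_information_batch(
        W, fi[ia], fi[ib], params.di_tol, params.di_max_iter
    )
    scores: dict[tuple[int, int], float] = {
        (res[a], res[b]): float(d) for a, b, d in zip(ia, ib, di)
    }
    if params.apc:
        scores = _apc(scores)
    entries = tuple((i, j, s) for (i, j), s in scores.items())
    return PredictionList(predictor_name="mfdca", entries=entries)


#: Field positions (1-based) of i, j, score in known output dialects.
FORMAT_PRESETS = {
    "psicov": (1, 2, 5),
    "freecontact": (1, 3, 6),
    "generic": (1, 2, 3),
}


def load_external_predictions(
    path: str,
    format_spec: str | tuple[int, int, int],
    column_map: ColumnMap | None = None,
    predictor_name: str | None = None,
    max_index: int | None = None,
) -> PredictionList:
    """Parse an external predictor's ranked contact list.

    ``format_spec`` is a preset name ("psicov", "freecontact",
    "generic") or a tuple of 1-based field positions for (i, j, score).
    If ``column_map`` is given the file's indices are treated as
    alignment columns and reindexed to structure residues (unmapped
    columns are dropped); otherwise they are taken as structure indices
    already.  Duplicate (i, j) keep the maximum score with a warning.
    """
    if isinstance(format_spec, str):
        try:
            fields = FORMAT_PRESETS[format_spec]
        except KeyError:
            raise FormatError(f"unknown format preset {format_spec!r}")
    else:
        fields = tuple(format_spec)
    fi_, fj_, fs_ = (f - 1 for f in fields)
    name = predictor_name or (
        format_spec if isinstance(format_spec, str) else "external"
    )
    best: dict[tuple[int, int], float] = {}
    dupes = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                i = int(parts[fi_])
                j = int(parts[fj_])
                score = float(parts[fs_])
            except (IndexError, ValueError) as exc:
                raise FormatError(
                    f"{path}: cannot parse line {lineno}: {line!r}"
                ) from exc
            if column_map is not None:
                ri = column_map.col_to_res.get(i)
                rj = column_map.col_to_res.get(j)
                if ri is None or rj is None:
                    continue
                i, j = ri, rj
            if i == j:
                raise FormatError(f"{path}: line {lineno}: i == j")
            if i > j:
                i, j = j, i
            if max_index is not None and (i < 1 or j > max_index):
                raise FormatError(
                    f"{path}: line {lineno}: index outside 1..{max_index}"
                )
            if (i, j) in best:
                dupes += 1
                best[(i, j)] = max(best[(i, j)], score)
            else:
                best[(i, j)] = score
    if dupes:
        warnings.warn(f"{path}: {dupes} duplicate pairs; kept max scores")
    if not best:
        raise DegenerateInputError(f"{path}: no predictions parsed")
    return PredictionList(
        predictor_name=name,
        entries=tuple((i, j, s) for (i, j), s in best.items()),
    )


def write_predictions(preds: PredictionList, path: str) -> None:
    """Write a prediction list as 'i j score' text, ranked."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, j, s in preds.entries:
            fh.write(f"{i} {j} {s:.6g}\n")
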