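"""Pairwise alignment, percent identity, p-distances and neighbor-joining.

Marker-gene identity analysis for barcode panels: sequences are compared by
optimal global (Needleman–Wunsch) alignment with affine gaps, identity is
summarized per pair, and the resulting p-distance matrix feeds a standard
neighbor-joining agglomeration.  NJ is exact on additive matrices, which is
what the tests exploit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import skbio

from ._iupac import GAP, IUPAC_MASK, encode_mask, reverse_complement
from .seqio import NucleotideSequence, SpeciesSequenceSet

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring: a gap run of length k costs
    ``gap_open + (k-1) * gap_extend``."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    params: AlignParams

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)


@dataclass(frozen=True)
class IdentityResult:
    percent_identity: float
    compared_columns: int


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(m < 0):
            raise ValueError("negative distances")
        self.matrix = m

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths, serializable to Newick."""

    root: skbio.TreeNode

    def newick(self) -> str:
        return str(self.root).strip()

    @property
    def leaf_names(self) -> list[str]:
        return sorted(n.name for n in self.root.tips())


def _score_matrix(a: str, b: str, params: AlignParams) -> np.ndarray:
    ma = encode_mask(a)
    mb = encode_mask(b)
    compat = (ma[:, None] & mb[None, :]) != 0
    return np.where(compat, params.match, params.mismatch)


def global_align(a: str, b: str, params: AlignParams | None = None) -> PairwiseAlignment:
    """Optimal global alignment (Gotoh three-state DP) with deterministic
    traceback preferring diagonal, then up (gap in ``b``), then left.

    Degenerate IUPAC codes score as a match iff their base sets intersect.
    """
    params = params or AlignParams()
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    n, m = len(a), len(b)
    go, ge = params.gap_open, params.gap_extend
    s = _score_matrix(a, b, params)

    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)  # gap in b, consumes a ("up")
    Iy = np.full((n + 1, m + 1), neg)  # gap in a, consumes b ("left")
    M[0, 0] = 0.0
    i_idx = np.arange(1, m + 1)
    Iy[0, 1:] = go + (i_idx - 1) * ge
    for i in range(1, n + 1):
        Ix[i, 0] = go + (i - 1) * ge
        M[i, 1:] = s[i - 1, :] + np.maximum.reduce(
            [M[i - 1, :-1], Ix[i - 1, :-1], Iy[i - 1, :-1]]
        )
        Ix[i, 1:] = np.maximum.reduce(
            [M[i - 1, 1:] + go, Iy[i - 1, 1:] + go, Ix[i - 1, 1:] + ge]
        )
        # Iy needs a running max along the row: Iy[j] = max_{k<j} X[k]+go+ge*(j-1-k)
        X = np.maximum(M[i], Ix[i])
        B = X[:-1] + go - ge * np.arange(m)
        Iy[i, 1:] = np.maximum.accumulate(B) + ge * np.arange(m)

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    finals = (M[n, m], Ix[n, m], Iy[n, m])
    score = max(finals)
    state = next(k for k in range(3) if finals[k] >= score - _EPS)
    while i > 0 or j > 0:
        if state == 0:  # M
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            best = max(prev)
            state = next(k for k in range(3) if prev[k] >= best - _EPS)
        elif state == 1:  # Ix: a aligned to gap
            out_a.append(a[i - 1])
            out_b.append(GAP)
            here = Ix[i, j]
            i -= 1
            if M[i, j] + go >= here - _EPS:
                state = 0
            elif Ix[i, j] + ge >= here - _EPS:
                state = 1
            else:
                state = 2
        else:  # Iy: b aligned to gap
            out_a.append(GAP)
            out_b.append(b[j - 1])
            here = Iy[i, j]
            j -= 1
            if M[i, j] + go >= here - _EPS:
                state = 0
            elif Ix[i, j] + go >= here - _EPS:
                state = 1
            else:
                state = 2
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                             float(score), params)


def _columns_identity(
    col_a: str, col_b: str, mode: str
) -> IdentityResult:
    """Identity over two already-aligned equal-length strings."""
    if len(col_a) != len(col_b):
        raise ValueError("aligned strings differ in length")
    start, end = 0, len(col_a)
    if mode == "exclude_end_gaps":
        for seq in (col_a, col_b):
            start = max(start, len(seq) - len(seq.lstrip(GAP)))
            end = min(end, len(seq.rstrip(GAP)))
    elif mode != "all_columns":
        raise ValueError(f"unknown mode {mode!r}")
    if end <= start:
        return IdentityResult(0.0, 0)
    pairs = [
        (x, y)
        for x, y in zip(col_a[start:end], col_b[start:end])
        if not (x == GAP and y == GAP)
    ]
    if not pairs:
        return IdentityResult(0.0, 0)
    matches = sum(1 for x, y in pairs if IUPAC_MASK[x] & IUPAC_MASK[y])
    return IdentityResult(100.0 * matches / len(pairs), len(pairs))


def percent_identity(
    a: str,
    b: str,
    params: AlignParams | None = None,
    mode: str = "exclude_end_gaps",
) -> IdentityResult:
    """Percent identity after optimal global alignment.

    ``exclude_end_gaps`` (default) trims terminal gap runs from the
    denominator, so a short fragment against a full-length marker is scored
    over the overlap only; ``all_columns`` counts every alignment column.

    Co-optimal alignments can differ in identity, so the pair is
    canonicalized (lexicographically smallest of the swapped and jointly
    reverse-complemented variants) before aligning — identity is then
    symmetric in its inputs and strand-invariant by construction.
    """
    a, b = a.upper(), b.upper()
    ra, rb = reverse_complement(a), reverse_complement(b)
    x, y = min((a, b), (b, a), (ra, rb), (rb, ra))
    aln = global_align(x, y, params)
    return _columns_identity(aln.aligned_a, aln.aligned_b, mode)


def p_distance_matrix(
    seq_set: SpeciesSequenceSet,
    params: AlignParams | None = None,
    mode: str = "exclude_end_gaps",
) -> DistanceMatrix:
    """Pairwise p-distances (1 - identity/100) over all sequences in a set.

    Pre-aligned sets are compared column-wise; unaligned sets are aligned
    pair by pair.
    """
    records = list(seq_set)
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [r.id for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if seq_set.aligned:
                ident = _columns_identity(
                    records[i].residues, records[j].residues, mode
                )
            else:
                ident = percent_identity(
                    records[i].residues, records[j].residues, params, mode
                )
            d[i, j] = d[j, i] = 1.0 - ident.percent_identity / 100.0
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Standard neighbor-joining agglomeration.

    Negative branch lengths are clamped to zero; ties in the Q criterion are
    broken by label order so repeated runs give identical trees.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    d = dm.matrix.copy()
    nodes = [skbio.TreeNode(name=lbl) for lbl in dm.labels]
    names = list(dm.labels)

    while len(nodes) > 3:
        k = len(nodes)
        r = d.sum(axis=1)
        q = (k - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = [
            (tuple(sorted((names[i], names[j]))), i, j)
            for i in range(k)
            for j in range(i + 1, k)
            if q[i, j] <= qmin + 1e-12
        ]
        _, i, j = min(ties)
        vi = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (k - 2))
        vj = d[i, j] - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = skbio.TreeNode()
        nodes[i].length = vi
        nodes[j].length = vj
        parent.extend([nodes[i], nodes[j]])
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(k) if x not in (i, j)]
        new_d = np.zeros((len(keep) + 1, len(keep) + 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = du[keep]
        d = new_d
        nodes = [nodes[x] for x in keep] + [parent]
        names = [names[x] for x in keep] + [f"({min(names[i], names[j])})"]

    # final three-point resolution
    (a, b, c) = nodes
    va = max(0.0, (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0)
    vb = max(0.0, (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0)
    vc = max(0.0, (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0)
    root = skbio.TreeNode()
    a.length, b.length, c.length = va, vb, vc
    root.extend([a, b, c])
    return PhyloTree(root)


def reference_anchored_alignment(
    seq_set: SpeciesSequenceSet,
    reference_id: str,
    params: AlignParams | None = None,
) -> SpeciesSequenceSet:
    """Project every sequence onto the coordinate system of one reference.

    Each sequence is globally aligned to the reference; alignment columns are
    the reference positions, deletions become gaps, and insertions relative
    to the reference are dropped (their total is logged).  Already-aligned
    input is returned unchanged.  This is a deliberately simple stand-in for
    a proper multiple aligner, adequate for barcode markers where indels are
    rare; externally aligned FASTA can be supplied instead.
    """
    if seq_set.aligned:
        return seq_set
    ref = seq_set.get_by_id(reference_id).residues
    dropped = 0
    by_species: dict[str, list[NucleotideSequence]] = {}
    for rec in seq_set:
        if rec.id == reference_id:
            projected = ref
        else:
            aln = global_align(ref, rec.residues, params)
            cols = []
            for ca, cb in zip(aln.aligned_a, aln.aligned_b):
                if ca == GAP:
                    dropped += 1  # insertion relative to the reference
                else:
                    cols.append(cb)
            projected = "".join(cols)
        by_species.setdefault(rec.species_label, []).append(
            NucleotideSequence(rec.id, rec.species_label, projected, aligned=True)
        )
    if dropped:
        logger.warning(
            "reference-anchored alignment dropped %d inserted columns", dropped
        )
    return SpeciesSequenceSet(by_species, aligned=True)
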