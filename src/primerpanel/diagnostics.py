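"""Diagnostic-region discovery from a species-labeled multiple alignment.

A diagnostic window is a stretch of alignment columns where the target
species is internally conserved but differs from every non-target species at
enough columns — the raw material for a species-specific primer.  Candidate
windows are scored against the per-species *majority* base profile (one
consensus row per species, the way alignment figures in barcoding papers are
drawn), with an optional strict per-sequence re-check available downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._iupac import GAP, IUPAC_SETS
from .seqio import SpeciesSequenceSet

_ALPHABET = ("A", "C", "G", "T", GAP)
_GAP_IDX = 4

# char -> fractional weight over (A, C, G, T, gap)
_WEIGHTS: dict[str, np.ndarray] = {}
for _code, _bases in IUPAC_SETS.items():
    w = np.zeros(5)
    for _b in _bases:
        w[_ALPHABET.index(_b)] = 1.0 / len(_bases)
    _WEIGHTS[_code] = w
_WEIGHTS[GAP] = np.array([0.0, 0.0, 0.0, 0.0, 1.0])


@dataclass
class ColumnProfiles:
    """Per-species, per-column base frequency vectors over (A,C,G,T,gap).

    ``freq`` has shape (n_species, n_columns, 5); rows sum to 1 per species
    per column.  Majority base indices use a fixed A<C<G<T<gap tie-break.
    """

    species: list[str]
    freq: np.ndarray

    def __post_init__(self) -> None:
        self._maj: dict[str, np.ndarray] = {}
        self._seq: dict[str, str] = {}

    @property
    def n_columns(self) -> int:
        return self.freq.shape[1]

    def majority_index(self, species: str) -> np.ndarray:
        if species not in self._maj:
            self._maj[species] = np.argmax(
                self.freq[self.species.index(species)], axis=1
            )
        return self._maj[species]

    def majority_frequency(self, species: str) -> np.ndarray:
        return np.max(self.freq[self.species.index(species)], axis=1)

    def majority_sequence(self, species: str) -> str:
        if species not in self._seq:
            self._seq[species] = "".join(
                _ALPHABET[i] for i in self.majority_index(species)
            )
        return self._seq[species]


@dataclass(frozen=True)
class WindowParams:
    min_conservation: float = 0.9
    min_mismatch_per_nontarget: int = 2
    three_prime_k: int = 3
    min_specific_in_3prime: int = 1
    window_min: int = 18
    window_max: int = 33


@dataclass(frozen=True)
class DiagnosticWindow:
    """Alignment window (0-based, half-open) diagnostic for one species.

    ``strand_role`` says which primer the window would become: a
    ``forward_site`` primes rightward (3' end at the window's right edge), a
    ``reverse_site`` primes leftward after reverse-complementing (3' end at
    the window's left edge).
    """

    start: int
    end: int
    target_species: str
    strand_role: str
    conservation: float
    nontarget_mismatches: dict[str, int] = field(hash=False)
    three_prime_discriminative: int = 0

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def total_mismatches(self) -> int:
        return sum(self.nontarget_mismatches.values())


def profile_columns(aligned_set: SpeciesSequenceSet) -> ColumnProfiles:
    """Exact per-species column base frequencies.

    Degenerate codes distribute fractional weight across their compatible
    bases (an R contributes 0.5 to A and 0.5 to G).
    """
    if not aligned_set.aligned:
        raise ValueError("profile_columns requires an aligned set")
    if len(aligned_set.species) < 2:
        raise ValueError("need at least 2 species")
    ncol = aligned_set.alignment_length()
    species = aligned_set.species
    freq = np.zeros((len(species), ncol, 5))
    for si, sp in enumerate(species):
        records = aligned_set[sp]
        for rec in records:
            for j, c in enumerate(rec.residues):
                freq[si, j] += _WEIGHTS[c]
        freq[si] /= len(records)
    return ColumnProfiles(list(species), freq)


def find_diagnostic_windows(
    profiles: ColumnProfiles,
    target: str,
    params: WindowParams | None = None,
) -> list[DiagnosticWindow]:
    """All windows satisfying the conservation/discrimination thresholds,
    ranked by (total non-target mismatches, 3'-discriminative count)
    descending, ties by leftmost start.

    A column counts as a mismatch against a non-target only when both
    majority bases are real bases (gap columns never count), and windows
    whose target majority contains a gap are discarded so that the extracted
    primer is gap-free.
    """
    params = params or WindowParams()
    if target not in profiles.species:
        raise ValueError(f"target species {target!r} not in profiles")
    nontargets = [s for s in profiles.species if s != target]
    ncol = profiles.n_columns

    tmaj = profiles.majority_index(target)
    tcons = profiles.majority_frequency(target)
    ok = (tcons >= params.min_conservation) & (tmaj != _GAP_IDX)

    diff = np.zeros((len(nontargets), ncol), dtype=int)
    for k, sp in enumerate(nontargets):
        nmaj = profiles.majority_index(sp)
        diff[k] = (tmaj != nmaj) & (tmaj != _GAP_IDX) & (nmaj != _GAP_IDX)
    specific = diff.all(axis=0).astype(int)

    ok_cum = np.concatenate([[0], np.cumsum(~ok)])
    diff_cum = np.concatenate([np.zeros((len(nontargets), 1), int),
                               np.cumsum(diff, axis=1)], axis=1)
    spec_cum = np.concatenate([[0], np.cumsum(specific)])

    k3 = params.three_prime_k
    windows: list[DiagnosticWindow] = []
    for width in range(params.window_min, params.window_max + 1):
        for start in range(ncol - width + 1):
            end = start + width
            if ok_cum[end] - ok_cum[start] > 0:
                continue
            per_nt = diff_cum[:, end] - diff_cum[:, start]
            if per_nt.min() < params.min_mismatch_per_nontarget:
                continue
            cons = float(tcons[start:end].min())
            mism = {sp: int(per_nt[k]) for k, sp in enumerate(nontargets)}
            for role in ("forward_site", "reverse_site"):
                if role == "forward_site":
                    n3 = int(spec_cum[end] - spec_cum[max(end - k3, start)])
                else:
                    n3 = int(spec_cum[min(start + k3, end)] - spec_cum[start])
                if n3 < params.min_specific_in_3prime:
                    continue
                windows.append(
                    DiagnosticWindow(start, end, target, role, cons, mism, n3)
                )
    windows.sort(
        key=lambda w: (
            -w.total_mismatches,
            -w.three_prime_discriminative,
            w.start,
            w.width,
            w.strand_role,
        )
    )
    return windows


def windows_to_bed(windows: list[DiagnosticWindow]) -> str:
    """BED-like TSV export (0-based half-open, *alignment* coordinates)."""
    lines = ["#coords=alignment\tstart\tend\tname\tmismatches\tstrand"]
    for w in windows:
        strand = "+" if w.strand_role == "forward_site" else "-"
        lines.append(
            f"alignment\t{w.start}\t{w.end}\t{w.target_species}"
            f"\t{w.total_mismatches}\t{strand}"
        )
    return "\n".join(lines) + "\n"
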