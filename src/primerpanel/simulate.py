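"""Synthetic multi-species barcode marker sets.

The generator emulates the data regime of a multi-species barcoding study:
a conserved universal-primer flank at each end of the marker, a divergent
species-diagnostic interior (between-species divergence much larger than
within-species divergence), and several sequences per species.  Evolution is
Jukes–Cantor (equal rates, no indels) applied site-wise via the exact JC
transition probability, so realized p-distances have the closed-form
expectation p = 3/4·(1 − e^(−4d/3)) that the tests check against.

Species sit on a star phylogeny by default; a two-clade mode groups the
first two species on a shared internal branch to emulate nested clusters.
All randomness flows from a single seeded generator, so runs are
byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._iupac import reverse_complement
from .seqio import NucleotideSequence, SpeciesSequenceSet

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 3
    seqs_per_species: int = 4
    marker_length_bp: int = 450
    between_divergence: float = 0.10  # expected substitutions/site per species branch
    within_divergence: float = 0.005
    flank_bp: int = 25  # conserved flank at each end
    conserved_flanks: tuple[tuple[int, int], ...] | None = None
    universal_forward: str | None = None
    universal_reverse: str | None = None
    topology: str = "star"  # star | two_clade
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_divergence < 0 or self.between_divergence < 0:
            raise ValueError("divergences must be >= 0")
        if self.between_divergence > 0 and self.within_divergence >= self.between_divergence:
            raise ValueError("within_divergence must be < between_divergence")
        if self.topology not in ("star", "two_clade"):
            raise ValueError(f"unknown topology {self.topology!r}")
        flanks = self.flanks()
        prev_end = 0
        for s, e in flanks:
            if s < prev_end or e > self.marker_length_bp or s >= e:
                raise ValueError(f"bad flank interval ({s}, {e})")
            prev_end = e
        if self.universal_forward and len(self.universal_forward) > flanks[0][1] - flanks[0][0]:
            raise ValueError("universal_forward longer than the first flank")
        if self.universal_reverse and len(self.universal_reverse) > flanks[-1][1] - flanks[-1][0]:
            raise ValueError("universal_reverse longer than the last flank")

    def flanks(self) -> tuple[tuple[int, int], ...]:
        if self.conserved_flanks is not None:
            return self.conserved_flanks
        L, f = self.marker_length_bp, self.flank_bp
        return ((0, f), (L - f, L))

    def variable_mask(self) -> np.ndarray:
        mask = np.ones(self.marker_length_bp, dtype=bool)
        for s, e in self.flanks():
            mask[s:e] = False
        return mask

    @property
    def species_labels(self) -> list[str]:
        return [f"species_{chr(ord('A') + i)}" for i in range(self.n_species)]


@dataclass
class SimulatedTruth:
    ancestral: str
    consensus: dict[str, str]
    mutations: dict[str, list[int]]  # per sequence id, positions differing from consensus
    species_labels: list[str] = field(default_factory=list)


def _jc_evolve(
    seq: np.ndarray, d: float, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One Jukes–Cantor branch of length d (expected substitutions/site);
    sites outside ``mask`` are held fixed."""
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    out = seq.copy()
    hit = mask & (rng.random(len(seq)) < p_diff)
    idx = np.nonzero(hit)[0]
    if len(idx):
        # uniform among the three other bases
        shift = rng.integers(1, 4, size=len(idx))
        out[idx] = (out[idx] + shift) % 4
    return out


def simulate_marker_set(
    config: SimulationConfig,
) -> tuple[SpeciesSequenceSet, SimulatedTruth]:
    """Draw a species-labeled marker set and its generating truth.

    The ancestor is uniform random; each species consensus evolves from it
    at ``between_divergence`` (through a shared internal branch in two-clade
    mode), and each sequence adds ``within_divergence`` of private noise.
    Universal primer sequences, when given, are planted verbatim in the
    flanks (forward at the 5' end, reverse as its reverse-complement at the
    3' end).
    """
    rng = np.random.default_rng(config.seed)
    L = config.marker_length_bp
    mask = config.variable_mask()
    ancestor = rng.integers(0, 4, size=L)

    labels = config.species_labels
    consensus_idx: dict[str, np.ndarray] = {}
    if config.topology == "two_clade" and config.n_species >= 2:
        half = config.between_divergence / 2.0
        clade = _jc_evolve(ancestor, half, mask, rng)
        for i, sp in enumerate(labels):
            start = clade if i < 2 else ancestor
            consensus_idx[sp] = _jc_evolve(start, half, mask, rng)
    else:
        for sp in labels:
            consensus_idx[sp] = _jc_evolve(ancestor, config.between_divergence, mask, rng)

    def planted(chars: str) -> str:
        if config.universal_forward:
            f = config.universal_forward.upper()
            s0 = config.flanks()[0][0]
            chars = chars[:s0] + f + chars[s0 + len(f):]
        if config.universal_reverse:
            r = reverse_complement(config.universal_reverse.upper())
            chars = chars[: L - len(r)] + r
        return chars

    to_str = lambda idx: planted("".join(_BASES[idx]))

    by_species: dict[str, list[NucleotideSequence]] = {}
    mutations: dict[str, list[int]] = {}
    for sp in labels:
        cons = consensus_idx[sp]
        records = []
        for k in range(config.seqs_per_species):
            seq_idx = _jc_evolve(cons, config.within_divergence, mask, rng)
            seq_id = f"{sp}_{k:02d}"
            mutations[seq_id] = np.nonzero(seq_idx != cons)[0].tolist()
            records.append(
                NucleotideSequence(seq_id, sp, to_str(seq_idx), aligned=True)
            )
        by_species[sp] = records

    truth = SimulatedTruth(
        ancestral=to_str(ancestor),
        consensus={sp: to_str(consensus_idx[sp]) for sp in labels},
        mutations=mutations,
        species_labels=labels,
    )
    # no indels are simulated, so the set is alignment-ready as emitted
    return SpeciesSequenceSet(by_species, aligned=True), truth


def simulate_held_out(
    truth: SimulatedTruth,
    config: SimulationConfig,
    n_per_species: int,
    seed: int,
) -> SpeciesSequenceSet:
    """Fresh samples from the same species consensuses (new within-species
    noise only) — held-out data for classification tests.

    Planted primer flanks carry degenerate codes verbatim; they are conserved
    and excluded from the mutation mask, so consensus strings round-trip.
    """
    rng = np.random.default_rng(seed)
    mask = config.variable_mask()
    base_idx = {b: i for i, b in enumerate("ACGT")}
    by_species: dict[str, list[NucleotideSequence]] = {}
    for sp in truth.species_labels:
        cons = truth.consensus[sp]
        cons_idx = np.array([base_idx.get(c, 0) for c in cons])
        records = []
        for k in range(n_per_species):
            seq_idx = _jc_evolve(cons_idx, config.within_divergence, mask, rng)
            chars = list(cons)
            for p in np.nonzero(seq_idx != cons_idx)[0]:
                chars[p] = _BASES[seq_idx[p]]
            records.append(
                NucleotideSequence(
                    f"held_{sp}_{k:03d}", sp, "".join(chars), aligned=True
                )
            )
        by_species[sp] = records
    return SpeciesSequenceSet(by_species, aligned=True)


def simulate_extract_samples(
    truth: SimulatedTruth,
    config: SimulationConfig,
    n_per_species: int,
    molecules_per_sample: int = 3,
    seed: int = 0,
) -> list[tuple[str, list[NucleotideSequence]]]:
    """Held-out *samples* as small pools of template molecules.

    A PCR sample is a DNA extract, not a single molecule: amplification
    succeeds if any template copy in the tube primes.  Each returned sample
    is ``molecules_per_sample`` fresh within-species draws around the true
    species consensus, labeled with the true species for scoring.
    """
    rng = np.random.default_rng(seed)
    mask = config.variable_mask()
    base_idx = {b: i for i, b in enumerate("ACGT")}
    out: list[tuple[str, list[NucleotideSequence]]] = []
    for sp in truth.species_labels:
        cons = truth.consensus[sp]
        cons_idx = np.array([base_idx.get(c, 0) for c in cons])
        for k in range(n_per_species):
            molecules = []
            for mno in range(molecules_per_sample):
                seq_idx = _jc_evolve(cons_idx, config.within_divergence, mask, rng)
                chars = list(cons)
                for p in np.nonzero(seq_idx != cons_idx)[0]:
                    chars[p] = _BASES[seq_idx[p]]
                molecules.append(
                    NucleotideSequence(
                        f"pool_{sp}_{k:03d}_{mno}", sp, "".join(chars), aligned=True
                    )
                )
            out.append((sp, molecules))
    return out


def plant_diagnostic_sites(
    seq_set: SpeciesSequenceSet,
    species: str,
    positions: list[int],
    bases: list[str],
    config: SimulationConfig,
) -> SpeciesSequenceSet:
    """Engineer diagnostic columns: set the given bases at the given
    positions in every sequence of one species, leaving others untouched.

    Positions must lie in the variable interior (planting inside a conserved
    flank would contradict the flank contract and is rejected).
    """
    if len(positions) != len(bases):
        raise ValueError("positions and bases differ in length")
    mask = config.variable_mask()
    for p in positions:
        if not (0 <= p < config.marker_length_bp) or not mask[p]:
            raise ValueError(f"position {p} is inside a conserved flank or out of range")
    if species not in seq_set.by_species:
        raise KeyError(species)
    by_species: dict[str, list[NucleotideSequence]] = {}
    for sp, records in seq_set.by_species.items():
        if sp != species:
            by_species[sp] = list(records)
            continue
        new_records = []
        for rec in records:
            chars = list(rec.residues)
            for p, b in zip(positions, bases):
                chars[p] = b.upper()
            new_records.append(
                NucleotideSequence(rec.id, sp, "".join(chars), aligned=rec.aligned)
            )
        by_species[sp] = new_records
    return SpeciesSequenceSet(by_species, aligned=seq_set.aligned)


def write_truth_tsv(truth: SimulatedTruth, path) -> None:
    """Truth table as TSV: one row per sequence with its mutated positions."""
    import pandas as pd

    rows = [
        {"sequence_id": sid, "n_private_mutations": len(pos),
         "positions": ",".join(map(str, pos))}
        for sid, pos in truth.mutations.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
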