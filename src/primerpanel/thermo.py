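"""Oligo thermodynamics: GC content, nearest-neighbor Tm, hairpin screening,
degenerate-code expansion.

The duplex model is the unified nearest-neighbor parameter set (Allawi &
SantaLucia 1997 dinucleotide ΔH/ΔS with initiation and terminal-A·T
corrections).  The two-state melting temperature at 1 M Na+ is

    Tm = ΔH / (ΔS + R · ln(CT/4))

for a non-self-complementary duplex with primer and complement each present
at the stated oligo concentration (CT is the total strand concentration).
The monovalent-salt dependence follows Owczarzy et al. (2004), applied to
1/Tm with the GC fraction of the oligo — the convention common oligo
analyzers use, under which published panel Tm values are reproduced to
within about 1 °C.

The hairpin screen uses a deliberately simple stem-loop model (Watson–Crick
stems, no bulges or internal loops): ΔG is the sum of stem stacking energies
plus a tabulated loop-initiation penalty.  This is a coarse self-structure
filter, not a secondary-structure prediction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from ._iupac import IUPAC_SETS, degeneracy

R_GAS = 1.987  # cal/(mol·K)

# Unified NN parameters, keyed by top-strand dinucleotide: (ΔH kcal/mol, ΔS cal/mol·K)
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# Duplex initiation per terminal base pair
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)

# Hairpin loop initiation ΔG37 (kcal/mol) by loop length; intermediate sizes
# interpolated, larger sizes extrapolated logarithmically.
HAIRPIN_LOOP_DG37: dict[int, float] = {
    3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.2, 8: 4.3, 9: 4.5, 10: 4.4,
    12: 4.7, 14: 5.0, 16: 5.2, 18: 5.4, 20: 5.5, 25: 5.8, 30: 6.0,
}

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class ThermoConditions:
    """Solution conditions for Tm and ΔG computations.

    Defaults (0.25 uM oligo, 50 mM monovalent, no divalent) mirror the
    defaults of common oligo-analyzer tools, under which the packaged panel
    tables' printed Tm values are assumed computed.
    """

    oligo_conc_uM: float = 0.25
    monovalent_mM: float = 50.0
    divalent_mM: float = 0.0
    dntp_mM: float = 0.0
    temperature_C_for_dG: float = 37.0

    def __post_init__(self) -> None:
        if self.oligo_conc_uM <= 0 or self.monovalent_mM <= 0:
            raise ValueError("oligo and monovalent concentrations must be > 0")
        if self.divalent_mM < 0 or self.dntp_mM < 0:
            raise ValueError("divalent and dNTP concentrations must be >= 0")

    def effective_monovalent_M(self) -> float:
        """Monovalent concentration in mol/L with free Mg2+ folded in via
        the von Ahsen square-root equivalence (a documented approximation;
        zero under the defaults)."""
        free_mg_mM = max(self.divalent_mM - self.dntp_mM, 0.0)
        return (self.monovalent_mM + 120.0 * math.sqrt(free_mg_mM)) / 1000.0


@dataclass(frozen=True)
class ThermoResult:
    tm_C: float
    dH_kcal_mol: float
    dS_cal_molK: float
    dG37_kcal_mol: float


@dataclass(frozen=True)
class HairpinResult:
    min_dG_kcal_mol: float
    stem_len_bp: int
    loop_len_nt: int


def _require_concrete(sequence: str) -> None:
    for i, c in enumerate(sequence):
        if c not in "ACGT":
            raise ValueError(
                f"degenerate code {c!r} at position {i + 1}; expand first "
                "(see expand_degenerate / degenerate_tm_range)"
            )


def gc_percent(sequence: str) -> float:
    """GC content in percent.

    For degenerate codes the expectation over a uniform choice among the
    code's bases is used, which equals the mean GC% over all expansions.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    total = 0.0
    for c in seq:
        bases = IUPAC_SETS[c]
        total += len(bases & {"G", "C"}) / len(bases)
    return 100.0 * total / len(seq)


def gc_percent_range(sequence: str) -> tuple[float, float, float]:
    """(min, mean, max) GC% over all expansions of a degenerate sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    lo = sum(1 for c in seq if IUPAC_SETS[c] <= {"G", "C"})
    hi = sum(1 for c in seq if IUPAC_SETS[c] & {"G", "C"})
    return (100.0 * lo / len(seq), gc_percent(seq), 100.0 * hi / len(seq))


def nn_sums(sequence: str) -> tuple[float, float]:
    """Unified NN ΔH (kcal/mol) and ΔS (cal/mol·K) including initiation and
    terminal-A·T corrections."""
    dH, dS = 0.0, 0.0
    for i in range(len(sequence) - 1):
        h, s = NN_PARAMS[sequence[i:i + 2]]
        dH += h
        dS += s
    for terminal in (sequence[0], sequence[-1]):
        h, s = INIT_AT if terminal in "AT" else INIT_GC
        dH += h
        dS += s
    return dH, dS


def nn_tm(sequence: str, conditions: ThermoConditions | None = None) -> ThermoResult:
    """Nearest-neighbor melting temperature of a non-degenerate oligo.

    Tm at 1 M Na+ comes from ΔH/(ΔS + R·ln(CT/4)); the Owczarzy (2004)
    GC-fraction correction then rescales 1/Tm to the working monovalent
    concentration.
    """
    cond = conditions or ThermoConditions()
    seq = sequence.upper()
    if len(seq) < 6:
        raise ValueError(f"oligo too short for the NN model ({len(seq)} < 6 nt)")
    _require_concrete(seq)

    dH, dS = nn_sums(seq)
    ct = 2.0 * cond.oligo_conc_uM * 1e-6  # primer + complement
    tm_1m = dH * 1000.0 / (dS + R_GAS * math.log(ct / 4.0))

    na = cond.effective_monovalent_M()
    fgc = gc_percent(seq) / 100.0
    inv_tm = (1.0 / tm_1m
              + (4.29 * fgc - 3.95) * 1e-5 * math.log(na)
              + 9.40e-6 * math.log(na) ** 2)
    tm = 1.0 / inv_tm - 273.15

    t_k = cond.temperature_C_for_dG + 273.15
    dg = dH - t_k * dS / 1000.0
    return ThermoResult(tm_C=tm, dH_kcal_mol=dH, dS_cal_molK=dS, dG37_kcal_mol=dg)


def expand_degenerate(sequence: str) -> set[str]:
    """All concrete sequences matching a degenerate IUPAC pattern."""
    seq = sequence.upper()
    pools = [sorted(IUPAC_SETS[c]) for c in seq]
    return {"".join(p) for p in itertools.product(*pools)}


_MAX_FULL_EXPANSION = 4096
_SAMPLE_SIZE = 1024
_SAMPLE_SEED = 7_2025


@dataclass(frozen=True)
class TmRange:
    min_C: float
    mean_C: float
    max_C: float


def degenerate_tm_range(
    sequence: str, conditions: ThermoConditions | None = None
) -> TmRange:
    """Tm statistics over the expansions of a degenerate primer.

    Patterns with more than 4096 expansions are subsampled (1024 draws,
    fixed seed) — degenerate universal barcode primers can reach degeneracies
    in the thousands.
    """
    seq = sequence.upper()
    if degeneracy(seq) <= _MAX_FULL_EXPANSION:
        variants = sorted(expand_degenerate(seq))
    else:
        rng = np.random.default_rng(_SAMPLE_SEED)
        pools = [sorted(IUPAC_SETS[c]) for c in seq]
        variants = [
            "".join(pool[rng.integers(len(pool))] for pool in pools)
            for _ in range(_SAMPLE_SIZE)
        ]
    tms = np.array([nn_tm(v, conditions).tm_C for v in variants])
    return TmRange(float(tms.min()), float(tms.mean()), float(tms.max()))


def _loop_penalty(loop_len: int) -> float:
    if loop_len in HAIRPIN_LOOP_DG37:
        return HAIRPIN_LOOP_DG37[loop_len]
    sizes = sorted(HAIRPIN_LOOP_DG37)
    if loop_len > sizes[-1]:
        # Jacobson–Stockmayer style logarithmic extrapolation
        g30 = HAIRPIN_LOOP_DG37[sizes[-1]]
        return g30 + 1.75 * (R_GAS / 1000.0) * 310.15 * math.log(loop_len / sizes[-1])
    lo = max(s for s in sizes if s < loop_len)
    hi = min(s for s in sizes if s > loop_len)
    frac = (loop_len - lo) / (hi - lo)
    return HAIRPIN_LOOP_DG37[lo] + frac * (HAIRPIN_LOOP_DG37[hi] - HAIRPIN_LOOP_DG37[lo])


def hairpin_decompositions(sequence: str):
    """Yield (dG, stem_len, loop_len) for every simple stem-loop decomposition
    (Watson–Crick stems >= 2 bp, loops >= 3 nt) of a non-degenerate oligo."""
    seq = sequence.upper()
    n = len(seq)
    t_k = 310.15
    for i in range(n):
        for stem in range(2, n // 2 + 1):
            for loop in range(3, n - i - 2 * stem + 1):
                k = i + stem + loop  # start of 3' arm
                if k + stem > n:
                    continue
                arm5 = seq[i:i + stem]
                arm3 = seq[k:k + stem]
                if any(_WC.get(arm5[t]) != arm3[stem - 1 - t] for t in range(stem)):
                    continue
                dg = _loop_penalty(loop)
                for t in range(stem - 1):
                    h, s = NN_PARAMS[arm5[t:t + 2]]
                    dg += h - t_k * s / 1000.0
                yield dg, stem, loop


def hairpin_min_dg(
    sequence: str, conditions: ThermoConditions | None = None
) -> HairpinResult:
    """Most stable simple stem-loop of an oligo.

    Returns the minimum ΔG over all decompositions, or a zero result when no
    stabilizing (ΔG <= 0) structure exists.  Only Watson–Crick stems are
    considered; the loop penalty is the 37 °C table regardless of
    ``conditions`` (the screen is a coarse filter).
    """
    _require_concrete(sequence.upper())
    best: tuple[float, int, int] | None = None
    for dg, stem, loop in hairpin_decompositions(sequence):
        if best is None or (dg, -stem, loop) < (best[0], -best[1], best[2]):
            best = (dg, stem, loop)
    if best is None or best[0] > 0:
        return HairpinResult(0.0, 0, 0)
    return HairpinResult(best[0], best[1], best[2])
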