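"""Candidate primer enumeration, the seven-factor evaluation, and panel
assembly.

A species-specific primer candidate is a sub-slice of a diagnostic window's
target consensus (reverse-site candidates are emitted reverse-complemented,
i.e. 5'->3' as synthesized).  Each candidate is scored on seven factors:

  (1) length within [18, 33] bp;
  (2) one or more target-specific bases within the 3'-terminal window;
  (3) no hairpin more stabilizing than the ΔG threshold (-1 kcal/mol);
  (4) GC content within [35, 60] %;
  (5) discrimination: enough consensus mismatches against every non-target;
  (6) no perfect full-length match anywhere in a non-target (false priming);
  (7) melting temperature compatible with the universal partner.

A panel pairs, per target species, the best passing candidate with the
shared universal primer, and is accepted only when the resulting in-silico
specificity matrix is diagonal-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._iupac import GAP, encode_mask, reverse_complement
from .diagnostics import (
    ColumnProfiles,
    DiagnosticWindow,
    WindowParams,
    find_diagnostic_windows,
    profile_columns,
)
from .pcr import MatchPolicy, predict_amplicons, specificity_matrix
from .seqio import Primer, PrimerPair, SpeciesSequenceSet
from .thermo import (
    ThermoConditions,
    degenerate_tm_range,
    gc_percent,
    hairpin_min_dg,
    nn_tm,
)

FACTOR_NAMES = (
    "length",
    "three_prime_specific",
    "hairpin",
    "gc_content",
    "discrimination",
    "false_priming",
    "tm_compatibility",
)


@dataclass(frozen=True)
class DesignCriteria:
    """Numeric thresholds for the seven-factor candidate evaluation."""

    length_min: int = 18
    length_max: int = 33
    min_specific_3prime: int = 1
    hairpin_dg_threshold: float = -1.0  # pass iff min_dG >= threshold
    gc_min: float = 35.0
    gc_max: float = 60.0
    require_discrimination: bool = True
    min_mismatch_per_nontarget: int = 2
    false_priming_max_identity: float = 100.0
    pair_tm_max_gap: float = 5.0
    three_prime_k: int = 3

    def __post_init__(self) -> None:
        # min > max is allowed (factor (1) then simply never passes); the
        # bounds themselves must stay in the primer-sane range
        if not (6 <= self.length_min <= 50 and 6 <= self.length_max <= 50):
            raise ValueError("length bounds must lie within [6, 50]")

    def window_params(self) -> WindowParams:
        return WindowParams(
            min_mismatch_per_nontarget=self.min_mismatch_per_nontarget,
            three_prime_k=self.three_prime_k,
            min_specific_in_3prime=self.min_specific_3prime,
            window_min=self.length_min,
            window_max=self.length_max,
        )


@dataclass(frozen=True)
class Candidate:
    """A primer candidate extracted from a diagnostic window.

    ``aln_start``/``aln_end`` give the footprint in alignment columns;
    ``sequence`` is 5'->3' as synthesized (reverse-complemented for
    reverse-site candidates).
    """

    sequence: str
    target_species: str
    strand_role: str  # forward_site | reverse_site
    aln_start: int
    aln_end: int
    nontarget_mismatches: dict[str, int] = field(hash=False)
    three_prime_specific: int = 0

    @property
    def discrimination_sum(self) -> int:
        return sum(self.nontarget_mismatches.values())

    @property
    def orientation(self) -> str:
        return "forward" if self.strand_role == "forward_site" else "reverse"


@dataclass(frozen=True)
class FactorResult:
    passed: bool
    value: float


@dataclass
class CandidateEvaluation:
    candidate: Candidate
    factors: dict[str, FactorResult]

    @property
    def passed(self) -> bool:
        return all(f.passed for f in self.factors.values())

    def failed_factors(self) -> list[str]:
        return [name for name, f in self.factors.items() if not f.passed]


@dataclass
class FalsePrimingReport:
    max_identity: float
    best_hits: dict[str, float]
    passed: bool


class PanelDesignError(RuntimeError):
    """Raised when no passing candidate exists for some species; carries a
    per-factor failure summary."""

    def __init__(self, message: str, failure_summary: dict[str, dict[str, int]]):
        super().__init__(message)
        self.failure_summary = failure_summary


@dataclass
class PanelDesign:
    """A complete species-identification panel for one marker."""

    marker: str
    universal_pair: PrimerPair
    pairs: dict[str, PrimerPair]
    evaluations: dict[str, CandidateEvaluation]
    universal_products: dict[str, int] = field(default_factory=dict)

    def primers(self) -> list[Primer]:
        """Unique primers, universals first, in deterministic order."""
        out: list[Primer] = []
        seen: set[str] = set()
        for p in (self.universal_pair.forward, self.universal_pair.reverse):
            if p.name not in seen:
                out.append(p)
                seen.add(p.name)
        for pair in self.pairs.values():
            for p in (pair.forward, pair.reverse):
                if p.name not in seen:
                    out.append(p)
                    seen.add(p.name)
        return out


@dataclass
class LoadedPanel:
    """A panel reconstructed from a primer table (pairs only, no
    evaluations) — enough to run in-silico PCR and classification."""

    marker: str
    universal_pair: PrimerPair | None
    pairs: dict[str, PrimerPair]


def panel_from_primers(primers: list[Primer], marker: str = "marker") -> LoadedPanel:
    """Rebuild species pairs from a flat primer table.

    Universal primers are rows with role ``universal``; each
    species-specific primer is paired with the *last* universal primer of
    opposite orientation in table order — published panels list the shared
    genus- or group-level partner after the outer universal pair, and
    design-written tables carry a single partner per orientation.
    """
    universals = [p for p in primers if p.role == "universal"]
    specifics = [p for p in primers if p.role == "species_specific"]
    u_fwd = [p for p in universals if p.orientation == "forward"]
    u_rev = [p for p in universals if p.orientation == "reverse"]
    universal_pair = (
        PrimerPair(u_fwd[0], u_rev[0]) if u_fwd and u_rev else None
    )
    pairs: dict[str, PrimerPair] = {}
    for p in specifics:
        target = p.target_species or p.name
        if p.orientation == "reverse":
            if not u_fwd:
                raise ValueError(f"no universal forward partner for {p.name!r}")
            pairs[target] = PrimerPair(u_fwd[-1], p)
        else:
            if not u_rev:
                raise ValueError(f"no universal reverse partner for {p.name!r}")
            pairs[target] = PrimerPair(p, u_rev[-1])
    return LoadedPanel(marker, universal_pair, pairs)


def _candidate_metrics(
    profiles: ColumnProfiles, target: str, start: int, end: int, role: str, k: int
) -> tuple[dict[str, int], int]:
    """Per-non-target consensus mismatches and 3'-window specific count for a
    footprint, recomputed from the column profiles."""
    nontargets = [s for s in profiles.species if s != target]
    tmaj = profiles.majority_index(target)
    diffs: dict[str, int] = {}
    specific = np.ones(end - start, dtype=bool)
    for sp in nontargets:
        nmaj = profiles.majority_index(sp)
        d = (tmaj[start:end] != nmaj[start:end]) & (tmaj[start:end] != 4) & (
            nmaj[start:end] != 4
        )
        diffs[sp] = int(d.sum())
        specific &= d
    if role == "forward_site":
        n3 = int(specific[-k:].sum())
    else:
        n3 = int(specific[:k].sum())
    return diffs, n3


def enumerate_candidates(
    aligned_set: SpeciesSequenceSet | ColumnProfiles,
    windows: list[DiagnosticWindow],
    criteria: DesignCriteria | None = None,
) -> list[Candidate]:
    """One candidate per (window, length, offset) combination within the
    length bounds, deduplicated on footprint.

    Candidates whose target consensus slice contains a gap are discarded.
    """
    criteria = criteria or DesignCriteria()
    profiles = (
        aligned_set
        if isinstance(aligned_set, ColumnProfiles)
        else profile_columns(aligned_set)
    )
    out: list[Candidate] = []
    seen: set[tuple[str, str, int, int]] = set()
    for w in windows:
        consensus = profiles.majority_sequence(w.target_species)
        for length in range(criteria.length_min, min(criteria.length_max, w.width) + 1):
            for off in range(w.width - length + 1):
                s, e = w.start + off, w.start + off + length
                key = (w.target_species, w.strand_role, s, e)
                if key in seen:
                    continue
                seen.add(key)
                slice_ = consensus[s:e]
                if GAP in slice_:
                    continue
                seq = slice_ if w.strand_role == "forward_site" else reverse_complement(slice_)
                mism, n3 = _candidate_metrics(
                    profiles, w.target_species, s, e, w.strand_role,
                    criteria.three_prime_k,
                )
                out.append(
                    Candidate(seq, w.target_species, w.strand_role, s, e, mism, n3)
                )
    return out


def check_false_priming(
    candidate: Candidate | str,
    nontarget_sequences,
    criteria: DesignCriteria | None = None,
) -> FalsePrimingReport:
    """Best full-length ungapped match identity of a candidate against each
    non-target sequence, both strands.

    Fails iff some identity reaches the threshold (default 100%, i.e. a
    perfect full-length match somewhere in a non-target).
    """
    criteria = criteria or DesignCriteria()
    seq = candidate.sequence if isinstance(candidate, Candidate) else str(candidate).upper()
    m = len(seq)
    best_hits: dict[str, float] = {}
    for rec in nontarget_sequences:
        tid = getattr(rec, "id", "seq")
        tseq = rec.degapped() if hasattr(rec, "degapped") else str(rec).upper()
        best = 0.0
        if len(tseq) >= m:
            tmask = encode_mask(tseq)
            windows = np.lib.stride_tricks.sliding_window_view(tmask, m)
            for pattern in (seq, reverse_complement(seq)):
                pmask = encode_mask(pattern)
                mism = ((windows & pmask) == 0).sum(axis=1)
                best = max(best, 100.0 * (m - int(mism.min())) / m)
        best_hits[tid] = best
    max_identity = max(best_hits.values(), default=0.0)
    return FalsePrimingReport(
        max_identity=max_identity,
        best_hits=best_hits,
        passed=max_identity < criteria.false_priming_max_identity,
    )


def primer_tm(sequence: str, conditions: ThermoConditions | None = None) -> float:
    """Tm used for filtering: exact NN Tm for concrete oligos, the minimum
    over expansions for degenerate ones (the worst-case variant anneals
    last)."""
    if set(sequence.upper()) <= set("ACGT"):
        return nn_tm(sequence, conditions).tm_C
    return degenerate_tm_range(sequence, conditions).min_C


def evaluate_candidate(
    candidate: Candidate,
    aligned_set: SpeciesSequenceSet,
    criteria: DesignCriteria | None = None,
    conditions: ThermoConditions | None = None,
    universal_partner: Primer | None = None,
) -> CandidateEvaluation:
    """Measure all seven factors; the overall verdict is their conjunction.

    Factor (7) needs the universal partner's Tm; with no partner supplied the
    candidate's own Tm is recorded and the factor passes vacuously.
    """
    criteria = criteria or DesignCriteria()
    conditions = conditions or ThermoConditions()
    n = len(candidate.sequence)
    factors: dict[str, FactorResult] = {}

    factors["length"] = FactorResult(
        criteria.length_min <= n <= criteria.length_max, float(n)
    )
    factors["three_prime_specific"] = FactorResult(
        candidate.three_prime_specific >= criteria.min_specific_3prime,
        float(candidate.three_prime_specific),
    )
    hp = hairpin_min_dg(candidate.sequence, conditions)
    factors["hairpin"] = FactorResult(
        hp.min_dG_kcal_mol >= criteria.hairpin_dg_threshold, hp.min_dG_kcal_mol
    )
    gc = gc_percent(candidate.sequence)
    factors["gc_content"] = FactorResult(criteria.gc_min <= gc <= criteria.gc_max, gc)
    worst = min(candidate.nontarget_mismatches.values(), default=0)
    factors["discrimination"] = FactorResult(
        (not criteria.require_discrimination)
        or worst >= criteria.min_mismatch_per_nontarget,
        float(worst),
    )
    nontarget_records = [
        rec
        for sp in aligned_set.species
        if sp != candidate.target_species
        for rec in aligned_set[sp]
    ]
    fp = check_false_priming(candidate, nontarget_records, criteria)
    factors["false_priming"] = FactorResult(fp.passed, fp.max_identity)
    tm = primer_tm(candidate.sequence, conditions)
    if universal_partner is not None:
        gap = abs(tm - primer_tm(universal_partner.sequence, conditions))
        factors["tm_compatibility"] = FactorResult(gap <= criteria.pair_tm_max_gap, gap)
    else:
        factors["tm_compatibility"] = FactorResult(True, tm)
    return CandidateEvaluation(candidate, factors)


def _consensus_map(profiles: ColumnProfiles, species: str) -> tuple[str, np.ndarray]:
    """Degapped consensus and an alignment-column -> consensus-position map
    (-1 at gap columns)."""
    maj = profiles.majority_sequence(species)
    pos = np.full(len(maj), -1, dtype=int)
    p = 0
    chars = []
    for j, c in enumerate(maj):
        if c != GAP:
            pos[j] = p
            p += 1
            chars.append(c)
    return "".join(chars), pos


def assemble_panel(
    aligned_set: SpeciesSequenceSet,
    universal_forward: Primer,
    universal_reverse: Primer,
    criteria: DesignCriteria | None = None,
    conditions: ThermoConditions | None = None,
    marker: str = "marker",
    orientation: str = "reverse",
    policy: MatchPolicy | None = None,
    restrict_to_universal_amplicon: bool = True,
    max_failure_log: int = 200,
) -> PanelDesign:
    """Design one species-specific pair per species and assemble the panel.

    ``orientation`` selects the design shape: ``"reverse"`` pairs a
    species-specific reverse primer with the universal forward (the classic
    16S shape), ``"forward"`` pairs a species-specific forward with the
    universal reverse (the COI shape).  Candidates are restricted to the
    universal amplicon interior by default so every specific product nests
    inside the universal product.

    The chosen candidate must amplify every sequence of its target and no
    sequence of any other panel species; the assembled panel is finally
    re-checked as a full specificity matrix and rejected on any
    cross-species amplification.
    """
    criteria = criteria or DesignCriteria()
    conditions = conditions or ThermoConditions()
    policy = policy or MatchPolicy()
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"bad orientation {orientation!r}")
    if criteria.length_min > criteria.length_max:
        raise PanelDesignError(
            "no candidate can satisfy the length factor: "
            f"length_min={criteria.length_min} > length_max={criteria.length_max}",
            {sp: {"length": 1} for sp in aligned_set.species},
        )

    profiles = profile_columns(aligned_set)
    universal_pair_product: dict[str, int] = {}
    spans: dict[str, tuple[int, int]] = {}
    upair = PrimerPair(universal_forward, universal_reverse)
    for sp in aligned_set.species:
        consensus, colmap = _consensus_map(profiles, sp)
        amps = predict_amplicons(consensus, upair, policy)
        if not amps:
            raise PanelDesignError(
                f"universal primers do not amplify species {sp!r}", {}
            )
        a = amps[0]
        universal_pair_product[sp] = a.length_bp
        # interior between the two universal footprints, in alignment columns
        interior = np.nonzero(
            (colmap >= a.forward_site.end) & (colmap < a.reverse_site.start)
        )[0]
        spans[sp] = (int(interior[0]), int(interior[-1]) + 1) if len(interior) else (0, 0)

    partner = universal_forward if orientation == "reverse" else universal_reverse
    wanted_role = "reverse_site" if orientation == "reverse" else "forward_site"
    wp = criteria.window_params()

    pairs: dict[str, PrimerPair] = {}
    evaluations: dict[str, CandidateEvaluation] = {}
    failure_summary: dict[str, dict[str, int]] = {}

    for sp in aligned_set.species:
        windows = [
            w
            for w in find_diagnostic_windows(profiles, sp, wp)
            if w.strand_role == wanted_role
        ]
        if restrict_to_universal_amplicon:
            lo, hi = spans[sp]
            windows = [w for w in windows if w.start >= lo and w.end <= hi]
        candidates = enumerate_candidates(profiles, windows, criteria)
        candidates.sort(
            key=lambda c: (
                -c.discrimination_sum,
                -c.three_prime_specific,
                c.aln_start,
                c.aln_end - c.aln_start,
            )
        )
        chosen = None
        fails: dict[str, int] = {name: 0 for name in FACTOR_NAMES}
        n_logged = 0
        for cand in candidates:
            ev = evaluate_candidate(cand, aligned_set, criteria, conditions, partner)
            if not ev.passed:
                if n_logged < max_failure_log:
                    for name in ev.failed_factors():
                        fails[name] += 1
                    n_logged += 1
                continue
            primer = Primer(
                name=f"{marker}_{sp}_{'r' if orientation == 'reverse' else 'f'}",
                sequence=cand.sequence,
                orientation=orientation,
                role="species_specific",
                target_species=sp,
                reported_tm_C=round(primer_tm(cand.sequence, conditions), 1),
            )
            pair = (
                PrimerPair(universal_forward, primer)
                if orientation == "reverse"
                else PrimerPair(primer, universal_reverse)
            )
            target_ok = all(
                predict_amplicons(rec, pair, policy) for rec in aligned_set[sp]
            )
            cross = any(
                predict_amplicons(rec, pair, policy)
                for other in aligned_set.species
                if other != sp
                for rec in aligned_set[other]
            )
            if not target_ok or cross:
                continue
            consensus, _ = _consensus_map(profiles, sp)
            amps = predict_amplicons(consensus, pair, policy)
            product = amps[0].length_bp if amps else None
            chosen = (
                PrimerPair(pair.forward, pair.reverse, expected_product_bp=product),
                ev,
            )
            break
        if chosen is None:
            failure_summary[sp] = fails
            continue
        pairs[sp], evaluations[sp] = chosen

    if failure_summary:
        lines = []
        for sp, fails in failure_summary.items():
            detail = ", ".join(f"{k}={v}" for k, v in fails.items() if v)
            lines.append(f"{sp}: no passing candidate (failures: {detail or 'none enumerated'})")
        raise PanelDesignError("; ".join(lines), failure_summary)

    panel = PanelDesign(
        marker=marker,
        universal_pair=PrimerPair(
            universal_forward,
            universal_reverse,
            expected_product_bp=universal_pair_product[aligned_set.species[0]],
        ),
        pairs=pairs,
        evaluations=evaluations,
        universal_products=universal_pair_product,
    )
    matrix = specificity_matrix(panel, aligned_set, policy)
    if not matrix.is_diagonal_only():
        raise PanelDesignError(
            "assembled panel shows cross-species amplification", {}
        )
    return panel
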