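"""Degenerate-aware in-silico PCR: binding-site search, amplicon prediction,
specificity matrices and panel-based species assignment.

Matching is IUPAC set-intersection on 4-bit base masks: a primer position
matches a template position iff their base sets overlap, so degenerate codes
on either side behave correctly.  Coordinates are 0-based half-open on the
template top strand throughout.

By default a primer's 5' tail may overhang the template ends with the
overhang uncounted as mismatches ("terminal truncation") — deposited
barcode sequences are often partially primer-trimmed amplicons, and with
truncation allowed they still report the full published product size (the
overhang is counted into the product length).  The 3' anchor (the policy's
3' window) must always lie on the template: extension starts there, and
without that constraint any primer whose terminal base matched a template
edge would bind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol

import numpy as np

from ._iupac import encode_mask, reverse_complement
from .seqio import NucleotideSequence, Primer, PrimerPair, SpeciesSequenceSet


@dataclass(frozen=True)
class MatchPolicy:
    max_mismatch: int = 2
    three_prime_window: int = 3
    three_prime_max_mismatch: int = 0
    min_product: int = 50
    max_product: int = 2000
    allow_terminal_truncation: bool = True

    def __post_init__(self) -> None:
        if self.min_product > self.max_product:
            raise ValueError("min_product > max_product")


@dataclass(frozen=True)
class BindingSite:
    """Primer footprint on the template top strand.

    ``start``/``end`` give the full footprint (end - start equals the primer
    length); with terminal truncation the footprint may extend beyond the
    template, so ``start`` can be negative and ``end`` can exceed the
    template length.  ``mismatches_3prime`` is counted over the policy's 3'
    window measured from the primer's own 3' terminus.
    """

    template_id: str
    start: int
    end: int
    strand: str  # "+" | "-"
    mismatches_total: int
    mismatches_3prime: int


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    product_start: int
    product_end: int
    forward_site: BindingSite
    reverse_site: BindingSite

    @property
    def length_bp(self) -> int:
        return self.product_end - self.product_start


def _as_template(template) -> tuple[str, str]:
    if isinstance(template, NucleotideSequence):
        return template.id, template.degapped()
    return "template", str(template).upper()


def _primer_seq(primer: Primer | str) -> str:
    return primer.sequence if isinstance(primer, Primer) else str(primer).upper()


def find_binding_sites(
    template,
    primer: Primer | str,
    policy: MatchPolicy | None = None,
) -> list[BindingSite]:
    """All policy-satisfying binding sites of a primer on both strands.

    On the plus strand the primer sequence reads along the top strand
    (3' end rightmost); on the minus strand its reverse-complement appears
    on the top strand (primer 3' end leftmost in top-strand coordinates).
    With terminal truncation, only the 5' side may overhang a template end;
    the 3' window must sit fully on the template.
    """
    policy = policy or MatchPolicy()
    tid, tseq = _as_template(template)
    pseq = _primer_seq(primer)
    m = len(pseq)
    if m < policy.three_prime_window:
        raise ValueError(
            f"primer length {m} shorter than 3' window {policy.three_prime_window}"
        )
    n = len(tseq)
    pad = m - 1 if policy.allow_terminal_truncation else 0
    # N pads match every primer base, so overhang positions are uncounted
    tmask = np.full(n + 2 * pad, 15, dtype=np.uint8)
    tmask[pad:pad + n] = encode_mask(tseq)
    if len(tmask) < m:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(tmask, m)

    sites: list[BindingSite] = []
    k = policy.three_prime_window
    for strand, pattern in (("+", pseq), ("-", reverse_complement(pseq))):
        pmask = encode_mask(pattern)
        mism = (windows & pmask) == 0
        totals = mism.sum(axis=1)
        if strand == "+":
            three = mism[:, m - k:].sum(axis=1)
        else:
            three = mism[:, :k].sum(axis=1)
        ok = (totals <= policy.max_mismatch) & (three <= policy.three_prime_max_mismatch)
        if pad:
            starts = np.arange(len(windows)) - pad
            if strand == "+":  # 3' end rightmost: anchor [end-k, end) on template
                ok &= (starts + m <= n) & (starts + m - k >= 0)
            else:  # 3' end leftmost on the top strand
                ok &= (starts >= 0) & (starts + k <= n)
        hits = np.nonzero(ok)[0]
        for h in hits:
            start = int(h) - pad
            sites.append(
                BindingSite(
                    template_id=tid,
                    start=start,
                    end=start + m,
                    strand=strand,
                    mismatches_total=int(totals[h]),
                    mismatches_3prime=int(three[h]),
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(
    template,
    pair: PrimerPair,
    policy: MatchPolicy | None = None,
) -> list[AmpliconPrediction]:
    """All products of a primer pair on one template, sorted by length.

    A product needs a plus-strand forward site upstream of a minus-strand
    reverse site; its length spans both primer footprints inclusively
    (reverse_site.end - forward_site.start).
    """
    policy = policy or MatchPolicy()
    fwd = [s for s in find_binding_sites(template, pair.forward, policy)
           if s.strand == "+"]
    rev = [s for s in find_binding_sites(template, pair.reverse, policy)
           if s.strand == "-"]
    tid, _ = _as_template(template)
    out = []
    for f in fwd:
        for r in rev:
            if f.start >= r.end or f.end > r.start:
                continue
            length = r.end - f.start
            if policy.min_product <= length <= policy.max_product:
                out.append(AmpliconPrediction(tid, f.start, r.end, f, r))
    out.sort(key=lambda a: (a.length_bp, a.product_start))
    return out


class _PanelLike(Protocol):
    pairs: dict[str, PrimerPair]


@dataclass
class SpecificityMatrix:
    """Primer-pair (row) x species (column) amplification table — the
    computational analogue of a specificity gel panel."""

    targets: list[str]
    species: list[str]
    amplified: np.ndarray  # bool, shape (targets, species)
    products: dict[tuple[str, str], list[int]]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.amplified, index=self.targets, columns=self.species)

    def is_diagonal_only(self) -> bool:
        """True iff every pair amplifies its own target species and nothing
        else (extra columns such as off-panel species must be all-negative)."""
        return all(
            bool(self.amplified[i, j]) == (t == s)
            for i, t in enumerate(self.targets)
            for j, s in enumerate(self.species)
        )


def specificity_matrix(
    panel: _PanelLike,
    species_set: SpeciesSequenceSet,
    policy: MatchPolicy | None = None,
    extra_columns: Iterable[str] = ("NTC",),
) -> SpecificityMatrix:
    """Exhaustive pair x species in-silico amplification matrix.

    A cell is positive iff the pair yields at least one predicted amplicon on
    some sequence of that species.  ``extra_columns`` adds always-empty
    template columns (default a no-template control) that must come out
    negative.
    """
    policy = policy or MatchPolicy()
    targets = list(panel.pairs)
    species = list(species_set.species) + [
        c for c in extra_columns if c not in species_set.species
    ]
    amp = np.zeros((len(targets), len(species)), dtype=bool)
    products: dict[tuple[str, str], list[int]] = {}
    for i, t in enumerate(targets):
        pair = panel.pairs[t]
        for j, sp in enumerate(species):
            lengths: list[int] = []
            for rec in species_set.by_species.get(sp, []):
                lengths += [a.length_bp for a in predict_amplicons(rec, pair, policy)]
            amp[i, j] = bool(lengths)
            products[(t, sp)] = sorted(lengths)
    return SpecificityMatrix(targets, species, amp, products)


@dataclass(frozen=True)
class SampleCall:
    sample_id: str
    call: str  # species label | "none" | "ambiguous"
    amplified_targets: tuple[str, ...]
    products: dict[str, tuple[int, ...]] = field(hash=False, default_factory=dict)


def classify_sample(
    sequences,
    panel: _PanelLike,
    policy: MatchPolicy | None = None,
    sample_id: str = "sample",
) -> SampleCall:
    """Assign a species to an unknown sample by running the whole panel.

    The call is the target species whose pair amplifies, ``none`` when no
    pair does, and ``ambiguous`` when more than one does (e.g. a chimeric
    template carrying two species' diagnostic sites).
    """
    policy = policy or MatchPolicy()
    if isinstance(sequences, (str, NucleotideSequence)):
        sequences = [sequences]
    elif isinstance(sequences, SpeciesSequenceSet):
        sequences = list(sequences)
    hits: list[str] = []
    products: dict[str, tuple[int, ...]] = {}
    for target, pair in panel.pairs.items():
        lengths: list[int] = []
        for seq in sequences:
            lengths += [a.length_bp for a in predict_amplicons(seq, pair, policy)]
        if lengths:
            hits.append(target)
            products[target] = tuple(sorted(lengths))
    if len(hits) == 1:
        call = hits[0]
    elif not hits:
        call = "none"
    else:
        call = "ambiguous"
    return SampleCall(sample_id, call, tuple(hits), products)
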