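"""Scikit-learn style wrapper around panel design and species assignment.

``PanelClassifier.fit`` designs a species-specific primer panel from labeled
marker sequences; ``predict`` runs the panel in silico on unknown sequences
and returns species calls.  The estimator composes with sklearn model
selection (``get_params``/``set_params``, accuracy ``score``); samples that
amplify with no pair or more than one pair are called ``"none"`` /
``"ambiguous"``, which count against accuracy.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .design import DesignCriteria, PanelDesign, assemble_panel
from .pcr import MatchPolicy, classify_sample, specificity_matrix
from .phylo import reference_anchored_alignment
from .seqio import NucleotideSequence, Primer, SpeciesSequenceSet
from .thermo import ThermoConditions


class PanelClassifier(BaseEstimator, ClassifierMixin):
    """Species identification by designed PCR panel.

    Parameters
    ----------
    universal_forward, universal_reverse:
        Universal primer sequences (5'->3' as synthesized) bounding the
        marker; both are required at fit time.
    orientation:
        ``"reverse"`` designs species-specific reverse primers paired with
        the universal forward; ``"forward"`` the opposite shape.
    criteria, conditions, policy:
        Seven-factor design thresholds, thermodynamic conditions and the
        in-silico match policy; defaults are the package defaults.
    marker:
        Label carried into primer names and reports.
    """

    def __init__(
        self,
        universal_forward: str | None = None,
        universal_reverse: str | None = None,
        orientation: str = "reverse",
        criteria: DesignCriteria | None = None,
        conditions: ThermoConditions | None = None,
        policy: MatchPolicy | None = None,
        marker: str = "marker",
    ):
        self.universal_forward = universal_forward
        self.universal_reverse = universal_reverse
        self.orientation = orientation
        self.criteria = criteria
        self.conditions = conditions
        self.policy = policy
        self.marker = marker

    def _to_set(self, X, y) -> SpeciesSequenceSet:
        seqs = [str(x).upper() for x in X]
        if len(seqs) != len(y):
            raise ValueError("X and y differ in length")
        if not seqs:
            raise ValueError("empty training set")
        by_species: dict[str, list[NucleotideSequence]] = {}
        aligned = len({len(s) for s in seqs}) == 1
        for i, (s, label) in enumerate(zip(seqs, y)):
            by_species.setdefault(str(label), []).append(
                NucleotideSequence(f"train_{i:03d}", str(label), s, aligned=aligned)
            )
        seq_set = SpeciesSequenceSet(by_species, aligned=aligned)
        if not aligned:
            seq_set = reference_anchored_alignment(seq_set, "train_000")
        return seq_set

    def fit(self, X, y):
        """Design the panel from labeled marker sequences.

        X is a sequence of nucleotide strings (pre-aligned if equal length,
        otherwise anchored on the first record); y the species labels.
        """
        if not self.universal_forward or not self.universal_reverse:
            raise ValueError("universal_forward and universal_reverse are required")
        seq_set = self._to_set(X, y)
        uf = Primer("universal_f", self.universal_forward, "forward", "universal")
        ur = Primer("universal_r", self.universal_reverse, "reverse", "universal")
        self.panel_: PanelDesign = assemble_panel(
            seq_set,
            uf,
            ur,
            criteria=self.criteria,
            conditions=self.conditions,
            marker=self.marker,
            orientation=self.orientation,
            policy=self.policy,
        )
        self.classes_ = np.array(sorted(seq_set.species))
        self.specificity_matrix_ = specificity_matrix(self.panel_, seq_set, self.policy)
        return self

    def predict(self, X):
        if not hasattr(self, "panel_"):
            raise RuntimeError("PanelClassifier is not fitted")
        calls = [
            classify_sample(str(x).upper(), self.panel_, self.policy).call for x in X
        ]
        return np.asarray(calls, dtype=object)
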