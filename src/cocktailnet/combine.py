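"""Predicting a combination drug's expression profile from its members.

For small doses the expression value of gene i under n simultaneous drugs is
approximated by a first-order Taylor expansion around the untreated state.
Rewriting in case/control ratios (which cancels the unequal baselines of
separate experiments), the combination ratio for gene i is

    F_i = 1 + sum_j (r_ij - 1)

where r_ij is the single-drug ratio of gene i under drug j.  When all members
push a gene in the same direction the linear sum can overshoot (and for
co-repression can even go negative), so a saturating variant caps the
combined deviation at the most extreme member deviation:

    F_i = 1 + s * max_j |r_ij - 1|   (s the shared sign)

falling back to the additive form when member deviations disagree in sign.
Either way the predicted ratio is clipped from below at a small positive
floor so that downstream log-weights stay defined; clip events are recorded
per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionProfile, abs_log2

logger = logging.getLogger(__name__)

MODES = ("additive", "saturating")

#: lower clip applied to predicted ratios (log-weights need r > 0)
RATIO_FLOOR = 0.01


@dataclass
class ComboPrediction:
    """Predicted ratio profile of an n-drug combination."""

    member_labels: list[str]
    combo_ratios: pd.Series
    mode_used_per_gene: pd.Series
    weights: pd.Series

    @property
    def label(self) -> str:
        return "+".join(self.member_labels)

    def as_profile(self) -> ExpressionProfile:
        return ExpressionProfile(self.label, self.combo_ratios, weights=self.weights)


def combine_ratios(
    member_ratios: Sequence[float],
    mode: str = "additive",
    ratio_floor: float = RATIO_FLOOR,
) -> tuple[float, str]:
    """Combine one gene's single-drug ratios into a combination ratio.

    Returns ``(ratio, mode_used)`` where ``mode_used`` is ``additive``,
    ``saturated`` or ``clipped``.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    r = np.asarray(member_ratios, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one member ratio")
    if (r <= 0).any():
        raise ValueError("member ratios must be strictly positive")
    dev = r - 1.0
    used = "additive"
    value = 1.0 + dev.sum()
    if mode == "saturating" and r.size > 1:
        nonzero = dev[dev != 0]
        if nonzero.size and (np.all(nonzero > 0) or np.all(nonzero < 0)):
            s = 1.0 if nonzero[0] > 0 else -1.0
            value = 1.0 + s * np.abs(dev).max()
            used = "saturated"
    if value < ratio_floor:
        value = ratio_floor
        used = "clipped"
    return float(value), used


def predict_profile(
    members: Sequence[ExpressionProfile],
    mode: str = "additive",
    ratio_floor: float = RATIO_FLOOR,
) -> ComboPrediction:
    """Gene-wise combination prediction over the members' shared genes.

    The prediction is defined on the intersection of the member gene sets so
    that every predicted gene has a ratio (and hence a weight) from each
    member.  Weights are recomputed from the predicted ratios.
    """
    if len(members) == 0:
        raise ValueError("need at least one member profile")
    genes = set.intersection(*(m.genes for m in members))
    if not genes:
        raise ValueError("member profiles share no genes")
    idx = sorted(genes)
    mat = np.column_stack([m.ratios.reindex(idx).to_numpy() for m in members])
    values, modes = [], []
    for row in mat:
        v, used = combine_ratios(row, mode=mode, ratio_floor=ratio_floor)
        values.append(v)
        modes.append(used)
    n_clipped = sum(1 for m in modes if m == "clipped")
    if n_clipped:
        logger.info("predict_profile: clipped %d gene ratios at %g", n_clipped, ratio_floor)
    ratios = pd.Series(values, index=idx, dtype=float)
    return ComboPrediction(
        member_labels=[m.treatment_label for m in members],
        combo_ratios=ratios,
        mode_used_per_gene=pd.Series(modes, index=idx),
        weights=abs_log2(ratios),
    )
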