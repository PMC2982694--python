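"""Efficacy / side-effect scoring of affected subnetworks.

A drug's overall effect is judged from its affected subnetwork.  The weight
it puts on disease genes measures efficacy; the weight it puts on essential
genes that are unrelated to the disease (knockout-lethal "innocent"
bystanders) measures side-effect liability.  Both are normalised by the
corresponding weight totals over the whole background network, so they live
in [0, 1] and are invariant to rescaling all weights.  The two terms are
balanced by a parameter lambda:

    S_eff = lambda * sum_{SD} w / sum_{BD} w  -  (1 - lambda) * sum_{ED} w / sum_{EB} w

with SD the disease genes in the subnetwork, BD the disease genes in the
background, ED the essential-non-disease genes in the subnetwork and EB the
same set over the background.  A combination is called effective when its
S_eff exceeds that of every member drug alone.

Each treatment is scored with its own weights: member drugs use their
single-drug profiles, a combination uses its predicted profile.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .combine import predict_profile
from .expression import ExpressionProfile
from .network import MolecularNetwork
from .subnetwork import AffectedSubnetworkModel, InfeasibleModelError, SubnetworkResult

logger = logging.getLogger(__name__)


def _wsum(genes: Iterable[str], weights: Mapping[str, float]) -> float:
    return float(sum(float(weights.get(g, 0.0)) for g in genes))


def efficacy_score(
    subnet_genes: Iterable[str],
    weights: Mapping[str, float],
    disease_genes: Iterable[str],
    background_genes: Iterable[str],
) -> float:
    """Fraction of background disease-gene weight captured by the subnetwork."""
    disease = set(disease_genes)
    if not disease:
        raise ValueError("disease gene set is empty")
    bd = set(background_genes) & disease
    sd = set(subnet_genes) & disease
    denom = _wsum(bd, weights)
    if denom == 0:
        logger.warning("efficacy_score: zero disease weight in background")
        return 0.0
    return _wsum(sd, weights) / denom


def side_effect_score(
    subnet_genes: Iterable[str],
    weights: Mapping[str, float],
    essential_genes: Iterable[str],
    disease_genes: Iterable[str],
    background_genes: Iterable[str],
) -> float:
    """Fraction of background essential-non-disease weight captured.

    Essential genes that are also disease genes are excluded from both the
    numerator and denominator sets: hitting them is intended, not collateral.
    """
    essential = set(essential_genes) - set(disease_genes)
    background = set(background_genes)
    eb = background & essential
    ed = set(subnet_genes) & essential
    denom = _wsum(eb, weights)
    if denom == 0:
        return 0.0
    return _wsum(ed, weights) / denom


def s_eff(efficacy: float, side_effect: float, lam: float) -> float:
    """Balanced overall score lambda*efficacy - (1-lambda)*side_effect."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    return lam * efficacy - (1.0 - lam) * side_effect


def lambda_scan(
    efficacy: float, side_effect: float, grid_step: float = 0.05
) -> pd.DataFrame:
    """Table of S_eff over a lambda grid from 0 to 1."""
    n = round(1.0 / grid_step)
    if abs(n * grid_step - 1.0) > 1e-9:
        raise ValueError("grid_step must divide 1")
    lams = np.linspace(0.0, 1.0, n + 1)
    return pd.DataFrame({
        "lambda": lams,
        "s_eff": [s_eff(efficacy, side_effect, l) for l in lams],
    })


@dataclass
class ScoreBreakdown:
    """Full scoring record for one treatment's subnetwork."""

    treatment_label: str
    lam: float
    efficacy: float
    side_effect: float
    s_eff: float
    sd: tuple[str, ...]
    bd: tuple[str, ...]
    ed: tuple[str, ...]
    subnetwork: SubnetworkResult | None = None


def score_subnetwork(
    label: str,
    subnet_genes: Iterable[str],
    weights: Mapping[str, float],
    disease_genes: Iterable[str],
    essential_genes: Iterable[str],
    background_genes: Iterable[str],
    lam: float = 0.5,
    subnetwork: SubnetworkResult | None = None,
) -> ScoreBreakdown:
    subnet = set(subnet_genes)
    disease = set(disease_genes)
    background = set(background_genes)
    eff = efficacy_score(subnet, weights, disease, background)
    se = side_effect_score(subnet, weights, essential_genes, disease, background)
    return ScoreBreakdown(
        treatment_label=label,
        lam=lam,
        efficacy=eff,
        side_effect=se,
        s_eff=s_eff(eff, se, lam),
        sd=tuple(sorted(subnet & disease)),
        bd=tuple(sorted(background & disease)),
        ed=tuple(sorted((subnet & set(essential_genes)) - disease)),
        subnetwork=subnetwork,
    )


@dataclass
class CombinationVerdict:
    combo_label: str
    combo_score: float
    member_scores: list[float]
    effective: bool


class CombinationScreen:
    """Screen all size-k drug subsets for effective combinations.

    Built from the background network, one expression profile per drug, the
    drug->target map and the disease / essential gene sets.  ``fit()``
    predicts each combination's profile from its members, extracts the
    affected subnetwork for every member drug and every combination, scores
    them all at the chosen lambda and returns the ranked verdict table.
    """

    def __init__(
        self,
        network: MolecularNetwork,
        profiles: Mapping[str, ExpressionProfile],
        targets_map: Mapping[str, Iterable[str]],
        disease_genes: Iterable[str],
        essential_genes: Iterable[str],
        lam: float = 0.5,
        combine_mode: str = "saturating",
        order: int = 2,
        r_step: int = 1,
    ):
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        if order < 2:
            raise ValueError("combination order must be >= 2")
        self.network = network
        self.disease_genes = {g.upper() for g in disease_genes}
        self.essential_genes = {g.upper() for g in essential_genes}
        self.lam = lam
        self.combine_mode = combine_mode
        self.order = order
        self.r_step = r_step
        # exclude drugs whose targets are outside the background network
        self.profiles: dict[str, ExpressionProfile] = {}
        self.targets_map: dict[str, tuple[str, ...]] = {}
        for drug in sorted(profiles):
            targets = {t.upper() for t in targets_map.get(drug, ())}
            outside = targets - network.nodes
            if not targets or outside:
                logger.warning(
                    "excluding drug %s: targets %s not in background network",
                    drug, sorted(outside) or "(none given)",
                )
                continue
            self.profiles[drug] = profiles[drug]
            self.targets_map[drug] = tuple(sorted(targets))

    # -- internals --------------------------------------------------------
    def _weights_on_network(self, profile: ExpressionProfile) -> pd.Series:
        return profile.weights.reindex(sorted(self.network.nodes)).fillna(0.0)

    def _score_treatment(self, label: str, profile: ExpressionProfile,
                         targets: Sequence[str]) -> ScoreBreakdown:
        w = self._weights_on_network(profile)
        res = AffectedSubnetworkModel(self.network, w, targets).fit(r_step=self.r_step)
        return score_subnetwork(
            label, res.genes, dict(w.items()), self.disease_genes,
            self.essential_genes, self.network.nodes, lam=self.lam,
            subnetwork=res.subnetwork,
        )

    # -- fitting ----------------------------------------------------------
    def fit(self) -> "CombinationScreenResults":
        members = {d: self._score_treatment(d, p, self.targets_map[d])
                   for d, p in self.profiles.items()}
        combos: dict[str, ScoreBreakdown] = {}
        verdicts: list[CombinationVerdict] = []
        for subset in itertools.combinations(sorted(self.profiles), self.order):
            prediction = predict_profile(
                [self.profiles[d] for d in subset], mode=self.combine_mode
            )
            targets = sorted(set().union(*(self.targets_map[d] for d in subset)))
            breakdown = self._score_treatment(
                prediction.label, prediction.as_profile(), targets
            )
            combos[prediction.label] = breakdown
            member_scores = [members[d].s_eff for d in subset]
            verdicts.append(CombinationVerdict(
                combo_label=prediction.label,
                combo_score=breakdown.s_eff,
                member_scores=member_scores,
                effective=breakdown.s_eff > max(member_scores),
            ))
        verdicts.sort(key=lambda v: (-v.combo_score, v.combo_label))
        return CombinationScreenResults(self, members, combos, verdicts)


class CombinationScreenResults:
    """Ranked combination verdicts plus per-treatment score breakdowns."""

    def __init__(self, model: CombinationScreen,
                 member_breakdowns: dict[str, ScoreBreakdown],
                 combo_breakdowns: dict[str, ScoreBreakdown],
                 verdicts: list[CombinationVerdict]):
        self.model = model
        self.member_breakdowns = member_breakdowns
        self.combo_breakdowns = combo_breakdowns
        self.verdicts_list = verdicts

    @property
    def verdicts(self) -> pd.DataFrame:
        rows = []
        for v in self.verdicts_list:
            rows.append({
                "combination": v.combo_label,
                "combo_score": v.combo_score,
                "member_scores": ", ".join(f"{s:.6f}" for s in v.member_scores),
                "effective": v.effective,
            })
        return pd.DataFrame(rows)

    def lambda_scan(self, label: str, grid_step: float = 0.05) -> pd.DataFrame:
        """S_eff over lambda for one scored treatment (member or combo)."""
        b = self.combo_breakdowns.get(label) or self.member_breakdowns.get(label)
        if b is None:
            raise KeyError(f"no scored treatment {label!r}")
        return lambda_scan(b.efficacy, b.side_effect, grid_step=grid_step)

    def summary(self) -> str:
        df = self.verdicts
        lines = [
            "Drug-combination screen",
            "=" * 44,
            f"drugs screened:    {len(self.member_breakdowns)}",
            f"combinations:      {len(self.verdicts_list)} (order {self.model.order})",
            f"lambda:            {self.model.lam}",
            f"combine mode:      {self.model.combine_mode}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.6f}"),
        ]
        return "\n".join(lines)
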