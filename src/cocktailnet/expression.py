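"""Expression preprocessing: probe matrices -> per-drug ratio profiles.

The raw input mirrors large perturbation-compendium experiments (drug-treated
cell lines versus vehicle controls, probe-level intensities, batches spread
over several array runs).  Processing proceeds in stages:

1. probe-level values are collapsed to gene symbols, resolving composite
   symbol strings such as ``HSPA1A /// HSPA1B``;
2. the sample table is filtered (batch merge, removal of single-perturbagen
   batches, restriction to one cell line);
3. for each (drug, dose) a single case vector T and control vector C are
   formed by averaging replicate cases within a batch against the mean of
   their linked controls, then averaging across batches;
4. the per-gene case/control ratio T_i / C_i becomes the treatment's
   expression profile, and the node weight is w_i = |log2(T_i / C_i)| —
   a symmetric magnitude of differential expression (w(r) = w(1/r)).

The weight function is pluggable; any monotone transform of |log r| only
rescales all downstream scores jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL_LABEL = "CONTROL"

#: floor applied to control intensities before forming ratios
DEFAULT_CONTROL_FLOOR = 1e-6

META_COLUMNS = ["sample_id", "batch_id", "cell_line", "perturbagen", "dose", "control_ids"]


def abs_log2(ratios: pd.Series) -> pd.Series:
    """Default node-weight function: w_i = |log2 ratio_i|."""
    if (ratios <= 0).any():
        bad = ratios.index[ratios <= 0][:5].tolist()
        raise ValueError(f"non-positive ratios for {bad}")
    return np.abs(np.log2(ratios.astype(float)))


WEIGHT_FUNCTIONS: dict[str, Callable[[pd.Series], pd.Series]] = {"abs_log2": abs_log2}


@dataclass
class ExpressionProfile:
    """Per-gene case/control ratios and node weights for one treatment."""

    treatment_label: str
    ratios: pd.Series
    weights: pd.Series = field(default=None)  # type: ignore[assignment]
    weight_fn: Callable[[pd.Series], pd.Series] = abs_log2

    def __post_init__(self) -> None:
        self.ratios = pd.Series(self.ratios, dtype=float)
        if (self.ratios <= 0).any():
            raise ValueError("ratios must be strictly positive")
        if self.weights is None:
            self.weights = self.weight_fn(self.ratios)
        else:
            self.weights = pd.Series(self.weights, dtype=float)
            if (self.weights < 0).any():
                raise ValueError("weights must be non-negative")

    @property
    def genes(self) -> set[str]:
        return set(self.ratios.index)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the sample table invariants and normalise dtypes.

    ``control_ids`` may be a list or a ';'-separated string; it is normalised
    to a list of sample ids.  Every referenced control must exist and every
    non-control sample must have dose > 0.
    """
    meta = meta.copy()
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["batch_id"] = meta["batch_id"].astype(str)
    meta["dose"] = meta["dose"].astype(float)

    def _to_list(v) -> list[str]:
        if isinstance(v, (list, tuple)):
            return [str(x) for x in v]
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            return []
        return [x for x in str(v).split(";") if x]

    meta["control_ids"] = meta["control_ids"].map(_to_list)
    known = set(meta["sample_id"])
    for _, row in meta.iterrows():
        unknown = [c for c in row["control_ids"] if c not in known]
        if unknown:
            raise ValueError(f"sample {row['sample_id']} references unknown controls {unknown}")
        if row["perturbagen"] != CONTROL_LABEL and row["dose"] <= 0:
            raise ValueError(f"non-control sample {row['sample_id']} has dose <= 0")
    return meta


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_gene_map: pd.Series | dict
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples.

    Two-step rule.  First, every distinct symbol string (possibly composite,
    e.g. ``"A /// B"``) gets the arithmetic mean of its probes.  Second, a
    true gene's value is the mean over all symbol strings that equal it or
    contain it as a '///'-separated token.  Probes without a mapping entry
    are dropped (count logged).
    """
    if probe_matrix.shape[1] == 0:
        raise ValueError("probe matrix has zero samples")
    mapping = pd.Series(probe_gene_map).astype(str)
    mapped = probe_matrix.index.intersection(mapping.index)
    n_dropped = probe_matrix.shape[0] - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    if len(mapped) == 0:
        raise ValueError("no probe has a mapping entry")
    mat = probe_matrix.loc[mapped].astype(float)
    by_string = mat.groupby(mapping.loc[mapped]).mean()

    tokens: dict[str, list[str]] = {}
    for sym_string in by_string.index:
        for tok in (t.strip() for t in sym_string.split("///")):
            if tok:
                tokens.setdefault(tok, []).append(sym_string)
    rows = {gene: by_string.loc[strings].mean(axis=0) for gene, strings in tokens.items()}
    out = pd.DataFrame(rows).T
    out.index.name = "gene"
    return out.sort_index()


def filter_samples(
    meta: pd.DataFrame,
    cell_line: str = "MCF7",
    merge_batches: tuple[str, str] = ("2", "2a"),
) -> pd.DataFrame:
    """Apply the sample-table filters, in order.

    1. The two historically split batches (default ids "2" and "2a") are
       relabeled to one batch.
    2. Batches whose non-control samples contain exactly one distinct
       perturbagen are removed entirely (cases and controls).
    3. Only samples from the configured cell line survive.
    """
    meta = validate_metadata(meta)
    keep_id, drop_id = merge_batches
    meta.loc[meta["batch_id"] == drop_id, "batch_id"] = keep_id

    def _n_drugs(group: pd.DataFrame) -> int:
        return group.loc[group["perturbagen"] != CONTROL_LABEL, "perturbagen"].nunique()

    counts = meta.groupby("batch_id").apply(_n_drugs, include_groups=False)
    single = set(counts.index[counts == 1])
    if single:
        logger.info("filter_samples: removing single-perturbagen batches %s", sorted(single))
    meta = meta[~meta["batch_id"].isin(single)]
    meta = meta[meta["cell_line"] == cell_line]
    if meta.empty:
        logger.warning("filter_samples: no samples left after filtering")
    return meta.reset_index(drop=True)


def aggregate_case_control(
    gene_matrix: pd.DataFrame,
    meta: pd.DataFrame,
    drug: str,
    dose: float,
) -> tuple[pd.Series, pd.Series]:
    """One case vector T and one control vector C for (drug, dose).

    Within each batch, every case sample is compared against the arithmetic
    mean of its linked controls; replicate cases (and their control means)
    are averaged.  Across batches, T and C are the means of the per-batch
    vectors.
    """
    meta = validate_metadata(meta)
    cases = meta[(meta["perturbagen"] == drug) & (meta["dose"] == float(dose))]
    if cases.empty:
        raise ValueError(f"no case samples for drug={drug!r} dose={dose}")
    batch_T, batch_C = [], []
    for _, group in cases.groupby("batch_id"):
        case_vals, ctrl_vals = [], []
        for _, row in group.iterrows():
            ctrl_ids = list(dict.fromkeys(row["control_ids"]))  # dedup, keep order
            if not ctrl_ids:
                raise ValueError(f"case sample {row['sample_id']} has no linked controls")
            case_vals.append(gene_matrix[row["sample_id"]].astype(float))
            ctrl_vals.append(gene_matrix[ctrl_ids].astype(float).mean(axis=1))
        batch_T.append(pd.concat(case_vals, axis=1).mean(axis=1))
        batch_C.append(pd.concat(ctrl_vals, axis=1).mean(axis=1))
    T = pd.concat(batch_T, axis=1).mean(axis=1)
    C = pd.concat(batch_C, axis=1).mean(axis=1)
    return T, C


def compute_ratios(
    T: pd.Series, C: pd.Series, control_floor: float = DEFAULT_CONTROL_FLOOR
) -> pd.Series:
    """Per-gene ratio T_i / C_i; genes with C_i <= floor are dropped."""
    T, C = T.align(C, join="inner")
    ok = C > control_floor
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("compute_ratios: dropped %d genes with control <= %g", n_dropped, control_floor)
    if not ok.any():
        raise ValueError("all genes dropped: every control value at or below the floor")
    return (T[ok] / C[ok]).astype(float)


def compute_weights(
    ratios: pd.Series, weight_fn: Callable[[pd.Series], pd.Series] = abs_log2
) -> pd.Series:
    """Node weights from ratios (default |log2 r|, symmetric in r <-> 1/r)."""
    return weight_fn(pd.Series(ratios, dtype=float))


def drug_profile(
    gene_matrix: pd.DataFrame,
    meta: pd.DataFrame,
    drug: str,
    dose: float | None = None,
    weight_fn: Callable[[pd.Series], pd.Series] = abs_log2,
    control_floor: float = DEFAULT_CONTROL_FLOOR,
) -> ExpressionProfile:
    """Single representative ratio profile for a drug.

    With ``dose=None`` the profile averages the per-dose ratio profiles over
    every dose observed for the drug (gene-wise mean of ratios); a specific
    dose restricts to that dose alone.
    """
    meta = validate_metadata(meta)
    if dose is None:
        doses = sorted(
            meta.loc[meta["perturbagen"] == drug, "dose"].unique().tolist()
        )
        if not doses:
            raise ValueError(f"no case samples for drug={drug!r}")
    else:
        doses = [float(dose)]
    per_dose = []
    for d in doses:
        T, C = aggregate_case_control(gene_matrix, meta, drug, d)
        per_dose.append(compute_ratios(T, C, control_floor=control_floor))
    ratios = pd.concat(per_dose, axis=1, join="inner").mean(axis=1)
    return ExpressionProfile(drug, ratios, weight_fn=weight_fn)
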