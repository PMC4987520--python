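"""Bench-assay statistics: Ig rearrangement frequency by qPCR, relative
expression, comet-assay outlier calling, gammaH2AX focus scoring, and
peripheral-blood lineage counts.

Ct (cycle threshold) arithmetic follows the delta-Ct convention throughout:
one PCR cycle is one doubling, so a Ct difference of d cycles corresponds to
a 2**d abundance ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FOCI_POSITIVE_MIN = 4
MIN_CELLS_PER_SAMPLE = 50
MAD_MULTIPLIER = 3.0


def rearrangement_frequency(ct_actb: float, ct_ig: float) -> float:
    """Ig rearrangement frequency from qPCR cycle thresholds.

    Computed as 2**(Ct_Actb - Ct_Ig): the Ig segment amplifies from only the
    rearranged alleles while Actb amplifies from every genome, so the cycle
    offset measures the rearranged fraction.
    """
    if not (math.isfinite(ct_actb) and math.isfinite(ct_ig)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (ct_actb - ct_ig)


def rearrangement_frequencies(table: pd.DataFrame, target: str) -> pd.Series:
    """Per-sample rearrangement frequency from a long-format Ct table.

    The table needs columns sample_id, target, ct and an Actb row per sample.
    """
    out = {}
    for sid, grp in table.groupby("sample_id"):
        actb = grp.loc[grp["target"] == "Actb", "ct"]
        ig = grp.loc[grp["target"] == target, "ct"]
        if actb.empty:
            raise ValueError(f"sample {sid!r} has no Actb record")
        if ig.empty:
            continue
        out[sid] = rearrangement_frequency(float(actb.iloc[0]), float(ig.iloc[0]))
    return pd.Series(out, name="frequency")


def relative_expression(ct_gene: float, ct_actb: float) -> float:
    """Expression of a gene relative to the Actb reference: 2**(Ct_Actb - Ct_gene)."""
    if not (math.isfinite(ct_gene) and math.isfinite(ct_actb)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (ct_actb - ct_gene)


def normalize_to_control(
    values: Sequence[float], groups: Sequence[str], control_group: str = "control"
) -> np.ndarray:
    """Express each value as fold of the control-group mean.

    The control-group mean maps to exactly 1.0. Composing with
    :func:`relative_expression` gives the delta-delta-Ct quantity.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ctrl = values[groups == control_group]
    if ctrl.size == 0:
        raise ValueError(f"no samples in control group {control_group!r}")
    mean = ctrl.mean()
    if mean == 0:
        raise ValueError("control-group mean is zero")
    return values / mean


@dataclass(frozen=True)
class MadOutlierResult:
    """Outcome of MAD-based outlier calling on a tail-moment sample."""

    flags: np.ndarray
    median: float
    mad: float

    @property
    def outlier_fraction(self) -> float:
        return float(self.flags.mean())


def mad_outlier_classify(
    tail_moments: Sequence[float], multiplier: float = MAD_MULTIPLIER
) -> MadOutlierResult:
    """Flag comet tail moments whose absolute deviation from the median is
    at least ``multiplier`` (default 3) median absolute deviations.

    The MAD is unscaled (no 1.4826 normal-consistency factor). When the MAD
    is zero — at least half the cells share the median value — the literal
    rule would flag every cell, so instead only cells with any nonzero
    deviation are flagged.
    """
    x = np.asarray(tail_moments, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 cells to estimate median and MAD")
    m = float(np.median(x))
    dev = np.abs(x - m)
    mad = float(np.median(dev))
    if mad == 0:
        flags = dev > 0
    else:
        flags = dev >= multiplier * mad
    return MadOutlierResult(flags=flags, median=m, mad=mad)


def foci_classify(
    records: pd.DataFrame, threshold: int = FOCI_POSITIVE_MIN
) -> tuple[pd.Series, pd.DataFrame]:
    """Score gammaH2AX focus counts: positive at >= ``threshold`` foci.

    ``records`` needs columns sample_id and n_foci; a missing (NA) n_foci
    marks an unscorable cell. Returns the per-cell boolean labels (False
    for unscorable cells) and a per-sample table with the positive fraction
    over scored cells (``positive_fraction``) and over all cells including
    unscorable ones (``positive_fraction_raw``); the two coincide when every
    cell was scored. Samples with fewer than 50 scored cells trigger a
    warning (scoring conventions call for more).
    """
    n_foci = pd.to_numeric(records["n_foci"], errors="raise")
    scored = n_foci.notna()
    vals = n_foci[scored]
    if (vals < 0).any() or (vals != vals.round()).any():
        raise ValueError("n_foci must be non-negative integers")
    positive = (n_foci >= threshold).fillna(False)
    by_sample = records["sample_id"]
    fractions = pd.DataFrame(
        {
            "positive_fraction": positive[scored].groupby(by_sample[scored]).mean(),
            "positive_fraction_raw": positive.groupby(by_sample).mean(),
        }
    )
    for sid, n in scored.groupby(by_sample).sum().items():
        if n < MIN_CELLS_PER_SAMPLE:
            logger.warning("sample %s has only %d scored cells (<%d)", sid, n, MIN_CELLS_PER_SAMPLE)
    return positive, fractions


def lineage_cell_count(wbc: float, lineage_fraction: float) -> float:
    """Absolute lineage cell count per microlitre of blood.

    Multiplies the complete-blood-count white-cell concentration by the
    flow-cytometry lineage fraction.
    """
    if not 0 <= lineage_fraction <= 1:
        raise ValueError("lineage_fraction must be in [0, 1]")
    return wbc * lineage_fraction


def group_summary(values: Sequence[float], groups: Sequence[str]) -> pd.DataFrame:
    """Mean, s.d. and s.e.m. per group, the summaries figures typically report."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    g = df.groupby("group")["value"]
    out = g.agg(["count", "mean", "std"])
    out["sem"] = out["std"] / np.sqrt(out["count"])
    return out
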