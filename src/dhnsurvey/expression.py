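"""TPM expression classification: bins, expression calls, UR/DR status.

Expression is consumed as TPM matrices (genes x conditions; quantification
from raw reads is out of scope).  Values are binned into three levels —
low (< 1), medium ([1, 10]) and high (> 10); the "> 10" boundary is strict,
and 1 falls in medium so that "expressed" (max TPM >= 1) and "medium or
above" agree.  A gene is up-regulated (UR) under a treatment when its fold
change over control exceeds the fold threshold (default 1, i.e. any
increase) AND its TPM increases by more than the delta threshold (default
10); down-regulation (DR) is the exact mirror, so
``call_regulation(a, b) == UR`` iff ``call_regulation(b, a) == DR``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import DEFAULT_CONFIG, Config

BINS = ("low", "medium", "high")


@dataclass(frozen=True)
class ExpressionCall:
    """Bin and regulation status for one gene under one condition."""

    gene: str
    condition: str
    bin: str
    regulation: str  # "UR", "DR" or "none"


def _check_matrix(matrix: pd.DataFrame) -> None:
    if (matrix.values < 0).any():
        raise ValueError("TPM matrix contains negative values")


def bin_expression(tpm_value: float, config: Config = DEFAULT_CONFIG) -> str:
    """Three-level expression bin of a single TPM value."""
    if tpm_value < 0:
        raise ValueError("negative TPM")
    if tpm_value < config.tpm_low:
        return "low"
    if tpm_value <= config.tpm_high:
        return "medium"
    return "high"


def call_regulation(
    tpm_treatment: float, tpm_control: float, config: Config = DEFAULT_CONFIG
) -> str:
    """UR / DR / none for one treatment-vs-control TPM pair.

    A zero denominator in the fold ratio is guarded by the configured
    pseudocount.  The rule is antisymmetric by construction.
    """
    if tpm_treatment < 0 or tpm_control < 0:
        raise ValueError("negative TPM")

    def fold(num: float, den: float) -> float:
        return num / (den if den > 0 else config.pseudocount)

    delta = tpm_treatment - tpm_control
    if fold(tpm_treatment, tpm_control) > config.fold_threshold and delta > config.delta_threshold:
        return "UR"
    if fold(tpm_control, tpm_treatment) > config.fold_threshold and -delta > config.delta_threshold:
        return "DR"
    return "none"


def expressed_in(
    matrix: pd.DataFrame,
    gene: str,
    condition_set=None,
    config: Config = DEFAULT_CONFIG,
) -> bool:
    """True iff the gene's maximum TPM over the condition set reaches the
    low/medium cut-point (default 1)."""
    if gene not in matrix.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    row = matrix.loc[gene]
    if condition_set is not None:
        row = row[list(condition_set)]
    return float(row.max()) >= config.tpm_low


def summarize_bins(
    matrix: pd.DataFrame, condition: str, config: Config = DEFAULT_CONFIG
) -> dict[str, int]:
    """Gene counts per expression bin for one condition (sums to n genes)."""
    _check_matrix(matrix)
    counts = {b: 0 for b in BINS}
    for value in matrix[condition]:
        counts[bin_expression(float(value), config)] += 1
    return counts


def call_matrix(
    matrix: pd.DataFrame,
    contrasts: dict[str, str] | None = None,
    config: Config = DEFAULT_CONFIG,
) -> list[ExpressionCall]:
    """Per gene x condition calls for a whole matrix.

    ``contrasts`` maps treatment column -> control column; conditions without
    a contrast get regulation "none".
    """
    _check_matrix(matrix)
    contrasts = contrasts or {}
    calls = []
    for gene in matrix.index:
        for condition in matrix.columns:
            tpm = float(matrix.loc[gene, condition])
            regulation = "none"
            if condition in contrasts:
                control = float(matrix.loc[gene, contrasts[condition]])
                regulation = call_regulation(tpm, control, config)
            calls.append(
                ExpressionCall(str(gene), str(condition), bin_expression(tpm, config), regulation)
            )
    return calls
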