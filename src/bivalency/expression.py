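"""Relating chromatin states to expression.

Groups expression values by consensus chromatin state with pairwise Wilcoxon
rank-sum comparisons, and filters externally supplied differential-expression
tables by FDR and log2 fold-change thresholds. DE model fitting itself is
upstream; this module only consumes its output table.
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np
import pandas as pd

from .signal_quant import compare_groups
from .states import STATE_ORDER, ChromatinState

logger = logging.getLogger(__name__)


def log2p1(x):
    """log2(x + 1), the conventional abundance transform (0 maps to 0)."""
    return np.log2(np.asanyarray(x, dtype=float) + 1.0)


def expression_by_state(
    expression: pd.Series,
    consensus_states,
    transform: Callable | None = log2p1,
    exact_max_n: int = 8,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Per-state expression vectors plus all pairwise Wilcoxon p-values.

    ``expression`` maps gene_id to abundance (TPM/FPKM). Only genes present
    in both inputs are used; empty categories are skipped with a notice.
    """
    from .dynamics import _as_state_series

    states = _as_state_series(consensus_states)
    common = expression.index.intersection(states.index)
    groups: dict[str, np.ndarray] = {}
    for state in STATE_ORDER:
        genes = [g for g in common if ChromatinState(states[g]) is state]
        if not genes:
            logger.info("expression_by_state: no genes in %s; skipped", state.value)
            continue
        values = expression[genes].to_numpy(dtype=float)
        groups[state.value] = transform(values) if transform else values
    pvalues = compare_groups(groups, exact_max_n=exact_max_n) if len(groups) >= 2 \
        else pd.DataFrame(columns=["group_a", "group_b", "p_value"])
    return groups, pvalues


def filter_de_genes(
    de_records: pd.DataFrame, fdr_max: float = 0.05, lfc_min: float = 1.0
) -> set[str]:
    """Genes with fdr strictly below ``fdr_max`` and |log2fc| strictly above
    ``lfc_min`` (both boundaries exclusive)."""
    required = {"gene_id", "log2fc", "fdr"}
    if not required <= set(de_records.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    if ((de_records["fdr"] < 0) | (de_records["fdr"] > 1)).any():
        raise ValueError("fdr values must lie in [0, 1]")
    keep = (de_records["fdr"] < fdr_max) & (de_records["log2fc"].abs() > lfc_min)
    return set(de_records.loc[keep, "gene_id"])
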