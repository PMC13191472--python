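"""Chromatin-state dynamics across conditions: transition flows, origin
attribution of newly bivalent genes, conserved vs cancer-specific bivalency,
and Venn set partitions."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Mapping

import pandas as pd

from .states import STATE_ORDER, ChromatinState, ConsensusStateTable

logger = logging.getLogger(__name__)


def _as_state_series(states) -> pd.Series:
    if isinstance(states, ConsensusStateTable):
        return states.consensus
    return pd.Series(states)


@dataclass
class FlowMatrix:
    """4x4 gene counts of state transitions between two conditions.

    Rows are the state in condition A, columns the state in condition B;
    ``gene_lists[(a, b)]`` holds the genes of each cell.
    """

    counts: pd.DataFrame
    gene_lists: dict[tuple[ChromatinState, ChromatinState], list[str]]

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def flow_matrix(states_a, states_b) -> FlowMatrix:
    """Cross-tabulate per-gene states between two conditions.

    Only genes present in both tables are counted; dropped genes are logged.
    """
    a, b = _as_state_series(states_a), _as_state_series(states_b)
    common = a.index.intersection(b.index)
    dropped = len(a.index.union(b.index)) - len(common)
    if len(common) == 0:
        raise ValueError("no genes shared between the two state tables")
    if dropped:
        logger.info("flow_matrix: %d genes absent from one condition dropped", dropped)

    labels = [s.value for s in STATE_ORDER]
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    gene_lists: dict[tuple[ChromatinState, ChromatinState], list[str]] = {
        (s, t): [] for s in STATE_ORDER for t in STATE_ORDER
    }
    for gene in common:
        s, t = ChromatinState(a[gene]), ChromatinState(b[gene])
        counts.loc[s.value, t.value] += 1
        gene_lists[(s, t)].append(gene)
    return FlowMatrix(counts=counts, gene_lists=gene_lists)


def origin_fractions(
    flow: FlowMatrix, target: ChromatinState = ChromatinState.BIVALENT
) -> dict[ChromatinState, float] | None:
    """Among genes newly in ``target`` in condition B, the fraction arriving
    from each condition-A state. Returns None when no gene is newly in target."""
    col = flow.counts[target.value]
    newly = {s: int(col[s.value]) for s in STATE_ORDER if s != target}
    denom = sum(newly.values())
    if denom == 0:
        logger.info("origin_fractions: no genes newly in %s", target.value)
        return None
    return {s: n / denom for s, n in newly.items()}


class BivalencyClass(str, Enum):
    CONSERVED_BIVALENT = "CONSERVED_BIVALENT"
    CANCER_SPECIFIC_BIVALENT = "CANCER_SPECIFIC_BIVALENT"
    OTHER = "OTHER"


def classify_cross_tissue(
    esc_states, normal_states, cancer_states, relaxed: bool = False
) -> pd.Series:
    """Classify genes as conserved vs cancer-specific bivalent.

    CONSERVED_BIVALENT: bivalent in both ESC and cancer. CANCER_SPECIFIC_BIVALENT:
    H3K4me3-only in both ESC and normal tissue but bivalent in cancer (with
    ``relaxed``, any non-bivalent ESC/normal state qualifies). Everything else
    is OTHER.
    """
    esc = _as_state_series(esc_states)
    normal = _as_state_series(normal_states)
    cancer = _as_state_series(cancer_states)
    genes = esc.index.intersection(normal.index).intersection(cancer.index)

    out = {}
    for gene in genes:
        e, n, c = ChromatinState(esc[gene]), ChromatinState(normal[gene]), ChromatinState(cancer[gene])
        if e is ChromatinState.BIVALENT and c is ChromatinState.BIVALENT:
            out[gene] = BivalencyClass.CONSERVED_BIVALENT
        elif c is ChromatinState.BIVALENT and (
            (e is ChromatinState.K4_ONLY and n is ChromatinState.K4_ONLY)
            if not relaxed
            else (e is not ChromatinState.BIVALENT and n is not ChromatinState.BIVALENT)
        ):
            out[gene] = BivalencyClass.CANCER_SPECIFIC_BIVALENT
        else:
            out[gene] = BivalencyClass.OTHER
    series = pd.Series(out, dtype=object)
    series.index.name = "gene_id"
    return series


@dataclass
class VennPartition:
    """Exact region counts and memberships for a 2- or 3-set Venn."""

    regions: pd.DataFrame  # columns: region, count
    members: dict[str, set]

    def count(self, region: str) -> int:
        row = self.regions.loc[self.regions["region"] == region, "count"]
        return int(row.iloc[0])


def venn_partition(named_sets: Mapping[str, set]) -> VennPartition:
    """Partition 2 or 3 named gene sets into disjoint Venn regions.

    Region names are '&'-joined sorted member names (e.g. ``"A_only"``,
    ``"A&B"``, ``"A&B&C"``).
    """
    names = list(named_sets)
    if len(names) not in (2, 3):
        raise ValueError("venn_partition supports exactly 2 or 3 sets")
    sets = {k: set(v) for k, v in named_sets.items()}

    members: dict[str, set] = {}
    for r in range(len(names), 0, -1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            region = "&".join(combo) if r > 1 else f"{combo[0]}_only"
            members[region] = inside - outside
    rows = [{"region": k, "count": len(v)} for k, v in members.items()]
    return VennPartition(regions=pd.DataFrame(rows), members=members)
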