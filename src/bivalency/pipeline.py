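"""End-to-end pipeline over a manifest-described run directory.

Stages run in order: sample QC -> per-sample state calls -> cohort consensus
-> condition dynamics -> signal quantification -> methylation -> expression.
All outputs are TSV/JSON next to the inputs; the run report lists every
output with a checksum so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import dynamics, expression, methylation, signal_quant, states
from .genome_io import read_gene_models, read_peak_bed, promoter_windows
from .states import K4, K27, ChromatinState

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Scalar parameters of the whole pipeline (defaults match the method)."""

    half_width: int = 2000
    consensus_threshold: float = 0.5
    qc_tol: float = 0.3
    strict_overlap: bool = False
    pseudocount: float = 1.0
    min_cpg: int = 30
    meth_threshold: float = 0.5
    de_fdr: float = 0.05
    de_lfc: float = 1.0
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        for name in ("consensus_threshold", "qc_tol", "meth_threshold", "de_fdr"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.min_cpg < 1:
            raise ValueError("min_cpg must be >= 1")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunReport:
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    warnings: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})

    def checksum(self, path: Path) -> None:
        self.outputs[str(path.name)] = _sha256(path)

    def write(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "stages": self.stages,
            "outputs": self.outputs,
            "warnings": self.warnings,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_manifest_peaks(run_dir: Path, manifest: pd.DataFrame):
    """Read every peak BED named in the manifest, grouped condition/sample/mark."""
    cohorts: dict[str, dict[str, dict[str, object]]] = {}
    for row in manifest.itertuples(index=False):
        try:
            ps = read_peak_bed(
                run_dir / row.path, row.sample_id, row.mark,
                total_mapped_reads=int(row.total_mapped_reads),
                spike_reads=int(row.spike_reads),
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage read_peak_bed failed on {row.path}: {exc}"
            ) from exc
        cohorts.setdefault(row.condition, {}).setdefault(row.sample_id, {})[row.mark] = ps
    return cohorts


def run_pipeline(run_dir, config: AnalysisConfig | None = None) -> RunReport:
    """Run every stage on a simulate-style run directory; idempotent."""
    config = config or AnalysisConfig()
    config.validate()
    run_dir = Path(run_dir)
    out = run_dir / "analysis"
    out.mkdir(exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config) | {"paths": {}})

    manifest = pd.read_csv(run_dir / "manifest.tsv", sep="\t")
    genes = read_gene_models(run_dir / "genes.bed", fmt="BED")
    cohorts = load_manifest_peaks(run_dir, manifest)
    report.record("load", n_genes=len(genes), n_files=len(manifest))

    consensus_by_condition = {}
    for condition, peak_sets in sorted(cohorts.items()):
        counts = {
            mark: {
                s: by_mark[mark].n_peaks
                for s, by_mark in peak_sets.items() if mark in by_mark
            }
            for mark in (K4, K27)
        }
        qc = states.qc_filter_samples(counts, tol=config.qc_tol)
        retained = {s: peak_sets[s] for s in qc.retained_samples}
        qc_path = out / f"qc_{condition}.tsv"
        qc.per_sample.to_csv(qc_path, sep="\t", index=False)
        report.checksum(qc_path)
        report.record(f"qc[{condition}]", retained=len(retained),
                      excluded=len(peak_sets) - len(retained))
        if not retained:
            raise RuntimeError(f"stage qc: no sample retained in condition {condition}")

        table = states.call_states_cohort(
            genes, retained, half_width=config.half_width,
            require_mutual_overlap=config.strict_overlap, cohort_id=condition,
        )
        st_path = out / f"states_{condition}.tsv"
        table.states.map(lambda s: s.value).to_csv(st_path, sep="\t")
        report.checksum(st_path)

        cons = states.consensus_states(table, threshold=config.consensus_threshold)
        cons_out = cons.table.copy()
        cons_out["consensus_state"] = cons_out["consensus_state"].map(lambda s: s.value)
        cons_path = out / f"consensus_{condition}.tsv"
        cons_out.to_csv(cons_path, sep="\t")
        report.checksum(cons_path)
        report.record(f"states[{condition}]", n_genes=len(cons.table),
                      n_bivalent=int((cons.consensus == ChromatinState.BIVALENT).sum()))
        consensus_by_condition[condition] = cons

    if len(consensus_by_condition) >= 2:
        names = sorted(consensus_by_condition)
        a, b = names[0], names[1]
        flow = dynamics.flow_matrix(consensus_by_condition[a], consensus_by_condition[b])
        flow_long = (
            flow.counts.rename_axis("state_a")
            .reset_index()
            .melt(id_vars="state_a", var_name="state_b", value_name="count")
        )
        flow_path = out / f"flow_{a}_to_{b}.tsv"
        flow_long.to_csv(flow_path, sep="\t", index=False)
        report.checksum(flow_path)
        origins = dynamics.origin_fractions(flow)
        report.record("dynamics", total=flow.total,
                      origins={s.value: f for s, f in origins.items()} if origins else None)

    spike = {
        row.sample_id: int(row.spike_reads)
        for row in manifest.drop_duplicates("sample_id").itertuples(index=False)
    }
    factors = signal_quant.spike_scaling_factors(spike)
    spike_path = out / "spike_factors.tsv"
    pd.Series(factors.factors, name="factor").rename_axis("sample_id").to_csv(
        spike_path, sep="\t")
    report.checksum(spike_path)
    report.record("quantify", n_samples=len(factors.factors))

    cpg_path = run_dir / "cpg_calls.tsv"
    if cpg_path.exists():
        calls = methylation.read_cpg_calls(cpg_path)
        windows = promoter_windows(genes, config.half_width)
        last = sorted(consensus_by_condition)[-1]
        cons = consensus_by_condition[last]
        classes = {}
        rows = []
        for w in windows:
            rm = methylation.classify_region_methylation(
                w.interval, calls, min_cpg=config.min_cpg,
                threshold=config.meth_threshold,
            )
            classes[w.gene_id] = rm.classification
            rows.append({
                "gene_id": w.gene_id, "n_cpg": rm.n_cpg,
                "weighted_level": rm.weighted_level,
                "classification": rm.classification.value,
            })
        meth_path = out / "methylation.tsv"
        pd.DataFrame(rows).to_csv(meth_path, sep="\t", index=False)
        report.checksum(meth_path)
        by_state = methylation.methylation_by_state(classes, cons)
        bys_path = out / "methylation_by_state.tsv"
        by_state.to_csv(bys_path, sep="\t", index=False)
        report.checksum(bys_path)
        report.record("methylation", n_regions=len(rows))

    expr_path = run_dir / "expression.tsv"
    if expr_path.exists():
        expr = pd.read_csv(expr_path, sep="\t", index_col="gene_id")
        last = sorted(consensus_by_condition)[-1]
        groups, pvals = expression.expression_by_state(
            expr["tpm_b"], consensus_by_condition[last])
        pv_path = out / "expression_wilcoxon.tsv"
        pvals.to_csv(pv_path, sep="\t", index=False)
        report.checksum(pv_path)
        d_expr = signal_quant.log2fc_signal(
            expr["tpm_a"], expr["tpm_b"], config.pseudocount)
        report.record("expression", n_genes=len(expr),
                      groups={k: len(v) for k, v in groups.items()},
                      mean_abs_d_expr=float(d_expr.abs().mean()))

    report_path = out / "run_report.json"
    report.write(report_path)
    return report
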