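"""End-to-end orchestration: simulate → build-ref → demux → quantify → stats.

One declarative YAML config drives a run.  When a ``simulate`` block is
present the pipeline generates its own library (and writes the matching
ground truth next to the results); otherwise it consumes external FASTQ
plus a sample sheet.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .align import AlignParams, PairAligner, counts_frame, quantify_sample
from .demux import BarcodeTable, DemuxReport, demux_and_trim, read_fastq_pairs
from .reference import ReferenceSet, build_reference, parse_gene_fasta
from .simulate import (
    ADAPTER3,
    ADAPTER5,
    ChargingProfile,
    Scenario,
    SimConfig,
    SimulatedLibrary,
    default_scenario,
    simulate_library,
)
from .stats import compare_conditions, fraction_charged, normalize, summarize_replicates
from .util import revcomp

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "trnacharge_out"
    genes_fasta: str | None = None          # gene set (genomic, no CCA)
    r1_fastq: str | None = None
    r2_fastq: str | None = None
    sample_sheet: str | None = None
    simulate: dict[str, Any] | None = None  # present -> simulate the library
    barcode_mismatch: int = 0
    min_len: int = 20
    classification_mode: str = "sequence"
    normalization_basis: str = "classified"
    contrasts: list[tuple[str, str]] = field(default_factory=list)
    write_per_sample_fastq: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "contrasts" in raw:
            raw["contrasts"] = [tuple(str(c).split(":")) if isinstance(c, str)
                                else tuple(c) for c in raw["contrasts"]]
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("genes_fasta", "r1_fastq", "r2_fastq", "sample_sheet"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigError(f"config needs {name} (or a simulate block)")
                if not Path(p).exists():
                    raise ConfigError(f"{name} path does not exist: {p}")
        if self.classification_mode not in ("sequence", "end_anchored"):
            raise ConfigError(f"bad classification_mode {self.classification_mode!r}")
        if self.barcode_mismatch not in (0, 1):
            raise ConfigError("barcode_mismatch must be 0 or 1")
        if self.min_len < 1:
            raise ConfigError("min_len must be positive")

    def content_hash(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """Everything a pipeline run produced, in memory."""

    reference: ReferenceSet
    demux_report: DemuxReport
    counts: pd.DataFrame
    coefficients: pd.Series
    fractions: pd.DataFrame
    summary: pd.DataFrame
    results: pd.DataFrame
    manifest: dict[str, Any]
    truth: pd.DataFrame | None = None


def run_stages(
    genes_fasta: str | Path,
    pairs,
    barcode_table: BarcodeTable,
    design: pd.DataFrame,
    *,
    contrasts: list[tuple[str, str]],
    barcode_mismatch: int = 0,
    min_len: int = 20,
    classification_mode: str = "sequence",
    normalization_basis: str = "classified",
    align_params: AlignParams | None = None,
) -> RunResult:
    """Run demux → align/classify → stats on an in-memory pair stream."""
    genes = parse_gene_fasta(genes_fasta)
    reference = build_reference(genes)
    iso_map = dict(reference.isodecoder_of)

    per_sample, report = demux_and_trim(
        pairs, barcode_table,
        constant_adapter3=ADAPTER3,
        r2_adapter=revcomp(ADAPTER5),
        barcode_mismatch=barcode_mismatch,
        min_len=min_len,
    )
    aligner = PairAligner(reference, align_params)
    tabs = {
        sample: quantify_sample(sample_pairs, aligner, classification_mode)
        for sample, sample_pairs in per_sample.items()
    }
    counts = counts_frame(tabs)
    norm, coeff = normalize(counts, basis=normalization_basis)
    fractions = fraction_charged(norm, iso_map)
    summary = summarize_replicates(fractions, design)
    results = (
        compare_conditions(fractions, design, contrasts)
        if contrasts else pd.DataFrame()
    )

    manifest = {
        "tool_version": __version__,
        "stages": ["demux", "quantify", "stats"],
        "total_pairs": report.total_pairs,
        "unassigned": report.unassigned,
        "assigned": dict(report.assigned),
        "retained": dict(report.retained),
        "discarded_short": dict(report.discarded_short),
        "mapped": {s: t.mapped for s, t in tabs.items()},
        "unmapped_low": {s: t.unmapped_low for s, t in tabs.items()},
        "unmapped_ambiguous": {s: t.unmapped_ambiguous for s, t in tabs.items()},
        "classified_fraction": {
            s: round(t.classified_fraction, 6) for s, t in tabs.items()
        },
        "n_reference_entries": len(reference),
        "n_aliases": len(reference.aliases),
    }
    _check_manifest_conservation(manifest, tabs)
    return RunResult(
        reference=reference,
        demux_report=report,
        counts=counts,
        coefficients=coeff,
        fractions=fractions,
        summary=summary,
        results=results,
        manifest=manifest,
    )


def _check_manifest_conservation(manifest, tabs) -> None:
    assert manifest["total_pairs"] == (
        sum(manifest["assigned"].values()) + manifest["unassigned"]
    )
    for s, t in tabs.items():
        c = sum(v[0] for v in t.counts.values())
        u = sum(v[1] for v in t.counts.values())
        d = sum(v[2] for v in t.counts.values())
        assert t.mapped == c + u + d, f"count conservation violated for {s}"
        # every retained pair is mapped, unmapped or ambiguous
        assert manifest["retained"][s] == t.mapped + t.unmapped_low + t.unmapped_ambiguous


def design_frame(table: BarcodeTable) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(sample=r.sample, condition=r.condition, replicate=r.replicate)
         for r in table.rows]
    )


def simulate_scenario(config: PipelineConfig) -> tuple[Scenario, SimulatedLibrary]:
    """Build the simulation scenario named by the config's simulate block."""
    block = dict(config.simulate or {})
    sim_keys = {f for f in SimConfig.__dataclass_fields__}
    overrides = {k: v for k, v in block.items() if k in sim_keys}
    overrides.setdefault("seed", config.seed)
    cfg = SimConfig(**overrides)
    scenario = default_scenario(
        seed=config.seed,
        n_isodecoders=int(block.get("n_isodecoders", 12)),
        genes_per_isodecoder=int(block.get("genes_per_isodecoder", 2)),
        sim_config=cfg,
    )
    library = simulate_library(
        scenario.genes_fasta, scenario.profiles, scenario.barcode_table, cfg
    )
    return scenario, library


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Full run with all stage outputs written under ``config.outdir``."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulate is not None:
        scenario, library = simulate_scenario(config)
        genes_fasta = scenario.genes_fasta
        (out / "genes.fa").write_text(genes_fasta)
        library.write_fastq(out / "reads_R1.fastq.gz", out / "reads_R2.fastq.gz")
        library.write_truth_tsv(out / "truth.tsv")
        scenario.barcode_table.to_tsv(out / "samples.tsv")
        table = scenario.barcode_table
        pairs = library.pairs
        truth = library.truth
        contrasts = config.contrasts or [
            ("GCN2iB", "vehicle"), ("GCN2iB_EAA", "GCN2iB")
        ]
    else:
        genes_fasta = config.genes_fasta
        table = BarcodeTable.from_tsv(config.sample_sheet)
        pairs = read_fastq_pairs(config.r1_fastq, config.r2_fastq)
        contrasts = config.contrasts

    design = design_frame(table)
    result = run_stages(
        genes_fasta, pairs, table, design,
        contrasts=contrasts,
        barcode_mismatch=config.barcode_mismatch,
        min_len=config.min_len,
        classification_mode=config.classification_mode,
        normalization_basis=config.normalization_basis,
    )
    result.truth = truth
    result.manifest["config_hash"] = config.content_hash()
    result.manifest["seed"] = config.seed

    result.reference.write_fasta(out / "reference.fa")
    result.reference.write_aliases_tsv(out / "aliases.tsv")
    result.reference.write_isodecoder_tsv(out / "isodecoders.tsv")
    result.demux_report.to_json(out / "demux_report.json")
    result.counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    result.fractions.to_csv(out / "fractions.tsv", sep="\t")
    result.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    if not result.results.empty:
        result.results.to_csv(out / "results.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    (out / "report.txt").write_text(report_text(result))
    return result


def report_text(result: RunResult, alpha: float = 0.05) -> str:
    """Human-readable run summary."""
    m = result.manifest
    lines = [
        f"trnacharge {m.get('tool_version', '?')} run report",
        "=" * 46,
        f"total pairs: {m['total_pairs']}   unassigned: {m['unassigned']}",
        "",
        "per-sample classified fraction of mapped reads:",
    ]
    for s, f in m["classified_fraction"].items():
        lines.append(f"  {s:<16} {f:.4f}")
    if result.summary.empty:
        lines.append("\nno isodecoders quantified")
        return "\n".join(lines) + "\n"
    lines.append("\nmean fraction charged ± SD per isodecoder:")
    for cond, grp in result.summary.groupby("condition"):
        lines.append(f"  condition {cond}:")
        for _, r in grp.iterrows():
            sd = f"{r['sd']:.4f}" if pd.notna(r["sd"]) else "NA"
            lines.append(
                f"    {r['isodecoder']:<12} {r['mean']:.4f} ± {sd} (n={int(r['n'])})"
            )
    if not result.results.empty:
        lines.append("\ncontrasts (BH-significant rows flagged *):")
        for _, r in result.results.iterrows():
            flag = "*" if pd.notna(r["p_adj"]) and r["p_adj"] <= alpha else " "
            p = f"{r['p']:.3g}" if pd.notna(r["p"]) else "NA"
            q = f"{r['p_adj']:.3g}" if pd.notna(r["p_adj"]) else "NA"
            lines.append(
                f" {flag} {r['contrast']:<22} {r['isodecoder']:<12} "
                f"Δ={r['delta']:+.4f}  p={p}  p_adj={q}"
            )
    return "\n".join(lines) + "\n"
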