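"""End-to-end orchestration and reporting.

``run`` drives the stages in order — exon quantification, breakpoint
calling, chromatin promoter evidence, stop-anchored ORF scan, proteomic
validation — over either a synthetic scenario or user-supplied files, and
aggregates everything into a single JSON-serializable report with a
provenance block (config hash, seed, package version).  Optional inputs
(chromatin tracks, peptide tables) skip their stage with an explicit
report entry rather than failing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .boundary import IsoformCall, calls_to_tsv, consensus_call, detect_breakpoint
from .exonquant import ExonExpressionMatrix
from .genemodel import read_annotation, read_domains
from .orfscan import (
    assess_domains,
    candidates_to_tsv,
    enumerate_orfs,
    translate,
)
from .promoter import SignalTrack, classify_alternative_promoter
from .proteomics import (
    infer_isoform_support,
    map_peptides,
    quantify,
    read_peptide_table,
    _occurrences,
)
from .simulate import (
    SimulationConfig,
    simulate_chip_tracks,
    simulate_counts,
    simulate_gene_model,
    simulate_peptides,
)

log = logging.getLogger(__name__)

_TOP_KEYS = {
    "seed", "out_dir", "synthetic", "inputs", "transcript_id", "groups",
    "boundary", "promoter", "orfscan", "proteomics",
}


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# DE-table intersection (top-N shared upregulated genes)
# ---------------------------------------------------------------------------


def rank_and_intersect(
    tables: Mapping[str, pd.DataFrame],
    n: int,
    lfc_min: float = 1.0,
    padj_max: float = 0.05,
) -> set[str]:
    """Intersect the top-``n`` most strongly upregulated genes across tables.

    Each table needs columns ``gene_id``, ``log2FC``, ``padj``.  Genes are
    filtered to ``padj < padj_max`` and ``log2FC > lfc_min``, ranked by
    descending log2FC (ties by ascending padj, then gene id), and the per-
    table top-``n`` sets are intersected.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(tables) < 2:
        raise ValueError("need at least two tables to intersect")
    tops = []
    for name, df in tables.items():
        missing = {"gene_id", "log2FC", "padj"} - set(df.columns)
        if missing:
            raise ValueError(f"table {name!r} lacks column(s): {sorted(missing)}")
        sel = df[(df["padj"] < padj_max) & (df["log2FC"] > lfc_min)]
        sel = sel.sort_values(
            ["log2FC", "padj", "gene_id"], ascending=[False, True, True]
        )
        tops.append(set(sel["gene_id"].head(n)))
    return set.intersection(*tops)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


@dataclass
class PipelineReport:
    per_sample_calls: dict[str, IsoformCall] = field(default_factory=dict)
    consensus: dict[str, IsoformCall] = field(default_factory=dict)
    breakpoint_k: int | None = None
    promoter_evidence: dict | None = None
    orf_candidates: list = field(default_factory=list)
    coverage: dict | None = None
    quant: dict | None = None
    isoform_support: str | None = None
    skipped: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def call_dict(c: IsoformCall) -> dict:
            return {
                "class": c.expression_class.value,
                "breakpoint_k": c.breakpoint_k,
                "mean_5prime": round(c.mean_5prime, 6),
                "mean_3prime": round(c.mean_3prime, 6),
                "score": round(c.score, 6),
            }

        return {
            "per_sample_calls": {s: call_dict(c) for s, c in self.per_sample_calls.items()},
            "consensus": {g: call_dict(c) for g, c in self.consensus.items()},
            "breakpoint_k": self.breakpoint_k,
            "promoter_evidence": self.promoter_evidence,
            "orf_candidates": [
                {
                    "start_nt": c.start_nt,
                    "start_exon": c.start_exon,
                    "length_aa": c.length_aa,
                    "mass_da": round(c.mass_da, 2),
                    "mass_kda": c.mass_kda,
                    "delta": c.delta,
                    "domains_lost": c.domains_lost,
                    "domains_retained": c.domains_retained,
                    "domains_truncated": c.domains_truncated,
                }
                for c in self.orf_candidates
            ],
            "coverage": self.coverage,
            "quant": self.quant,
            "isoform_support": self.isoform_support,
            "skipped": self.skipped,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def _config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: Mapping[str, Any]) -> dict:
    return {
        "tool": "isotrunc",
        "version": __version__,
        "seed": config.get("seed"),
        "config_sha256": _config_hash(config),
        "inputs": sorted(map(str, config.get("inputs", {}).values()))
        if isinstance(config.get("inputs"), dict)
        else [],
    }


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------


def validate_config(config: Mapping[str, Any]) -> None:
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if ("synthetic" in config) == ("inputs" in config):
        raise ConfigError("config must set exactly one of 'synthetic' or 'inputs'")


def run(config: Mapping[str, Any]) -> PipelineReport:
    """Execute the pipeline per a structured config dict.

    The config carries either a ``synthetic`` block (SimulationConfig
    overrides) or an ``inputs`` block of file paths, plus optional
    per-stage parameter blocks ``boundary``, ``promoter``, ``proteomics``.
    When ``out_dir`` is set, per-stage TSVs and the report JSON are written
    there.
    """
    validate_config(config)
    bp = dict(config.get("boundary", {}))
    pp = dict(config.get("promoter", {}))
    qp = dict(config.get("proteomics", {}))
    report = PipelineReport(provenance=_provenance(dict(config)))

    if "synthetic" in config:
        syn = dict(config.get("synthetic") or {})
        if "seed" in config and "seed" not in syn:
            syn["seed"] = config["seed"]
        try:
            cfg = SimulationConfig(**syn)
        except TypeError as exc:
            raise ConfigError(f"invalid synthetic config: {exc}") from exc
        _run_synthetic_stages(cfg, report, bp, pp, qp)
    else:
        _run_file_stages(dict(config), report, bp, pp, qp)

    out_dir = config.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if report.per_sample_calls:
            calls_to_tsv(report.per_sample_calls, out / "isoform_calls.tsv")
        if report.orf_candidates:
            candidates_to_tsv(report.orf_candidates, out / "orf_candidates.tsv")
        report.to_json(out / "report.json")
    return report


def _boundary_stage(
    matrix: ExonExpressionMatrix,
    groups: Mapping[str, str],
    report: PipelineReport,
    bp: dict,
    treated: str,
) -> int | None:
    for sample in matrix.samples:
        report.per_sample_calls[sample] = detect_breakpoint(
            matrix.exon_profile(sample), **bp
        )
    report.consensus = consensus_call(report.per_sample_calls, dict(groups))
    call = report.consensus.get(treated)
    return call.breakpoint_k if call is not None else None


def _orf_stage(
    t, spliced, domains, k: int | None, report: PipelineReport, window=None
) -> str | None:
    """Run the ORF scan; returns the short protein of the longest candidate."""
    if not t.has_cds:
        report.skipped["orfscan"] = "transcript has no annotated CDS"
        return None
    if window is None:
        if k is None:
            report.skipped["orfscan"] = "no breakpoint to anchor the search window"
            return None
        window = (sum(t.exon_lengths[: k - 1]), t.cds_stop)
    candidates = enumerate_orfs(t, spliced, window)
    canonical = translate(spliced[t.cds_start : t.cds_stop])
    for c in candidates:
        assess_domains(c, domains, len(canonical), canonical)
    report.orf_candidates = candidates
    return candidates[0].protein if candidates else None


def _proteomics_stage(
    obs: pd.DataFrame,
    signature: list[str],
    short_protein: str | None,
    canonical_protein: str,
    report: PipelineReport,
    qp: dict,
) -> None:
    m_min = qp.pop("m_min", 2)
    sequences = sorted(obs["sequence"].unique())
    if short_protein is not None:
        report.coverage = map_peptides(sequences, short_protein).to_dict()
    spans = []
    for pep in sequences:
        for h in _occurrences(pep, canonical_protein):
            spans.append((h + 1, h + len(pep)))
    delta = len(canonical_protein) - (len(short_protein) if short_protein else 0)
    report.isoform_support = infer_isoform_support(spans, delta, m_min=m_min)
    report.quant = quantify(obs, signature or sequences, **qp).to_dict()


def _run_synthetic_stages(
    cfg: SimulationConfig, report: PipelineReport, bp: dict, pp: dict, qp: dict
) -> None:
    gene = simulate_gene_model(cfg)
    t = gene.transcript

    rng = cfg.rng("counts")
    treated, lib_t = simulate_counts(cfg, "short", prefix="treated", rng=rng)
    control, lib_c = simulate_counts(cfg, "off", prefix="control", rng=rng)
    counts = pd.concat([control, treated], axis=1)
    matrix = ExonExpressionMatrix.from_counts(
        t,
        {s: counts[s].to_numpy() for s in counts.columns},
        {**lib_c, **lib_t},
    )
    groups = {s: s.rsplit("_", 1)[0] for s in matrix.samples}
    k = _boundary_stage(matrix, groups, report, bp, treated="treated")
    report.breakpoint_k = k

    if k is not None:
        tracks = simulate_chip_tracks(cfg, t, "alternative_promoter")
        report.promoter_evidence = classify_alternative_promoter(
            tracks, t, k, **pp
        ).to_dict()
    else:
        report.skipped["promoter"] = "no breakpoint called"

    short_protein = _orf_stage(t, gene.transcript_seq, gene.domains, k, report)
    canonical = translate(gene.transcript_seq[t.cds_start : t.cds_stop])
    if short_protein is None:
        report.skipped["proteomics"] = "no ORF candidate"
        return
    obs, signature = simulate_peptides(cfg, short_protein)
    _proteomics_stage(obs, signature, short_protein, canonical, report, qp)


def _run_file_stages(
    config: dict, report: PipelineReport, bp: dict, pp: dict, qp: dict
) -> None:
    inputs = config["inputs"]
    models = read_annotation(inputs["annotation"])
    tid = config.get("transcript_id")
    if tid is None:
        if len(models) != 1:
            raise ConfigError(
                "annotation holds multiple transcripts; set 'transcript_id'"
            )
        tid = next(iter(models))
    if tid not in models:
        raise ConfigError(f"transcript {tid!r} not found in annotation")
    t = models[tid]

    counts = pd.read_csv(inputs["counts"], sep="\t", index_col="exon_index")
    libs = pd.read_csv(inputs["library_sizes"], sep="\t", index_col="sample")[
        "library_size"
    ].to_dict()
    matrix = ExonExpressionMatrix.from_counts(
        t, {s: counts[s].to_numpy() for s in counts.columns}, libs
    )
    groups = config.get("groups") or {
        s: s.rsplit("_", 1)[0] for s in matrix.samples
    }
    treated = qp.get("treated", "treated")
    k = _boundary_stage(matrix, groups, report, bp, treated=treated)
    report.breakpoint_k = k

    chip = inputs.get("chip")
    if chip and k is not None:
        tracks = {
            mark: SignalTrack.from_bedgraph(path, mark) for mark, path in chip.items()
        }
        report.promoter_evidence = classify_alternative_promoter(
            tracks, t, k, **pp
        ).to_dict()
    else:
        report.skipped["promoter"] = (
            "no chromatin tracks supplied" if not chip else "no breakpoint called"
        )

    short_protein = None
    if "genome" in inputs:
        import pyfaidx

        genome = pyfaidx.Fasta(str(inputs["genome"]))
        spliced = t.spliced_sequence(genome)
        domains = read_domains(inputs["domains"]) if "domains" in inputs else []
        short_protein = _orf_stage(t, spliced, domains, k, report)
        canonical = translate(spliced[t.cds_start : t.cds_stop]) if t.has_cds else ""
    else:
        report.skipped["orfscan"] = "no genome FASTA supplied"
        canonical = ""

    if "peptides" in inputs and canonical:
        obs = read_peptide_table(inputs["peptides"])
        signature = []
        if "signature_peptides" in inputs:
            signature = [
                ln.strip()
                for ln in Path(inputs["signature_peptides"]).read_text().splitlines()
                if ln.strip()
            ]
        _proteomics_stage(obs, signature, short_protein, canonical, report, qp)
    else:
        report.skipped.setdefault("proteomics", "no peptide table supplied")
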