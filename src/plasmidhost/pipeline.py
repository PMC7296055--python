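"""Run orchestration: configuration, stages, and report files.

A run reads one plasmid FASTA, one or more chromosome FASTA files and a
metadata TSV, scores the plasmid against every chromosome at the requested
k, and writes: the host-prediction table, the per-k group comparison, a
GC-vs-distance table (the data behind the usual scatter plot), top-fraction
genus lists, and a plain-text log with versions, seed and NA accounting.
Outputs are deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .screen import PlasmidHostScreen
from .stats import InsufficientDataError

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {detail}")


@dataclass
class RunConfig:
    plasmid_fasta: str
    genomes_fasta: List[str]
    metadata: str
    output_dir: str
    ks: Sequence[int] = (2, 3, 4)
    window_bp: int = 5000
    strand: str = "given"
    top_fractions: Sequence[float] = (0.1, 0.3)
    transconjugant_genera: Optional[List[str]] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.ks:
            raise ValueError("ks must be non-empty")
        if self.window_bp < 1000:
            raise ValueError(f"window_bp must be >= 1000, got {self.window_bp}")
        if isinstance(self.genomes_fasta, (str, Path)):
            self.genomes_fasta = [str(self.genomes_fasta)]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def run_pipeline(config: RunConfig) -> Dict[str, str]:
    """Execute the full screen; returns a name -> path map of outputs."""
    logging.basicConfig(
        stream=sys.stderr, level=getattr(logging, config.log_level.upper(), 20)
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        screen = PlasmidHostScreen.from_fasta(
            config.plasmid_fasta,
            config.genomes_fasta,
            config.metadata,
            ks=config.ks,
            window_bp=config.window_bp,
            strand=config.strand,
            transconjugant_genera=(
                set(config.transconjugant_genera)
                if config.transconjugant_genera else None
            ),
        )
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    try:
        results = screen.fit()
    except Exception as exc:
        raise PipelineError("score", str(exc)) from exc

    paths: Dict[str, str] = {}
    table_path = outdir / "host_predictions.tsv"
    results.to_tsv(table_path)
    paths["host_predictions"] = str(table_path)

    # GC-vs-distance table (data behind the GC scatter)
    gc_cols = ["accession", "gc_percent"] + [f"d2_k{k}" for k in screen.ks] + ["group"]
    gc_path = outdir / "gc_vs_distance.tsv"
    results.table[gc_cols].to_csv(
        gc_path, sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )
    paths["gc_vs_distance"] = str(gc_path)

    # group comparison per k
    comp_rows = []
    comp_errors: Dict[int, str] = {}
    labeled = set(results.table["group"]) - {"Unlabeled"}
    for k in screen.ks:
        if not labeled:
            comp_errors[k] = "no group labels"
            continue
        try:
            c = results.compare_groups(k)
        except InsufficientDataError as exc:
            comp_errors[k] = str(exc)
            continue
        comp_rows.append(
            {
                "k": k, "n1": c.n_transconjugants, "n2": c.n_others,
                "median1": c.median_transconjugants, "median2": c.median_others,
                "cliffs_delta": c.cliffs_delta, "z": c.z_statistic,
                "p_two_sided": c.p_value_two_sided,
            }
        )
    comp_path = outdir / "group_comparison.tsv"
    pd.DataFrame(
        comp_rows,
        columns=["k", "n1", "n2", "median1", "median2", "cliffs_delta", "z",
                 "p_two_sided"],
    ).to_csv(comp_path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    paths["group_comparison"] = str(comp_path)

    # top-fraction genus lists
    for frac in config.top_fractions:
        try:
            _, genera = results.top_fraction(frac, policy="any_k")
        except ValueError as exc:
            raise PipelineError("rank", str(exc)) from exc
        p = outdir / f"top_{int(round(frac * 100))}pct_genera.txt"
        p.write_text("".join(g + "\n" for g in sorted(genera)))
        paths[f"top_{int(round(frac * 100))}pct"] = str(p)

    # run log
    na = results.na_counts()
    n_rows = len(results.table)
    log_lines = [
        f"plasmidhost version {__version__}",
        f"python {sys.version.split()[0]}",
        f"seed {config.seed}",
        f"plasmid {screen.plasmid.id} ({len(screen.plasmid)} bp)",
        f"chromosomes {n_rows}",
        f"window_bp {config.window_bp}  strand {config.strand}  ks {list(screen.ks)}",
    ]
    for k in screen.ks:
        log_lines.append(
            f"k={k}: rows_total={n_rows} rows_nonNA={n_rows - na[k]} rows_NA={na[k]}"
        )
    for k, msg in sorted(comp_errors.items()):
        log_lines.append(f"k={k}: group comparison skipped: {msg}")
    log_path = outdir / "run_log.txt"
    log_path.write_text("".join(line + "\n" for line in log_lines))
    paths["run_log"] = str(log_path)
    return paths
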