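"""All-pairs orchestration of the reconstruction pipeline.

One pairwise run is: RBH search -> Δ1 anchor chaining -> block filtering ->
Δ2 non-RBH completion -> breakpoint extraction -> statistics -> text
outputs and optional plots.  ``run_all_pairs`` applies this to every
unordered genome pair and aggregates the per-pair statistics into one
table; a failure in one pair is logged and reported without aborting the
others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import genome_io, viz
from .analysis import PairwiseStats, compute_stats
from .genome_io import Genome
from .homology import AlignmentParams, HomologyPair, find_rbh
from .synteny import (BreakpointRegion, SyntenyBlock, SyntenyParams,
                      extract_breakpoints, reconstruct_blocks)

log = logging.getLogger(__name__)


@dataclass
class PairResult:
    genome_a: Genome
    genome_b: Genome
    rbh: list[HomologyPair]
    blocks: list[SyntenyBlock]
    breakpoints_a: list[BreakpointRegion]
    breakpoints_b: list[BreakpointRegion]
    stats: PairwiseStats

    @property
    def all_pairs(self) -> list[HomologyPair]:
        seen = set()
        out = list(self.rbh)
        for b in self.blocks:
            for p in b.completions:
                if p.key not in seen:
                    seen.add(p.key)
                    out.append(p)
        return out


def run_pair(genome_a: Genome, genome_b: Genome,
             align_params: Optional[AlignmentParams] = None,
             syn_params: Optional[SyntenyParams] = None,
             out_dir: Optional[Path] = None,
             plots: tuple[str, ...] = ()) -> PairResult:
    """Run the full reconstruction for one genome pair."""
    align_params = align_params or AlignmentParams()
    syn_params = syn_params or SyntenyParams()
    rbh = find_rbh(genome_a, genome_b, align_params)
    log.info("%s/%s: %d RBH", genome_a.id, genome_b.id, len(rbh))
    blocks = reconstruct_blocks(rbh, genome_a, genome_b, syn_params, align_params)
    n_anchors = sum(len(b.anchors) for b in blocks)
    n_comp = sum(len(b.completions) for b in blocks)
    log.info("%s/%s: %d blocks, %d anchors, %d completions",
             genome_a.id, genome_b.id, len(blocks), n_anchors, n_comp)
    bp_a = extract_breakpoints(blocks, genome_a)
    bp_b = extract_breakpoints(blocks, genome_b)
    stats = compute_stats(blocks, bp_a + bp_b, (genome_a, genome_b), rbh)
    result = PairResult(genome_a, genome_b, rbh, blocks, bp_a, bp_b, stats)
    if out_dir is not None:
        out_dir = Path(out_dir)
        genome_io.write_results(blocks, result.all_pairs, out_dir)
        genome_io.write_breakpoints(bp_a + bp_b, out_dir / "breakpoints.tsv")
        stats_frame([result]).to_csv(out_dir / "stats.tsv", sep="\t", index=False)
        render_plots(result, out_dir, plots)
    return result


def render_plots(result: PairResult, out_dir: Path,
                 plots: tuple[str, ...]) -> None:
    pair_name = f"{result.genome_a.id}_{result.genome_b.id}"
    genomes = (result.genome_a, result.genome_b)
    syntenic_pairs = [p for b in result.blocks for p in b.member_pairs()]
    if "dotplot" in plots:
        viz.render_dotplot(syntenic_pairs, genomes, viz.RenderSpec(
            path=str(out_dir / f"{pair_name}.dotplot.svg"), kind="dotplot"))
    if "painting" in plots:
        viz.render_painting(result.blocks, genomes, viz.RenderSpec(
            path=str(out_dir / f"{pair_name}.painting.svg"), kind="painting"))
    if "map" in plots:
        viz.render_synteny_map(
            result.blocks, result.breakpoints_a + result.breakpoints_b,
            genomes, viz.RenderSpec(
                path=str(out_dir / f"{pair_name}.map.svg"), kind="map"))


def stats_frame(results: list[PairResult]) -> pd.DataFrame:
    """One summary row per pairwise comparison."""
    rows = []
    for r in results:
        row = {"genome_a": r.genome_a.id, "genome_b": r.genome_b.id}
        row.update(vars(r.stats))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Configuration of a multi-genome all-pairs run."""

    genomes: list[tuple[str, str, str]]  # (genome id, gene table, fasta)
    align_params: AlignmentParams = field(default_factory=AlignmentParams)
    syn_params: SyntenyParams = field(default_factory=SyntenyParams)
    out_dir: Path = Path("syntenic_out")
    plots: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.genomes) < 2:
            raise ValueError("an all-pairs run needs at least two genomes")


def run_all_pairs(config: RunConfig) -> tuple[list[PairResult], pd.DataFrame, int]:
    """Run every unordered genome pair; returns (results, stats table, #failed)."""
    genomes = [genome_io.read_genome(t, f, genome_id=gid)
               for gid, t, f in config.genomes]
    results: list[PairResult] = []
    failures = 0
    out_root = Path(config.out_dir)
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            ga, gb = genomes[i], genomes[j]
            pair_dir = out_root / f"{ga.id}_{gb.id}"
            try:
                results.append(run_pair(ga, gb, config.align_params,
                                        config.syn_params, pair_dir,
                                        config.plots))
            except Exception:
                failures += 1
                log.exception("pair %s/%s failed", ga.id, gb.id)
    table = stats_frame(results)
    out_root.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_root / "summary.tsv", sep="\t", index=False)
    return results, table, failures
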