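"""End-to-end orchestration: simulate -> quantify -> compare/diff -> screen -> motif.

`run_pipeline` executes the full analysis on simulated data for one
viewpoint: per-sample QC, windowing and interaction calling, replicate
intersection into high-fidelity sites, replicate-correlation QC on 1 Mb
bins, differential interaction analysis between the two conditions on the
union of their high-fidelity sets, the candidate-enhancer screen per
condition, and an E-box scan of the candidate sequences.  Every stage's
outputs are written under `out_dir` (when given) and stamped with the
config hash and seed; stage failures abort with a stage-named error, and
partially written stage files keep a ``.partial`` suffix.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import compare, io, motif, quantify, simulate
from .config import PipelineConfig
from .digest import FragmentMap, resolve_viewpoint
from .screen import CandidateEnhancer, SignalTrack, annotate_conservation
from .screen import candidates_to_frame, screen as run_screen

log = logging.getLogger("fourcat")


@dataclass
class PipelineResult:
    config: PipelineConfig
    sim_config: simulate.SimConfig
    genome: Dict[str, str]
    fmap: FragmentMap
    truth: simulate.SimTruth
    tracks: Dict[str, pd.DataFrame]
    qc: Dict[str, quantify.QCReport] = field(default_factory=dict)
    calls: Dict[str, quantify.InteractionCallSet] = field(default_factory=dict)
    window_tracks: Dict[str, quantify.WindowTrack] = field(default_factory=dict)
    high_fidelity: Dict[str, quantify.HighFidelitySites] = field(default_factory=dict)
    replicate_pearson: Dict[str, float] = field(default_factory=dict)
    differential: Optional[compare.DifferentialResult] = None
    candidates: Dict[str, List[CandidateEnhancer]] = field(default_factory=dict)
    ebox_hits: Dict[str, Dict[str, int]] = field(default_factory=dict)
    run_log: Dict = field(default_factory=dict)


class _StageWriter:
    """Writes stage outputs to `<name>.partial` and renames on stage success."""

    def __init__(self, out_dir: Optional[str]):
        self.out_dir = out_dir
        self._pending: List[str] = []
        if out_dir:
            os.makedirs(out_dir, exist_ok=True)

    def path(self, name: str) -> Optional[str]:
        if not self.out_dir:
            return None
        p = os.path.join(self.out_dir, name + ".partial")
        self._pending.append(p)
        return p

    def commit(self) -> None:
        for p in self._pending:
            if os.path.exists(p):
                os.replace(p, p[: -len(".partial")])
        self._pending = []


def run_pipeline(
    config: PipelineConfig,
    sim_config: Optional[simulate.SimConfig] = None,
    out_dir: Optional[str] = None,
    pwms: Optional[List[motif.PWM]] = None,
) -> PipelineResult:
    """Run the full simulated-experiment analysis for one viewpoint."""
    if sim_config is None:
        sim_config = simulate.default_config(seed=config.seed)
    writer = _StageWriter(out_dir)
    stage = "simulate"
    try:
        genome, fmap = simulate.make_genome(sim_config)
        truth = simulate.build_truth(sim_config, fmap, window_size=config.window_size)
        tracks = simulate.simulate_tracks(sim_config, truth)
        if out_dir:
            io.write_fasta(genome, writer.path("genome.fa"))
            fmap.write_bed(writer.path("fragments.bed"))
            io.write_bed(tracks["h3k27ac"], writer.path("h3k27ac_peaks.bed"))
            io.write_bed(tracks["atac"], writer.path("atac_peaks.bed"))
            io.write_bed(tracks["promoters"], writer.path("promoters.bed"))
            io.write_bedgraph(tracks["atac_signal"], writer.path("atac_signal.bedGraph"))
        writer.commit()

        result = PipelineResult(
            config=config, sim_config=sim_config, genome=genome, fmap=fmap,
            truth=truth, tracks=tracks,
        )
        vp_chrom, vp_pos = sim_config.viewpoint
        viewpoint = resolve_viewpoint(fmap, vp_chrom, vp_pos)

        stage = "quantify"
        for condition in sim_config.conditions:
            for rep in range(1, sim_config.replicates + 1):
                reads = simulate.simulate_sample(sim_config, condition, rep, fmap)
                sample = f"{condition}_rep{rep}"
                result.qc[sample] = quantify.compute_qc(reads, viewpoint, config.cis_gate)
                filtered, _ = quantify.filter_invalid(reads, fmap, viewpoint)
                track = quantify.window_rpm(filtered, fmap, config.window_size, sample)
                result.window_tracks[sample] = track
                result.calls[sample] = quantify.call_interactions(
                    track, viewpoint,
                    alpha=config.alpha,
                    exclusion_radius=config.exclusion_radius,
                    background_span=config.background_span,
                    background_floor=config.background_floor,
                )
                if out_dir:
                    io.write_reads(reads, writer.path(f"reads_{sample}.tsv"))
                    io.write_bedgraph(
                        track.df.rename(columns={"rpm": "value"})[io.BEDGRAPH],
                        writer.path(f"rpm_{sample}.bedGraph"),
                    )
                    io.write_bed(
                        result.calls[sample].significant[["chrom", "start", "end"]],
                        writer.path(f"significant_{sample}.bed"),
                    )
        writer.commit()

        stage = "replicate_qc"
        for condition in sim_config.conditions:
            reps = [f"{condition}_rep{r}" for r in range(1, sim_config.replicates + 1)]
            a, b = result.calls[reps[0]], result.calls[reps[1]]
            result.high_fidelity[condition] = quantify.high_fidelity(a, b)
            pa = compare.bin_profile(a.significant, vp_chrom, fmap.chrom_sizes, config.bin_size)
            pb = compare.bin_profile(b.significant, vp_chrom, fmap.chrom_sizes, config.bin_size)
            r = compare.replicate_pearson(pa, pb)
            result.replicate_pearson[condition] = r
            for s in reps:
                result.qc[s].replicate_pearson = r
                result.qc[s].passes_corr_gate = bool(r > config.corr_gate) if np.isfinite(r) else False
            if out_dir:
                io.write_bed(
                    result.high_fidelity[condition].to_frame(),
                    writer.path(f"high_fidelity_{condition}.bed"),
                )
        if out_dir:
            qc_df = pd.DataFrame([q.as_dict() for q in result.qc.values()])
            qc_df.to_csv(writer.path("qc_report.tsv"), sep="\t", index=False)
        writer.commit()

        stage = "differential"
        cond_a, cond_b = sim_config.conditions[:2]
        union_ids = sorted(
            result.high_fidelity[cond_a].ids | result.high_fidelity[cond_b].ids
        )
        if union_ids:
            index = [f"{c}:{s}-{s + config.window_size}" for c, s in union_ids]

            def _counts(condition: str) -> pd.DataFrame:
                cols = {}
                for r in range(1, sim_config.replicates + 1):
                    sample = f"{condition}_rep{r}"
                    df = result.window_tracks[sample].df
                    lookup = {(c, int(s)): n for c, s, n in zip(df["chrom"], df["start"], df["count"])}
                    cols[sample] = [lookup.get(wid, 0) for wid in union_ids]
                return pd.DataFrame(cols, index=index)

            result.differential = compare.differential(
                _counts(cond_a), _counts(cond_b),
                lfc_min=config.lfc_min, alpha=config.alpha,
            )
            if out_dir:
                result.differential.df.to_csv(writer.path("differential.tsv"), sep="\t")
                sdis = result.differential.sdis
                rows = [wid.split(":")[0:1] + wid.split(":")[1].split("-") for wid in sdis.index]
                pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
                    writer.path("sdis.bed"), sep="\t", header=False, index=False
                )
        writer.commit()

        stage = "screen"
        signal = SignalTrack(tracks["atac_signal"])
        for condition in sim_config.conditions:
            hf = result.high_fidelity[condition].to_frame()
            cands = run_screen(
                hf, tracks["h3k27ac"], tracks["atac"], tracks["promoters"],
                signal, vp_chrom, width_cap=config.enhancer_width_cap,
            )
            cands, _ = annotate_conservation(cands, pd.DataFrame(columns=io.BED3))
            result.candidates[condition] = cands
            if out_dir:
                io.write_bed(
                    candidates_to_frame(cands),
                    writer.path(f"candidates_{condition}.bed"),
                )
        writer.commit()

        stage = "motif"
        for condition, cands in result.candidates.items():
            seqs = {
                f"cand_{i}": genome[c.chrom][c.start : c.end]
                for i, c in enumerate(cands)
            }
            result.ebox_hits[condition] = {
                cid: len(motif.ebox_scan(seq, cid)) for cid, seq in seqs.items()
            }
            if pwms and seqs:
                ranking = motif.rank_motifs(seqs, pwms)
                if out_dir:
                    ranking.to_csv(writer.path(f"motif_ranking_{condition}.tsv"), sep="\t", index=False)
        writer.commit()

        stage = "log"
        result.run_log = {
            "config_hash": config.digest_hash(),
            "seed": sim_config.seed,
            "thresholds": config.to_dict(),
            "n_samples": len(result.qc),
            "n_high_fidelity": {c: len(h.ids) for c, h in result.high_fidelity.items()},
            "n_candidates": {c: len(v) for c, v in result.candidates.items()},
        }
        if out_dir:
            with open(writer.path("run_log.json"), "w") as fh:
                json.dump(result.run_log, fh, indent=2, sort_keys=True)
        writer.commit()
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
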