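"""End-to-end orchestration: simulate -> filter/normalize -> DE -> targets
-> enrichment -> interplay -> summary, with a reproducibility manifest.

Every stage writes TSV/JSON outputs under ``config.out_dir``; the manifest
records parameters, the seed, SHA-256 checksums of the stage inputs, and
per-stage row counts, so two runs with the same config and seed produce
byte-identical outputs.  Progress and timings go to the logger (stderr in
the CLI), never to stdout.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import call_de, de_to_frame
from .duplex import default_params, screen_candidates
from .enrichment import enrich
from .interplay import common_pathways, mode_breakdown, overlap_analysis
from .io_formats import (
    read_annotation,
    read_expression_tsv,
    read_fasta,
    read_gmt,
    write_annotation_gtf,
    write_expression_tsv,
    write_fasta,
    write_gmt,
)
from .preprocess import filter_low_intensity, quantile_normalize
from .report import summarize
from .synthetic import SimulationConfig, simulate_dataset
from .targets import cis_targets, group_targets, trans_targets
from .types import BIOTYPE_LNCRNA, BIOTYPE_MRNA, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

STAGES = ("simulate", "normalize", "de", "duplex", "targets", "enrich",
          "interplay")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the reference settings."""

    out_dir: str = "results"
    seed: int = 0
    # thresholds
    lnc_intensity: float = 5.0
    mrna_intensity: float = 6.0
    fc: float = 2.0
    alpha: float = 0.05
    window: int = 10_000
    energy_cutoff: float = -20.0
    n_perm: int = 1000
    # optional pre-existing inputs; when all are set, simulation is skipped
    expression: str | None = None
    annotation: str | None = None
    fasta: str | None = None
    gmt: str | None = None
    groups: str | None = None
    # synthetic-data settings (used when inputs are not provided)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(**raw, simulation=sim) if "simulation" not in raw else cls(**raw)
        cfg.simulation = sim
        return cfg

    def uses_external_inputs(self) -> bool:
        return all(
            getattr(self, k) is not None
            for k in ("expression", "annotation", "fasta", "gmt", "groups")
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k != "simulation"
        },
        "simulation": asdict(config.simulation),
        "stages": {},
        "inputs": {},
    }
    t_all = time.perf_counter()

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                counts = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                (out / "manifest.json").write_text(
                    json.dumps(manifest, indent=2, sort_keys=True) + "\n"
                )
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            dt = time.perf_counter() - t0
            logger.info("stage %-9s done in %.2fs %s", name, dt, counts)
            manifest["stages"][name] = {"status": "complete", **counts}
            return counts
        return deco

    # ---- stage 1: inputs --------------------------------------------------
    holder: dict = {}

    @stage("simulate")
    def _simulate():
        if config.uses_external_inputs():
            group_df = pd.read_csv(config.groups, sep="\t")
            group_map = dict(zip(group_df["sample_id"], group_df["group"]))
            holder["matrix"] = read_expression_tsv(config.expression, group_map)
            holder["annotation"] = read_annotation(config.annotation, "gtf")
            holder["sequences"] = read_fasta(config.fasta)
            universe = {f.feature_id for f in holder["annotation"].genes}
            holder["genesets"] = read_gmt(config.gmt, universe=universe)
            holder["truth"] = None
            for k in ("expression", "annotation", "fasta", "gmt", "groups"):
                manifest["inputs"][k] = _sha256(Path(getattr(config, k)))
            return {"n_probes": holder["matrix"].shape[0], "simulated": False}
        ds = simulate_dataset(config.simulation, seed=config.seed)
        holder.update(
            matrix=ds.matrix, annotation=ds.annotation,
            sequences=ds.sequences, genesets=ds.genesets, truth=ds.truth,
        )
        write_expression_tsv(ds.matrix, out / "expression_raw.tsv")
        write_annotation_gtf(ds.annotation, out / "annotation.gtf")
        write_fasta(ds.sequences, out / "transcripts.fasta")
        write_gmt(ds.genesets, out / "genesets.gmt")
        _write_tsv(
            pd.DataFrame(
                {"sample_id": ds.matrix.sample_ids,
                 "group": [ds.matrix.groups[s] for s in ds.matrix.sample_ids]}
            ),
            out / "groups.tsv",
        )
        (out / "truth.json").write_text(
            json.dumps(ds.truth.to_json_dict(), indent=2, sort_keys=True) + "\n"
        )
        for name in ("expression_raw.tsv", "annotation.gtf", "transcripts.fasta",
                     "genesets.gmt", "groups.tsv"):
            manifest["inputs"][name] = _sha256(out / name)
        return {"n_probes": ds.matrix.shape[0], "simulated": True}

    # ---- stage 2: filter + quantile normalization -------------------------
    @stage("normalize")
    def _normalize():
        filtered, rep = filter_low_intensity(
            holder["matrix"], holder["annotation"],
            config.lnc_intensity, config.mrna_intensity,
        )
        norm = quantile_normalize(filtered)
        holder["norm"] = norm
        _write_tsv(
            pd.DataFrame(
                sorted(
                    [{"probe_id": p, "status": "kept"} for p in rep.kept]
                    + [{"probe_id": p, "status": "removed"} for p in rep.removed],
                    key=lambda r: r["probe_id"],
                )
            ),
            out / "filter_report.tsv",
        )
        write_expression_tsv(norm, out / "expression_norm.tsv")
        return {"kept": len(rep.kept), "removed": len(rep.removed)}

    # ---- stage 3: differential expression ---------------------------------
    @stage("de")
    def _de():
        results = call_de(holder["norm"], config.fc, config.alpha)
        ann = holder["annotation"]
        holder["de_lnc"] = [r for r in results
                            if ann[r.feature_id].biotype == BIOTYPE_LNCRNA]
        holder["de_mrna"] = [r for r in results
                             if ann[r.feature_id].biotype == BIOTYPE_MRNA]
        _write_tsv(de_to_frame(holder["de_lnc"]), out / "de_lncrna.tsv")
        _write_tsv(de_to_frame(holder["de_mrna"]), out / "de_mrna.tsv")
        n_up = sum(1 for r in results if r.direction == "up")
        n_down = sum(1 for r in results if r.direction == "down")
        return {"up": n_up, "down": n_down, "tested": len(results)}

    # ---- stage 4: duplex screen -------------------------------------------
    @stage("duplex")
    def _duplex():
        ann = holder["annotation"]
        seqs = holder["sequences"]
        dereg = [r.feature_id for r in holder["de_lnc"]
                 if r.direction in ("up", "down")]
        params = default_params()
        rows = []
        holder["screen_hits"] = {}
        for lnc_id in dereg:
            lnc = ann[lnc_id]
            candidates = {
                g.feature_id: seqs[g.feature_id]
                for g in ann.genes
                if g.chrom != lnc.chrom and g.feature_id in seqs
            }
            hits = screen_candidates(
                seqs[lnc_id], candidates, params, cutoff=config.energy_cutoff,
            )
            holder["screen_hits"][lnc_id] = hits
            for gene_id, res in hits:
                rows.append(
                    {"lnc_id": lnc_id, "gene_id": gene_id,
                     "energy_kcal_mol": res.energy,
                     "span_a": f"{res.span_a[0]}-{res.span_a[1]}",
                     "span_b": f"{res.span_b[0]}-{res.span_b[1]}",
                     "pairing": res.pairing_string()}
                )
        _write_tsv(
            pd.DataFrame(rows, columns=["lnc_id", "gene_id", "energy_kcal_mol",
                                        "span_a", "span_b", "pairing"]),
            out / "duplex_hits.tsv",
        )
        return {"screened_lncrnas": len(dereg), "hits": len(rows)}

    # ---- stage 5: target assignment ---------------------------------------
    @stage("targets")
    def _targets():
        ann = holder["annotation"]
        pairs = []
        for r in holder["de_lnc"]:
            if r.direction not in ("up", "down"):
                continue
            pairs.extend(cis_targets(r.feature_id, ann, config.window))
            pairs.extend(
                trans_targets(r.feature_id,
                              holder["screen_hits"].get(r.feature_id, []), ann)
            )
        buckets, kept = group_targets(pairs, holder["de_lnc"])
        holder["target_pairs"] = kept
        holder["buckets"] = buckets
        _write_tsv(
            pd.DataFrame(
                [
                    {"lnc_id": p.lnc_id, "gene_id": p.gene_id, "mode": p.mode,
                     "distance": "" if p.distance is None else p.distance,
                     "energy_kcal_mol": "" if p.energy is None else p.energy,
                     "lnc_direction": p.lnc_direction}
                    for p in kept
                ],
                columns=["lnc_id", "gene_id", "mode", "distance",
                         "energy_kcal_mol", "lnc_direction"],
            ),
            out / "targets.tsv",
        )
        return {k: len(v) for k, v in buckets.items()} | {"pairs": len(kept)}

    # ---- stage 6: enrichment ----------------------------------------------
    @stage("enrich")
    def _enrich():
        genesets = holder["genesets"]
        ann = holder["annotation"]
        gene_universe = {f.feature_id for f in ann.genes}
        target_query = {p.gene_id for p in holder["target_pairs"]}
        mrna_universe = {r.feature_id for r in holder["de_mrna"]}
        mrna_query = {r.feature_id for r in holder["de_mrna"]
                      if r.direction in ("up", "down")}
        root = np.random.SeedSequence(config.seed)
        s_t, s_m = root.spawn(2)
        if target_query:
            holder["enrich_targets"] = enrich(
                target_query, genesets, gene_universe,
                alpha=config.alpha, n_perm=config.n_perm,
                seed=int(s_t.generate_state(1)[0] % (2**31)),
            )
        else:
            holder["enrich_targets"] = []
        if mrna_query:
            holder["enrich_mrna"] = enrich(
                mrna_query, genesets, mrna_universe,
                alpha=config.alpha, n_perm=config.n_perm,
                seed=int(s_m.generate_state(1)[0] % (2**31)),
            )
        else:
            holder["enrich_mrna"] = []
        for name, res in (("enrichment_targets.tsv", holder["enrich_targets"]),
                          ("enrichment_mrna.tsv", holder["enrich_mrna"])):
            _write_tsv(
                pd.DataFrame(
                    [
                        {"set_id": r.set_id, "overlap": r.overlap,
                         "set_size": r.set_size, "query_size": r.query_size,
                         "universe_size": r.universe_size,
                         "p_hypergeom": r.p_hypergeom,
                         "p_permutation": r.p_permutation, "q_value": r.q_value}
                        for r in res
                    ],
                    columns=["set_id", "overlap", "set_size", "query_size",
                             "universe_size", "p_hypergeom", "p_permutation",
                             "q_value"],
                ),
                out / name,
            )
        return {"target_query": len(target_query), "mrna_query": len(mrna_query)}

    # ---- stage 7: interplay + summary --------------------------------------
    @stage("interplay")
    def _interplay():
        if holder["enrich_targets"] and holder["enrich_mrna"]:
            common = common_pathways(
                holder["enrich_targets"], holder["enrich_mrna"], config.alpha
            )
            rep = overlap_analysis(
                common, holder["target_pairs"],
                holder["de_lnc"] + holder["de_mrna"], holder["genesets"],
            )
        else:
            from .interplay import InterplayReport
            rep = InterplayReport(common_pathways=set())
        holder["interplay"] = rep
        breakdown = mode_breakdown(rep)
        payload = {
            "common_pathways": sorted(rep.common_pathways),
            "n_targets": rep.n_targets,
            "n_mrnas": rep.n_mrnas,
            "n_overlap": rep.n_overlap,
            "n_overlap_pairs": rep.n_overlap_pairs,
            "n_same_direction": rep.n_same_direction,
            "n_opposite": rep.n_opposite,
            "n_cis_pairs": rep.n_cis_pairs,
            "n_trans_pairs": rep.n_trans_pairs,
            "mode_breakdown": {k: list(v) for k, v in breakdown.items()},
        }
        (out / "interplay.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {"pathway": sid,
                     "n_targets": len(e.target_genes),
                     "n_de_mrnas": len(e.de_mrna_genes),
                     "n_overlap": len(e.overlap_genes),
                     "n_same_direction": e.n_same_direction,
                     "n_opposite": e.n_opposite,
                     "n_cis": e.n_cis, "n_trans": e.n_trans}
                    for sid, e in sorted(rep.per_pathway.items())
                ],
                columns=["pathway", "n_targets", "n_de_mrnas", "n_overlap",
                         "n_same_direction", "n_opposite", "n_cis", "n_trans"],
            ),
            out / "interplay_pathways.tsv",
        )
        counts = summarize(holder["de_lnc"], holder["de_mrna"], rep)
        _write_tsv(counts.to_frame(), out / "summary.tsv")
        _write_tsv(counts.bars_frame(), out / "pathway_bars.tsv")
        return {
            "common_pathways": len(rep.common_pathways),
            "overlap": rep.n_overlap,
            "same_direction": rep.n_same_direction,
            "opposite": rep.n_opposite,
        }

    # timings go to the log only, so reruns stay byte-identical
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    logger.info("pipeline complete in %.1fs", time.perf_counter() - t_all)
    return manifest
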