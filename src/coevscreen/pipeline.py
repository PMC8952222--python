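"""Stage orchestration: curate → quality → pair → scan → post → export.

Each stage reads its inputs from the work directory, writes its outputs
there, and drops a completion marker containing the configuration digest;
re-running skips completed stages unless forced.  Protein-pair scanning is
embarrassingly parallel: every pair draws its Monte-Carlo streams from the
global seed and its own pair id, so results are identical for any worker
count, scheduling order, or input listing order.
"""

from __future__ import annotations

import json
import multiprocessing as mp
import shutil
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from coevscreen import __version__
from coevscreen.caps_engine import ScanLog, bidirectional_scan, scan_pair
from coevscreen.config import PipelineConfig
from coevscreen.core_io import Msa, read_msa, read_newick, write_msa, write_newick
from coevscreen.msa_quality import (
    column_stats,
    good_blocks,
    read_quality_tsv,
    write_quality_tsv,
)
from coevscreen.ortholog_curation import (
    HomologSet,
    divergence_screen,
    select_best_hit,
)
from coevscreen.pairing import PairInput, build_pair_input, enumerate_pairs
from coevscreen.postprocess import (
    build_tables,
    export_network,
    filter_results,
    write_tables,
)

__all__ = ["STAGES", "StageError", "run_pipeline", "load_result_tables"]

STAGES = ["curate", "quality", "pair", "scan", "post", "export"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class _Workspace:
    input_dir: Path
    work_dir: Path

    @property
    def curated(self) -> Path:
        return self.work_dir / "curated"

    @property
    def quality(self) -> Path:
        return self.work_dir / "quality"

    @property
    def pairs(self) -> Path:
        return self.work_dir / "pairs"

    @property
    def scan(self) -> Path:
        return self.work_dir / "scan"

    @property
    def results(self) -> Path:
        return self.work_dir / "results"

    @property
    def markers(self) -> Path:
        return self.work_dir / "markers"


def _protein_list(ws: _Workspace) -> list[str]:
    listing = ws.input_dir / "proteins.txt"
    if listing.exists():
        names = [
            line.strip()
            for line in listing.read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
    else:
        names = [p.stem for p in (ws.input_dir / "msa").glob("*.fasta")]
    return sorted(names)


def _marker(ws: _Workspace, stage: str) -> Path:
    return ws.markers / f"{stage}.done"


def _stage_done(ws: _Workspace, stage: str, digest: str) -> bool:
    marker = _marker(ws, stage)
    return marker.exists() and marker.read_text().strip() == digest


def _mark(ws: _Workspace, stage: str, digest: str) -> None:
    ws.markers.mkdir(parents=True, exist_ok=True)
    _marker(ws, stage).write_text(digest + "\n", encoding="utf-8")


# ---------------------------------------------------------------- stages


def _stage_curate(ws: _Workspace, cfg: PipelineConfig) -> None:
    ws.curated.mkdir(parents=True, exist_ok=True)
    rejections: list[dict] = []
    removed_rows: list[dict] = []
    candidates_dir = ws.input_dir / "candidates"
    for pid in _protein_list(ws):
        if candidates_dir.is_dir() and (candidates_dir / f"{pid}.fasta").exists():
            chosen = _curate_from_candidates(ws, cfg, pid, rejections)
        else:
            msa = read_msa(ws.input_dir / "msa" / f"{pid}.fasta", pid)
            chosen = dict(msa.rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            retained, removed = divergence_screen(chosen, cfg.divergence_cutoff)
        for rec in removed:
            removed_rows.append({"protein": pid, **rec})
        msa_out = Msa(pid, sorted(retained.items()))
        write_msa(msa_out, ws.curated / f"{pid}.fasta")
    pd.DataFrame(
        rejections, columns=["protein", "species", "candidate", "reason", "identity", "gaps"]
    ).to_csv(ws.curated / "rejections.tsv", sep="\t", index=False, lineterminator="\n")
    pd.DataFrame(removed_rows, columns=["protein", "species", "score", "cutoff"]).to_csv(
        ws.curated / "divergence_removed.tsv", sep="\t", index=False, lineterminator="\n"
    )


def _curate_from_candidates(
    ws: _Workspace, cfg: PipelineConfig, pid: str, rejections: list[dict]
) -> dict[str, str]:
    """Best-hit selection from a ``species|candidate_id`` candidate FASTA
    plus a reference FASTA."""
    cand_msa_rows = []
    from Bio import SeqIO

    for rec in SeqIO.parse(str(ws.input_dir / "candidates" / f"{pid}.fasta"), "fasta"):
        species, _, cand_id = rec.id.partition("|")
        cand_msa_rows.append((species, cand_id or "c1", str(rec.seq)))
    ref_path = ws.input_dir / "references" / f"{pid}.fasta"
    ref = str(next(SeqIO.parse(str(ref_path), "fasta")).seq)
    hs = HomologSet(pid, ref, cand_msa_rows)
    chosen, rej, _missing = select_best_hit(
        hs, cfg.min_identity, cfg.max_gaps, cfg.matrix
    )
    rejections.extend(rej)
    return chosen


def _stage_quality(ws: _Workspace, cfg: PipelineConfig) -> None:
    ws.quality.mkdir(parents=True, exist_ok=True)
    for pid in _protein_list(ws):
        msa = read_msa(ws.curated / f"{pid}.fasta", pid)
        cq = good_blocks(
            column_stats(msa), cfg.min_block, cfg.max_nonconserved_stretch
        )
        write_quality_tsv(cq, ws.quality / f"{pid}.tsv")


def _stage_pair(ws: _Workspace, cfg: PipelineConfig) -> None:
    ws.pairs.mkdir(parents=True, exist_ok=True)
    proteins = _protein_list(ws)
    msas = {pid: read_msa(ws.curated / f"{pid}.fasta", pid) for pid in proteins}
    tree = None
    tree_path = ws.input_dir / "tree.nwk"
    if cfg.use_external_tree and tree_path.exists():
        tree = read_newick(tree_path)
    rejected = []
    accepted = []
    for a, b in enumerate_pairs(proteins):
        result = build_pair_input(
            msas[a],
            msas[b],
            tree_a=tree,
            tree_b=tree,
            min_shared=cfg.min_shared,
        )
        if isinstance(result, PairInput):
            pair_dir = ws.pairs / result.pair_id
            pair_dir.mkdir(exist_ok=True)
            write_msa(result.msa_a, pair_dir / f"{result.protein_a}.fasta")
            write_msa(result.msa_b, pair_dir / f"{result.protein_b}.fasta")
            if result.tree_a is not None:
                write_newick(result.tree_a, pair_dir / f"{result.protein_a}.nwk")
            if result.tree_b is not None:
                write_newick(result.tree_b, pair_dir / f"{result.protein_b}.nwk")
            accepted.append(result.pair_id)
        else:
            rejected.append(
                {"pair": result.pair_id, "n_shared": result.n_shared, "reason": result.reason}
            )
    pd.DataFrame(rejected, columns=["pair", "n_shared", "reason"]).to_csv(
        ws.pairs / "rejections.tsv", sep="\t", index=False, lineterminator="\n"
    )
    (ws.pairs / "accepted.txt").write_text(
        "\n".join(accepted) + ("\n" if accepted else ""), encoding="utf-8"
    )


def _build_pair(ws: _Workspace, cfg: PipelineConfig, pair_id: str) -> PairInput:
    a, _, b = pair_id.partition("__")
    msa_a = read_msa(ws.curated / f"{a}.fasta", a)
    msa_b = read_msa(ws.curated / f"{b}.fasta", b)
    tree = None
    tree_path = ws.input_dir / "tree.nwk"
    if cfg.use_external_tree and tree_path.exists():
        tree = read_newick(tree_path)
    quality_a = read_quality_tsv(ws.quality / f"{a}.tsv", a)
    quality_b = read_quality_tsv(ws.quality / f"{b}.tsv", b)
    result = build_pair_input(
        msa_a,
        msa_b,
        tree_a=tree,
        tree_b=tree,
        min_shared=cfg.min_shared,
        quality_a=quality_a,
        quality_b=quality_b,
    )
    if not isinstance(result, PairInput):
        raise StageError(f"scan: pair {pair_id} no longer passes the shared-species filter")
    return result


def _scan_one(args) -> tuple[str, str, list[dict], bool]:
    """Worker: scan one pair; returns (pair_id, hits_tsv_text, log_dicts,
    aborted)."""
    ws_dict, cfg_dict, pair_id = args
    ws = _Workspace(Path(ws_dict["input_dir"]), Path(ws_dict["work_dir"]))
    cfg = PipelineConfig(**cfg_dict)
    pair = _build_pair(ws, cfg, pair_id)
    hits, logs = bidirectional_scan(pair, cfg.engine())
    tsv = hits.to_csv(sep="\t", index=False, float_format="%.6g", lineterminator="\n")
    aborted = any(l.aborted for l in logs)
    return pair_id, tsv, [l.__dict__ for l in logs], aborted


def _stage_scan(ws: _Workspace, cfg: PipelineConfig) -> None:
    ws.scan.mkdir(parents=True, exist_ok=True)
    accepted_path = ws.pairs / "accepted.txt"
    pair_ids = [
        line.strip()
        for line in accepted_path.read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    ws_dict = {"input_dir": str(ws.input_dir), "work_dir": str(ws.work_dir)}
    jobs = [(ws_dict, cfg.as_dict(), pid) for pid in sorted(pair_ids)]
    if cfg.workers > 1 and len(jobs) > 1:
        # fork: avoids re-importing __main__ in workers; results are
        # scheduling-independent because every pair derives its own streams
        method = "fork" if "fork" in mp.get_all_start_methods() else "spawn"
        with mp.get_context(method).Pool(cfg.workers) as pool:
            outcomes = pool.map(_scan_one, jobs)
    else:
        outcomes = [_scan_one(job) for job in jobs]
    aborted = []
    for pair_id, tsv, log_dicts, was_aborted in sorted(outcomes):
        (ws.scan / f"{pair_id}.hits.tsv").write_text(tsv, encoding="utf-8")
        log_text = "\n\n".join(
            "\n".join(f"{k}: {v}" for k, v in d.items()) for d in log_dicts
        )
        (ws.scan / f"{pair_id}.log").write_text(log_text + "\n", encoding="utf-8")
        if was_aborted:
            aborted.append(pair_id)
    if aborted:
        raise StageError(
            f"scan: {len(aborted)} pair(s) aborted: {', '.join(aborted[:10])}"
        )


def _read_scan_outputs(ws: _Workspace) -> tuple[list[pd.DataFrame], list[ScanLog]]:
    frames = []
    logs = []
    for log_path in sorted(ws.scan.glob("*.log")):
        blocks = log_path.read_text(encoding="utf-8").strip().split("\n\n")
        for block in blocks:
            entries = {}
            for line in block.splitlines():
                key, _, value = line.partition(": ")
                entries[key] = value
            log = ScanLog(entries["pair_id"], entries["direction"])
            for int_key in (
                "n_species",
                "n_columns_a",
                "n_columns_b",
                "n_usable_a",
                "n_usable_b",
                "n_comparisons",
                "n_candidates",
                "n_hits",
            ):
                setattr(log, int_key, int(entries[int_key]))
            log.threshold = float(entries["threshold"])
            log.aborted = entries["aborted"] == "True"
            log.reason = entries.get("reason", "")
            logs.append(log)
    for tsv in sorted(ws.scan.glob("*.hits.tsv")):
        frame = pd.read_csv(tsv, sep="\t")
        if len(frame):
            frames.append(frame)
    return frames, logs


def _stage_post(ws: _Workspace, cfg: PipelineConfig) -> None:
    frames, logs = _read_scan_outputs(ws)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tables = build_tables(frames, logs, per_pair_fdr=cfg.per_pair_fdr)
        filtered = filter_results(tables, cfg.p_max, cfg.require_good, cfg.gap_max)
    write_tables(tables, ws.results)
    filtered_dir = ws.results / "filtered"
    write_tables(filtered, filtered_dir)


def _stage_export(ws: _Workspace, cfg: PipelineConfig) -> None:
    frames, logs = _read_scan_outputs(ws)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tables = build_tables(frames, logs, per_pair_fdr=cfg.per_pair_fdr)
        filtered = filter_results(tables, cfg.p_max, cfg.require_good, cfg.gap_max)
    export_network(tables, ws.results / "network")
    export_network(filtered, ws.results / "network_filtered")


_STAGE_FUNCS = {
    "curate": _stage_curate,
    "quality": _stage_quality,
    "pair": _stage_pair,
    "scan": _stage_scan,
    "post": _stage_post,
    "export": _stage_export,
}


def run_pipeline(
    cfg: PipelineConfig,
    input_dir: str | Path,
    stages: list[str] | None = None,
    force: bool = False,
) -> dict:
    """Run the requested stages in order; returns a run report.

    Completed stages (matching configuration digest) are skipped unless
    ``force``.  Raises :class:`StageError` on stage failure.
    """
    cfg.validate()
    stages = list(STAGES) if stages is None else stages
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise StageError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    ws = _Workspace(Path(input_dir), Path(cfg.work_dir))
    ws.work_dir.mkdir(parents=True, exist_ok=True)
    digest = cfg.digest()
    report = {"stages": {}, "config_digest": digest, "version": __version__}
    for stage in stages:
        if not force and _stage_done(ws, stage, digest):
            report["stages"][stage] = {"status": "skipped"}
            continue
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](ws, cfg)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"{stage}: {exc}") from exc
        _mark(ws, stage, digest)
        report["stages"][stage] = {
            "status": "completed",
            "seconds": round(time.time() - t0, 2),
        }
    manifest = {
        "config": cfg.as_dict(),
        "config_digest": digest,
        "version": __version__,
        "stages": report["stages"],
    }
    (ws.work_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report


def load_result_tables(work_dir: str | Path, filtered: bool = False):
    """Read the residue and pair tables written by the post stage."""
    base = Path(work_dir) / "results"
    if filtered:
        base = base / "filtered"
    residue = pd.read_csv(base / "residue_table.tsv", sep="\t")
    pair = pd.read_csv(base / "pair_table.tsv", sep="\t")
    return residue, pair
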