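"""One-command orchestration of the screen analysis with a run manifest.

``run_primary_analysis`` executes read -> assemble -> polish -> score ->
call -> summarize -> write; ``run_validation`` executes pairing -> IQR
normalization -> threshold derivation -> confirmation -> Spearman.  Every
run writes a manifest recording the configuration, package version and an
input checksum, so each artifact is reproducible from manifest + input
alone.  Stage progress and timings go to the logger (stderr by default).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .io import (
    assemble_matrix,
    read_edge_list,
    read_long_format,
    write_edge_list,
    write_matrix,
)
from .polish import MedianPolish
from .scoring import DEFAULT_CUTOFF, call_hits, score_residuals, summarize_hits
from .validation import PairedMeasurement, confirm_hits, derive_threshold

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a primary-analysis run."""

    input_path: str
    output_dir: str
    cutoff: float = DEFAULT_CUTOFF
    max_iter: int = 20
    tol: float = 1e-8
    duplicate_policy: str = "error"
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.cutoff > 0:
            raise ValueError("cutoff must be > 0")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)

    return _Timer()


def run_primary_analysis(config: RunConfig) -> dict:
    """Run the full primary-screen analysis, writing all artifacts.

    Artifacts in ``config.output_dir``: ``residuals.tsv``, ``scores.tsv``,
    ``hits.tsv`` (edge list of bidirectional + unidirectional pairs),
    ``summary.json`` and ``manifest.json``.  Returns a dict with the
    in-memory results and artifact paths.  Deterministic for fixed
    input and configuration.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    input_path = Path(config.input_path)

    with _stage("read"):
        records = read_long_format(input_path)
    with _stage("assemble"):
        matrix = assemble_matrix(records, duplicate_policy=config.duplicate_policy)
        n_missing = int(matrix.isna().to_numpy().sum())
        if n_missing:
            logger.warning("assembled matrix has %d missing cells", n_missing)
        # hit calling needs an orientation-resolved square matrix; control
        # wells (e.g. prey-only rows) and one-sided ids are excluded from
        # the analysis matrix with a warning
        common = sorted(set(matrix.index) & set(matrix.columns))
        if len(common) < matrix.shape[0] or len(common) < matrix.shape[1]:
            dropped = sorted(
                (set(matrix.index) | set(matrix.columns)) - set(common)
            )
            logger.warning(
                "excluding %d identifier(s) not present as both bait and "
                "prey (control wells or one-sided measurements): %s%s",
                len(dropped),
                dropped[:5],
                "..." if len(dropped) > 5 else "",
            )
        square = matrix.loc[common, common]
    with _stage("polish"):
        polish = MedianPolish(max_iter=config.max_iter, tol=config.tol).fit(square)
        residuals = polish.residuals_
        if not polish.converged_:
            logger.warning(
                "median polish did not converge in %d sweeps "
                "(last max |median| = %.3g)",
                polish.n_iter_,
                polish.max_abs_change_,
            )
    with _stage("score"):
        scores = score_residuals(residuals)
    with _stage("call"):
        hits = call_hits(scores, cutoff=config.cutoff)
    with _stage("summarize"):
        summary = summarize_hits(hits)
        summary["cutoff"] = config.cutoff
        summary["n_baits"] = int(matrix.shape[0])
        summary["n_preys"] = int(matrix.shape[1])
        summary["n_proteins_analyzed"] = len(common)
        summary["polish_converged"] = polish.converged_
        summary["polish_n_iterations"] = polish.n_iter_
    with _stage("write"):
        paths = {
            "residuals": out_dir / "residuals.tsv",
            "scores": out_dir / "scores.tsv",
            "hits": out_dir / "hits.tsv",
            "summary": out_dir / "summary.json",
            "manifest": out_dir / "manifest.json",
        }
        write_matrix(residuals, paths["residuals"])
        write_matrix(scores, paths["scores"])
        write_edge_list(hits, paths["hits"], which="all")
        paths["summary"].write_text(json.dumps(summary, indent=2) + "\n")
        manifest = {
            "tool": "ecia",
            "version": __version__,
            "command": "run_primary_analysis",
            "config": asdict(config),
            "input_sha256": _sha256(input_path),
            "artifacts": {k: str(v) for k, v in paths.items() if k != "manifest"},
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")

    return {
        "matrix": matrix,
        "polish": polish.decomposition_(),
        "scores": scores,
        "hits": hits,
        "summary": summary,
        "paths": paths,
    }


def _orientation_map(records) -> dict[tuple[str, str], float]:
    return {(r.bait_id, r.prey_id): r.absorbance for r in records}


def pair_screens(
    primary_records, retest_records, hits=None
) -> list[PairedMeasurement]:
    """Pair the two screens' raw values per unordered pair.

    A pair is retained when at least one orientation was measured in each
    screen.  ``hits`` (a hit table or edge-list frame) flags predicted
    bidirectional hits.
    """
    prim = _orientation_map(primary_records)
    rt = _orientation_map(retest_records)

    def unordered(mapping):
        return {tuple(sorted(k)) for k in mapping}

    shared = unordered(prim) & unordered(rt)
    if not shared:
        raise ValueError(
            "no unordered pair is measured in both the primary and retest "
            "screens; nothing to validate"
        )
    predicted = set()
    if hits is not None:
        bid = hits[hits["hit_class"] == "bidirectional"]
        predicted = {tuple(sorted(t)) for t in zip(bid["id_a"], bid["id_b"])}
    pairs = []
    for a, b in sorted(shared):
        pairs.append(
            PairedMeasurement(
                pair=(a, b),
                primary_ab=prim.get((a, b), math.nan),
                primary_ba=prim.get((b, a), math.nan),
                retest_ab=rt.get((a, b), math.nan),
                retest_ba=rt.get((b, a), math.nan),
                is_predicted_hit=(a, b) in predicted,
            )
        )
    return pairs


def run_validation(
    primary_path: str | Path,
    retest_path: str | Path,
    hits_path: str | Path,
    output_dir: str | Path,
) -> dict:
    """Confirm primary hits against a retest screen, writing artifacts.

    Artifacts: ``validation.tsv`` (per-pair normalized geometric means and
    confirmed flag) and ``validation_summary.json`` (threshold,
    confirmation rate, Spearman rho).
    """
    import pandas as pd

    from .validation import _normalized_geo_means

    out_dir = Path(output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with _stage("pair"):
        primary_records = read_long_format(primary_path)
        retest_records = read_long_format(retest_path)
        hits = read_edge_list(hits_path)
        pairs = pair_screens(primary_records, retest_records, hits)
    with _stage("threshold"):
        threshold = derive_threshold(pairs, hits)
    with _stage("confirm"):
        result = confirm_hits(pairs, threshold)
    with _stage("write"):
        primary_geo = _normalized_geo_means(pairs, "primary")
        retest_geo = _normalized_geo_means(pairs, "retest")
        table = pd.DataFrame(
            {
                "id_a": [p.pair[0] for p in pairs],
                "id_b": [p.pair[1] for p in pairs],
                "primary_geo_mean": [primary_geo[p.pair] for p in pairs],
                "retest_geo_mean": [retest_geo[p.pair] for p in pairs],
                "is_predicted_hit": [p.is_predicted_hit for p in pairs],
                "confirmed": [p.pair in result.confirmed for p in pairs],
            }
        )
        validation_path = out_dir / "validation.tsv"
        table.to_csv(validation_path, sep="\t", index=False, na_rep="NA")
        summary = {
            "threshold": result.threshold,
            "n_pairs": len(pairs),
            "n_predicted_hits": int(table["is_predicted_hit"].sum()),
            "n_confirmed": len(result.confirmed),
            "confirmation_rate": result.confirmation_rate,
            "spearman_rho": result.spearman_rho,
        }
        summary_path = out_dir / "validation_summary.json"
        summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    return {
        "pairs": pairs,
        "result": result,
        "table": table,
        "summary": summary,
        "paths": {"validation": validation_path, "summary": summary_path},
    }
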