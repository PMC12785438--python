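"""End-to-end orchestration: ingest -> filter/impute -> differential -> Venn
-> bioactive matching -> parent-protein profiles -> report bundle.

Every stage writes its result to a file in the output directory and the
summary is recomputed from those files, so there is no hidden state; a rerun
with the same configuration and seed reproduces byte-identical outputs (the
run manifest deliberately carries no wall-clock timestamp — timing goes to
the stderr log only).
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import __version__
from .differential import (
    DEFAULT_ALPHA,
    DEFAULT_FC_THRESHOLD,
    DEFAULT_MIN_DETECTED,
    detect_filter,
    differential_analysis,
    impute_missing,
    results_to_frame,
    venn_summary,
)
from .io import (
    PeptideTable,
    load_bioactive_reference,
    load_parent_proteins,
    read_bioactive_db,
    read_fasta,
    read_peptide_table,
)
from .matching import DEFAULT_GROUPS, DEFAULT_THRESHOLD, SubstitutionGroups, annotate_differential
from .profiles import build_profile, compare_profiles, profile_to_frame
from .simulate import make_study_like, simulate_table

logger = logging.getLogger("lactopept")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (flat, manifest-serialisable)."""

    out_dir: Path
    # input: either a peptide table + group map, or a simulation preset
    table_path: Path | None = None
    group_map: Mapping[str, str] | None = None
    preset: str | None = None
    seed: int = 0
    # analysis parameters
    group_a: str | None = None
    group_b: str | None = None
    alpha: float = DEFAULT_ALPHA
    fc_threshold: float = DEFAULT_FC_THRESHOLD
    min_detected: int = DEFAULT_MIN_DETECTED
    imputation: str = "half_group_min"
    adjust: bool = False
    homology_threshold: float = DEFAULT_THRESHOLD
    substitution_groups: tuple[str, ...] = ("VIL", "DE", "RK")
    collapse_il: bool = False
    fasta_path: Path | None = None
    db_path: Path | None = None
    profile_parents: tuple[str, ...] = ("beta_CN",)

    def manifest(self) -> dict:
        return {
            "lactopept_version": __version__,
            "seed": self.seed,
            "input": {
                "table": str(self.table_path) if self.table_path else None,
                "preset": self.preset,
                "groups": dict(self.group_map) if self.group_map else None,
                "fasta": str(self.fasta_path) if self.fasta_path else None,
                "db": str(self.db_path) if self.db_path else None,
            },
            "parameters": {
                "group_a": self.group_a,
                "group_b": self.group_b,
                "alpha": self.alpha,
                "fc_threshold": self.fc_threshold,
                "min_detected": self.min_detected,
                "imputation": self.imputation,
                "adjust": self.adjust,
                "homology_threshold": self.homology_threshold,
                "substitution_groups": list(self.substitution_groups),
                "collapse_il": self.collapse_il,
                "profile_parents": list(self.profile_parents),
            },
        }


@dataclass
class RunResult:
    """Paths and in-memory objects produced by :func:`run_all`."""

    out_dir: Path
    summary: dict
    files: dict[str, Path] = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _load_input(config: RunConfig) -> PeptideTable:
    if config.table_path is not None:
        if config.group_map is None:
            raise StageError("ingest: a peptide table needs a sample->group map")
        return read_peptide_table(config.table_path, config.group_map)
    if config.preset is not None:
        spec = make_study_like(config.preset, seed=config.seed)
        table, _ = simulate_table(spec)
        return table
    raise StageError("ingest: provide either table_path+group_map or a preset")


def run_all(config: RunConfig) -> RunResult:
    """Run the full analysis, writing the report bundle to ``config.out_dir``.

    On any stage failure partial outputs are removed and a
    :class:`StageError` naming the stage is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    t0 = time.perf_counter()
    try:
        # -- ingest ----------------------------------------------------------
        table = _load_input(config)
        group_a, group_b = config.group_a, config.group_b
        if group_a is None or group_b is None:
            labels = table.group_labels
            if len(labels) != 2:
                raise StageError(f"ingest: expected two groups, got {labels}")
            group_a, group_b = labels
        logger.info("ingest: %d peptides, groups %s/%s", len(table.records), group_a, group_b)

        # -- Venn on detected sets (pre-filter, distinct peptides) -----------
        venn = venn_summary(
            table.group_sequences(group_a), table.group_sequences(group_b)
        )
        files["venn"] = out / "venn.json"
        _write_json(venn.as_dict(), files["venn"])

        # -- filter / impute / differential ----------------------------------
        try:
            filtered = detect_filter(table, config.min_detected)
            imputed = impute_missing(filtered, config.imputation)  # type: ignore[arg-type]
            results = differential_analysis(
                imputed,
                group_a,
                group_b,
                alpha=config.alpha,
                fc_threshold=config.fc_threshold,
                adjust=config.adjust,
            )
        except Exception as exc:
            raise StageError(f"differential: {exc}") from exc
        diff_frame = results_to_frame(results)
        files["differential"] = out / "differential.tsv"
        diff_frame.to_csv(files["differential"], sep="\t", index=False)

        # -- bioactive matching ----------------------------------------------
        try:
            db = (
                read_bioactive_db(config.db_path)
                if config.db_path
                else load_bioactive_reference()
            )
            groups = SubstitutionGroups.from_strings(config.substitution_groups)
            annotations, match_summary = annotate_differential(
                results,
                db,
                threshold=config.homology_threshold,
                groups=groups,
                collapse_il=config.collapse_il,
            )
        except Exception as exc:
            raise StageError(f"match: {exc}") from exc
        files["bioactive"] = out / "bioactive.tsv"
        with open(files["bioactive"], "w", encoding="utf-8") as fh:
            fh.write("sequence\tstatus\tn_hits\tbest_homology_pct\tbest_parent\tfunctions\n")
            for ann in annotations:
                best = ann.hits[0].homology_pct if ann.hits else float("nan")
                fh.write(
                    f"{ann.sequence}\t{ann.status}\t{len(ann.hits)}\t{best:.4f}\t"
                    f"{ann.best_parent or ''}\t{';'.join(ann.functions)}\n"
                )
        files["bioactive_summary"] = out / "bioactive_summary.json"
        _write_json(match_summary, files["bioactive_summary"])

        # -- per-parent residue profiles --------------------------------------
        try:
            fasta = (
                read_fasta(config.fasta_path) if config.fasta_path else load_parent_proteins()
            )
            parents = {p.id: p for p in fasta}
            profile_files, profile_summary = _profile_stage(
                imputed, parents, config, group_a, group_b, out
            )
            files.update(profile_files)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"profile: {exc}") from exc

        # -- summary + manifest -----------------------------------------------
        summary = build_summary(venn, results, match_summary, profile_summary)
        files["summary"] = out / "summary.json"
        _write_json(summary, files["summary"])
        files["manifest"] = out / "manifest.json"
        _write_json(config.manifest(), files["manifest"])
    except Exception:
        for path in files.values():
            path.unlink(missing_ok=True)
        raise
    logger.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    return RunResult(out_dir=out, summary=summary, files=files)


def _profile_stage(imputed, parents, config, group_a, group_b, out):
    """Group-mean residue profiles per requested parent, plus comparisons."""
    files: dict[str, Path] = {}
    profile_summary: dict[str, dict] = {}
    mode = "il_collapsed" if config.collapse_il else "exact"
    for pid in config.profile_parents:
        if pid not in parents:
            raise StageError(f"profile: unknown parent id {pid!r}")
        parent = parents[pid]
        group_profiles = {}
        for group in (group_a, group_b):
            cols = imputed.samples_of(group)
            abundances = {
                rec.sequence: sum(rec.abundances.get(s, 0.0) for s in cols) / len(cols)
                for rec in imputed.records
            }
            profile = build_profile(abundances, parent, mode)
            group_profiles[group] = profile
            key = f"profile_{pid}_{group}"
            files[key] = out / f"{key}.tsv"
            profile_to_frame(profile, parent).to_csv(
                files[key], sep="\t", index=False, float_format="%.6g"
            )
        comparison = compare_profiles(group_profiles[group_a], group_profiles[group_b])
        profile_summary[pid] = {
            "coverage_a": group_profiles[group_a].coverage_fraction,
            "coverage_b": group_profiles[group_b].coverage_fraction,
            "delta_coverage": comparison.delta_coverage,
            "delta_total_count": comparison.delta_total_count,
            "delta_total_abundance": comparison.delta_total_abundance,
        }
        files[f"profile_compare_{pid}"] = out / f"profile_compare_{pid}.json"
        _write_json(profile_summary[pid], files[f"profile_compare_{pid}"])
    return files, profile_summary


def build_summary(venn, results, match_summary, profile_summary) -> dict:
    """Machine-readable run summary; every count is recomputable from stage files."""
    n_up = sum(1 for r in results if r.status == "up")
    n_down = sum(1 for r in results if r.status == "down")
    parents_up = match_summary.get("parents_up", {})
    n_up_bioactive = match_summary["n_up_bioactive"]
    beta_up = sum(1 for p in parents_up.values() if p == "beta_CN")
    return {
        "venn": venn.as_dict(),
        "n_up": n_up,
        "n_down": n_down,
        "n_ns": sum(1 for r in results if r.status == "ns"),
        "n_not_tested": sum(1 for r in results if r.status == "not_tested"),
        "n_up_bioactive": n_up_bioactive,
        "n_down_bioactive": match_summary["n_down_bioactive"],
        "functions_up": match_summary["functions_up"],
        "functions_down": match_summary["functions_down"],
        "beta_cn_share_of_up_bioactive": (
            beta_up / n_up_bioactive if n_up_bioactive else 0.0
        ),
        "profiles": profile_summary,
    }


def report_summary(out_dir: str | Path) -> str:
    """Human-readable digest of a completed run, recomputed from its files."""
    out = Path(out_dir)
    required = ["summary.json", "venn.json", "bioactive_summary.json"]
    for name in required:
        if not (out / name).exists():
            raise StageError(f"report: missing stage file {name}")
    summary = json.loads((out / "summary.json").read_text())
    venn = summary["venn"]
    lines = [
        f"Distinct peptides: A={venn['n_a']}, B={venn['n_b']}, "
        f"shared={venn['n_shared']}, union={venn['n_union']}",
        f"Group-specific: A={venn['n_unique_a']}, B={venn['n_unique_b']}",
        f"Differential: {summary['n_up']} up, {summary['n_down']} down, "
        f"{summary['n_ns']} ns, {summary['n_not_tested']} not tested",
        f"Bioactive candidates: {summary['n_up_bioactive']} up, "
        f"{summary['n_down_bioactive']} down",
        f"beta-CN share of upregulated bioactive candidates: "
        f"{summary['beta_cn_share_of_up_bioactive']:.2f}",
    ]
    for pid, prof in summary.get("profiles", {}).items():
        lines.append(
            f"{pid} coverage: A={prof['coverage_a']:.3f}, B={prof['coverage_b']:.3f}"
        )
    return "\n".join(lines)


def clean_output(out_dir: str | Path) -> None:
    shutil.rmtree(out_dir, ignore_errors=True)
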