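"""End-to-end pipeline: filter -> error -> select/iterate -> permtest -> AMOVA.

A single YAML configuration drives a full run; all randomness flows from
one master seed split per stage, so a rerun with the same configuration
and seed reproduces every artifact byte for byte (timestamps excluded).

Configuration schema (all sections optional unless noted)::

    seed: 11
    output_dir: run1            # where artifacts are written
    simulate:                   # EITHER a simulation block ...
      large_study: true          #   start from the frozen large-study config
      n_loci: 500               #   any SimulationConfig field may override
    inputs:                     # ... OR paths to existing files
      matrix: calls.tsv
      pairs: pairs.tsv
      hierarchy: hier.tsv
    filter:
      min_present: 3
      drop_monomorphic: true
    select:
      rounds: 2
      min_loci: 50
    fixed_thresholds: [0.20, 0.10, 0.05]
    permutation:
      n_perm: 1000
    amova:
      enabled: true
      n_perm: 999
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .amova import AmovaResult, amova_three_level
from .error_rates import (
    LocusStats,
    locus_error_rates,
    mean_error_rate,
    write_locus_stats,
)
from .exceptions import ValidationError
from .matrix import (
    Hierarchy,
    MarkerMatrix,
    ReplicateSet,
    drop_replicate_partners,
    filter_monomorphic,
    filter_rare_loci,
    read_hierarchy,
    read_marker_matrix,
    read_replicate_pairs,
    write_hierarchy,
    write_marker_matrix,
    write_replicate_pairs,
)
from .permutation import PermutationResult, permutation_test
from .simulate import SimulationConfig, large_study_config, simulate_dataset
from .threshold import SelectionResult, iterate_selection, select_fixed

logger = logging.getLogger("aflpselect")

__all__ = ["RunReport", "run_pipeline", "load_config"]


@dataclass
class RunReport:
    """Summary of one pipeline run.

    ``selection_rows`` mirrors the classic selection-summary table: one
    row per locus subset (no selection, each moving-threshold round, each
    fixed threshold) with locus count, mean present-allele frequency and
    mean error rate.  Every number is recomputable from the artifacts
    written next to it.
    """

    selection_rows: list[dict[str, Any]] = field(default_factory=list)
    models: list[dict[str, Any]] = field(default_factory=list)
    permutation: dict[str, Any] | None = None
    amova_tables: dict[str, dict[str, Any]] = field(default_factory=dict)
    seed: int = 0
    config_hash: str = ""
    version: str = __version__

    def body_text(self) -> str:
        """Human-readable report body (deterministic; no timestamps)."""
        lines = [
            f"aflpselect {self.version}  seed={self.seed}  config={self.config_hash}",
            "",
            "Selection summary",
            f"{'subset':<24}{'# loci':>8}{'mean freq':>12}{'error rate':>12}",
        ]
        for r in self.selection_rows:
            lines.append(
                f"{r['label']:<24}{r['n_loci']:>8}"
                f"{r['mean_freq']:>12.3f}{100 * r['mean_error']:>11.2f}%"
            )
        for mrow in self.models:
            lines.append("")
            lines.append(
                f"Round {mrow['round']}: y = {mrow['b0']:.4f} + {mrow['b1']:.3f} f "
                f"{mrow['b2']:+.3f} f^2   R^2 = {mrow['r_squared']:.3f}  "
                f"p = {mrow['f_pvalue']:.3g}  (n = {mrow['n_loci_fit']})"
            )
        if self.permutation is not None:
            p = self.permutation
            lines += [
                "",
                f"Permutation test: {p['n_perm']} draws of {p['n_selected']} loci; "
                f"null mean error {100 * p['null_mean']:.2f}% "
                f"(range {100 * p['null_min']:.2f}-{100 * p['null_max']:.2f}%); "
                f"observed {100 * p['observed_mean']:.2f}%  p = {p['p_value']:.4g}",
            ]
        for label, t in self.amova_tables.items():
            lines += ["", f"AMOVA ({label}; {t['n_perm']} permutations)"]
            lines.append(
                f"{'source':<28}{'df':>5}{'SS':>12}{'var':>10}{'%':>8}{'Phi':>8}{'p':>8}"
            )
            for src in ("among_groups", "among_pops_within_groups", "within_pops"):
                row = t[src]
                phi = f"{row['phi']:.3f}" if row["phi"] == row["phi"] else "  --"
                pv = f"{row['p']:.3f}" if row["p"] == row["p"] else "  --"
                lines.append(
                    f"{src:<28}{row['df']:>5}{row['ss']:>12.3f}"
                    f"{row['var']:>10.3f}{row['pct']:>7.1f}%{phi:>8}{pv:>8}"
                )
            lines.append(
                f"{'total':<28}{t['df_total']:>5}{t['ss_total']:>12.3f}"
                f"{t['var_total']:>10.3f}{100.0:>7.1f}%"
            )
        return "\n".join(lines) + "\n"


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return cfg


def _config_hash(cfg: dict[str, Any]) -> str:
    # output_dir is a location, not an analysis parameter
    hashed = {k: v for k, v in cfg.items() if k != "output_dir"}
    blob = yaml.safe_dump(hashed, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _stage_seeds(master: int, n: int) -> list[int]:
    """Independent per-stage seeds derived from one master seed (< 2**31)."""
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _selection_row(label: str, stats: Sequence[LocusStats]) -> dict[str, Any]:
    usable = [s for s in stats if s.defined]
    err, _ = mean_error_rate(list(stats))
    freq = float(np.mean([s.present_freq for s in usable]))
    return {"label": label, "n_loci": len(stats), "mean_freq": freq, "mean_error": err}


def _amova_dict(r: AmovaResult) -> dict[str, Any]:
    p = r.p_values or (float("nan"),) * 3
    return {
        "n_perm": r.n_perm,
        "among_groups": {
            "df": r.df[0], "ss": r.ss_among_groups, "var": r.var_components[0],
            "pct": r.pct_variance[0], "phi": r.phi_rt, "p": p[0],
        },
        "among_pops_within_groups": {
            "df": r.df[1], "ss": r.ss_among_pops_within_groups,
            "var": r.var_components[1], "pct": r.pct_variance[1],
            "phi": r.phi_pr, "p": p[1],
        },
        "within_pops": {
            "df": r.df[2], "ss": r.ss_within_pops, "var": r.var_components[2],
            "pct": r.pct_variance[2], "phi": r.phi_pt, "p": p[2],
        },
        "df_total": sum(r.df),
        "ss_total": r.ss_total,
        "var_total": sum(r.var_components),
    }


def run_pipeline(config: str | Path | dict[str, Any]) -> RunReport:
    """Execute the full workflow described by ``config``.

    Returns the :class:`RunReport`; writes all intermediate artifacts
    (matrix, pairs, hierarchy, locus stats, per-round kept-locus lists
    and filtered matrices, report TSV and text) under ``output_dir``.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    seed = int(cfg.get("seed", 0))
    out_dir = Path(cfg.get("output_dir", "aflpselect_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed, 4)  # simulate, permutation, amova-none, amova-final

    # -- inputs ---------------------------------------------------------
    if "simulate" in cfg and "inputs" in cfg:
        raise ValidationError("config must give either 'simulate' or 'inputs', not both")
    if "simulate" in cfg:
        sim = dict(cfg["simulate"] or {})
        base = large_study_config() if sim.pop("large_study", False) else SimulationConfig()
        fields = {k: v for k, v in sim.items()}
        unknown = set(fields) - set(SimulationConfig.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown simulate options: {sorted(unknown)}")
        from dataclasses import replace as dc_replace

        if "pops_per_group" in fields and isinstance(fields["pops_per_group"], list):
            fields["pops_per_group"] = tuple(fields["pops_per_group"])
        sim_cfg = dc_replace(base, **fields)
        matrix, reps, hierarchy, _ = simulate_dataset(sim_cfg, seed=seeds[0])
        logger.info("simulate: %d samples x %d loci, %d replicate pairs",
                    matrix.n_samples, matrix.n_loci, len(reps))
        write_marker_matrix(matrix, out_dir / "matrix.tsv")
        write_replicate_pairs(reps, out_dir / "pairs.tsv")
        write_hierarchy(hierarchy, out_dir / "hierarchy.tsv")
    elif "inputs" in cfg:
        inputs = cfg["inputs"] or {}
        for key in ("matrix", "pairs"):
            if key not in inputs:
                raise ValidationError(f"inputs.{key} is required")
            if not Path(inputs[key]).exists():
                raise ValidationError(f"inputs.{key}: no such file {inputs[key]!r}")
        matrix = read_marker_matrix(inputs["matrix"])
        reps = read_replicate_pairs(inputs["pairs"])
        reps.validate_against(matrix)
        hierarchy = None
        if "hierarchy" in inputs:
            if not Path(inputs["hierarchy"]).exists():
                raise ValidationError(
                    f"inputs.hierarchy: no such file {inputs['hierarchy']!r}"
                )
            hierarchy = read_hierarchy(inputs["hierarchy"])
            hierarchy.validate_against(matrix, exclude=reps.partners)
    else:
        raise ValidationError("config needs a 'simulate' or 'inputs' section")

    # -- pre-filters ----------------------------------------------------
    fcfg = cfg.get("filter", {}) or {}
    n0 = matrix.n_loci
    matrix = filter_rare_loci(matrix, int(fcfg.get("min_present", 3)))
    if fcfg.get("drop_monomorphic", True):
        matrix = filter_monomorphic(matrix)
    logger.info("filter: %d -> %d loci", n0, matrix.n_loci)

    # -- error statistics ------------------------------------------------
    stats = locus_error_rates(matrix, reps)
    write_locus_stats(stats, out_dir / "locus_stats.tsv")
    report = RunReport(seed=seed, config_hash=_config_hash(cfg))
    report.selection_rows.append(_selection_row("no selection", stats))

    # -- moving-threshold selection --------------------------------------
    scfg = cfg.get("select", {}) or {}
    rounds = int(scfg.get("rounds", 2))
    results = iterate_selection(
        matrix, reps, rounds=rounds, min_loci=int(scfg.get("min_loci", 50))
    )
    stats_by_id = {s.locus_id: s for s in stats}
    for res in results:
        kept_stats = [stats_by_id[l] for l in res.kept]
        report.selection_rows.append(
            _selection_row(f"moving threshold, round {res.round_index}", kept_stats)
        )
        report.models.append(
            {
                "round": res.round_index,
                "b0": res.model.b0, "b1": res.model.b1, "b2": res.model.b2,
                "r_squared": res.model.r_squared, "f_pvalue": res.model.f_pvalue,
                "n_loci_fit": res.model.n_loci_fit,
            }
        )
        (out_dir / f"kept_round{res.round_index}.txt").write_text(
            "\n".join(res.kept) + "\n"
        )
        write_marker_matrix(
            matrix.take_loci(res.kept), out_dir / f"matrix_round{res.round_index}.tsv"
        )
        logger.info(
            "select round %d: %d kept, %d removed (%.0f%%), mean error %.4f -> %.4f",
            res.round_index, res.n_kept, res.n_removed,
            100 * res.n_removed / max(1, res.n_kept + res.n_removed),
            res.mean_error_before, res.mean_error_after,
        )

    # -- fixed thresholds -------------------------------------------------
    for tau in cfg.get("fixed_thresholds", []) or []:
        res = select_fixed(stats, float(tau))
        kept_stats = [stats_by_id[l] for l in res.kept]
        report.selection_rows.append(
            _selection_row(f"fixed threshold {100 * float(tau):g}%", kept_stats)
        )
        logger.info("fixed threshold %.2f: %d kept", tau, res.n_kept)

    # -- permutation test -------------------------------------------------
    pcfg = cfg.get("permutation", {}) or {}
    perm: PermutationResult | None = None
    if results and pcfg.get("enabled", True):
        final = results[-1]
        observed, _ = mean_error_rate([stats_by_id[l] for l in final.kept])
        perm = permutation_test(
            stats,
            n_selected=len(final.kept),
            observed_mean=observed,
            n_perm=int(pcfg.get("n_perm", 1000)),
            seed=seeds[1],
        )
        null = np.array(perm.null_means)
        report.permutation = {
            "n_perm": perm.n_perm, "n_selected": perm.n_selected,
            "null_mean": float(null.mean()), "null_min": float(null.min()),
            "null_max": float(null.max()),
            "observed_mean": perm.observed_mean, "p_value": perm.p_value,
        }
        (out_dir / "permutation_null.txt").write_text(
            "\n".join(f"{v:.6f}" for v in perm.null_means) + "\n"
        )
        logger.info("permutation: p = %.4g", perm.p_value)

    # -- AMOVA ------------------------------------------------------------
    acfg = cfg.get("amova", {}) or {}
    if acfg.get("enabled", True) and hierarchy is not None:
        n_perm = int(acfg.get("n_perm", 999))
        unique = drop_replicate_partners(matrix, reps)
        subsets = {"no selection": unique}
        if results:
            subsets[f"round {results[-1].round_index} loci"] = unique.take_loci(
                results[-1].kept
            )
        for i, (label, sub) in enumerate(subsets.items()):
            res = amova_three_level(
                sub, hierarchy, n_perm=n_perm, seed=seeds[2 + i], replicates=reps
            )
            report.amova_tables[label] = _amova_dict(res)
            logger.info("amova (%s): %%var = %.1f/%.1f/%.1f", label, *res.pct_variance)

    # -- emit -------------------------------------------------------------
    import pandas as pd

    pd.DataFrame(report.selection_rows).to_csv(
        out_dir / "report.tsv", sep="\t", index=False
    )
    (out_dir / "report.txt").write_text(report.body_text())
    return report
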