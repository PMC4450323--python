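"""End-to-end orchestration: config, logging, intermediate tables, report.

A run is fully specified by a :class:`RunConfig` (threshold set, input
paths, seed).  Inputs missing from the config are simulated with
:mod:`progressionkit.synthetic` at the configured seed, so the bundled demo
(`progressionkit run-all` with no inputs) is deterministic end to end.  All
intermediate tables are written as TSV into the output directory together
with an echo of the config and a text report whose cohort fractions are
pure functions of the per-unit tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from . import report as rpt
from .methylation import (adjust_for_composition, b_cell_orientation,
                          b_cell_score, deconvolve_samples,
                          paired_progression_test, progression_score,
                          BetaMatrix, change_magnitude_summary)
from .somatic import (assign_locus_labels, classify_cohort, drift_test_table,
                      group_cna_segments, somatic_call_table)
from .synthetic import (SimulationConfig, config_to_dict,
                        simulate_cna_segments, simulate_genetic_cohort,
                        simulate_methylation_cohort)

logger = logging.getLogger("progressionkit")


@dataclass
class RunConfig:
    """All thresholds and inputs of one pipeline run."""

    out_dir: str = "progressionkit_out"
    seed: int = 0
    # thresholds
    somatic_p: float = 0.001
    germline_af: float = 0.10
    fdr: float = 0.05
    window: int = 200
    diff: float = 0.10
    quantile: float = 0.05
    magnitude: tuple[float, float] = (0.05, 0.20)
    merge_distance: int = 1_000_000
    n_perm: int = 10_000
    n_resamples: int = 10_000
    fold_contracting: bool = False
    # inputs (None -> simulated demo data)
    exome_counts: str | None = None
    amplicon_counts: str | None = None
    cna_segments: str | None = None
    beta_values: str | None = None
    beta_metadata: str | None = None
    reference_panel: str | None = None
    peaks: str | None = None
    # simulation knobs for the demo path
    simulation: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, lo, hi in (("somatic_p", 0, 1), ("germline_af", 0, 1),
                             ("fdr", 0, 1), ("quantile", 0, 0.5)):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.window <= 0 or self.window % 2:
            raise ValueError("window must be a positive even integer")
        if self.n_perm < 1 or self.n_resamples < 1:
            raise ValueError("n_perm and n_resamples must be positive")

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "magnitude" in raw:
        raw["magnitude"] = tuple(raw["magnitude"])
    return RunConfig(**raw)


def _setup_run(config: RunConfig) -> Path:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    if not logger.handlers:
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    echo = dataclasses.asdict(config)
    echo["magnitude"] = list(echo["magnitude"])
    (out / "run_config.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
    logger.info("run: out_dir=%s seed=%d", out, config.seed)
    for name in ("exome_counts", "amplicon_counts", "beta_values"):
        path = getattr(config, name)
        if path:
            digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
            logger.info("input %s: %s sha256:%s", name, path, digest)
    return out


def run_genetic(config: RunConfig) -> dict:
    """Somatic calling, drift testing, classification, sCNA grouping."""
    out = _setup_run(config)
    if config.exome_counts and config.amplicon_counts:
        exome = pio.read_allele_counts(config.exome_counts)
        amplicon = pio.read_allele_counts(config.amplicon_counts)
        truth = None
    else:
        logger.info("no count tables supplied; simulating demo genetic cohort")
        cohort = simulate_genetic_cohort(config.sim_config())
        exome, amplicon, truth = cohort.exome_counts, cohort.amplicon_counts, cohort.truth

    somatic = somatic_call_table(exome, n_perm=config.n_perm, seed=config.seed,
                                 p_threshold=config.somatic_p,
                                 max_germline_af=config.germline_af)
    pio.write_tsv(somatic, out / "somatic_calls.tsv")

    somatic_sites = set(somatic.loc[somatic["is_somatic"], "site_id"])
    validated = amplicon[amplicon["site_id"].isin(somatic_sites)]
    drift = drift_test_table(validated, fdr=config.fdr)
    pio.write_tsv(drift, out / "drift_results.tsv")

    calls = classify_cohort(drift, fold_contracting=config.fold_contracting)
    pio.write_tsv(calls, out / "evolution_calls.tsv")

    sections: dict = {
        "Somatic drift summary": rpt.summarize_drift(drift, large_change=config.diff),
        "Evolution categories": rpt.summarize_categories(calls),
    }
    if config.cna_segments:
        segments = pio.read_segments(config.cna_segments)
        groups = group_cna_segments(segments, merge_distance=config.merge_distance)
        groups["locus_label"] = assign_locus_labels(groups)
        pio.write_tsv(groups, out / "cna_groups.tsv")
        n_patients = calls["patient_id"].nunique()
        sections["sCNA recurrence"] = rpt.summarize_cna(groups, n_patients)

    result = {"somatic": somatic, "drift": drift, "calls": calls,
              "sections": sections, "truth": truth}
    _write_report(out, "genetic_report", sections)
    return result


def run_methylation(config: RunConfig) -> dict:
    """Deconvolution, adjustment, scores, paired progression testing."""
    out = _setup_run(config)
    if config.beta_values and config.beta_metadata and config.reference_panel:
        bm = pio.read_beta_matrix(config.beta_values, config.beta_metadata)
        panel = pio.read_reference_panel(config.reference_panel)
        truth = None
    else:
        logger.info("no beta matrix supplied; simulating demo methylation cohort")
        cohort = simulate_methylation_cohort(config.sim_config())
        bm, panel, truth = cohort.betas, cohort.reference.panel, cohort.truth
        pio.write_tsv(cohort.annotation, out / "cpg_annotation.tsv")
        pio.write_bed(cohort.peaks, out / "h3k27me3_peaks.bed")

    comps = deconvolve_samples(bm.values.loc[panel.marker_ids], panel)
    pio.write_tsv(comps, out / "compositions.tsv", index=True)

    adjusted = BetaMatrix(adjust_for_composition(bm.values, comps), bm.metadata)
    pio.write_tsv(adjusted.values, out / "adjusted_betas.tsv", index=True)

    results = paired_progression_test(adjusted, fdr=config.fdr)
    pio.write_tsv(results, out / "progression_results.tsv")

    prog_cpgs = list(results.loc[results["significant"], "cpg_id"])
    orientation = b_cell_orientation(panel, panel.marker_ids)
    t1, t2 = bm.paired()
    adj_t1, adj_t2 = adjusted.paired()
    scores = []
    for patient in t1.columns:
        scores.append({
            "patient_id": patient,
            "b_cell_score_delta": b_cell_score(
                t1[patient].loc[panel.marker_ids], t2[patient].loc[panel.marker_ids],
                panel.marker_ids, orientation=orientation),
            "progression_score": progression_score(
                adj_t1[patient], adj_t2[patient], prog_cpgs) if prog_cpgs else 0.0,
        })
    scores_df = pd.DataFrame(scores)
    pio.write_tsv(scores_df, out / "methylation_scores.tsv")

    deltas = adjusted.paired_deltas()
    magnitude, magnitude_means = change_magnitude_summary(deltas, config.magnitude)
    pio.write_tsv(magnitude, out / "change_magnitude.tsv", index=True)

    sections = {
        "Progression CpG summary": rpt.summarize_progression(results),
        "Change magnitude (cohort means)": dict(magnitude_means),
    }
    _write_report(out, "methylation_report", sections)
    return {"betas": bm, "adjusted": adjusted, "compositions": comps,
            "results": results, "scores": scores_df, "sections": sections,
            "truth": truth}


def run_all(config: RunConfig) -> dict:
    """Full pipeline; genetic and methylation halves share the seed."""
    genetic = run_genetic(config)
    methylation = run_methylation(config)
    sections = {**genetic["sections"], **methylation["sections"]}
    _write_report(Path(config.out_dir), "cohort_report", sections)
    return {"genetic": genetic, "methylation": methylation, "sections": sections}


def _write_report(out: Path, stem: str, sections: dict) -> None:
    (out / f"{stem}.txt").write_text(rpt.format_report(sections))
    rows = []
    for section, content in sections.items():
        if isinstance(content, pd.DataFrame):
            for _, r in content.iterrows():
                for k, v in r.items():
                    rows.append((section, f"{r.iloc[0]}::{k}", v))
        else:
            rows.extend((section, k, v) for k, v in content.items())
    pio.write_tsv(pd.DataFrame(rows, columns=["section", "key", "value"]),
                  out / f"{stem}.tsv")


def demo_simulation_config(seed: int = 0) -> SimulationConfig:
    """Small, quick demo cohort (sizes chosen for a sub-minute run)."""
    return SimulationConfig(seed=seed, n_patients=20, n_variants_min=15,
                            n_variants_max=25, n_cpgs=3000,
                            frac_progression_cpgs=0.02)


__all__ = ["RunConfig", "load_config", "run_genetic", "run_methylation",
           "run_all", "demo_simulation_config", "config_to_dict"]
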