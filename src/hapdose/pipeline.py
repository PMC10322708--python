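"""End-to-end orchestration: simulate -> quantify -> classify -> infer, and
simulate-atac -> normalize -> permute -> flag.

`RunConfig` gathers every threshold of the analysis with its standard default
(TPM floor 25, allelic window 0.3-0.7, nullisomic bound 0.1, alpha 0.05, QC
gene floors 6000/4000, ATAC fold-change cut 0.70, k = 50 background peaks)
plus simulation sizes; all randomness derives from one integer seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import atac as atac_mod
from . import io as io_mod
from .classify import classify_cells
from .core import Family, SegregationScenario
from .family import analyze_family
from .quant import QuantConfig, qc_filter_cell, quantify_cells
from .reference import build_aneuploid_reference, build_reference
from .simulate import (
    generate_gene_catalog,
    simulate_atac_clones,
    simulate_controls,
    simulate_family,
)

log = logging.getLogger("hapdose")


@dataclass
class RunConfig:
    """All tunables of a run; defaults are the analysis' standard values."""

    seed: int = 0
    outdir: str | None = None

    # quantification thresholds
    tpm_floor: float = 25.0
    frac_window: tuple[float, float] = (0.3, 0.7)
    nullisomic_bound: float = 0.1
    alpha: float = 0.05
    qc_min_genes_control: int = 6000
    qc_min_genes_mn: int = 4000

    # simulation sizes (single-cell arm)
    n_chromosomes: int = 5
    chrom_length: int = 100_000_000
    genes_per_chromosome: int = 100
    depth: float = 100.0
    n_control: int = 30
    n_families: int = 10

    # ATAC arm
    atac_n_peaks: int = 12_000
    atac_n_control_clones: int = 10
    atac_n_case_clones: int = 12
    atac_suppression_factor: float = 0.5
    atac_interval_mb: int = 10
    atac_n_perm: int = 10_000
    atac_k_background: int = 50
    atac_fc_threshold: float = 0.70
    atac_alpha: float = 1.0e-3

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.atac_alpha < 1:
            raise ValueError(f"atac_alpha must lie in (0, 1), got {self.atac_alpha}")
        lo, hi = self.frac_window
        if not 0 <= lo < hi <= 1:
            raise ValueError(f"invalid allelic window {self.frac_window}")
        if not 0 <= self.nullisomic_bound < 0.5:
            raise ValueError("nullisomic bound must lie in [0, 0.5)")
        if not 0 < self.atac_fc_threshold <= 1:
            raise ValueError("fold-change threshold must lie in (0, 1]")
        if self.tpm_floor < 0 or self.qc_min_genes_control < 0 or self.qc_min_genes_mn < 0:
            raise ValueError("thresholds must be non-negative")
        if self.atac_interval_mb not in (1, 5, 10):
            raise ValueError("atac_interval_mb must be 1, 5 or 10")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def random_scenarios(
    config: RunConfig, rng: np.random.Generator
) -> list[SegregationScenario]:
    """A mixed batch of ground-truth scenarios for a simulated cohort."""
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    out = []
    for i in range(config.n_families):
        pattern = "1:3" if rng.random() < 0.5 else "2:2"
        generation = 1 if rng.random() < 0.5 else 2
        a = float(np.round(rng.uniform(0.0, 0.5), 3))
        split = float(rng.choice([1.0, 0.5])) if generation == 2 else None
        out.append(
            SegregationScenario(
                chrom=str(rng.choice(chroms)),
                mn_haplotype=str(rng.choice(["A", "B"])),
                pattern=pattern,
                generation=generation,
                mn_yield=a,
                split=split,
            )
        )
    return out


def run_sc_pipeline(
    config: RunConfig,
    families: list[Family] | None = None,
    controls=None,
    catalog=None,
) -> dict:
    """Simulate (or consume) a family cohort and run the full inference chain.

    Returns a dict with per-cell QC metrics, chromosome summaries, state
    tables, per-family assignments and yield estimates, and a summary tally
    of defective vs normal MN chromosomes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    if families is None:
        catalog = catalog or generate_gene_catalog(
            config.n_chromosomes, config.chrom_length, config.genes_per_chromosome,
            seed=rng,
        )
        scenarios = random_scenarios(config, rng)
        families = []
        for i, sc in enumerate(scenarios):
            fam, _ = simulate_family(
                catalog, sc, n_control=0, depth=config.depth, seed=rng,
                family_id=f"F{i + 1:03d}",
            )
            families.append(fam)
        controls = simulate_controls(
            catalog, n_control=config.n_control, depth=config.depth, seed=rng
        )
    elif controls is None or catalog is None:
        raise ValueError("supplying families requires controls and a catalog")

    qc_rows, passing_controls = [], []
    for c in controls:
        ok, metrics = qc_filter_cell(
            c, min_genes_control=config.qc_min_genes_control,
            min_genes_mn=config.qc_min_genes_mn,
        )
        qc_rows.append(metrics)
        if ok:
            passing_controls.append(c)
    kept_families = []
    for fam in families:
        all_ok = True
        for c in fam.cells:
            ok, metrics = qc_filter_cell(
                c, min_genes_control=config.qc_min_genes_control,
                min_genes_mn=config.qc_min_genes_mn,
            )
            qc_rows.append(metrics)
            all_ok &= ok
        if all_ok:
            kept_families.append(fam)
    qc = pd.DataFrame(qc_rows)
    log.info(
        "QC: %d/%d controls, %d/%d families pass",
        len(passing_controls), len(controls), len(kept_families), len(families),
    )

    qcfg = QuantConfig(tpm_floor=config.tpm_floor, frac_window=config.frac_window)
    control_summaries = quantify_cells(passing_controls, passing_controls, catalog, qcfg)
    refset = build_reference(control_summaries)
    refset.nullisomic_bound = config.nullisomic_bound

    family_cells = [c for fam in kept_families for c in fam.cells]
    summaries = quantify_cells(family_cells, passing_controls, catalog, qcfg)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # fallback warning is expected pre-harvest
        aneu = build_aneuploid_reference(None, refset,
                                         nullisomic_bound=config.nullisomic_bound)
    states = classify_cells(summaries, refset, aneu, alpha=config.alpha)

    assignments, yields = [], []
    for fam in kept_families:
        ids = [c.cell_id for c in fam.cells]
        fam_states = states[states["cell_id"].isin(ids)].copy()
        fam_states["family_id"] = fam.family_id
        assignment, est = analyze_family(
            fam, fam_states, summaries, refset, alpha=config.alpha
        )
        arow = {
            "family_id": fam.family_id,
            "generation": fam.generation,
            "chrom": assignment.chrom,
            "haplotype": assignment.haplotype,
            "pattern": assignment.pattern,
            "confidence": assignment.confidence,
            "notes": assignment.notes,
        }
        if fam.truth is not None:
            arow.update(
                true_chrom=fam.truth.chrom,
                true_haplotype=fam.truth.mn_haplotype,
                true_pattern=fam.truth.pattern,
                true_a=fam.truth.mn_yield,
            )
        assignments.append(arow)
        if est is not None:
            yields.append(
                {
                    "family_id": fam.family_id,
                    "a_hat": est.a,
                    "basis": est.basis,
                    "classification": est.classification,
                }
            )
    assignments = pd.DataFrame(assignments)
    yields = pd.DataFrame(yields)
    tally = (
        yields["classification"].value_counts().to_dict() if len(yields) else {}
    )
    tally["defective"] = tally.get("reduced", 0) + tally.get("near-silent", 0)

    result = {
        "qc": qc,
        "control_summaries": control_summaries,
        "summaries": summaries,
        "reference": refset,
        "states": states,
        "assignments": assignments,
        "yields": yields,
        "tally": tally,
        "catalog": catalog,
    }
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        qc.to_csv(out / "qc.tsv", sep="\t", index=False)
        summaries.to_csv(out / "summaries.tsv", sep="\t", index=False)
        states.to_csv(out / "states.tsv", sep="\t", index=False)
        assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
        yields.to_csv(out / "yields.tsv", sep="\t", index=False)
        io_mod.write_reference(refset, out / "reference.tsv")
        (out / "tally.json").write_text(json.dumps(tally, indent=2))
        io_mod.write_run_manifest(out, config.config_hash())
    return result


def run_atac_pipeline(config: RunConfig, data: dict | None = None) -> dict:
    """Simulate (or consume) a clone ATAC dataset and run the interval test.

    ``data`` may carry pre-made ``peaks``, ``counts``, ``cn`` (as from
    :func:`hapdose.simulate.simulate_atac_clones`); otherwise a dataset is
    simulated under the config's sizes with one suppressed interval.
    """
    config.validate()
    if data is None:
        data = simulate_atac_clones(
            n_peaks=config.atac_n_peaks,
            n_control_clones=config.atac_n_control_clones,
            n_case_clones=config.atac_n_case_clones,
            suppression_factor=config.atac_suppression_factor,
            seed=config.seed,
        )
    peaks, counts, cn = data["peaks"], data["counts"], data.get("cn")
    control_samples = data.get("truth", {}).get(
        "control_samples",
        [s for s in counts.columns if s.startswith("ctrl")],
    )
    norm = atac_mod.normalize_counts(counts, peaks, cn)
    ctrl_mean = norm[control_samples].mean(axis=1).to_numpy()
    sets = atac_mod.select_background_peaks(
        peaks, ctrl_mean, k=config.atac_k_background, seed=config.seed,
    )
    chrom_lengths = data.get("chrom_lengths") or {
        c: int(peaks.loc[peaks["chrom"] == c, "end"].max())
        for c in peaks["chrom"].unique()
    }
    case_samples = data.get("truth", {}).get(
        "case_samples", [s for s in counts.columns if not s.startswith("ctrl")]
    )
    results = atac_mod.scan_intervals(
        norm, peaks, sets, chrom_lengths, samples=case_samples,
        interval_mb=config.atac_interval_mb, n_perm=config.atac_n_perm,
        seed=config.seed,
    )
    flagged = atac_mod.flag_suppressed_intervals(
        results, fc_threshold=config.atac_fc_threshold, alpha=config.atac_alpha
    )
    out = {"results": results, "flagged": flagged, "normalized": norm,
           "background_sets": sets, "truth": data.get("truth")}
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        flagged.to_csv(outdir / "atac_intervals.tsv", sep="\t", index=False)
        io_mod.write_run_manifest(outdir, config.config_hash())
    return out
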