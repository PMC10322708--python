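"""Synthetic-data generators with known ground truth.

Everything downstream (quantification, reference building, classification,
family inference, the clone ATAC permutation test) is exercised on data from
this module, so the generators encode the statistical structure the analysis
assumes rather than read-level realism:

* gene baseline expression is log-normal and heavy-tailed, truncated so the
  bulk of genes clear the TPM > 25 analysis floor;
* a cell's expected expression of a gene scales linearly with the total
  transcriptional dosage of its chromosome (the dosage-proportionality
  assumption underlying aneuploidy inference from expression);
* haplotype-assigned read counts are binomial around the haplotype's dosage
  share, given a Poisson per-gene informative read total;
* clone ATAC fragment counts are Poisson with log-normal peak baselines whose
  mean correlates with GC content, so GC-matched background selection has
  real structure to match on.

All generators are deterministic given their seed; independent substreams are
spawned from one ``numpy`` SeedSequence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    Cell,
    Family,
    GeneCatalog,
    ROLE_CONTROL,
    ROLE_MN_CELL,
    ROLE_MN_DAUGHTER,
    ROLE_MN_NIECE,
    ROLE_MN_SISTER,
    SegregationScenario,
    other_haplotype,
)

TPM_SCALE = 1.0e6
DEFAULT_BIN_BP = 10_000_000
DISOMIC_DOSAGE = (0.5, 0.5)

# Log-normal baseline for gene mean TPM (log-mean 4, log-s.d. 1), with a lower
# truncation chosen so that at least 80% of genes exceed the TPM > 25 floor.
_TPM_LOG_MEAN = 4.0
_TPM_LOG_SD = 1.0
_TPM_TRUNC = 11.0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_gene_catalog(
    n_chromosomes: int = 5,
    chrom_length: int = 100_000_000,
    genes_per_chromosome: int = 100,
    seed: int | np.random.Generator = 0,
    gene_width: int = 10_000,
    dispersion: float = 0.15,
) -> GeneCatalog:
    """Build a synthetic gene catalog on ``n_chromosomes`` equal chromosomes.

    Gene placement is stratified over 10-Mb bins (every bin receives at least
    ``genes_per_chromosome // n_bins`` genes) so regional binning downstream is
    always informative.  ``dispersion`` is the log-scale s.d. of per-cell
    multiplicative expression noise attached to every gene.
    """
    if n_chromosomes < 2:
        raise ValueError(f"need at least 2 chromosomes, got {n_chromosomes}")
    if genes_per_chromosome < 20:
        raise ValueError(f"need at least 20 genes per chromosome, got {genes_per_chromosome}")
    chrom_length = int(chrom_length)
    if chrom_length <= gene_width:
        raise ValueError("chromosome length must exceed gene width")
    rng = _rng(seed)

    n_bins = max(1, int(np.ceil(chrom_length / DEFAULT_BIN_BP)))
    if genes_per_chromosome < n_bins:
        raise ValueError(
            f"{genes_per_chromosome} genes cannot cover {n_bins} bins of 10 Mb"
        )
    records = []
    for ci in range(n_chromosomes):
        chrom = f"chr{ci + 1}"
        # round-robin allocation of genes to bins guarantees full bin coverage
        bins = np.arange(genes_per_chromosome) % n_bins
        bin_edges = np.linspace(0, chrom_length, n_bins + 1).astype(np.int64)
        for gi, b in enumerate(bins):
            lo, hi = bin_edges[b], bin_edges[b + 1]
            start = int(rng.integers(lo, max(lo + 1, hi - gene_width)))
            records.append((chrom, start, start + gene_width, f"{chrom}_g{gi:04d}"))
    genes = pd.DataFrame(records, columns=["chrom", "start", "end", "gene_id"])

    n = len(genes)
    tpm = rng.lognormal(_TPM_LOG_MEAN, _TPM_LOG_SD, size=n)
    while (low := tpm < _TPM_TRUNC).any():  # truncated log-normal via rejection
        tpm[low] = rng.lognormal(_TPM_LOG_MEAN, _TPM_LOG_SD, size=int(low.sum()))
    genes["mean_tpm"] = tpm
    genes["dispersion"] = float(dispersion)
    lengths = {f"chr{ci + 1}": chrom_length for ci in range(n_chromosomes)}
    return GeneCatalog(genes=genes, chrom_lengths=lengths)


def simulate_cell(
    catalog: GeneCatalog,
    dosage: dict[str, tuple[float, float]] | None = None,
    depth: float = 100.0,
    seed: int | np.random.Generator = 0,
    cell_id: str = "cell",
    role: str = ROLE_CONTROL,
    generation: int = 0,
) -> Cell:
    """Simulate one cell's gene-level table under a per-chromosome dosage map.

    ``dosage`` maps chromosome -> (dose_A, dose_B) in per-homologue yield
    units; the disomic baseline is (0.5, 0.5) and omitted chromosomes default
    to it.  Expected TPM scales linearly with total dosage; haplotype-A read
    counts are Binomial(n_reads, dose_A / total); the TPM column is
    renormalized to sum to 10^6 (so expression is compositional, as TPM is).
    """
    rng = _rng(seed)
    dosage = dict(dosage or {})
    unknown = set(dosage) - set(catalog.chrom_lengths)
    if unknown:
        raise ValueError(f"dosage references unknown chromosome(s): {sorted(unknown)}")
    for chrom, (da, db) in dosage.items():
        if da < 0 or db < 0:
            raise ValueError(f"negative dosage for {chrom}")

    g = catalog.genes
    dose_a = np.full(len(g), DISOMIC_DOSAGE[0])
    dose_b = np.full(len(g), DISOMIC_DOSAGE[1])
    for chrom, (da, db) in dosage.items():
        on = (g["chrom"] == chrom).to_numpy()
        dose_a[on] = da
        dose_b[on] = db
    total = dose_a + dose_b

    noise = np.exp(rng.normal(0.0, g["dispersion"].to_numpy()))
    expr = g["mean_tpm"].to_numpy() * total * noise
    tpm = expr / expr.sum() * TPM_SCALE if expr.sum() > 0 else expr

    n_reads = rng.poisson(depth * total * noise)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = np.where(total > 0, dose_a / np.where(total > 0, total, 1.0), 0.0)
    hap_a = rng.binomial(n_reads, p_a)
    hap_b = n_reads - hap_a

    data = pd.DataFrame(
        {
            "gene_id": g["gene_id"].to_numpy(),
            "tpm": tpm,
            "hapA_count": hap_a,
            "hapB_count": hap_b,
        }
    )
    return Cell(cell_id=cell_id, role=role, generation=generation, data=data)


def scenario_dosages(scenario: SegregationScenario) -> dict[str, dict[str, tuple[float, float]]]:
    """Per-role dosage maps implied by a segregation scenario.

    Returns role -> {chrom: (dose_A, dose_B)} for the affected chromosome only
    (all other chromosomes stay disomic).  Generation-2 daughter roles are
    keyed ``mn_daughter/1`` and ``mn_daughter/2``; nieces ``mn_niece/1|2``.
    """
    c, h, a = scenario.chrom, scenario.mn_haplotype, scenario.mn_yield

    def hap_dose(mn: float, other: float = 0.5) -> tuple[float, float]:
        return (mn, other) if h == "A" else (other, mn)

    if scenario.generation == 1:
        if scenario.pattern == "1:3":
            return {
                ROLE_MN_SISTER: {c: hap_dose(0.0)},
                ROLE_MN_CELL: {c: hap_dose(0.5 + a)},
            }
        return {  # 2:2 - sister disomic, MN chromatid transcribing at a
            ROLE_MN_SISTER: {c: hap_dose(0.5)},
            ROLE_MN_CELL: {c: hap_dose(a)},
        }
    s = scenario.split
    if scenario.pattern == "1:3":
        return {
            f"{ROLE_MN_NIECE}/1": {c: hap_dose(0.0)},
            f"{ROLE_MN_NIECE}/2": {c: hap_dose(0.0)},
            f"{ROLE_MN_DAUGHTER}/1": {c: hap_dose(0.5 + a * s)},
            f"{ROLE_MN_DAUGHTER}/2": {c: hap_dose(0.5 + a * (1 - s))},
        }
    return {
        f"{ROLE_MN_NIECE}/1": {c: hap_dose(0.5)},
        f"{ROLE_MN_NIECE}/2": {c: hap_dose(0.5)},
        f"{ROLE_MN_DAUGHTER}/1": {c: hap_dose(a * s)},
        f"{ROLE_MN_DAUGHTER}/2": {c: hap_dose(a * (1 - s))},
    }


def simulate_family(
    catalog: GeneCatalog,
    scenario: SegregationScenario,
    n_control: int = 30,
    depth: float = 100.0,
    seed: int | np.random.Generator = 0,
    include_nieces: bool = True,
    family_id: str = "F1",
) -> tuple[Family, list[Cell]]:
    """Simulate one micronucleation family plus a control population."""
    rng = _rng(seed)
    dosages = scenario_dosages(scenario)
    cells: list[Cell] = []
    for role_key, dmap in dosages.items():
        role = role_key.split("/")[0]
        if role == ROLE_MN_NIECE and not include_nieces:
            continue
        cid = f"{family_id}_{role_key.replace('/', '')}"
        cells.append(
            simulate_cell(
                catalog, dmap, depth=depth, seed=rng, cell_id=cid, role=role,
                generation=scenario.generation,
            )
        )
    family = Family(
        family_id=family_id, generation=scenario.generation, cells=cells, truth=scenario
    )
    controls = [
        simulate_cell(
            catalog, None, depth=depth, seed=rng, cell_id=f"ctrl_{i:03d}",
            role=ROLE_CONTROL,
        )
        for i in range(n_control)
    ]
    return family, controls


def simulate_controls(
    catalog: GeneCatalog,
    n_control: int = 30,
    depth: float = 100.0,
    seed: int | np.random.Generator = 0,
) -> list[Cell]:
    """Simulate a disomic control-cell population."""
    rng = _rng(seed)
    return [
        simulate_cell(
            catalog, None, depth=depth, seed=rng, cell_id=f"ctrl_{i:03d}",
            role=ROLE_CONTROL,
        )
        for i in range(n_control)
    ]


def simulate_atac_clones(
    n_peaks: int = 12_000,
    n_control_clones: int = 10,
    n_case_clones: int = 12,
    suppressed_interval: tuple[str, int, int] = ("chr4", 30_000_000, 40_000_000),
    suppression_factor: float = 0.5,
    seed: int | np.random.Generator = 0,
    chrom_lengths: dict[str, int] | None = None,
    peak_width: int = 300,
    base_log_mean: float = 4.0,
    base_log_sd: float = 0.6,
    gc_effect: float = 1.0,
    noise_sd: float = 0.15,
    cn_events: list[tuple[str, str, int, int, int]] | None = None,
    suppressed_samples: list[str] | None = None,
) -> dict:
    """Simulate a clone ATAC experiment with one suppressed interval.

    Returns a dict with ``peaks`` (chrom, start, end, peak_id, gc),
    ``counts`` (peaks x samples fragment counts), ``cn`` (250-kb copy-number
    track per sample, long format) and ``truth``.  Case-clone counts inside
    ``suppressed_interval`` are multiplied by ``suppression_factor`` before
    Poisson noise; ``suppressed_samples`` restricts the injection to a subset
    of case clones (default: all).  ``cn_events`` injects copy-number changes
    as (sample, chrom, start, end, copy_number).
    """
    if not 0.0 < suppression_factor <= 1.0:
        raise ValueError("suppression_factor must lie in (0, 1]")
    rng = _rng(seed)
    if chrom_lengths is None:
        chrom_lengths = {f"chr{i + 1}": 100_000_000 for i in range(5)}
    chrom_names = list(chrom_lengths)
    s_chrom, s_start, s_end = suppressed_interval
    if s_chrom not in chrom_lengths or s_end > chrom_lengths[s_chrom] or s_start < 0:
        raise ValueError(f"suppressed interval {suppressed_interval} outside simulated genome")

    total_bp = float(sum(chrom_lengths.values()))
    counts_per_chrom = rng.multinomial(
        n_peaks, [chrom_lengths[c] / total_bp for c in chrom_names]
    )
    rows = []
    for chrom, k in zip(chrom_names, counts_per_chrom):
        starts = np.sort(rng.integers(0, chrom_lengths[chrom] - peak_width, size=k))
        for st in starts:
            rows.append((chrom, int(st), int(st) + peak_width))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    peaks["peak_id"] = [f"peak_{i:06d}" for i in range(len(peaks))]

    gc = np.clip(rng.normal(0.5, 0.12, size=len(peaks)), 0.2, 0.8)
    peaks["gc"] = gc
    # accessibility correlates with GC so background matching is non-trivial
    base = np.exp(rng.normal(base_log_mean + gc_effect * (gc - 0.5), base_log_sd))

    mid = (peaks["start"] + peaks["end"]).to_numpy() // 2
    in_interval = (
        (peaks["chrom"] == s_chrom).to_numpy() & (mid >= s_start) & (mid < s_end)
    )
    width_mb = (s_end - s_start) / 1.0e6
    if in_interval.sum() < 10 * width_mb:
        raise ValueError(
            f"suppressed interval holds {int(in_interval.sum())} peaks; "
            f"needs >= 10 per Mb ({int(10 * width_mb)})"
        )

    samples = [f"ctrl_clone_{i + 1:02d}" for i in range(n_control_clones)] + [
        f"case_clone_{i + 1:02d}" for i in range(n_case_clones)
    ]
    case_set = set(samples[n_control_clones:])
    if suppressed_samples is None:
        suppressed = case_set
    else:
        unknown = set(suppressed_samples) - case_set
        if unknown:
            raise ValueError(f"suppressed_samples not case clones: {sorted(unknown)}")
        suppressed = set(suppressed_samples)

    counts = {}
    for s in samples:
        lib = np.exp(rng.normal(0.0, 0.1))
        mean = base * lib
        if s in suppressed:
            mean = np.where(in_interval, mean * suppression_factor, mean)
        counts[s] = rng.poisson(mean * np.exp(rng.normal(0.0, noise_sd, size=len(mean))))
    counts = pd.DataFrame(counts, index=peaks["peak_id"].to_numpy())

    cn_bin = 250_000
    cn_rows = []
    for chrom in chrom_names:
        edges = np.arange(0, chrom_lengths[chrom], cn_bin)
        for st in edges:
            en = min(st + cn_bin, chrom_lengths[chrom])
            cn_rows.append((chrom, int(st), int(en)))
    cn_base = pd.DataFrame(cn_rows, columns=["chrom", "start", "end"])
    cn_frames = []
    for s in samples:
        t = cn_base.copy()
        t["sample"] = s
        t["copy_number"] = 2
        cn_frames.append(t)
    cn = pd.concat(cn_frames, ignore_index=True)
    for sample, chrom, st, en, value in cn_events or []:
        sel = (
            (cn["sample"] == sample)
            & (cn["chrom"] == chrom)
            & (cn["start"] < en)
            & (cn["end"] > st)
        )
        cn.loc[sel, "copy_number"] = value
    truth = {
        "interval": suppressed_interval,
        "suppression_factor": suppression_factor,
        "suppressed_samples": sorted(suppressed),
        "control_samples": samples[:n_control_clones],
        "case_samples": samples[n_control_clones:],
        "n_peaks_in_interval": int(in_interval.sum()),
    }
    return {"peaks": peaks, "counts": counts, "cn": cn, "truth": truth}
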