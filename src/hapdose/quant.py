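"""Expression quantification: QC, gene filters, rescaling, weighted binning.

The chain per analysis cell is: QC on informative-read coverage; gene
retention from control-cell statistics (expression floor and allelic-balance
window); per-gene TPM ratio against the control mean; a robust (median-based)
global rescaling so transcriptome-wide shifts from a few dominant genes do not
masquerade as dosage changes; then precision-weighted aggregation of ratios
and allele fractions into 10-Mb bins, chromosome arms, or whole chromosomes;
finally the normalized haplotype-specific transcription (yield)
y_h = (mean TPM ratio) x (mean fraction of haplotype h), whose disomic
expectation is 0.5 per homologue.

Weighting: TPM ratios are aggregated with inverse-variance weights
w_g = 1 / (var_g + eps) estimated from control cells, winsorized at the 95th
percentile so no single quiet gene dominates; allele fractions are aggregated
with per-cell informative-read counts (similarly winsorized), since a gene's
allelic precision is binomial in its read depth.  Both strategies are
pluggable through the function parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Cell, GeneCatalog, ROLE_CONTROL

BIN_BP = 10_000_000

QC_MIN_GENES_CONTROL = 6000
QC_MIN_GENES_MN = 4000
QC_MIN_READS = 5


# ---------------------------------------------------------------- QC


def qc_filter_cell(
    cell: Cell,
    role: str | None = None,
    min_genes_control: int = QC_MIN_GENES_CONTROL,
    min_genes_mn: int = QC_MIN_GENES_MN,
    min_reads: int = QC_MIN_READS,
) -> tuple[bool, dict]:
    """Pass/fail a cell on the number of genes with >= ``min_reads`` reads.

    Control cells require ``min_genes_control`` qualifying genes;
    micronucleation-related roles require ``min_genes_mn``.  The boundary is
    inclusive (a cell with exactly the floor passes).
    """
    role = role if role is not None else cell.role
    for col in ("hapA_count", "hapB_count"):
        if col not in cell.data.columns:
            raise ValueError(
                f"cell {cell.cell_id} lacks column {col!r}; provide haplotype "
                "read counts (or a depth proxy) to run QC"
            )
    n_qual = int((cell.reads >= min_reads).sum())
    floor = min_genes_control if role == ROLE_CONTROL else min_genes_mn
    metrics = {
        "cell_id": cell.cell_id,
        "role": role,
        "n_genes_covered": n_qual,
        "min_required": floor,
        "passed": n_qual >= floor,
    }
    return metrics["passed"], metrics


# ---------------------------------------------------------------- gene filters


def control_gene_stats(controls: list[Cell], min_controls: int = 5) -> pd.DataFrame:
    """Per-gene control statistics: mean TPM, pooled allele fraction, reads.

    The allele fraction is read-pooled across control cells (sum of A reads
    over sum of informative reads), which weights each cell by its evidence.
    """
    if len(controls) < min_controls:
        raise ValueError(f"need >= {min_controls} control cells, got {len(controls)}")
    gene_ids = controls[0].data["gene_id"]
    tpm = np.column_stack([c.data["tpm"].to_numpy() for c in controls])
    hap_a = np.column_stack([c.data["hapA_count"].to_numpy() for c in controls])
    hap_b = np.column_stack([c.data["hapB_count"].to_numpy() for c in controls])
    tot = hap_a.sum(axis=1) + hap_b.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_a = np.where(tot > 0, hap_a.sum(axis=1) / np.where(tot > 0, tot, 1), np.nan)
    return pd.DataFrame(
        {
            "gene_id": gene_ids.to_numpy(),
            "mean_tpm": tpm.mean(axis=1),
            "frac_A": frac_a,
            "total_reads": tot,
        }
    ).set_index("gene_id")


def gene_filters(
    controls: list[Cell],
    catalog: GeneCatalog | None = None,
    tpm_floor: float = 25.0,
    frac_window: tuple[float, float] = (0.3, 0.7),
    x_chroms: tuple[str, ...] = (),
    trisomy_regions: tuple[tuple[str, int, int, str], ...] = (),
    trisomy_window: tuple[float, float] = (0.2, 0.4),
    min_controls: int = 5,
) -> pd.Index:
    """Retain genes with control mean TPM > floor and balanced allelic output.

    Exceptions: genes on ``x_chroms`` are retained regardless of allelic
    balance (one homologue may be epigenetically inactive); genes inside a
    declared clonal-trisomy region (chrom, start, end, single_copy_hap) use
    the shifted ``trisomy_window`` for the single-copy haplotype's fraction.
    Raises if nothing survives.
    """
    stats = control_gene_stats(controls, min_controls=min_controls)
    expressed = stats["mean_tpm"] > tpm_floor

    lo, hi = frac_window
    balanced = (stats["frac_A"] >= lo) & (stats["frac_A"] <= hi)
    balanced = balanced.fillna(False)

    if (x_chroms or trisomy_regions) and catalog is None:
        raise ValueError("catalog required to resolve X-linked / trisomy-region genes")
    if catalog is not None:
        pos = catalog.genes.set_index("gene_id").loc[stats.index]
        mid = (pos["start"] + pos["end"]) // 2
        if x_chroms:
            balanced |= pos["chrom"].isin(x_chroms)
        for chrom, start, end, single_hap in trisomy_regions:
            in_region = (pos["chrom"] == chrom) & (mid >= start) & (mid < end)
            tlo, thi = trisomy_window
            if single_hap == "A":
                win = (stats["frac_A"] >= tlo) & (stats["frac_A"] <= thi)
            else:
                win = (stats["frac_A"] >= 1 - thi) & (stats["frac_A"] <= 1 - tlo)
            balanced = balanced.where(~in_region, win.fillna(False))

    retained = stats.index[expressed & balanced]
    if len(retained) == 0:
        raise ValueError("no genes survive the expression and allelic-balance filters")
    return retained


# ---------------------------------------------------------------- rescaling


def rescale_global(
    ratios: pd.Series,
    min_genes: int = 50,
    groups: pd.Series | None = None,
    weights: pd.Series | None = None,
) -> tuple[pd.Series, float]:
    """Rescale one cell's TPM ratios so the median ratio equals 1.

    Without ``groups`` the factor centres the plain retained-gene median,
    which is robust to the handful of highly transcribed genes whose up/down
    swings would otherwise shift every ratio in the cell.  When ``groups``
    (chromosome per gene) is supplied - the form the per-cell pipeline uses -
    the factor centres the *median across chromosomes of the chromosome-level
    (optionally weighted) mean ratio*.  This keeps the robustness (an outlier
    gene only perturbs its own chromosome's mean, which the across-chromosome
    median discards) while fixing two biases of the gene median on a compact
    genome: TPM is compositional, so an aneuploid chromosome drags the plain
    gene median with it when it holds a big fraction of genes; and centring a
    right-skewed ratio distribution by its median leaves the downstream
    *weighted means* ~exp(sigma^2/2) above 1.  Centring the statistic that is
    actually reported (the chromosome-level weighted mean) removes both.
    Returns the scaled ratios and the multiplicative factor applied.
    """
    vals = ratios.dropna()
    if len(vals) < min_genes:
        raise ValueError(f"need >= {min_genes} retained genes to rescale, got {len(vals)}")
    if groups is None:
        med = float(np.median(vals))
    else:
        df = pd.DataFrame({"value": vals, "group": groups.reindex(vals.index)})
        df["weight"] = (
            weights.reindex(vals.index) if weights is not None else 1.0
        )
        chrom_means = df.groupby("group").apply(
            lambda s: np.average(s["value"], weights=s["weight"]),
            include_groups=False,
        )
        # two-pass: drop chromosomes that deviate > 20% from the median of
        # chromosome means (aneuploid or outlier-dominated), then centre on
        # the unbiased mean of the remaining euploid chromosomes
        centre = float(np.median(chrom_means))
        keep = (chrom_means / centre - 1.0).abs() <= 0.2
        med = float(chrom_means[keep].mean()) if keep.any() else centre
    if not np.isfinite(med) or med <= 0:
        raise ValueError("median TPM ratio is zero or undefined; cannot rescale")
    factor = 1.0 / med
    return ratios * factor, factor


# ---------------------------------------------------------------- weights


def compute_gene_weights(
    controls: list[Cell],
    retained: pd.Index,
    eps: float = 0.01,
    winsor_quantile: float = 0.95,
) -> pd.Series:
    """Inverse-variance weights for TPM-ratio aggregation.

    Per-gene variance of the rescaled TPM ratio across control cells; weights
    w = 1/(var + eps), winsorized at ``winsor_quantile`` so near-deterministic
    genes cannot dominate a bin.
    """
    stats = control_gene_stats(controls)
    mean_tpm = stats["mean_tpm"]
    ratios = []
    for c in controls:
        r = pd.Series(c.data["tpm"].to_numpy(), index=c.data["gene_id"].to_numpy())
        r = (r / mean_tpm).loc[retained]
        r, _ = rescale_global(r, min_genes=min(50, len(retained)))
        ratios.append(r)
    mat = pd.concat(ratios, axis=1)
    var = mat.var(axis=1, ddof=1)
    w = 1.0 / (var + eps)
    cap = w.quantile(winsor_quantile)
    return w.clip(upper=cap)


def winsorize_weights(w: pd.Series, quantile: float = 0.95) -> pd.Series:
    return w.clip(upper=w.quantile(quantile))


# ---------------------------------------------------------------- aggregation


def weighted_aggregate(
    values: pd.Series, weights: pd.Series, groups: pd.Series
) -> pd.DataFrame:
    """Weighted mean of ``values`` within ``groups``.

    All three inputs must align in length.  NaN values are dropped before
    averaging; groups with no contributing genes are absent from the output
    (never reported as zero).
    """
    if not (len(values) == len(weights) == len(groups)):
        raise ValueError(
            f"length mismatch: values={len(values)}, weights={len(weights)}, "
            f"groups={len(groups)}"
        )
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float),
         "weight": np.asarray(weights, dtype=float),
         "group": np.asarray(groups)}
    ).dropna(subset=["value"])
    df = df[df["weight"] > 0]
    if df.empty:
        return pd.DataFrame(columns=["group", "mean", "n_genes"])
    g = df.groupby("group", sort=True)
    out = pd.DataFrame(
        {
            "mean": g.apply(
                lambda s: np.average(s["value"], weights=s["weight"]),
                include_groups=False,
            ),
            "n_genes": g.size(),
        }
    ).reset_index()
    return out


def assign_groups(
    catalog: GeneCatalog,
    gene_ids: pd.Index,
    by: str = "chromosome",
    centromeres: dict[str, int] | None = None,
) -> pd.Series:
    """Group label per gene: 'chromosome', 10-Mb 'bin', or 'arm'.

    Genes are assigned by midpoint.  Bins are 0-based half-open
    [k*10Mb, (k+1)*10Mb).  Arm grouping needs centromere positions; synthetic
    genomes default to the chromosome midpoint.
    """
    pos = catalog.genes.set_index("gene_id").loc[gene_ids]
    mid = (pos["start"] + pos["end"]) // 2
    if by == "chromosome":
        return pos["chrom"].rename("group")
    if by == "bin":
        idx = (mid // BIN_BP).astype(int)
        return (pos["chrom"] + ":" + idx.astype(str)).rename("group")
    if by == "arm":
        if centromeres is None:
            centromeres = {c: length // 2 for c, length in catalog.chrom_lengths.items()}
        arm = np.where(mid < pos["chrom"].map(centromeres), "p", "q")
        return (pos["chrom"] + arm).rename("group")
    raise ValueError(f"unknown grouping {by!r}")


# ---------------------------------------------------------------- per-cell summary


@dataclass
class QuantConfig:
    """Knobs of the quantification chain (defaults are the analysis values)."""

    tpm_floor: float = 25.0
    frac_window: tuple[float, float] = (0.3, 0.7)
    x_chroms: tuple[str, ...] = ()
    trisomy_regions: tuple[tuple[str, int, int, str], ...] = ()
    weight_eps: float = 0.01
    winsor_quantile: float = 0.95
    min_rescale_genes: int = 50
    #: per-chromosome display scaling of yields (e.g. 0.6 for X); affects
    #: reported yields uniformly for cells and references, never the z-tests.
    yield_scaling: dict[str, float] = field(default_factory=dict)


def summarize_cell(
    cell: Cell,
    control_stats: pd.DataFrame,
    gene_weights: pd.Series,
    catalog: GeneCatalog,
    retained: pd.Index,
    config: QuantConfig | None = None,
    by: str = "chromosome",
    centromeres: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Summaries per chromosome (or bin/arm) for one cell.

    Columns: cell_id, group, tpm_ratio, frac_A, yield_A, yield_B, n_genes,
    scale_factor.  yield_A + yield_B equals tpm_ratio times the group's
    display scaling (identically 1 by default).
    """
    config = config or QuantConfig()
    tpm = pd.Series(cell.data["tpm"].to_numpy(), index=cell.data["gene_id"].to_numpy())
    ratios = (tpm / control_stats["mean_tpm"]).loc[retained]
    chrom_groups = assign_groups(catalog, retained, by="chromosome")
    ratios, factor = rescale_global(
        ratios, min_genes=config.min_rescale_genes, groups=chrom_groups,
        weights=gene_weights.loc[retained],
    )

    hap_a = pd.Series(
        cell.data["hapA_count"].to_numpy(), index=cell.data["gene_id"].to_numpy()
    ).loc[retained]
    reads = pd.Series(
        cell.reads.to_numpy(), index=cell.data["gene_id"].to_numpy()
    ).loc[retained]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (hap_a / reads).where(reads > 0)

    groups = assign_groups(catalog, retained, by=by, centromeres=centromeres)
    w_ratio = gene_weights.loc[retained]
    w_frac = winsorize_weights(reads.astype(float), config.winsor_quantile)

    agg_r = weighted_aggregate(ratios, w_ratio, groups).rename(columns={"mean": "tpm_ratio"})
    agg_f = weighted_aggregate(frac, w_frac, groups).rename(columns={"mean": "frac_A"})
    out = agg_r.merge(agg_f[["group", "frac_A"]], on="group", how="left")

    chrom_of = out["group"].str.split(":").str[0].str.replace(r"[pq]$", "", regex=True)
    scale = chrom_of.map(lambda c: config.yield_scaling.get(c, 1.0))
    out["yield_A"] = out["tpm_ratio"] * out["frac_A"] * scale
    out["yield_B"] = out["tpm_ratio"] * (1.0 - out["frac_A"]) * scale
    out.insert(0, "cell_id", cell.cell_id)
    out["scale_factor"] = factor
    return out


def quantify_cells(
    cells: list[Cell],
    controls: list[Cell],
    catalog: GeneCatalog,
    config: QuantConfig | None = None,
    by: str = "chromosome",
) -> pd.DataFrame:
    """Run the full quantification chain for a batch of cells.

    Control statistics, gene retention and aggregation weights are computed
    once from ``controls`` and shared by every analysis cell.
    """
    config = config or QuantConfig()
    retained = gene_filters(
        controls,
        catalog=catalog if (config.x_chroms or config.trisomy_regions) else None,
        tpm_floor=config.tpm_floor,
        frac_window=config.frac_window,
        x_chroms=config.x_chroms,
        trisomy_regions=config.trisomy_regions,
    )
    stats = control_gene_stats(controls)
    weights = compute_gene_weights(
        controls, retained, eps=config.weight_eps,
        winsor_quantile=config.winsor_quantile,
    )
    frames = [
        summarize_cell(c, stats, weights, catalog, retained, config=config, by=by)
        for c in cells
    ]
    return pd.concat(frames, ignore_index=True)


def homologue_yields_long(summaries: pd.DataFrame) -> pd.DataFrame:
    """Reshape wide summaries to (cell_id, group, haplotype, yield)."""
    a = summaries[["cell_id", "group", "yield_A"]].rename(columns={"yield_A": "yield"})
    a["haplotype"] = "A"
    b = summaries[["cell_id", "group", "yield_B"]].rename(columns={"yield_B": "yield"})
    b["haplotype"] = "B"
    return pd.concat([a, b], ignore_index=True)[
        ["cell_id", "group", "haplotype", "yield"]
    ]
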