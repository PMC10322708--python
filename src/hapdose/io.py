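"""TSV/BED readers and writers for every table the package consumes or emits.

All genomic coordinates are 0-based half-open.  Formats:

* gene catalog: BED-like TSV (chrom, start, end, gene_id, mean_tpm[, dispersion])
* cell table: TSV (gene_id, tpm, hapA_count, hapB_count)
* family manifest: TSV (cell_id, family_id, role, generation, path)
* peaks: BED + gc column (chrom, start, end, peak_id, gc)
* counts: TSV, peak_id index x sample columns
* copy-number track: TSV (chrom, start, end, sample, copy_number)
* reference: TSV (group, haplotype, mu, sigma, n, n_excluded, excluded_cells)
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .core import Cell, Family, GeneCatalog
from .reference import ReferenceSet


def write_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    path = Path(path)
    header = "#chrom_lengths=" + json.dumps(catalog.chrom_lengths)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        catalog.genes.to_csv(fh, sep="\t", index=False)


def read_catalog(path: str | Path) -> GeneCatalog:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        lengths = json.loads(first.split("=", 1)[1]) if first.startswith("#") else None
        genes = pd.read_csv(fh, sep="\t")
    if lengths is None:
        lengths = genes.groupby("chrom")["end"].max().astype(int).to_dict()
    if "dispersion" not in genes.columns:
        genes["dispersion"] = 0.15
    return GeneCatalog(genes=genes, chrom_lengths={k: int(v) for k, v in lengths.items()})


def write_cell(cell: Cell, path: str | Path) -> None:
    cell.data.to_csv(path, sep="\t", index=False)


def read_cell(path: str | Path, cell_id: str, role: str, generation: int = 0) -> Cell:
    data = pd.read_csv(path, sep="\t")
    return Cell(cell_id=cell_id, role=role, generation=generation, data=data)


def write_family(family: Family, controls: list[Cell], outdir: str | Path) -> Path:
    """Write a family's cells + controls and a manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cell in list(family.cells) + list(controls):
        fname = f"{cell.cell_id}.tsv"
        write_cell(cell, outdir / fname)
        fam = family.family_id if cell in family.cells else ""
        rows.append((cell.cell_id, fam, cell.role, cell.generation, fname))
    manifest = pd.DataFrame(
        rows, columns=["cell_id", "family_id", "role", "generation", "path"]
    )
    mpath = outdir / "manifest.tsv"
    manifest.to_csv(mpath, sep="\t", index=False)
    return mpath


def read_manifest(path: str | Path) -> tuple[list[Family], list[Cell]]:
    """Load families and control cells from a manifest TSV."""
    path = Path(path)
    manifest = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"cell_id", "family_id", "role", "generation", "path"}
    if missing := required - set(manifest.columns):
        raise ValueError(f"malformed manifest: missing columns {sorted(missing)}")
    bad = manifest[manifest["cell_id"] == ""]
    if len(bad):
        raise ValueError(f"malformed manifest rows (empty cell_id): {bad.index.tolist()}")
    controls: list[Cell] = []
    fam_cells: dict[str, list[Cell]] = {}
    for r in manifest.itertuples():
        cell = read_cell(path.parent / r.path, r.cell_id, r.role, int(r.generation))
        if r.family_id:
            fam_cells.setdefault(str(r.family_id), []).append(cell)
        else:
            controls.append(cell)
    families = [
        Family(family_id=fid, generation=max(c.generation for c in cells), cells=cells)
        for fid, cells in fam_cells.items()
    ]
    return families, controls


def write_reference(refset: ReferenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#nullisomic_bound={refset.nullisomic_bound}\n")
        refset.homologue.to_csv(fh, sep="\t", index=False)
        fh.write("#total\n")
        refset.total.to_csv(fh, sep="\t", index=False)


def write_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[["chrom", "start", "end", "peak_id", "gc"]].to_csv(
        path, sep="\t", index=False
    )


def read_peaks(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="peak_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="peak_id")


def write_cn(cn: pd.DataFrame, path: str | Path) -> None:
    cn.to_csv(path, sep="\t", index=False)


def read_cn(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def write_run_manifest(outdir: str | Path, config_hash: str) -> Path:
    """Hash every emitted file so reruns can be verified byte-identical."""
    outdir = Path(outdir)
    entries = []
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "run_manifest.json":
            entries.append({"path": str(p.relative_to(outdir)), "sha256": file_sha256(p)})
    mpath = outdir / "run_manifest.json"
    mpath.write_text(
        json.dumps({"config_hash": config_hash, "files": entries}, indent=2)
    )
    return mpath
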