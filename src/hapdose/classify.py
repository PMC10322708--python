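"""Transcriptional copy-number state classification per homologue.

Each homologue's normalized transcription yield y is compared by two-tailed
z-tests (reference s.d. treated as known) against the one-copy normal
reference and the duplicated-homologue reference, with Bonferroni correction
over all homologues tested in the cell.  The decision cascade:

1. y below the nullisomic bound (default 0.1) -> "0"; no p-value is computed
   because a truly absent haplotype should yield exactly zero and residual
   signal reflects technical error of unknown distribution.
2. consistent with one normal copy (corrected p >= alpha) -> "1".
3. otherwise consistent with a duplicated homologue -> "2".
4. rejected by both -> intermediate "1-" / "1+", signed by which side of the
   nearer reference mean the yield falls; yields beyond the duplicated range
   keep the maximal label "2" so the label order 0 < 1- < 1 < 1+ < 2 is
   monotone in y.

If both tests accept (overlapping references), the label with the smaller
standardized deviation wins.
"""

from __future__ import annotations

import pandas as pd

from .reference import AneuploidReference, ReferenceSet
from .stats import bonferroni, z_test_two_tailed

ALPHA = 0.05


def classify_homologue(
    y: float,
    mono_mu: float,
    mono_sigma: float,
    di_mu: float,
    di_sigma: float,
    n_tests: int,
    alpha: float = ALPHA,
    nullisomic_bound: float = 0.1,
) -> tuple[str, float, float]:
    """Label one homologue's yield; returns (label, p_mono, p_di) corrected."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    p_mono = bonferroni(z_test_two_tailed(y, mono_mu, mono_sigma), n_tests)
    p_di = bonferroni(z_test_two_tailed(y, di_mu, di_sigma), n_tests)
    if y < nullisomic_bound:
        return "0", p_mono, p_di
    ok_mono = p_mono >= alpha
    ok_di = p_di >= alpha
    if ok_mono and ok_di:
        z_m = abs(y - mono_mu) / mono_sigma
        z_d = abs(y - di_mu) / di_sigma
        return ("1" if z_m <= z_d else "2"), p_mono, p_di
    if ok_mono:
        return "1", p_mono, p_di
    if ok_di:
        return "2", p_mono, p_di
    # rejected by both integer states: intermediate, or beyond the top state
    if y >= di_mu:
        return "2", p_mono, p_di
    nearer_mu = mono_mu if abs(y - mono_mu) <= abs(y - di_mu) else di_mu
    if nearer_mu == mono_mu:
        return ("1+" if y > mono_mu else "1-"), p_mono, p_di
    return "1+", p_mono, p_di


def classify_cell(
    cell_summary: pd.DataFrame,
    refset: ReferenceSet,
    aneuploid: AneuploidReference,
    alpha: float = ALPHA,
    n_tests: int | None = None,
    duplicated_groups: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Classify every homologue of one cell.

    ``cell_summary`` is the wide per-group quantification of a single cell.
    The Bonferroni family defaults to the number of homologues tested in the
    cell.  Groups in ``duplicated_groups`` (clonally duplicated segments) are
    only assessed against the duplicated-homologue reference.  Non-"1"
    homologues are flagged as candidate aberrations.
    """
    from .quant import homologue_yields_long

    long = homologue_yields_long(cell_summary).dropna(subset=["yield"])
    long = long.rename(columns={"yield": "y"})
    if n_tests is None:
        n_tests = len(long)
    rows = []
    for r in long.itertuples():
        mono_mu, mono_sigma = refset.lookup(r.group, r.haplotype)
        di_mu, di_sigma = aneuploid.trisomic_mu, aneuploid.trisomic_sigma
        if r.group in duplicated_groups:
            p_di = bonferroni(z_test_two_tailed(r.y, di_mu, di_sigma), n_tests)
            label = "2" if p_di >= alpha else "1+"
            p_mono = float("nan")
        else:
            label, p_mono, p_di = classify_homologue(
                r.y,
                mono_mu,
                mono_sigma,
                di_mu,
                di_sigma,
                n_tests,
                alpha=alpha,
                nullisomic_bound=refset.nullisomic_bound,
            )
        rows.append(
            {
                "cell_id": r.cell_id,
                "group": r.group,
                "haplotype": r.haplotype,
                "yield": r.y,
                "label": label,
                "p_mono": p_mono,
                "p_di": p_di,
                "flagged": label != "1",
            }
        )
    return pd.DataFrame(rows)


def classify_cells(
    summaries: pd.DataFrame,
    refset: ReferenceSet,
    aneuploid: AneuploidReference,
    alpha: float = ALPHA,
    duplicated_groups: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Classify all homologues of all cells in a batch of summaries."""
    frames = [
        classify_cell(
            sub, refset, aneuploid, alpha=alpha, duplicated_groups=duplicated_groups
        )
        for _, sub in summaries.groupby("cell_id", sort=False)
    ]
    return pd.concat(frames, ignore_index=True)
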