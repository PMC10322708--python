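"""Reference distributions of normal and aneuploid transcription.

The per-homologue reference is the empirical mean and s.d. of normalized
haplotype-specific transcription (yield) across control cells, fitted
separately for every (chromosome-or-arm, haplotype).  Chromosomes that are
karyotypically unstable in the cell line can be designated for an automated
two-pass outlier screen: control cells whose yield deviates by more than
``outlier_sd`` standard deviations in the first pass are dropped and the
reference refitted (this replaces a manual per-cell review with a
reproducible rule).

Aneuploid references calibrate what a duplicated homologue (trisomy) or a
lost homologue (monosomy) normally transcribes.  Bona fide events harvested
from families must satisfy three criteria before they contribute: a
proportional chromosome-wide TPM-ratio shift (to ~1.5 for trisomy, ~0.5 for
monosomy), allele fractions matching the DNA dosage (2/3 or 1/3; ~0 or ~1
for monosomy), and sibling support (the event is shared by siblings or
mirrored by a reciprocal loss/gain in a sibling), which acts as a biological
replicate.  When no event qualifies, the duplicated-homologue reference falls
back to the distribution of *total* disomic transcription in controls (the
two copies of a duplicated homologue should transcribe like the two
homologues of a disomic chromosome).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .quant import homologue_yields_long

NULLISOMIC_BOUND = 0.1


@dataclass
class ReferenceSet:
    """Per-homologue and per-chromosome-total normal transcription references.

    ``homologue``: DataFrame (group, haplotype, mu, sigma, n, n_excluded,
    excluded_cells).  ``total``: DataFrame (group, mu, sigma, n) of the
    chromosome-wide TPM ratio (= yield_A + yield_B).
    """

    homologue: pd.DataFrame
    total: pd.DataFrame
    nullisomic_bound: float = NULLISOMIC_BOUND

    def lookup(self, group: str, haplotype: str) -> tuple[float, float]:
        sel = self.homologue[
            (self.homologue["group"] == group)
            & (self.homologue["haplotype"] == haplotype)
        ]
        if sel.empty:
            raise KeyError(f"no reference for homologue ({group}, {haplotype})")
        row = sel.iloc[0]
        return float(row["mu"]), float(row["sigma"])

    def lookup_total(self, group: str) -> tuple[float, float]:
        sel = self.total[self.total["group"] == group]
        if sel.empty:
            raise KeyError(f"no total-transcription reference for {group}")
        row = sel.iloc[0]
        return float(row["mu"]), float(row["sigma"])


def build_reference(
    control_summaries: pd.DataFrame,
    min_controls: int = 5,
    unstable_groups: tuple[str, ...] = (),
    outlier_sd: float = 3.0,
) -> ReferenceSet:
    """Fit normal-transcription references from control-cell summaries.

    ``control_summaries`` is the wide per-cell output of
    :func:`hapdose.quant.quantify_cells` on control cells.  Display scalings
    (X, clonal trisomy) are already baked into the yields there, so references
    and observations stay on one scale and z-scores are unaffected.
    """
    n_cells = control_summaries["cell_id"].nunique()
    if n_cells < min_controls:
        raise ValueError(f"need >= {min_controls} control cells, got {n_cells}")

    long = homologue_yields_long(control_summaries)
    # chromosome-level outlier screen for designated unstable chromosomes: a
    # control that deviates > outlier_sd s.d. on either homologue is dropped
    # from that chromosome's reference (both homologues)
    excluded_per_group: dict[str, list[str]] = {}
    for group in unstable_groups:
        dropped: set[str] = set()
        for hap, sub in long[long["group"] == group].groupby("haplotype"):
            y = sub.set_index("cell_id")["yield"].dropna()
            if len(y) < min_controls:
                continue
            mu0, sd0 = y.mean(), y.std(ddof=1)
            dropped |= set(y.index[(y - mu0).abs() > outlier_sd * sd0])
        excluded_per_group[group] = sorted(dropped)
    rows = []
    for (group, hap), sub in long.groupby(["group", "haplotype"], sort=True):
        y = sub.set_index("cell_id")["yield"].dropna()
        excluded = excluded_per_group.get(group, [])
        if excluded and len(y) - len(excluded) >= min_controls:
            y = y[~y.index.isin(excluded)]
        if len(y) < min_controls:
            raise ValueError(
                f"homologue ({group}, {hap}) has {len(y)} usable controls (< {min_controls})"
            )
        rows.append(
            {
                "group": group,
                "haplotype": hap,
                "mu": float(y.mean()),
                "sigma": float(y.std(ddof=1)),
                "n": int(len(y)),
                "n_excluded": len(excluded),
                "excluded_cells": ",".join(excluded),
            }
        )
    homologue = pd.DataFrame(rows)
    if (homologue["sigma"] <= 0).any():
        raise ValueError("degenerate reference: zero variance across controls")

    tot_rows = []
    for group, sub in control_summaries.groupby("group", sort=True):
        r = sub["tpm_ratio"].dropna()
        tot_rows.append(
            {"group": group, "mu": float(r.mean()), "sigma": float(r.std(ddof=1)),
             "n": int(len(r))}
        )
    return ReferenceSet(homologue=homologue, total=pd.DataFrame(tot_rows))


@dataclass
class AneuploidReference:
    """Reference ranges for duplicated and lost homologues.

    ``trisomic_mu/sigma``: distribution of the duplicated homologue's yield
    (both copies transcribing).  ``source`` is "events" when fitted from bona
    fide family-supported trisomies, "disomic-total" for the fallback.
    ``nullisomic_bound`` is the residual-yield ceiling below which a
    haplotype is called transcriptionally absent; ``nullisomic_residuals``
    records the observed residuals of bona fide lost homologues.
    """

    trisomic_mu: float
    trisomic_sigma: float
    source: str
    nullisomic_bound: float = NULLISOMIC_BOUND
    provenance: list[str] = field(default_factory=list)
    nullisomic_residuals: list[float] = field(default_factory=list)


def build_aneuploid_reference(
    candidates: pd.DataFrame | None,
    refset: ReferenceSet,
    ratio_tol: float = 0.2,
    frac_tol: float = 0.1,
    nullisomic_bound: float = NULLISOMIC_BOUND,
) -> AneuploidReference:
    """Screen candidate aneuploidies and fit the duplicated-homologue range.

    ``candidates`` rows: family_id, cell_id, group, haplotype, kind
    ('trisomy'|'monosomy'), tpm_ratio, frac_hap (fraction of the affected
    haplotype), yield_hap, sibling_support (bool).  A trisomy qualifies when
    |tpm_ratio - 1.5| <= ratio_tol, |frac_hap - 2/3| <= frac_tol and it has
    sibling support; the monosomy mirror requires ratio ~0.5 and a residual
    fraction ~0 of the lost haplotype.  With no qualifying trisomy, the
    duplicated-homologue reference falls back to the control disomic-total
    distribution (with a warning).
    """
    accepted_tri: pd.DataFrame | None = None
    residuals: list[float] = []
    provenance: list[str] = []
    if candidates is not None and len(candidates):
        tri = candidates[candidates["kind"] == "trisomy"]
        ok = (
            ((tri["tpm_ratio"] - 1.5).abs() <= ratio_tol)
            & ((tri["frac_hap"] - 2.0 / 3.0).abs() <= frac_tol)
            & tri["sibling_support"].astype(bool)
        )
        accepted_tri = tri[ok]
        mono = candidates[candidates["kind"] == "monosomy"]
        ok_m = (
            ((mono["tpm_ratio"] - 0.5).abs() <= ratio_tol)
            & (mono["frac_hap"] <= frac_tol)
            & mono["sibling_support"].astype(bool)
        )
        residuals = [float(v) for v in mono.loc[ok_m, "yield_hap"]]
        provenance = [
            f"{r.family_id}:{r.cell_id}:{r.group}{r.haplotype}:{r.kind}"
            for r in candidates[ok.reindex(candidates.index, fill_value=False)
                                | ok_m.reindex(candidates.index, fill_value=False)].itertuples()
        ]

    if accepted_tri is not None and len(accepted_tri) >= 2:
        mu = float(accepted_tri["yield_hap"].mean())
        sigma = float(accepted_tri["yield_hap"].std(ddof=1))
        source = "events"
        if not sigma > 0:
            accepted_tri = None  # degenerate; fall through to strategy 1
    if accepted_tri is None or len(accepted_tri) < 2:
        warnings.warn(
            "no (or too few) bona fide trisomies; duplicated-homologue "
            "reference falls back to the control disomic-total distribution",
            stacklevel=2,
        )
        mu = float(refset.total["mu"].mean())
        sigma = float(refset.total["sigma"].mean())
        source = "disomic-total"
    return AneuploidReference(
        trisomic_mu=mu,
        trisomic_sigma=sigma,
        source=source,
        nullisomic_bound=nullisomic_bound,
        provenance=provenance,
        nullisomic_residuals=residuals,
    )


def collect_aneuploidy_candidates(
    family_states: pd.DataFrame,
    summaries: pd.DataFrame,
) -> pd.DataFrame:
    """Harvest trisomy/monosomy candidates with family context.

    ``family_states`` carries (family_id, cell_id, group, haplotype, label);
    ``summaries`` the wide quantification output for the same cells.  A "2"
    label is a trisomy candidate; sibling support means another cell in the
    family shares the "2" on the same homologue or shows "0" there (reciprocal
    loss).  A "0" label is the monosomy mirror (supported by a sibling "2" or
    shared "0").
    """
    wide = summaries.set_index(["cell_id", "group"])
    rows = []
    for (fam, group, hap), sub in family_states.groupby(
        ["family_id", "group", "haplotype"], sort=False
    ):
        labels = sub.set_index("cell_id")["label"]
        for cell_id, label in labels.items():
            if label not in ("2", "0"):
                continue
            others = labels.drop(cell_id)
            if label == "2":
                support = bool(((others == "2") | (others == "0")).any())
                kind = "trisomy"
            else:
                support = bool(((others == "2") | (others == "0")).any())
                kind = "monosomy"
            srow = wide.loc[(cell_id, group)]
            frac_a = float(srow["frac_A"])
            frac_hap = frac_a if hap == "A" else 1.0 - frac_a
            yield_hap = float(srow["yield_A"] if hap == "A" else srow["yield_B"])
            rows.append(
                {
                    "family_id": fam,
                    "cell_id": cell_id,
                    "group": group,
                    "haplotype": hap,
                    "kind": kind,
                    "tpm_ratio": float(srow["tpm_ratio"]),
                    "frac_hap": frac_hap,
                    "yield_hap": yield_hap,
                    "sibling_support": support,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "family_id", "cell_id", "group", "haplotype", "kind",
            "tpm_ratio", "frac_hap", "yield_hap", "sibling_support",
        ],
    )
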