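"""Micronucleus chromosome identification and yield estimation from families.

The key identifiability principle: the micronucleated (MN) chromatid's own
transcription is never assumed.  A candidate (chromosome, haplotype, pattern)
is scored against the *other* family members, whose nuclei are normal and
whose transcription therefore tracks DNA dosage:

* 1:3 mis-segregation -> the MN sister (generation 1) or both MN nieces
  (generation 2) are monosomic for the MN haplotype and show near-complete
  transcriptional loss ("0"), the most definitive signal (weighted x2);
* 2:2 segregation -> the sister/nieces are disomic and normal, and evidence
  comes from reduced or absent MN-haplotype output in the MN cell itself
  (generation 1) or in the MN daughters (generation 2) - the slots the
  prediction leaves free, so a fully transcribing MN chromatid legitimately
  renders the event invisible ("invisible-normal").

Every candidate is scored by its satisfied role constraints; observed labels
outside a candidate's expected set and flags a candidate leaves unexplained
are penalized.  Exact ties between distinct chromosomes are surfaced as
"unresolved", never broken silently.  A 1:3 family whose MN chromatid
transcribes fully is transcriptionally indistinguishable from a
micronucleus-independent reciprocal loss/gain between the siblings; since
families are ascertained on an observed micronucleus, the MN reading is
reported and the reciprocal explanation recorded as a competing note.
Reciprocal events on other chromosomes are recorded separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Family,
    HAPLOTYPES,
    ROLE_MN_CELL,
    ROLE_MN_DAUGHTER,
    ROLE_MN_NIECE,
    ROLE_MN_SISTER,
    other_haplotype,
)
from .reference import ReferenceSet
from .stats import z_test_two_tailed

ALL_LABELS = frozenset({"0", "1-", "1", "1+", "2"})
NORMAL = frozenset({"1"})

#: evidence-strength bounds (units: scenario-score points)
S_MAX = 2.0   # definitive: near-complete loss "0", or vanishing p
S_MIN = 0.5   # a flag just past the rejection boundary
#: minimum total score for an assignment to be accepted
SCORE_FLOOR = 1.0


def _strength(label: str, p_mono: float) -> float:
    """Evidence weight of one flagged homologue.

    Near-complete transcriptional loss ("0") is the definitive signal and
    carries the maximal weight; other aberrant labels are graded by how far
    their corrected p falls below the rejection boundary, so a marginal flag
    (barely significant, as produced by reference-estimation noise) neither
    anchors nor vetoes a scenario on its own.
    """
    if label == "1":
        return 0.0
    if label == "0" or p_mono is None or not np.isfinite(p_mono):
        return S_MAX
    return float(min(S_MAX, max(S_MIN, -np.log10(max(p_mono, 1e-300)) / 4.0)))


def _expected_sets(pattern: str, generation: int) -> dict[str, tuple[frozenset, frozenset]]:
    """Per-role (expected set on the MN homologue, on the other homologue)."""
    up = frozenset({"1", "1+", "2"})      # one normal copy plus unconstrained extra
    down = frozenset({"0", "1-", "1"})    # single chromatid of unconstrained yield
    if generation == 1:
        if pattern == "1:3":
            return {ROLE_MN_CELL: (up, NORMAL), ROLE_MN_SISTER: (frozenset({"0"}), NORMAL)}
        return {ROLE_MN_CELL: (down, NORMAL), ROLE_MN_SISTER: (NORMAL, NORMAL)}
    if pattern == "1:3":
        return {
            ROLE_MN_DAUGHTER: (up, NORMAL),
            ROLE_MN_NIECE: (frozenset({"0"}), NORMAL),
        }
    return {ROLE_MN_DAUGHTER: (down, NORMAL), ROLE_MN_NIECE: (NORMAL, NORMAL)}


@dataclass
class ScenarioScore:
    chrom: str
    haplotype: str
    pattern: str
    score: float
    n_informative: int
    n_silent_matches: int
    n_violations: int


@dataclass
class MNAssignment:
    """Inferred MN chromosome for one family."""

    chrom: str | None
    haplotype: str | None
    pattern: str | None
    confidence: str  # direct | inferred-without-nieces | invisible-normal | unresolved
    notes: str = ""
    competing: list[tuple[str, str, str]] = field(default_factory=list)
    independent_events: list[str] = field(default_factory=list)


@dataclass
class MNYieldEstimate:
    """Estimated transcriptional yield a of the MN chromatid."""

    a: float | None
    basis: str  # direct-2:2 | vs-disomic-3:1 | combined-daughters | per-daughter-vs-mono-and-di | consistent-with-normal
    classification: str  # normal | reduced | near-silent
    details: dict = field(default_factory=dict)


def _state_lookup(states: pd.DataFrame) -> dict[tuple[str, str, str], tuple[str, float]]:
    has_p = "p_mono" in states.columns
    return {
        (r.cell_id, r.group, r.haplotype): (
            r.label, float(r.p_mono) if has_p else float("nan")
        )
        for r in states.itertuples()
    }


def enumerate_scenarios(
    family: Family,
    states: pd.DataFrame,
    downweighted_groups: tuple[str, ...] = (),
    downweight: float = 0.5,
) -> pd.DataFrame:
    """Score every (chromosome, haplotype, pattern) candidate for a family.

    ``states`` is the concatenated classification table of the family's
    cells.  ``downweighted_groups`` lists chromosomes with known excess
    transcriptional variability (acrocentric analogues); evidence from them
    is multiplied by ``downweight``.
    """
    if len(family.cells) < 2:
        raise ValueError("family with < 2 cells cannot constrain a scenario")
    lut = _state_lookup(states)
    groups = sorted(states["group"].unique())
    cells = [(c.cell_id, c.role) for c in family.cells]

    rows = []
    for pattern in ("1:3", "2:2"):
        templates = _expected_sets(pattern, family.generation)
        for chrom in groups:
            for hap in HAPLOTYPES:
                score = 0.0
                n_inf = n_sil = n_vio = 0
                w_chrom = downweight if chrom in downweighted_groups else 1.0
                for cell_id, role in cells:
                    exp_mn, exp_other = templates.get(role, (NORMAL, NORMAL))
                    for g in groups:
                        for h in HAPLOTYPES:
                            entry = lut.get((cell_id, g, h))
                            if entry is None:
                                continue
                            obs, p_mono = entry
                            if g == chrom and h == hap:
                                expected = exp_mn
                            elif g == chrom and h == other_haplotype(hap):
                                expected = exp_other
                            else:
                                expected = NORMAL
                            w = downweight if g in downweighted_groups else 1.0
                            s = _strength(obs, p_mono)
                            if obs in expected:
                                if g == chrom and obs != "1" and expected != NORMAL:
                                    score += s * w_chrom
                                    n_inf += 1
                                    n_sil += int(obs == "0")
                            elif obs == "1":
                                # expected a specific aberration (e.g. sister
                                # silence) but the homologue looks normal
                                score -= 1.0 * w
                                n_vio += 1
                            else:
                                score -= s * w
                                n_vio += 1
                rows.append(
                    {
                        "chrom": chrom,
                        "haplotype": hap,
                        "pattern": pattern,
                        "score": score,
                        "n_informative": n_inf + n_sil,
                        "n_silent_matches": n_sil,
                        "n_violations": n_vio,
                    }
                )
    out = pd.DataFrame(rows).sort_values(
        ["score", "n_informative"], ascending=False, kind="mergesort"
    )
    return out.reset_index(drop=True)


def _reciprocal_events(family: Family, states: pd.DataFrame) -> list[str]:
    """(chrom, hap) showing reciprocal loss+gain between sibling cells."""
    events = []
    for (g, h), sub in states.groupby(["group", "haplotype"], sort=True):
        labels = set(sub["label"])
        if "0" in labels and "2" in labels:
            events.append(f"{g}:{h}:reciprocal-loss-gain")
    return events


def infer_mn_chromosome(
    family: Family,
    states: pd.DataFrame,
    downweighted_groups: tuple[str, ...] = (),
) -> MNAssignment:
    """Pick the best-supported scenario, surfacing ties and invisible events."""
    scored = enumerate_scenarios(
        family, states, downweighted_groups=downweighted_groups
    )
    any_flag = bool(states["flagged"].any())
    confidence_base = (
        "inferred-without-nieces"
        if family.generation == 2 and not family.has_nieces
        else "direct"
    )

    if not any_flag:
        return MNAssignment(
            chrom=None,
            haplotype=None,
            pattern="2:2",
            confidence="invisible-normal",
            notes=(
                "no homologue deviates from normal transcription; consistent "
                "with a 2:2-segregated MN chromosome with normal output"
            ),
        )

    best = scored.iloc[0]
    top = scored[np.isclose(scored["score"], best["score"])]
    top_loci = {(r.chrom, r.haplotype) for r in top.itertuples()}
    if len(top_loci) > 1 and best["n_informative"] > 0:
        ties = [(r.chrom, r.haplotype, r.pattern) for r in top.itertuples()]
        return MNAssignment(
            chrom=None, haplotype=None, pattern=None, confidence="unresolved",
            notes="multiple chromosomes tie for the best-supported scenario",
            competing=ties,
        )
    if best["score"] < SCORE_FLOOR or best["n_informative"] == 0:
        return MNAssignment(
            chrom=None, haplotype=None, pattern=None, confidence="unresolved",
            notes="flags present but no scenario positively supported",
        )
    # unique locus; same-locus pattern ties resolved by informative evidence
    assignment = MNAssignment(
        chrom=str(best["chrom"]),
        haplotype=str(best["haplotype"]),
        pattern=str(best["pattern"]),
        confidence=confidence_base,
    )
    recips = _reciprocal_events(family, states)
    locus_tag = f"{assignment.chrom}:{assignment.haplotype}:reciprocal-loss-gain"
    if locus_tag in recips:
        assignment.notes = (
            "a micronucleus-independent reciprocal loss/gain between siblings "
            "is equally consistent; MN reading preferred because the family "
            "was ascertained on an observed micronucleus"
        )
        assignment.competing.append(
            (assignment.chrom, assignment.haplotype, "reciprocal")
        )
    assignment.independent_events = [e for e in recips if e != locus_tag]
    # degenerate a ~ 0 without nieces: both daughters silent for the haplotype
    if (
        family.generation == 2
        and not family.has_nieces
        and assignment.pattern == "2:2"
    ):
        d_labels = states[
            (states["group"] == assignment.chrom)
            & (states["haplotype"] == assignment.haplotype)
        ]["label"]
        if (d_labels == "0").all():
            assignment.notes = (
                assignment.notes + " " if assignment.notes else ""
            ) + (
                "both daughters lack output from the MN haplotype: the extra "
                "MN chromatid, whichever daughter holds it, is silenced"
            )
    return assignment


def _classify_yield(
    a: float,
    mu: float,
    sigma: float,
    alpha: float = 0.05,
    nullisomic_bound: float = 0.1,
) -> str:
    if a < nullisomic_bound:
        return "near-silent"
    p = z_test_two_tailed(a, mu, sigma)
    return "normal" if p >= alpha else "reduced"


def estimate_mn_yield(
    family: Family,
    assignment: MNAssignment,
    summaries: pd.DataFrame,
    refset: ReferenceSet,
    alpha: float = 0.05,
) -> MNYieldEstimate:
    """Estimate the MN chromatid's transcriptional yield per its scenario.

    Bases: generation-1 2:2 reads the MN haplotype's yield in the MN cell
    directly; generation-1 1:3 reports the excess of the MN haplotype over
    the one-copy reference mean (PN sister chromatid); generation-2 2:2 sums
    the MN haplotype over both daughters (fragments may be split);
    generation-2 1:3 sums each daughter's excess over the one-copy reference.
    Classification reuses the z-test machinery against the matching
    reference.
    """
    if assignment.confidence == "unresolved":
        raise ValueError("cannot estimate a yield for an unresolved assignment")
    if assignment.confidence == "invisible-normal":
        return MNYieldEstimate(
            a=None, basis="consistent-with-normal", classification="normal",
            details={"note": "no deviation observed; no point estimate"},
        )
    chrom, hap = assignment.chrom, assignment.haplotype
    mu1, s1 = refset.lookup(chrom, hap)

    def yield_of(cell_id: str) -> float:
        row = summaries[
            (summaries["cell_id"] == cell_id) & (summaries["group"] == chrom)
        ].iloc[0]
        return float(row["yield_A"] if hap == "A" else row["yield_B"])

    nb = refset.nullisomic_bound
    if family.generation == 1:
        mn = family.cells_by_role(ROLE_MN_CELL)[0]
        y = yield_of(mn.cell_id)
        if assignment.pattern == "2:2":
            a = max(0.0, y)
            cls = _classify_yield(a, mu1, s1, alpha, nb)
            return MNYieldEstimate(a=a, basis="direct-2:2", classification=cls,
                                   details={"yield_mn_hap": y})
        # 1:3 - MN haplotype combines the PN chromatid (one normal copy) and
        # the MN chromatid; compare against disomic-level transcription
        mu_t, s_t = refset.lookup_total(chrom)
        a = max(0.0, y - mu1)
        if a < nb:
            cls = "near-silent"
        else:
            cls = "normal" if z_test_two_tailed(y, mu_t, s_t) >= alpha else "reduced"
        return MNYieldEstimate(a=a, basis="vs-disomic-3:1", classification=cls,
                               details={"yield_mn_hap": y})

    daughters = family.cells_by_role(ROLE_MN_DAUGHTER)
    ys = [yield_of(d.cell_id) for d in daughters]
    if assignment.pattern == "2:2":
        a = max(0.0, float(sum(ys)))
        s_comb = s1 * np.sqrt(len(ys))
        cls = _classify_yield(a, mu1, s_comb, alpha, nb)
        return MNYieldEstimate(
            a=a, basis="combined-daughters", classification=cls,
            details={"daughter_yields": ys},
        )
    # generation-2 1:3 - each daughter holds one intact copy plus a share of
    # the MN chromatid; per-daughter yields are compared to the one-copy and
    # the duplicated (disomic-level) ranges
    mu_t, s_t = refset.lookup_total(chrom)
    shares = [y - mu1 for y in ys]
    a = max(0.0, float(sum(shares)))
    per = []
    for y in ys:
        if z_test_two_tailed(y, mu1, s1) >= alpha:
            per.append("one-copy")        # share of MN chromatid ~ absent
        elif z_test_two_tailed(y, mu_t, s_t) >= alpha:
            per.append("two-copy")        # share fully transcribing
        else:
            per.append("intermediate")
    if a < nb:
        cls = "near-silent"
    elif all(p in ("one-copy", "two-copy") for p in per) and "two-copy" in per:
        cls = "normal" if abs(a - 0.5) <= 3 * s1 * np.sqrt(2) else "reduced"
    else:
        cls = "reduced"
    return MNYieldEstimate(
        a=a, basis="per-daughter-vs-mono-and-di", classification=cls,
        details={"daughter_yields": ys, "per_daughter": per},
    )


def analyze_family(
    family: Family,
    states: pd.DataFrame,
    summaries: pd.DataFrame,
    refset: ReferenceSet,
    alpha: float = 0.05,
    downweighted_groups: tuple[str, ...] = (),
) -> tuple[MNAssignment, MNYieldEstimate | None]:
    """Convenience wrapper: infer the MN chromosome then estimate its yield."""
    assignment = infer_mn_chromosome(
        family, states, downweighted_groups=downweighted_groups
    )
    if assignment.confidence == "unresolved":
        return assignment, None
    est = estimate_mn_yield(family, assignment, summaries, refset, alpha=alpha)
    return assignment, est
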