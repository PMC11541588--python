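"""Parent-of-origin assignment for de novo SNVs by fragment voting.

A DNM is phased by read fragments that carry its alternate allele together
with the allele of a nearby phase-informative inherited heterozygous site —
a site where the child is heterozygous and each child allele can only have
come from one parent.  Fragments vote for the parent whose transmitted
allele they carry; a verdict requires at least ``min_support`` concordant
votes and zero votes for the other parent.  Single-link voting only; no
multi-site haplotype assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "InformativeSite",
    "PhaseCall",
    "find_informative_sites",
    "phase_dnm",
    "phase_cohort",
    "summarize_phasing",
]

_AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


@dataclass(frozen=True)
class InformativeSite:
    """A phase-informative inherited het site near a DNM."""

    pos: int
    allele_of_father: str
    allele_of_mother: str
    distance: int


@dataclass
class PhaseCall:
    dnm_key: str
    verdict: str  # paternal | maternal | unknown | conflict
    paternal_support: int
    maternal_support: int
    n_ignored_fragments: int = 0


def _gt_alleles(gt: str) -> tuple[str, str]:
    sep = "/" if "/" in gt else "|"
    a, _, b = gt.partition(sep)
    return a, b


def find_informative_sites(
    dnm_pos: int,
    trio_genotypes: pd.DataFrame,
    window: int = 500,
) -> list[InformativeSite]:
    """Sites within ``window`` bp of the DNM where transmission is unambiguous.

    ``trio_genotypes`` needs columns site_pos / child_gt / father_gt /
    mother_gt.  A site qualifies when the child is heterozygous and exactly
    one assignment of its two alleles to the parents is consistent with the
    parental genotypes (e.g. child A/G, father A/A, mother G/G).  An empty
    list is a valid result.
    """
    out: list[InformativeSite] = []
    for r in trio_genotypes.itertuples(index=False):
        dist = abs(int(r.site_pos) - int(dnm_pos))
        if dist > window or dist == 0:
            continue
        c1, c2 = _gt_alleles(r.child_gt)
        if c1 == c2:
            continue
        fa = set(_gt_alleles(r.father_gt))
        mo = set(_gt_alleles(r.mother_gt))
        # which child allele could each parent have transmitted?
        assignments = []
        for pat, mat in ((c1, c2), (c2, c1)):
            if pat in fa and mat in mo:
                assignments.append((pat, mat))
        if len(assignments) == 1:
            pat, mat = assignments[0]
            out.append(
                InformativeSite(
                    pos=int(r.site_pos), allele_of_father=pat, allele_of_mother=mat, distance=dist
                )
            )
    return out


def phase_dnm(
    dnm_key: str,
    dnm_alt: str,
    fragments: pd.DataFrame,
    sites: list[InformativeSite],
    min_support: int = 1,
) -> PhaseCall:
    """Vote fragments carrying the DNM alt allele into a parent-of-origin verdict.

    ``fragments`` rows carry (dnm_allele, site_pos, site_allele).  Fragments
    whose site is not in ``sites`` are ignored (counted).  Verdict is
    paternal/maternal iff one parent gets >= min_support votes and the other
    zero; conflict if both parents receive votes; unknown otherwise.  The
    verdict is invariant to fragment order.
    """
    by_pos = {s.pos: s for s in sites}
    pat = mat = ignored = 0
    for r in fragments.itertuples(index=False):
        if r.dnm_allele != dnm_alt:
            continue  # reference-carrying fragment: no vote
        site = by_pos.get(int(r.site_pos))
        if site is None:
            ignored += 1
            continue
        if r.site_allele == site.allele_of_father:
            pat += 1
        elif r.site_allele == site.allele_of_mother:
            mat += 1
        else:
            ignored += 1
    if pat > 0 and mat > 0:
        verdict = "conflict"
    elif pat >= min_support and mat == 0:
        verdict = "paternal"
    elif mat >= min_support and pat == 0:
        verdict = "maternal"
    else:
        verdict = "unknown"
    return PhaseCall(dnm_key, verdict, pat, mat, ignored)


def phase_cohort(
    dnms: pd.DataFrame,
    sites: pd.DataFrame,
    fragments: pd.DataFrame,
    min_support: int = 1,
    window: int = 500,
) -> pd.DataFrame:
    """Phase every DNM in a cohort table against simulated or parsed fragments.

    ``sites`` carries per-DNM trio genotypes (dnm_key, site_pos, child_gt,
    father_gt, mother_gt); ``fragments`` the per-fragment allele observations
    keyed by dnm_key.  Returns one row per DNM with the verdict and support.
    """
    frag_by_key = dict(tuple(fragments.groupby("dnm_key"))) if len(fragments) else {}
    site_by_key = dict(tuple(sites.groupby("dnm_key"))) if len(sites) else {}
    rows = []
    for r in dnms.itertuples(index=False):
        key = f"{r.child_id}:{r.chrom}:{r.pos}:{r.alt}"
        s_df = site_by_key.get(key)
        info = (
            find_informative_sites(int(r.pos), s_df, window=window) if s_df is not None else []
        )
        f_df = frag_by_key.get(key)
        if f_df is None or not info:
            call = PhaseCall(key, "unknown", 0, 0)
        else:
            call = phase_dnm(key, r.alt, f_df, info, min_support=min_support)
        rows.append(
            {
                "dnm_key": key,
                "family_id": r.family_id,
                "child_id": r.child_id,
                "chrom": r.chrom,
                "verdict": call.verdict,
                "paternal_support": call.paternal_support,
                "maternal_support": call.maternal_support,
            }
        )
    return pd.DataFrame(rows)


def summarize_phasing(
    calls: pd.DataFrame,
    pedigrees: pd.DataFrame,
    autosomes_only: bool = True,
) -> dict:
    """Per-family phased/paternal proportions and the pooled paternal:maternal ratio.

    Families with zero phased calls are excluded from the mean-of-family
    proportions (flagged in the per-family table).  The pooled ratio is total
    paternal / total maternal across the cohort, reported alongside the mean
    of per-family proportions (they differ unless families are balanced).
    """
    df = calls.copy()
    if autosomes_only and "chrom" in df.columns:
        df = df[df["chrom"].isin(_AUTOSOMES) | df["chrom"].isna()]
    df["phased"] = df["verdict"].isin(["paternal", "maternal"])

    fam_rows = []
    for fam in sorted(pedigrees["family_id"].unique()):
        sub = df[df["family_id"] == fam]
        n = len(sub)
        n_phased = int(sub["phased"].sum())
        n_pat = int((sub["verdict"] == "paternal").sum())
        fam_rows.append(
            {
                "family_id": fam,
                "n_dnms": n,
                "n_phased": n_phased,
                "phased_fraction": n_phased / n if n else float("nan"),
                "paternal_fraction": n_pat / n_phased if n_phased else float("nan"),
                "has_phased": n_phased > 0,
            }
        )
    per_family = pd.DataFrame(fam_rows)

    n_pat = int((df["verdict"] == "paternal").sum())
    n_mat = int((df["verdict"] == "maternal").sum())
    with_phased = per_family[per_family["has_phased"]]
    return {
        "per_family": per_family,
        "n_paternal": n_pat,
        "n_maternal": n_mat,
        "pooled_paternal_fraction": n_pat / (n_pat + n_mat) if (n_pat + n_mat) else float("nan"),
        "paternal_maternal_ratio": n_pat / n_mat if n_mat else float("inf"),
        "mean_family_phased_fraction": float(with_phased["phased_fraction"].mean())
        if len(with_phased)
        else float("nan"),
        "mean_family_paternal_fraction": float(with_phased["paternal_fraction"].mean())
        if len(with_phased)
        else float("nan"),
        "n_families_excluded": int((~per_family["has_phased"]).sum()),
    }
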