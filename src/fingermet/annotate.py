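"""Feature annotation by adduct-mass matching and pathway enrichment.

Panel m/z values are matched against a metabolite reference through the
three cation-adduct rules at a ppm tolerance (default 5 ppm, the
accuracy window of high-resolution confirmatory MS); over-representation
of pathways in the annotated panel is scored with the one-sided
hypergeometric tail and Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .adducts import DEFAULT_RULES, AdductRule, adduct_mz
from .refdata import DEFAULT_PATHWAYS, MetaboliteRecord, reference_metabolites

__all__ = ["Annotation", "match_features", "enrich_pathways",
           "MetaboliteRecord", "reference_metabolites"]


@dataclass(frozen=True)
class Annotation:
    feature_mz: float
    metabolite: str
    adduct: str
    theoretical_mz: float
    ppm_error: float


def match_features(feature_mz: list[float] | np.ndarray,
                   db: list[MetaboliteRecord] | None = None,
                   rules: dict[str, AdductRule] | None = None,
                   ppm_tol: float = 5.0) -> dict[float, list[Annotation]]:
    """Candidate (metabolite, adduct) annotations for each feature m/z.

    A candidate is reported when |observed − theoretical| / theoretical
    ≤ ppm_tol parts per million; candidates are ranked by absolute ppm
    error.  Features without a match map to an empty list.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    db = db if db is not None else reference_metabolites()
    rules = rules if rules is not None else DEFAULT_RULES
    theo = [(rec, rname, adduct_mz(rec.monoisotopic_mass, rule))
            for rec in db for rname, rule in rules.items()]
    out: dict[float, list[Annotation]] = {}
    for fmz in np.asarray(feature_mz, float):
        cands = []
        for rec, rname, tmz in theo:
            ppm = (fmz - tmz) / tmz * 1e6
            if abs(ppm) <= ppm_tol:
                cands.append(Annotation(float(fmz), rec.name, rname, tmz, float(ppm)))
        cands.sort(key=lambda a: abs(a.ppm_error))
        out[float(fmz)] = cands
    return out


def annotations_table(matches: dict[float, list[Annotation]]) -> pd.DataFrame:
    rows = [{"feature_mz": a.feature_mz, "metabolite": a.metabolite,
             "adduct": a.adduct, "theoretical_mz": a.theoretical_mz,
             "ppm_error": a.ppm_error}
            for cands in matches.values() for a in cands]
    return pd.DataFrame(rows, columns=["feature_mz", "metabolite", "adduct",
                                       "theoretical_mz", "ppm_error"])


def enrich_pathways(panel_metabolites: list[str],
                    pathway_db: dict[str, tuple[str, ...]] | None = None,
                    background: int | None = None) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per pathway.

    For a pathway of size K in a background universe of N metabolites,
    with a panel of n metabolites overlapping the pathway in k, the p
    value is P[X ≥ k] for X ~ Hypergeom(N, K, n); q is the BH adjustment
    across pathways.  An empty panel yields an empty table.
    """
    pathway_db = pathway_db if pathway_db is not None else DEFAULT_PATHWAYS
    panel = sorted(set(panel_metabolites))
    if not panel:
        return pd.DataFrame(columns=["pathway", "overlap", "pathway_size",
                                     "panel_size", "background", "p", "q"])
    universe = set().union(*map(set, pathway_db.values())) | set(panel)
    n_bg = background if background is not None else len(universe)
    if n_bg < len(panel):
        raise ValueError("background universe smaller than the panel")
    rows = []
    n = len(panel)
    for name, members in pathway_db.items():
        members = set(members)
        if len(members) > n_bg:
            raise ValueError(f"pathway {name!r} larger than the background universe")
        k = len(members & set(panel))
        # P[X >= k] = survival function at k-1
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(members), n))
        rows.append({"pathway": name, "overlap": k, "pathway_size": len(members),
                     "panel_size": n, "background": n_bg, "p": min(p, 1.0)})
    df = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    df["q"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    return df
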