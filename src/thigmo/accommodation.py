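"""Decision-tree classification of early mechanoresponsive genes by their
response to a second bending.

A gene differentially expressed 0.5 h after a single bending may, upon a
second bending applied 24 h later, show no significant response at all
(fully accommodated), a significant but reduced response (accommodated with
reduced amplitude), an indistinguishable response (non-accommodated), or —
for genes silent after a single bending — a response appearing only after
the second stimulus (newly regulated). The tree operates purely on the
ternary significance statuses of four comparisons plus the two log2 ratios:

* C0.5 — response 0.5 h after one bending (ratio ``r_1b``);
* C24 — residual response 24 h after one bending (shifted-baseline flag);
* 2Bvs1B24 — second-bending response vs. its immediate baseline (``r_2b``);
* 2Bvs1B0.5 — amplitude of the second response vs. the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CATEGORIES = (
    "accommodated_null",
    "accommodated_reduced",
    "non_accommodated",
    "newly_regulated",
    "amplified",
    "unclassified",
    "not_applicable",
)

REQUIRED_COMPARISONS = ("C0.5", "C24", "2Bvs1B24", "2Bvs1B0.5")


class InputError(ValueError):
    pass


@dataclass
class AccommodationCall:
    gene_id: str
    r_1b: float
    r_2b: float
    de_first_05h: bool
    de_first_24h: bool
    de_second: bool
    amplitude_changed: bool
    category: str


def classify_gene(gene_id: str, statuses: dict, r_1b: float,
                  r_2b: float) -> AccommodationCall:
    """Classify one gene through the accommodation decision tree.

    ``statuses`` maps the four required comparison ids to ternary statuses.
    Magnitude rule: when both the second response and the amplitude change
    are significant, |r_2b| < |r_1b| means reduced, |r_2b| > |r_1b| means
    amplified, exact equality stays non_accommodated, and a sign flip
    between two significant responses is unclassified.
    """
    missing = [c for c in REQUIRED_COMPARISONS if c not in statuses]
    if missing:
        raise InputError(f"missing comparison status(es): {missing}")
    de_05 = statuses["C0.5"] != 0
    de_24 = statuses["C24"] != 0
    de_2nd = statuses["2Bvs1B24"] != 0
    amp = statuses["2Bvs1B0.5"] != 0

    if not de_05:
        category = "newly_regulated" if de_2nd else "not_applicable"
    elif not de_2nd:
        category = "accommodated_null"
    elif not amp:
        category = "non_accommodated"
    elif r_1b * r_2b < 0:
        category = "unclassified"
    elif abs(abs(r_2b) - abs(r_1b)) <= 1e-9 * max(1.0, abs(r_1b)):
        category = "non_accommodated"  # amplitudes numerically equal
    elif abs(r_2b) < abs(r_1b):
        category = "accommodated_reduced"
    else:
        category = "amplified"
    return AccommodationCall(gene_id, float(r_1b), float(r_2b),
                             de_05, de_24, de_2nd, amp, category)


def classify_all(cset) -> pd.DataFrame:
    """Run the tree over a gene-level ComparisonSet.

    Genes filtered out of a comparison count as non-significant there with
    ratio 0. Output columns mirror the published table layout: gene, the two
    fold-changes (first bending vs. control; second bending vs. 24 h after
    the first), the four statuses and the category. ``shifted_baseline``
    flags genes still differentially expressed 24 h after the first bending,
    whose second-bending ratio rides on a non-basal reference level.
    """
    missing = [c for c in REQUIRED_COMPARISONS if c not in cset.results]
    if missing:
        raise InputError(f"comparison(s) not run: {missing}")
    key = "gene_id" if "gene_id" in cset.results["C0.5"].columns else "probeset_id"
    tables = {c: cset.results[c].set_index(key) for c in REQUIRED_COMPARISONS}
    genes = sorted(set().union(*(t.index for t in tables.values())))
    rows = []
    for g in genes:
        statuses, ratios = {}, {}
        for c, tbl in tables.items():
            statuses[c] = int(tbl.at[g, "status"]) if g in tbl.index else 0
            ratios[c] = float(tbl.at[g, "log2fc"]) if g in tbl.index else 0.0
        call = classify_gene(g, statuses, ratios["C0.5"], ratios["2Bvs1B24"])
        rows.append({
            "gene_id": g, "r_1b": call.r_1b, "r_2b": call.r_2b,
            "status_C0.5": statuses["C0.5"], "status_C24": statuses["C24"],
            "status_2Bvs1B24": statuses["2Bvs1B24"],
            "status_2Bvs1B0.5": statuses["2Bvs1B0.5"],
            "shifted_baseline": call.de_first_24h,
            "category": call.category,
        })
    return pd.DataFrame(rows)


def attenuated_percent(n_null: int, n_reduced: int, n_first_deg: int):
    """Percent of first-bending DEG whose second response is attenuated
    (absent or reduced), rounded to the nearest integer; NA when no gene
    responded to the first bending."""
    if n_first_deg == 0:
        return None
    return round(100.0 * (n_null + n_reduced) / n_first_deg)


def summarize_accommodation(calls: pd.DataFrame) -> dict:
    """Category counts plus the attenuated-percent headline number."""
    counts = {c: int((calls["category"] == c).sum()) for c in CATEGORIES}
    n_first = int((calls["status_C0.5"] != 0).sum()) if "status_C0.5" in calls \
        else sum(counts[c] for c in CATEGORIES
                 if c not in ("newly_regulated", "not_applicable"))
    return {
        "counts": counts,
        "n_first_bending_deg": n_first,
        "attenuated_percent": attenuated_percent(
            counts["accommodated_null"], counts["accommodated_reduced"], n_first),
    }
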