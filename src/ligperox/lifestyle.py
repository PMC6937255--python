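"""CcP co-occurrence rule and trophism-vs-CII-presence association.

Across fungal genomes, cytochrome c peroxidase (CcP, class I) copy number
co-varies with class II peroxidase presence: genomes without any CII
sequence tend to carry two CcP copies, genomes with at least one CII carry
a single CcP.  Separately, CII presence tracks trophic life style
(lignin-degrading and necrotrophic/hemibiotrophic fungi carry them,
symbionts/endophytes/biotrophs generally do not).  This module scores a
species table against the rule and tests the life-style association with a
permutation test on the odds ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Controlled trophism vocabulary: saprotroph (wood decay: brown rot, white
#: rot, decay not defined), plant pathogens (necrotrophic, biotrophic,
#: hemibiotrophic, opportunistic), animal pathogens (mammal, entomopathogenic),
#: symbionts (ecto-/ericoid/orchid mycorrhiza, lichen), endophyte.
TROPHISM_CODES = (
    "S", "BR", "WR", "DND", "NPP", "BPP", "HPP", "OP",
    "APM", "APE", "Sy", "ECM", "ERM", "OMF", "Li", "END",
)

CII_CLASSES = ("MnP", "LiP", "VP", "CIIBA", "CIIBB", "CIIBC", "CIIAA", "CIIAB", "CIIAC")

#: Default trophism grouping for the association test; codes not listed on
#: either side must be assigned by the caller's grouping.
DEFAULT_GROUPING = {
    **{c: "lignin" for c in ("NPP", "HPP", "WR")},
    **{c: "other" for c in ("Sy", "ECM", "ERM", "OMF", "Li", "END", "BPP",
                            "S", "BR", "DND", "OP", "APM", "APE")},
}


def total_cii(table: pd.DataFrame) -> pd.Series:
    present = [c for c in CII_CLASSES if c in table.columns]
    return table[present].sum(axis=1)


def ccp_rule_check(table: pd.DataFrame) -> tuple[pd.Series, float]:
    """Flag each species as consistent with the CcP/CII rule.

    Consistent iff (CII == 0 and CcP == 2) or (CII >= 1 and CcP == 1).
    Returns the per-species boolean series and the overall fraction.
    """
    if table.empty:
        raise ValueError("species table is empty")
    cii = table["total_cii"] if "total_cii" in table.columns else total_cii(table)
    count_cols = [c for c in CII_CLASSES if c in table.columns] + ["ccp"]
    if (table[count_cols] < 0).any().any():
        raise ValueError("negative counts in species table")
    consistent = ((cii == 0) & (table["ccp"] == 2)) | ((cii >= 1) & (table["ccp"] == 1))
    return consistent, float(consistent.mean())


def trophism_contingency(
    table: pd.DataFrame,
    grouping: dict[str, str] | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """2x2 association between trophism group and CII presence.

    The statistic is the odds ratio with a Haldane 0.5 correction; the
    p-value is a one-sided label-permutation p, computed through its exact
    hypergeometric equivalent (permuting the binary presence labels makes
    the lignin-and-present cell hypergeometric):
    ``p = (1 + #{perm >= observed}) / (1 + n_permutations)``.
    """
    grouping = DEFAULT_GROUPING if grouping is None else grouping
    codes = set(table["trophism"])
    unmapped = sorted(codes - set(grouping))
    if unmapped:
        raise ValueError(f"trophism codes not covered by grouping: {unmapped}")
    group = table["trophism"].map(grouping)
    cii = table["total_cii"] if "total_cii" in table.columns else total_cii(table)
    present = cii > 0

    n_lig = int((group == "lignin").sum())
    n_oth = int((group == "other").sum())
    if n_lig == 0 or n_oth == 0:
        raise ValueError("a trophism group is empty; association is undefined")

    a = int((present & (group == "lignin")).sum())  # lignin, CII present
    b = n_lig - a
    c = int((present & (group == "other")).sum())
    d = n_oth - c
    observed = _odds_ratio(a, b, c, d)

    rng = np.random.default_rng(seed)
    n_present = a + c
    perm_a = rng.hypergeometric(n_present, len(table) - n_present, n_lig, size=n_permutations)
    perm_or = _odds_ratio(perm_a, n_lig - perm_a, n_present - perm_a,
                          n_oth - (n_present - perm_a))
    p = (1 + int((perm_or >= observed).sum())) / (1 + n_permutations)
    return {
        "table": pd.DataFrame(
            [[a, b], [c, d]],
            index=pd.Index(["lignin", "other"], name="group"),
            columns=["cii_present", "cii_absent"],
        ),
        "odds_ratio": float(observed),
        "p_value": float(p),
        "n_permutations": n_permutations,
    }


def _odds_ratio(a, b, c, d):
    a, b, c, d = (np.asarray(x, float) + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def presence_report(table: pd.DataFrame) -> dict:
    """Per-species presence/absence matrix and per-phylum class totals."""
    df = table.sort_values(["phylum", "order", "species"]).reset_index(drop=True)
    present_cols = [c for c in CII_CLASSES if c in df.columns]
    matrix = (df[present_cols] > 0).astype(int)
    matrix.insert(0, "species", df["species"])
    totals = df[present_cols].sum(axis=1)
    per_phylum = df.groupby("phylum")[present_cols].apply(lambda g: (g > 0).sum())
    return {
        "matrix": matrix,
        "species_totals": pd.Series(totals.values, index=df["species"], name="total_cii"),
        "per_phylum": per_phylum,
        "grand_total": int(df[present_cols].sum().sum()),
    }
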